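"""Isomer generation against the brute-force oracle; problem construction."""

import random

import pytest

import casepy
from casepy.chem_model import MoleculeGraph, canonical_signature, parse_formula
from casepy.constraint_detection import AtomConstraint
from casepy.exceptions import ProblemBuildError
from casepy.peaklist import read_peaklist
from casepy.structure_generation import (
    ElucidationProblem,
    ProblemAtom,
    build_problem,
    embeds,
    generate,
    problem_from_formula,
    verify_solution,
)

from oracles import brute_force_isomers, oracle_solution_set, satisfies


def signatures(result):
    return {canonical_signature(g) for g in result.structures}


@pytest.mark.parametrize("formula,count", [
    ("CH4O", 1),     # methanol only
    ("C2H6O", 2),    # ethanol, dimethyl ether
    ("C3H8O", 3),    # 1-/2-propanol, methyl ethyl ether
    ("C2H7N", 2),    # ethylamine, dimethylamine
    ("C2H4O2", 10),  # acetic acid, methyl formate, glycolaldehyde, enols,
                     # epoxides and peroxides
])
def test_known_isomer_counts(formula, count):
    result = generate(problem_from_formula(parse_formula(formula)))
    assert len(result) == count
    assert signatures(result) == set(brute_force_isomers(formula))


def test_all_outputs_verify_and_validate():
    problem = problem_from_formula(parse_formula("C3H6O"))
    result = generate(problem)
    for graph in result.structures:
        graph.validate()
        assert graph.is_connected()
        assert verify_solution(graph, problem)


def test_mandatory_neighbour_filters_to_ether():
    mf = parse_formula("C2H6O")
    base = problem_from_formula(mf)
    atoms = list(base.atoms)
    for k in (0, 1):  # both carbons must touch oxygen
        atoms[k] = ProblemAtom(element="C", label=atoms[k].label,
                               mandatory=frozenset({"O"}))
    problem = ElucidationProblem(atoms=tuple(atoms), total_h=6)
    result = generate(problem)
    assert signatures(result) == {canonical_signature(MoleculeGraph.from_smiles("COC"))}


def test_forbidden_neighbour_excludes_ethanol():
    mf = parse_formula("C2H6O")
    base = problem_from_formula(mf)
    atoms = list(base.atoms)
    atoms[0] = ProblemAtom(element="C", label="C1", forbidden=frozenset({"O"}))
    atoms[1] = ProblemAtom(element="C", label="C2", forbidden=frozenset({"O"}))
    problem = ElucidationProblem(atoms=tuple(atoms), total_h=6)
    assert generate(problem).structures == []


def test_verify_solution_rejects_violations():
    mf = parse_formula("C2H6O")
    problem = problem_from_formula(mf)
    ethanol = MoleculeGraph.from_smiles("CCO")
    assert verify_solution(ethanol, problem)
    atoms = list(problem.atoms)
    atoms[0] = ProblemAtom(element="C", label="C1", forbidden=frozenset({"O"}))
    atoms[1] = ProblemAtom(element="C", label="C2", forbidden=frozenset({"O"}))
    stricter = ElucidationProblem(atoms=tuple(atoms), total_h=6)
    assert not verify_solution(ethanol, stricter)


def test_verify_agrees_with_oracle_membership():
    formula = "C4H10O"
    problem = problem_from_formula(parse_formula(formula))
    oracle = brute_force_isomers(formula)
    for graph in oracle.values():
        assert verify_solution(graph, problem) == satisfies(graph, problem)
        assert verify_solution(graph, problem)


def test_permutation_invariance_of_solution_set():
    """Shuffling the heavy-atom declaration order leaves the signature set
    unchanged."""
    mf = parse_formula("C3H9N")
    base = problem_from_formula(mf)
    reference = signatures(generate(base))
    rng = random.Random(9)
    for _ in range(5):
        atoms = list(base.atoms)
        rng.shuffle(atoms)
        assert signatures(generate(ElucidationProblem(atoms=tuple(atoms), total_h=9))) \
            == reference


def test_constraint_monotonicity():
    mf = parse_formula("C3H8O")
    free = signatures(generate(problem_from_formula(mf)))
    atoms = list(problem_from_formula(mf).atoms)
    atoms[0] = ProblemAtom(element="C", label="C1", mandatory=frozenset({"O"}))
    constrained = signatures(generate(ElucidationProblem(atoms=tuple(atoms), total_h=8)))
    assert constrained <= free


def test_truncation_flag():
    result = generate(problem_from_formula(parse_formula("C5H12O"), max_solutions=3))
    assert len(result) == 3
    assert result.truncated


def test_hhb_flag_controls_heteroatom_bonds():
    mf = parse_formula("CH4N2")
    allowed = signatures(generate(problem_from_formula(mf, hhb_allowed=True)))
    blocked = signatures(generate(problem_from_formula(mf, hhb_allowed=False)))
    # only formamidine (N-C=N) survives without a nitrogen-nitrogen bond
    assert blocked == {canonical_signature(MoleculeGraph.from_smiles("N=CN"))}
    assert blocked < allowed and len(allowed) == 4


def test_embeds_substructure():
    target = MoleculeGraph.from_smiles("CC(=O)Nc1ccccc1")
    amide = MoleculeGraph([
        casepy.Atom("C", 0), casepy.Atom("O", 0), casepy.Atom("N", 1),
    ], [(0, 1, 2), (0, 2, 1)])
    assert embeds(amide, target)
    ester = MoleculeGraph([
        casepy.Atom("C", 0), casepy.Atom("O", 0), casepy.Atom("O", 0),
    ], [(0, 1, 2), (0, 2, 1)])
    assert not embeds(ester, target)


def test_goodlist_restricts_solutions():
    mf = parse_formula("C2H6O")
    ether_core = MoleculeGraph([casepy.Atom("C", 3), casepy.Atom("O", 0)], [(0, 1, 1)])
    problem = problem_from_formula(mf)
    problem = ElucidationProblem(atoms=problem.atoms, total_h=6,
                                 goodlist=(ether_core,))
    # a CH3 bonded to O embeds in both ethanol (no) and dimethyl ether (yes):
    # ethanol's O-carbon is a CH2, so only the ether survives
    assert signatures(generate(problem)) == {
        canonical_signature(MoleculeGraph.from_smiles("COC"))}


# ---------------------------------------------------------------------------
# Correlation-table problems
# ---------------------------------------------------------------------------


def test_build_problem_counts_for_large_worked_case():
    corr, mf = read_peaklist(casepy.bundled_peaklist_path("testcase15_synthetic"))
    problem = build_problem(corr, mf)
    assert len(problem.atoms) == 17       # 12 carbons + 5 oxygens
    assert len(problem.proximity) == 18   # 14 HMBC + 4 COSY
    # the hydroxyl proton sits on the first oxygen placeholder
    oxygens = [a for a in problem.atoms if a.element == "O"]
    assert [o.attached_h for o in oxygens] == [1, 0, 0, 0, 0]


def test_build_problem_free_when_no_2d_data():
    from casepy.structure_generation import CarbonSignal, CorrelationSet

    corr = CorrelationSet(carbons=(
        CarbonSignal(id="C1", shift=30.0, multiplicity=3),
        CarbonSignal(id="C2", shift=60.0, multiplicity=3),
    ))
    problem = build_problem(corr, parse_formula("C2H6O"))
    assert problem.proximity == ()
    assert {a.element for a in problem.atoms} == {"C", "O"}


def test_build_problem_proton_mismatch():
    from casepy.structure_generation import CarbonSignal, CorrelationSet

    corr = CorrelationSet(carbons=(
        CarbonSignal(id="C1", shift=30.0, multiplicity=3),
        CarbonSignal(id="C2", shift=60.0, multiplicity=3),
    ))
    with pytest.raises(ProblemBuildError):
        build_problem(corr, parse_formula("C2H9O"))


def test_ambiguous_multiplicity_branches():
    """An edited-HSQC CH/CH3 ambiguity is explored over both values."""
    from casepy.structure_generation import CarbonSignal, CorrelationSet

    corr = CorrelationSet(carbons=(
        CarbonSignal(id="C1", shift=70.0, multiplicity=frozenset({1, 3})),
        CarbonSignal(id="C2", shift=25.0, multiplicity=frozenset({1, 3})),
    ))
    problem = build_problem(corr, parse_formula("C2H6O"))
    result = generate(problem)
    # the search branches over {1,3} x {1,3}; only the 3+3 resolution can
    # host all six protons, leaving dimethyl ether as the unique solution
    assert signatures(result) == {
        canonical_signature(MoleculeGraph.from_smiles("COC")),
    }


def test_small_correlated_elucidation_recovers_structure(fixture_kb):
    """A complete synthetic correlation table pins down its parent molecule."""
    from casepy.fixtures import correlation_set_for

    record = next(r for r in fixture_kb
                  if canonical_signature(r.molecule)
                  == canonical_signature(MoleculeGraph.from_smiles("CC(=O)OCC")))
    corr = correlation_set_for(record)
    problem = build_problem(corr, record.molecule.formula())
    result = generate(problem)
    assert canonical_signature(record.molecule) in signatures(result)
    for graph in result.structures:
        assert verify_solution(graph, problem)


def test_generator_matches_oracle_with_random_constraints():
    """Spot-check of the exhaustive sweep: random constraint sets on a few
    formulas give exactly the oracle's enumerate-and-filter set."""
    rng = random.Random(77)
    for formula in ("C2H6O", "C3H8O", "C2H7N", "C3H6", "C2H4O2"):
        mf = parse_formula(formula)
        for _ in range(5):
            problem = random_problem(mf, rng)
            assert signatures(generate(problem)) == oracle_solution_set(formula, problem)


def random_problem(mf, rng):
    base = problem_from_formula(mf, hhb_allowed=rng.random() < 0.7,
                                max_solutions=10 ** 9)
    atoms = list(base.atoms)
    heavy_elements = sorted(mf.heavy_elements)
    for k in range(len(atoms)):
        if rng.random() < 0.4:
            hyb = frozenset(s for s in ("sp", "sp2", "sp3") if rng.random() < 0.6)
            if not hyb:
                hyb = frozenset({"sp", "sp2", "sp3"})
            atoms[k] = ProblemAtom(element=atoms[k].element, label=atoms[k].label,
                                   hybridizations=hyb)
        if rng.random() < 0.3:
            el = rng.choice(heavy_elements)
            kind = rng.random()
            atoms[k] = ProblemAtom(
                element=atoms[k].element, label=atoms[k].label,
                hybridizations=atoms[k].hybridizations,
                forbidden=frozenset({el}) if kind < 0.5 else atoms[k].forbidden,
                mandatory=frozenset({el}) if kind >= 0.5 else atoms[k].mandatory,
            )
    proximity = []
    if len(atoms) >= 2 and rng.random() < 0.5:
        a, b = rng.sample(range(len(atoms)), 2)
        dset = frozenset(d for d in (1, 2, 3) if rng.random() < 0.5) or frozenset({1, 2})
        proximity.append((a, b, dset))
    return ElucidationProblem(atoms=tuple(atoms), total_h=mf.count("H"),
                              proximity=tuple(proximity),
                              hhb_allowed=base.hhb_allowed,
                              max_solutions=10 ** 9)
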