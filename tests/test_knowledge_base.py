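"""Record ingestion, equivalence indices, HOSE library, statistics, SDF I/O."""

import pytest

from casepy.chem_model import Atom, MoleculeGraph, canonical_signature
from casepy.exceptions import IngestionError, ValidationError
from casepy.knowledge_base import (
    accumulate_statistics,
    assign_equivalence,
    build_hose_library,
    ingest_record,
    read_assigned_sdf,
    write_assigned_sdf,
)

# N-phenylpropanamide with its published per-atom assignment; SMILES atom
# order: 0 CH3, 1 CH2, 2 C=O, 3 O, 4 N, 5 ipso, 6-10 ring
NPP_SMILES = "CCC(=O)Nc1ccccc1"
NPP_SHIFTS = {0: 9.89, 1: 30.8, 2: 172.2, 5: 137.9,
              6: 119.8, 10: 119.8, 7: 129.0, 9: 129.0, 8: 124.2}


def test_equivalence_worked_example():
    """The monosubstituted ring collapses ortho and meta pairs into two
    equivalence-2 signals; indices sum to the carbon count."""
    mol = MoleculeGraph.from_smiles(NPP_SMILES)
    record = ingest_record(mol, NPP_SHIFTS, "npp")
    signals = record.spectrum.signals
    assert len(signals) == 7
    assert sorted(s.equivalence for s in signals) == [1, 1, 1, 1, 1, 2, 2]
    assert record.spectrum.equivalence_sum == 9
    by_shift = {s.shift: (s.equivalence, s.multiplicity) for s in signals}
    assert by_shift[119.8] == (2, 1)
    assert by_shift[129.0] == (2, 1)
    assert by_shift[172.2] == (1, 0)


def test_assign_equivalence_grouping():
    signals = assign_equivalence([(10.0, 1, 0), (20.0, 1, 1), (10.0, 1, 2), (10.0, 0, 3)])
    assert [(s.shift, s.multiplicity, s.equivalence) for s in signals] == [
        (10.0, 1, 2), (20.0, 1, 1), (10.0, 0, 1)]
    three = assign_equivalence([(50.0, 2, 0), (50.0, 2, 1), (50.0, 2, 2)])
    assert len(three) == 1 and three[0].equivalence == 3
    with pytest.raises(ValidationError):
        assign_equivalence([(1.0, 0, 0), (2.0, 0, 0)])  # duplicate atom index


def test_ingest_benzene_single_signal():
    benzene = MoleculeGraph.from_smiles("c1ccccc1")
    record = ingest_record(benzene, {i: 128.5 for i in range(6)}, "benzene")
    assert len(record.spectrum.signals) == 1
    assert record.spectrum.signals[0].equivalence == 6


def test_ingest_missing_shift_names_atom():
    mol = MoleculeGraph.from_smiles("CCO")
    with pytest.raises(IngestionError, match="1"):
        ingest_record(mol, {0: 18.0})


def test_hose_library_statistics(fixture_kb):
    lib = build_hose_library(fixture_kb[:20], max_sphere=6)
    total_carbons = sum(len(r.molecule.carbons()) for r in fixture_kb[:20])
    for sphere in range(1, 7):
        # every carbon contributes exactly once per sphere
        assert lib.entry_count(sphere) == total_carbons
    for sphere, table in lib.spheres.items():
        for entry in table.values():
            assert entry.min_shift <= entry.mean_shift <= entry.max_shift
            assert entry.count >= 1


def test_hose_library_shared_code_arithmetic():
    # two single-carbon records with identical environments, shifts 10 and 20
    m1 = MoleculeGraph.from_smiles("CO")
    r1 = ingest_record(m1, {0: 10.0}, "a")
    r2 = ingest_record(m1, {0: 20.0}, "b")
    lib = build_hose_library([r1, r2], max_sphere=2)
    (entry,) = lib.spheres[1].values()
    assert (entry.mean_shift, entry.count, entry.min_shift, entry.max_shift) == (15.0, 2, 10.0, 20.0)


def test_library_build_deterministic(fixture_kb):
    a = build_hose_library(fixture_kb[:30], max_sphere=4).to_json()
    b = build_hose_library(fixture_kb[:30], max_sphere=4).to_json()
    assert a == b


def test_statistics_additivity(fixture_kb):
    half = len(fixture_kb) // 4
    a = accumulate_statistics(fixture_kb[:half])
    b = accumulate_statistics(fixture_kb[half:2 * half])
    merged = a.merge(b)
    direct = accumulate_statistics(fixture_kb[:2 * half])
    assert merged.to_json() == direct.to_json()


def test_statistics_hhb_counts():
    # one N-N bond among the bonds of methylhydrazine-like CH3-NH-NH2
    mol = MoleculeGraph([Atom("C", 3), Atom("N", 1), Atom("N", 2)],
                        [(0, 1, 1), (1, 2, 1)])
    record = ingest_record(mol, {0: 38.0}, "hz")
    stats = accumulate_statistics([record])
    hetero, total = stats.query_hhb(frozenset({"C", "H", "N"}))
    assert (hetero, total) == (1, 2)


def test_statistics_no_hhb_in_plain_kb(fixture_kb):
    stats = accumulate_statistics([r for r in fixture_kb
                                   if len(r.molecule.element_set()) <= 2])
    hetero, _ = stats.query_hhb(frozenset({"C", "H"}))
    assert hetero == 0


def test_equivalence_sum_invariant(fixture_kb):
    for record in fixture_kb:
        assert record.spectrum.equivalence_sum == len(record.molecule.carbons())
        record.spectrum.validate(record.molecule)


def test_assigned_sdf_round_trip(tmp_path, fixture_kb):
    subset = fixture_kb[:25]
    path = tmp_path / "kb.sdf"
    write_assigned_sdf(subset, path)
    back = read_assigned_sdf(path)
    assert len(back) == len(subset)
    for original, restored in zip(subset, back):
        assert restored.identifier == original.identifier
        assert canonical_signature(restored.molecule) == canonical_signature(original.molecule)
        assert restored.shift_map() == original.shift_map()


def test_assigned_sdf_missing_property(tmp_path):
    from rdkit import Chem

    mol = MoleculeGraph.from_smiles("CCO").to_rdkit()
    writer = Chem.SDWriter(str(tmp_path / "bad.sdf"))
    writer.write(mol)
    writer.close()
    with pytest.raises(IngestionError, match="CS_13C"):
        read_assigned_sdf(tmp_path / "bad.sdf")
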