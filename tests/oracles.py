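"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's search/matching code paths: isomers
are enumerated by plain recursive bond-order assignment with only arithmetic
feasibility pruning and filtered afterwards by direct predicate evaluation;
spectrum matching is solved exactly by exhaustive assignment enumeration.
"""

from __future__ import annotations

import itertools

from casepy.chem_model import (
    VALENCES,
    Atom,
    MoleculeGraph,
    canonical_signature,
    parse_formula,
)


def _h_distributions(elements, total_h):
    """All attached-H assignments compatible with lowest standard valences."""
    n = len(elements)
    caps = [VALENCES[el][0] - (0 if n == 1 else 1) for el in elements]

    def rec(i, remaining):
        if i == n:
            if remaining == 0:
                yield ()
            return
        for h in range(0, min(caps[i], remaining) + 1):
            for rest in rec(i + 1, remaining - h):
                yield (h,) + rest

    yield from rec(0, total_h)


def brute_force_isomers(formula: str) -> dict[str, MoleculeGraph]:
    """All connected valence-complete structures of a formula, by signature."""
    mf = parse_formula(formula)
    elements = []
    heavy = mf.heavy_counts()
    for el in ["C"] + sorted(e for e in heavy if e != "C"):
        elements.extend([el] * heavy[el])
    n = len(elements)
    valences = [VALENCES[el][0] for el in elements]
    out: dict[str, MoleculeGraph] = {}
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for hs in _h_distributions(elements, mf.count("H")):
        rem = [valences[i] - hs[i] for i in range(n)]
        if sum(rem) % 2 or (n > 1 and sum(rem) < 2 * (n - 1)):
            continue
        orders = [0] * len(pairs)

        def rec(k):
            if k == len(pairs):
                if any(rem):
                    return
                bonds = [(i, j, o) for (i, j), o in zip(pairs, orders) if o]
                graph = MoleculeGraph([Atom(el, h) for el, h in zip(elements, hs)], bonds)
                if not graph.is_connected():
                    return
                out.setdefault(canonical_signature(graph), graph)
                return
            i, j = pairs[k]
            # arithmetic necessity: atom i must be able to shed its valence
            if rem[i] > 3 * (n - j):
                return
            for o in range(0, min(3, rem[i], rem[j]) + 1):
                rem[i] -= o
                rem[j] -= o
                orders[k] = o
                rec(k + 1)
                orders[k] = 0
                rem[i] += o
                rem[j] += o

        rec(0)
    return out


def satisfies(graph: MoleculeGraph, problem) -> bool:
    """Direct constraint filter, written independently of the package."""
    for i, pa in enumerate(problem.atoms):
        atom = graph.atoms[i]
        if atom.element != pa.element:
            return False
        if pa.attached_h is not None and atom.attached_h != pa.attached_h:
            return False
        if pa.attached_h is None and pa.h_options is not None \
                and atom.attached_h not in pa.h_options:
            return False
        d = sum(1 for _, o in graph.neighbors(i) if o == 2)
        t = sum(1 for _, o in graph.neighbors(i) if o == 3)
        hyb = {(0, 0): "sp3", (1, 0): "sp2", (0, 1): "sp", (2, 0): "sp"}.get((d, t))
        if hyb not in pa.hybridizations:
            return False
        nbr = {graph.atoms[j].element for j, _ in graph.neighbors(i)}
        if nbr & pa.forbidden or not pa.mandatory <= nbr:
            return False
    if not problem.hhb_allowed:
        for i, j, _ in graph.bonds:
            if graph.atoms[i].element != "C" and graph.atoms[j].element != "C":
                return False
    for a, b, dset in problem.proximity:
        dist = graph.distances_from(a)[b]
        if dist not in dset:
            return False
    bonded = {(min(i, j), max(i, j)): o for i, j, o in graph.bonds}
    for i, j, order in problem.fixed_bonds:
        key = (min(i, j), max(i, j))
        if key not in bonded or (order is not None and bonded[key] != order):
            return False
    return True


def oracle_solution_set(formula: str, problem=None) -> set[str]:
    """Signature set of brute-force enumeration, optionally constraint-filtered.

    Element order of ``problem.atoms`` must match the enumeration order
    (carbons first, then heteroatoms alphabetically), which is how
    ``problem_from_formula`` lays atoms out.  Because constraints on
    identical unconstrained atoms are symmetric only per-index, the filter
    accepts a structure when ANY permutation of same-element atom indices
    satisfies the constraints — matching the generator, which explores all
    labelled graphs before deduplicating.
    """
    isomers = brute_force_isomers(formula)
    if problem is None:
        return set(isomers)
    out = set()
    for signature, graph in isomers.items():
        if _any_relabel_satisfies(graph, problem):
            out.add(signature)
    return out


def _any_relabel_satisfies(graph: MoleculeGraph, problem) -> bool:
    # permute atoms within each element class; n <= 5 keeps this tiny
    by_element: dict[str, list[int]] = {}
    for i, a in enumerate(graph.atoms):
        by_element.setdefault(a.element, []).append(i)
    element_classes = list(by_element.values())
    for perms in itertools.product(*(itertools.permutations(c) for c in element_classes)):
        mapping = {}
        for cls, perm in zip(element_classes, perms):
            for old, new in zip(cls, perm):
                mapping[new] = old
        order = [mapping[k] for k in range(len(graph.atoms))]
        if satisfies(graph.permuted(order), problem):
            return True
    return False


def optimal_assignment_deviation(query_shifts, reference_shifts, tolerance):
    """Exhaustive best complete matching (test oracle for the greedy matcher).

    Returns (best average deviation, number of pairs) over all maximal valid
    assignments, or (None, 0) if no valid pair exists.
    """
    best = None
    nq, nr = len(query_shifts), len(reference_shifts)
    k = min(nq, nr)
    for size in range(k, 0, -1):
        for q_idx in itertools.combinations(range(nq), size):
            for r_perm in itertools.permutations(range(nr), size):
                devs = [abs(query_shifts[q] - reference_shifts[r])
                        for q, r in zip(q_idx, r_perm)]
                if any(d > tolerance for d in devs):
                    continue
                avg = sum(devs) / size
                if best is None or avg < best:
                    best = avg
        if best is not None:
            return best, size
    return None, 0
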