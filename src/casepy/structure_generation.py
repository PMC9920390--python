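"""Exhaustive generation of constitutional isomers under NMR constraints.

The generator enumerates all connected heavy-atom graphs that satisfy a
molecular formula together with the constraints of an elucidation problem:
fixed attached-hydrogen counts, hybridization candidate sets, forbidden and
mandatory neighbour elements, proximity constraints derived from HMBC/COSY
correlations, the hetero-hetero-bond permission, and good-/bad-list
fragments.  The search is a deterministic backtracking over bond-order
assignments on an internally sorted atom list with incremental pruning on
remaining valence, multiple-bond patterns, neighbourhood-decidable proximity
constraints and component closure; solutions are deduplicated by canonical
signature and the enumeration stops (flagged) at a solution cap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx

from .chem_model import (
    VALENCES,
    Atom,
    MolecularFormula,
    MoleculeGraph,
    canonical_signature,
    default_valence,
    hybridization_of,
)
from .constraint_detection import ALL_HYBRIDIZATIONS, AtomConstraint
from .exceptions import ProblemBuildError, ValidationError

# ---------------------------------------------------------------------------
# Correlation data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CarbonSignal:
    id: str
    shift: float
    # int, frozenset of candidate values (edited-HSQC ambiguity), or None
    multiplicity: int | frozenset | None = None


@dataclass(frozen=True)
class ProtonGroup:
    id: str
    shift: float
    integral: float = 1.0


@dataclass(frozen=True)
class CorrelationSet:
    """Query-side summary table: 13C/1H signals and 2D correlation pairs."""

    carbons: tuple[CarbonSignal, ...]
    proton_groups: tuple[ProtonGroup, ...] = ()
    hsqc: tuple[tuple[str, str], ...] = ()            # (proton group, carbon)
    hmbc: tuple[tuple[str, str], ...] = ()            # (proton group, target carbon)
    cosy: tuple[tuple[str, str], ...] = ()            # (proton group, proton group)
    hetero_attachments: tuple[tuple[str, str], ...] = ()  # (proton group, element)

    def carbon_ids(self) -> list[str]:
        return [c.id for c in self.carbons]


# ---------------------------------------------------------------------------
# Elucidation problem (the MCD)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProblemAtom:
    element: str
    attached_h: int | None = None           # fixed H count, or None if open
    h_options: tuple[int, ...] | None = None  # candidate H counts when open
    hybridizations: frozenset = ALL_HYBRIDIZATIONS
    forbidden: frozenset = frozenset()
    mandatory: frozenset = frozenset()
    label: str = ""
    valence: int | None = None

    def resolved_valence(self) -> int:
        return self.valence if self.valence is not None else default_valence(self.element)

    def h_candidates(self, n_atoms: int) -> tuple[int, ...]:
        if self.attached_h is not None:
            return (self.attached_h,)
        if self.h_options is not None:
            return tuple(sorted(self.h_options))
        v = self.resolved_valence()
        upper = v if n_atoms == 1 else v - 1  # multi-atom molecules need a free valence
        return tuple(range(0, upper + 1))


@dataclass(frozen=True)
class ElucidationProblem:
    atoms: tuple[ProblemAtom, ...]
    total_h: int
    fixed_bonds: tuple[tuple[int, int, int | None], ...] = ()
    proximity: tuple[tuple[int, int, frozenset], ...] = ()
    hhb_allowed: bool = True
    goodlist: tuple[MoleculeGraph, ...] = ()
    badlist: tuple[MoleculeGraph, ...] = ()
    max_solutions: int = 500


def problem_from_formula(mf: MolecularFormula, hhb_allowed: bool = True,
                         max_solutions: int = 500) -> ElucidationProblem:
    """Unconstrained problem: every isomer of the formula is admissible."""
    atoms: list[ProblemAtom] = []
    heavy = mf.heavy_counts()
    if heavy.get("C", 0) < 1:
        raise ProblemBuildError("an elucidation problem needs at least one carbon")
    order = ["C"] + sorted(el for el in heavy if el != "C")
    for el in order:
        for k in range(heavy[el]):
            atoms.append(ProblemAtom(element=el, label=f"{el}{k + 1}"))
    return ElucidationProblem(atoms=tuple(atoms), total_h=mf.count("H"),
                              hhb_allowed=hhb_allowed, max_solutions=max_solutions)


def build_problem(correlations: CorrelationSet, mf: MolecularFormula,
                  constraints: Sequence[AtomConstraint] = (),
                  hmbc_distances: Iterable[int] = (1, 2),
                  cosy_distances: Iterable[int] = (1,),
                  hhb_allowed: bool = True,
                  goodlist: Sequence[MoleculeGraph] = (),
                  badlist: Sequence[MoleculeGraph] = (),
                  max_solutions: int = 500) -> ElucidationProblem:
    """Translate a correlation table into an elucidation problem.

    HSQC pins attached-hydrogen counts on carbons; each HMBC correlation from
    a proton on atom *a* to carbon *c* becomes a proximity constraint with
    heavy-atom distances ``hmbc_distances`` (default 1-2 bonds, i.e. 2-3 bonds
    from the proton); COSY links the carbons bearing the coupled protons at
    distance 1.  Heavy atoms of the formula without a signal are appended as
    placeholders; explicit hetero attachments put protons on them.
    """
    if len(correlations.carbons) != mf.count("C"):
        raise ProblemBuildError(
            f"correlation table has {len(correlations.carbons)} carbons but the "
            f"formula {mf.hill()} has {mf.count('C')}"
        )
    constraint_map = {c.signal_id: c for c in constraints}
    atoms: list[ProblemAtom] = []
    index_of: dict[str, int] = {}
    for c in correlations.carbons:
        kw = dict(element="C", label=c.id)
        if isinstance(c.multiplicity, int):
            kw["attached_h"] = c.multiplicity
        elif isinstance(c.multiplicity, frozenset):
            kw["h_options"] = tuple(sorted(c.multiplicity))
        else:
            kw["h_options"] = (0, 1, 2, 3)
        ac = constraint_map.get(c.id)
        if ac is not None:
            kw["hybridizations"] = ac.hybridizations
            kw["forbidden"] = ac.forbidden_neighbours
            kw["mandatory"] = ac.mandatory_neighbours
        index_of[c.id] = len(atoms)
        atoms.append(ProblemAtom(**kw))

    # placeholder heteroatoms, labelled e.g. O1..O5
    heavy = mf.heavy_counts()
    for el in sorted(e for e in heavy if e != "C"):
        for k in range(heavy[el]):
            label = f"{el}{k + 1}"
            index_of[label] = len(atoms)
            atoms.append(ProblemAtom(element=el, attached_h=0, label=label))

    # explicit proton-on-hetero assignments
    integral_of = {p.id: p.integral for p in correlations.proton_groups}
    proton_host: dict[str, int] = {}
    for proton_id, carbon_id in correlations.hsqc:
        if carbon_id in index_of:
            if proton_id in proton_host:
                raise ProblemBuildError(f"proton group {proton_id} HSQC-links twice")
            proton_host[proton_id] = index_of[carbon_id]
    hetero_used: dict[str, int] = {}
    for proton_id, element in correlations.hetero_attachments:
        k = hetero_used.get(element, 0)
        label = f"{element}{k + 1}"
        if label not in index_of:
            raise ProblemBuildError(f"no free {element} placeholder for proton {proton_id}")
        hetero_used[element] = k + 1
        idx = index_of[label]
        n_h = max(1, round(integral_of.get(proton_id, 1.0)))
        atoms[idx] = replace(atoms[idx], attached_h=(atoms[idx].attached_h or 0) + n_h)
        proton_host[proton_id] = idx

    _check_proton_balance(atoms, mf)

    proximity: list[tuple[int, int, frozenset]] = []
    hmbc_set = frozenset(hmbc_distances)
    cosy_set = frozenset(cosy_distances)
    for proton_id, target_id in correlations.hmbc:
        if proton_id not in proton_host:
            raise ProblemBuildError(f"HMBC proton group {proton_id} is bound to no heavy atom")
        if target_id not in index_of:
            raise ProblemBuildError(f"HMBC target {target_id} is not a known signal")
        a, b = proton_host[proton_id], index_of[target_id]
        if a != b:
            proximity.append((a, b, hmbc_set))
    for p1, p2 in correlations.cosy:
        if p1 not in proton_host or p2 not in proton_host:
            continue  # COSY between protons with no carbon host carries no constraint
        a, b = proton_host[p1], proton_host[p2]
        if a != b:
            proximity.append((a, b, cosy_set))

    return ElucidationProblem(
        atoms=tuple(atoms), total_h=mf.count("H"),
        proximity=tuple(proximity), hhb_allowed=hhb_allowed,
        goodlist=tuple(goodlist), badlist=tuple(badlist),
        max_solutions=max_solutions,
    )


def _check_proton_balance(atoms: Sequence[ProblemAtom], mf: MolecularFormula) -> None:
    fixed = sum(a.attached_h for a in atoms if a.attached_h is not None)
    flexible = [a.h_candidates(len(atoms)) for a in atoms if a.attached_h is None]
    target = mf.count("H")
    reachable = {fixed}
    for options in flexible:
        reachable = {r + o for r in reachable for o in options}
    if target not in reachable:
        raise ProblemBuildError(
            f"proton bookkeeping mismatch: heavy atoms carry {sorted(reachable)} "
            f"protons but the formula {mf.hill()} has {target}"
        )


# ---------------------------------------------------------------------------
# Substructure embedding (goodlist / badlist)
# ---------------------------------------------------------------------------


def _to_nx(graph: MoleculeGraph) -> nx.Graph:
    g = nx.Graph()
    for i, a in enumerate(graph.atoms):
        closed = graph.bond_order_sum(i) + a.attached_h in VALENCES.get(a.element, ())
        g.add_node(i, element=a.element, attached_h=a.attached_h, closed=closed)
    for i, j, o in graph.bonds:
        g.add_edge(i, j, order=o)
    return g


def embeds(fragment: MoleculeGraph, target: MoleculeGraph) -> bool:
    """Substructure monomorphism test.

    Elements and bond orders must match everywhere; attached-hydrogen counts
    must match only at the fragment's interior atoms (those whose valence is
    already complete), leaving attachment points free to grow.
    """
    g_frag = _to_nx(fragment)
    g_target = _to_nx(target)

    def node_match(t, f):
        if t["element"] != f["element"]:
            return False
        if f["closed"]:
            return t["attached_h"] == f["attached_h"]
        return True

    def edge_match(t, f):
        return t["order"] == f["order"]

    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g_target, g_frag, node_match=node_match, edge_match=edge_match
    )
    return matcher.subgraph_is_monomorphic()


# ---------------------------------------------------------------------------
# Solution verification (independent of the search)
# ---------------------------------------------------------------------------


def verify_solution(graph: MoleculeGraph, problem: ElucidationProblem) -> bool:
    """Direct predicate evaluation of every generation constraint."""
    atoms = problem.atoms
    if len(graph) != len(atoms):
        return False
    total_h = 0
    for i, pa in enumerate(atoms):
        a = graph.atoms[i]
        if a.element != pa.element:
            return False
        if pa.attached_h is not None and a.attached_h != pa.attached_h:
            return False
        if pa.attached_h is None and pa.h_options is not None \
                and a.attached_h not in pa.h_options:
            return False
        total_h += a.attached_h
        if graph.bond_order_sum(i) + a.attached_h != pa.resolved_valence():
            return False
        try:
            if hybridization_of(graph, i) not in pa.hybridizations:
                return False
        except ValidationError:
            return False
        nbr_elements = {graph.atoms[j].element for j, _ in graph.neighbors(i)}
        if nbr_elements & pa.forbidden:
            return False
        if not pa.mandatory <= nbr_elements:
            return False
    if total_h != problem.total_h:
        return False
    if not problem.hhb_allowed:
        for i, j, _ in graph.bonds:
            if graph.atoms[i].element != "C" and graph.atoms[j].element != "C":
                return False
    bonded = {(min(i, j), max(i, j)): o for i, j, o in graph.bonds}
    for i, j, order in problem.fixed_bonds:
        key = (min(i, j), max(i, j))
        if key not in bonded:
            return False
        if order is not None and bonded[key] != order:
            return False
    g = nx.Graph()
    g.add_nodes_from(range(len(graph)))
    g.add_edges_from((i, j) for i, j, _ in graph.bonds)
    if len(graph) > 1 and not nx.is_connected(g):
        return False
    for a, b, dset in problem.proximity:
        try:
            if nx.shortest_path_length(g, a, b) not in dset:
                return False
        except nx.NetworkXNoPath:
            return False
    for fragment in problem.goodlist:
        if not embeds(fragment, graph):
            return False
    for fragment in problem.badlist:
        if embeds(fragment, graph):
            return False
    return True


# ---------------------------------------------------------------------------
# Backtracking search
# ---------------------------------------------------------------------------


@dataclass
class GenerationResult:
    structures: list[MoleculeGraph]
    truncated: bool = False

    def __iter__(self):
        return iter(self.structures)

    def __len__(self):
        return len(self.structures)


_FINAL_HYB = {(0, 0): "sp3", (1, 0): "sp2", (0, 1): "sp", (2, 0): "sp"}


def _hyb_feasible(allowed: frozenset, d: int, t: int) -> bool:
    if "sp" in allowed and ((t <= 1 and d == 0) or (t == 0 and d <= 2)):
        return True
    if "sp2" in allowed and t == 0 and d <= 1:
        return True
    if "sp3" in allowed and t == 0 and d == 0:
        return True
    return False


class _Search:
    def __init__(self, problem: ElucidationProblem):
        self.problem = problem
        n = len(problem.atoms)
        self.n = n
        prox_count = [0] * n
        prox_links: list[set[int]] = [set() for _ in range(n)]
        for a, b, _ in problem.proximity:
            prox_count[a] += 1
            prox_count[b] += 1
            prox_links[a].add(b)
            prox_links[b].add(a)
        # Cluster proximity-linked atoms contiguously (greedy accretion over
        # the constraint graph) so that both neighbourhoods of a constrained
        # pair close early and the adjacency checks prune near the root.
        remaining = set(range(n))
        order: list[int] = []
        while remaining:
            chosen = set(order)
            best = max(
                remaining,
                key=lambda i: (
                    len(prox_links[i] & chosen),
                    prox_count[i],
                    -len(problem.atoms[i].hybridizations),
                    1 if problem.atoms[i].element == "C" else 0,
                    -i,
                ),
            )
            order.append(best)
            remaining.discard(best)
        self.order = order
        self.inv = {old: new for new, old in enumerate(self.order)}
        self.atoms = [problem.atoms[i] for i in self.order]
        self.elements = [a.element for a in self.atoms]
        self.valences = [a.resolved_valence() for a in self.atoms]
        self.is_carbon = [el == "C" for el in self.elements]

        self.forbidden_pair = [[False] * n for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if self.elements[j] in self.atoms[i].forbidden \
                        or self.elements[i] in self.atoms[j].forbidden:
                    self.forbidden_pair[i][j] = True
                if not problem.hhb_allowed and not self.is_carbon[i] \
                        and not self.is_carbon[j]:
                    self.forbidden_pair[i][j] = True

        self.fixed: dict[tuple[int, int], int | None] = {}
        for a, b, order in problem.fixed_bonds:
            sa, sb = self.inv[a], self.inv[b]
            self.fixed[(min(sa, sb), max(sa, sb))] = order
        self.prox: list[tuple[int, int, frozenset]] = []
        for a, b, dset in problem.proximity:
            sa, sb = self.inv[a], self.inv[b]
            key = (min(sa, sb), max(sa, sb))
            if dset == frozenset({1}):
                # adjacency constraint doubles as a forced bond
                if key not in self.fixed:
                    self.fixed[key] = None
            self.prox.append((key[0], key[1], dset))
        # proximity constraints decidable from the two neighbourhoods alone
        self.local_prox: dict[int, list[tuple[int, int, frozenset]]] = {}
        self.global_prox: list[tuple[int, int, frozenset]] = []
        for a, b, dset in self.prox:
            if dset <= frozenset({1, 2}):
                self.local_prox.setdefault(max(a, b), []).append((a, b, dset))
            else:
                self.global_prox.append((a, b, dset))

        self.pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        self.solutions: list[MoleculeGraph] = []
        self.seen: set[str] = set()
        self.truncated = False

    # -- entry point -------------------------------------------------------

    def run(self) -> GenerationResult:
        for h in self._h_assignments():
            if self.truncated:
                break
            self._search_bonds(h)
        return GenerationResult(structures=self.solutions, truncated=self.truncated)

    def _h_assignments(self):
        n, total = self.n, self.problem.total_h
        cands = [a.h_candidates(n) for a in self.atoms]
        suffix_min = [0] * (n + 1)
        suffix_max = [0] * (n + 1)
        for i in range(n - 1, -1, -1):
            suffix_min[i] = suffix_min[i + 1] + min(cands[i])
            suffix_max[i] = suffix_max[i + 1] + max(cands[i])
        out: list[int] = []

        def rec(i: int, remaining: int):
            if i == n:
                if remaining == 0:
                    yield list(out)
                return
            for h in cands[i]:
                rest = remaining - h
                if suffix_min[i + 1] <= rest <= suffix_max[i + 1]:
                    if h > self.valences[i]:
                        continue
                    out.append(h)
                    yield from rec(i + 1, rest)
                    out.pop()

        yield from rec(0, total)

    # -- bond search -------------------------------------------------------

    def _search_bonds(self, h: list[int]) -> None:
        n = self.n
        rem = [self.valences[i] - h[i] for i in range(n)]
        if any(r < 0 for r in rem):
            return
        if n > 1 and any(r == 0 for r in rem):
            return
        if sum(rem) % 2 != 0 or (n > 1 and sum(rem) < 2 * (n - 1)):
            return
        if n == 1:
            if rem[0] == 0 and _FINAL_HYB.get((0, 0)) in self.atoms[0].hybridizations \
                    and not self.atoms[0].mandatory:
                self._emit(h, {})
            return
        bonds: dict[tuple[int, int], int] = {}
        nbrs: list[set[int]] = [set() for _ in range(n)]
        dbl = [0] * n
        trp = [0] * n

        pairs = self.pairs

        def place(k: int) -> None:
            if self.truncated:
                return
            if k == len(pairs):
                self._finish(h, bonds, nbrs, rem, dbl, trp)
                return
            i, j = pairs[k]
            if rem[i] > 3 * (n - j):
                return  # atom i cannot shed its valence on the partners left
            last_of_row = j == n - 1
            fixed = self.fixed.get((i, j), "free")
            for order in self._pair_orders(i, j, rem, last_of_row, fixed):
                if order > 0:
                    if order == 2:
                        if not (_hyb_feasible(self.atoms[i].hybridizations, dbl[i] + 1, trp[i])
                                and _hyb_feasible(self.atoms[j].hybridizations, dbl[j] + 1, trp[j])):
                            continue
                    elif order == 3:
                        if not (_hyb_feasible(self.atoms[i].hybridizations, dbl[i], trp[i] + 1)
                                and _hyb_feasible(self.atoms[j].hybridizations, dbl[j], trp[j] + 1)):
                            continue
                    bonds[(i, j)] = order
                    nbrs[i].add(j)
                    nbrs[j].add(i)
                    rem[i] -= order
                    rem[j] -= order
                    if order == 2:
                        dbl[i] += 1
                        dbl[j] += 1
                    elif order == 3:
                        trp[i] += 1
                        trp[j] += 1
                ok = True
                if last_of_row:
                    ok = self._row_complete(i, nbrs, rem, dbl, trp)
                if ok:
                    place(k + 1)
                if order > 0:
                    del bonds[(i, j)]
                    nbrs[i].discard(j)
                    nbrs[j].discard(i)
                    rem[i] += order
                    rem[j] += order
                    if order == 2:
                        dbl[i] -= 1
                        dbl[j] -= 1
                    elif order == 3:
                        trp[i] -= 1
                        trp[j] -= 1
                if self.truncated:
                    return

        place(0)

    def _pair_orders(self, i: int, j: int, rem: list[int], last_of_row: bool,
                     fixed) -> list[int]:
        cap = min(rem[i], rem[j], 3)
        if last_of_row:
            # the row of atom i closes here: its remaining valence must vanish
            need = rem[i]
            if need == 0:
                base = [0]
            elif 1 <= need <= cap:
                base = [need]
            else:
                return []
        else:
            base = list(range(0, cap + 1))
        if fixed is None:  # forced bond, free order
            base = [o for o in base if o >= 1]
        elif fixed != "free":
            base = [o for o in base if o == fixed]
        if self.forbidden_pair[i][j]:
            base = [o for o in base if o == 0]
        return base

    def _row_complete(self, i: int, nbrs: list[set[int]], rem: list[int],
                      dbl: list[int], trp: list[int]) -> bool:
        n = self.n
        # atom i's neighbourhood is now final
        if rem[i] != 0:
            return False
        if not nbrs[i]:
            return False
        if _FINAL_HYB.get((dbl[i], trp[i])) not in self.atoms[i].hybridizations:
            return False
        nbr_elements = {self.elements[j] for j in nbrs[i]}
        if not self.atoms[i].mandatory <= nbr_elements:
            return False
        # proximity constraints whose two neighbourhoods are both final
        for a, b, dset in self.local_prox.get(i, ()):
            if b in nbrs[a]:
                d = 1
            elif nbrs[a] & nbrs[b]:
                d = 2
            else:
                return False  # true distance >= 3, outside any {1,2} subset
            if d not in dset:
                return False
        # remaining valence must be coverable by undecided pairs
        for k in range(i + 1, n):
            undecided = n - i - 2  # partners of k with index > i, excluding k
            if rem[k] > 3 * undecided:
                return False
        # component closure: a finished component that cannot grow is dead
        seen: set[int] = set()
        for a in range(i + 1):
            if a in seen:
                continue
            comp = {a}
            stack = [a]
            while stack:
                for b in nbrs[stack.pop()]:
                    if b not in comp:
                        comp.add(b)
                        stack.append(b)
            seen |= comp
            if len(comp) < n and all(m <= i for m in comp):
                return False
        return True

    def _finish(self, h: list[int], bonds: dict[tuple[int, int], int],
                nbrs: list[set[int]], rem: list[int], dbl: list[int],
                trp: list[int]) -> None:
        n = self.n
        last = n - 1
        if rem[last] != 0 or (n > 1 and not nbrs[last]):
            return
        if _FINAL_HYB.get((dbl[last], trp[last])) not in self.atoms[last].hybridizations:
            return
        if not self.atoms[last].mandatory <= {self.elements[j] for j in nbrs[last]}:
            return
        # connectivity
        comp = {0}
        stack = [0]
        while stack:
            for b in nbrs[stack.pop()]:
                if b not in comp:
                    comp.add(b)
                    stack.append(b)
        if len(comp) != n:
            return
        # the last atom closes no row of its own: its neighbourhood-local
        # proximity constraints are checked here
        for a, b, dset in self.local_prox.get(last, ()):
            if b in nbrs[a]:
                d = 1
            elif nbrs[a] & nbrs[b]:
                d = 2
            else:
                return
            if d not in dset:
                return
        # distance-3+ proximity constraints need real graph distances
        if self.global_prox:
            for a, b, dset in self.global_prox:
                if self._distance(a, b, nbrs) not in dset:
                    return
        self._emit(h, bonds)

    def _distance(self, a: int, b: int, nbrs: list[set[int]]) -> int:
        dist = {a: 0}
        queue = [a]
        while queue:
            nxt = []
            for i in queue:
                for j in nbrs[i]:
                    if j not in dist:
                        dist[j] = dist[i] + 1
                        if j == b:
                            return dist[j]
                        nxt.append(j)
            queue = nxt
        return -1

    def _emit(self, h: list[int], bonds: dict[tuple[int, int], int]) -> None:
        # map back from search order to problem order
        atoms = [None] * self.n
        for search_idx in range(self.n):
            atoms[self.order[search_idx]] = Atom(self.elements[search_idx], h[search_idx])
        bond_list = [
            (self.order[i], self.order[j], o) for (i, j), o in bonds.items()
        ]
        graph = MoleculeGraph(atoms, bond_list)
        for fragment in self.problem.goodlist:
            if not embeds(fragment, graph):
                return
        for fragment in self.problem.badlist:
            if embeds(fragment, graph):
                return
        signature = canonical_signature(graph, allow_open=True)
        if signature in self.seen:
            return
        self.seen.add(signature)
        self.solutions.append(graph)
        if len(self.solutions) >= self.problem.max_solutions:
            self.truncated = True


def generate(problem: ElucidationProblem) -> GenerationResult:
    """Enumerate all constitutional isomers satisfying the problem."""
    return _Search(problem).run()
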