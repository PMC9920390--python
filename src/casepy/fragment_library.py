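"""Spherical fragmentation, subspectrum bit strings, screening and ranking.

Fragments are grown from every heavy atom of a knowledge-base record by
breadth-first spheres.  Two preservation rules keep chemically load-bearing
connectivity intact: a bond between a carbon and a hetero atom is never cut
(whenever one end is included, so is the other), and when the start atom sits
in a ring, the whole fused ring system containing it is included.  Each
fragment carries the assigned shifts of its carbons and a 1-ppm-bin bit
string over those shifts; a fragment survives screening against a query
spectrum when every set bit lies inside the (optionally dilated) query bit
string.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .chem_model import MoleculeGraph, canonical_signature
from .dereplication import MatchParams, match_spectra
from .exceptions import ParameterError
from .knowledge_base import AssignedSpectrum, KbRecord, assign_equivalence

# Bit axis: 1-ppm bins spanning [-20, 260) ppm.
BIT_OFFSET = 20
BIT_WIDTH = 280


@dataclass(frozen=True)
class ShiftBitset:
    """Fixed-width bit vector over 1-ppm chemical-shift bins."""

    mask: int = 0

    @staticmethod
    def bin_index(shift: float) -> int:
        import math

        idx = math.floor(shift) + BIT_OFFSET
        if not 0 <= idx < BIT_WIDTH:
            raise ParameterError(
                f"shift {shift} ppm outside the [-{BIT_OFFSET}, {BIT_WIDTH - BIT_OFFSET}) ppm bit axis"
            )
        return idx

    @classmethod
    def from_shifts(cls, shifts) -> "ShiftBitset":
        mask = 0
        for s in shifts:
            mask |= 1 << cls.bin_index(s)
        return cls(mask)

    def bits(self) -> list[int]:
        return [i for i in range(BIT_WIDTH) if self.mask >> i & 1]

    def dilated(self, bin_tolerance: int) -> "ShiftBitset":
        if bin_tolerance < 0:
            raise ParameterError("bin_tolerance must be >= 0")
        mask = self.mask
        full = (1 << BIT_WIDTH) - 1
        for _ in range(bin_tolerance):
            mask |= (mask << 1) | (mask >> 1)
            mask &= full
        return ShiftBitset(mask)

    def contains(self, other: "ShiftBitset") -> bool:
        return other.mask & ~self.mask == 0

    def to_hex(self) -> str:
        return f"{self.mask:x}"

    @classmethod
    def from_hex(cls, text: str) -> "ShiftBitset":
        return cls(int(text, 16))


def subspectrum_bitset(shifts) -> ShiftBitset:
    """Bit string of a list of shifts; duplicate bins collapse to one bit."""
    return ShiftBitset.from_shifts(shifts)


@dataclass(frozen=True)
class Fragment:
    """A spherically grown substructure with its assigned subspectrum.

    ``subgraph`` atom indices are local; ``atom_map`` records the parent atom
    each local atom came from.  Attachment points are local atoms whose
    valence is intentionally unsaturated in the subgraph.
    """

    subgraph: MoleculeGraph
    atom_map: tuple[int, ...]
    subspectrum: tuple[tuple[int, float], ...]  # (local carbon index, shift)
    bits: ShiftBitset
    parent_id: str
    start_atom: int
    sphere: int

    @property
    def heavy_atom_count(self) -> int:
        return len(self.subgraph)

    def shifts(self) -> list[float]:
        return [s for _, s in self.subspectrum]

    def attachment_points(self) -> list[int]:
        """Local indices of atoms with unsatisfied valence (cut sites)."""
        from .chem_model import VALENCES

        out = []
        for i, atom in enumerate(self.subgraph.atoms):
            total = self.subgraph.bond_order_sum(i) + atom.attached_h
            if total not in VALENCES[atom.element]:
                out.append(i)
        return out

    def assigned_spectrum(self) -> AssignedSpectrum:
        entries = [
            (shift, self.subgraph.atoms[i].attached_h, i) for i, shift in self.subspectrum
        ]
        return AssignedSpectrum(signals=tuple(assign_equivalence(entries)))


def _ring_systems(graph: MoleculeGraph) -> list[set[int]]:
    """Fused ring systems = connected components of the non-bridge edges."""
    g = nx.Graph()
    g.add_nodes_from(range(len(graph)))
    g.add_edges_from((i, j) for i, j, _ in graph.bonds)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    ring_graph = nx.Graph()
    for i, j, _ in graph.bonds:
        if frozenset((i, j)) not in bridges:
            ring_graph.add_edge(i, j)
    return [set(c) for c in nx.connected_components(ring_graph)]


def _closure(graph: MoleculeGraph, included: set[int]) -> set[int]:
    """Apply the carbon-hetero preservation rule to a fixed point."""
    included = set(included)
    changed = True
    while changed:
        changed = False
        for i in list(included):
            for j, _ in graph.neighbors(i):
                if j in included:
                    continue
                ei, ej = graph.atoms[i].element, graph.atoms[j].element
                if (ei == "C") != (ej == "C"):  # carbon-hetero bond: never cut
                    included.add(j)
                    changed = True
    return included


def fragment_record(record: KbRecord, max_sphere: int = 3) -> list[Fragment]:
    """Grow one fragment series per heavy start atom, spheres 1..max_sphere."""
    if max_sphere < 1:
        raise ParameterError("max_sphere must be >= 1")
    graph = record.molecule
    shifts = record.shift_map()
    systems = _ring_systems(graph)
    fragments: list[Fragment] = []
    seen: set[tuple[str, tuple[float, ...]]] = set()
    for start in range(len(graph)):
        dist = graph.distances_from(start)
        start_system = next((s for s in systems if start in s), None)
        for sphere in range(1, max_sphere + 1):
            included = {i for i, d in enumerate(dist) if 0 <= d <= sphere}
            if start_system:
                included |= start_system
            included = _closure(graph, included)
            fragment = _build_fragment(record, sorted(included), shifts,
                                       start, sphere)
            key = (
                canonical_signature(fragment.subgraph, allow_open=True),
                tuple(sorted(fragment.shifts())),
            )
            if key in seen:
                continue
            seen.add(key)
            fragments.append(fragment)
    return fragments


def _build_fragment(record: KbRecord, atom_indices: list[int],
                    shifts: dict[int, float], start: int, sphere: int) -> Fragment:
    graph = record.molecule
    local = {old: new for new, old in enumerate(atom_indices)}
    atoms = [graph.atoms[i] for i in atom_indices]
    bonds = [
        (local[i], local[j], o)
        for i, j, o in graph.bonds
        if i in local and j in local
    ]
    sub = MoleculeGraph(atoms, bonds)
    subspectrum = tuple(
        (local[i], shifts[i]) for i in atom_indices if graph.atoms[i].element == "C"
    )
    return Fragment(
        subgraph=sub,
        atom_map=tuple(atom_indices),
        subspectrum=subspectrum,
        bits=subspectrum_bitset([s for _, s in subspectrum]),
        parent_id=record.identifier,
        start_atom=start,
        sphere=sphere,
    )


def screen_fragments(query_bits: ShiftBitset, library: list[Fragment],
                     bin_tolerance: int = 1) -> list[Fragment]:
    """Keep fragments whose bits are contained in the dilated query bits."""
    dilated = query_bits.dilated(bin_tolerance)
    return [f for f in library if dilated.contains(f.bits)]


def rank_fragments(candidates: list[Fragment], query: AssignedSpectrum,
                   params: MatchParams = MatchParams()) -> list[Fragment]:
    """Order by descending size, then spectral deviation, then parent id."""
    def key(fragment: Fragment):
        match = match_spectra(fragment.assigned_spectrum(), query, params)
        avg = match.average_deviation
        return (
            -fragment.heavy_atom_count,
            avg if avg is not None else float("inf"),
            fragment.parent_id,
            fragment.start_atom,
            fragment.sphere,
        )

    return sorted(candidates, key=key)
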