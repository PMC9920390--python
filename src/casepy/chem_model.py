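"""Molecular graphs, formulas, canonical signatures and spherical environment codes.

Everything downstream (knowledge base, generator, predictor) works on a single
kekulized heavy-atom graph model: each atom carries an element symbol and an
explicit attached-hydrogen count, each bond an integer order 1-3.  Aromaticity
is never stored; rings are always represented with alternating bond orders so
the structure generator, which assigns explicit orders, and the environment
encoder speak the same dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem

from .exceptions import FormulaParseError, ParameterError, ValidationError

# Accepted valence states per element; the first entry is the default used by
# the structure generator unless a problem explicitly widens it.
VALENCES: dict[str, tuple[int, ...]] = {
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "S": (2, 4, 6),
    "P": (3, 5),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
    "H": (1,),
}




def default_valence(element: str) -> int:
    try:
        return VALENCES[element][0]
    except KeyError:
        raise ValidationError(f"unsupported element: {element!r}") from None


# ---------------------------------------------------------------------------
# Molecular formula
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a neutral molecule, hydrogen explicit."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "MolecularFormula":
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def count(self, element: str) -> int:
        return self.as_dict().get(element, 0)

    @property
    def heavy_elements(self) -> frozenset[str]:
        return frozenset(el for el, n in self.counts if el != "H" and n > 0)

    @property
    def element_set(self) -> frozenset[str]:
        return frozenset(el for el, n in self.counts if n > 0)

    def heavy_counts(self) -> dict[str, int]:
        return {el: n for el, n in self.counts if el != "H"}

    def hill(self) -> str:
        """Canonical Hill notation (C, H first, then alphabetical)."""
        d = self.as_dict()
        parts = []
        if "C" in d:
            order = ["C"] + (["H"] if "H" in d else [])
            order += sorted(el for el in d if el not in ("C", "H"))
        else:
            order = sorted(d)
        for el in order:
            n = d[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style molecular formula such as ``C12H12O5``."""
    if not text or not text.strip():
        raise FormulaParseError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaParseError(f"malformed token at {text[pos:]!r} in {text!r}")
        element, digits = m.groups()
        if element not in VALENCES:
            raise FormulaParseError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula.from_dict(counts)


# ---------------------------------------------------------------------------
# Molecular graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    element: str
    attached_h: int = 0


class MoleculeGraph:
    """Simple undirected heavy-atom graph with integer bond orders.

    Formal charges, isotopes and radicals are unsupported by design; inputs
    carrying them are rejected at the conversion boundary.
    """

    __slots__ = ("atoms", "bonds", "_adj", "_aromatic")

    def __init__(self, atoms: Sequence[Atom], bonds: Iterable[tuple[int, int, int]]):
        self.atoms: tuple[Atom, ...] = tuple(atoms)
        norm: list[tuple[int, int, int]] = []
        seen: set[tuple[int, int]] = set()
        n = len(self.atoms)
        for i, j, order in bonds:
            if i == j:
                raise ValidationError(f"self-loop on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i},{j}) references a missing atom")
            if order not in (1, 2, 3):
                raise ValidationError(f"bond order {order} not in 1..3")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValidationError(f"parallel bond between atoms {i} and {j}")
            seen.add(key)
            norm.append((key[0], key[1], order))
        self.bonds: tuple[tuple[int, int, int], ...] = tuple(norm)
        adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        self._adj = tuple(tuple(a) for a in adj)
        self._aromatic: frozenset[tuple[int, int]] | None = None

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> tuple[tuple[int, int], ...]:
        """(neighbor index, bond order) pairs of atom *i*."""
        return self._adj[i]

    def bond_order_sum(self, i: int) -> int:
        return sum(order for _, order in self._adj[i])

    def heavy_degree(self, i: int) -> int:
        return len(self._adj[i])

    def carbons(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element == "C"]

    def formula(self) -> MolecularFormula:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
            counts["H"] = counts.get("H", 0) + a.attached_h
        return MolecularFormula.from_dict(counts)

    def element_set(self) -> frozenset[str]:
        return frozenset(a.element for a in self.atoms)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check per-atom valence completeness against the accepted states."""
        for i, atom in enumerate(self.atoms):
            if atom.element not in VALENCES:
                raise ValidationError(f"atom {i}: unsupported element {atom.element!r}")
            if atom.attached_h < 0:
                raise ValidationError(f"atom {i}: negative hydrogen count")
            total = self.bond_order_sum(i) + atom.attached_h
            if total not in VALENCES[atom.element]:
                raise ValidationError(
                    f"atom {i} ({atom.element}): valence {total} not in "
                    f"{VALENCES[atom.element]}"
                )

    def is_connected(self) -> bool:
        n = len(self.atoms)
        if n <= 1:
            return True
        seen = {0}
        stack = [0]
        while stack:
            for j, _ in self._adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n

    def distances_from(self, start: int) -> list[int]:
        """Heavy-atom graph distances (BFS); unreachable atoms get -1."""
        dist = [-1] * len(self.atoms)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for i in queue:
                for j, _ in self._adj[i]:
                    if dist[j] < 0:
                        dist[j] = dist[i] + 1
                        nxt.append(j)
            queue = nxt
        return dist

    def aromatic_bonds(self) -> frozenset[tuple[int, int]]:
        """Bonds of perceived aromatic rings, as sorted index pairs.

        Perception runs on the kekulized graph via RDKit; the stored bond
        orders stay untouched.  Used by the environment encoder so that the
        two Kekule patterns of a symmetric aromatic ring encode identically.
        """
        if self._aromatic is None:
            try:
                mol = self.to_rdkit()
                Chem.SetAromaticity(mol)
                pairs = frozenset(
                    (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                     max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
                    for b in mol.GetBonds() if b.GetIsAromatic()
                )
            except Exception:
                pairs = frozenset()
            self._aromatic = pairs
        return self._aromatic

    def permuted(self, order: Sequence[int]) -> "MoleculeGraph":
        """Return the same molecule with atoms re-indexed by *order*.

        ``order[k]`` is the old index that becomes new index ``k``.
        """
        inv = {old: new for new, old in enumerate(order)}
        atoms = [self.atoms[old] for old in order]
        bonds = [(inv[i], inv[j], o) for i, j, o in self.bonds]
        return MoleculeGraph(atoms, bonds)

    # -- RDKit bridge ------------------------------------------------------

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetNumExplicitHs(atom.attached_h)
            a.SetNoImplicit(True)
            mol.AddAtom(a)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        for i, j, order in self.bonds:
            mol.AddBond(i, j, order_map[order])
        m = mol.GetMol()
        m.UpdatePropertyCache(strict=False)
        Chem.GetSymmSSSR(m)
        return m

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MoleculeGraph":
        mol = Chem.Mol(mol)
        if any(b.GetIsAromatic() for b in mol.GetBonds()):
            Chem.Kekulize(mol, clearAromaticFlags=True)
        index_map: dict[int, int] = {}
        atoms: list[Atom] = []
        for a in mol.GetAtoms():
            if a.GetSymbol() == "H":
                continue
            if a.GetFormalCharge() != 0:
                raise ValidationError("charged atoms are not supported")
            if a.GetIsotope() != 0:
                raise ValidationError("isotope labels are not supported")
            index_map[a.GetIdx()] = len(atoms)
            atoms.append(Atom(a.GetSymbol(), a.GetTotalNumHs(includeNeighbors=True)))
        bonds = []
        for b in mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i not in index_map or j not in index_map:
                continue  # bond to an explicit hydrogen
            order = int(round(b.GetBondTypeAsDouble()))
            bonds.append((index_map[i], index_map[j], order))
        return cls(atoms, bonds)

    @classmethod
    def from_smiles(cls, smiles: str) -> "MoleculeGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValidationError(f"unparsable SMILES: {smiles!r}")
        return cls.from_rdkit(mol)

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


# ---------------------------------------------------------------------------
# Canonical signature
# ---------------------------------------------------------------------------


def canonical_signature(graph: MoleculeGraph, allow_open: bool = False) -> str:
    """Canonical string identifying a graph up to atom-index permutation.

    Two graphs get the same signature iff they are isomorphic at the
    heavy-atom + hydrogen-count + bond-order level (distinct Kekule patterns
    of an unsymmetric ring therefore stay distinct, matching the generator's
    bond-order semantics).  With ``allow_open`` unsaturated fragments are
    accepted; otherwise valences are validated first.
    """
    if not allow_open:
        graph.validate()
    return Chem.MolToSmiles(graph.to_rdkit())


# ---------------------------------------------------------------------------
# Hybridization
# ---------------------------------------------------------------------------


def hybridization_of(graph: MoleculeGraph, atom_index: int) -> str:
    """Classify an atom as ``sp``, ``sp2`` or ``sp3`` from its bond orders.

    All-single bonds mean sp3, exactly one double bond sp2, one triple or two
    double bonds sp.  Anything else is a valence inconsistency.
    """
    doubles = sum(1 for _, o in graph.neighbors(atom_index) if o == 2)
    triples = sum(1 for _, o in graph.neighbors(atom_index) if o == 3)
    if triples == 0 and doubles == 0:
        return "sp3"
    if triples == 0 and doubles == 1:
        return "sp2"
    if (triples == 1 and doubles == 0) or (triples == 0 and doubles == 2):
        return "sp"
    raise ValidationError(
        f"atom {atom_index}: inconsistent multiple-bond pattern "
        f"({doubles} double, {triples} triple)"
    )


# ---------------------------------------------------------------------------
# Spherical environment (HOSE) codes
# ---------------------------------------------------------------------------

MAX_SPHERES = 6

_BOND_SYMBOL = {1: "", 2: "=", 3: "#"}


@dataclass(frozen=True)
class HoseCode:
    text: str
    sphere_count: int
    center_element: str


def _atom_token(graph: MoleculeGraph, i: int) -> str:
    a = graph.atoms[i]
    return a.element + (f"H{a.attached_h}" if a.attached_h else "")


def _bond_symbol(aromatic: frozenset, i: int, j: int, order: int) -> str:
    if (min(i, j), max(i, j)) in aromatic:
        return "*"
    return _BOND_SYMBOL[order]


def _environment(graph: MoleculeGraph, i: int, parent: int, depth: int,
                 aromatic: frozenset) -> str:
    tok = _atom_token(graph, i)
    if depth == 0:
        return tok
    subs = sorted(
        _bond_symbol(aromatic, i, j, order) + _environment(graph, j, i, depth - 1, aromatic)
        for j, order in graph.neighbors(i)
        if j != parent
    )
    if not subs:
        return tok
    return tok + "(" + ",".join(subs) + ")"


def hose_code(graph: MoleculeGraph, atom_index: int, spheres: int) -> HoseCode:
    """Canonical spherical environment code of an atom.

    The code is a pure function of the graph structure around the center: at
    each node the outgoing branches are ordered by their own canonical
    sub-code, so automorphic atoms always receive identical strings and the
    encoding is invariant under atom re-indexing.  Branch exploration only
    excludes the immediate parent, so ring environments keep unfolding with
    the sphere count, which makes deeper codes strictly more specific lookup
    keys.  Spheres run from 1 (direct neighbors) to 6.
    """
    if not 1 <= spheres <= MAX_SPHERES:
        raise ParameterError(f"spheres must be within 1..{MAX_SPHERES}, got {spheres}")
    if not 0 <= atom_index < len(graph):
        raise ParameterError(f"atom index {atom_index} out of range")
    center = graph.atoms[atom_index]
    aromatic = graph.aromatic_bonds()
    head = f"{_atom_token(graph, atom_index)}-{graph.heavy_degree(atom_index) + center.attached_h}"
    branches = sorted(
        _bond_symbol(aromatic, atom_index, j, order)
        + _environment(graph, j, atom_index, spheres - 1, aromatic)
        for j, order in graph.neighbors(atom_index)
    )
    text = head + ";(" + ",".join(branches) + ")"
    return HoseCode(text=text, sphere_count=spheres, center_element=center.element)
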