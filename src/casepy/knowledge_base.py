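"""Structure-and-spectrum knowledge base.

A record couples a molecular graph with its assigned 13C spectrum.  Signals
with identical chemical shift and multiplicity are merged into one signal with
an equivalence index, so that the equivalence indices of a spectrum always sum
to the carbon count of the molecule.  From a set of records the module builds

* a per-sphere HOSE-code shift library (mean / count / min / max per code),
  consumed by the spectrum predictor, and
* an occurrence-statistics store keyed by (1-ppm shift bin, multiplicity,
  element set of the parent molecule), consumed by constraint detection.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from .chem_model import MAX_SPHERES, MoleculeGraph, hose_code, hybridization_of
from .exceptions import IngestionError, ValidationError

NUCLEUS_13C = "13C"


# ---------------------------------------------------------------------------
# Assigned spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssignedSignal:
    """One 13C signal: shift, attached-proton count, equivalence index."""

    shift: float
    multiplicity: int
    equivalence: int
    atom_indices: tuple[int, ...]

    def __post_init__(self):
        if self.equivalence != len(self.atom_indices):
            raise ValidationError(
                f"equivalence {self.equivalence} != {len(self.atom_indices)} assigned atoms"
            )
        if not 0 <= self.multiplicity <= 3:
            raise ValidationError(f"multiplicity {self.multiplicity} not in 0..3")


@dataclass(frozen=True)
class AssignedSpectrum:
    signals: tuple[AssignedSignal, ...]
    nucleus: str = NUCLEUS_13C
    solvent: str | None = None

    @property
    def equivalence_sum(self) -> int:
        return sum(s.equivalence for s in self.signals)

    def validate(self, molecule: MoleculeGraph | None = None) -> None:
        seen: set[tuple[float, int]] = set()
        assigned: set[int] = set()
        for s in self.signals:
            key = (s.shift, s.multiplicity)
            if key in seen:
                raise ValidationError(f"duplicate signal after grouping: {key}")
            seen.add(key)
            for idx in s.atom_indices:
                if idx in assigned:
                    raise ValidationError(f"atom {idx} assigned to two signals")
                assigned.add(idx)
        if molecule is not None:
            carbons = set(molecule.carbons())
            if assigned != carbons:
                raise ValidationError(
                    f"assigned atoms {sorted(assigned)} do not cover carbons {sorted(carbons)}"
                )
            for s in self.signals:
                for idx in s.atom_indices:
                    if molecule.atoms[idx].attached_h != s.multiplicity:
                        raise ValidationError(
                            f"atom {idx}: attached H {molecule.atoms[idx].attached_h} "
                            f"!= signal multiplicity {s.multiplicity}"
                        )


@dataclass(frozen=True)
class KbRecord:
    molecule: MoleculeGraph
    spectrum: AssignedSpectrum
    identifier: str = ""

    def shift_of(self, atom_index: int) -> float:
        for s in self.spectrum.signals:
            if atom_index in s.atom_indices:
                return s.shift
        raise KeyError(atom_index)

    def shift_map(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for s in self.spectrum.signals:
            for idx in s.atom_indices:
                out[idx] = s.shift
        return out


def assign_equivalence(
    shift_list: Sequence[tuple[float, int, int]]
) -> list[AssignedSignal]:
    """Merge per-atom (shift, multiplicity, atom index) entries into signals.

    Entries agreeing exactly in shift and multiplicity collapse into a single
    signal whose equivalence index is the number of merged atoms; order of
    first appearance is preserved.
    """
    seen_atoms: set[int] = set()
    groups: dict[tuple[float, int], list[int]] = {}
    order: list[tuple[float, int]] = []
    for shift, mult, atom_index in shift_list:
        if atom_index in seen_atoms:
            raise ValidationError(f"duplicate atom index {atom_index} in shift list")
        seen_atoms.add(atom_index)
        key = (shift, mult)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(atom_index)
    return [
        AssignedSignal(shift=k[0], multiplicity=k[1],
                       equivalence=len(groups[k]), atom_indices=tuple(groups[k]))
        for k in order
    ]


def ingest_record(
    molecule: MoleculeGraph,
    per_atom_shifts: Mapping[int, float],
    identifier: str = "",
    solvent: str | None = None,
) -> KbRecord:
    """Build a validated record from a molecule and its per-carbon shifts."""
    molecule.validate()
    carbons = molecule.carbons()
    if not carbons:
        raise IngestionError("record has no carbon atoms")
    missing = [i for i in carbons if i not in per_atom_shifts]
    if missing:
        raise IngestionError(f"missing 13C shift for carbon atoms {missing}")
    entries = []
    for i in carbons:
        h = molecule.atoms[i].attached_h
        if h > 3:
            raise IngestionError(f"carbon {i} carries {h} protons (multiplicity > 3)")
        entries.append((float(per_atom_shifts[i]), h, i))
    spectrum = AssignedSpectrum(signals=tuple(assign_equivalence(entries)), solvent=solvent)
    spectrum.validate(molecule)
    record = KbRecord(molecule=molecule, spectrum=spectrum, identifier=identifier)
    return record


# ---------------------------------------------------------------------------
# HOSE-code shift library
# ---------------------------------------------------------------------------


@dataclass
class LibraryEntry:
    count: int
    shift_sum: float
    min_shift: float
    max_shift: float

    @property
    def mean_shift(self) -> float:
        # clamp: summation round-off must not push the mean outside the range
        return min(max(self.shift_sum / self.count, self.min_shift), self.max_shift)

    def add(self, shift: float) -> None:
        self.count += 1
        self.shift_sum += shift
        self.min_shift = min(self.min_shift, shift)
        self.max_shift = max(self.max_shift, shift)


class HoseLibrary:
    """Per-sphere map from environment code to aggregated shift statistics."""

    VERSION = 1

    def __init__(self, max_sphere: int = MAX_SPHERES):
        if not 1 <= max_sphere <= MAX_SPHERES:
            raise ValidationError(f"max_sphere must be in 1..{MAX_SPHERES}")
        self.max_sphere = max_sphere
        self.spheres: dict[int, dict[str, LibraryEntry]] = {
            s: {} for s in range(1, max_sphere + 1)
        }

    def add(self, sphere: int, code: str, shift: float) -> None:
        table = self.spheres[sphere]
        entry = table.get(code)
        if entry is None:
            table[code] = LibraryEntry(1, shift, shift, shift)
        else:
            entry.add(shift)

    def lookup(self, sphere: int, code: str) -> LibraryEntry | None:
        return self.spheres.get(sphere, {}).get(code)

    def entry_count(self, sphere: int) -> int:
        return sum(e.count for e in self.spheres.get(sphere, {}).values())

    def remove_sphere(self, sphere: int) -> None:
        """Drop all entries of one sphere (used to exercise prediction fallback)."""
        self.spheres[sphere] = {}

    def to_json(self) -> str:
        doc = {
            "version": self.VERSION,
            "max_sphere": self.max_sphere,
            "spheres": {
                str(s): {
                    code: [e.count, e.shift_sum, e.min_shift, e.max_shift]
                    for code, e in sorted(table.items())
                }
                for s, table in self.spheres.items()
            },
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HoseLibrary":
        doc = json.loads(text)
        lib = cls(max_sphere=doc["max_sphere"])
        for s, table in doc["spheres"].items():
            for code, (count, ssum, mn, mx) in table.items():
                lib.spheres[int(s)][code] = LibraryEntry(count, ssum, mn, mx)
        return lib


def build_hose_library(records: Iterable[KbRecord], max_sphere: int = MAX_SPHERES) -> HoseLibrary:
    """Aggregate every carbon of every record into per-sphere code entries."""
    lib = HoseLibrary(max_sphere=max_sphere)
    for record in records:
        shifts = record.shift_map()
        for i in record.molecule.carbons():
            for sphere in range(1, max_sphere + 1):
                code = hose_code(record.molecule, i, sphere)
                lib.add(sphere, code.text, shifts[i])
    return lib


# ---------------------------------------------------------------------------
# Occurrence statistics
# ---------------------------------------------------------------------------


def shift_bin(shift: float) -> int:
    """1-ppm statistics bin of a chemical shift (floor)."""
    import math

    return math.floor(shift)


StatKey = tuple[int, int, frozenset[str]]


class StatsStore:
    """Hybridization / neighbour-element / hetero-hetero-bond occurrence counts.

    Keys are (1-ppm shift bin, multiplicity, element set of the parent
    molecule).  Queries aggregate over all stored keys whose element set is a
    subset of the query formula's element set, so sparse compositions still
    contribute.
    """

    VERSION = 1

    def __init__(self):
        self.hybridization: dict[StatKey, Counter] = {}
        self.neighbours: dict[StatKey, Counter] = {}
        self.observations: dict[StatKey, int] = {}
        # per element set: [hetero-hetero bond count, total bond count]
        self.hhb: dict[frozenset[str], list[int]] = {}

    # -- accumulation ------------------------------------------------------

    def observe_carbon(
        self, key: StatKey, hybridization: str, neighbour_elements: Iterable[str]
    ) -> None:
        self.hybridization.setdefault(key, Counter())[hybridization] += 1
        nb = self.neighbours.setdefault(key, Counter())
        for el in set(neighbour_elements):
            nb[el] += 1
        self.observations[key] = self.observations.get(key, 0) + 1

    def observe_bonds(self, element_set: frozenset[str], hetero_hetero: int, total: int) -> None:
        acc = self.hhb.setdefault(element_set, [0, 0])
        acc[0] += hetero_hetero
        acc[1] += total

    def merge(self, other: "StatsStore") -> "StatsStore":
        out = StatsStore()
        for src in (self, other):
            for key, counter in src.hybridization.items():
                out.hybridization.setdefault(key, Counter()).update(counter)
            for key, counter in src.neighbours.items():
                out.neighbours.setdefault(key, Counter()).update(counter)
            for key, n in src.observations.items():
                out.observations[key] = out.observations.get(key, 0) + n
            for es, (h, t) in src.hhb.items():
                out.observe_bonds(es, h, t)
        return out

    # -- aggregated queries ------------------------------------------------

    def _matching_keys(self, shift: float, multiplicity: int,
                       element_set: frozenset[str]) -> list[StatKey]:
        b = shift_bin(shift)
        return [
            key for key in self.observations
            if key[0] == b and key[1] == multiplicity and key[2] <= element_set
        ]

    def query_hybridization(self, shift: float, multiplicity: int,
                            element_set: frozenset[str]) -> tuple[Counter, int]:
        counts: Counter = Counter()
        total = 0
        for key in self._matching_keys(shift, multiplicity, element_set):
            counts.update(self.hybridization.get(key, Counter()))
            total += self.observations[key]
        return counts, total

    def query_neighbours(self, shift: float, multiplicity: int,
                         element_set: frozenset[str]) -> tuple[Counter, int]:
        counts: Counter = Counter()
        total = 0
        for key in self._matching_keys(shift, multiplicity, element_set):
            counts.update(self.neighbours.get(key, Counter()))
            total += self.observations[key]
        return counts, total

    def query_hhb(self, element_set: frozenset[str]) -> tuple[int, int]:
        hetero = total = 0
        for es, (h, t) in self.hhb.items():
            if es <= element_set:
                hetero += h
                total += t
        return hetero, total

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        def key_str(key: StatKey) -> str:
            return f"{key[0]}|{key[1]}|{','.join(sorted(key[2]))}"

        doc = {
            "version": self.VERSION,
            "hybridization": {key_str(k): dict(c) for k, c in self.hybridization.items()},
            "neighbours": {key_str(k): dict(c) for k, c in self.neighbours.items()},
            "observations": {key_str(k): n for k, n in self.observations.items()},
            "hhb": {",".join(sorted(es)): v for es, v in self.hhb.items()},
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StatsStore":
        doc = json.loads(text)

        def parse_key(s: str) -> StatKey:
            b, m, els = s.split("|")
            return int(b), int(m), frozenset(e for e in els.split(",") if e)

        store = cls()
        for k, c in doc["hybridization"].items():
            store.hybridization[parse_key(k)] = Counter(c)
        for k, c in doc["neighbours"].items():
            store.neighbours[parse_key(k)] = Counter(c)
        for k, n in doc["observations"].items():
            store.observations[parse_key(k)] = n
        for els, v in doc["hhb"].items():
            store.hhb[frozenset(e for e in els.split(",") if e)] = list(v)
        return store


def accumulate_statistics(records: Iterable[KbRecord]) -> StatsStore:
    """Count hybridizations, neighbour elements and hetero-hetero bonds."""
    store = StatsStore()
    for record in records:
        mol = record.molecule
        element_set = mol.element_set()
        shifts = record.shift_map()
        for i in mol.carbons():
            key: StatKey = (shift_bin(shifts[i]), mol.atoms[i].attached_h, element_set)
            neighbour_elements = [mol.atoms[j].element for j, _ in mol.neighbors(i)]
            store.observe_carbon(key, hybridization_of(mol, i), neighbour_elements)
        hetero = sum(
            1 for i, j, _ in mol.bonds
            if mol.atoms[i].element != "C" and mol.atoms[j].element != "C"
        )
        store.observe_bonds(element_set, hetero, len(mol.bonds))
    return store


# ---------------------------------------------------------------------------
# Assigned-SDF I/O
# ---------------------------------------------------------------------------

SDF_SHIFT_PROPERTY = "CS_13C"


def write_assigned_sdf(records: Iterable[KbRecord], path: str) -> None:
    """Write records as a V2000 SDF with per-atom shifts in ``CS_13C`` lines."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for record in records:
            mol = record.molecule.to_rdkit()
            mol.SetProp("_Name", record.identifier)
            lines = [f"{i}:{shift}" for i, shift in sorted(record.shift_map().items())]
            mol.SetProp(SDF_SHIFT_PROPERTY, "\n".join(lines))
            if record.spectrum.solvent:
                mol.SetProp("SOLVENT", record.spectrum.solvent)
            writer.write(mol)
    finally:
        writer.close()


def read_assigned_sdf(path: str) -> list[KbRecord]:
    """Read records written by :func:`write_assigned_sdf` (lossless round-trip)."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    records: list[KbRecord] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise IngestionError(f"record {idx}: unreadable SDF block")
        # sanitize without aromaticity perception so stored Kekule bond orders
        # survive the round-trip unchanged
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        )
        if not mol.HasProp(SDF_SHIFT_PROPERTY):
            raise IngestionError(
                f"record {idx} ({mol.GetProp('_Name') if mol.HasProp('_Name') else '?'}): "
                f"missing {SDF_SHIFT_PROPERTY} property"
            )
        graph = MoleculeGraph.from_rdkit(mol)
        shifts: dict[int, float] = {}
        for line in mol.GetProp(SDF_SHIFT_PROPERTY).splitlines():
            line = line.strip()
            if not line:
                continue
            try:
                key, value = line.split(":")
                shifts[int(key)] = float(value)
            except ValueError:
                raise IngestionError(f"record {idx}: malformed shift line {line!r}") from None
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        solvent = mol.GetProp("SOLVENT") if mol.HasProp("SOLVENT") else None
        records.append(ingest_record(graph, shifts, identifier=name, solvent=solvent))
    return records


# ---------------------------------------------------------------------------
# Record JSON serialization (used by the CLI)
# ---------------------------------------------------------------------------


def records_to_json(records: Iterable[KbRecord]) -> str:
    docs = []
    for r in records:
        docs.append({
            "identifier": r.identifier,
            "atoms": [[a.element, a.attached_h] for a in r.molecule.atoms],
            "bonds": [list(b) for b in r.molecule.bonds],
            "shifts": {str(i): s for i, s in sorted(r.shift_map().items())},
            "solvent": r.spectrum.solvent,
        })
    return json.dumps({"version": 1, "records": docs})


def records_from_json(text: str) -> list[KbRecord]:
    from .chem_model import Atom

    doc = json.loads(text)
    records = []
    for d in doc["records"]:
        graph = MoleculeGraph(
            [Atom(el, h) for el, h in d["atoms"]],
            [tuple(b) for b in d["bonds"]],
        )
        shifts = {int(k): v for k, v in d["shifts"].items()}
        records.append(ingest_record(graph, shifts, identifier=d.get("identifier", ""),
                                     solvent=d.get("solvent")))
    return records
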