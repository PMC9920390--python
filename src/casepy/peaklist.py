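"""Peak-list documents: the JSON interchange format for query data.

A document carries the molecular formula, the 13C signal rows, proton
ranges, and the HSQC/HMBC/COSY correlation lists.  Multiplicity-edited HSQC
signs are translated on read: a negative peak (``-``) means CH2, a positive
peak (``+``) means CH or CH3 and stays ambiguous ({1, 3}) unless a ``protons``
field resolves it.  Signal rows tagged with a kind other than ``signal``
(solvent, impurity, ...) are excluded from correlation extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .chem_model import MolecularFormula, parse_formula
from .exceptions import PeakListError
from .structure_generation import CarbonSignal, CorrelationSet, ProtonGroup

SCHEMA = "casepy-peaklist/1"


@dataclass(frozen=True)
class PeakListDocument:
    """A schema-validated peak-list document plus its raw JSON payload."""

    raw: dict

    @property
    def formula(self) -> MolecularFormula:
        return parse_formula(self.raw["mf"])

    def correlations(self) -> CorrelationSet:
        return _extract_correlations(self.raw)


def _require(condition: bool, pointer: str, message: str) -> None:
    if not condition:
        raise PeakListError(f"{pointer}: {message}")


def _validate(doc: dict) -> None:
    _require(isinstance(doc, dict), "/", "document must be a JSON object")
    _require(doc.get("schema") == SCHEMA, "/schema", f"expected {SCHEMA!r}")
    _require(isinstance(doc.get("mf"), str), "/mf", "molecular formula string required")
    _require(isinstance(doc.get("c13"), list), "/c13", "13C signal list required")
    for i, row in enumerate(doc["c13"]):
        _require("id" in row, f"/c13/{i}", "missing signal id")
        _require(isinstance(row.get("shift"), (int, float)), f"/c13/{i}/shift",
                 "numeric shift required")
    for section in ("h1", "hsqc", "hmbc", "cosy", "hetero_attachments"):
        if section in doc:
            _require(isinstance(doc[section], list), f"/{section}", "must be a list")


def _multiplicity(row: dict, hsqc_rows: list[dict]):
    if "multiplicity" in row and row["multiplicity"] is not None:
        return int(row["multiplicity"])
    for h in hsqc_rows:
        if h.get("carbon") != row["id"]:
            continue
        sign = h.get("sign")
        if sign == "-":
            return 2
        if sign == "+":
            if "protons" in h and h["protons"] is not None:
                return int(h["protons"])
            return frozenset({1, 3})
        return None
    return 0  # no HSQC partner: quaternary carbon


def _extract_correlations(doc: dict) -> CorrelationSet:
    hsqc_rows = doc.get("hsqc", [])
    carbons = []
    active_ids = set()
    for row in doc["c13"]:
        if row.get("kind", "signal") != "signal":
            continue
        active_ids.add(row["id"])
        carbons.append(CarbonSignal(
            id=row["id"], shift=float(row["shift"]),
            multiplicity=_multiplicity(row, hsqc_rows),
        ))
    protons = tuple(
        ProtonGroup(id=r["id"], shift=float(r["shift"]),
                    integral=float(r.get("integral", 1.0)))
        for r in doc.get("h1", [])
    )
    hsqc = tuple(
        (r["proton"], r["carbon"]) for r in hsqc_rows if r.get("carbon") in active_ids
    )
    hmbc = tuple(
        (r["proton"], r["target"])
        for r in doc.get("hmbc", [])
        if r.get("target") in active_ids
    )
    cosy = tuple((r["a"], r["b"]) for r in doc.get("cosy", []))
    hetero = tuple(
        (r["proton"], r["element"]) for r in doc.get("hetero_attachments", [])
    )
    return CorrelationSet(
        carbons=tuple(carbons), proton_groups=protons,
        hsqc=hsqc, hmbc=hmbc, cosy=cosy, hetero_attachments=hetero,
    )


def query_spectrum(correlations: CorrelationSet):
    """Build the query 13C spectrum from the correlation table.

    Mirrors the manual workflow for edited-HSQC data: an unresolved CH/CH3
    ambiguity is set to CH (the common resolution when no 3H integral
    exists), and carbons without any multiplicity information count as
    quaternary.  Rows sharing shift and multiplicity merge into one signal
    with the corresponding equivalence index.
    """
    from .knowledge_base import AssignedSpectrum, assign_equivalence

    entries = []
    for k, c in enumerate(correlations.carbons):
        if isinstance(c.multiplicity, int):
            mult = c.multiplicity
        elif isinstance(c.multiplicity, frozenset):
            mult = min(c.multiplicity)
        else:
            mult = 0
        entries.append((c.shift, mult, k))
    return AssignedSpectrum(signals=tuple(assign_equivalence(entries)))


def read_document(path) -> PeakListDocument:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise PeakListError(f"/: invalid JSON ({exc})") from exc
    _validate(doc)
    return PeakListDocument(raw=doc)


def read_peaklist(path) -> tuple[CorrelationSet, MolecularFormula]:
    """Load a peak-list document into (correlations, molecular formula)."""
    document = read_document(path)
    return document.correlations(), document.formula


def write_peaklist(document: PeakListDocument, path) -> None:
    """Write a document back out (lossless: the raw payload is preserved)."""
    Path(path).write_text(json.dumps(document.raw, indent=2, sort_keys=True) + "\n")
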