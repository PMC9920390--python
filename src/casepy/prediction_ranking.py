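"""HOSE-library 13C shift prediction with sphere fallback, and candidate ranking.

Each carbon of a candidate structure is predicted by looking its environment
code up in the library at the highest available sphere, falling back sphere by
sphere (6 -> 1) until an entry exists; a carbon whose environment is unknown
at every sphere stays unpredicted (sphere 0) and is excluded from matching.
Candidates are ranked by the average deviation between their predicted
spectrum and the query, ties broken by descending matched-signal count, and
the list is truncated to a configurable cap (500 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem_model import MoleculeGraph, canonical_signature, hose_code
from .dereplication import MatchParams, SpectrumMatch, match_spectra
from .knowledge_base import AssignedSpectrum, HoseLibrary, assign_equivalence


@dataclass(frozen=True)
class AtomPrediction:
    """Prediction metadata for one carbon atom."""

    atom_index: int
    shift: float | None            # None = unpredicted
    sphere_used: int               # 0 when unpredicted
    entry_count: int
    shift_range: tuple[float, float] | None

    @property
    def predicted(self) -> bool:
        return self.shift is not None


@dataclass(frozen=True)
class PredictedSpectrum:
    per_atom: tuple[AtomPrediction, ...]

    @property
    def predicted_atoms(self) -> tuple[AtomPrediction, ...]:
        return tuple(p for p in self.per_atom if p.predicted)

    @property
    def unpredicted_atoms(self) -> tuple[int, ...]:
        return tuple(p.atom_index for p in self.per_atom if not p.predicted)

    def assigned_spectrum(self, molecule: MoleculeGraph) -> AssignedSpectrum:
        """Equivalence-grouped signal list over the predicted carbons."""
        entries = [
            (p.shift, molecule.atoms[p.atom_index].attached_h, p.atom_index)
            for p in self.per_atom
            if p.predicted
        ]
        return AssignedSpectrum(signals=tuple(assign_equivalence(entries)))


def predict_spectrum(molecule: MoleculeGraph, library: HoseLibrary,
                     max_sphere: int = 6) -> PredictedSpectrum:
    """Predict every carbon from the library with sphere fallback."""
    top = min(max_sphere, library.max_sphere)
    predictions = []
    for i in molecule.carbons():
        found = None
        for sphere in range(top, 0, -1):
            code = hose_code(molecule, i, sphere)
            entry = library.lookup(sphere, code.text)
            if entry is not None:
                found = AtomPrediction(
                    atom_index=i,
                    shift=entry.mean_shift,
                    sphere_used=sphere,
                    entry_count=entry.count,
                    shift_range=(entry.min_shift, entry.max_shift),
                )
                break
        if found is None:
            found = AtomPrediction(atom_index=i, shift=None, sphere_used=0,
                                   entry_count=0, shift_range=None)
        predictions.append(found)
    return PredictedSpectrum(per_atom=tuple(predictions))


@dataclass(frozen=True)
class RankedCandidate:
    structure: MoleculeGraph
    prediction: PredictedSpectrum
    match: SpectrumMatch
    average_deviation: float | None
    matched_signals: tuple[int, int]   # (paired, total query signals)


@dataclass
class RankingResult:
    candidates: list[RankedCandidate]
    truncated: bool = False

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)


def rank_candidates(candidates: list[MoleculeGraph], query: AssignedSpectrum,
                    library: HoseLibrary, params: MatchParams = MatchParams(),
                    limit: int = 500, max_sphere: int = 6) -> RankingResult:
    """Predict, match against the query, and sort candidates.

    Ordering: ascending average deviation over matched pairs, then descending
    paired count (coverage), then canonical signature for a stable total
    order.  Candidates whose carbons are partly unpredicted are ranked on the
    predicted subset; ``matched_signals`` exposes the coverage.
    """
    ranked: list[tuple[tuple, RankedCandidate]] = []
    for structure in candidates:
        prediction = predict_spectrum(structure, library, max_sphere=max_sphere)
        predicted = prediction.assigned_spectrum(structure)
        match = match_spectra(query, predicted, params)
        avg = match.average_deviation
        candidate = RankedCandidate(
            structure=structure,
            prediction=prediction,
            match=match,
            average_deviation=avg,
            matched_signals=(match.paired_count, len(query.signals)),
        )
        key = (
            avg if avg is not None else float("inf"),
            -match.paired_count,
            canonical_signature(structure, allow_open=True),
        )
        ranked.append((key, candidate))
    ranked.sort(key=lambda t: t[0])
    truncated = len(ranked) > limit
    return RankingResult(candidates=[c for _, c in ranked[:limit]], truncated=truncated)
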