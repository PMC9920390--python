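"""Spectrum matching and database dereplication.

Two 13C spectra are compared by pairing signals whose shifts agree within a
tolerance (optionally requiring equal multiplicity and/or equivalence), using
a greedy closest-first unique assignment.  The distance between two spectra is
the mean absolute shift difference over the matched pairs only; unmatched
signals are reported but do not enter the distance.  The same matcher ranks
fragments and generated candidates elsewhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exceptions import ParameterError, ValidationError
from .knowledge_base import AssignedSpectrum, KbRecord


@dataclass(frozen=True)
class MatchParams:
    shift_tolerance: float = 2.0
    max_average_deviation: float = 1.0
    check_multiplicity: bool = True
    check_equivalence: bool = False
    min_match_ratio: float = 1.0

    def __post_init__(self):
        if self.shift_tolerance <= 0:
            raise ParameterError("shift_tolerance must be > 0")
        if not 0 < self.min_match_ratio <= 1:
            raise ParameterError("min_match_ratio must be in (0, 1]")


@dataclass(frozen=True)
class SpectrumMatch:
    """Result of pairing a query spectrum against a reference spectrum."""

    pairs: tuple[tuple[int, int, float], ...]  # (query idx, reference idx, |delta|)
    unpaired_query: tuple[int, ...]
    unpaired_reference: tuple[int, ...]

    @property
    def average_deviation(self) -> float | None:
        if not self.pairs:
            return None
        return sum(d for _, _, d in self.pairs) / len(self.pairs)

    @property
    def paired_count(self) -> int:
        return len(self.pairs)


def match_spectra(query: AssignedSpectrum, reference: AssignedSpectrum,
                  params: MatchParams = MatchParams()) -> SpectrumMatch:
    """Greedy closest-first unique matching of valid signal pairs."""
    if query.nucleus != reference.nucleus:
        raise ValidationError(
            f"nucleus mismatch: {query.nucleus} vs {reference.nucleus}"
        )
    candidates: list[tuple[float, int, int]] = []
    for qi, qs in enumerate(query.signals):
        for ri, rs in enumerate(reference.signals):
            if params.check_multiplicity and qs.multiplicity != rs.multiplicity:
                continue
            if params.check_equivalence and qs.equivalence != rs.equivalence:
                continue
            dev = abs(qs.shift - rs.shift)
            if dev <= params.shift_tolerance:
                candidates.append((dev, qi, ri))
    candidates.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for dev, qi, ri in candidates:
        if qi in used_q or ri in used_r:
            continue
        used_q.add(qi)
        used_r.add(ri)
        pairs.append((qi, ri, dev))
    pairs.sort()
    return SpectrumMatch(
        pairs=tuple(pairs),
        unpaired_query=tuple(i for i in range(len(query.signals)) if i not in used_q),
        unpaired_reference=tuple(i for i in range(len(reference.signals)) if i not in used_r),
    )


def dereplicate(query: AssignedSpectrum, kb: list[KbRecord],
                params: MatchParams = MatchParams()) -> list[tuple[KbRecord, SpectrumMatch]]:
    """Rank knowledge-base records by spectral distance to the query.

    A record is a hit when at least ``min_match_ratio`` of the query signals
    are paired and the average deviation stays within
    ``max_average_deviation``.  Hits are sorted by ascending deviation, ties
    by descending paired count, then by reference-side coverage (a reference
    spectrum fully explained by the query beats one with leftover signals —
    this separates a compound from extensions that embed its spectrum), then
    identifier.
    """
    if not kb:
        warnings.warn("dereplication against an empty knowledge base", stacklevel=2)
        return []
    hits: list[tuple[KbRecord, SpectrumMatch]] = []
    n_query = len(query.signals)
    for record in kb:
        match = match_spectra(query, record.spectrum, params)
        if n_query == 0 or match.paired_count / n_query < params.min_match_ratio:
            continue
        avg = match.average_deviation
        if avg is None or avg > params.max_average_deviation:
            continue
        hits.append((record, match))
    hits.sort(key=lambda h: (h[1].average_deviation, -h[1].paired_count,
                             len(h[1].unpaired_reference), h[0].identifier))
    return hits
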