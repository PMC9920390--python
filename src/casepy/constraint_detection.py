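"""Statistics-driven detection of structural constraints.

For every query 13C signal the knowledge-base statistics are interrogated at
the (1-ppm shift bin, multiplicity, element-set) key to decide which
hybridization states are plausible and which neighbour elements are
forbidden or mandatory.  Occurrence fractions below a lower threshold (1% by
default) discard a hybridization or forbid a neighbour element; fractions at
or above an upper threshold (95% by default) make a neighbour mandatory.  A
hetero-hetero bond is only permitted when such bonds reach a minimal
occurrence (1% by default) among all bonds of molecules with a compatible
element set.  All thresholds are overridable per run, which reproduces the
stricter 0.1%/100% setting occasionally needed for unusual chemistry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .chem_model import MolecularFormula
from .exceptions import ParameterError
from .knowledge_base import StatsStore

ALL_HYBRIDIZATIONS = frozenset({"sp", "sp2", "sp3"})


@dataclass(frozen=True)
class DetectionParams:
    hybridization_min_occurrence: float = 0.01
    neighbour_lower_bound: float = 0.01
    neighbour_upper_bound: float = 0.95
    hhb_min_occurrence: float = 0.01

    def __post_init__(self):
        for name in ("hybridization_min_occurrence", "neighbour_lower_bound",
                     "neighbour_upper_bound", "hhb_min_occurrence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be within [0, 1], got {v}")
        if self.neighbour_lower_bound > self.neighbour_upper_bound:
            raise ParameterError("neighbour_lower_bound must not exceed neighbour_upper_bound")


@dataclass(frozen=True)
class AtomConstraint:
    """Detected constraints attached to one query 13C signal."""

    signal_id: str
    hybridizations: frozenset[str]
    forbidden_neighbours: frozenset[str]
    mandatory_neighbours: frozenset[str]

    def __post_init__(self):
        if self.mandatory_neighbours & self.forbidden_neighbours:
            raise ParameterError("mandatory and forbidden neighbour sets overlap")


def detect_hybridizations(shift: float, multiplicity: int, mf: MolecularFormula,
                          stats: StatsStore,
                          params: DetectionParams = DetectionParams()) -> frozenset[str]:
    """Hybridization states whose occurrence fraction reaches the threshold.

    With no statistics at the key, all three states are returned (with a
    warning) so detection never renders a problem infeasible by silence.
    """
    counts, total = stats.query_hybridization(shift, multiplicity, mf.element_set)
    if total == 0 or not counts:
        warnings.warn(
            f"no hybridization statistics at {shift:.1f} ppm / {multiplicity}H; "
            "keeping all states", stacklevel=2)
        return ALL_HYBRIDIZATIONS
    observed = sum(counts.values())
    return frozenset(
        state for state, n in counts.items()
        if n / observed >= params.hybridization_min_occurrence
    )


def detect_neighbours(shift: float, multiplicity: int, mf: MolecularFormula,
                      stats: StatsStore,
                      params: DetectionParams = DetectionParams()
                      ) -> tuple[frozenset[str], frozenset[str]]:
    """(forbidden, mandatory) neighbour element sets for a query signal.

    Candidate elements are the heavy elements of the query formula; hydrogen
    is encoded by the multiplicity and never appears here.  An element seen
    on fewer than the lower-bound fraction of carbons at the key is
    forbidden; one seen on at least the upper-bound fraction is mandatory.
    """
    counts, total = stats.query_neighbours(shift, multiplicity, mf.element_set)
    if total == 0:
        return frozenset(), frozenset()
    forbidden: set[str] = set()
    mandatory: set[str] = set()
    for element in mf.heavy_elements:
        fraction = counts.get(element, 0) / total
        if fraction < params.neighbour_lower_bound:
            forbidden.add(element)
        elif fraction >= params.neighbour_upper_bound:
            mandatory.add(element)
    return frozenset(forbidden), frozenset(mandatory)


def detect_hhb(mf: MolecularFormula, stats: StatsStore,
               params: DetectionParams = DetectionParams()) -> bool:
    """Whether bonds between two non-carbon heavy atoms are allowed."""
    hetero, total = stats.query_hhb(mf.element_set)
    if total == 0:
        return False
    return hetero / total >= params.hhb_min_occurrence


def detect_constraints(signals, mf: MolecularFormula, stats: StatsStore,
                       params: DetectionParams = DetectionParams()
                       ) -> list[AtomConstraint]:
    """Run hybridization and neighbour detection for a list of query signals.

    ``signals`` is an iterable of (signal id, shift, multiplicity) triples,
    typically the carbon rows of a correlation table.
    """
    constraints = []
    for signal_id, shift, multiplicity in signals:
        if not isinstance(multiplicity, int):
            # ambiguous multiplicity: skip statistics, keep everything open
            constraints.append(AtomConstraint(
                signal_id=signal_id,
                hybridizations=ALL_HYBRIDIZATIONS,
                forbidden_neighbours=frozenset(),
                mandatory_neighbours=frozenset(),
            ))
            continue
        hyb = detect_hybridizations(shift, multiplicity, mf, stats, params)
        forbidden, mandatory = detect_neighbours(shift, multiplicity, mf, stats, params)
        constraints.append(AtomConstraint(
            signal_id=signal_id,
            hybridizations=hyb,
            forbidden_neighbours=forbidden,
            mandatory_neighbours=mandatory,
        ))
    return constraints
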