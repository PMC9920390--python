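"""Threshold semantics of statistics-driven constraint detection."""

import random

import pytest

from casepy.chem_model import parse_formula
from casepy.constraint_detection import (
    ALL_HYBRIDIZATIONS,
    DetectionParams,
    detect_hhb,
    detect_hybridizations,
    detect_neighbours,
)
from casepy.exceptions import ParameterError
from casepy.knowledge_base import StatsStore, accumulate_statistics


def synthetic_store(hyb_counts, nbr_counts, total, element_set=frozenset({"C", "H", "O", "N"}),
                    bin_=128, mult=1, hhb=(0, 0)):
    store = StatsStore()
    key = (bin_, mult, element_set)
    for state, n in hyb_counts.items():
        store.hybridization.setdefault(key, __import__("collections").Counter())[state] = n
    for el, n in nbr_counts.items():
        store.neighbours.setdefault(key, __import__("collections").Counter())[el] = n
    store.observations[key] = total
    store.hhb[element_set] = list(hhb)
    return store


MF = parse_formula("C10H12N2O3")


def test_hybridization_threshold_discard():
    store = synthetic_store({"sp2": 95, "sp3": 5}, {}, 100)
    assert detect_hybridizations(128.5, 1, MF, store) == frozenset({"sp2", "sp3"})
    strict = DetectionParams(hybridization_min_occurrence=0.10)
    assert detect_hybridizations(128.5, 1, MF, store, strict) == frozenset({"sp2"})


def test_hybridization_singleton_any_threshold():
    store = synthetic_store({"sp2": 40}, {}, 40)
    for threshold in (0.001, 0.5, 1.0):
        params = DetectionParams(hybridization_min_occurrence=threshold)
        assert detect_hybridizations(128.5, 1, MF, store, params) == frozenset({"sp2"})


def test_hybridization_empty_fallback():
    store = StatsStore()
    with pytest.warns(UserWarning):
        assert detect_hybridizations(10.0, 3, MF, store) == ALL_HYBRIDIZATIONS


def test_neighbour_bounds():
    # carbinol-like key: O on 97% of carbons, C on 99%, N never seen
    store = synthetic_store({}, {"O": 97, "C": 99}, 100)
    forbidden, mandatory = detect_neighbours(128.5, 1, MF, store)
    assert mandatory == frozenset({"O", "C"})
    assert forbidden == frozenset({"N"})


def test_neighbour_between_bounds_unconstrained():
    store = synthetic_store({}, {"O": 50, "C": 60, "N": 30}, 100)
    assert detect_neighbours(128.5, 1, MF, store) == (frozenset(), frozenset())


def test_neighbour_override_to_strictest():
    # the 0.1% / 100% override: mandatory only at full occurrence
    store = synthetic_store({}, {"O": 99, "C": 100, "N": 1}, 100)
    params = DetectionParams(neighbour_lower_bound=0.001, neighbour_upper_bound=1.0)
    forbidden, mandatory = detect_neighbours(128.5, 1, MF, store, params)
    assert mandatory == frozenset({"C"})
    assert forbidden == frozenset()


def test_hhb_threshold():
    low = synthetic_store({}, {}, 1, hhb=(5, 1000))   # 0.5% < 1%
    high = synthetic_store({}, {}, 1, hhb=(20, 1000))  # 2% >= 1%
    assert detect_hhb(MF, low) is False
    assert detect_hhb(MF, high) is True
    permissive = DetectionParams(hhb_min_occurrence=0.001)
    assert detect_hhb(MF, low, permissive) is True


def test_hhb_absent_in_hetero_free_kb(fixture_kb):
    stats = accumulate_statistics(
        [r for r in fixture_kb if r.molecule.element_set() == frozenset({"C"})])
    assert detect_hhb(parse_formula("C6H6"), stats) is False


def test_threshold_monotonicity_random():
    rng = random.Random(2024)
    for _ in range(100):
        hyb = {s: rng.randint(0, 50) for s in ("sp", "sp2", "sp3")}
        if sum(hyb.values()) == 0:
            hyb["sp2"] = 1
        nbr = {el: rng.randint(0, 100) for el in ("C", "N", "O")}
        total = 100
        store = synthetic_store(hyb, nbr, total)
        t1, t2 = sorted((rng.random(), rng.random()))
        a = detect_hybridizations(128.5, 1, MF, store,
                                  DetectionParams(hybridization_min_occurrence=t1))
        b = detect_hybridizations(128.5, 1, MF, store,
                                  DetectionParams(hybridization_min_occurrence=t2))
        assert b <= a  # raising the threshold never enlarges the set

        lo1, lo2 = sorted((rng.random() * 0.5, rng.random() * 0.5))
        up1, up2 = sorted((0.5 + rng.random() * 0.5, 0.5 + rng.random() * 0.5))
        f_lo1, m_up1 = detect_neighbours(
            128.5, 1, MF, store, DetectionParams(neighbour_lower_bound=lo1,
                                                 neighbour_upper_bound=up1))
        f_lo2, m_up2 = detect_neighbours(
            128.5, 1, MF, store, DetectionParams(neighbour_lower_bound=lo2,
                                                 neighbour_upper_bound=up2))
        assert f_lo1 <= f_lo2   # lowering the lower bound never adds forbidden
        assert m_up2 <= m_up1   # raising the upper bound never adds mandatory


def test_single_molecule_self_consistency(fixture_kb):
    """Constraints detected from a one-molecule KB are satisfied by that
    molecule itself."""
    for record in fixture_kb[:15]:
        stats = accumulate_statistics([record])
        mol = record.molecule
        mf = mol.formula()
        shifts = record.shift_map()
        from casepy.chem_model import hybridization_of

        for i in mol.carbons():
            hyb = detect_hybridizations(shifts[i], mol.atoms[i].attached_h, mf, stats)
            assert hybridization_of(mol, i) in hyb
            forbidden, mandatory = detect_neighbours(
                shifts[i], mol.atoms[i].attached_h, mf, stats)
            nbr = {mol.atoms[j].element for j, _ in mol.neighbors(i)}
            assert not nbr & forbidden
            assert mandatory <= nbr


def test_invalid_params_rejected():
    with pytest.raises(ParameterError):
        DetectionParams(neighbour_lower_bound=0.9, neighbour_upper_bound=0.1)
    with pytest.raises(ParameterError):
        DetectionParams(hybridization_min_occurrence=1.5)
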