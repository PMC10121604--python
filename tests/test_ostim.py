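import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nigracircuit.core import PeriEventRaster, ValidationError
from nigracircuit.sdf import SDF, BaselineStats
from nigracircuit.ostim import (ModulationResult, auroc_from_counts,
                                auroc_modulation, detect_latency_from_sdf,
                                distance_metric_correlation, distance_to_port,
                                min_port_distance, near_far_latency_split,
                                welch_from_summary)

counts_lists = st.lists(st.integers(min_value=0, max_value=6),
                        min_size=2, max_size=12)


def brute_force_auroc(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    gt = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    return gt / (x.size * y.size)


def _raster_from_counts(counts, rng):
    trials = [np.sort(rng.uniform(0.0, 0.2, int(c))) for c in counts]
    return PeriEventRaster("u", "stim_onset", (0.0, 0.2), trials)


def test_auroc_worked_examples():
    assert auroc_from_counts([2, 3], [1, 2]) == pytest.approx(0.875)  # 3.5/4
    assert auroc_from_counts([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)
    assert auroc_from_counts([5, 6, 7], [1, 2, 3]) == 1.0


@settings(derandomize=True, max_examples=120, deadline=None)
@given(counts_lists, counts_lists)
def test_auroc_matches_exhaustive_pairwise_enumeration(x, y):
    assert auroc_from_counts(x, y) == pytest.approx(brute_force_auroc(x, y))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(counts_lists, counts_lists)
def test_auroc_invariant_to_monotone_transform_and_swap(x, y):
    base = auroc_from_counts(x, y)
    fx = [3 * v + 1 for v in x]
    fy = [3 * v + 1 for v in y]
    assert auroc_from_counts(fx, fy) == pytest.approx(base)
    cx = [v ** 3 for v in x]
    cy = [v ** 3 for v in y]
    assert auroc_from_counts(cx, cy) == pytest.approx(base)
    assert auroc_from_counts(y, x) == pytest.approx(1.0 - base)


def test_identical_paired_counts_are_degenerate_null():
    rng = np.random.default_rng(0)
    counts = rng.poisson(4, 20)
    stim = _raster_from_counts(counts, rng)
    sham = _raster_from_counts(counts, rng)
    auroc, p, sign = auroc_modulation(stim, sham)
    assert auroc == 0.5 and p == 1.0 and sign == "ns"


def test_auroc_sign_convention():
    rng = np.random.default_rng(1)
    stim = _raster_from_counts(rng.poisson(8, 40), rng)
    sham = _raster_from_counts(rng.poisson(3, 40), rng)
    auroc, p, sign = auroc_modulation(stim, sham)
    assert auroc > 0.5 and p < 0.05 and sign == "excited"
    with pytest.raises(ValidationError):
        auroc_modulation(_raster_from_counts([1], rng), sham)


# ---------------------------------------------------------------------------
# latency rule
# ---------------------------------------------------------------------------

def _sdf(rates, t0_ms=-100.0):
    rates = np.asarray(rates, dtype=float)
    return SDF(t0_ms + np.arange(rates.size), rates, 20.0, 100)


def _base(mean, sd):
    return BaselineStats(mean, sd, (-0.1, 0.0), "across_bins")


def test_latency_step_fixture_detects_onset():
    # baseline mean 20, sd 2; rate steps 20 -> 40 at t = 50 ms
    rates = np.where(np.arange(-100, 250) >= 50, 40.0, 20.0)
    lat = detect_latency_from_sdf(_sdf(rates), _base(20, 2), "excited",
                                  search_window=(0.0, 0.25))
    assert lat == 50.0


def test_latency_boundary_seven_of_ten():
    rates = np.full(350, 20.0)
    t = np.arange(-100, 250)
    rates[np.isin(t, np.arange(30, 37))] = 40.0   # exactly 7 qualifying bins
    lat = detect_latency_from_sdf(_sdf(rates), _base(20, 2), "excited",
                                  search_window=(0.0, 0.25))
    assert lat == 30.0
    rates6 = np.full(350, 20.0)
    rates6[np.isin(t, np.arange(30, 36))] = 40.0  # only 6: never qualifies
    assert detect_latency_from_sdf(_sdf(rates6), _base(20, 2), "excited",
                                   search_window=(0.0, 0.25)) is None


def test_flat_sdf_yields_no_latency_even_with_zero_sd():
    flat = np.full(350, 20.0)
    assert detect_latency_from_sdf(_sdf(flat), _base(20, 2), "excited",
                                   search_window=(0.0, 0.25)) is None
    assert detect_latency_from_sdf(_sdf(flat), _base(20, 0), "excited",
                                   search_window=(0.0, 0.25)) is None
    assert detect_latency_from_sdf(_sdf(flat), _base(20, 0), "inhibited",
                                   search_window=(0.0, 0.25)) is None


def test_latency_inhibited_direction_and_consecutive_rule():
    t = np.arange(-100, 250)
    rates = np.where(t >= 80, 5.0, 20.0)
    sdf = _sdf(rates)
    assert detect_latency_from_sdf(sdf, _base(20, 2), "inhibited",
                                   search_window=(0.0, 0.25)) == 80.0
    assert detect_latency_from_sdf(sdf, _base(20, 2), "inhibited",
                                   search_window=(0.0, 0.25),
                                   rule="consecutive") == 80.0


# ---------------------------------------------------------------------------
# geometry and population statistics
# ---------------------------------------------------------------------------

def test_distance_to_port_examples(layouts):
    sn = layouts["SN"]
    # port 0 sits between 1-based contacts 3 and 4 (0-based 2 and 3)
    assert distance_to_port(2, 0, sn) == pytest.approx(0.05)
    assert distance_to_port(20, 2, sn) == pytest.approx(0.05)
    assert distance_to_port(11, 0, sn) == pytest.approx(0.85)
    d, p = min_port_distance(11, sn)
    assert (round(d, 3), p) == (0.05, 1)
    with pytest.raises(ValidationError):
        distance_to_port(99, 0, sn)


def _mk(unit, dist, lat, sign="inhibited", auroc=0.2):
    return ModulationResult(unit, 0, auroc, 0.001, sign, lat, dist)


def test_distance_latency_correlation_affine_is_perfect():
    res = [_mk(f"u{i}", d, 40 + 180 * d) for i, d in
           enumerate([0.05, 0.15, 0.25, 0.35, 0.45])]
    r, p, n = distance_metric_correlation(res, "latency")
    assert r == pytest.approx(1.0) and n == 5
    with pytest.raises(ValidationError):
        distance_metric_correlation(res[:2], "latency")
    flat = [_mk(f"v{i}", 0.1, 50.0) for i in range(4)]
    with pytest.raises(ValidationError):
        distance_metric_correlation(flat, "latency")


def test_near_far_split_welch():
    rng = np.random.default_rng(0)

    def sample(n, mean, sd):
        x = rng.normal(size=n)
        return (x - x.mean()) / x.std(ddof=1) * sd + mean

    near = [_mk(f"n{i}", 0.1, v) for i, v in enumerate(sample(17, 47.6, 31.9))]
    far = [_mk(f"f{i}", 0.5, v) for i, v in enumerate(sample(8, 93.0, 51.3))]
    out = near_far_latency_split(near + far, cutoff_mm=0.25)
    assert out["near"]["n"] == 17 and out["far"]["n"] == 8
    assert out["near"]["mean_ms"] == pytest.approx(47.6)
    assert out["p"] == pytest.approx(0.0453, abs=0.005)
    # same from the printed summaries directly
    _, p = welch_from_summary(17, 47.6, 31.9, 8, 93.0, 51.3)
    assert p == pytest.approx(0.0453, abs=0.005)


def test_near_far_split_degenerate_cases():
    same = ([_mk(f"a{i}", 0.1, 50.0 + i) for i in range(5)]
            + [_mk(f"b{i}", 0.5, 50.0 + i) for i in range(5)])
    out = near_far_latency_split(same)
    assert out["p"] == pytest.approx(1.0)
    apart = ([_mk(f"c{i}", 0.1, 10.0 + 0.1 * i) for i in range(6)]
             + [_mk(f"d{i}", 0.5, 100.0 + 0.1 * i) for i in range(6)])
    assert near_far_latency_split(apart)["p"] < 1e-3
    with pytest.raises(ValidationError):
        near_far_latency_split(same[:5])  # empty far group
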