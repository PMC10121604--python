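"""Optogenetic modulation metrics: AUROC index, sustained-threshold latency,
port distances, and the population distance/latency analyses.

The modulation index is the area under the ROC curve of per-trial spike
counts in a 200-ms post-event window, stimulation vs sham events (ties count
one half; 0.5 is the null point, > 0.5 excitation, < 0.5 inhibition).
Significance comes from a two-sided paired t-test pairing the i-th
stimulation with the i-th sham event in session order.

Latency is the earliest time at which the trial-averaged spike-density
function leaves the baseline band (mean +/- 2 SD) for at least 7 out of 10
consecutive 1-ms bins; units that never satisfy the rule are flagged
``excluded_no_latency`` and drop out of latency analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (PeriEventRaster, ProbeLayout, SessionEvents, SpikeTrain,
                   ValidationError, extract_raster)
from .sdf import SDF, BaselineStats, baseline_stats, gaussian_sdf, spike_counts

__all__ = ["ModulationResult", "auroc_from_counts", "auroc_modulation",
           "detect_latency", "detect_latency_from_sdf", "distance_to_port",
           "min_port_distance", "distance_metric_correlation",
           "near_far_latency_split", "welch_from_summary",
           "ostim_session_analysis", "effective_results"]

ALPHA = 0.05
DEFAULT_WINDOW = (0.0, 0.2)
DEFAULT_RASTER_WINDOW = (-0.6, 0.45)
DEFAULT_BASELINE_WINDOW = (-0.5, 0.0)


@dataclass
class ModulationResult:
    unit_id: str
    port_index: int
    auroc: float
    p_value: float
    sign: str                   # excited | inhibited | ns
    latency_ms: float | None
    distance_mm: float
    excluded_no_latency: bool = False
    n_stim: int = 0
    n_sham: int = 0
    area: str = "unknown"
    channel_index: int = -1


def auroc_from_counts(x: np.ndarray, y: np.ndarray) -> float:
    """AUROC of ``x`` (stim) over ``y`` (sham): P(x > y) + P(x = y)/2.

    Computed from the Mann-Whitney statistic via midranks, which counts ties
    as one half.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("AUROC needs at least one trial per condition")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u1 / (x.size * y.size))


def auroc_modulation(raster_stim: PeriEventRaster, raster_sham: PeriEventRaster,
                     window: tuple = DEFAULT_WINDOW, alpha: float = ALPHA):
    """Stim-vs-sham modulation in ``window``: ``(auroc, p_value, sign)``.

    The paired t-test pairs events in session order; with unequal counts the
    pairing truncates to the common length (the AUROC uses all trials).  If
    every paired difference is zero the result is degenerate: p = 1, sign ns.
    """
    x = spike_counts(raster_stim, window)
    y = spike_counts(raster_sham, window)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need >= 2 trials per condition")
    auroc = auroc_from_counts(x, y)
    m = min(x.size, y.size)
    diff = x[:m].astype(float) - y[:m].astype(float)
    if np.all(diff == diff[0]) and diff[0] == 0.0:
        p = 1.0
    else:
        _, p = stats.ttest_rel(x[:m], y[:m])
        p = 1.0 if np.isnan(p) else float(p)
    sign = "ns"
    if p < alpha:
        if auroc > 0.5:
            sign = "excited"
        elif auroc < 0.5:
            sign = "inhibited"
    return auroc, p, sign


def detect_latency_from_sdf(sdf: SDF, baseline: BaselineStats, direction: str,
                            search_window: tuple = DEFAULT_WINDOW,
                            rule: str = "window7of10") -> float | None:
    """Sustained 2-SD threshold crossing on a 1-ms SDF grid.

    ``rule='window7of10'`` (default): latency is the first qualifying bin
    inside the earliest 10-bin window containing >= 7 bins beyond threshold.
    ``rule='consecutive'``: first bin of the earliest run of >= 7 strictly
    consecutive qualifying bins.  Returns ms relative to the alignment event,
    or None when the criterion is never met.
    """
    lo_ms, hi_ms = search_window[0] * 1e3, search_window[1] * 1e3
    sub = sdf.restrict(lo_ms, hi_ms)
    if sub.rate.size < 10:
        return None
    # strict inequalities: with a zero-variance baseline a signal sitting at
    # the mean must not qualify (no infinite sensitivity)
    if direction == "excited":
        qual = sub.rate > baseline.mean + 2.0 * baseline.sd
    elif direction == "inhibited":
        qual = sub.rate < baseline.mean - 2.0 * baseline.sd
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    q = qual.astype(int)
    if rule == "window7of10":
        counts = np.convolve(q, np.ones(10, dtype=int), mode="valid")
        hits = np.flatnonzero(counts >= 7)
        if hits.size == 0:
            return None
        s = hits[0]
        first = s + int(np.argmax(q[s:s + 10]))
        return float(sub.time_ms[first])
    if rule == "consecutive":
        run = 0
        for i, flag in enumerate(q):
            run = run + 1 if flag else 0
            if run >= 7:
                return float(sub.time_ms[i - 6])
        return None
    raise ValidationError(f"unknown latency rule {rule!r}")


def detect_latency(raster_stim: PeriEventRaster, baseline: BaselineStats,
                   direction: str | None = None,
                   search_window: tuple = DEFAULT_WINDOW,
                   sigma_ms: float = 20.0,
                   rule: str = "window7of10") -> float | None:
    """Latency of stimulation-locked modulation, or None if never sustained.

    With ``direction=None`` both directions are searched and the earlier
    qualifying crossing wins (tie -> excited).
    """
    sdf = gaussian_sdf(raster_stim, sigma_ms=sigma_ms)
    if direction is not None:
        return detect_latency_from_sdf(sdf, baseline, direction,
                                       search_window, rule)
    exc = detect_latency_from_sdf(sdf, baseline, "excited", search_window, rule)
    inh = detect_latency_from_sdf(sdf, baseline, "inhibited", search_window, rule)
    if exc is None:
        return inh
    if inh is None or exc <= inh:
        return exc
    return inh


def distance_to_port(channel_index: int, port_index: int,
                     layout: ProbeLayout) -> float:
    """|contact position - port position| in mm."""
    return abs(layout.contact_mm(channel_index) - layout.port_mm(port_index))


def min_port_distance(channel_index: int, layout: ProbeLayout):
    """Minimum distance over ports: ``(distance_mm, port_index)``."""
    if layout.n_ports == 0:
        raise ValidationError(f"probe {layout.probe_id!r} has no ports")
    d = np.abs(layout.port_positions_mm - layout.contact_mm(channel_index))
    idx = int(np.argmin(d))
    return float(d[idx]), idx


def distance_metric_correlation(results: Sequence[ModulationResult],
                                metric: str = "latency"):
    """Pearson correlation (r, two-sided p, n) of distance vs latency or AUROC.

    Uncorrected for multiple comparisons, matching the population figures.
    """
    if metric == "latency":
        pairs = [(r.distance_mm, r.latency_ms) for r in results
                 if r.latency_ms is not None]
    elif metric == "auroc":
        pairs = [(r.distance_mm, r.auroc) for r in results]
    else:
        raise ValidationError(f"unknown metric {metric!r}")
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 units with defined {metric}")
    x, y = np.array(pairs).T
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(pairs)


def welch_from_summary(n1: int, mean1: float, sd1: float,
                       n2: int, mean2: float, sd2: float):
    """Two-sided Welch t-test from group summaries: ``(t, p)``."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=False)
    return float(t), float(p)


def near_far_latency_split(results: Sequence[ModulationResult],
                           cutoff_mm: float = 0.25) -> dict:
    """Latency summary of units nearer vs farther than ``cutoff_mm`` from the
    stimulating port, with a two-sided Welch (unequal-variance) t-test."""
    lat = np.array([r.latency_ms for r in results if r.latency_ms is not None])
    dist = np.array([r.distance_mm for r in results if r.latency_ms is not None])
    near, far = lat[dist <= cutoff_mm], lat[dist > cutoff_mm]
    if near.size < 2 or far.size < 2:
        raise ValidationError("need >= 2 units on each side of the cutoff")
    t, p = stats.ttest_ind(near, far, equal_var=False)
    return {
        "cutoff_mm": cutoff_mm,
        "near": {"n": int(near.size), "mean_ms": float(np.mean(near)),
                 "sd_ms": float(np.std(near, ddof=1))},
        "far": {"n": int(far.size), "mean_ms": float(np.mean(far)),
                "sd_ms": float(np.std(far, ddof=1))},
        "t": float(t), "p": float(p),
    }


# ---------------------------------------------------------------------------
# Session-level driver
# ---------------------------------------------------------------------------

def ostim_session_analysis(trains: Sequence[SpikeTrain], events: SessionEvents,
                           layout: ProbeLayout,
                           window: tuple = DEFAULT_WINDOW,
                           raster_window: tuple = DEFAULT_RASTER_WINDOW,
                           baseline_window: tuple = DEFAULT_BASELINE_WINDOW,
                           baseline_basis: str = "across_trials",
                           alpha: float = ALPHA,
                           rule: str = "window7of10"):
    """Per-(unit, port) modulation results for a stimulation session.

    Each fiber port is analyzed as its own contrast (its stimulation events
    vs the session's sham events); latency is detected, in the direction of
    the AUROC sign, only for significant pairs.
    """
    shams = events.select_stims(is_sham=True)
    stims = events.select_stims(is_sham=False)
    port_indices = sorted(int(p) for p in
                          stims.stims["port_index"].dropna().unique())
    results = []
    for train in trains:
        sham_raster = extract_raster(train, shams, "stim_onset", raster_window)
        for p in port_indices:
            sel = events.select_stims(is_sham=False, port_index=p)
            stim_raster = extract_raster(train, sel, "stim_onset", raster_window)
            auroc, pval, sign = auroc_modulation(stim_raster, sham_raster,
                                                 window, alpha)
            latency, excluded = None, False
            if sign != "ns":
                base = baseline_stats(stim_raster, baseline_window,
                                      basis=baseline_basis)
                latency = detect_latency(stim_raster, base, direction=sign,
                                         search_window=window, rule=rule)
                excluded = latency is None
            try:
                dist = distance_to_port(train.channel_index, p, layout)
            except ValidationError:
                dist = float("nan")
            results.append(ModulationResult(
                unit_id=train.unit_id, port_index=p, auroc=auroc, p_value=pval,
                sign=sign, latency_ms=latency, distance_mm=dist,
                excluded_no_latency=excluded,
                n_stim=stim_raster.n_trials, n_sham=sham_raster.n_trials,
                area=train.area, channel_index=train.channel_index))
    return results


def effective_results(results: Sequence[ModulationResult]):
    """Reduce per-(unit, port) results to one row per unit.

    The effective port is the significant result with max |AUROC - 0.5|; a
    unit with no significant port keeps its most extreme (ns) result.
    """
    by_unit: dict = {}
    for r in results:
        by_unit.setdefault(r.unit_id, []).append(r)
    out = []
    for unit_id, rows in by_unit.items():
        sig = [r for r in rows if r.sign != "ns"]
        pool = sig if sig else rows
        out.append(max(pool, key=lambda r: abs(r.auroc - 0.5)))
    return out
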