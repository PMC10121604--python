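"""Environment-driven tonic and event-driven phasic response quantification.

Tonic responses compare per-trial rates in the 0-1200 ms window before CS
onset against the same trial's 0-500 ms pre-scene baseline (paired two-sided
t-test, PR trials).  Phasic responses use 0-300 ms post-event windows
(0-500 ms for GABAergic scene responses).  The 0%-CS truncation effect
compares sustained post-CS activity (0.3-1.5 s, skipping the phasic CS
transient) between 0% and 100% CS trials.  The scene-set control correlates
per-unit tonic responses across the two PR scene-image sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (EmptyRasterError, PeriEventRaster, SessionEvents,
                   SpikeTrain, ValidationError, extract_raster)
from .sdf import windowed_rate

__all__ = ["ContextResponse", "paired_rate_test", "tonic_response",
           "phasic_response", "truncation_test", "sceneset_correlation",
           "population_summary", "context_session_analysis"]

ALPHA = 0.05
BASELINE_WINDOW = (-0.5, 0.0)      # relative to scene onset
TONIC_WINDOW = (-1.2, 0.0)         # relative to CS onset
TRUNCATION_WINDOW = (0.3, 1.5)     # relative to CS onset


@dataclass
class ContextResponse:
    unit_id: str
    label: str
    tonic_delta: float
    tonic_p: float
    tonic_sign: str                     # excited | inhibited | ns
    phasic_scene_delta: float
    phasic_scene_p: float
    cs_deltas: dict = field(default_factory=dict)    # cs_prob -> delta
    cs_ps: dict = field(default_factory=dict)
    us_deltas: dict = field(default_factory=dict)    # cs_prob -> delta (delivered)
    truncation_delta: float | None = None
    truncation_p: float | None = None
    sceneset_pair: tuple | None = None               # (tonic set 1, tonic set 2)
    tonic_delta_nr: float | None = None
    tonic_p_nr: float | None = None


def paired_rate_test(raster_a: PeriEventRaster, raster_b: PeriEventRaster,
                     alpha: float = ALPHA):
    """Paired two-sided t-test of per-trial rates (a minus b): (delta, p, sign).

    Both rasters must come from the same trials in the same order.
    """
    if raster_a.n_trials != raster_b.n_trials:
        raise ValidationError(
            f"trial-count mismatch: {raster_a.n_trials} vs {raster_b.n_trials}")
    ra = windowed_rate(raster_a, raster_a.window)
    rb = windowed_rate(raster_b, raster_b.window)
    delta = float(np.mean(ra - rb))
    if np.all(ra - rb == (ra - rb)[0]) and (ra - rb)[0] == 0.0:
        return delta, 1.0, "ns"
    _, p = stats.ttest_rel(ra, rb)
    p = 1.0 if np.isnan(p) else float(p)
    sign = "ns"
    if p < alpha:
        sign = "excited" if delta > 0 else "inhibited"
    return delta, p, sign


def tonic_response(raster_tonic: PeriEventRaster,
                   raster_baseline: PeriEventRaster, alpha: float = ALPHA):
    """Tonic scene response: 0-1200 ms pre-CS rate vs pre-scene baseline."""
    if raster_tonic.n_trials < 10:
        raise ValidationError("tonic response needs >= 10 trials")
    return paired_rate_test(raster_tonic, raster_baseline, alpha)


def phasic_response(raster: PeriEventRaster, raster_baseline: PeriEventRaster,
                    alpha: float = ALPHA):
    """Phasic event response (0-300/0-500 ms window) vs pre-scene baseline."""
    return paired_rate_test(raster, raster_baseline, alpha)


def truncation_test(rasters_by_prob: dict, alpha: float = ALPHA):
    """Sustained post-CS rate, 0% vs 100% CS trials: ``(delta, p)``.

    Two-sample two-sided t-test; for a tonically excited unit the expected
    delta (0% minus 100%) is negative -- the 0% CS forecloses reward and
    truncates the tonic response.
    """
    for prob in (0.0, 1.0):
        if prob not in rasters_by_prob:
            raise ValidationError(f"missing {int(prob*100)}% CS condition")
    r0 = windowed_rate(rasters_by_prob[0.0], rasters_by_prob[0.0].window)
    r1 = windowed_rate(rasters_by_prob[1.0], rasters_by_prob[1.0].window)
    delta = float(np.mean(r0) - np.mean(r1))
    if np.ptp(np.concatenate([r0, r1])) == 0:
        return delta, 1.0
    _, p = stats.ttest_ind(r0, r1)
    return delta, (1.0 if np.isnan(p) else float(p))


def sceneset_correlation(responses_set1, responses_set2):
    """Pearson correlation of per-unit responses across the two PR scene sets."""
    x = np.asarray(responses_set1, dtype=float)
    y = np.asarray(responses_set2, dtype=float)
    if x.size != y.size:
        raise ValidationError("scene-set response vectors differ in length")
    if x.size < 3:
        raise ValidationError("need >= 3 units with both measurements")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def population_summary(responses: Sequence[ContextResponse]):
    """Counts of tonically excited / inhibited / ns units per class label."""
    table: dict = {}
    for resp in responses:
        row = table.setdefault(resp.label, {"excited": 0, "inhibited": 0, "ns": 0})
        row[resp.tonic_sign] += 1
    return table


# ---------------------------------------------------------------------------
# Session-level driver
# ---------------------------------------------------------------------------

def _tonic_for(train: SpikeTrain, events_sel: SessionEvents, alpha: float):
    tonic = extract_raster(train, events_sel, "cs_onset", TONIC_WINDOW)
    base = extract_raster(train, events_sel, "scene_onset", BASELINE_WINDOW)
    return paired_rate_test(tonic, base, alpha)


def context_session_analysis(trains: Sequence[SpikeTrain], events: SessionEvents,
                             labels: dict | None = None,
                             alpha: float = ALPHA):
    """Per-unit :class:`ContextResponse` for a task session.

    ``labels`` maps unit_id to a classification label; GABAergic units get the
    0-500 ms scene window, everything else 0-300 ms.
    """
    labels = labels or {}
    events_pr = events.select_trials(environment="PR")
    if events_pr.n_trials < 10:
        raise ValidationError("need >= 10 PR trials")
    out = []
    for train in trains:
        label = labels.get(train.unit_id, "unclassified")
        tonic_delta, tonic_p, tonic_sign = _tonic_for(train, events_pr, alpha)

        base_pr = extract_raster(train, events_pr, "scene_onset", BASELINE_WINDOW)
        w_scene = 0.5 if label == "putative_GABA" else 0.3
        scene = extract_raster(train, events_pr, "scene_onset", (0.0, w_scene))
        scene_delta, scene_p, _ = paired_rate_test(scene, base_pr, alpha)

        cs_deltas, cs_ps, us_deltas = {}, {}, {}
        trunc_rasters = {}
        for prob in (1.0, 0.5, 0.0):
            sel = events_pr.select_trials(cs_prob=prob)
            if sel.n_trials < 2:
                continue
            cs = extract_raster(train, sel, "cs_onset", (0.0, 0.3))
            cb = extract_raster(train, sel, "scene_onset", BASELINE_WINDOW)
            d, p, _ = paired_rate_test(cs, cb, alpha)
            cs_deltas[prob], cs_ps[prob] = d, p
            trunc_rasters[prob] = extract_raster(train, sel, "cs_onset",
                                                 TRUNCATION_WINDOW)
            delivered = sel.trials[sel.trials["us_type"] != "none"]
            if len(delivered) >= 2:
                sel_del = SessionEvents(delivered, validate=False)
                us = extract_raster(train, sel_del, "us_onset", (0.0, 0.3))
                ub = extract_raster(train, sel_del, "scene_onset", BASELINE_WINDOW)
                us_deltas[prob], _, _ = paired_rate_test(us, ub, alpha)

        trunc_delta = trunc_p = None
        if 0.0 in trunc_rasters and 1.0 in trunc_rasters:
            trunc_delta, trunc_p = truncation_test(trunc_rasters, alpha)

        pair = None
        set1 = events_pr.select_trials(scene_set_id=1)
        set2 = events_pr.select_trials(scene_set_id=2)
        if set1.n_trials >= 2 and set2.n_trials >= 2:
            d1, _, _ = _tonic_for(train, set1, alpha)
            d2, _, _ = _tonic_for(train, set2, alpha)
            pair = (d1, d2)

        nr_delta = nr_p = None
        events_nr = events.select_trials(environment="NR")
        if events_nr.n_trials >= 10:
            try:
                nr_delta, nr_p, _ = _tonic_for(train, events_nr, alpha)
            except EmptyRasterError:
                pass

        out.append(ContextResponse(
            unit_id=train.unit_id, label=label,
            tonic_delta=tonic_delta, tonic_p=tonic_p, tonic_sign=tonic_sign,
            phasic_scene_delta=scene_delta, phasic_scene_p=scene_p,
            cs_deltas=cs_deltas, cs_ps=cs_ps, us_deltas=us_deltas,
            truncation_delta=trunc_delta, truncation_p=trunc_p,
            sceneset_pair=pair, tonic_delta_nr=nr_delta, tonic_p_nr=nr_p))
    return out
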