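"""Putative cell-class assignment from task-session activity.

Rules (evaluated on PR trials, alpha = 0.05, two-sided paired t-tests of
windowed rates against the 0-500 ms pre-scene baseline):

* putative_DA  -- SN unit, baseline < 10 sp/s, significant excitation in the
  0-300 ms post-scene window, and mean 0-300 ms CS response larger for the
  100% reward CS than for both the 50% and 0% CS;
* putative_GABA -- SN unit, baseline > 15 sp/s, significant inhibition in the
  0-500 ms post-scene window;
* amygdala -- AMY unit with significant 0-300 ms post-scene excitation;
* unclassified otherwise (this includes SN units in the 10-15 sp/s gap the
  two thresholds leave open).

Baseline is measured on PR and NR trials pooled: the pre-scene inter-trial
interval carries no environment information, and pooling maximizes trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import SessionEvents, SpikeTrain, ValidationError, extract_raster
from .sdf import windowed_rate

__all__ = ["ClassificationResult", "classify_unit", "classify_session",
           "BASELINE_WINDOW"]

BASELINE_WINDOW = (-0.5, 0.0)   # relative to scene onset
ALPHA = 0.05


@dataclass
class ClassificationResult:
    unit_id: str
    label: str                  # putative_DA | putative_GABA | amygdala | unclassified
    baseline_rate: float
    scene_response_p: float
    scene_response_sign: str    # excited | inhibited | none
    cs_value_ordering_ok: bool
    area: str = "unknown"


def _paired_scene_test(train: SpikeTrain, events_pr: SessionEvents,
                       window_s: float):
    """Paired t of per-trial post-scene rate vs same-trial pre-scene baseline."""
    base = windowed_rate(
        extract_raster(train, events_pr, "scene_onset", BASELINE_WINDOW),
        BASELINE_WINDOW)
    resp = windowed_rate(
        extract_raster(train, events_pr, "scene_onset", (0.0, window_s)),
        (0.0, window_s))
    diff = resp - base
    if np.allclose(diff, diff[0]) and diff[0] == 0:
        return 0.0, 1.0, "none"
    t, p = stats.ttest_rel(resp, base)
    p = 1.0 if np.isnan(p) else float(p)
    delta = float(np.mean(diff))
    sign = "none"
    if p < ALPHA:
        sign = "excited" if delta > 0 else "inhibited"
    return delta, p, sign


def classify_unit(train: SpikeTrain, events: SessionEvents,
                  layout=None) -> ClassificationResult:
    events_pr = events.select_trials(environment="PR")
    if events_pr.n_trials < 10:
        raise ValidationError(
            f"unit {train.unit_id!r}: need >= 10 PR trials, got {events_pr.n_trials}")
    base_raster = extract_raster(train, events, "scene_onset", BASELINE_WINDOW)
    baseline = float(np.mean(windowed_rate(base_raster, BASELINE_WINDOW)))

    _, p300, sign300 = _paired_scene_test(train, events_pr, 0.3)
    _, p500, sign500 = _paired_scene_test(train, events_pr, 0.5)

    cs_means = {}
    for prob in (1.0, 0.5, 0.0):
        sel = events_pr.select_trials(cs_prob=prob)
        if sel.n_trials:
            raster = extract_raster(train, sel, "cs_onset", (0.0, 0.3))
            cs_means[prob] = float(np.mean(windowed_rate(raster, (0.0, 0.3))))
    ordering_ok = (set(cs_means) == {1.0, 0.5, 0.0}
                   and cs_means[1.0] > cs_means[0.5]
                   and cs_means[1.0] > cs_means[0.0])

    label = "unclassified"
    scene_p, scene_sign = p300, sign300
    if train.area == "SN":
        if baseline < 10.0 and sign300 == "excited" and ordering_ok:
            label = "putative_DA"
        elif baseline > 15.0 and sign500 == "inhibited":
            label = "putative_GABA"
            scene_p, scene_sign = p500, sign500
    elif train.area == "AMY":
        if sign300 == "excited":
            label = "amygdala"
    return ClassificationResult(train.unit_id, label, baseline, scene_p,
                                scene_sign, ordering_ok, area=train.area)


def classify_session(trains, events: SessionEvents, layout=None):
    """Classify every unit; per-unit failures are collected, not fatal.

    Returns ``(results, errors)`` where ``errors`` maps unit_id to the message.
    """
    results, errors = [], {}
    for train in trains:
        try:
            results.append(classify_unit(train, events, layout))
        except (ValidationError, ValueError) as exc:
            errors[train.unit_id] = str(exc)
    return results, errors
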