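import numpy as np
import pytest
from scipy import stats

from nigracircuit import (SimConfig, build_circuit, simulate_ostim_session,
                          simulate_task_session)
from nigracircuit.core import SCENE_TO_CS_S
from nigracircuit.ostim import ostim_session_analysis
from nigracircuit.sdf import spike_counts
from nigracircuit.synth import ConfigError, default_layouts


def _null_task_config(**kw):
    zero = {"amy": 0.0, "gaba": 0.0, "da": 0.0}
    zero_probs = {c: {1.0: 0.0, 0.5: 0.0, 0.0: 0.0} for c in zero}
    return SimConfig(tonic_pr_delta=dict(zero), tonic_unit_sd=0.0,
                     scene_gain=dict(zero), cs_gain=zero_probs,
                     us_gain=zero_probs, **kw)


def test_same_seed_gives_identical_output(layouts):
    cfg = SimConfig(seed=5, n_units={"amy": 2, "gaba": 2, "da": 2},
                    trials_per_condition=4)
    out = []
    for _ in range(2):
        graph = build_circuit(cfg, layouts)
        trains, events, _ = simulate_task_session(cfg, graph, layouts)
        out.append((graph, trains, events))
    (g1, t1, e1), (g2, t2, e2) = out
    assert g1.amy_to_gaba == g2.amy_to_gaba
    assert g1.gaba_to_da == g2.gaba_to_da
    for a, b in zip(t1, t2):
        np.testing.assert_array_equal(a.spike_times, b.spike_times)
    assert e1 == e2


def test_circuit_wiring_invariants(layouts):
    cfg = SimConfig(seed=3, n_units={"amy": 5, "gaba": 1, "da": 4})
    graph = build_circuit(cfg, layouts)
    gaba_ids = {u.unit_id for u in graph.units_of("gaba")}
    for g in gaba_ids:
        assert graph.afferent_synapses(g).size >= 1
    # DA units receive only GABA -> DA edges by default
    assert graph.amy_to_da == []
    da_ids = {u.unit_id for u in graph.units_of("da")}
    assert all(d in da_ids and g in gaba_ids for g, d in graph.gaba_to_da)


def test_zero_units_in_a_class_is_a_config_error(layouts):
    cfg = SimConfig(n_units={"amy": 0, "gaba": 2, "da": 2})
    with pytest.raises(ConfigError):
        build_circuit(cfg, layouts)


def test_null_generator_is_homogeneous_poisson(layouts):
    cfg = _null_task_config(seed=9, n_units={"amy": 1, "gaba": 1, "da": 1},
                            trials_per_condition=4)
    graph = build_circuit(cfg, layouts)
    trains, events, _ = simulate_task_session(cfg, graph, layouts)
    session_end = float(events.trials["us_onset"].max()) + 2.0
    for train in trains:
        lam = cfg.baseline_rate[{"AM": "amy", "GB": "gaba", "DA": "da"}
                                [train.unit_id[:2]]]
        expected = lam * session_end
        # empirical count within 3 SE of the Poisson mean
        assert abs(train.n_spikes - expected) < 3 * np.sqrt(expected)


def test_poisson_counts_in_fixed_windows_pass_ks(layouts):
    cfg = _null_task_config(seed=4, n_units={"amy": 1, "gaba": 1, "da": 1},
                            trials_per_condition=6)
    graph = build_circuit(cfg, layouts)
    trains, _, _ = simulate_task_session(cfg, graph, layouts)
    gaba = next(t for t in trains if t.unit_id.startswith("GB"))
    counts = [np.searchsorted(gaba.spike_times, k + 1.0)
              - np.searchsorted(gaba.spike_times, float(k))
              for k in range(100)]
    p = stats.kstest(counts, stats.poisson(cfg.baseline_rate["gaba"]).cdf).pvalue
    assert p > 0.01


def test_class_baselines_respect_classifier_thresholds(task_session):
    _, _, trains, events, manifest = task_session
    from nigracircuit.core import extract_raster
    from nigracircuit.sdf import windowed_rate
    for train in trains:
        cls = manifest["units"][train.unit_id]["cls"]
        raster = extract_raster(train, events, "scene_onset", (-0.5, 0.0))
        baseline = float(np.mean(windowed_rate(raster, (-0.5, 0.0))))
        if cls == "da":
            assert baseline < 10.0
        elif cls == "gaba":
            assert baseline > 15.0


def test_task_design_emits_six_by_n_trials_with_stated_timing(task_session):
    _, _, _, events, _ = task_session
    trials = events.trials
    assert len(trials) == 192
    counts = trials.groupby(["environment", "cs_prob"]).size()
    assert set(counts) == {32}
    np.testing.assert_allclose(trials["timingcue_onset"] - trials["scene_onset"],
                               1.08)
    np.testing.assert_allclose(trials["cs_onset"] - trials["timingcue_onset"],
                               0.68)
    np.testing.assert_allclose(trials["us_onset"] - trials["cs_onset"], 1.5)
    np.testing.assert_allclose(trials["cs_onset"] - trials["scene_onset"],
                               SCENE_TO_CS_S)
    # both PR scene sets represented
    assert set(trials[trials.environment == "PR"]["scene_set_id"]) == {1, 2}


def test_ostim_session_structure(ostim_session, layouts):
    _, events, _ = ostim_session
    stims = events.stims
    assert len(stims) == 400
    assert int(stims["is_sham"].astype(bool).sum()) == 200
    real = stims[~stims["is_sham"].astype(bool)]
    assert set(real["port_index"].astype(int)) <= {0, 1, 2}
    assert np.all(np.diff(stims["stim_onset"]) > 0)


def test_zero_reach_circuit_is_null(layouts):
    cfg = SimConfig(seed=2, n_units={"amy": 2, "gaba": 4, "da": 4},
                    n_stim_events=60, effect_radius_mm=0.0,
                    effect_length_constant_mm=0.0, amy_effect_radius_mm=0.0)
    graph = build_circuit(cfg, layouts)
    trains, events, manifest = simulate_ostim_session(cfg, graph, layouts,
                                                      "nigra_terminals")
    assert all(not info["effects"] for info in manifest["units"].values())
    sn = [t for t in trains if t.area == "SN"]
    mods = ostim_session_analysis(sn, events, layouts["SN"])
    aurocs = [r.auroc for r in mods]
    assert abs(np.mean(aurocs) - 0.5) < 0.05
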