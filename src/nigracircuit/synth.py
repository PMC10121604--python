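"""Synthetic amygdala -> nigral GABAergic -> dopamine circuit generator.

Simulates the two session types the analysis pipeline consumes:

* a Pavlovian task with scene session -- six conditions (possible-reward PR /
  no-reward NR environment crossed with 100/50/0% outcome CS), tonic
  PR-environment modulation that is truncated by a 0% CS, and value-ordered
  phasic scene/CS/US responses per cell class;
* an optical-stimulation session -- stimulation and sham events pseudo-randomly
  interleaved, with direct (monosynaptic, inhibitory, distance-dependent
  latency) effects on GABAergic units whose amygdala afferents lie near the
  active fiber port, and indirect (disynaptic, excitatory, distance-independent
  latency, probabilistic efficacy) disinhibition of dopamine units downstream
  of an affected GABAergic unit.

Spikes are drawn as an inhomogeneous Poisson process by thinning against an
explicit per-unit rate envelope (additive task terms, floored at zero, times
multiplicative stimulation factors with an exponential post-pulse decay).
Fixed seed implies byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (CS_TO_US_S, SCENE_TO_CS_S, SCENE_TO_TIMINGCUE_S,
                   SessionEvents, SpikeTrain, ProbeLayout, ValidationError,
                   default_amygdala_layout, default_nigra_layout)

__all__ = ["StimEffect", "SimConfig", "UnitSpec", "CircuitGraph",
           "default_layouts", "build_circuit", "simulate_task_session",
           "simulate_ostim_session"]

CLASS_AREAS = {"amy": "AMY", "gaba": "SN", "da": "SN"}
CS_PROBS = (1.0, 0.5, 0.0)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class StimEffect:
    """One connection type's optogenetic effect.

    sign: +1 excitation / -1 inhibition; latency is affine in unit-to-port
    distance (slope 0 => distance-independent); magnitude is the fractional
    rate change during the pulse; efficacy is the per-event probability that
    the effect reaches the unit at all.
    """

    sign: int
    latency_mean_ms: float
    latency_sd_ms: float
    distance_slope_ms_per_mm: float
    magnitude: float
    efficacy: float = 1.0


def _default_n_units():
    return {"amy": 25, "gaba": 25, "da": 12}


def _default_baseline():
    # DA < 10 sp/s, GABAergic > 15 sp/s by construction
    return {"amy": 8.0, "gaba": 25.0, "da": 5.0}


def _default_tonic():
    return {"amy": 4.0, "gaba": -6.0, "da": 3.0}


def _default_scene_gain():
    return {"amy": 10.0, "gaba": -10.0, "da": 8.0}


def _default_scene_window():
    return {"amy": 0.3, "gaba": 0.5, "da": 0.3}


def _default_cs_gain():
    # value ordering: DA & AMY 100% > 50% > 0%; GABA (inhibition) 0% > 50% > 100%
    return {"amy": {1.0: 10.0, 0.5: 6.0, 0.0: 2.0},
            "gaba": {1.0: -2.0, 0.5: -5.0, 0.0: -8.0},
            "da": {1.0: 12.0, 0.5: 7.0, 0.0: 2.0}}


def _default_us_gain():
    # DA US response maximal under outcome uncertainty (50%)
    return {"amy": {1.0: 8.0, 0.5: 8.0, 0.0: 0.0},
            "gaba": {1.0: -3.0, 0.5: -3.0, 0.0: 0.0},
            "da": {1.0: 5.0, 0.5: 12.0, 0.0: 0.0}}


@dataclass
class SimConfig:
    """All generator parameters; defaults are the study conditions."""

    seed: int = 0
    n_units: dict = field(default_factory=_default_n_units)
    baseline_rate: dict = field(default_factory=_default_baseline)
    tonic_pr_delta: dict = field(default_factory=_default_tonic)
    tonic_unit_sd: float = 1.5          # per-unit spread of the tonic effect, sp/s
    sceneset_shared: bool = True        # same per-unit tonic effect for both PR scene sets
    truncation: bool = True             # 0% CS abolishes the tonic term at CS onset
    scene_gain: dict = field(default_factory=_default_scene_gain)
    scene_window_s: dict = field(default_factory=_default_scene_window)
    cs_gain: dict = field(default_factory=_default_cs_gain)
    us_gain: dict = field(default_factory=_default_us_gain)
    phasic_window_s: float = 0.3
    trials_per_condition: int = 32      # x 6 conditions = 192 trials
    trial_spacing_s: float = 6.0
    n_stim_events: int = 200            # plus an equal number of shams
    stim_duration_s: float = 0.2
    stim_interval_s: float = 1.2
    stim_jitter_s: float = 0.3
    effect_radius_mm: float = 0.05      # full-effect core around a port
    effect_length_constant_mm: float = 0.15  # exponential decay of optical reach
    synapse_jitter_mm: float = 0.05     # terminal scatter around the target contact
    mean_afferents: float = 3.0         # amygdala afferents per GABAergic unit (>= 1)
    gaba_out_degree: float = 2.0        # mean GABA -> DA edges per GABAergic unit
    direct_effect: StimEffect = field(default_factory=lambda: StimEffect(
        sign=-1, latency_mean_ms=40.0, latency_sd_ms=15.0,
        distance_slope_ms_per_mm=180.0, magnitude=0.85, efficacy=1.0))
    indirect_effect: StimEffect = field(default_factory=lambda: StimEffect(
        sign=+1, latency_mean_ms=90.0, latency_sd_ms=30.0,
        distance_slope_ms_per_mm=0.0, magnitude=2.5, efficacy=0.7))
    amy_effect_radius_mm: float = 0.6
    amy_inhibited_fraction: float = 0.3  # local-network suppression of ChR2- somata
    amy_excite: StimEffect = field(default_factory=lambda: StimEffect(
        sign=+1, latency_mean_ms=10.0, latency_sd_ms=3.0,
        distance_slope_ms_per_mm=0.0, magnitude=2.0, efficacy=1.0))
    amy_inhibit: StimEffect = field(default_factory=lambda: StimEffect(
        sign=-1, latency_mean_ms=35.0, latency_sd_ms=10.0,
        distance_slope_ms_per_mm=0.0, magnitude=0.8, efficacy=1.0))
    decay_tau_s: float = 0.05           # post-pulse exponential decay of the effect
    direct_da_fraction: float = 0.0     # ablation knob: give DA units direct afferents

    def __post_init__(self) -> None:
        for cls in ("amy", "gaba", "da"):
            if cls not in self.n_units:
                raise ConfigError(f"n_units missing class {cls!r}")
            if self.baseline_rate[cls] < 0:
                raise ConfigError(f"negative baseline rate for {cls!r}")
        for cls, gains in self.cs_gain.items():
            if set(gains) != set(CS_PROBS):
                raise ConfigError(
                    f"cs_gain[{cls!r}] must have keys {CS_PROBS}")

    # -- (de)serialization for the YAML CLI config ------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        for key in ("direct_effect", "indirect_effect", "amy_excite", "amy_inhibit"):
            if key in data and isinstance(data[key], Mapping):
                data[key] = StimEffect(**data[key])
        for key in ("cs_gain", "us_gain"):
            if key in data:
                data[key] = {cls: {float(p): float(v) for p, v in gains.items()}
                             for cls, gains in data[key].items()}
        return cls(**data)

    def null_stim(self) -> "SimConfig":
        """Copy with every optogenetic effect magnitude set to zero."""
        other = SimConfig.from_dict(self.to_dict())
        for eff in (other.direct_effect, other.indirect_effect,
                    other.amy_excite, other.amy_inhibit):
            eff.magnitude = 0.0
        return other


@dataclass
class UnitSpec:
    unit_id: str
    cls: str       # "amy" | "gaba" | "da"
    area: str
    channel_index: int
    probe_id: str


@dataclass
class CircuitGraph:
    """Three-population wiring with terminal positions along the nigra probe."""

    units: list
    amy_to_gaba: list   # (amy_id, gaba_id, synapse_pos_mm)
    gaba_to_da: list    # (gaba_id, da_id)
    amy_to_da: list = field(default_factory=list)  # ablation-only direct edges

    def units_of(self, cls: str) -> list:
        return [u for u in self.units if u.cls == cls]

    def unit(self, unit_id: str) -> UnitSpec:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def afferent_synapses(self, gaba_id: str) -> np.ndarray:
        return np.array([pos for _, g, pos in self.amy_to_gaba if g == gaba_id])

    def upstream_gaba(self, da_id: str) -> list:
        return [g for g, d in self.gaba_to_da if d == da_id]


def default_layouts() -> dict:
    return {"AMY": default_amygdala_layout(), "SN": default_nigra_layout()}


def build_circuit(config: SimConfig, layouts: Mapping[str, ProbeLayout] | None = None
                  ) -> CircuitGraph:
    """Wire the circuit and place units on probe contacts (reproducible under seed).

    Every GABAergic unit receives >= 1 amygdala afferent whose terminal
    position is scattered around the unit's own contact, so stimulating a port
    near the unit activates its afferents.  GABA -> DA edges are assigned
    uniformly at random; DA units receive no direct amygdala edge unless the
    ablation knob ``direct_da_fraction`` is set.
    """
    if layouts is None:
        layouts = default_layouts()
    for cls, n in config.n_units.items():
        if n < 1:
            raise ConfigError(f"need >= 1 unit of class {cls!r}, got {n}")
    rng = np.random.default_rng([config.seed, 11])
    units = []
    prefixes = {"amy": "AM", "gaba": "GB", "da": "DA"}
    for cls in ("amy", "gaba", "da"):
        layout = layouts[CLASS_AREAS[cls]]
        channels = rng.integers(0, layout.n_contacts, size=config.n_units[cls])
        for i, ch in enumerate(channels):
            units.append(UnitSpec(f"{prefixes[cls]}{i:02d}", cls,
                                  CLASS_AREAS[cls], int(ch), layout.probe_id))
    sn = layouts["SN"]
    span = (float(sn.contact_positions_mm.min()),
            float(sn.contact_positions_mm.max()))
    amy_ids = [u.unit_id for u in units if u.cls == "amy"]
    amy_to_gaba = []
    for g in (u for u in units if u.cls == "gaba"):
        n_aff = 1 + rng.poisson(max(config.mean_afferents - 1.0, 0.0))
        sources = rng.choice(amy_ids, size=n_aff, replace=True)
        center = sn.contact_mm(g.channel_index)
        positions = np.clip(center + rng.normal(0, config.synapse_jitter_mm, n_aff),
                            span[0], span[1])
        amy_to_gaba.extend((str(s), g.unit_id, float(p))
                           for s, p in zip(sources, positions))
    da_ids = [u.unit_id for u in units if u.cls == "da"]
    gaba_to_da = []
    for g in (u for u in units if u.cls == "gaba"):
        k = min(rng.poisson(config.gaba_out_degree), len(da_ids))
        targets = rng.choice(da_ids, size=k, replace=False)
        gaba_to_da.extend((g.unit_id, str(d)) for d in targets)
    amy_to_da = []
    if config.direct_da_fraction > 0:
        n_direct = int(round(config.direct_da_fraction * len(da_ids)))
        chosen = rng.choice(da_ids, size=n_direct, replace=False)
        for d in chosen:
            du = next(u for u in units if u.unit_id == d)
            center = sn.contact_mm(du.channel_index)
            pos = float(np.clip(center + rng.normal(0, config.synapse_jitter_mm),
                                span[0], span[1]))
            amy_to_da.append((str(rng.choice(amy_ids)), str(d), pos))
    return CircuitGraph(units, amy_to_gaba, gaba_to_da, amy_to_da)


# ---------------------------------------------------------------------------
# Rate envelope + thinning sampler
# ---------------------------------------------------------------------------

class RateEnvelope:
    """Piecewise rate function: max(0, baseline + additive steps) * stim factors."""

    def __init__(self, baseline: float):
        if baseline < 0:
            raise ConfigError("negative configured baseline")
        self.baseline = float(baseline)
        self._add = []    # (t0, t1, delta)
        self._mult = []   # (t_on, t_off, factor, tau)
        self._frozen = None

    def add_step(self, t0: float, t1: float, delta: float) -> None:
        if t1 > t0 and delta != 0.0:
            self._add.append((float(t0), float(t1), float(delta)))
            self._frozen = None

    def add_stim(self, t_on: float, t_off: float, sign: int, magnitude: float,
                 tau_s: float) -> None:
        factor = 1.0 + sign * magnitude
        if factor < 0:
            factor = 0.0
        if t_off > t_on and factor != 1.0:
            self._mult.append((float(t_on), float(t_off), factor, float(tau_s)))
            self._frozen = None

    def _freeze(self):
        if self._frozen is None:
            if self._add:
                starts = np.array([a[0] for a in self._add])
                ends = np.array([a[1] for a in self._add])
                deltas = np.array([a[2] for a in self._add])
                bp = np.concatenate([starts, ends])
                dd = np.concatenate([deltas, -deltas])
                order = np.argsort(bp, kind="stable")
                bp, dd = bp[order], dd[order]
                levels = np.cumsum(dd)
            else:
                bp = np.empty(0)
                levels = np.empty(0)
            mult = sorted(self._mult)
            self._frozen = (bp, levels, mult)
        return self._frozen

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the rate at sorted times ``t``."""
        bp, levels, mult = self._freeze()
        r = np.full(t.shape, self.baseline)
        if bp.size:
            idx = np.searchsorted(bp, t, side="right") - 1
            valid = idx >= 0
            r[valid] += levels[idx[valid]]
        np.maximum(r, 0.0, out=r)
        for t_on, t_off, factor, tau in mult:
            i0 = np.searchsorted(t, t_on, side="left")
            i1 = np.searchsorted(t, t_off, side="left")
            i2 = np.searchsorted(t, t_off + 5.0 * tau, side="left")
            r[i0:i1] *= factor
            if i2 > i1:
                r[i1:i2] *= 1.0 + (factor - 1.0) * np.exp(-(t[i1:i2] - t_off) / tau)
        return r

    def max_rate(self) -> float:
        bp, levels, mult = self._freeze()
        peak_add = self.baseline + (float(levels.max()) if levels.size else 0.0)
        peak_add = max(peak_add, self.baseline, 0.0)
        fmax = max([1.0] + [f for _, _, f, _ in mult])
        return peak_add * fmax

    def sample(self, duration_s: float, rng: np.random.Generator) -> np.ndarray:
        """Poisson thinning against the envelope over [0, duration_s)."""
        lam = self.max_rate()
        if lam <= 0:
            return np.empty(0)
        n_cand = rng.poisson(lam * duration_s)
        t = np.sort(rng.uniform(0.0, duration_s, n_cand))
        keep = rng.uniform(0.0, lam, n_cand) < self(t)
        return t[keep]


# ---------------------------------------------------------------------------
# Task session
# ---------------------------------------------------------------------------

def _task_events(config: SimConfig, rng: np.random.Generator) -> SessionEvents:
    conds = [(env, prob) for env in ("PR", "NR") for prob in CS_PROBS]
    rows = []
    for env, prob in conds:
        n = config.trials_per_condition
        sets = np.array([1] * (n // 2) + [2] * (n - n // 2))
        rng.shuffle(sets)
        for k in range(n):
            rows.append({"environment": env, "cs_prob": prob,
                         "scene_set_id": int(sets[k])})
    order = rng.permutation(len(rows))
    table = []
    for i, j in enumerate(order):
        row = dict(rows[j])
        scene = 1.0 + i * config.trial_spacing_s
        row.update(scene_onset=scene,
                   timingcue_onset=scene + SCENE_TO_TIMINGCUE_S,
                   cs_onset=scene + SCENE_TO_CS_S,
                   us_onset=scene + SCENE_TO_CS_S + CS_TO_US_S)
        delivered = rng.uniform() < row["cs_prob"]
        if row["environment"] == "PR":
            row["us_type"] = "water" if delivered else "none"
        else:
            row["us_type"] = "airpuff" if delivered else "none"
        table.append(row)
    return SessionEvents.from_frames(trials=pd.DataFrame(table))


def simulate_task_session(config: SimConfig, graph: CircuitGraph,
                          layouts: Mapping[str, ProbeLayout] | None = None):
    """Simulate the Pavlovian task session.

    Returns ``(trains, events, manifest)``; the manifest records per-unit
    ground truth (class, channel, tonic effect per scene set).
    """
    if layouts is None:
        layouts = default_layouts()
    rng_ev = np.random.default_rng([config.seed, 21])
    events = _task_events(config, rng_ev)
    trials = events.trials
    session_end = float(trials["us_onset"].max()) + 2.0
    trains, unit_truth = [], {}
    for i, unit in enumerate(graph.units):
        rng_u = np.random.default_rng([config.seed, 22, i])
        cls = unit.cls
        env = RateEnvelope(config.baseline_rate[cls])
        d1 = config.tonic_pr_delta[cls] + rng_u.normal(0, config.tonic_unit_sd)
        d2 = (d1 if config.sceneset_shared
              else config.tonic_pr_delta[cls] + rng_u.normal(0, config.tonic_unit_sd))
        tonic_by_set = {1: d1, 2: d2}
        w_scene = config.scene_window_s[cls]
        for _, trial in trials.iterrows():
            scene, cs, us = trial["scene_onset"], trial["cs_onset"], trial["us_onset"]
            prob = trial["cs_prob"]
            if trial["environment"] == "PR":
                tonic_end = cs if (config.truncation and prob == 0.0) else us
                env.add_step(scene, tonic_end, tonic_by_set[int(trial["scene_set_id"])])
            env.add_step(scene, scene + w_scene, config.scene_gain[cls])
            env.add_step(cs, cs + config.phasic_window_s, config.cs_gain[cls][prob])
            if trial["us_type"] != "none":
                env.add_step(us, us + config.phasic_window_s,
                             config.us_gain[cls][prob])
        spikes = env.sample(session_end, rng_u)
        trains.append(SpikeTrain(unit.unit_id, unit.area, unit.channel_index, spikes))
        unit_truth[unit.unit_id] = {
            "cls": cls, "channel_index": unit.channel_index,
            "baseline_rate": config.baseline_rate[cls],
            "tonic_delta_set1": float(d1), "tonic_delta_set2": float(d2)}
    manifest = {"session": "task", "seed": config.seed,
                "n_trials": int(len(trials)), "units": unit_truth,
                "config": config.to_dict()}
    return trains, events, manifest


# ---------------------------------------------------------------------------
# Optical-stimulation session
# ---------------------------------------------------------------------------

def _ostim_events(config: SimConfig, rng: np.random.Generator,
                  ports: np.ndarray) -> SessionEvents:
    n = config.n_stim_events
    is_sham = np.array([False] * n + [True] * n)
    rng.shuffle(is_sham)
    port_seq = np.tile(np.arange(len(ports)), n // len(ports) + 1)[:n]
    rng.shuffle(port_seq)
    rows, t, k = [], 1.0, 0
    for sham in is_sham:
        rows.append({"stim_onset": t, "stim_duration": config.stim_duration_s,
                     "port_index": -1 if sham else int(port_seq[k]),
                     "is_sham": bool(sham)})
        if not sham:
            k += 1
        t += config.stim_interval_s + rng.uniform(0, config.stim_jitter_s)
    return SessionEvents.from_frames(stims=pd.DataFrame(rows))


def _port_recruits(synapses_mm: np.ndarray, port_mm: float, config: SimConfig,
                   rng: np.random.Generator) -> bool:
    """Whether the light at a port recruits any of a unit's afferent terminals.

    Light attenuates roughly exponentially in tissue: a terminal within the
    full-effect core (``effect_radius_mm``) is always recruited; beyond it,
    recruitment probability decays with length constant
    ``effect_length_constant_mm`` (0 => hard radius).  Drawn once per
    (unit, port): a recruited afferent is driven on every pulse of the session.
    """
    d = np.abs(np.asarray(synapses_mm) - port_mm)
    excess = d - config.effect_radius_mm
    lam = config.effect_length_constant_mm
    if lam <= 0:
        prob = (excess <= 0).astype(float)
    else:
        prob = np.where(excess <= 0, 1.0, np.exp(-np.maximum(excess, 0) / lam))
    miss = np.prod(1.0 - prob)
    return bool(rng.uniform() < 1.0 - miss)


def _draw_latency(eff: StimEffect, distance_mm: float,
                  rng: np.random.Generator) -> float:
    lat = (eff.latency_mean_ms + eff.distance_slope_ms_per_mm * distance_mm
           + rng.normal(0, eff.latency_sd_ms))
    return float(max(lat, 1.0))


def simulate_ostim_session(config: SimConfig, graph: CircuitGraph,
                           layouts: Mapping[str, ProbeLayout] | None = None,
                           target: str = "nigra_terminals"):
    """Simulate a stimulation session (``amygdala_soma`` or ``nigra_terminals``).

    Returns ``(trains, events, manifest)``.  The manifest records, per unit and
    port, whether the unit is affected and the realized onset latency, sign and
    magnitude -- the ground truth for parameter-recovery tests.
    """
    if layouts is None:
        layouts = default_layouts()
    if target not in ("amygdala_soma", "nigra_terminals"):
        raise ConfigError(f"unknown stimulation target {target!r}")
    stim_layout = layouts["AMY" if target == "amygdala_soma" else "SN"]
    ports = stim_layout.port_positions_mm
    tag = 31 if target == "amygdala_soma" else 32
    rng_ev = np.random.default_rng([config.seed, tag])
    events = _ostim_events(config, rng_ev, ports)
    stims = events.stims
    real_stims = stims[~stims["is_sham"].astype(bool)]
    if len(real_stims) and real_stims["port_index"].max() >= len(ports):
        raise ConfigError("stim event port_index outside layout")
    session_end = float(stims["stim_onset"].max()) + 2.0

    # --- resolve which unit is affected from which port, with what effect ---
    sn = layouts["SN"]
    effects: dict = {u.unit_id: {} for u in graph.units}  # unit -> port -> dict
    for i, unit in enumerate(graph.units):
        rng_fx = np.random.default_rng([config.seed, tag + 10, i])
        if target == "amygdala_soma":
            if unit.cls != "amy":
                continue
            pos = layouts["AMY"].contact_mm(unit.channel_index)
            polarity = ("inhibit" if rng_fx.uniform() < config.amy_inhibited_fraction
                        else "excite")
            eff = config.amy_inhibit if polarity == "inhibit" else config.amy_excite
            for p, port_pos in enumerate(ports):
                dist = abs(pos - port_pos)
                if dist <= config.amy_effect_radius_mm:
                    effects[unit.unit_id][p] = {
                        "sign": eff.sign, "magnitude": eff.magnitude,
                        "efficacy": eff.efficacy, "distance_mm": dist,
                        "latency_ms": _draw_latency(eff, 0.0, rng_fx)}
            continue
        # nigra_terminals
        if unit.cls == "gaba":
            syn = graph.afferent_synapses(unit.unit_id)
            pos = sn.contact_mm(unit.channel_index)
            eff = config.direct_effect
            for p, port_pos in enumerate(ports):
                if syn.size and _port_recruits(syn, port_pos, config, rng_fx):
                    dist = abs(pos - port_pos)
                    effects[unit.unit_id][p] = {
                        "sign": eff.sign, "magnitude": eff.magnitude,
                        "efficacy": eff.efficacy, "distance_mm": dist,
                        "latency_ms": _draw_latency(eff, dist, rng_fx)}
        elif unit.cls == "da":
            pos = sn.contact_mm(unit.channel_index)
            # ablation: direct amygdala terminals onto this DA unit
            own_direct = np.array([s for _, d, s in graph.amy_to_da
                                   if d == unit.unit_id])
            eff_d = config.direct_effect
            for p, port_pos in enumerate(ports):
                if own_direct.size and _port_recruits(own_direct, port_pos,
                                                      config, rng_fx):
                    dist = abs(pos - port_pos)
                    effects[unit.unit_id][p] = {
                        "sign": eff_d.sign, "magnitude": eff_d.magnitude,
                        "efficacy": eff_d.efficacy, "distance_mm": dist,
                        "latency_ms": _draw_latency(eff_d, dist, rng_fx)}
            eff = config.indirect_effect
            upstream = graph.upstream_gaba(unit.unit_id)
            for p, port_pos in enumerate(ports):
                if p in effects[unit.unit_id]:
                    continue
                relayed = any(p in effects[g] for g in upstream)
                if relayed:
                    dist = abs(pos - port_pos)
                    effects[unit.unit_id][p] = {
                        "sign": eff.sign, "magnitude": eff.magnitude,
                        "efficacy": eff.efficacy, "distance_mm": dist,
                        "latency_ms": _draw_latency(eff, 0.0, rng_fx)}

    # --- build envelopes and sample --------------------------------------
    trains = []
    for i, unit in enumerate(graph.units):
        rng_u = np.random.default_rng([config.seed, tag + 20, i])
        env = RateEnvelope(config.baseline_rate[unit.cls])
        unit_fx = effects[unit.unit_id]
        if unit_fx:
            for _, ev in real_stims.iterrows():
                p = int(ev["port_index"])
                if p not in unit_fx:
                    continue
                fx = unit_fx[p]
                if rng_u.uniform() >= fx["efficacy"]:
                    continue
                t_on = ev["stim_onset"] + fx["latency_ms"] * 1e-3
                env.add_stim(t_on, t_on + config.stim_duration_s,
                             fx["sign"], fx["magnitude"], config.decay_tau_s)
        spikes = env.sample(session_end, rng_u)
        trains.append(SpikeTrain(unit.unit_id, unit.area, unit.channel_index, spikes))

    manifest = {"session": f"ostim:{target}", "seed": config.seed,
                "n_stim": int(len(real_stims)),
                "n_sham": int(stims["is_sham"].astype(bool).sum()),
                "units": {u.unit_id: {"cls": u.cls,
                                      "channel_index": u.channel_index,
                                      "effects": {str(p): fx for p, fx in
                                                  effects[u.unit_id].items()}}
                          for u in graph.units},
                "config": config.to_dict()}
    return trains, events, manifest
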