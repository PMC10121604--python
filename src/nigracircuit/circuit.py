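"""Direct-vs-indirect connectivity inference and population report arithmetic.

The decision rule formalizes the circuit argument: a population whose
stimulation-response latency grows with distance from the fiber port receives
*direct* (monosynaptic) input from the stimulated axons, while a population
with slower, distance-independent latencies receives *indirect* (disynaptic)
input relayed through a directly driven population.  Applied to the default
circuit this yields: GABAergic units -- inhibited, distance-dependent, direct;
dopamine units -- excited, distance-independent, slower, indirect
(disinhibition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ostim import (ModulationResult, distance_metric_correlation,
                    welch_from_summary)
from .core import ValidationError

__all__ = ["ConnectivityVerdict", "infer_connectivity", "percent",
           "modulation_summary", "congruence_table"]

ALPHA = 0.05


@dataclass
class ConnectivityVerdict:
    population: str
    dominant_sign: str           # excited | inhibited | ns
    latency_mean_ms: float | None
    latency_sd_ms: float | None
    n_significant: int
    n_with_latency: int
    distance_dependent: bool
    distance_r: float | None
    distance_p: float | None
    verdict: str                 # direct_input | indirect_input | undetermined
    latency_comparison_p: float | None = None   # Welch vs the direct comparator


def _population_stats(results: Sequence[ModulationResult], alpha: float):
    sig = [r for r in results if r.sign != "ns"]
    n_exc = sum(1 for r in sig if r.sign == "excited")
    n_inh = len(sig) - n_exc
    if not sig:
        dominant = "ns"
    else:
        dominant = "excited" if n_exc >= n_inh else "inhibited"
    with_lat = [r for r in sig if r.sign == dominant and r.latency_ms is not None]
    lat = np.array([r.latency_ms for r in with_lat])
    dd, r_val, p_val = False, None, None
    if len(with_lat) >= 3:
        try:
            r_val, p_val, _ = distance_metric_correlation(with_lat, "latency")
            dd = (p_val < alpha) and (r_val > 0)
        except ValidationError:
            pass
    return {
        "sig": sig, "dominant": dominant, "with_lat": with_lat,
        "lat_mean": float(np.mean(lat)) if lat.size else None,
        "lat_sd": float(np.std(lat, ddof=1)) if lat.size > 1 else None,
        "dd": dd, "r": r_val, "p": p_val,
    }


def infer_connectivity(results_by_class: Mapping[str, Sequence[ModulationResult]],
                       min_units: int = 5, alpha: float = ALPHA):
    """Per-population connectivity verdicts from modulation results.

    A population is ``direct_input`` when its latency-distance correlation is
    significantly positive; ``indirect_input`` when it is not
    distance-dependent and some direct population responds faster (Welch
    two-sided p reported); ``undetermined`` otherwise or with < ``min_units``
    modulated units carrying latencies.
    """
    stats_by_class = {cls: _population_stats(res, alpha)
                      for cls, res in results_by_class.items()}
    direct = {cls for cls, st in stats_by_class.items()
              if st["dd"] and len(st["with_lat"]) >= min_units}
    verdicts = []
    for cls, st in stats_by_class.items():
        verdict, comp_p = "undetermined", None
        if len(st["sig"]) >= min_units and len(st["with_lat"]) >= min_units:
            if cls in direct:
                verdict = "direct_input"
            else:
                faster = [d for d in direct
                          if stats_by_class[d]["lat_mean"] is not None
                          and stats_by_class[d]["lat_mean"] < st["lat_mean"]]
                if faster:
                    comp = min(faster, key=lambda d: stats_by_class[d]["lat_mean"])
                    cs = stats_by_class[comp]
                    _, comp_p = welch_from_summary(
                        len(st["with_lat"]), st["lat_mean"], st["lat_sd"] or 0.0,
                        len(cs["with_lat"]), cs["lat_mean"], cs["lat_sd"] or 0.0)
                    verdict = "indirect_input"
        verdicts.append(ConnectivityVerdict(
            population=cls, dominant_sign=st["dominant"],
            latency_mean_ms=st["lat_mean"], latency_sd_ms=st["lat_sd"],
            n_significant=len(st["sig"]), n_with_latency=len(st["with_lat"]),
            distance_dependent=st["dd"], distance_r=st["r"],
            distance_p=st["p"], verdict=verdict,
            latency_comparison_p=comp_p))
    return verdicts


# ---------------------------------------------------------------------------
# Report arithmetic
# ---------------------------------------------------------------------------

def percent(k: int, n: int) -> float:
    """Percentage k/n as printed in summaries (e.g. percent(76, 211) -> 36.0
    after rounding to integer precision)."""
    if n <= 0:
        raise ValidationError("percentage of an empty denominator")
    return 100.0 * k / n


def modulation_summary(effective: Sequence[ModulationResult]) -> dict:
    """Counts and printed-style percentages for one population's modulation."""
    n_total = len(effective)
    sig = [r for r in effective if r.sign != "ns"]
    n_exc = sum(1 for r in sig if r.sign == "excited")
    n_inh = len(sig) - n_exc
    out = {"n_total": n_total, "n_modulated": len(sig),
           "n_excited": n_exc, "n_inhibited": n_inh}
    if n_total:
        out["pct_modulated"] = percent(len(sig), n_total)
    if sig:
        out["pct_excited_of_modulated"] = percent(n_exc, len(sig))
        out["pct_inhibited_of_modulated"] = percent(n_inh, len(sig))
    return out


def congruence_table(context_results, effective_mod_results) -> dict:
    """Cross-table of task tonic sign vs stimulation sign per unit label.

    Reported, not asserted: counts of units that are both tonically modulated
    in the task and significantly modulated by stimulation, split by whether
    the signs agree.
    """
    mod_by_unit = {r.unit_id: r for r in effective_mod_results}
    table: dict = {}
    for ctx in context_results:
        mod = mod_by_unit.get(ctx.unit_id)
        if mod is None:
            continue
        row = table.setdefault(ctx.label, {"both_modulated": 0, "congruent": 0})
        if ctx.tonic_sign != "ns" and mod.sign != "ns":
            row["both_modulated"] += 1
            if ctx.tonic_sign == mod.sign:
                row["congruent"] += 1
    return table
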