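"""Core data model: spike trains, session event tables, probe layouts, rasters.

Time is in seconds from session start throughout; all windows are half-open
``[t_start, t_end)`` so a spike landing exactly on a window edge is counted
once and only once.  Contact and port indices are stored 0-based; figures and
lab convention label contacts 1-based, and conversion happens at read/report
time only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AREAS",
    "SCENE_TO_TIMINGCUE_S",
    "TIMINGCUE_TO_CS_S",
    "SCENE_TO_CS_S",
    "CS_TO_US_S",
    "SchemaError",
    "ValidationError",
    "EmptyRasterError",
    "SpikeTrain",
    "SessionEvents",
    "ProbeLayout",
    "PeriEventRaster",
    "default_amygdala_layout",
    "default_nigra_layout",
    "extract_raster",
    "read_session",
    "write_session",
]

AREAS = ("AMY", "SN", "unknown")

# Pavlovian task timing: scene -> (1.08 s) timing cue -> (0.68 s) CS -> (1.5 s) US.
SCENE_TO_TIMINGCUE_S = 1.08
TIMINGCUE_TO_CS_S = 0.68
SCENE_TO_CS_S = SCENE_TO_TIMINGCUE_S + TIMINGCUE_TO_CS_S  # 1.76 s pre-CS period
CS_TO_US_S = 1.5
_TIMING_TOL_S = 1e-3  # tolerance on read


class SchemaError(ValueError):
    """An on-disk file does not conform to the expected schema."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


class EmptyRasterError(ValueError):
    """Raster extraction matched no events."""


@dataclass
class SpikeTrain:
    """Sorted spike timestamps for one unit.

    Parameters
    ----------
    unit_id : str
        Unique unit label within the session.
    area : str
        Recording area, one of ``AMY``, ``SN``, ``unknown``.
    channel_index : int
        0-based contact index on the unit's probe.
    spike_times : array-like of float
        Spike times in seconds from session start, non-decreasing, finite, >= 0.
    """

    unit_id: str
    area: str
    channel_index: int
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        if self.area not in AREAS:
            raise ValidationError(
                f"unit {self.unit_id!r}: area {self.area!r} not in {AREAS}")
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValidationError(f"unit {self.unit_id!r}: spike_times must be 1-D")
        if t.size and (not np.all(np.isfinite(t)) or t[0] < 0):
            raise ValidationError(
                f"unit {self.unit_id!r}: spike times must be finite and >= 0")
        if np.any(np.diff(t) < 0):
            raise ValidationError(f"unit {self.unit_id!r}: spike_times not sorted")
        if int(self.channel_index) < 0:
            raise ValidationError(f"unit {self.unit_id!r}: negative channel_index")
        self.channel_index = int(self.channel_index)
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def shifted(self, delta_s: float) -> "SpikeTrain":
        return SpikeTrain(self.unit_id, self.area, self.channel_index,
                          self.spike_times + delta_s)


@dataclass
class ProbeLayout:
    """Linear probe geometry: contact and fiber-port positions in mm along the shank."""

    probe_id: str
    contact_positions_mm: np.ndarray
    port_positions_mm: np.ndarray

    def __post_init__(self) -> None:
        self.contact_positions_mm = np.asarray(self.contact_positions_mm, dtype=float)
        self.port_positions_mm = np.asarray(self.port_positions_mm, dtype=float)
        if self.contact_positions_mm.size < 1:
            raise ValidationError(f"probe {self.probe_id!r}: no contacts")

    @property
    def n_contacts(self) -> int:
        return int(self.contact_positions_mm.size)

    @property
    def n_ports(self) -> int:
        return int(self.port_positions_mm.size)

    def contact_mm(self, channel_index: int) -> float:
        if not 0 <= channel_index < self.n_contacts:
            raise ValidationError(
                f"channel {channel_index} outside probe {self.probe_id!r} "
                f"({self.n_contacts} contacts)")
        return float(self.contact_positions_mm[channel_index])

    def port_mm(self, port_index: int) -> float:
        if not 0 <= port_index < self.n_ports:
            raise ValidationError(
                f"port {port_index} outside probe {self.probe_id!r} "
                f"({self.n_ports} ports)")
        return float(self.port_positions_mm[port_index])


def default_amygdala_layout() -> ProbeLayout:
    """16-contact probe, 200 um spacing, one fiber port at mid-shank."""
    contacts = 0.2 * np.arange(16)
    port = 0.5 * (contacts[7] + contacts[8])
    return ProbeLayout("amy16", contacts, np.array([port]))


def default_nigra_layout() -> ProbeLayout:
    """24-contact probe, 100 um spacing; ports at the midpoints of contacts
    3/4, 11/12 and 20/21 (1-based labels; stored 0-based)."""
    contacts = 0.1 * np.arange(24)
    ports = np.array([
        0.5 * (contacts[2] + contacts[3]),
        0.5 * (contacts[10] + contacts[11]),
        0.5 * (contacts[19] + contacts[20]),
    ])
    return ProbeLayout("sn24", contacts, ports)


_TRIAL_COLS = ["environment", "scene_set_id", "scene_onset", "timingcue_onset",
               "cs_onset", "cs_prob", "us_onset", "us_type"]
_STIM_COLS = ["stim_onset", "stim_duration", "port_index", "is_sham"]
EVENT_COLUMNS = ["event_kind"] + _TRIAL_COLS + _STIM_COLS


class SessionEvents:
    """Typed event table of a task or stimulation session.

    One row per trial (``event_kind == 'trial'``) or per stimulation/sham event
    (``event_kind == 'stim'``).  Sham events are explicit rows with
    ``is_sham == True`` so stimulation and control windows are structurally
    identical for the AUROC contrast.
    """

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        table = table.copy().reset_index(drop=True)
        for col in EVENT_COLUMNS:
            if col not in table.columns:
                table[col] = np.nan
        if table["is_sham"].dtype == object:
            # CSV round trip leaves booleans as strings when NaNs are present
            table["is_sham"] = table["is_sham"].map(
                lambda v: {"True": True, "False": False}.get(v, v))
        self.table = table[EVENT_COLUMNS]
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_frames(cls, trials: pd.DataFrame | None = None,
                    stims: pd.DataFrame | None = None) -> "SessionEvents":
        parts = []
        if trials is not None and len(trials):
            t = trials.copy()
            t["event_kind"] = "trial"
            parts.append(t)
        if stims is not None and len(stims):
            s = stims.copy()
            s["event_kind"] = "stim"
            parts.append(s)
        if not parts:
            raise ValidationError("no events supplied")
        return cls(pd.concat(parts, ignore_index=True))

    # -- views ------------------------------------------------------------
    @property
    def trials(self) -> pd.DataFrame:
        return self.table[self.table["event_kind"] == "trial"]

    @property
    def stims(self) -> pd.DataFrame:
        return self.table[self.table["event_kind"] == "stim"]

    @property
    def n_trials(self) -> int:
        return int(len(self.trials))

    def select_trials(self, **criteria) -> "SessionEvents":
        """Filtered copy keeping only trials matching equality ``criteria``."""
        sub = self.trials
        for key, value in criteria.items():
            sub = sub[sub[key] == value]
        return SessionEvents(sub, validate=False)

    def select_stims(self, **criteria) -> "SessionEvents":
        sub = self.stims
        for key, value in criteria.items():
            sub = sub[sub[key] == value]
        return SessionEvents(sub, validate=False)

    def event_times(self, event_label: str) -> np.ndarray:
        """Onset times (s) for ``event_label`` (a *_onset column)."""
        if event_label in ("scene_onset", "timingcue_onset", "cs_onset", "us_onset"):
            vals = self.trials[event_label]
        elif event_label == "stim_onset":
            vals = self.stims[event_label]
        else:
            raise KeyError(f"unknown event label {event_label!r}")
        return np.asarray(vals, dtype=float)

    def shifted(self, delta_s: float) -> "SessionEvents":
        t = self.table.copy()
        for col in ("scene_onset", "timingcue_onset", "cs_onset", "us_onset",
                    "stim_onset"):
            t[col] = t[col] + delta_s
        return SessionEvents(t, validate=False)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        trials = self.trials
        for row_idx, row in trials.iterrows():
            label = f"events row {row_idx}"
            times = (row["scene_onset"], row["timingcue_onset"],
                     row["cs_onset"], row["us_onset"])
            if not (times[0] < times[1] < times[2] < times[3]):
                raise ValidationError(f"{label}: trial onsets not increasing")
            checks = [
                ("timingcue_onset - scene_onset", times[1] - times[0],
                 SCENE_TO_TIMINGCUE_S),
                ("cs_onset - timingcue_onset", times[2] - times[1],
                 TIMINGCUE_TO_CS_S),
                ("us_onset - cs_onset", times[3] - times[2], CS_TO_US_S),
                ("cs_onset - scene_onset", times[2] - times[0], SCENE_TO_CS_S),
            ]
            for name, got, want in checks:
                if abs(got - want) > _TIMING_TOL_S:
                    raise ValidationError(
                        f"{label}: {name} = {got:.4f} s, expected {want} s")
            if row["environment"] not in ("PR", "NR"):
                raise ValidationError(f"{label}: bad environment {row['environment']!r}")
            if row["cs_prob"] not in (0.0, 0.5, 1.0):
                raise ValidationError(f"{label}: bad cs_prob {row['cs_prob']!r}")
            if row["us_type"] == "water" and row["environment"] != "PR":
                raise ValidationError(f"{label}: water outside PR")
            if row["us_type"] == "airpuff" and row["environment"] != "NR":
                raise ValidationError(f"{label}: airpuff outside NR")
            if row["cs_prob"] == 0.0 and row["us_type"] != "none":
                raise ValidationError(f"{label}: outcome delivered on a 0% trial")
        stims = self.stims
        for row_idx, row in stims.iterrows():
            if not np.isfinite(row["stim_onset"]) or row["stim_onset"] < 0:
                raise ValidationError(f"events row {row_idx}: bad stim_onset")
            if not row["stim_duration"] > 0:
                raise ValidationError(f"events row {row_idx}: bad stim_duration")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionEvents):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.table, other.table,
                                          check_dtype=False)
        except AssertionError:
            return False
        return True


@dataclass
class PeriEventRaster:
    """Per-trial spike times relative to an alignment event.

    ``trials[i]`` holds relative spike times of the i-th matching event, each
    within the half-open ``window = (t_start, t_end)``.
    """

    unit_id: str
    event_label: str
    window: tuple
    trials: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))


def extract_raster(train: SpikeTrain, events: SessionEvents, event_label: str,
                   window: tuple) -> PeriEventRaster:
    """Align ``train`` on every event named ``event_label``.

    Raises :class:`EmptyRasterError` when no event matches (an explicit error
    instead of a silently empty raster).
    """
    t_start, t_end = float(window[0]), float(window[1])
    if not t_start < t_end:
        raise ValidationError(f"bad window {window}")
    onsets = events.event_times(event_label)
    if onsets.size == 0:
        raise EmptyRasterError(f"no events named {event_label!r} in session")
    spikes = train.spike_times
    lo = np.searchsorted(spikes, onsets + t_start, side="left")
    hi = np.searchsorted(spikes, onsets + t_end, side="left")
    trials = [spikes[a:b] - t0 for a, b, t0 in zip(lo, hi, onsets)]
    return PeriEventRaster(train.unit_id, event_label, (t_start, t_end), trials)


# ---------------------------------------------------------------------------
# On-disk schemas: spikes.csv, events.csv, layout.json
# ---------------------------------------------------------------------------

def write_session(out_dir, trains: Sequence[SpikeTrain], events: SessionEvents,
                  layouts: Mapping[str, ProbeLayout]) -> dict:
    """Write spikes.csv / events.csv / layout.json under ``out_dir``.

    ``layouts`` maps area ("AMY"/"SN") to its probe layout.  Returns the paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in trains:
        rows.append(pd.DataFrame({
            "unit_id": tr.unit_id,
            "area": tr.area,
            "channel_index": tr.channel_index,
            "spike_time_s": tr.spike_times,
        }))
    spikes = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["unit_id", "area", "channel_index",
                                         "spike_time_s"]))
    paths = {
        "spikes": out_dir / "spikes.csv",
        "events": out_dir / "events.csv",
        "layout": out_dir / "layout.json",
    }
    # %.17g guarantees binary round trip of the float64 timestamps
    spikes.to_csv(paths["spikes"], index=False, float_format="%.17g")
    events.table.to_csv(paths["events"], index=False, float_format="%.17g")
    payload = {"probes": [
        {"probe_id": layout.probe_id,
         "area": area,
         "contact_positions_mm": layout.contact_positions_mm.tolist(),
         "port_positions_mm": layout.port_positions_mm.tolist()}
        for area, layout in layouts.items()]}
    paths["layout"].write_text(json.dumps(payload, indent=1))
    return paths


def _read_layouts(layout_path) -> dict:
    raw = json.loads(Path(layout_path).read_text())
    entries = raw["probes"] if "probes" in raw else [raw]
    layouts = {}
    for entry in entries:
        try:
            layout = ProbeLayout(entry["probe_id"],
                                 entry["contact_positions_mm"],
                                 entry.get("port_positions_mm", []))
        except KeyError as exc:
            raise SchemaError(f"layout file missing field {exc}") from exc
        layouts[entry.get("area", layout.probe_id)] = layout
    return layouts


def read_session(spikes_path, events_path, layout_path):
    """Read and validate a session from the three on-disk files.

    Returns ``(trains, events, layouts)`` where ``layouts`` maps area to
    :class:`ProbeLayout`.  Schema or invariant violations raise
    :class:`SchemaError` / :class:`ValidationError` naming field and row.
    """
    layouts = _read_layouts(layout_path)
    spikes = pd.read_csv(spikes_path, float_precision="round_trip")
    required = {"unit_id", "area", "channel_index", "spike_time_s"}
    missing = required - set(spikes.columns)
    if missing:
        raise SchemaError(f"spikes file missing columns {sorted(missing)}")
    trains = []
    for unit_id, grp in spikes.groupby("unit_id", sort=False):
        area = grp["area"].iloc[0]
        channel = int(grp["channel_index"].iloc[0])
        train = SpikeTrain(str(unit_id), str(area), channel,
                           grp["spike_time_s"].to_numpy())
        layout = layouts.get(train.area)
        if layout is not None and train.channel_index >= layout.n_contacts:
            raise ValidationError(
                f"unit {unit_id!r}: channel {channel} outside "
                f"{layout.probe_id!r} ({layout.n_contacts} contacts)")
        trains.append(train)
    events_tbl = pd.read_csv(events_path, float_precision="round_trip")
    if "event_kind" not in events_tbl.columns:
        raise SchemaError("events file missing column 'event_kind'")
    events = SessionEvents(events_tbl)
    return trains, events, layouts
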