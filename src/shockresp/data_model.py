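"""Shared domain types and plain-text readers/writers.

All times are seconds, floating point, zero-based from recording start.
Alignment windows are half-open ``[a, b)``.  CSV files are comma-separated
with a mandatory header row and ``.`` as the decimal separator.

Readers are total: any input file either parses into a validated typed
object or raises a :class:`ParseError` / :class:`SchemaError` /
:class:`ValidationError` that names the offending line or column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("shockresp")

RESULTS_SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ShockrespError(Exception):
    """Base class for all package errors."""


class ParseError(ShockrespError):
    """A file could not be parsed (names the line where parsing failed)."""


class SchemaError(ShockrespError):
    """A CSV is missing a required column or carries illegal values."""


class ValidationError(ShockrespError):
    """A parsed object violates a domain-type invariant."""


class InsufficientDataError(ShockrespError):
    """Too few samples/spikes/trials for the requested statistic."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Ordered spike times of one extracellular unit.

    ``spike_times`` must be strictly increasing and contained in
    ``[t_start, t_stop]``.  Duplicate timestamps are invalid: a single
    unit cannot fire twice at one instant at millisecond resolution.
    """

    spike_times: np.ndarray
    t_start: float = 0.0
    t_stop: Optional[float] = None
    unit_id: str = "unit0"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError("spike_times must be one-dimensional")
        if self.t_stop is None:
            self.t_stop = float(self.spike_times[-1]) if self.n_spikes else self.t_start
        self.t_start = float(self.t_start)
        self.t_stop = float(self.t_stop)
        if self.t_stop < self.t_start:
            raise ValidationError("t_stop must be >= t_start")
        d = np.diff(self.spike_times)
        if np.any(d == 0):
            raise ValidationError("duplicate spike timestamps are invalid")
        if np.any(d < 0):
            raise ValidationError("spike_times must be strictly increasing")
        if self.n_spikes and (
            self.spike_times[0] < self.t_start or self.spike_times[-1] > self.t_stop
        ):
            raise ValidationError("spike_times must lie within [t_start, t_stop]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds."""
        return np.diff(self.spike_times)


@dataclass
class EventSeries:
    """Stimulus onset times with shared per-event metadata."""

    event_times: np.ndarray
    event_duration: float = 0.5
    amplitude: float = 3.0

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        d = np.diff(self.event_times)
        if np.any(d <= 0):
            raise ValidationError("event_times must be strictly increasing")
        if self.event_duration < 0:
            raise ValidationError("event_duration must be >= 0")
        if d.size and np.any(d < self.event_duration):
            raise ValidationError(
                "consecutive events closer than event_duration overlap"
            )

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)

    @property
    def inter_event_interval(self) -> float:
        """Median interval between consecutive events (s); nan for <2 events."""
        d = np.diff(self.event_times)
        return float(np.median(d)) if d.size else float("nan")


SIGNAL_CHANNEL = 470
REFERENCE_CHANNEL = 405


@dataclass
class PhotometryRecording:
    """Interleaved two-wavelength fluorescence samples.

    The 470 nm channel carries calcium-dependent fluorescence; 405 nm is
    the isosbestic reference reporting calcium-independent changes
    (movement artifacts, bleaching).
    """

    sample_times: np.ndarray
    channel_labels: np.ndarray  # int, 470 or 405 per sample
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.channel_labels = np.asarray(self.channel_labels, dtype=int)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        n = self.sample_times.size
        if self.channel_labels.size != n or self.fluorescence.size != n:
            raise ValidationError("photometry columns must have equal length")
        if np.any(np.diff(self.sample_times) < 0):
            raise ValidationError("sample_times must be increasing")
        labels = set(np.unique(self.channel_labels).tolist())
        if not labels <= {SIGNAL_CHANNEL, REFERENCE_CHANNEL}:
            raise ValidationError(f"unknown channel labels: {labels}")

    @property
    def alternation_rate(self) -> float:
        """Per-channel sampling rate in Hz estimated from the 470 channel."""
        t = self.sample_times[self.channel_labels == SIGNAL_CHANNEL]
        if t.size < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(t)))


@dataclass(frozen=True)
class ShuttleTrial:
    trial_index: int
    shock_onset: float
    escape_time: Optional[float]  # s from shock onset; None = failure


@dataclass
class ShuttleSession:
    """One shuttle-box session: escapable foot-shocks with escape latencies."""

    trials: list[ShuttleTrial]
    shock_max_duration: float = 10.0

    def __post_init__(self) -> None:
        idx = [t.trial_index for t in self.trials]
        if len(idx) != len(set(idx)):
            raise ValidationError("trial_index values must be unique")
        for t in self.trials:
            if t.escape_time is not None and not (
                0.0 < t.escape_time <= self.shock_max_duration
            ):
                raise ValidationError(
                    f"trial {t.trial_index}: escape_time {t.escape_time} outside "
                    f"(0, {self.shock_max_duration}]"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class SynapticCellRecord:
    """Whole-cell record: evoked current magnitudes and recording QC trace.

    Current magnitudes are stored as positive scalars; sign conventions
    (inward negative at -60 mV) are normalized at the reader.
    """

    cell_id: str
    connected: bool
    I_ampa: float = 0.0  # pA magnitude at -60 mV
    I_gaba: float = 0.0  # pA magnitude at +10 mV
    access_resistance_series: np.ndarray = field(
        default_factory=lambda: np.array([10.0])
    )
    group: str = ""
    amp1: Optional[float] = None  # paired-pulse first amplitude, pA
    amp2: Optional[float] = None

    def __post_init__(self) -> None:
        self.access_resistance_series = np.asarray(
            self.access_resistance_series, dtype=float
        )
        if self.I_ampa < 0 or self.I_gaba < 0:
            raise ValidationError("current magnitudes must be >= 0")
        if np.any(self.access_resistance_series <= 0):
            raise ValidationError("access resistance must be positive")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return df


def read_spike_train(
    path,
    unit_id: Optional[str] = None,
    t_start: float = 0.0,
    t_stop: Optional[float] = None,
) -> SpikeTrain:
    """Read spike times from a one-float-per-line file or a (unit,time_s) CSV.

    Out-of-order files are sorted with a logged warning; duplicate
    timestamps raise :class:`ValidationError`.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln]
    if not lines:
        raise ParseError(f"{path}: empty spike file")
    header = lines[0][1].replace(" ", "").lower()
    if header.startswith("unit,"):
        df = _read_csv(path, ["unit", "time_s"])
        if df.empty:
            raise ParseError(f"{path}: no spike rows")
        if unit_id is not None:
            df = df[df["unit"].astype(str) == str(unit_id)]
            if df.empty:
                raise ParseError(f"{path}: no rows for unit '{unit_id}'")
        elif df["unit"].nunique() > 1:
            raise SchemaError(
                f"{path}: multiple units present; pass unit_id to select one"
            )
        times = pd.to_numeric(df["time_s"], errors="coerce").to_numpy()
        if np.any(~np.isfinite(times)):
            bad = int(df.index[~np.isfinite(times)][0]) + 2  # header + 1-based
            raise ParseError(f"{path}: non-numeric time_s at line {bad}")
        unit = str(unit_id) if unit_id is not None else str(df["unit"].iloc[0])
    else:
        times_list = []
        for lineno, ln in lines:
            try:
                times_list.append(float(ln))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric value '{ln}' at line {lineno}"
                ) from exc
        times = np.asarray(times_list)
        unit = unit_id if unit_id is not None else path.stem
    if np.any(np.diff(times) < 0):
        logger.warning("%s: spike times out of order; sorting", path)
        times = np.sort(times)
    if t_stop is None:
        t_stop = float(times[-1])
    return SpikeTrain(times, t_start=t_start, t_stop=t_stop, unit_id=unit)


def read_events(path) -> EventSeries:
    """Read a stimulus-event CSV with columns event_time_s,duration_s,amplitude."""
    df = _read_csv(path, ["event_time_s", "duration_s", "amplitude"])
    if df.empty:
        raise ParseError(f"{path}: no event rows")
    durations = df["duration_s"].to_numpy(dtype=float)
    amplitudes = df["amplitude"].to_numpy(dtype=float)
    if np.unique(durations).size > 1 or np.unique(amplitudes).size > 1:
        raise SchemaError(f"{path}: heterogeneous duration_s/amplitude not supported")
    return EventSeries(
        df["event_time_s"].to_numpy(dtype=float),
        event_duration=float(durations[0]),
        amplitude=float(amplitudes[0]),
    )


def read_photometry(path) -> PhotometryRecording:
    """Read a photometry CSV (time_s,channel,fluorescence); rows are sorted by time."""
    df = _read_csv(path, ["time_s", "channel", "fluorescence"])
    if df.empty:
        raise ParseError(f"{path}: no photometry rows")
    df = df.sort_values("time_s", kind="stable")
    return PhotometryRecording(
        df["time_s"].to_numpy(dtype=float),
        df["channel"].to_numpy(dtype=int),
        df["fluorescence"].to_numpy(dtype=float),
    )


def read_shuttle(path, shock_max_duration: float = 10.0) -> ShuttleSession:
    """Read a shuttle-box CSV (trial,shock_onset_s,escape_time_s).

    An empty escape_time_s cell means the mouse failed to shuttle within
    the shock.
    """
    df = _read_csv(path, ["trial", "shock_onset_s", "escape_time_s"])
    if df.empty:
        raise ParseError(f"{path}: no trial rows")
    trials = []
    for _, row in df.iterrows():
        esc = row["escape_time_s"]
        esc = None if pd.isna(esc) else float(esc)
        trials.append(ShuttleTrial(int(row["trial"]), float(row["shock_onset_s"]), esc))
    return ShuttleSession(trials, shock_max_duration=shock_max_duration)


def read_synaptic_cells(path) -> list[SynapticCellRecord]:
    """Read a slice-physiology cell table.

    Columns: cell_id, group, connected (0/1), I_ampa_pA, I_gaba_pA,
    amp1_pA, amp2_pA, Ra_series (semicolon-separated MOhm).  Current
    signs are normalized to magnitudes.
    """
    df = _read_csv(
        path, ["cell_id", "group", "connected", "I_ampa_pA", "I_gaba_pA", "Ra_series"]
    )
    cells = []
    for _, row in df.iterrows():
        ra = np.array([float(x) for x in str(row["Ra_series"]).split(";") if x])
        amp1 = row.get("amp1_pA")
        amp2 = row.get("amp2_pA")
        cells.append(
            SynapticCellRecord(
                cell_id=str(row["cell_id"]),
                group=str(row["group"]),
                connected=bool(int(row["connected"])),
                I_ampa=abs(float(row["I_ampa_pA"])),
                I_gaba=abs(float(row["I_gaba_pA"])),
                access_resistance_series=ra,
                amp1=None if pd.isna(amp1) else abs(float(amp1)),
                amp2=None if pd.isna(amp2) else abs(float(amp2)),
            )
        )
    if not cells:
        raise ParseError(f"{path}: no cell rows")
    return cells


@dataclass
class PositionTrack:
    """Video-tracked animal position in a rectangular arena."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_size: tuple[float, float] = (50.0, 50.0)  # cm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.size == self.x.size == self.y.size):
            raise ValidationError("track columns must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("track time must be strictly increasing")
        w, h = self.arena_size
        if np.any((self.x < 0) | (self.x > w) | (self.y < 0) | (self.y > h)):
            raise ValidationError("positions outside arena bounds")


def read_track(path, arena_size: tuple[float, float] = (50.0, 50.0)) -> PositionTrack:
    """Read a position track CSV (time_s,x_cm,y_cm)."""
    df = _read_csv(path, ["time_s", "x_cm", "y_cm"])
    if df.empty:
        raise ParseError(f"{path}: no track rows")
    return PositionTrack(
        df["time_s"].to_numpy(dtype=float),
        df["x_cm"].to_numpy(dtype=float),
        df["y_cm"].to_numpy(dtype=float),
        arena_size=arena_size,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_spike_train(train: SpikeTrain, path) -> None:
    pd.DataFrame({"unit": train.unit_id, "time_s": train.spike_times}).to_csv(
        path, index=False
    )


def write_events(events: EventSeries, path) -> None:
    pd.DataFrame(
        {
            "event_time_s": events.event_times,
            "duration_s": events.event_duration,
            "amplitude": events.amplitude,
        }
    ).to_csv(path, index=False)


def write_photometry(rec: PhotometryRecording, path) -> None:
    pd.DataFrame(
        {
            "time_s": rec.sample_times,
            "channel": rec.channel_labels,
            "fluorescence": rec.fluorescence,
        }
    ).to_csv(path, index=False)


def write_shuttle(session: ShuttleSession, path) -> None:
    pd.DataFrame(
        {
            "trial": [t.trial_index for t in session.trials],
            "shock_onset_s": [t.shock_onset for t in session.trials],
            "escape_time_s": [t.escape_time for t in session.trials],
        }
    ).to_csv(path, index=False)


def write_synaptic_cells(cells: Sequence[SynapticCellRecord], path) -> None:
    pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "group": [c.group for c in cells],
            "connected": [int(c.connected) for c in cells],
            "I_ampa_pA": [c.I_ampa for c in cells],
            "I_gaba_pA": [c.I_gaba for c in cells],
            "amp1_pA": [c.amp1 for c in cells],
            "amp2_pA": [c.amp2 for c in cells],
            "Ra_series": [
                ";".join(f"{r:g}" for r in c.access_resistance_series) for c in cells
            ],
        }
    ).to_csv(path, index=False)


def write_results(results: dict, path) -> None:
    """Write an analysis-result dictionary as versioned JSON."""
    payload = {"schema_version": RESULTS_SCHEMA_VERSION, "results": results}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))


def read_results(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if "schema_version" not in payload:
        raise SchemaError(f"{path}: results JSON lacks schema_version")
    return payload["results"]


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
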