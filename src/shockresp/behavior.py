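"""Scoring of escape-behavior assays.

Shuttle-box sessions (30 escapable 10 s foot-shocks; failure = no
shuttle within the shock), looming-stimulus trials (latency to reach the
nest, freezing after escape, escape-first vs freeze-first strategy) and
real-time place aversion (occupancy of the stimulation-paired side and
locomotion velocity) are scored from trial tables or position tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .data_model import (
    PositionTrack,
    ShockrespError,
    ShuttleSession,
    ShuttleTrial,
    ValidationError,
)

logger = logging.getLogger("shockresp")

SHOCK_MAX_DURATION_S = 10.0
EXPECTED_N_TRIALS = 30
FREEZE_SPEED_THRESHOLD_CM_S = 2.0  # below this speed the animal counts as still
FREEZE_MIN_DURATION_S = 1.0  # stillness must last this long to be freezing
LOOMING_SCORING_WINDOW_S = 60.0


def score_shuttle_trial(
    trial: ShuttleTrial, shock_max_duration: float = SHOCK_MAX_DURATION_S
) -> tuple[Optional[float], bool]:
    """Latency and failure flag for one escapable-shock trial.

    Failure means no shuttle to the opposite compartment within the
    shock; an escape at exactly the shock end counts as success (the
    shock ends when the animal shuttles).
    """
    esc = trial.escape_time
    if esc is None:
        return None, True
    if not (0.0 < esc <= shock_max_duration):
        raise ValidationError(
            f"trial {trial.trial_index}: escape_time {esc} outside "
            f"(0, {shock_max_duration}]"
        )
    return float(esc), False


@dataclass
class SessionSummary:
    """Failure rate and escape latencies of one shuttle-box session."""

    n_trials: int
    n_failures: int
    failure_rate: float  # %
    mean_latency: Optional[float]  # s, over successful trials by default
    latencies: list[Optional[float]] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        return 100.0 - self.failure_rate


def summarize_shuttle_session(
    session: ShuttleSession, impute_failures_at_max: bool = False
) -> SessionSummary:
    """Failure rate (%) and mean escape latency over a session.

    Failed trials are excluded from the latency mean by default (failure
    and latency are reported as separate measures);
    ``impute_failures_at_max`` instead scores failures at the maximum
    shock duration.  Sessions with other than 30 trials are summarized
    with a warning.
    """
    if session.n_trials == 0:
        raise ShockrespError("cannot summarize an empty session")
    if session.n_trials != EXPECTED_N_TRIALS:
        logger.warning(
            "session has %d trials (expected %d)", session.n_trials, EXPECTED_N_TRIALS
        )
    latencies: list[Optional[float]] = []
    n_failures = 0
    for trial in session.trials:
        lat, failed = score_shuttle_trial(trial, session.shock_max_duration)
        latencies.append(lat)
        n_failures += failed
    if impute_failures_at_max:
        included = [
            lat if lat is not None else session.shock_max_duration for lat in latencies
        ]
    else:
        included = [lat for lat in latencies if lat is not None]
    mean_lat = float(np.mean(included)) if included else None
    return SessionSummary(
        n_trials=session.n_trials,
        n_failures=n_failures,
        failure_rate=100.0 * n_failures / session.n_trials,
        mean_latency=mean_lat,
        latencies=latencies,
    )


def _speeds(track: PositionTrack) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval speeds (cm/s) and interval durations (s)."""
    dt = np.diff(track.time)
    dist = np.hypot(np.diff(track.x), np.diff(track.y))
    return dist / dt, dt


def _still_bouts(
    track: PositionTrack,
    speed_threshold: float,
    min_duration: float,
    t_from: float,
    t_to: float,
) -> list[tuple[float, float]]:
    """Maximal runs of sub-threshold speed lasting >= min_duration within [t_from, t_to]."""
    speeds, dt = _speeds(track)
    t0 = track.time[:-1]
    t1 = track.time[1:]
    still = (speeds < speed_threshold) & (t0 >= t_from) & (t1 <= t_to)
    bouts = []
    i = 0
    n = still.size
    while i < n:
        if still[i]:
            j = i
            while j + 1 < n and still[j + 1]:
                j += 1
            start, stop = float(t0[i]), float(t1[j])
            if stop - start >= min_duration:
                bouts.append((start, stop))
            i = j + 1
        else:
            i += 1
    return bouts


@dataclass
class LoomingScore:
    escape_latency: Optional[float]  # s from stimulus onset; None = censored
    escape_censored: bool
    freezing_time: float  # s, after nest entry
    strategy: Optional[str]  # "escape-first" | "freeze-first"


def score_looming(
    track: PositionTrack,
    stimulus_onset: float,
    nest: Sequence[tuple[float, float]],
    freeze_speed_threshold: float = FREEZE_SPEED_THRESHOLD_CM_S,
    freeze_min_duration: float = FREEZE_MIN_DURATION_S,
    scoring_window: float = LOOMING_SCORING_WINDOW_S,
) -> LoomingScore:
    """Escape latency, post-escape freezing and defensive strategy.

    Escape latency is the first entry of the tracked position into the
    nest polygon after stimulus onset.  Freezing time totals the still
    bouts (speed below threshold for at least ``freeze_min_duration``)
    after nest entry within the scoring window.  The strategy label is
    decided by whichever criterion is met first after onset: nest entry
    (escape-first) or a freezing bout (freeze-first).  No nest entry
    within the window censors the latency.
    """
    poly = MplPath(np.asarray(nest, dtype=float))
    window_end = stimulus_onset + scoring_window
    in_window = (track.time >= stimulus_onset) & (track.time <= window_end)
    inside = poly.contains_points(np.column_stack([track.x, track.y]))
    entries = np.flatnonzero(inside & in_window)
    entry_time = float(track.time[entries[0]]) if entries.size else None

    first_freeze = None
    bouts = _still_bouts(
        track, freeze_speed_threshold, freeze_min_duration, stimulus_onset, window_end
    )
    if bouts:
        first_freeze = bouts[0][0]

    if entry_time is None:
        logger.warning("no nest entry within %.0f s of onset; latency censored",
                       scoring_window)
        freezing = sum(b - a for a, b in bouts)
        strategy = "freeze-first" if first_freeze is not None else None
        return LoomingScore(None, True, float(freezing), strategy)

    post_entry_bouts = _still_bouts(
        track, freeze_speed_threshold, freeze_min_duration, entry_time, window_end
    )
    freezing = float(sum(b - a for a, b in post_entry_bouts))
    if first_freeze is not None and first_freeze < entry_time:
        strategy = "freeze-first"
    else:
        strategy = "escape-first"
    return LoomingScore(entry_time - stimulus_onset, False, freezing, strategy)


def _parse_half_plane(side: str) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Parse a half-plane spec like ``x>25`` or ``y<=10`` into a predicate."""
    s = side.replace(" ", "")
    for op in (">=", "<=", ">", "<"):
        if op in s:
            axis, value = s.split(op)
            if axis not in ("x", "y"):
                raise ShockrespError(f"unknown axis in side spec '{side}'")
            v = float(value)
            fn = {
                ">": np.greater,
                "<": np.less,
                ">=": np.greater_equal,
                "<=": np.less_equal,
            }[op]
            return lambda x, y: fn(x if axis == "x" else y, v)
    raise ShockrespError(f"cannot parse side spec '{side}'")


def score_rtpa(
    track: PositionTrack,
    stimulation_side: str | Callable[[np.ndarray, np.ndarray], np.ndarray],
    max_gap_s: float = 1.0,
) -> tuple[float, float]:
    """Occupancy of the stimulation-paired side and mean locomotion velocity.

    Occupancy is sample-time weighted: each inter-sample interval is
    attributed to the side occupied at its start.  Velocity is the mean
    of finite-difference speeds.  Tracking gaps longer than ``max_gap_s``
    trigger a warning (the interval is still linearly attributed).
    """
    pred = (
        _parse_half_plane(stimulation_side)
        if isinstance(stimulation_side, str)
        else stimulation_side
    )
    speeds, dt = _speeds(track)
    if np.any(dt > max_gap_s):
        logger.warning(
            "track has %d gaps longer than %.1f s; occupancy interpolated across them",
            int(np.sum(dt > max_gap_s)),
            max_gap_s,
        )
    on_side = np.asarray(pred(track.x[:-1], track.y[:-1]), dtype=bool)
    percent = 100.0 * float(dt[on_side].sum()) / float(dt.sum())
    mean_velocity = float(np.average(speeds, weights=dt))
    return percent, mean_velocity
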