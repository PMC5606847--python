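"""Two-wavelength fiber-photometry processing.

The 470 nm excitation reports calcium-dependent GCaMP fluorescence and
the 405 nm (isosbestic) excitation reports calcium-independent changes
such as movement artifacts.  The pipeline demultiplexes the interleaved
channels, computes dF/F = (F - F0)/F0 per channel with F0 the median of
a baseline window, subtracts the 405 dF/F from the 470 dF/F, and builds
event-triggered averages of the corrected trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import (
    REFERENCE_CHANNEL,
    SIGNAL_CHANNEL,
    EventSeries,
    InsufficientDataError,
    PhotometryRecording,
    ShockrespError,
)

logger = logging.getLogger("shockresp")

F0_BASELINE_S = 10.0  # F0 = median over the first 10 s of each trial


@dataclass
class FluorescenceTrace:
    """Raw single-channel fluorescence on its own timestamps."""

    time: np.ndarray
    fluorescence: np.ndarray
    channel: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)


@dataclass
class DffTrace:
    """Fractional fluorescence change of one channel (or the corrected signal)."""

    time: np.ndarray
    dff: np.ndarray
    f0: float
    channel: str  # "470", "405" or "corrected"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if not np.all(np.isfinite(self.dff)):
            raise ShockrespError("dF/F contains non-finite values")


def demultiplex(rec: PhotometryRecording) -> tuple[FluorescenceTrace, FluorescenceTrace]:
    """Split an interleaved recording into the 470 and 405 traces."""
    out = []
    for ch in (SIGNAL_CHANNEL, REFERENCE_CHANNEL):
        mask = rec.channel_labels == ch
        if mask.sum() < 2:
            raise InsufficientDataError(f"channel {ch} has fewer than 2 samples")
        out.append(
            FluorescenceTrace(rec.sample_times[mask], rec.fluorescence[mask], ch)
        )
    return out[0], out[1]


def compute_dff(
    trace: FluorescenceTrace,
    baseline_window: tuple[float, float] | None = None,
    f0_statistic: str = "median",
) -> DffTrace:
    """dF/F = (F - F0)/F0 with F0 a robust statistic of a baseline window.

    The default baseline window is the first 10 s of the trace (the
    trial-start convention); ``f0_statistic`` may be ``median`` (default,
    robust to transients in the baseline) or ``mean``.  A non-positive
    F0 is non-physical and raises.
    """
    if baseline_window is None:
        t0 = float(trace.time[0])
        baseline_window = (t0, t0 + F0_BASELINE_S)
    a, b = baseline_window
    mask = (trace.time >= a) & (trace.time < b)
    if not mask.any():
        raise ShockrespError(f"no samples in baseline window [{a}, {b})")
    stat = {"median": np.median, "mean": np.mean}.get(f0_statistic)
    if stat is None:
        raise ShockrespError(f"unknown f0 statistic '{f0_statistic}'")
    f0 = float(stat(trace.fluorescence[mask]))
    if f0 <= 0:
        raise ShockrespError(f"non-physical baseline fluorescence F0={f0}")
    return DffTrace(
        time=trace.time,
        dff=(trace.fluorescence - f0) / f0,
        f0=f0,
        channel=str(trace.channel),
    )


def isosbestic_correct(
    dff470: DffTrace, dff405: DffTrace, scaled_regression: bool = False
) -> DffTrace:
    """Subtract the isosbestic dF/F from the calcium-dependent dF/F.

    When the two channels are interleaved, the 405 trace is linearly
    interpolated onto the 470 timestamps before subtraction (the samples
    are offset by half an alternation period).  Plain subtraction is the
    default and cancels exactly any contamination that is additive and
    equal in dF/F units across channels; ``scaled_regression=True``
    instead fits ``dff470 ~ a*dff405 + b`` by least squares and subtracts
    the fit, which tolerates channel gain mismatch.
    """
    if dff470.time.size == dff405.time.size and np.allclose(
        dff470.time, dff405.time
    ):
        ref = dff405.dff
    else:
        if (
            dff405.time[0] > dff470.time[0] + 1e-9
            or dff405.time[-1] < dff470.time[-1] - 1e-9
        ):
            logger.warning(
                "405 trace does not fully cover the 470 timestamps; "
                "edge samples are extrapolated by endpoint hold"
            )
        ref = np.interp(dff470.time, dff405.time, dff405.dff)
    if scaled_regression:
        a, b = np.polyfit(ref, dff470.dff, 1)
        corrected = dff470.dff - (a * ref + b)
    else:
        corrected = dff470.dff - ref
    return DffTrace(
        time=dff470.time, dff=corrected, f0=dff470.f0, channel="corrected"
    )


def process_recording(
    rec: PhotometryRecording,
    baseline_window: tuple[float, float] | None = None,
    scaled_regression: bool = False,
) -> tuple[DffTrace, DffTrace, DffTrace]:
    """Demultiplex, compute per-channel dF/F, and isosbestic-correct.

    Returns ``(dff470, dff405, corrected)``.
    """
    sig, ref = demultiplex(rec)
    d470 = compute_dff(sig, baseline_window)
    d405 = compute_dff(ref, baseline_window)
    return d470, d405, isosbestic_correct(d470, d405, scaled_regression)


@dataclass
class EventTriggeredAverage:
    """Pointwise mean +/- SEM of peri-event dF/F snippets."""

    lag: np.ndarray  # s relative to event onset
    mean_dff: np.ndarray
    sem_dff: np.ndarray
    n_events: int

    @property
    def peak(self) -> float:
        return float(np.max(self.mean_dff))


def event_triggered_average(
    dff: DffTrace, events: EventSeries, pre_s: float, post_s: float
) -> EventTriggeredAverage:
    """Average dF/F snippets aligned at each event onset (lag 0).

    Snippets are sampled on a uniform lag grid at the trace's native
    sampling interval via linear interpolation.  Events whose peri-event
    window falls outside the trace are excluded with a warning.
    """
    if dff.time.size < 2:
        raise InsufficientDataError("trace too short for an event-triggered average")
    dt = float(np.median(np.diff(dff.time)))
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    lag = (np.arange(n_pre + n_post + 1) - n_pre) * dt
    snippets = []
    for e in events.event_times:
        t = e + lag
        if t[0] < dff.time[0] - 1e-9 or t[-1] > dff.time[-1] + 1e-9:
            logger.warning("event at t=%.3f s outside trace span; excluded", e)
            continue
        snippets.append(np.interp(t, dff.time, dff.dff))
    if not snippets:
        raise ShockrespError("no events with a complete peri-event window")
    stack = np.vstack(snippets)
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        sem = np.zeros_like(mean)
    return EventTriggeredAverage(
        lag=lag, mean_dff=mean, sem_dff=sem, n_events=stack.shape[0]
    )
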