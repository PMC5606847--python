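"""Peristimulus time histograms and the evoked-excitation criterion.

A PSTH is built by summing spike counts over stimulus-aligned sweeps in
10 ms bins covering a 2 s pre-stimulus baseline and a post window.  A
unit counts as excited when the mean spikes/bin in at least one of the
four 50 ms epochs after stimulus onset exceeds the baseline mean by
more than twice the baseline SD.  Onset, duration and magnitude of the
response are then extracted with consecutive-bin run rules, and PSTHs
are baseline-normalized per sweep for population averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import EventSeries, ShockrespError, SpikeTrain

PSTH_BIN_MS = 10.0
PSTH_PRE_S = 2.0
PSTH_POST_S = 1.0
EPOCH_MS = 50.0
N_EPOCHS = 4
SD_MULTIPLIER = 2.0
ONSET_CONSECUTIVE_BINS = 2
OFFSET_CONSECUTIVE_BINS = 5


@dataclass
class PSTH:
    """Sweep-summed peristimulus histogram with baseline statistics.

    ``counts[b]`` is the total number of spikes over all sweeps in bin
    ``b``; bins are half-open, and time 0 (stimulus onset) is the left
    edge of bin ``n_pre_bins``.  Baseline statistics are computed across
    the pre-window bins of the sweep-summed histogram (sample SD).
    """

    counts: np.ndarray
    bin_ms: float
    pre_s: float
    post_s: float
    n_sweeps: int
    baseline_mean: float  # spikes/bin, summed over sweeps
    baseline_sd: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = self.n_pre_bins + self.n_post_bins
        if self.counts.size != expected:
            raise ShockrespError(
                f"PSTH has {self.counts.size} bins, expected {expected}"
            )

    @property
    def n_pre_bins(self) -> int:
        return int(round(self.pre_s * 1000.0 / self.bin_ms))

    @property
    def n_post_bins(self) -> int:
        return int(round(self.post_s * 1000.0 / self.bin_ms))

    @property
    def bin_edges_ms(self) -> np.ndarray:
        """Bin edges in ms relative to stimulus onset."""
        return (np.arange(self.counts.size + 1) - self.n_pre_bins) * self.bin_ms

    @property
    def threshold(self) -> float:
        """Excitation threshold: baseline mean + 2 baseline SDs (spikes/bin)."""
        return self.baseline_mean + SD_MULTIPLIER * self.baseline_sd

    def post_counts(self) -> np.ndarray:
        return self.counts[self.n_pre_bins :]


def build_psth(
    train: SpikeTrain,
    events: EventSeries,
    bin_ms: float = PSTH_BIN_MS,
    pre_s: float = PSTH_PRE_S,
    post_s: float = PSTH_POST_S,
) -> PSTH:
    """Sum spike counts over sweeps aligned at each event onset.

    Every sweep window ``[event - pre, event + post)`` must lie inside
    the recording span; offending events are reported in the error.
    """
    if bin_ms <= 0 or pre_s < 0 or post_s <= 0:
        raise ShockrespError("bin width and post window must be positive")
    for name, span in (("pre", pre_s), ("post", post_s)):
        nb = span * 1000.0 / bin_ms
        if abs(nb - round(nb)) > 1e-9:
            raise ShockrespError(f"{name} window is not a whole number of bins")
    bad = [
        float(e)
        for e in events.event_times
        if e - pre_s < train.t_start or e + post_s > train.t_stop
    ]
    if bad:
        raise ShockrespError(f"event sweeps outside recording span at t={bad}")
    n_pre = int(round(pre_s * 1000.0 / bin_ms))
    n_post = int(round(post_s * 1000.0 / bin_ms))
    edges_s = (np.arange(n_pre + n_post + 1) - n_pre) * (bin_ms / 1000.0)
    counts = np.zeros(n_pre + n_post, dtype=np.int64)
    for e in events.event_times:
        rel = train.spike_times - e
        lo, hi = np.searchsorted(rel, [edges_s[0], edges_s[-1]], side="left")
        counts += np.histogram(rel[lo:hi], bins=edges_s)[0]
    baseline = counts[:n_pre].astype(float)
    if n_pre >= 2:
        b_mean, b_sd = float(baseline.mean()), float(baseline.std(ddof=1))
    elif n_pre == 1:
        b_mean, b_sd = float(baseline[0]), 0.0
    else:
        b_mean = b_sd = 0.0
    return PSTH(
        counts=counts,
        bin_ms=bin_ms,
        pre_s=pre_s,
        post_s=post_s,
        n_sweeps=events.n_events,
        baseline_mean=b_mean,
        baseline_sd=b_sd,
    )


def classify_excitation(psth: PSTH) -> tuple[bool, Optional[int]]:
    """Apply the four-epoch baseline + 2 SD excitation criterion.

    Splits the first 200 ms after stimulus onset into four 50 ms epochs
    and compares each epoch's mean spikes/bin against
    ``baseline_mean + 2 * baseline_sd`` (strict inequality; a tie does
    not count).  Returns ``(excited, first crossing epoch index)``.
    """
    bins_per_epoch = int(round(EPOCH_MS / psth.bin_ms))
    needed_ms = N_EPOCHS * EPOCH_MS
    if psth.post_s * 1000.0 < needed_ms:
        raise ShockrespError(
            f"post window {psth.post_s * 1000:.0f} ms shorter than the "
            f"{needed_ms:.0f} ms epoch criterion"
        )
    post = psth.post_counts()
    thr = psth.threshold
    for e in range(N_EPOCHS):
        epoch = post[e * bins_per_epoch : (e + 1) * bins_per_epoch]
        if float(epoch.mean()) > thr:
            return True, e
    return False, None


def response_onset(
    psth: PSTH, search_window_ms: Optional[float] = None
) -> Optional[float]:
    """Latency (ms) of the first run of >= 2 consecutive supra-threshold bins.

    Returns the left edge of the first post-stimulus bin that, together
    with its successor, exceeds baseline mean + 2 SD; ``None`` when no
    such pair exists (single isolated supra-threshold bins do not
    qualify).  By default the whole post window is searched.
    """
    post = psth.post_counts()
    if search_window_ms is not None:
        post = post[: int(round(search_window_ms / psth.bin_ms))]
    above = post > psth.threshold
    for b in range(above.size - ONSET_CONSECUTIVE_BINS + 1):
        if above[b : b + ONSET_CONSECUTIVE_BINS].all():
            return b * psth.bin_ms
    return None


def response_duration(psth: PSTH, onset_ms: float) -> tuple[float, bool]:
    """Response duration (ms) from onset to the return to baseline.

    The response terminates at the start of the first run of >= 5
    consecutive bins not different from baseline (count <= baseline mean
    + 2 SD) occurring after onset.  Returns ``(duration_ms, censored)``;
    if no terminating run exists before the end of the post window the
    duration is censored there.
    """
    post = psth.post_counts()
    start = int(round(onset_ms / psth.bin_ms))
    below = post <= psth.threshold
    run = OFFSET_CONSECUTIVE_BINS
    for b in range(start + 1, below.size - run + 1):
        if below[b : b + run].all():
            return b * psth.bin_ms - onset_ms, False
    return post.size * psth.bin_ms - onset_ms, True


def response_magnitude(psth: PSTH, onset_ms: float, duration_ms: float) -> float:
    """Evoked rate increase in Hz: response-window rate minus baseline rate.

    Rates are per-sweep: spikes in ``[onset, onset + duration)`` divided
    by ``n_sweeps * duration``, minus the baseline firing rate.
    """
    if duration_ms <= 0:
        raise ShockrespError("response duration must be positive")
    b0 = psth.n_pre_bins + int(round(onset_ms / psth.bin_ms))
    b1 = psth.n_pre_bins + int(round((onset_ms + duration_ms) / psth.bin_ms))
    resp_count = float(psth.counts[b0:b1].sum())
    resp_rate = resp_count / (psth.n_sweeps * duration_ms / 1000.0)
    baseline_rate = psth.baseline_mean / (psth.n_sweeps * psth.bin_ms / 1000.0)
    return resp_rate - baseline_rate


@dataclass
class ResponseProfile:
    """Classification plus onset/duration/magnitude of an evoked response."""

    excited: bool
    epoch_index: Optional[int] = None
    onset_latency_ms: Optional[float] = None
    duration_ms: Optional[float] = None
    duration_censored: bool = False
    magnitude_hz: Optional[float] = None


def analyze_response(
    psth: PSTH, onset_search_window_ms: Optional[float] = None
) -> ResponseProfile:
    """Run the full excitation analysis on one PSTH.

    Non-excited units carry no onset/duration/magnitude.  Excited units
    whose onset is undefined (no pair of consecutive supra-threshold
    bins) are flagged by an absent onset.
    """
    excited, epoch = classify_excitation(psth)
    if not excited:
        return ResponseProfile(excited=False)
    onset = response_onset(psth, onset_search_window_ms)
    if onset is None:
        return ResponseProfile(excited=True, epoch_index=epoch)
    duration, censored = response_duration(psth, onset)
    magnitude = response_magnitude(psth, onset, duration)
    return ResponseProfile(
        excited=True,
        epoch_index=epoch,
        onset_latency_ms=onset,
        duration_ms=duration,
        duration_censored=censored,
        magnitude_hz=magnitude,
    )


@dataclass
class NormalizedPSTH:
    """Per-sweep, baseline-subtracted PSTH of one cell.

    ``values[b] = counts[b]/n_sweeps - baseline_mean/n_sweeps``, so the
    mean over the baseline window is 0 by construction.
    """

    values: np.ndarray
    bin_ms: float
    pre_s: float
    post_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def normalize_psth(psth: PSTH) -> NormalizedPSTH:
    """Subtract the per-sweep averaged baseline from every per-sweep bin."""
    values = psth.counts / psth.n_sweeps - psth.baseline_mean / psth.n_sweeps
    return NormalizedPSTH(
        values=values, bin_ms=psth.bin_ms, pre_s=psth.pre_s, post_s=psth.post_s
    )


def population_psth(
    cells: Sequence[NormalizedPSTH],
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SEM across cells of normalized PSTHs.

    All cells must share bin width and windows.
    """
    if not cells:
        raise ShockrespError("population PSTH needs at least one cell")
    ref = cells[0]
    for c in cells[1:]:
        if (c.bin_ms, c.pre_s, c.post_s) != (ref.bin_ms, ref.pre_s, ref.post_s):
            raise ShockrespError("heterogeneous binning across cells")
    stack = np.vstack([c.values for c in cells])
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        sem = np.zeros_like(mean)
    return mean, sem
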