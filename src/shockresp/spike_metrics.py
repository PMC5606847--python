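"""Spontaneous-activity metrics for single-unit spike trains.

Firing rate, interspike-interval (ISI) statistics, burst segmentation by
the two-threshold ISI rule (a burst starts with an ISI < 10 ms and ends
before the first ISI > 20 ms), spike-train autocorrelograms, and a
deterministic operationalization of the classical qualitative firing-mode
labels (regular / irregular / bursting) read off the autocorrelogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .data_model import InsufficientDataError, ShockrespError, SpikeTrain, ValidationError

BURST_START_ISI_MS = 10.0
BURST_END_ISI_MS = 20.0
ACG_BIN_MS = 10.0
ACG_MAX_LAG_MS = 2000.0


def mean_firing_rate(
    train: SpikeTrain, window: Optional[tuple[float, float]] = None
) -> float:
    """Mean firing rate (Hz) over ``window`` = [a, b), default the whole recording.

    An empty train (or empty window) gives 0 Hz; a zero-length window is an
    error.
    """
    if window is None:
        window = (train.t_start, train.t_stop)
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise ShockrespError(f"zero-length or inverted window [{a}, {b})")
    if a < train.t_start or b > train.t_stop:
        raise ShockrespError("window outside recording span")
    lo, hi = np.searchsorted(train.spike_times, [a, b], side="left")
    return float(hi - lo) / (b - a)


def coefficient_of_variation(train: SpikeTrain) -> float:
    """CV of the ISI distribution: sample SD of ISIs over mean ISI.

    0 for clock-like firing, ~1 for Poisson firing.  Uses the unbiased
    (n-1) standard deviation.  Requires at least 2 ISIs (3 spikes).
    """
    isis = train.isis()
    if isis.size < 2:
        raise InsufficientDataError("CV needs at least 2 interspike intervals")
    return float(np.std(isis, ddof=1) / np.mean(isis))


@dataclass
class BurstSegmentation:
    """Result of the two-threshold ISI burst scan.

    ``bursts`` holds half-open index intervals ``(i, j)`` into the spike
    train: spikes ``i .. j-1`` belong to the burst.  Intervals are disjoint
    and ordered; each burst has >= 2 spikes; the first intra-burst ISI is
    below the start threshold, every later intra-burst ISI is at or below
    the end threshold, and the ISI following the burst (if any) exceeds
    the end threshold.
    """

    bursts: list[tuple[int, int]]
    n_spikes: int
    start_isi_threshold: float = BURST_START_ISI_MS  # ms
    end_isi_threshold: float = BURST_END_ISI_MS  # ms

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def spikes_in_bursts(self) -> int:
        return sum(j - i for i, j in self.bursts)

    @property
    def percent_in_bursts(self) -> float:
        if self.n_spikes == 0:
            return 0.0
        return 100.0 * self.spikes_in_bursts / self.n_spikes


def detect_bursts(
    train: SpikeTrain,
    start_isi_ms: float = BURST_START_ISI_MS,
    end_isi_ms: float = BURST_END_ISI_MS,
) -> BurstSegmentation:
    """Segment bursts with a single left-to-right ISI scan.

    A burst is initiated by at least two spikes within ``start_isi_ms``
    (ISI strictly below the threshold); it keeps accruing spikes while
    ISIs stay at or below ``end_isi_ms`` and ends before the first ISI
    that exceeds it.  A spike belongs to at most one burst; the scan
    resumes at the spike following the burst.  Thresholds are in ms,
    spike times in s.
    """
    if start_isi_ms <= 0 or end_isi_ms <= 0:
        raise ShockrespError("burst ISI thresholds must be positive")
    isis_ms = train.isis() * 1000.0
    n = train.n_spikes
    bursts: list[tuple[int, int]] = []
    i = 0
    while i < n - 1:
        if isis_ms[i] < start_isi_ms:
            j = i + 1
            while j < n - 1 and isis_ms[j] <= end_isi_ms:
                j += 1
            bursts.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return BurstSegmentation(
        bursts, n_spikes=n, start_isi_threshold=start_isi_ms, end_isi_threshold=end_isi_ms
    )


@dataclass
class Autocorrelogram:
    """Histogram of all positive pairwise spike-time lags of one unit."""

    lag_bin_edges: np.ndarray  # ms, uniform bins
    counts: np.ndarray
    mode_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.lag_bin_edges = np.asarray(self.lag_bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("autocorrelogram counts must be >= 0")

    @property
    def bin_width(self) -> float:
        return float(self.lag_bin_edges[1] - self.lag_bin_edges[0])

    @property
    def lag_bin_centers(self) -> np.ndarray:
        return 0.5 * (self.lag_bin_edges[:-1] + self.lag_bin_edges[1:])


def autocorrelogram(
    train: SpikeTrain, bin_ms: float = ACG_BIN_MS, max_lag_ms: float = ACG_MAX_LAG_MS
) -> Autocorrelogram:
    """Autocorrelogram over lags in (0, max_lag]; zero-lag self pairs excluded.

    All spike pairs (not only adjacent ones) contribute.  ``bin_ms`` must
    divide ``max_lag_ms`` exactly.
    """
    n_bins = max_lag_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ShockrespError(f"bin {bin_ms} ms does not divide max lag {max_lag_ms} ms")
    if train.n_spikes < 2:
        raise InsufficientDataError("autocorrelogram needs at least 2 spikes")
    t_ms = train.spike_times * 1000.0
    edges = np.linspace(0.0, max_lag_ms, int(round(n_bins)) + 1)
    hi = np.searchsorted(t_ms, t_ms + max_lag_ms, side="right")
    diffs = [t_ms[i + 1 : hi[i]] - t_ms[i] for i in range(t_ms.size - 1)]
    lags = np.concatenate(diffs) if diffs else np.empty(0)
    counts, _ = np.histogram(lags, bins=edges)
    return Autocorrelogram(edges, counts)


@dataclass
class FiringModeConfig:
    """Tunables of the quantitative firing-mode classifier.

    The classical labels are assigned by eye from the autocorrelogram
    shape; this config pins the visual judgement down to numbers so the
    label is deterministic and testable.
    """

    smooth_bins: int = 3  # moving-average width
    peak_sd_multiplier: float = 2.0  # peak must exceed steady state by k Poisson SDs
    spacing_tolerance: float = 0.20  # fraction of the fundamental lag
    early_window_ms: float = 100.0  # window tested for the burst-related peak
    steady_state_fraction: float = 0.25  # last quartile of lags


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w) / w
    # edge bins averaged over the available neighbours only
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def classify_firing_mode(
    acg: Autocorrelogram, config: Optional[FiringModeConfig] = None
) -> str:
    """Label an autocorrelogram as regular / irregular / bursting / unclassified.

    Operationalization of the classical visual read-out:

    - counts are smoothed with a short moving average and the steady-state
      level is estimated from the last quartile of lags, with a Poisson SD
      ``sqrt(steady)``;
    - *bursting*: the mean over the first ``early_window_ms`` significantly
      exceeds the steady state and the histogram's global maximum lies in
      that window (an initial peak decaying to steady state; burst-firing
      autocorrelograms are overdispersed at all lags, so the initial-peak
      shape, not peak counting, is the discriminating feature);
    - *regular*: >= 3 peaks above steady + k*SD whose lags sit at
      near-integer multiples of a common fundamental — specifically peaks
      within the spacing tolerance of 2x and 3x the first peak's lag;
    - *irregular*: the first bin sits significantly below the steady state
      (refractoriness trough rising smoothly to steady state);
    - otherwise *unclassified*.
    """
    cfg = config or FiringModeConfig()
    counts = acg.counts.astype(float)
    if counts.sum() == 0:
        raise InsufficientDataError("empty autocorrelogram cannot be classified")
    sm = _moving_average(counts, cfg.smooth_bins)
    n = counts.size
    tail = max(1, int(round(n * cfg.steady_state_fraction)))
    steady = float(np.mean(sm[-tail:]))
    sd = float(np.sqrt(max(steady, 1.0)))
    k = cfg.peak_sd_multiplier

    # -- bursting: initial peak decaying to steady state --------------------
    n_early = max(1, int(round(cfg.early_window_ms / acg.bin_width)))
    early_mean = float(np.mean(counts[:n_early]))
    sd_of_early_mean = float(np.sqrt(max(steady, 1.0) / n_early))
    if (
        early_mean > steady + k * sd_of_early_mean
        and int(np.argmax(sm)) < n_early
    ):
        return "bursting"

    # -- regular: harmonic peaks -------------------------------------------
    peak_idx, _ = find_peaks(sm, height=steady + k * sd)
    if peak_idx.size >= 3:
        centers = acg.lag_bin_centers
        fundamental = centers[peak_idx[0]]
        tol = cfg.spacing_tolerance * fundamental
        peak_lags = centers[peak_idx]
        harmonics_found = all(
            np.any(np.abs(peak_lags - m * fundamental) <= tol) for m in (2, 3)
        )
        if harmonics_found:
            return "regular"

    # -- irregular: initial refractory trough -------------------------------
    if counts[0] < steady - k * sd:
        return "irregular"

    return "unclassified"


@dataclass
class SpontaneousActivitySummary:
    """Bundle of the spontaneous-activity metrics for one unit."""

    unit_id: str
    firing_rate_hz: float
    cv: Optional[float]
    percent_spikes_in_bursts: float
    n_bursts: int
    mode_label: str
    n_spikes: int = 0
    extras: dict = field(default_factory=dict)


def summarize_spontaneous_activity(
    train: SpikeTrain,
    start_isi_ms: float = BURST_START_ISI_MS,
    end_isi_ms: float = BURST_END_ISI_MS,
    acg_bin_ms: float = ACG_BIN_MS,
    acg_max_lag_ms: float = ACG_MAX_LAG_MS,
) -> SpontaneousActivitySummary:
    """Firing rate, CV, burst percentage and firing mode for one unit."""
    rate = mean_firing_rate(train)
    try:
        cv = coefficient_of_variation(train)
    except InsufficientDataError:
        cv = None
    seg = detect_bursts(train, start_isi_ms, end_isi_ms)
    try:
        acg = autocorrelogram(train, acg_bin_ms, acg_max_lag_ms)
        mode = classify_firing_mode(acg)
    except InsufficientDataError:
        mode = "unclassified"
    return SpontaneousActivitySummary(
        unit_id=train.unit_id,
        firing_rate_hz=rate,
        cv=cv,
        percent_spikes_in_bursts=seg.percent_in_bursts,
        n_bursts=seg.n_bursts,
        mode_label=mode,
        n_spikes=train.n_spikes,
    )
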