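"""Synthetic-data generators with recorded ground truth.

Every analysis input type can be generated with known parameters so the
whole pipeline is testable closed-loop: renewal-process spike trains of
prescribed regularity, stimulus-locked evoked responses (inhomogeneous
Poisson rate steps), two-channel photometry with a shared motion
artifact, shuttle-box sessions, looming-escape tracks and slice-
physiology cohorts.  Each generator takes an explicit seed, draws from
its own :class:`numpy.random.Generator` (no global state), and returns
the dataset together with a :class:`GroundTruth` record; the same seed
and parameters reproduce the output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import (
    REFERENCE_CHANNEL,
    SIGNAL_CHANNEL,
    EventSeries,
    PhotometryRecording,
    PositionTrack,
    ShockrespError,
    ShuttleSession,
    ShuttleTrial,
    SpikeTrain,
    SynapticCellRecord,
)

SPIKE_MODES = ("regular", "irregular", "bursting")
REGULAR_GAMMA_SHAPE = 100.0  # CV = 1/sqrt(shape) = 0.1
IRREGULAR_REFRACTORY_S = 0.002
BURST_SPIKES_RANGE = (3, 6)
BURST_INTRA_ISI_MS = (4.0, 8.0)  # satisfies the <10 ms burst-start rule


@dataclass
class GroundTruth:
    """Name, seed and true parameters of one generator call."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)


def _check_seed(seed: int) -> int:
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ShockrespError("seed must be a non-negative integer")
    return int(seed)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def gen_spike_train(
    mode: str, rate: float, duration: float, seed: int, unit_id: Optional[str] = None
) -> tuple[SpikeTrain, GroundTruth]:
    """Renewal-process spike train of a prescribed firing mode.

    - ``regular``: gamma renewal with shape 100 (CV ~ 0.1) at ``rate`` Hz;
    - ``irregular``: Poisson with a 2 ms absolute refractory period
      (CV ~ 1), mean rate corrected for the dead time;
    - ``bursting``: burst onsets as a Poisson process at ``rate`` Hz
      (the burst-event rate), each burst carrying 3-6 spikes at 4-8 ms
      intra-burst ISIs, so every burst satisfies the <10 ms start rule.
    """
    seed = _check_seed(seed)
    if rate <= 0:
        raise ShockrespError("rate must be positive")
    if mode not in SPIKE_MODES:
        raise ShockrespError(f"unknown mode '{mode}'; expected one of {SPIKE_MODES}")
    rng = np.random.default_rng(seed)
    if mode == "regular":
        shape = REGULAR_GAMMA_SHAPE
        scale = 1.0 / (rate * shape)
        n_draw = int(rate * duration * 1.5) + 50
        isis = rng.gamma(shape, scale, size=n_draw)
        times = np.cumsum(isis)
        times = times[times < duration]
        truth_cv = 1.0 / math.sqrt(shape)
    elif mode == "irregular":
        t_ref = IRREGULAR_REFRACTORY_S
        if rate * t_ref >= 1.0:
            raise ShockrespError("rate too high for the refractory period")
        lam = rate / (1.0 - rate * t_ref)  # dead-time-corrected exponential rate
        n_draw = int(rate * duration * 1.5) + 50
        isis = t_ref + rng.exponential(1.0 / lam, size=n_draw)
        times = np.cumsum(isis)
        times = times[times < duration]
        truth_cv = None
    else:  # bursting
        onsets = np.cumsum(rng.exponential(1.0 / rate, size=int(rate * duration * 2) + 20))
        onsets = onsets[onsets < duration]
        spikes = []
        t_prev_end = -np.inf
        for onset in onsets:
            if onset <= t_prev_end + 0.05:  # keep bursts separated
                continue
            n = int(rng.integers(BURST_SPIKES_RANGE[0], BURST_SPIKES_RANGE[1] + 1))
            intra = rng.uniform(*BURST_INTRA_ISI_MS, size=n - 1) / 1000.0
            burst = onset + np.concatenate([[0.0], np.cumsum(intra)])
            spikes.append(burst)
            t_prev_end = burst[-1]
        times = np.concatenate(spikes) if spikes else np.empty(0)
        times = times[times < duration]
        truth_cv = None
    train = SpikeTrain(
        times, t_start=0.0, t_stop=duration, unit_id=unit_id or f"{mode}_{seed}"
    )
    truth = GroundTruth(
        generator="gen_spike_train",
        seed=seed,
        params={
            "mode": mode,
            "rate_hz": rate,
            "duration_s": duration,
            "cv_target": truth_cv,
        },
    )
    return train, truth


def gen_evoked_recording(
    baseline_rate: float,
    onset_ms: float,
    duration_ms: float,
    rate_increment: float,
    n_events: int,
    iei_s: float = 5.0,
    seed: int = 0,
    pre_pad_s: float = 5.0,
    post_pad_s: float = 2.0,
    multiplicative: bool = False,
) -> tuple[SpikeTrain, EventSeries, GroundTruth]:
    """Inhomogeneous-Poisson recording with a stimulus-locked rate step.

    The rate is ``baseline_rate`` everywhere plus ``rate_increment`` on
    ``[event + onset, event + onset + duration)`` for each event
    (superposition of independent Poisson processes, which is exact).
    ``multiplicative=True`` instead multiplies the baseline by
    ``1 + rate_increment/baseline_rate`` over the response window —
    numerically the same added rate, provided for symmetry with
    multiplicative response models.  A negative increment (inhibition)
    is rejected.
    """
    seed = _check_seed(seed)
    if baseline_rate <= 0:
        raise ShockrespError("baseline rate must be positive")
    if rate_increment < 0:
        raise ShockrespError("negative rate increments (inhibition) not supported")
    if (onset_ms + duration_ms) / 1000.0 >= iei_s:
        raise ShockrespError("response window must fit inside the inter-event interval")
    rng = np.random.default_rng(seed)
    event_times = pre_pad_s + iei_s * np.arange(n_events)
    total = pre_pad_s + iei_s * n_events + post_pad_s
    n_base = rng.poisson(baseline_rate * total)
    base = rng.uniform(0.0, total, size=n_base)
    evoked = []
    dur_s = duration_ms / 1000.0
    for e in event_times:
        n_ev = rng.poisson(rate_increment * dur_s)
        start = e + onset_ms / 1000.0
        evoked.append(start + rng.uniform(0.0, dur_s, size=n_ev))
    times = np.sort(np.concatenate([base] + evoked))
    times = np.unique(times)  # guard against measure-zero collisions
    train = SpikeTrain(times, t_start=0.0, t_stop=total, unit_id=f"evoked_{seed}")
    events = EventSeries(event_times, event_duration=0.5, amplitude=3.0)
    truth = GroundTruth(
        generator="gen_evoked_recording",
        seed=seed,
        params={
            "baseline_rate_hz": baseline_rate,
            "onset_ms": onset_ms,
            "duration_ms": duration_ms,
            "rate_increment_hz": rate_increment,
            "n_events": n_events,
            "iei_s": iei_s,
        },
    )
    return train, events, truth


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------

def gen_photometry(
    transient_times: Sequence[float] = (),
    amplitude: float = 0.5,
    tau_decay_s: float = 1.0,
    artifact_times: Sequence[float] = (),
    artifact_amplitude: float = 0.0,
    artifact_width_s: float = 0.2,
    noise_sd: float = 0.05,
    f0: float = 100.0,
    duration_s: float = 60.0,
    seed: int = 0,
    sampling: str = "interleaved",
    rate_hz: float = 20.0,
    gain_mismatch: float = 1.0,
) -> tuple[PhotometryRecording, GroundTruth]:
    """Two-channel fluorescence with calcium transients and a shared artifact.

    The 470 channel is ``f0 * (1 + transients + artifact) + noise``; the
    405 channel is ``f0 * (1 + gain_mismatch * artifact) + noise``, with
    transients a single-exponential kernel (instantaneous rise, decay
    ``tau_decay_s``), the artifact Gaussian bumps, amplitudes in dF/F
    units and noise in raw fluorescence units.  With ``gain_mismatch=1``
    the artifact contributes equally in dF/F to both channels — the case
    plain isosbestic subtraction cancels exactly.

    ``sampling="interleaved"`` alternates the channels (405 offset by
    half a period, the realistic acquisition); ``"simultaneous"`` samples
    both on a common clock.
    """
    seed = _check_seed(seed)
    if f0 <= 0:
        raise ShockrespError("f0 must be positive")
    if sampling not in ("interleaved", "simultaneous"):
        raise ShockrespError(f"unknown sampling mode '{sampling}'")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    t470 = np.arange(0.0, duration_s, dt)
    t405 = t470 + (dt / 2.0 if sampling == "interleaved" else 0.0)

    def transient_signal(t: np.ndarray) -> np.ndarray:
        s = np.zeros_like(t)
        for tt in transient_times:
            m = t >= tt
            s[m] += amplitude * np.exp(-(t[m] - tt) / tau_decay_s)
        return s

    def artifact_signal(t: np.ndarray) -> np.ndarray:
        a = np.zeros_like(t)
        for ta in artifact_times:
            a += artifact_amplitude * np.exp(-0.5 * ((t - ta) / artifact_width_s) ** 2)
        return a

    f470 = f0 * (1.0 + transient_signal(t470) + artifact_signal(t470))
    f405 = f0 * (1.0 + gain_mismatch * artifact_signal(t405))
    if noise_sd > 0:
        f470 = f470 + rng.normal(0.0, noise_sd, size=t470.size)
        f405 = f405 + rng.normal(0.0, noise_sd, size=t405.size)

    times = np.concatenate([t470, t405])
    labels = np.concatenate(
        [
            np.full(t470.size, SIGNAL_CHANNEL),
            np.full(t405.size, REFERENCE_CHANNEL),
        ]
    )
    fluor = np.concatenate([f470, f405])
    order = np.argsort(times, kind="stable")
    rec = PhotometryRecording(times[order], labels[order], fluor[order])
    truth = GroundTruth(
        generator="gen_photometry",
        seed=seed,
        params={
            "transient_times_s": list(transient_times),
            "amplitude_dff": amplitude,
            "tau_decay_s": tau_decay_s,
            "artifact_times_s": list(artifact_times),
            "artifact_amplitude_dff": artifact_amplitude,
            "artifact_width_s": artifact_width_s,
            "noise_sd": noise_sd,
            "f0": f0,
            "duration_s": duration_s,
            "sampling": sampling,
            "rate_hz": rate_hz,
            "gain_mismatch": gain_mismatch,
        },
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def gen_shuttle_session(
    escape_prob: float = 0.8,
    latency_logmean: float = math.log(2.0),
    latency_logsigma: float = 0.5,
    n_trials: int = 30,
    seed: int = 0,
    iti_s: float = 30.0,
    shock_max_duration: float = 10.0,
) -> tuple[ShuttleSession, GroundTruth]:
    """Shuttle-box session with Bernoulli escapes and log-normal latencies.

    Latencies are drawn log-normal (``exp(N(logmean, logsigma))``) and
    resampled in the rare case they exceed the shock duration.
    """
    seed = _check_seed(seed)
    if not 0.0 <= escape_prob <= 1.0:
        raise ShockrespError("escape_prob must be in [0, 1]")
    if n_trials < 1:
        raise ShockrespError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        onset = i * (shock_max_duration + iti_s)
        if rng.random() < escape_prob:
            lat = float(rng.lognormal(latency_logmean, latency_logsigma))
            while lat > shock_max_duration:
                lat = float(rng.lognormal(latency_logmean, latency_logsigma))
            trials.append(ShuttleTrial(i, onset, lat))
        else:
            trials.append(ShuttleTrial(i, onset, None))
    session = ShuttleSession(trials, shock_max_duration=shock_max_duration)
    truth = GroundTruth(
        generator="gen_shuttle_session",
        seed=seed,
        params={
            "escape_prob": escape_prob,
            "latency_logmean": latency_logmean,
            "latency_logsigma": latency_logsigma,
            "n_trials": n_trials,
        },
    )
    return session, truth


NEST_POLYGON = ((0.0, 0.0), (20.0, 0.0), (0.0, 12.0))  # triangular corner nest, cm


def gen_looming_track(
    escape_latency: float = 1.5,
    freeze_bouts: Sequence[tuple[float, float]] = ((2.0, 3.0),),
    seed: int = 0,
    stimulus_onset: float = 10.0,
    fs_hz: float = 20.0,
    total_duration: float = 70.0,
) -> tuple[PositionTrack, GroundTruth]:
    """Looming-trial kinematics: center wander, straight escape run, nest stay.

    The animal wanders near the arena center until ``stimulus_onset``,
    runs straight into the nest polygon arriving (first in-nest sample)
    exactly ``escape_latency`` after onset, then moves inside the nest at
    ~5 cm/s except during the requested freeze bouts, given as
    ``(offset after nest entry, duration)`` pairs during which the
    position is held constant.  Bout edges are snapped to the sample
    grid so scored freezing equals the requested durations exactly.
    """
    seed = _check_seed(seed)
    dt = 1.0 / fs_hz
    n = int(round(total_duration * fs_hz)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    y = np.empty(n)
    center = np.array([25.0, 25.0])
    entry_target = np.array([9.8, 5.8])  # strictly inside the nest triangle
    t_entry = stimulus_onset + escape_latency
    # snap entry to the sample grid (the generated truth is the snapped value)
    k_entry = int(round(t_entry / dt))
    t_entry = k_entry * dt
    k_onset = int(round(stimulus_onset / dt))

    # pre-onset wander around the center, speed ~8 cm/s, radius <= 5 cm
    pos = center.copy()
    for k in range(k_onset + 1):
        x[k], y[k] = pos
        step = 8.0 * dt
        theta = rng.uniform(0, 2 * np.pi)
        cand = pos + step * np.array([np.cos(theta), np.sin(theta)])
        if np.linalg.norm(cand - center) > 5.0:
            cand = pos - step * (cand - pos) / np.linalg.norm(cand - pos)
        pos = cand
    # straight run: frames k_onset+1 .. k_entry interpolate run start -> target
    run_start = np.array([x[k_onset], y[k_onset]])
    for k in range(k_onset + 1, k_entry + 1):
        frac = (k - k_onset) / (k_entry - k_onset)
        x[k], y[k] = run_start + frac * (entry_target - run_start)
    # in-nest wander at ~5 cm/s within 2 cm of a point deep in the nest
    nest_center = np.array([6.0, 4.0])
    pos = entry_target.copy()
    hold: list[tuple[int, int]] = []
    for off, dur in freeze_bouts:
        k0 = k_entry + int(round(off / dt))
        k1 = k0 + int(round(dur / dt))
        hold.append((k0, k1))
    for k in range(k_entry + 1, n):
        holding = any(k0 < k <= k1 for k0, k1 in hold)
        if holding:
            x[k], y[k] = x[k - 1], y[k - 1]
            pos = np.array([x[k], y[k]])
            continue
        step = 5.0 * dt
        theta = rng.uniform(0, 2 * np.pi)
        cand = pos + step * np.array([np.cos(theta), np.sin(theta)])
        if np.linalg.norm(cand - nest_center) > 2.0:
            cand = pos + step * (nest_center - pos) / np.linalg.norm(nest_center - pos)
        pos = cand
        x[k], y[k] = pos
    track = PositionTrack(t, x, y)
    truth = GroundTruth(
        generator="gen_looming_track",
        seed=seed,
        params={
            "escape_latency_s": t_entry - stimulus_onset,
            "freeze_bouts": [list(b) for b in freeze_bouts],
            "freezing_time_s": float(sum(d for _, d in freeze_bouts)),
            "stimulus_onset_s": stimulus_onset,
            "fs_hz": fs_hz,
            "nest_polygon": [list(p) for p in NEST_POLYGON],
        },
    )
    return track, truth


# ---------------------------------------------------------------------------
# Slice physiology
# ---------------------------------------------------------------------------

def gen_synaptic_cohort(
    connect_p: float = 0.8,
    ratio_logmean: float = 0.0,
    ratio_logsd: float = 0.5,
    n_cells: int = 28,
    seed: int = 0,
    group: str = "",
    ampa_logmean: float = math.log(100.0),
    ampa_logsd: float = 0.5,
    ppr_mean: Optional[float] = None,
    ppr_logsd: float = 0.2,
    ra_drift_sd: float = 0.03,
) -> tuple[list[SynapticCellRecord], GroundTruth]:
    """Cohort of whole-cell records with Bernoulli connectivity.

    Connected cells carry log-normal I-AMPA amplitudes and log-normal
    I-GABA/I-AMPA ratios (so ``exp(ratio_logmean)`` is the true median
    ratio); unconnected cells have zero evoked currents.  When
    ``ppr_mean`` is given, paired-pulse amplitudes are drawn with a
    log-normal PPR around it — a presynaptic release-probability drop is
    emulated simply by passing a larger ``ppr_mean``.  Access-resistance
    series follow a small multiplicative random walk.
    """
    seed = _check_seed(seed)
    if not 0.0 <= connect_p <= 1.0:
        raise ShockrespError("connect_p must be in [0, 1]")
    if n_cells < 1:
        raise ShockrespError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        connected = bool(rng.random() < connect_p)
        if connected:
            i_ampa = float(rng.lognormal(ampa_logmean, ampa_logsd))
            ratio = float(rng.lognormal(ratio_logmean, ratio_logsd))
            i_gaba = ratio * i_ampa
        else:
            i_ampa = i_gaba = 0.0
        ra0 = float(rng.uniform(8.0, 15.0))
        ra = ra0 * np.cumprod(1.0 + rng.normal(0.0, ra_drift_sd, size=10))
        ra = np.concatenate([[ra0], ra])
        amp1 = amp2 = None
        if ppr_mean is not None and connected:
            amp1 = float(rng.lognormal(math.log(100.0), 0.3))
            amp2 = amp1 * float(rng.lognormal(math.log(ppr_mean), ppr_logsd))
        cells.append(
            SynapticCellRecord(
                cell_id=f"{group or 'cell'}_{i}",
                group=group,
                connected=connected,
                I_ampa=i_ampa,
                I_gaba=i_gaba,
                access_resistance_series=ra,
                amp1=amp1,
                amp2=amp2,
            )
        )
    truth = GroundTruth(
        generator="gen_synaptic_cohort",
        seed=seed,
        params={
            "connect_p": connect_p,
            "ratio_logmean": ratio_logmean,
            "ratio_logsd": ratio_logsd,
            "ratio_median": math.exp(ratio_logmean),
            "n_cells": n_cells,
            "ppr_mean": ppr_mean,
        },
    )
    return cells, truth
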