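"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's code paths: the burst scan is a
list-based claimed-spike sweep, and the excitation criterion bins
spikes by floor division and accumulates baseline statistics by
explicit sums instead of numpy histogram/statistics calls.
"""

from __future__ import annotations

import math


def brute_force_bursts(times_s, start_ms: float = 10.0, end_ms: float = 20.0):
    """Burst index intervals by a naive claimed-spike sweep.

    Returns half-open (start, stop) index pairs, matching the package's
    convention, but derived by explicitly claiming spikes one at a time.
    """
    times = [float(t) for t in times_s]
    n = len(times)
    claimed = [False] * n
    bursts = []
    s = 0
    while s < n - 1:
        if claimed[s]:
            s += 1
            continue
        gap_ms = (times[s + 1] - times[s]) * 1000.0
        if gap_ms < start_ms:
            e = s + 1
            while e + 1 < n and (times[e + 1] - times[e]) * 1000.0 <= end_ms:
                e += 1
            for k in range(s, e + 1):
                claimed[k] = True
            bursts.append((s, e + 1))
            s = e + 1
        else:
            s += 1
    return bursts


def excitation_criterion_oracle(
    spike_times,
    event_times,
    bin_ms: float = 10.0,
    pre_s: float = 2.0,
    post_s: float = 1.0,
    epoch_ms: float = 50.0,
    n_epochs: int = 4,
    sd_mult: float = 2.0,
) -> bool:
    """Straightforward re-coding of the four-epoch baseline + 2 SD criterion.

    Bins each sweep by floor division, sums over sweeps, computes the
    baseline mean and sample SD by explicit accumulation, and tests each
    post-stimulus epoch mean against mean + 2 SD with strict inequality.
    """
    binw = bin_ms / 1000.0
    n_pre = int(round(pre_s / binw))
    n_post = int(round(post_s / binw))
    counts = [0] * (n_pre + n_post)
    for e in event_times:
        for t in spike_times:
            r = t - e
            if -pre_s <= r < post_s:
                counts[int((r + pre_s) // binw)] += 1
    base = counts[:n_pre]
    m = sum(base) / n_pre
    var = sum((c - m) ** 2 for c in base) / (n_pre - 1)
    threshold = m + sd_mult * math.sqrt(var)
    bins_per_epoch = int(round(epoch_ms / bin_ms))
    post = counts[n_pre:]
    for ep in range(n_epochs):
        chunk = post[ep * bins_per_epoch : (ep + 1) * bins_per_epoch]
        if sum(chunk) / len(chunk) > threshold:
            return True
    return False
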