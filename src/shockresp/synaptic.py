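"""Slice-physiology summary computations.

Quality control on access resistance, connectivity rates across recorded
cohorts, the I-GABA/I-AMPA ratio (outward GABAergic current magnitude at
+10 mV over inward AMPA-receptor current magnitude at -60 mV; > 1 means
inhibition-dominated input), and paired-pulse ratios (second/first
evoked amplitude, a presynaptic release-probability proxy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data_model import ShockrespError, SynapticCellRecord

MAX_ACCESS_RESISTANCE_INCREASE_PCT = 20.0


def qc_access_resistance(
    series: np.ndarray | Sequence[float],
    max_increase_pct: float = MAX_ACCESS_RESISTANCE_INCREASE_PCT,
) -> bool:
    """Keep a recording unless access resistance rose more than 20%.

    The rise is measured from the initial value to the series maximum;
    a rise of exactly the threshold is kept (the discard rule is a
    strict "more than").
    """
    ra = np.asarray(series, dtype=float)
    if ra.size < 2:
        raise ShockrespError("access-resistance QC needs at least 2 samples")
    if np.any(ra <= 0):
        raise ShockrespError("access resistance must be positive")
    rise_pct = 100.0 * (float(ra.max()) - float(ra[0])) / float(ra[0])
    return rise_pct <= max_increase_pct


@dataclass
class ConnectivitySummary:
    """Fraction of recorded cells with a detectable light-evoked input."""

    n_connected: int
    n_recorded: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.n_connected <= self.n_recorded):
            raise ShockrespError("0 <= n_connected <= n_recorded violated")

    @property
    def percent(self) -> float:
        return 100.0 * self.n_connected / self.n_recorded


def connectivity_rate(
    cells: Sequence[SynapticCellRecord], group_label: str = ""
) -> ConnectivitySummary:
    """Percent of cells with ``connected=True`` (connection decided upstream).

    The connected flag is an acquisition-side judgement; no amplitude
    re-thresholding is applied here.
    """
    if not cells:
        raise ShockrespError("connectivity rate undefined for an empty cohort")
    return ConnectivitySummary(
        n_connected=sum(1 for c in cells if c.connected),
        n_recorded=len(cells),
        group_label=group_label,
    )


def gaba_ampa_ratio(cell: SynapticCellRecord) -> float:
    """|I_GABA| / |I_AMPA| for one cell; undefined when I_AMPA is zero."""
    if cell.I_ampa == 0:
        raise ShockrespError(
            f"cell {cell.cell_id}: I-GABA/I-AMPA undefined for I_AMPA = 0"
        )
    return abs(cell.I_gaba) / abs(cell.I_ampa)


def paired_pulse_ratio(amp1: float, amp2: float) -> float:
    """Second over first evoked amplitude; < 1 depressing, > 1 facilitating."""
    if amp1 == 0:
        raise ShockrespError("paired-pulse ratio undefined for a zero first pulse")
    return amp2 / amp1


@dataclass
class CohortSummary:
    """Distributional summary of per-cell ratios for one group."""

    group_label: str
    n_cells: int
    ratios: np.ndarray
    median: float
    mean: float
    sem: float


def summarize_ratios(
    cells: Sequence[SynapticCellRecord], group_label: str = ""
) -> CohortSummary:
    """I-GABA/I-AMPA ratios of a cohort; cells with zero I_AMPA are excluded."""
    ratios = []
    for c in cells:
        try:
            ratios.append(gaba_ampa_ratio(c))
        except ShockrespError:
            continue
    if not ratios:
        raise ShockrespError("no cells with a defined I-GABA/I-AMPA ratio")
    r = np.asarray(ratios)
    sem = float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else 0.0
    return CohortSummary(
        group_label=group_label,
        n_cells=r.size,
        ratios=r,
        median=float(np.median(r)),
        mean=float(r.mean()),
        sem=sem,
    )


def compare_ratio_distributions(
    a: CohortSummary, b: CohortSummary
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of two ratio cohorts.

    Returns ``(D statistic, p value)`` — descriptive output mirroring the
    cumulative-probability comparison used for group data.
    """
    res = stats.ks_2samp(a.ratios, b.ratios)
    return float(res.statistic), float(res.pvalue)


def summarize_cohort(
    cells: Sequence[SynapticCellRecord],
    group_label: str = "",
    apply_qc: bool = True,
) -> dict:
    """QC, connectivity and ratio summary for one recorded cohort."""
    kept = [
        c
        for c in cells
        if not apply_qc
        or c.access_resistance_series.size < 2
        or qc_access_resistance(c.access_resistance_series)
    ]
    if not kept:
        raise ShockrespError("no cells pass access-resistance QC")
    conn = connectivity_rate(kept, group_label)
    connected = [c for c in kept if c.connected]
    out = {
        "group": group_label,
        "n_recorded": conn.n_recorded,
        "n_connected": conn.n_connected,
        "connectivity_percent": round(conn.percent, 1),
        "n_discarded_qc": len(cells) - len(kept),
    }
    try:
        ratios = summarize_ratios(connected, group_label)
        out.update(
            {
                "ratio_median": ratios.median,
                "ratio_mean": ratios.mean,
                "ratio_sem": ratios.sem,
                "n_ratio_cells": ratios.n_cells,
            }
        )
    except ShockrespError:
        pass
    pprs = [
        paired_pulse_ratio(c.amp1, c.amp2)
        for c in kept
        if c.amp1 is not None and c.amp2 is not None and c.amp1 != 0
    ]
    if pprs:
        out["ppr_mean"] = float(np.mean(pprs))
        out["n_ppr_cells"] = len(pprs)
    return out
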