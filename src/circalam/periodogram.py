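"""Chi-square periodogram rhythmicity analysis.

The chi-square periodogram folds an activity series at every trial period P
and asks whether the variance between fold-phase means exceeds what sampling
noise alone would give.  With the series rebinned to ``bin_min``-minute bins,
a trial period of K bins, and N = ⌊T/K⌋ complete cycles (only the first N·K
bins are used), the statistic is

    Qp = N²·K · Σ_h (M_h − M̄)² / Σ_i (x_i − M̄)²

where M_h is the mean of the h-th phase column and M̄ the grand mean of the
bins used.  Under independent noise Qp is asymptotically chi-square with
K − 1 degrees of freedom, so rhythmicity at period P is called when Qp
exceeds the upper-alpha chi-square quantile.  Alpha is Bonferroni-corrected
across the scanned period grid by default, since every trial period is
tested.

An individual with no significant peak anywhere in the scanned range
(5–32 h by default) is *arrhythmic*.  Among significant peaks, the
*fundamental* free-running period tau is the peak inside the circadian
acceptance band 23 ± 2 h with the largest margin above threshold;
individuals whose circadian-range peaks all fall outside that band are
flagged *atypical* and excluded from period-length analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lam_io import ChannelSeries

#: secondary period lengths (hours) recorded as presence/absence bits
CANONICAL_PERIODS_H = (6.0, 8.0, 12.0, 16.0, 18.0, 20.0, 30.0)

#: circadian acceptance band for the fundamental period, tau = 23 +/- 2 h
CIRCADIAN_BAND_H = (21.0, 25.0)

#: broader band within which an off-target peak still counts as "circadian"
#: for the atypical flag
CIRCADIAN_RANGE_H = (18.0, 30.0)


@dataclass
class Periodogram:
    """Qp against trial period, with per-period significance threshold."""

    periods_h: np.ndarray
    qp: np.ndarray
    df: np.ndarray
    threshold: np.ndarray
    alpha: float
    alpha_effective: float
    bin_min: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (len(self.periods_h) == len(self.qp) == len(self.df) == len(self.threshold)):
            raise ValueError("periodogram grids differ in length")


@dataclass
class RhythmCall:
    """Rhythmicity classification of one individual."""

    is_rhythmic: bool
    fundamental_period_h: float | None = None
    significant_periods_h: tuple = ()
    atypical: bool = False
    peak_margins: dict = field(default_factory=dict)


def rebin_counts(counts: np.ndarray, step_s: int, bin_min: float) -> np.ndarray:
    """Sum counts into ``bin_min``-minute bins; a trailing partial bin is dropped."""
    per_bin = int(round(bin_min * 60 / step_s))
    if per_bin < 1 or abs(per_bin * step_s - bin_min * 60) > 1e-9:
        raise ValueError(f"bin of {bin_min} min is not a multiple of the {step_s} s step")
    n = (len(counts) // per_bin) * per_bin
    return np.asarray(counts[:n], dtype=float).reshape(-1, per_bin).sum(axis=1)


def chi_square_periodogram(
    series: ChannelSeries,
    bin_min: float = 5.0,
    period_range_h: tuple = (5.0, 32.0),
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> Periodogram:
    """Compute the chi-square periodogram of one (trimmed) series.

    Trial periods run over every integer number of bins K with
    ``period_range_h[0] <= K*bin_min/60 <= period_range_h[1]``.
    ``correction``: ``"bonferroni"`` divides alpha by the number of trial
    periods; ``"none"`` tests each period at raw alpha.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    x = rebin_counts(series.counts, series.step, bin_min)
    lo_k = int(np.ceil(period_range_h[0] * 60 / bin_min - 1e-9))
    hi_k = int(np.floor(period_range_h[1] * 60 / bin_min + 1e-9))
    if hi_k < lo_k or hi_k < 2:
        raise ValueError("empty trial-period grid")
    if len(x) < 2 * lo_k:
        raise ValueError("series shorter than two cycles of the smallest trial period")
    hi_k = min(hi_k, len(x) // 2)  # need at least two complete cycles

    ks = np.arange(lo_k, hi_k + 1)
    periods = ks * bin_min / 60.0
    alpha_eff = alpha / len(ks) if correction == "bonferroni" else alpha
    dfs = (ks - 1).astype(float)
    thresholds = stats.chi2.ppf(1.0 - alpha_eff, dfs)

    qp = np.zeros(len(ks))
    degenerate = bool(np.ptp(x) == 0)
    if not degenerate:
        for j, k in enumerate(ks):
            n_cycles = len(x) // k
            used = x[: n_cycles * k]
            folded = used.reshape(n_cycles, k)
            col_means = folded.mean(axis=0)
            grand = used.mean()
            denom = ((used - grand) ** 2).sum()
            if denom == 0:
                qp[j] = 0.0
                continue
            qp[j] = n_cycles**2 * k * ((col_means - grand) ** 2).sum() / denom

    return Periodogram(
        periods_h=periods,
        qp=qp,
        df=dfs,
        threshold=thresholds,
        alpha=alpha,
        alpha_effective=alpha_eff,
        bin_min=bin_min,
        degenerate=degenerate,
    )


def find_significant_peaks(pg: Periodogram) -> dict:
    """Significant periodogram peaks and their margins above threshold.

    Contiguous runs of super-threshold trial periods contribute one peak
    each: the period maximising Qp − threshold within the run (earliest,
    i.e. shortest period, on exact ties).  Returns ``{period_h: margin}``.
    """
    if pg.degenerate:
        return {}
    excess = pg.qp - pg.threshold
    above = pg.qp > pg.threshold
    peaks: dict = {}
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            run = slice(i, j + 1)
            best = i + int(np.argmax(excess[run]))
            peaks[float(pg.periods_h[best])] = float(excess[best])
            i = j + 1
        else:
            i += 1
    return peaks


def classify_rhythmicity(
    pg: Periodogram,
    band_h: tuple = CIRCADIAN_BAND_H,
    circadian_range_h: tuple = CIRCADIAN_RANGE_H,
) -> RhythmCall:
    """Call an individual rhythmic/arrhythmic and extract its fundamental tau.

    Arrhythmic iff no significant peak anywhere in the scanned range.  The
    fundamental is the in-band peak with the largest margin (shorter period
    breaks ties).  ``atypical`` marks rhythmic individuals whose peaks in the
    broader circadian range all fall outside the acceptance band — their
    period is discarded from tau analyses.
    """
    peaks = find_significant_peaks(pg)
    if not peaks:
        return RhythmCall(is_rhythmic=False)
    in_band = {p: m for p, m in peaks.items() if band_h[0] <= p <= band_h[1]}
    fundamental = None
    if in_band:
        fundamental = min(in_band, key=lambda p: (-in_band[p], p))
    in_range = [p for p in peaks if circadian_range_h[0] <= p <= circadian_range_h[1]]
    atypical = bool(in_range) and not in_band
    return RhythmCall(
        is_rhythmic=True,
        fundamental_period_h=fundamental,
        significant_periods_h=tuple(sorted(peaks)),
        atypical=atypical,
        peak_margins=peaks,
    )


def map_to_canonical(
    peaks,
    canonical_h: tuple = CANONICAL_PERIODS_H,
    tol_h: float = 0.5,
) -> dict:
    """Presence flags over the canonical secondary periods.

    Each significant peak is assigned to its nearest canonical period if
    within ``tol_h`` hours; a peak maps to at most one canonical period,
    with equidistant ties resolved toward the shorter period.
    """
    flags = {c: False for c in canonical_h}
    for p in peaks:
        dists = [(abs(p - c), c) for c in canonical_h]
        d, c = min(dists)  # tuple order breaks ties toward the shorter period
        if d <= tol_h + 1e-12:
            flags[c] = True
    return flags
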