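"""Chronotype barcodes and Shannon diversity of their combinations.

Each individual's periodogram output is condensed into an 8-bit *barcode*:
presence/absence of each canonical secondary period (6, 8, 12, 16, 18, 20,
30 h) plus an eighth bit for a circadian fundamental in the 23 ± 2 h band.
Arrhythmic individuals carry the all-zero barcode.  Within a treatment
group the Shannon index H = −Σ p_k ln p_k over the empirical frequencies of
the distinct barcode combinations measures how heterogeneous the group's
rhythmic makeup is: H = 0 when every individual shares one chronotype,
ln(n) when all n differ.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .periodogram import CANONICAL_PERIODS_H, RhythmCall

logger = logging.getLogger(__name__)

BARCODE_LABELS = tuple(f"{int(p)}h" for p in CANONICAL_PERIODS_H) + ("fundamental",)


def make_barcode(call: RhythmCall, canonical_flags: dict) -> tuple:
    """8-bit barcode: canonical-period bits in ascending order + fundamental bit."""
    bits = tuple(int(bool(canonical_flags.get(c, False))) for c in CANONICAL_PERIODS_H)
    bits += (int(call.fundamental_period_h is not None),)
    if not call.is_rhythmic and any(bits):
        raise ValueError("arrhythmic individual with nonzero barcode bits")
    return bits


def shannon_diversity(barcodes, base: float | None = None) -> float:
    """Shannon index of the barcode composition (natural log by default).

    H = −Σ_k p_k log p_k over the frequencies of distinct barcodes.
    """
    barcodes = list(barcodes)
    if not barcodes:
        raise ValueError("cannot compute diversity of an empty group")
    counts = pd.Series(barcodes).value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h if h > 0 else 0.0


def diversity_table(
    calls_df: pd.DataFrame,
    group_cols=("insemination", "meal", "regimen"),
    pooled_margins=(),
    base: float | None = None,
) -> pd.DataFrame:
    """Shannon diversity per treatment group.

    ``calls_df`` must carry one row per retained individual with a
    ``barcode`` column (tuples) and the grouping columns.  Size-zero groups
    are omitted with a log entry.  ``pooled_margins`` lists column subsets
    (e.g. ``[("insemination",)]``) to additionally pool over.
    """
    if "barcode" not in calls_df.columns:
        raise ValueError("calls_df needs a 'barcode' column")
    rows = []
    group_cols = list(group_cols)
    for key, sub in calls_df.groupby(group_cols, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        if not len(sub):
            logger.info("diversity: empty group %s omitted", key)
            continue
        rec = dict(zip(group_cols, key))
        rec.update(n=len(sub), n_distinct=sub["barcode"].nunique(), H=shannon_diversity(sub["barcode"], base=base))
        rows.append(rec)
    for margin in pooled_margins:
        margin = list(margin)
        for key, sub in calls_df.groupby(margin, sort=True, observed=True):
            key = key if isinstance(key, tuple) else (key,)
            rec = {c: "(all)" for c in group_cols}
            rec.update(dict(zip(margin, key)))
            rec.update(n=len(sub), n_distinct=sub["barcode"].nunique(), H=shannon_diversity(sub["barcode"], base=base))
            rows.append(rec)
    return pd.DataFrame(rows, columns=group_cols + ["n", "n_distinct", "H"])
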