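"""Record filters applied before any rhythm analysis.

Three rules, applied cohort-wide:

* the first and last recording day are discarded (handling/transfer
  artefacts), so a 7-day run yields 5 analysis days;
* an individual showing 24 h of continuous inactivity at the 1-min
  resolution (1440 consecutive zero scores) is considered dead and
  discarded — evaluated on the untrimmed series, so a death on the last
  day still removes the individual;
* control tubes (empty tubes monitoring spurious beam breaks) and, when a
  sperm-check outcome is recorded, inseminated-arm females that failed the
  check, are removed.

Every removal is appended to the cohort's QC log as
``(individual_id, action, reason)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lam_io import ChannelSeries, CohortTable


def trim_days(series: ChannelSeries) -> ChannelSeries:
    """Drop the first and last recording day, keeping whole days only.

    Days are calendar days anchored at midnight.  A partial leading (or
    trailing) calendar day is dropped together with the adjacent first
    (or last) full day.  The retained counts are an untouched contiguous
    slice of the input; ``day_offset`` is advanced so analysis days keep
    the original recording-day numbering.
    """
    spd = series.steps_per_day
    start = series.start
    midnight = start.normalize()
    # steps until the first midnight boundary at or after start
    lead_partial = 0 if start == midnight else int((midnight + pd.Timedelta(days=1) - start).total_seconds()) // series.step
    n = len(series.counts)
    n_after_lead = n - lead_partial
    if n_after_lead < 3 * spd:
        raise ValueError(f"series spans fewer than 3 whole days ({series.individual_id}: {series.n_days:.2f} days)")
    n_full = n_after_lead // spd
    # drop leading partial day + first full day; drop trailing partial + last full day
    lo = lead_partial + spd
    hi = lead_partial + (n_full - 1) * spd
    days_dropped_front = (1 if lead_partial else 0) + 1
    return series.with_counts(
        series.counts[lo:hi],
        start=start + pd.Timedelta(seconds=lo * series.step),
        day_offset=series.day_offset + days_dropped_front,
    )


def flag_dead(series: ChannelSeries, window_h: float = 24.0) -> bool:
    """True iff the series contains ``window_h`` hours of consecutive zeros."""
    window = int(round(window_h * 3600 / series.step))
    x = series.counts
    if len(x) < window:
        return False
    is_zero = x == 0
    if not is_zero.any():
        return False
    # lengths of zero runs via boundaries of the boolean signal
    padded = np.concatenate(([False], is_zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_lengths = edges[1::2] - edges[0::2]
    return bool((run_lengths >= window).max())


def apply_cohort_filters(cohort: CohortTable) -> CohortTable:
    """Remove control tubes, dead individuals, and failed sperm checks.

    Idempotent: running the filter on its own output removes nothing.
    The returned cohort carries the cumulative QC log.
    """
    kept = []
    log = list(cohort.qc_log)
    for s in cohort.series:
        if s.is_control_tube:
            reason = "control tube"
            if s.counts.any():
                reason += f" (nonzero counts: {int(s.counts.sum())} beam breaks — possible artifact)"
            log.append((s.individual_id, "removed", reason))
        elif flag_dead(s):
            log.append((s.individual_id, "removed", "dead: >= 24 h of continuous inactivity"))
        elif str(s.meta.get("insemination", "")) == "inseminated" and str(s.meta.get("sperm_check", "passed")) == "failed":
            log.append((s.individual_id, "removed", "sperm check failed: not inseminated"))
        else:
            kept.append(s)
    return CohortTable(series=kept, schedule=cohort.schedule, qc_log=log)


def qc_report(cohort: CohortTable) -> pd.DataFrame:
    """QC log as a DataFrame (individual_id, action, reason)."""
    return pd.DataFrame(cohort.qc_log, columns=["individual_id", "action", "reason"])
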