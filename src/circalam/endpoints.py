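"""Activity endpoints: actogram profiles, nightly activity, onset and peak times.

Endpoints are defined on wall-clock windows around the dusk transition:

* *nightly activity* — activity scores between 16:00 and 07:00 the next
  morning, expressed per 5 min (180 bins per night);
* *onset of activity* — the first minute in the dusk window from which the
  individual produces >= 1 beam break per minute for 3 consecutive minutes;
* *peak time* — the clock time of the maximal 1-min score inside a
  regimen-specific dusk window (17:30-19:30 under LD, 16:30-19:30 under
  DD), earliest minute on ties.

Nights and days are labelled by original recording-day number (a trimmed
7-day recording yields analysis days 2-6); a night is labelled by the day
on which it starts.  Missing onsets/peaks propagate as missing values.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .lam_io import ChannelSeries, CohortTable, LightSchedule

logger = logging.getLogger(__name__)

NIGHT_WINDOW = (dt.time(16, 0), dt.time(7, 0))
ONSET_WINDOW = (dt.time(17, 0), dt.time(19, 30))
PEAK_WINDOW_LD = (dt.time(17, 30), dt.time(19, 30))
PEAK_WINDOW_DD = (dt.time(16, 30), dt.time(19, 30))

NIGHTLY_BIN_MIN = 5


def analysis_days(series: ChannelSeries) -> list:
    """Original recording-day labels of the whole days present in the series."""
    if series.start != series.start.normalize():
        raise ValueError("series must be midnight-aligned (trimmed)")
    n_days = len(series.counts) // series.steps_per_day
    return [series.day_offset + 1 + d for d in range(n_days)]


def _day_slice(series: ChannelSeries, day: int, start_clock: dt.time, end_clock: dt.time):
    """Index slice of the window starting on recording day ``day``.

    The window may cross midnight (end <= start means "next morning").
    Returns ``None`` if the window is not fully inside the recording.
    """
    day_start = series.start.normalize() + pd.Timedelta(days=day - 1 - series.day_offset)
    t0 = day_start + pd.Timedelta(hours=start_clock.hour, minutes=start_clock.minute)
    t1 = day_start + pd.Timedelta(hours=end_clock.hour, minutes=end_clock.minute)
    if t1 <= t0:
        t1 += pd.Timedelta(days=1)
    i0 = int((t0 - series.start).total_seconds()) // series.step
    i1 = int((t1 - series.start).total_seconds()) // series.step
    if i0 < 0 or i1 > len(series.counts):
        return None
    return slice(i0, i1), t0


def mean_activity_profile(cohort: CohortTable, individual_ids=None) -> pd.DataFrame:
    """Pointwise mean activity score across individuals, by day and clock minute.

    Used to draw group actograms.  Returns a tidy frame with columns
    ``day``, ``clock_min`` (minute of day), ``mean_score``.
    """
    series = [s for s in cohort.series if individual_ids is None or s.individual_id in set(individual_ids)]
    if not series:
        raise ValueError("empty group: no individuals to average")
    frames = []
    for s in series:
        days = analysis_days(s)
        spd = s.steps_per_day
        mat = s.counts[: len(days) * spd].reshape(len(days), spd)
        frames.append(pd.DataFrame(mat, index=days))
    stacked = np.stack([f.to_numpy(dtype=float) for f in frames])
    days = frames[0].index
    if any(not f.index.equals(days) for f in frames):
        raise ValueError("individuals cover different analysis days")
    mean = stacked.mean(axis=0)
    step_min = series[0].step // 60
    out = pd.DataFrame(mean, index=days).stack().reset_index()
    out.columns = ["day", "bin", "mean_score"]
    out["clock_min"] = out.pop("bin") * step_min
    return out[["day", "clock_min", "mean_score"]]


def nightly_activity(
    series: ChannelSeries,
    schedule: LightSchedule,
    window: tuple = NIGHT_WINDOW,
    bin_min: int = NIGHTLY_BIN_MIN,
) -> dict:
    """Per-night activity, summed into ``bin_min``-minute bins.

    Returns ``{night_label: ndarray}`` with one array of 5-min sums per
    complete night window (16:00 -> 07:00 gives 180 bins); nights cut by the
    series edge are omitted with a log entry.
    """
    if series.step != 60:
        raise ValueError("nightly activity requires 1-min resolution")
    per_bin = bin_min
    out = {}
    for day in analysis_days(series):
        sl = _day_slice(series, day, window[0], window[1])
        if sl is None:
            logger.info("night %d of %s incomplete at series edge; omitted", day, series.individual_id)
            continue
        win = series.counts[sl[0]]
        n = (len(win) // per_bin) * per_bin
        out[day] = win[:n].reshape(-1, per_bin).sum(axis=1)
    return out


def onset_time(
    series: ChannelSeries,
    day: int,
    schedule: LightSchedule,
    window: tuple = ONSET_WINDOW,
    run_min: int = 3,
) -> dt.time | None:
    """Onset of sustained dusk activity on one day, or None.

    First minute m of the search window such that the scores at
    m, m+1, ..., m+run_min-1 are all >= 1.
    """
    if series.step != 60:
        raise ValueError("onset detection requires 1-min resolution")
    sl = _day_slice(series, day, window[0], window[1])
    if sl is None:
        return None
    win = series.counts[sl[0]]
    active = win >= 1
    if len(active) < run_min:
        return None
    runs = np.ones(len(active) - run_min + 1, dtype=bool)
    for k in range(run_min):
        runs &= active[k : k + len(runs)]
    idx = np.flatnonzero(runs)
    if not len(idx):
        return None
    return (sl[1] + pd.Timedelta(minutes=int(idx[0]))).time()


def peak_time(
    series: ChannelSeries,
    day: int,
    schedule: LightSchedule,
    window: tuple | None = None,
) -> dt.time | None:
    """Clock time of the maximal 1-min score in the dusk window, or None.

    The window defaults to 17:30-19:30 in LD and 16:30-19:30 in DD; the
    earliest minute wins ties; an all-zero window yields None.
    """
    if series.step != 60:
        raise ValueError("peak detection requires 1-min resolution")
    if window is None:
        window = PEAK_WINDOW_LD if schedule.regimen == "LD" else PEAK_WINDOW_DD
    sl = _day_slice(series, day, window[0], window[1])
    if sl is None:
        return None
    win = series.counts[sl[0]]
    if not win.any():
        return None
    return (sl[1] + pd.Timedelta(minutes=int(np.argmax(win)))).time()


def endpoint_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-individual per-day endpoints: onset, peak, nightly total.

    Clock times are reported as fractional hours of day; missing endpoints
    are NaN.
    """
    rows = []
    for s in cohort.series:
        nights = nightly_activity(s, cohort.schedule)
        for day in analysis_days(s):
            onset = onset_time(s, day, cohort.schedule)
            peak = peak_time(s, day, cohort.schedule)
            rows.append(
                {
                    "individual_id": s.individual_id,
                    "day": day,
                    "onset_clock_h": _time_to_h(onset),
                    "peak_clock_h": _time_to_h(peak),
                    "nightly_total": int(nights[day].sum()) if day in nights else np.nan,
                    **{k: s.meta.get(k) for k in ("insemination", "meal", "regimen")},
                }
            )
    return pd.DataFrame(rows)


def _time_to_h(t: dt.time | None) -> float:
    if t is None:
        return np.nan
    return t.hour + t.minute / 60.0 + t.second / 3600.0
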