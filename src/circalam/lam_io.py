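"""Reading and writing locomotor activity monitor (LAM) files.

Beam-break counters of the TriKinetics kind write one tab-delimited row per
recording interval: a reading index, a date, a clock time, a status code,
possibly further status columns, and then one integer count per channel
(32 channels per monitor).  Each channel holds one mosquito in a glass tube;
the count is the number of infrared beam crossings in the interval — the
*activity score*.

This module parses such files onto a strict regular time grid, attaches
per-channel metadata (insemination status, meal, light regimen, control-tube
flag), and defines the mapping from wall-clock time to Zeitgeber time (ZT,
under a light:dark cycle) or circadian time (CT, under constant darkness).
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CHANNELS = 32

#: date format used in monitor files, e.g. "4 Jan 21"
_DATE_FMT = "%d %b %y"


@dataclass(frozen=True)
class LightSchedule:
    """Light regimen and its clock anchors.

    A 12:12 light:dark (LD) cycle with one-hour linear twilight ramps:
    full light 11 h, full darkness 11 h, a linear dusk ramp ending at
    lights-off and a linear dawn ramp ending at lights-on.  Constant
    darkness (DD) keeps the same nominal anchors so that "subjective"
    dusk/dawn and circadian time remain defined.

    Zeitgeber/circadian time is anchored at lights-off by default
    (18:00 = ZT0, 06:00 = ZT12); ``zt_anchor="lights_on"`` flips the
    convention so that lights-on defines ZT0 (and lights-off ZT12).
    """

    regimen: str = "LD"
    lights_off: dt.time = dt.time(18, 0)
    lights_on: dt.time = dt.time(6, 0)
    dusk_ramp_min: int = 60
    dawn_ramp_min: int = 60
    zt_anchor: str = "lights_off"

    def __post_init__(self) -> None:
        if self.regimen not in ("LD", "DD"):
            raise ValueError(f"regimen must be 'LD' or 'DD', got {self.regimen!r}")
        if self.zt_anchor not in ("lights_off", "lights_on"):
            raise ValueError(f"unknown zt_anchor {self.zt_anchor!r}")
        if self.dusk_ramp_min < 0 or self.dawn_ramp_min < 0:
            raise ValueError("twilight ramps must be non-negative")
        # photophase + scotophase + both ramps must tile the 24 h day with
        # positive light and dark spans (ramps must fit inside their spans)
        if self.photophase_h <= 0 or self.scotophase_h <= 0:
            raise ValueError("photophase, scotophase and ramps do not tile 24 h with positive spans")

    @property
    def lights_off_h(self) -> float:
        return self.lights_off.hour + self.lights_off.minute / 60.0

    @property
    def lights_on_h(self) -> float:
        return self.lights_on.hour + self.lights_on.minute / 60.0

    @property
    def photophase_h(self) -> float:
        """Hours of full light (lights-on to dusk-ramp start)."""
        return (self.lights_off_h - self.lights_on_h) % 24.0 - self.dusk_ramp_min / 60.0

    @property
    def scotophase_h(self) -> float:
        """Hours of full darkness (lights-off to dawn-ramp start)."""
        return (self.lights_on_h - self.lights_off_h) % 24.0 - self.dawn_ramp_min / 60.0

    def is_dark(self, clock_h):
        """True where the lamp is off (between lights-off and dawn-ramp start).

        In DD the lamp is always off; this still reports the *subjective*
        scotophase from the nominal anchors.
        """
        return ((np.asarray(clock_h) - self.lights_off_h) % 24.0) < (self.scotophase_h + self.dawn_ramp_min / 60.0)


def to_reference_time(clock, schedule: LightSchedule):
    """Map wall-clock time to reference hours in [0, 24): ZT in LD, CT in DD.

    ``clock`` may be a timestamp, a ``datetime.time``, a float hour-of-day,
    or an array/index of any of these.  With the default anchor, reference 0
    is lights-off (18:00 → 0.0, 06:00 → 12.0).
    """
    clock_h = _clock_hours(clock)
    anchor = schedule.lights_off_h if schedule.zt_anchor == "lights_off" else schedule.lights_on_h
    return (clock_h - anchor) % 24.0


def _clock_hours(clock):
    """Hour-of-day as float(s) from flexible clock-time input."""
    if isinstance(clock, dt.time):
        return clock.hour + clock.minute / 60.0 + clock.second / 3600.0
    if isinstance(clock, (pd.Timestamp, dt.datetime)):
        t = pd.Timestamp(clock)
        return t.hour + t.minute / 60.0 + t.second / 3600.0
    if isinstance(clock, (pd.DatetimeIndex, pd.Series)) or (
        isinstance(clock, np.ndarray) and np.issubdtype(clock.dtype, np.datetime64)
    ):
        idx = pd.DatetimeIndex(clock)
        return (idx.hour + idx.minute / 60.0 + idx.second / 3600.0).to_numpy()
    return np.asarray(clock, dtype=float) % 24.0 if np.ndim(clock) else float(clock) % 24.0


@dataclass
class ChannelSeries:
    """One individual's beam-break counts on a regular time grid.

    ``counts[i]`` is the activity score in the interval starting at
    ``start + i*step`` seconds.  ``day_offset`` records how many leading
    whole days were trimmed from the original recording, so that analysis
    days can keep the original recording-day numbering.
    """

    individual_id: str
    monitor_id: str
    channel: int
    start: pd.Timestamp
    counts: np.ndarray
    step: int = 60
    meta: dict = field(default_factory=dict)
    day_offset: int = 0

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not (1 <= self.channel <= N_CHANNELS):
            raise ValueError(f"channel must be 1..{N_CHANNELS}, got {self.channel}")
        if self.step <= 0 or 86400 % self.step:
            raise ValueError(f"step {self.step} s must divide 86400")
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("negative activity scores")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def steps_per_day(self) -> int:
        return 86400 // self.step

    @property
    def n_days(self) -> float:
        return len(self.counts) / self.steps_per_day

    def time_index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.counts), freq=f"{self.step}s")

    @property
    def is_control_tube(self) -> bool:
        return bool(self.meta.get("is_control_tube", False))

    def with_counts(self, counts, start=None, day_offset=None) -> "ChannelSeries":
        return replace(
            self,
            counts=np.asarray(counts, dtype=np.int64),
            start=self.start if start is None else pd.Timestamp(start),
            day_offset=self.day_offset if day_offset is None else day_offset,
        )


@dataclass
class CohortTable:
    """A cohort of channel series sharing one light schedule and time step."""

    series: list
    schedule: LightSchedule
    qc_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.individual_id for s in self.series]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dup}")
        steps = {s.step for s in self.series}
        if len(steps) > 1:
            raise ValueError(f"mixed time steps in cohort: {sorted(steps)}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, individual_id: str) -> ChannelSeries:
        for s in self.series:
            if s.individual_id == individual_id:
                return s
        raise KeyError(individual_id)

    def meta_frame(self) -> pd.DataFrame:
        """Per-individual metadata as a DataFrame indexed by individual_id."""
        rows = []
        for s in self.series:
            row = {"individual_id": s.individual_id, "monitor_id": s.monitor_id, "channel": s.channel}
            row.update(s.meta)
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.set_index("individual_id") if len(df) else df


class MonitorParseError(ValueError):
    """Raised for malformed, duplicated or gapped monitor-file rows."""


def read_channel_meta(path) -> pd.DataFrame:
    """Read the channel metadata CSV (monitor_id, channel, individual_id, ...)."""
    meta = pd.read_csv(path, dtype={"monitor_id": str})
    required = {"monitor_id", "channel", "individual_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"channel metadata is missing columns: {sorted(missing)}")
    return meta


def read_monitor_file(path, channel_meta: pd.DataFrame, schedule: LightSchedule, monitor_id: str | None = None) -> CohortTable:
    """Parse one monitor file into a :class:`CohortTable`.

    Rows must be tab-delimited: reading index, date, time, then status
    columns, with the final 32 columns holding the channel counts.  Unknown
    extra status columns are tolerated and logged.  The rows must form a
    gapless regular grid; a missing or duplicated timestamp is an error.
    Channels without a metadata row are skipped with a warning; control-tube
    channels are retained and flagged.
    """
    path = str(path)
    if monitor_id is None:
        import os

        monitor_id = os.path.splitext(os.path.basename(path))[0]

    times = []
    counts_rows = []
    n_extra_logged = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields_ = line.split("\t")
            if len(fields_) < 3 + N_CHANNELS:
                raise MonitorParseError(f"{path}:{lineno}: expected at least {3 + N_CHANNELS} tab-delimited fields, got {len(fields_)}")
            try:
                ts = pd.Timestamp(dt.datetime.strptime(f"{fields_[1].strip()} {fields_[2]}", f"{_DATE_FMT} %H:%M:%S"))
                row_counts = [int(v) for v in fields_[-N_CHANNELS:]]
            except (ValueError, TypeError) as exc:
                raise MonitorParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if any(c < 0 for c in row_counts):
                raise MonitorParseError(f"{path}:{lineno}: negative count")
            n_status = len(fields_) - 3 - N_CHANNELS
            if n_status > 1 and not n_extra_logged:
                logger.info("%s: ignoring %d extra status column(s)", path, n_status - 1)
                n_extra_logged = True
            times.append(ts)
            counts_rows.append(row_counts)

    if not times:
        raise MonitorParseError(f"{path}: empty monitor file")

    index = pd.DatetimeIndex(times)
    step = 60
    expected = pd.date_range(index[0], index[-1], freq=f"{step}s")
    if index.duplicated().any():
        first_dup = index[index.duplicated()][0]
        raise MonitorParseError(f"{path}: duplicate timestamp {first_dup}")
    if len(index) != len(expected) or (index != expected).any():
        missing = expected.difference(index)
        if len(missing):
            raise MonitorParseError(f"{path}: gap in time grid, missing {missing[0]}")
        raise MonitorParseError(f"{path}: rows not in chronological 60 s order")

    matrix = np.asarray(counts_rows, dtype=np.int64)

    mmeta = channel_meta[channel_meta["monitor_id"].astype(str) == str(monitor_id)]
    by_channel = {int(r["channel"]): r for _, r in mmeta.iterrows()}

    series = []
    for ch in range(1, N_CHANNELS + 1):
        col = matrix[:, ch - 1]
        if ch not in by_channel:
            if col.any():
                warnings.warn(f"{path}: channel {ch} has activity but no metadata; skipped", stacklevel=2)
            continue
        row = by_channel[ch]
        meta = {k: row[k] for k in row.index if k not in ("monitor_id", "channel", "individual_id") and pd.notna(row[k])}
        meta["is_control_tube"] = bool(row.get("is_control_tube", False))
        meta.setdefault("regimen", schedule.regimen)
        series.append(
            ChannelSeries(
                individual_id=str(row["individual_id"]),
                monitor_id=str(monitor_id),
                channel=ch,
                start=index[0],
                counts=col,
                step=step,
                meta=meta,
            )
        )
    return CohortTable(series=series, schedule=schedule)


def read_monitor_files(paths, channel_meta: pd.DataFrame, schedule: LightSchedule) -> CohortTable:
    """Read several monitor files into one cohort."""
    all_series = []
    for p in paths:
        all_series.extend(read_monitor_file(p, channel_meta, schedule).series)
    return CohortTable(series=all_series, schedule=schedule)


def write_monitor_file(cohort, path) -> None:
    """Serialize a cohort (or list of series) from ONE monitor to a file.

    Emits the same dialect :func:`read_monitor_file` parses — reading index,
    date, time, one status column, 32 tab-separated counts — so that
    read∘write is the identity on counts and timestamps.  Channels without a
    series are written as zeros; more than 32 series is an error.
    """
    series = list(cohort.series if isinstance(cohort, CohortTable) else cohort)
    with open(path, "w") as fh:
        if not series:
            return
        if len(series) > N_CHANNELS:
            raise ValueError(f"{len(series)} series exceed the {N_CHANNELS} channels of one monitor")
        monitors = {s.monitor_id for s in series}
        if len(monitors) > 1:
            raise ValueError(f"one monitor file per monitor; got {sorted(monitors)}")
        channels = [s.channel for s in series]
        if len(set(channels)) != len(channels):
            raise ValueError("duplicate channel assignment")
        starts = {(s.start, len(s), s.step) for s in series}
        if len(starts) > 1:
            raise ValueError("all series in a monitor file must share the same grid")
        n = len(series[0])
        index = series[0].time_index()
        matrix = np.zeros((n, N_CHANNELS), dtype=np.int64)
        for s in series:
            matrix[:, s.channel - 1] = s.counts
        for i, ts in enumerate(index):
            date_s = f"{ts.day} {ts.strftime('%b %y')}"
            fields_ = [str(i + 1), date_s, ts.strftime("%H:%M:%S"), "1"] + [str(v) for v in matrix[i]]
            fh.write("\t".join(fields_) + "\n")
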