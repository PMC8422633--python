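"""Synthetic actogram cohorts with known ground truth.

The generator draws 1-min beam-break counts from a negative-binomial law
around a deterministic intensity that reproduces the qualitative structure
of female *Anopheles* locomotor activity in tube monitors:

* a burst of activity at dusk (one-sided exponential decay after the
  lights-off anchor), the dominant feature in both regimens;
* a smaller dawn burst under LD only, giving the bimodal LD profile;
* elevated night activity (plateau) relative to daytime quiescence;
* under DD, dusk/dawn anchors free-run: with an endogenous period tau < 24 h
  they advance by (24 − tau) hours each subjective day;
* blood-fed females are suppressed by a multiplicative factor for ~72 h
  after the meal, then recover linearly;
* inseminated females start dusk activity delta minutes later (the onset
  delay); and
* a configurable fraction of individuals is arrhythmic (flat intensity).

Every simulated individual carries its ground truth (arrhythmic flag, tau,
onset delay) so that parameter-recovery tests can score the pipeline.
Cohorts serialize to the monitor-file dialect plus a channel-metadata CSV,
making the generator's output indistinguishable, format-wise, from a real
recording.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lam_io import ChannelSeries, CohortTable, LightSchedule, write_monitor_file

#: channels per monitor left as empty control tubes
N_CONTROL_CHANNELS = 2
_SIM_CHANNELS = 30  # 32 minus the controls


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one treatment group.

    Rates are counts per minute; amplitudes are multiplicative relative to
    baseline.  ``nb_dispersion`` is the negative-binomial size parameter k
    (variance = m + m^2/k); ``None`` gives Poisson counts.
    """

    group: str = "group"
    insemination: str = "virgin"
    meal: str = "glucose"
    regimen: str = "LD"
    n_per_group: int = 15
    baseline_rate: float = 0.05
    dusk_amp: float = 60.0
    dusk_decay_min: float = 30.0
    dawn_amp: float = 30.0
    night_plateau: float = 8.0
    tau_h: float = 23.0
    tau_sd_h: float = 0.25
    onset_delay_min: float = 0.0
    blood_suppression: float = 0.3
    recovery_h: float = 72.0
    recovery_ramp_h: float = 24.0
    p_arrhythmic: float = 0.0
    nb_dispersion: float | None = 5.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.dusk_amp < 0 or self.dawn_amp < 0:
            raise ValueError("rates and amplitudes must be non-negative")
        if not 0.0 <= self.p_arrhythmic <= 1.0:
            raise ValueError("p_arrhythmic must be a probability")
        if self.meal == "blood" and not 0.0 < self.blood_suppression <= 1.0:
            raise ValueError("blood_suppression must be in (0, 1]")


def default_study(scale: float = 1.0) -> list:
    """The 2x2 factorial (insemination x meal) under LD and DD.

    Group sizes mirror the study design (LD groups of 33/25/22/36, DD
    groups of 15 each); ``scale`` shrinks them proportionally for quick
    runs.  Inseminated females carry a 4-min onset delay and an elevated
    arrhythmic fraction under DD; blood-fed groups are suppressed for 72 h.
    """
    sizes_ld = {("virgin", "glucose"): 33, ("inseminated", "glucose"): 25, ("inseminated", "blood"): 22, ("virgin", "blood"): 36}
    study = []
    for regimen in ("LD", "DD"):
        for (insem, meal), n_ld in sizes_ld.items():
            n = n_ld if regimen == "LD" else 15
            study.append(
                SimConfig(
                    group=f"{insem}_{meal}_{regimen}",
                    insemination=insem,
                    meal=meal,
                    regimen=regimen,
                    n_per_group=max(1, int(round(n * scale))),
                    dawn_amp=30.0 if regimen == "LD" else 0.0,
                    onset_delay_min=4.0 if insem == "inseminated" else 0.0,
                    p_arrhythmic=(0.25 if insem == "inseminated" else 0.03) if regimen == "DD" else 0.03,
                )
            )
    return study


def intensity_function(
    t_min: np.ndarray,
    params: SimConfig,
    schedule: LightSchedule,
    start_clock_h: float = 0.0,
    tau_h: float | None = None,
    arrhythmic: bool = False,
) -> np.ndarray:
    """Expected counts per minute at ``t_min`` minutes after recording start.

    lambda(t) = baseline * [1 + dusk_amp*exp(-dt_dusk/decay)
                              + dawn_amp*1{LD}*exp(-dt_dawn/decay)
                              + (night_plateau - 1)*1{scotophase}] * suppression(t)

    where dt_dusk/dt_dawn are minutes since the most recent (possibly
    free-running and delay-shifted) dusk/dawn anchor.  Arrhythmic
    individuals have lambda = baseline (times suppression).
    """
    t_min = np.asarray(t_min, dtype=float)
    lam = np.ones_like(t_min)
    if not arrhythmic:
        tau = params.tau_h if tau_h is None else tau_h
        free_run = params.regimen == "DD"
        drift_min_per_day = (24.0 - tau) * 60.0 if free_run else 0.0
        clock_min = (start_clock_h * 60.0 + t_min) % 1440.0
        day_idx = np.floor((start_clock_h * 60.0 + t_min) / 1440.0)

        def minutes_since(anchor_clock_h: float, delay_min: float) -> np.ndarray:
            # anchor on day d sits at anchor + delay - d*drift (clock minutes)
            anchor = anchor_clock_h * 60.0 + delay_min - day_idx * drift_min_per_day
            dt = (start_clock_h * 60.0 + t_min) - (day_idx * 1440.0 + anchor)
            # if today's anchor hasn't happened yet, refer to yesterday's
            # (consecutive anchors are 1440 - drift minutes apart)
            prev = dt + 1440.0 - drift_min_per_day
            return np.where(dt >= 0, dt, prev)

        dt_dusk = minutes_since(schedule.lights_off_h, params.onset_delay_min)
        lam = lam + params.dusk_amp * np.exp(-dt_dusk / params.dusk_decay_min)
        if params.regimen == "LD" and params.dawn_amp > 0:
            dt_dawn = minutes_since(schedule.lights_on_h, 0.0)
            lam = lam + params.dawn_amp * np.exp(-dt_dawn / params.dusk_decay_min)
        # night plateau between the (shifted) dusk anchor and dusk + scotophase
        night_len_min = schedule.scotophase_h * 60.0
        lam = lam + (params.night_plateau - 1.0) * (dt_dusk < night_len_min)
        del clock_min
    lam = params.baseline_rate * lam
    if params.meal == "blood" and params.blood_suppression < 1.0:
        t_h = t_min / 60.0
        ramp = np.clip((t_h - params.recovery_h) / params.recovery_ramp_h, 0.0, 1.0)
        suppression = params.blood_suppression + (1.0 - params.blood_suppression) * ramp
        lam = lam * suppression
    return lam


def _draw_counts(lam: np.ndarray, dispersion: float | None, rng: np.random.Generator) -> np.ndarray:
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(lam)
    k = float(dispersion)
    p = k / (k + np.maximum(lam, 1e-12))
    out = rng.negative_binomial(k, p)
    return np.where(lam <= 0, 0, out)


def simulate_individual(
    params: SimConfig,
    schedule: LightSchedule,
    seed,
    individual_id: str = "sim-1",
    n_days: int = 7,
    start: str | pd.Timestamp = "2021-01-04 00:00:00",
) -> tuple:
    """Simulate one individual's 7-day series; returns (series, truth dict)."""
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start)
    n = n_days * 1440
    t_min = np.arange(n, dtype=float)
    is_arr = bool(rng.random() < params.p_arrhythmic)
    tau = float(np.clip(rng.normal(params.tau_h, params.tau_sd_h), 21.0, 25.0)) if params.tau_sd_h > 0 else params.tau_h
    start_clock_h = start.hour + start.minute / 60.0
    lam = intensity_function(t_min, params, schedule, start_clock_h=start_clock_h, tau_h=tau, arrhythmic=is_arr)
    counts = _draw_counts(lam, params.nb_dispersion, rng)
    series = ChannelSeries(
        individual_id=individual_id,
        monitor_id="sim",
        channel=1,
        start=start,
        counts=counts,
        meta={
            "insemination": params.insemination,
            "meal": params.meal,
            "regimen": params.regimen,
            "is_control_tube": False,
            "group": params.group,
        },
    )
    truth = {
        "individual_id": individual_id,
        "group": params.group,
        "is_arrhythmic": is_arr,
        "tau_h": tau if not is_arr else np.nan,
        "onset_delay_min": params.onset_delay_min,
        "regimen": params.regimen,
        "insemination": params.insemination,
        "meal": params.meal,
    }
    return series, truth


def simulate_cohort(
    study: list,
    seed,
    n_days: int = 7,
    start: str | pd.Timestamp = "2021-01-04 00:00:00",
    out_dir: str | None = None,
) -> tuple:
    """Simulate a multi-group cohort; optionally write monitor files.

    Groups may mix LD and DD configs; each regimen gets its own
    :class:`LightSchedule` (same clock anchors).  Returns
    ``(cohorts, truth_df)`` with ``cohorts`` a dict regimen -> CohortTable.
    When ``out_dir`` is given, monitor files (30 simulated channels plus 2
    empty control tubes each), ``channel_meta.csv`` and
    ``ground_truth.csv`` are written there.
    """
    rng = np.random.default_rng(seed)
    schedules = {"LD": LightSchedule(regimen="LD"), "DD": LightSchedule(regimen="DD")}
    series_by_regimen: dict = {"LD": [], "DD": []}
    truths = []
    uid = 0
    for cfg in study:
        for _ in range(cfg.n_per_group):
            uid += 1
            child_seed = int(rng.integers(0, 2**31 - 1))
            s, t = simulate_individual(
                cfg,
                schedules[cfg.regimen],
                child_seed,
                individual_id=f"{cfg.group}-{uid:03d}",
                n_days=n_days,
                start=start,
            )
            series_by_regimen[cfg.regimen].append(s)
            truths.append(t)
    truth_df = pd.DataFrame(truths)

    # pack onto monitors: 30 test channels + 2 control tubes each
    meta_rows = []
    cohorts = {}
    monitor_idx = 0
    n = n_days * 1440
    for regimen, slist in series_by_regimen.items():
        if not slist:
            continue
        packed = []
        for i, s in enumerate(slist):
            if i % _SIM_CHANNELS == 0:
                monitor_idx += 1
                for ctrl_ch in (31, 32):
                    ctrl = ChannelSeries(
                        individual_id=f"control-M{monitor_idx:02d}-C{ctrl_ch}",
                        monitor_id=f"Monitor{monitor_idx:02d}",
                        channel=ctrl_ch,
                        start=pd.Timestamp(start),
                        counts=np.zeros(n, dtype=np.int64),
                        meta={"is_control_tube": True, "regimen": regimen},
                    )
                    packed.append(ctrl)
                    meta_rows.append(_meta_row(ctrl))
            s.monitor_id = f"Monitor{monitor_idx:02d}"
            s.channel = (i % _SIM_CHANNELS) + 1
            packed.append(s)
            meta_rows.append(_meta_row(s))
        cohorts[regimen] = CohortTable(series=packed, schedule=schedules[regimen])

    meta_df = pd.DataFrame(meta_rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for cohort in cohorts.values():
            by_monitor: dict = {}
            for s in cohort.series:
                by_monitor.setdefault(s.monitor_id, []).append(s)
            for mon, slist in by_monitor.items():
                write_monitor_file(slist, os.path.join(out_dir, f"{mon}.txt"))
        meta_df.to_csv(os.path.join(out_dir, "channel_meta.csv"), index=False)
        truth_df.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
        pd.DataFrame([dataclasses.asdict(c) for c in study]).to_csv(os.path.join(out_dir, "study_config.csv"), index=False)
    return cohorts, truth_df, meta_df


def _meta_row(s: ChannelSeries) -> dict:
    return {
        "monitor_id": s.monitor_id,
        "channel": s.channel,
        "individual_id": s.individual_id,
        "insemination": s.meta.get("insemination", ""),
        "meal": s.meta.get("meal", ""),
        "regimen": s.meta.get("regimen", ""),
        "is_control_tube": bool(s.meta.get("is_control_tube", False)),
        "group": s.meta.get("group", ""),
    }
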