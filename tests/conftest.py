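import numpy as np
import pandas as pd
import pytest

from circalam.lam_io import ChannelSeries, LightSchedule

START = pd.Timestamp("2021-01-04 00:00:00")


def make_series(counts, individual_id="ind-1", start=START, step=60, meta=None, channel=1):
    return ChannelSeries(
        individual_id=individual_id,
        monitor_id="M01",
        channel=channel,
        start=start,
        counts=np.asarray(counts, dtype=np.int64),
        step=step,
        meta=meta or {},
    )


@pytest.fixture
def ld_schedule():
    return LightSchedule(regimen="LD")


@pytest.fixture
def dd_schedule():
    return LightSchedule(regimen="DD")


@pytest.fixture
def square_wave_series():
    """Noiseless 24 h square wave: active 12 h, still 12 h, 5 recording days."""
    day = np.concatenate([np.zeros(720, dtype=np.int64), np.full(720, 4, dtype=np.int64)])
    return make_series(np.tile(day, 5))


def naive_qp(x, k):
    """Brute-force chi-square periodogram statistic at a trial period of k bins.

    Independent double-loop evaluation: fold the first N*k bins into N
    complete cycles, accumulate phase-column means and the grand mean with
    explicit loops, and form N^2 * k * sum_h (M_h - M)^2 / sum_i (x_i - M)^2.
    """
    x = [float(v) for v in x]
    n_cycles = len(x) // k
    used = x[: n_cycles * k]
    grand = sum(used) / len(used)
    num = 0.0
    for h in range(k):
        col_sum = 0.0
        for c in range(n_cycles):
            col_sum += used[c * k + h]
        m_h = col_sum / n_cycles
        num += (m_h - grand) ** 2
    denom = 0.0
    for v in used:
        denom += (v - grand) ** 2
    if denom == 0:
        return 0.0
    return n_cycles**2 * k * num / denom
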