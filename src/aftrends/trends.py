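"""Moving-average engine and trend-state classification.

For a daily parameter :math:`d_i` recorded from the day after implant, the
engine computes the cumulative moving average

.. math:: \\mathrm{CMA}(t) = \\frac{1}{t} \\sum_{i=1}^{t} d_i

and, for each clinical window :math:`p \\in \\{1,2,3,5,8,13,21\\}`, the simple
moving average

.. math:: \\mathrm{SMA}_p(t) = \\frac{1}{p} \\sum_{i=t-p+1}^{t} d_i .

Daily AF-burden trend states:

A
    sinus rhythm: burden CMA below 1% of the day (14.4 min/day);
B
    below-average burden: 21-day SMA strictly below the CMA;
C
    at/above-average burden: 21-day SMA at or above the CMA (inclusive);
D
    subset of C with burden CMA above 8.5 min/day and activity CMA below
    87 min/day (increasing burden with decreasing patient activity).

Two prespecified clinical comparators are flagged per day: the duration
threshold (a continuous AF episode of at least one hour, regardless of when
it started) and the quantity threshold (total AT/AF of at least 72 minutes,
5% of the day).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import TrendConfig
from .timeline import PatientTimeline

#: diagnostic parameters that receive the CMA/SMA treatment
TREND_PARAMETERS = ("af_burden_min", "activity_min", "vrate_day_bpm",
                    "vrate_night_bpm", "hrv_sd_ms")


class UndefinedWindowError(ValueError):
    """Requested an SMA value at a day earlier than the window length."""


# ---------------------------------------------------------------------------
# scalar operations (reference semantics)
# ---------------------------------------------------------------------------

def cumulative_moving_average(series: Sequence[float], t: int) -> float:
    """Mean of the first ``t`` daily values (``t`` is 1-based)."""
    if t < 1:
        raise ValueError(f"t must be >= 1, got {t}")
    x = np.asarray(series, dtype=float)
    if len(x) < t:
        raise ValueError(f"series has {len(x)} entries, fewer than t={t}")
    return float(x[:t].mean())


def simple_moving_average(series: Sequence[float], t: int, p: int) -> float:
    """Mean of the ``p`` daily values ending at day ``t`` (1-based)."""
    if p < 1:
        raise ValueError(f"window p must be >= 1, got {p}")
    if t < p:
        raise UndefinedWindowError(f"SMA_{p} is undefined at day t={t} < p")
    x = np.asarray(series, dtype=float)
    if len(x) < t:
        raise ValueError(f"series has {len(x)} entries, fewer than t={t}")
    return float(x[t - p:t].mean())


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------

def cma_series(values: np.ndarray) -> np.ndarray:
    """CMA at every day of a contiguous daily series (index i = day i+1)."""
    x = np.asarray(values, dtype=float)
    return np.cumsum(x) / np.arange(1, len(x) + 1)


def sma_series(values: np.ndarray, p: int) -> np.ndarray:
    """SMA_p at every day; NaN where the window is not yet complete (t < p)."""
    x = np.asarray(values, dtype=float)
    if p < 1:
        raise ValueError(f"window p must be >= 1, got {p}")
    out = np.full(len(x), np.nan)
    if len(x) >= p:
        c = np.concatenate(([0.0], np.cumsum(x)))
        out[p - 1:] = (c[p:] - c[:-p]) / p
    return out


def compute_trend_snapshots(tl: PatientTimeline,
                            config: TrendConfig | None = None) -> pd.DataFrame:
    """Per-day CMA and SMA_p for every diagnostic parameter, from the index day on.

    The history starts at the first recorded day (the day after implant), so
    at the default index day (22) every window up to 21 days is defined.
    """
    config = (config or TrendConfig()).validate()
    if tl.n_days == 0:
        raise ValueError(f"{tl.patient_id}: empty timeline")
    if tl.first_day != 1:
        raise ValueError(f"{tl.patient_id}: snapshots need history from day 1 "
                         f"(first record at day {tl.first_day})")
    days = tl.values("day_offset").astype(int)
    if not np.array_equal(days, np.arange(1, len(days) + 1)):
        raise ValueError(f"{tl.patient_id}: timeline must be contiguous (forward-fill first)")
    keep = days >= tl.index_day
    out = {"patient_id": np.repeat(tl.patient_id, int(keep.sum())),
           "day_offset": days[keep]}
    for param in TREND_PARAMETERS:
        x = tl.values(param)
        out[f"{param}_cma"] = cma_series(x)[keep]
        for p in config.sma_windows:
            out[f"{param}_sma{p}"] = sma_series(x, p)[keep]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# trend states and clinical thresholds
# ---------------------------------------------------------------------------

def classify_states(burden_cma: np.ndarray,
                    burden_sma_long: np.ndarray,
                    activity_cma: np.ndarray,
                    config: TrendConfig | None = None) -> np.ndarray:
    """Vectorized A/B/C/D classification; refuses undefined long-window SMAs."""
    config = config or TrendConfig()
    burden_cma = np.asarray(burden_cma, dtype=float)
    burden_sma_long = np.asarray(burden_sma_long, dtype=float)
    activity_cma = np.asarray(activity_cma, dtype=float)
    if np.isnan(burden_sma_long).any():
        raise UndefinedWindowError(
            "long-window SMA undefined on some days; classification refused")
    state = np.full(burden_cma.shape, "C", dtype="<U1")
    state[burden_sma_long < burden_cma] = "B"
    d_mask = ((state == "C")
              & (burden_cma > config.trend_d_burden_cma_min)
              & (activity_cma < config.trend_d_activity_cma_max))
    state[d_mask] = "D"
    # A takes precedence: little burden history means sinus rhythm regardless
    state[burden_cma < config.sinus_cma_threshold] = "A"
    return state


def classify_trend_state(burden_cma: float, burden_sma_long: float,
                         activity_cma: float,
                         config: TrendConfig | None = None) -> str:
    """Scalar A/B/C/D classification for one day."""
    return str(classify_states(np.array([burden_cma]), np.array([burden_sma_long]),
                               np.array([activity_cma]), config)[0])


def duration_threshold_met(max_continuous_af_min, config: TrendConfig | None = None):
    """Day meets the duration comparator: continuous AF of >= 1 hour."""
    thr = (config or TrendConfig()).duration_threshold_min
    return np.asarray(max_continuous_af_min, dtype=float) >= thr


def quantity_threshold_met(af_burden_min, config: TrendConfig | None = None):
    """Day meets the quantity comparator: total AT/AF >= 72 min (5% of the day)."""
    thr = (config or TrendConfig()).quantity_threshold_min
    return np.asarray(af_burden_min, dtype=float) >= thr


def flag_days(tl: PatientTimeline, config: TrendConfig | None = None) -> pd.DataFrame:
    """Per-day trend state and clinical-threshold flags from the index day on.

    Returns columns ``patient_id, day_offset, trend_state, duration_met,
    quantity_met``; crossover days are visible as state changes between
    consecutive rows.
    """
    config = (config or TrendConfig()).validate()
    days = tl.values("day_offset").astype(int)
    if tl.n_days == 0 or tl.first_day != 1 or not np.array_equal(days, np.arange(1, len(days) + 1)):
        raise ValueError(f"{tl.patient_id}: flagging needs a contiguous timeline from day 1")
    burden = tl.values("af_burden_min")
    activity = tl.values("activity_min")
    longest = tl.values("max_continuous_af_min")
    keep = days >= tl.index_day
    state = classify_states(cma_series(burden)[keep],
                            sma_series(burden, config.max_window)[keep],
                            cma_series(activity)[keep], config)
    return pd.DataFrame({
        "patient_id": np.repeat(tl.patient_id, int(keep.sum())),
        "day_offset": days[keep],
        "trend_state": state,
        "duration_met": duration_threshold_met(longest[keep], config),
        "quantity_met": quantity_threshold_met(burden[keep], config),
    })


def flag_cohort(cohort: Sequence[PatientTimeline],
                config: TrendConfig | None = None) -> pd.DataFrame:
    """Concatenated :func:`flag_days` table for a whole cohort.

    Equivalent to per-patient flagging but assembled in one pass.
    """
    config = (config or TrendConfig()).validate()
    pids, days_l, states_l, dur_l, qty_l = [], [], [], [], []
    for tl in cohort:
        if tl.n_days < tl.index_day:
            continue
        rec = tl.records
        days = rec["day_offset"].to_numpy(dtype=int)
        if tl.first_day != 1 or not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise ValueError(f"{tl.patient_id}: flagging needs a contiguous timeline from day 1")
        burden = rec["af_burden_min"].to_numpy(dtype=float)
        keep = slice(tl.index_day - 1, len(days))
        states_l.append(classify_states(
            cma_series(burden)[keep],
            sma_series(burden, config.max_window)[keep],
            cma_series(rec["activity_min"].to_numpy(dtype=float))[keep], config))
        dur_l.append(duration_threshold_met(
            rec["max_continuous_af_min"].to_numpy(dtype=float)[keep], config))
        qty_l.append(quantity_threshold_met(burden[keep], config))
        days_l.append(days[keep])
        pids.append(np.repeat(tl.patient_id, len(days) - tl.index_day + 1))
    if not pids:
        return pd.DataFrame(columns=["patient_id", "day_offset", "trend_state",
                                     "duration_met", "quantity_met"])
    return pd.DataFrame({
        "patient_id": np.concatenate(pids),
        "day_offset": np.concatenate(days_l),
        "trend_state": np.concatenate(states_l),
        "duration_met": np.concatenate(dur_l),
        "quantity_met": np.concatenate(qty_l),
    })
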