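"""Synthetic ICM cohort generator with known ground truth.

The generator emulates the statistical structure of a two-year ICM follow-up
study: a 94%/6% paroxysmal/persistent phenotype mix, a 2-minute detection
floor, sporadic follow-up gaps, a subcohort with linearly declining activity,
and cardiovascular hospitalization (CVH) events whose day-level hazard is the
baseline hazard multiplied by the patient's current AF-burden trend state.

Paroxysmal AF is generated as a per-day Bernoulli episode process whose
propensity follows a slowly varying AR(1) on the log scale, so that burden
exhibits genuine trends and moving-average crossovers are informative.
Persistent AF overlays runs of >= 7 consecutive saturated days (>= 23.5 h of
AT/AF) on a paroxysmal background.

Hazard linkage: the Bernoulli trial attached to follow-up day ``d`` (whose
trend state is known at the end of day ``d``) produces an event on day
``d + 1``, so diagnostic records always end the day before the event and the
day-level rate estimator recovers the generating multipliers exactly in
expectation.  The hazard is active from the index day (day 22) onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import (ConfigError, DAY_MINUTES, PERSISTENT_DAY_MIN,
                     SimulationConfig, TrendConfig)
from .timeline import (DEFAULT_INDEX_DAY, INDICATIONS, PatientTimeline,
                       VALUE_COLUMNS, make_timeline)
from . import trends

PHENOTYPES = ("paroxysmal", "persistent")


@dataclass
class GroundTruth:
    """Per-patient phenotype and per-day true trend state behind the hazard."""

    phenotype: dict[str, str] = field(default_factory=dict)
    states: dict[str, np.ndarray] = field(default_factory=dict)  # day 1..last record
    state_multipliers: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for pid, st in self.states.items():
            rows.append(pd.DataFrame({
                "patient_id": pid,
                "day_offset": np.arange(1, len(st) + 1),
                "true_state": st,
                "phenotype": self.phenotype[pid],
            }))
        if not rows:
            return pd.DataFrame(columns=["patient_id", "day_offset", "true_state", "phenotype"])
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# signal generators
# ---------------------------------------------------------------------------

def _ar1(n: int, rho: float, stationary_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series of length n with mean 0."""
    if stationary_sd == 0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, stationary_sd * np.sqrt(1.0 - rho ** 2), size=n)
    if n:
        eps[0] = rng.normal(0.0, stationary_sd)
    return lfilter([1.0], [1.0, -rho], eps)


def _paroxysmal_series(n_days: int, rng: np.random.Generator,
                       cfg: SimulationConfig, rate: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    burden = np.zeros(n_days)
    longest = np.zeros(n_days)
    if rate <= 0 or n_days == 0:
        return burden, longest
    # patient-level episode-duration scale: most of the cohort's burden is
    # carried by a minority of patients with long episodes
    log_scale = rng.normal(cfg.episode_duration_log_mean, cfg.episode_scale_log_sd)
    x = _ar1(n_days, cfg.propensity_rho, cfg.propensity_sd, rng)
    # mean-one multiplicative propensity keeps the marginal episode rate at `rate`
    p = np.clip(rate * np.exp(x - 0.5 * cfg.propensity_sd ** 2), 0.0, 1.0)
    episode_day = rng.random(n_days) < p
    idx = np.flatnonzero(episode_day)
    if idx.size == 0:
        return burden, longest
    n_ep = 1 + rng.poisson(cfg.extra_episode_mean, size=idx.size)
    total = int(n_ep.sum())
    durations = np.exp(rng.normal(log_scale, cfg.episode_duration_log_sd, size=total))
    durations = np.clip(durations, cfg.detection_floor_min, DAY_MINUTES)
    offsets = np.concatenate(([0], np.cumsum(n_ep)[:-1]))
    burden[idx] = np.minimum(np.add.reduceat(durations, offsets), DAY_MINUTES)
    longest[idx] = np.minimum(np.maximum.reduceat(durations, offsets), burden[idx])
    return burden, longest


def simulate_af_series(phenotype: str, n_days: int, rng: np.random.Generator,
                       config: SimulationConfig | None = None,
                       min_run_start: int = 1
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Daily (total burden, longest continuous episode) in minutes.

    ``persistent`` series are guaranteed to contain at least one run of >= 7
    consecutive days with burden >= 1410 min (23.5 h), starting no earlier
    than ``min_run_start``; if the series is shorter than 7 days every day is
    saturated.
    """
    cfg = (config or SimulationConfig()).validate()
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if phenotype == "paroxysmal":
        return _paroxysmal_series(n_days, rng, cfg, cfg.episode_rate)

    # persistent: paroxysmal background at an elevated rate, plus saturated runs
    burden, longest = _paroxysmal_series(n_days, rng, cfg, min(1.0, 2 * cfg.episode_rate))
    saturated = np.zeros(n_days, dtype=bool)
    if n_days < 7:
        saturated[:] = True
        cursor = None
    else:
        # anchor the first run at min_run_start so the phenotype is visible
        # from the index date even under early event truncation
        latest_start = n_days - 7 + 1
        cursor = max(1, min(min_run_start, latest_start))
    first = True
    while cursor is not None and cursor <= n_days:
        length = max(7, int(rng.geometric(1.0 / 30.0)))
        end = min(n_days, cursor + length - 1)
        if first or end - cursor + 1 >= 7:
            saturated[cursor - 1:end] = True
        first = False
        cursor = end + 1 + int(rng.geometric(1.0 / 45.0))
    n_sat = int(saturated.sum())
    if n_sat:
        sat_burden = rng.uniform(PERSISTENT_DAY_MIN, DAY_MINUTES, size=n_sat)
        burden[saturated] = sat_burden
        longest[saturated] = sat_burden  # one continuous episode spanning the day
    return burden, longest


def simulate_activity(n_days: int, decline: bool, rng: np.random.Generator,
                      config: SimulationConfig | None = None,
                      patient_mean: float | None = None) -> np.ndarray:
    """Daily activity minutes; optional linear decline, clipped to [0, 1440]."""
    cfg = (config or SimulationConfig()).validate()
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    mean = patient_mean
    if mean is None:
        mean = rng.normal(cfg.activity_mean_min, cfg.activity_between_sd_min)
    series = mean + (rng.normal(0.0, cfg.activity_sd_min, size=n_days)
                     if cfg.activity_sd_min > 0 else np.zeros(n_days))
    if decline:
        series = series - cfg.activity_decline_min_per_day * np.arange(n_days)
    return np.clip(series, 0.0, DAY_MINUTES)


def _heart_rate_channels(n_days: int, burden: np.ndarray,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Ancillary channels; AF days raise ventricular rates and RR irregularity."""
    frac = burden / DAY_MINUTES
    vday = rng.normal(78.0, 7.0) + rng.normal(0.0, 4.0, n_days) + 12.0 * frac
    vnight = rng.normal(66.0, 6.0) + rng.normal(0.0, 3.5, n_days) + 8.0 * frac
    hrv = rng.normal(100.0, 25.0) + rng.normal(0.0, 10.0, n_days) + 40.0 * frac
    return {
        "vrate_day_bpm": np.clip(vday, 30.0, 250.0),
        "vrate_night_bpm": np.clip(vnight, 30.0, 250.0),
        "hrv_sd_ms": np.clip(hrv, 0.0, None),
    }


# ---------------------------------------------------------------------------
# event assignment and gaps
# ---------------------------------------------------------------------------

def true_states(burden: np.ndarray, activity: np.ndarray,
                index_day: int = DEFAULT_INDEX_DAY,
                trend_config: TrendConfig | None = None) -> np.ndarray:
    """Per-day trend state used by the hazard; 'A' before the index day."""
    tcfg = trend_config or TrendConfig()
    n = len(burden)
    states = np.full(n, "A", dtype="<U1")
    if n >= index_day:
        keep = slice(index_day - 1, n)
        states[keep] = trends.classify_states(
            trends.cma_series(burden)[keep],
            trends.sma_series(burden, tcfg.max_window)[keep],
            trends.cma_series(activity)[keep], tcfg)
    return states


def _state_hazard(states: np.ndarray, index_day: int,
                  config: SimulationConfig) -> np.ndarray:
    mult = np.empty(len(states))
    for s, m in config.state_multipliers.items():
        mult[states == s] = m
    hazard = config.baseline_hazard * mult
    hazard[:index_day - 1] = 0.0
    if (hazard > 1.0).any():
        raise ConfigError("per-day hazard exceeds 1 after state multiplication")
    return hazard


def _draw_event_trial_day(states: np.ndarray, index_day: int,
                          config: SimulationConfig,
                          rng: np.random.Generator) -> int | None:
    """1-based follow-up day whose Bernoulli trial succeeds first, if any."""
    hazard = _state_hazard(states, index_day, config)
    hits = np.flatnonzero(rng.random(len(states)) < hazard)
    return int(hits[0]) + 1 if hits.size else None


def assign_events(tl: PatientTimeline, states: np.ndarray,
                  config: SimulationConfig, rng: np.random.Generator
                  ) -> PatientTimeline:
    """Draw the first CVH from the state-linked hazard and truncate records.

    Follow-up day ``d`` carries hazard ``baseline * multiplier[state_d]``
    (zero before the index day); a success produces the event on day
    ``d + 1`` and diagnostic records end on day ``d``.
    """
    n = tl.n_days
    if n == 0:
        raise ValueError("timeline has no days")
    d = _draw_event_trial_day(np.asarray(states[:n]), tl.index_day, config, rng)
    if d is None or d + 1 > config.max_follow_up_days:
        return replace(tl, cvh_day=None)
    rec = tl.records[tl.records["day_offset"] <= d].reset_index(drop=True)
    return replace(tl, cvh_day=d + 1, censor_day=min(tl.censor_day, d), records=rec)


def _draw_observed_mask(n: int, config: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray | None:
    """Observed-day mask after drawing gap starts/lengths; None when gap-free."""
    if n == 0 or config.gap_probability <= 0:
        return None
    starts = np.flatnonzero(rng.random(n) < config.gap_probability)
    starts = starts[starts > 0]  # keep the first day observed
    if starts.size == 0:
        return None
    lengths = rng.geometric(1.0 / config.gap_length_mean, size=starts.size)
    observed = np.ones(n, dtype=bool)
    for s, L in zip(starts, lengths):
        observed[s:s + int(L)] = False
    return observed


def inject_gaps(tl: PatientTimeline, config: SimulationConfig,
                rng: np.random.Generator) -> PatientTimeline:
    """Blank out follow-up gaps: unobserved days carry no diagnostic values.

    A gap starts on any day (after the first) with probability
    ``gap_probability`` and runs for a geometric number of days with the
    configured mean.  Overlapping gaps merge.
    """
    n = tl.n_days
    if n == 0 or config.gap_probability <= 0:
        return tl.copy()
    observed = _draw_observed_mask(n, config, rng)
    if observed is None:
        return tl.copy()
    rec = tl.records.copy()
    rec.loc[~observed, list(VALUE_COLUMNS)] = np.nan
    rec["observed"] = observed
    return replace(tl, records=rec)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig | None = None,
                    trend_config: TrendConfig | None = None
                    ) -> tuple[list[PatientTimeline], GroundTruth]:
    """Simulate ``n_patients`` timelines with ground-truth states and phenotypes.

    Fully deterministic under ``config.seed``: two runs with an equal config
    produce identical cohorts.
    """
    cfg = (config or SimulationConfig()).validate()
    tcfg = (trend_config or TrendConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    n, T = cfg.n_patients, cfg.max_follow_up_days
    persistent = rng.random(n) < cfg.phenotype_mix
    declining = rng.random(n) < cfg.activity_decline_fraction
    indications = rng.choice(INDICATIONS, size=n, p=[0.45, 0.30, 0.25]) if n else []

    cohort: list[PatientTimeline] = []
    truth = GroundTruth(state_multipliers=dict(cfg.state_multipliers))
    day_grid = np.arange(1, T + 1)
    for i in range(n):
        pid = f"P{i:05d}"
        phenotype = "persistent" if persistent[i] else "paroxysmal"
        burden, longest = simulate_af_series(
            phenotype, T, rng, cfg, min_run_start=DEFAULT_INDEX_DAY)
        activity = simulate_activity(T, bool(declining[i]), rng, cfg)
        channels = _heart_rate_channels(T, burden, rng)
        states = true_states(burden, activity, DEFAULT_INDEX_DAY, tcfg)
        d = _draw_event_trial_day(states, DEFAULT_INDEX_DAY, cfg, rng)
        if d is None or d + 1 > T:
            cvh, n_rec = None, T
        else:
            cvh, n_rec = d + 1, d
        observed = _draw_observed_mask(n_rec, cfg, rng)
        if observed is not None and phenotype == "persistent":
            # keep the anchor run observed so the device phenotype stays visible
            observed[DEFAULT_INDEX_DAY - 1:DEFAULT_INDEX_DAY + 6] = True
        cols = {"af_burden_min": burden[:n_rec],
                "max_continuous_af_min": longest[:n_rec],
                "activity_min": activity[:n_rec],
                **{k: v[:n_rec] for k, v in channels.items()}}
        if observed is not None:
            cols = {k: np.where(observed, v, np.nan) for k, v in cols.items()}
        tl = make_timeline(pid, day_grid[:n_rec], cols, observed=observed,
                           indication=str(indications[i]), cvh_day=cvh,
                           censor_day=n_rec)
        cohort.append(tl)
        truth.phenotype[pid] = phenotype
        truth.states[pid] = states[:n_rec].copy()
    return cohort, truth
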