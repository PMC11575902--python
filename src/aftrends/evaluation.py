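"""Holdout validation statistics for AF-burden risk criteria.

Implements day-level incidence rates and rate ratios with log-Wald confidence
intervals, the rank-statistic AUROC with a Hanley–McNeil interval, pooled
two-proportion tests, Venn event-yield accounting across competing criteria,
Poisson rate-equality comparison, and time-in-AT/AF distribution summaries.

Event attribution: an event is attributed to a criterion if any of the
``horizon`` (default 5) days preceding it meets the criterion — the same
window used to label risk days for rule discovery.  Trend-state rate ratios
use last-record-day attribution instead: each event is assigned to the trend
state of the last diagnostic day (the day before the event), which matches
the discrete-time hazard construction and makes the day-level rate estimator
unbiased for the generating multipliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata

from .config import TREND_STATES, TrendConfig
from .timeline import PatientTimeline, follow_up_summary
from . import trends

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateDataError(ValueError):
    """A statistic is undefined on the supplied data (e.g. one class only)."""


# ---------------------------------------------------------------------------
# rates and rate ratios
# ---------------------------------------------------------------------------

@dataclass
class RateRatioEstimate:
    rr: float
    log_rr: float
    ci_low: float
    ci_high: float
    exposed_events: int
    exposed_days: int
    reference_events: int
    reference_days: int
    degenerate: bool = False

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def incidence_rate(n_events: int, n_days: int) -> float:
    """Events per flagged day; undefined (raises) with zero flagged days."""
    if n_days <= 0:
        raise DegenerateDataError("incidence rate undefined: zero flagged days")
    return n_events / n_days


def rate_ratio(exposed_events: int, exposed_days: int,
               reference_events: int, reference_days: int) -> RateRatioEstimate:
    """Day-level incidence-rate ratio with a 95% log-Wald interval.

    ``rr = (a/PT1)/(c/PT0)``; ``CI = exp(log rr +/- 1.96 * sqrt(1/a + 1/c))``.
    Zero exposed events yield rr 0 with a one-sided interval, flagged
    ``degenerate``; zero reference events raise.
    """
    if reference_events <= 0:
        raise DegenerateDataError("rate ratio undefined: zero reference events")
    r0 = incidence_rate(reference_events, reference_days)
    r1 = incidence_rate(exposed_events, exposed_days)
    if exposed_events == 0:
        # one-sided bound from the upper limit of a Poisson count of 0 (~3.69)
        upper = (stats.chi2.ppf(0.975, 2) / 2) / exposed_days / r0
        return RateRatioEstimate(0.0, -math.inf, 0.0, upper,
                                 0, exposed_days, reference_events, reference_days,
                                 degenerate=True)
    rr = r1 / r0
    se = math.sqrt(1.0 / exposed_events + 1.0 / reference_events)
    return RateRatioEstimate(
        rr=rr, log_rr=math.log(rr),
        ci_low=rr * math.exp(-Z95 * se), ci_high=rr * math.exp(Z95 * se),
        exposed_events=exposed_events, exposed_days=exposed_days,
        reference_events=reference_events, reference_days=reference_days)


# ---------------------------------------------------------------------------
# event attribution
# ---------------------------------------------------------------------------

def event_table(cohort: Sequence[PatientTimeline]) -> pd.DataFrame:
    """One row per patient: cvh_day (NaN when censored) and last record day."""
    return pd.DataFrame({
        "patient_id": [tl.patient_id for tl in cohort],
        "cvh_day": [tl.cvh_day if tl.cvh_day is not None else np.nan for tl in cohort],
        "last_day": [tl.last_day for tl in cohort],
        "index_day": [tl.index_day for tl in cohort],
    })


def attribute_events(flags: pd.DataFrame, flag_col: str,
                     events: pd.DataFrame, horizon: int = 5) -> int:
    """Events with >= 1 flagged day among the ``horizon`` days before the event."""
    ev = events.dropna(subset=["cvh_day"])
    if ev.empty:
        return 0
    flagged = flags[flags[flag_col].astype(bool)][["patient_id", "day_offset"]]
    merged = flagged.merge(ev[["patient_id", "cvh_day"]], on="patient_id")
    in_window = ((merged["day_offset"] >= merged["cvh_day"] - horizon)
                 & (merged["day_offset"] <= merged["cvh_day"] - 1))
    return int(merged.loc[in_window, "patient_id"].nunique())


def criterion_counts(flags: pd.DataFrame, flag_col: str,
                     events: pd.DataFrame, horizon: int = 5) -> tuple[int, int]:
    """(attributed events, flagged person-days) for one criterion."""
    n_days = int(flags[flag_col].astype(bool).sum())
    return attribute_events(flags, flag_col, events, horizon), n_days


def state_counts(flags: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Per trend state: person-days and events attributed by last-record-day state."""
    days = flags.groupby("trend_state").size()
    ev = events.dropna(subset=["cvh_day"]).copy()
    last = flags.merge(
        ev[["patient_id", "last_day"]].assign(day_offset=lambda d: d["last_day"]),
        on=["patient_id", "day_offset"])
    ev_states = last.groupby("trend_state").size()
    out = pd.DataFrame({
        "days": days.reindex(list(TREND_STATES), fill_value=0),
        "events": ev_states.reindex(list(TREND_STATES), fill_value=0),
    })
    out.index.name = "trend_state"
    return out.astype(int)


def state_rate_ratios(flags: pd.DataFrame, events: pd.DataFrame,
                      reference: str = "A") -> dict[str, RateRatioEstimate]:
    """Rate ratios of each non-reference trend state versus the reference state."""
    counts = state_counts(flags, events)
    a, pt0 = int(counts.loc[reference, "events"]), int(counts.loc[reference, "days"])
    out = {}
    for state in TREND_STATES:
        if state == reference:
            continue
        out[state] = rate_ratio(int(counts.loc[state, "events"]),
                                int(counts.loc[state, "days"]), a, pt0)
    return out


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def day_level_auroc(scores: np.ndarray, labels: np.ndarray
                    ) -> tuple[float, tuple[float, float]]:
    """Rank-statistic AUROC (ties count 1/2) with Hanley–McNeil 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("AUROC undefined: both classes required")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
           + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    half = Z95 * math.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


def criteria_score(flags: pd.DataFrame, criteria: Sequence[str]) -> np.ndarray:
    """Day-level risk score: number of criteria met (0..len(criteria))."""
    return sum(flags[c].astype(int).to_numpy() for c in criteria)


# ---------------------------------------------------------------------------
# proportion and Poisson tests
# ---------------------------------------------------------------------------

def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sided z test for equality of two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    p1, p2 = x1 / n1, x2 / n2
    if p1 == p2:
        return 0.0, 1.0
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return z, 2.0 * stats.norm.sf(abs(z))


def poisson_rate_comparison(counts: Mapping[str, tuple[int, int]]) -> dict:
    """Log-linear rate model over criteria with a person-days offset.

    Fits ``log E[events] = beta_criterion + log(days)`` by IRLS (one indicator
    per criterion, no intercept) and reports Wald tests for pairwise
    coefficient equality.
    """
    names = list(counts)
    if len(names) < 2:
        raise ValueError("need >= 2 criteria")
    events = np.array([counts[k][0] for k in names], dtype=float)
    days = np.array([counts[k][1] for k in names], dtype=float)
    if (days <= 0).any():
        raise DegenerateDataError("every criterion needs nonzero person-days")
    X = np.eye(len(names))
    model = sm.GLM(events, X, family=sm.families.Poisson(), offset=np.log(days))
    import warnings
    with warnings.catch_warnings():
        # the saturated single-factor model has zero residual df by design
        warnings.simplefilter("ignore")
        res = model.fit()
    coefs = dict(zip(names, res.params))
    cov = res.cov_params()
    pairwise = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            diff = res.params[i] - res.params[j]
            var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            if diff == 0:
                z, p = 0.0, 1.0
            else:
                z = diff / math.sqrt(var)
                p = 2.0 * stats.norm.sf(abs(z))
            pairwise[(a, b)] = {"diff": float(diff), "z": float(z), "p": float(p)}
    return {"coefficients": {k: float(v) for k, v in coefs.items()},
            "pairwise": pairwise,
            "converged": bool(res.converged),
            "n_iterations": int(getattr(res, "fit_history", {}).get("iteration", 0))}


# ---------------------------------------------------------------------------
# Venn event yield
# ---------------------------------------------------------------------------

@dataclass
class YieldReport:
    """Events per criterion-combination region plus the trend-exclusive yield."""

    regions: dict[frozenset, int]
    total_captured: int
    trend_exclusive_events: int
    clinical_events: int
    percent_increase: float
    trend_days_total: int = 0
    trend_days_exclusive: int = 0

    @property
    def day_exclusivity_pct(self) -> float:
        if self.trend_days_total == 0:
            return float("nan")
        return 100.0 * self.trend_days_exclusive / self.trend_days_total


def percent_increase(extra_events: int, base_events: int) -> float:
    """Percent increase in event yield, e.g. 137 extra over 644 -> 21.3%."""
    if base_events <= 0:
        raise DegenerateDataError("percent increase undefined: zero base events")
    return 100.0 * extra_events / base_events


def relative_increase_pct(new: float, old: float) -> float:
    """Relative improvement of a statistic, in percent (0.55 -> 0.66 is 20%)."""
    if old == 0:
        raise DegenerateDataError("relative increase undefined: zero baseline")
    return 100.0 * (new - old) / old


def days_per_year(day_fraction: float, year_days: int = 365) -> float:
    """Expected flagged days per year from a daily occupancy fraction."""
    return day_fraction * year_days


def venn_event_yield(flags: pd.DataFrame, events: pd.DataFrame,
                     criteria: Sequence[str], trend_criterion: str,
                     horizon: int = 5) -> YieldReport:
    """Assign each event to the set of criteria met in its pre-event window.

    ``criteria`` lists every flag column (clinical comparators plus the trend
    criterion); the percent increase is trend-exclusive events over events
    captured by at least one clinical criterion.
    """
    ev = events.dropna(subset=["cvh_day"])
    clinical = [c for c in criteria if c != trend_criterion]
    per_event_sets: list[frozenset] = []
    merged = flags.merge(ev[["patient_id", "cvh_day"]], on="patient_id")
    in_window = merged[(merged["day_offset"] >= merged["cvh_day"] - horizon)
                       & (merged["day_offset"] <= merged["cvh_day"] - 1)]
    grouped = in_window.groupby("patient_id")
    for _, grp in grouped:
        met = frozenset(c for c in criteria if grp[c].astype(bool).any())
        if met:
            per_event_sets.append(met)
    regions: dict[frozenset, int] = {}
    for s in per_event_sets:
        regions[s] = regions.get(s, 0) + 1
    trend_excl = regions.get(frozenset([trend_criterion]), 0)
    clinical_events = sum(1 for s in per_event_sets if s & set(clinical))
    pct = (percent_increase(trend_excl, clinical_events)
           if clinical_events > 0 else (0.0 if trend_excl == 0 else float("inf")))
    trend_days = flags[trend_criterion].astype(bool)
    other_days = np.zeros(len(flags), dtype=bool)
    for c in clinical:
        other_days |= flags[c].astype(bool).to_numpy()
    return YieldReport(
        regions=regions,
        total_captured=len(per_event_sets),
        trend_exclusive_events=trend_excl,
        clinical_events=clinical_events,
        percent_increase=pct,
        trend_days_total=int(trend_days.sum()),
        trend_days_exclusive=int((trend_days.to_numpy() & ~other_days).sum()))


# ---------------------------------------------------------------------------
# time-in-AT/AF distributions
# ---------------------------------------------------------------------------

def time_in_af_distribution(flags: pd.DataFrame, cohort: Sequence[PatientTimeline],
                            criteria: Sequence[str],
                            phenotypes: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Quartiles of daily AT/AF hours over each criterion's days.

    Adds the fraction of criterion-days belonging to persistent-phenotype
    patients; phenotypes are classified from the records when not supplied.
    """
    from .timeline import classify_af_phenotype
    if phenotypes is None:
        phenotypes = {}
        for tl in cohort:
            try:
                phenotypes[tl.patient_id] = classify_af_phenotype(tl)
            except ValueError:
                phenotypes[tl.patient_id] = "paroxysmal"
    burden = pd.concat(
        [tl.records[["patient_id", "day_offset", "af_burden_min"]] for tl in cohort],
        ignore_index=True)
    table = flags.merge(burden, on=["patient_id", "day_offset"], how="left")
    rows = []
    for c in criteria:
        sel = table[table[c].astype(bool)]
        if sel.empty:
            rows.append({"criterion": c, "n_days": 0, "median_h": np.nan,
                         "q25_h": np.nan, "q75_h": np.nan, "persistent_day_frac": np.nan})
            continue
        hours = sel["af_burden_min"].to_numpy() / 60.0
        pers = sel["patient_id"].map(phenotypes).eq("persistent")
        rows.append({
            "criterion": c, "n_days": len(sel),
            "median_h": float(np.median(hours)),
            "q25_h": float(np.percentile(hours, 25)),
            "q75_h": float(np.percentile(hours, 75)),
            "persistent_day_frac": float(pers.mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full holdout report
# ---------------------------------------------------------------------------

def evaluate_holdout(cohort: Sequence[PatientTimeline],
                     trend_config: TrendConfig | None = None,
                     horizon: int = 5,
                     phenotypes: Mapping[str, str] | None = None) -> dict:
    """Full validation report on a (holdout) cohort with frozen thresholds.

    Includes state rate ratios versus A, clinical-criterion rate ratios and
    intersections, AUROC with and without the trend criterion, Venn event
    yield, equal-proportion tests, time-in-AT/AF distributions, and follow-up
    totals cross-checkable against :func:`timeline.follow_up_summary`.
    """
    tcfg = (trend_config or TrendConfig()).validate()
    flags = trends.flag_cohort(cohort, tcfg)
    events = event_table(cohort)
    report: dict = {"follow_up": follow_up_summary(cohort)}
    if flags.empty or events["cvh_day"].notna().sum() == 0:
        report["degenerate"] = True
        report["reason"] = "no classifiable days or no events"
        return report
    report["degenerate"] = False

    flags = flags.copy()
    flags["trend_d"] = (flags["trend_state"] == "D").to_numpy()
    criteria2 = ["duration_met", "quantity_met"]
    criteria3 = criteria2 + ["trend_d"]

    # trend-state rate ratios (last-record-day attribution)
    try:
        rrs = state_rate_ratios(flags, events)
        report["state_counts"] = state_counts(flags, events).to_dict()
        report["state_rate_ratios"] = {k: vars(v) for k, v in rrs.items()}
    except DegenerateDataError as exc:
        report["state_rate_ratios"] = {"error": str(exc)}

    # clinical criteria and intersections (pre-event-window attribution)
    counts: dict[str, tuple[int, int]] = {}
    for c in criteria3:
        counts[c] = criterion_counts(flags, c, events, horizon)
    inter = (flags["duration_met"].astype(bool) & flags["quantity_met"].astype(bool)
             & flags["trend_d"])
    flags["all_three"] = inter.to_numpy()
    counts["all_three"] = criterion_counts(flags, "all_three", events, horizon)
    report["criterion_counts"] = {k: {"events": v[0], "days": v[1]}
                                  for k, v in counts.items()}
    a_days = int((flags["trend_state"] == "A").sum())
    sc = state_counts(flags, events)
    a_events = int(sc.loc["A", "events"])
    report["criterion_rate_ratios"] = {}
    for k, (e, d) in counts.items():
        if d > 0 and a_events > 0:
            report["criterion_rate_ratios"][k] = vars(rate_ratio(e, d, a_events, a_days))

    # AUROC: 2-criterion versus 3-criterion day score
    labels = np.zeros(len(flags), dtype=bool)
    merged = flags.merge(events.dropna(subset=["cvh_day"])[["patient_id", "cvh_day"]],
                         on="patient_id", how="left")
    labels = ((merged["day_offset"] >= merged["cvh_day"] - horizon)
              & (merged["day_offset"] <= merged["cvh_day"] - 1)).fillna(False).to_numpy()
    try:
        auc2, ci2 = day_level_auroc(criteria_score(flags, criteria2), labels)
        auc3, ci3 = day_level_auroc(criteria_score(flags, criteria3), labels)
        report["auroc"] = {
            "clinical": {"auc": auc2, "ci": ci2},
            "with_trend": {"auc": auc3, "ci": ci3},
            "absolute_increase": auc3 - auc2,
            "relative_increase_pct": 100.0 * (auc3 - auc2) / auc2,
        }
    except DegenerateDataError as exc:
        report["auroc"] = {"error": str(exc)}

    report["yield"] = venn_event_yield(flags, events, criteria3, "trend_d", horizon)
    report["time_in_af"] = time_in_af_distribution(flags, cohort, criteria3, phenotypes)
    try:
        report["poisson_comparison"] = poisson_rate_comparison(
            {k: counts[k] for k in criteria3})
    except (DegenerateDataError, ValueError) as exc:
        report["poisson_comparison"] = {"error": str(exc)}

    # equal-proportion test: fraction of pre-event windows captured,
    # trend criterion versus the two clinical criteria pooled
    n_events = int(events["cvh_day"].notna().sum())
    x_trend = counts["trend_d"][0]
    x_clin = max(counts["duration_met"][0], counts["quantity_met"][0])
    z, p = two_proportion_test(x_trend, n_events, x_clin, n_events)
    report["proportion_test"] = {"z": z, "p": p}
    return report
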