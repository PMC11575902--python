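"""Day-level risk-rule mining from moving-average trend features.

Reproduces the derivation of the high-risk trend: every diagnostic parameter
is expanded into its CMA, its SMA over each clinical window, and all pairwise
binary trend indicators (shorter-window average at/above longer-window
average).  CART trees are trained on bootstrap 70%/30% learning/test patient
partitions to classify the 5 days preceding a CVH; root-to-leaf paths to
positive-majority leaves become candidate rules, which are scored by CVH
incidence rate (versus trend-A days) and patient percentage, and finally
matched against the prespecified duration and quantity comparators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .config import DiscoveryConfig, TrendConfig
from .timeline import PatientTimeline
from . import trends
from .evaluation import attribute_events, event_table

log = logging.getLogger(__name__)

INF = math.inf


# ---------------------------------------------------------------------------
# labels and splits
# ---------------------------------------------------------------------------

def label_risk_days(cohort: Sequence[PatientTimeline], horizon: int = 5) -> pd.DataFrame:
    """Label each post-index patient-day; true within ``horizon`` days before CVH.

    Censored patients contribute only negative days.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rows = []
    for tl in cohort:
        days = tl.values("day_offset").astype(int)
        days = days[days >= tl.index_day]
        lab = np.zeros(len(days), dtype=bool)
        if tl.cvh_day is not None:
            lab = (days >= tl.cvh_day - horizon) & (days <= tl.cvh_day - 1)
        rows.append(pd.DataFrame({"patient_id": tl.patient_id,
                                  "day_offset": days, "label": lab}))
    if not rows:
        return pd.DataFrame(columns=["patient_id", "day_offset", "label"])
    return pd.concat(rows, ignore_index=True)


def split_patients(cohort: Sequence[PatientTimeline], train_fraction: float = 0.7,
                   seed: int = 0) -> tuple[list[PatientTimeline], list[PatientTimeline]]:
    """Patient-level train/holdout split; no patient appears in both."""
    if len(cohort) < 2:
        raise ValueError("need >= 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    n_train = int(round(train_fraction * len(cohort)))
    train = [cohort[i] for i in sorted(order[:n_train])]
    holdout = [cohort[i] for i in sorted(order[n_train:])]
    if not holdout:
        log.warning("train_fraction=%s leaves an empty holdout", train_fraction)
    return train, holdout


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def feature_names(trend_config: TrendConfig | None = None) -> list[str]:
    tcfg = trend_config or TrendConfig()
    names: list[str] = []
    for param in trends.TREND_PARAMETERS:
        names.append(f"{param}_cma")
        for p in tcfg.sma_windows:
            names.append(f"{param}_sma{p}")
        wins = list(tcfg.sma_windows)
        for i, p in enumerate(wins):
            for q in wins[i + 1:]:
                names.append(f"{param}_sma{p}_ge_sma{q}")
            names.append(f"{param}_sma{p}_ge_cma")
    return names


def build_features(cohort: Sequence[PatientTimeline],
                   trend_config: TrendConfig | None = None) -> pd.DataFrame:
    """Per-day feature table: moving averages plus binary trend indicators.

    Each parameter contributes C(8,2) = 28 indicators over its 7 SMAs and CMA
    (1 where the shorter-window average is at/above the longer one), and the
    8 continuous averages themselves.  Includes the day's trend state for
    reference-day accounting.
    """
    tcfg = (trend_config or TrendConfig()).validate()
    wins = list(tcfg.sma_windows)
    frames = []
    for tl in cohort:
        if tl.n_days < tl.index_day:
            continue
        days = tl.values("day_offset").astype(int)
        keep = days >= tl.index_day
        cols: dict[str, np.ndarray] = {
            "patient_id": np.repeat(tl.patient_id, int(keep.sum())),
            "day_offset": days[keep],
        }
        burden_cma = burden_sma_long = act_cma = None
        for param in trends.TREND_PARAMETERS:
            x = tl.values(param)
            cma = trends.cma_series(x)[keep]
            smas = {p: trends.sma_series(x, p)[keep] for p in wins}
            cols[f"{param}_cma"] = cma.astype(np.float32)
            for p in wins:
                cols[f"{param}_sma{p}"] = smas[p].astype(np.float32)
            for i, p in enumerate(wins):
                for q in wins[i + 1:]:
                    cols[f"{param}_sma{p}_ge_sma{q}"] = (smas[p] >= smas[q]).astype(np.int8)
                cols[f"{param}_sma{p}_ge_cma"] = (smas[p] >= cma).astype(np.int8)
            if param == "af_burden_min":
                burden_cma, burden_sma_long = cma, smas[max(wins)]
            if param == "activity_min":
                act_cma = cma
        cols["trend_state"] = trends.classify_states(
            burden_cma, burden_sma_long, act_cma, tcfg)
        frames.append(pd.DataFrame(cols))
    if not frames:
        return pd.DataFrame(columns=["patient_id", "day_offset", "trend_state"]
                            + feature_names(tcfg))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# bootstrap forest
# ---------------------------------------------------------------------------

@dataclass
class BootstrapForest:
    trees: list
    in_patients: list[set]
    feature_names: list[str]
    n_replicates: int


def train_bootstrap_forest(features: pd.DataFrame, labels: np.ndarray,
                           n_replicates: int | None = None, seed: int = 0,
                           config: DiscoveryConfig | None = None) -> BootstrapForest:
    """Train one CART tree per bootstrap 70% learning partition of patients."""
    cfg = (config or DiscoveryConfig()).validate()
    n_replicates = n_replicates or cfg.n_replicates
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("labels are single-class; cannot train")
    names = feature_names_from(features)
    X = features[names].to_numpy(dtype=np.float32)
    pids = features["patient_id"].to_numpy()
    unique_pids = np.unique(pids)
    rng = np.random.default_rng(seed)
    trees, in_sets = [], []
    for r in range(n_replicates):
        n_in = max(1, int(round(cfg.bootstrap_fraction * len(unique_pids))))
        chosen = set(rng.choice(unique_pids, size=n_in, replace=False))
        mask = np.isin(pids, list(chosen))
        y = labels[mask]
        if y.all() or not y.any():
            continue  # degenerate partition; skip replicate
        tree = DecisionTreeClassifier(
            max_depth=cfg.max_depth,
            min_samples_leaf=cfg.min_leaf_days,
            class_weight="balanced" if cfg.balance_classes else None,
            random_state=int(rng.integers(0, 2 ** 31 - 1)),
        )
        tree.fit(X[mask], y)
        trees.append(tree)
        in_sets.append(chosen)
    if not trees:
        raise ValueError("no replicate had both classes in its learning partition")
    return BootstrapForest(trees, in_sets, names, n_replicates)


def feature_names_from(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns
            if c not in ("patient_id", "day_offset", "trend_state", "label")]


# ---------------------------------------------------------------------------
# rule extraction
# ---------------------------------------------------------------------------

@dataclass
class RuleCandidate:
    """A conjunction of interval conditions on feature columns."""

    intervals: dict[str, tuple[float, float]]  # col -> (low, high]: low < x <= high
    selection_frequency: float = 0.0
    n_trees: int = 0
    log_rr: float = float("nan")
    patient_pct: float = float("nan")
    day_pct: float = float("nan")
    excluded: bool = False

    @property
    def conditions(self) -> tuple[tuple[str, str, float], ...]:
        out = []
        for col in sorted(self.intervals):
            low, high = self.intervals[col]
            if low > -INF:
                out.append((col, ">", low))
            if high < INF:
                out.append((col, "<=", high))
        return tuple(out)

    def contains_column(self, col: str) -> bool:
        return col in self.intervals

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(table), dtype=bool)
        for col, (low, high) in self.intervals.items():
            x = table[col].to_numpy(dtype=float)
            if low > -INF:
                m &= x > low
            if high < INF:
                m &= x <= high
        return m

    def describe(self) -> str:
        return " AND ".join(f"{c} {op} {thr:g}" for c, op, thr in self.conditions)


def extract_tree_rules(tree, names: Sequence[str]) -> list[tuple[dict, int]]:
    """Root-to-leaf conjunctions for positive-majority leaves.

    Returns (intervals, leaf day count) per positive leaf; interval bounds
    follow the CART convention ``x <= threshold`` on the left branch.
    """
    t = tree.tree_
    out: list[tuple[dict, int]] = []

    def walk(node: int, bounds: dict[str, tuple[float, float]]) -> None:
        if t.children_left[node] == -1:  # leaf
            value = np.asarray(t.value[node]).ravel()
            if len(value) == 2 and value[1] > value[0]:
                out.append((dict(bounds), int(t.n_node_samples[node])))
            return
        col = names[t.feature[node]]
        thr = float(t.threshold[node])
        low, high = bounds.get(col, (-INF, INF))
        walk(t.children_left[node], {**bounds, col: (low, min(high, thr))})
        walk(t.children_right[node], {**bounds, col: (max(low, thr), high)})

    walk(0, {})
    return out


def _merge_thresholds(rules_per_tree: list[list[dict]], rel_tol: float) -> None:
    """Snap numerically adjacent split thresholds to a common representative.

    Mutates the interval dicts in place so that rules differing only by
    sub-tolerance threshold noise share a canonical form across replicates.
    """
    by_col: dict[str, list[float]] = {}
    for tree_rules in rules_per_tree:
        for iv in tree_rules:
            for col, (low, high) in iv.items():
                for v in (low, high):
                    if math.isfinite(v):
                        by_col.setdefault(col, []).append(v)
    snap: dict[str, list[tuple[float, float]]] = {}
    for col, vals in by_col.items():
        vals = sorted(set(vals))
        clusters: list[list[float]] = [[vals[0]]]
        for v in vals[1:]:
            ref = clusters[-1][0]
            tol = rel_tol * max(abs(ref), 1e-12)
            if abs(v - ref) <= tol:
                clusters[-1].append(v)
            else:
                clusters.append([v])
        snap[col] = [(c[0], float(np.mean(c))) for c in clusters]
    def snap_value(col: str, v: float) -> float:
        if not math.isfinite(v):
            return v
        best = min(snap[col], key=lambda cr: abs(cr[1] - v))
        return best[1]
    for tree_rules in rules_per_tree:
        for iv in tree_rules:
            for col in list(iv):
                low, high = iv[col]
                iv[col] = (snap_value(col, low), snap_value(col, high))


def extract_rules(forest: BootstrapForest,
                  config: DiscoveryConfig | None = None) -> list[RuleCandidate]:
    """Merge positive-leaf conjunctions across replicates into candidates.

    ``selection_frequency`` is the fraction of replicates whose tree contains
    the (canonicalized) rule at least once.
    """
    cfg = config or DiscoveryConfig()
    per_tree = [[iv for iv, _ in extract_tree_rules(tree, forest.feature_names)]
                for tree in forest.trees]
    _merge_thresholds(per_tree, cfg.merge_rel_tol)
    counts: dict[tuple, dict] = {}
    for tree_rules in per_tree:
        seen: set[tuple] = set()
        for iv in tree_rules:
            key = tuple(sorted((c, round(l, 9), round(h, 9)) for c, (l, h) in iv.items()))
            if key not in counts:
                counts[key] = {"intervals": iv, "trees": 0}
            if key not in seen:
                counts[key]["trees"] += 1
                seen.add(key)
    n = len(forest.trees)
    rules = [RuleCandidate(intervals=v["intervals"],
                           selection_frequency=v["trees"] / n,
                           n_trees=v["trees"])
             for v in counts.values()]
    rules.sort(key=lambda r: (-r.selection_frequency, r.describe()))
    return rules


# ---------------------------------------------------------------------------
# scoring and comparator matching
# ---------------------------------------------------------------------------

def score_rules(rules: Sequence[RuleCandidate], features: pd.DataFrame,
                events: pd.DataFrame, horizon: int = 5) -> list[RuleCandidate]:
    """Attach log incidence-rate ratio (vs trend-A days) and patient percent.

    An event counts for a rule when any of its ``horizon`` pre-event days
    satisfies the rule.  Rules matching no days are dropped; rules whose
    reference has zero events are flagged ``excluded``.
    """
    n_patients = features["patient_id"].nunique()
    a_mask = (features["trend_state"] == "A").to_numpy()
    a_days = int(a_mask.sum())
    ref_flags = features[["patient_id", "day_offset"]].copy()
    ref_flags["flag"] = a_mask
    a_events = attribute_events(ref_flags, "flag", events, horizon)
    scored = []
    for rule in rules:
        m = rule.mask(features)
        n_days = int(m.sum())
        if n_days == 0:
            continue
        flags = features[["patient_id", "day_offset"]].copy()
        flags["flag"] = m
        ev = attribute_events(flags, "flag", events, horizon)
        pct = features.loc[m, "patient_id"].nunique() / n_patients
        day_pct = n_days / len(features)
        if a_events == 0 or a_days == 0:
            scored.append(dc_replace(rule, log_rr=float("inf"), patient_pct=pct,
                                     day_pct=day_pct, excluded=True))
            continue
        rate = ev / n_days
        ref_rate = a_events / a_days
        log_rr = math.log(rate / ref_rate) if rate > 0 else -math.inf
        scored.append(dc_replace(rule, log_rr=log_rr, patient_pct=pct, day_pct=day_pct))
    return scored


def comparator_statistics(features: pd.DataFrame, cohort: Sequence[PatientTimeline],
                          events: pd.DataFrame, trend_config: TrendConfig | None = None,
                          horizon: int = 5) -> dict[str, dict]:
    """Log RR and patient percent for the duration and quantity thresholds.

    Computed on the same day table and reference (trend-A days) as the mined
    rules so the comparator match is apples-to-apples.
    """
    tcfg = (trend_config or TrendConfig()).validate()
    daily = pd.concat(
        [tl.records[["patient_id", "day_offset", "af_burden_min", "max_continuous_af_min"]]
         for tl in cohort], ignore_index=True)
    table = features[["patient_id", "day_offset", "trend_state"]].merge(
        daily, on=["patient_id", "day_offset"], how="left")
    table["duration"] = trends.duration_threshold_met(
        table["max_continuous_af_min"].to_numpy(), tcfg)
    table["quantity"] = trends.quantity_threshold_met(
        table["af_burden_min"].to_numpy(), tcfg)
    a_days = int((table["trend_state"] == "A").sum())
    ref_flags = table[["patient_id", "day_offset"]].copy()
    ref_flags["flag"] = (table["trend_state"] == "A").to_numpy()
    a_events = attribute_events(ref_flags, "flag", events, horizon)
    n_patients = table["patient_id"].nunique()
    out = {}
    for name in ("duration", "quantity"):
        n_days = int(table[name].sum())
        ev = attribute_events(table.rename(columns={name: "flag"}), "flag", events, horizon)
        log_rr = float("nan")
        if n_days and a_events and ev:
            log_rr = math.log((ev / n_days) / (a_events / a_days))
        out[name] = {
            "log_rr": log_rr,
            "patient_pct": table.loc[table[name], "patient_id"].nunique() / n_patients,
            "events": ev, "days": n_days,
        }
    return out


def match_to_comparators(rules: Sequence[RuleCandidate],
                         comparator_stats: Mapping[str, Mapping[str, float]]
                         ) -> RuleCandidate | None:
    """Select the top-frequency rule beating the comparator floors.

    The floors come from the comparator with the largest patient percentage
    (in practice the quantity threshold); both inequalities
    are strict.  Returns None when no rule qualifies.
    """
    if not comparator_stats:
        raise ValueError("comparator_stats must not be empty")
    floor = max(comparator_stats.values(), key=lambda s: s["patient_pct"])
    floor_rr, floor_pct = floor["log_rr"], floor["patient_pct"]
    for rule in sorted(rules, key=lambda r: (-r.selection_frequency,
                                             -(r.log_rr if math.isfinite(r.log_rr) else -INF))):
        if rule.excluded or not math.isfinite(rule.log_rr):
            continue
        if rule.log_rr > floor_rr and rule.patient_pct > floor_pct:
            return rule
    return None


def rule_to_trend_config(rule: RuleCandidate,
                         base: TrendConfig | None = None) -> TrendConfig:
    """Freeze a D-shaped matched rule into trend thresholds for validation.

    Reads the burden-CMA lower bound and activity-CMA upper bound from the
    rule when present; other thresholds keep their base values.
    """
    base = base or TrendConfig()
    kwargs = {}
    iv = rule.intervals.get("af_burden_min_cma")
    if iv and iv[0] > -INF:
        kwargs["trend_d_burden_cma_min"] = float(iv[0])
    iv = rule.intervals.get("activity_min_cma")
    if iv and iv[1] < INF:
        kwargs["trend_d_activity_cma_max"] = float(iv[1])
    return dc_replace(base, **kwargs)


def rules_to_text(rules: Sequence[RuleCandidate]) -> str:
    """One rule per line: frequency, log RR, patient pct, conjunction."""
    lines = ["# selection_frequency\tlog_rr\tpatient_pct\trule"]
    for r in rules:
        lines.append(f"{r.selection_frequency:.4f}\t{r.log_rr:.4f}\t"
                     f"{r.patient_pct:.4f}\t{r.describe()}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def mine_rules(train_cohort: Sequence[PatientTimeline],
               trend_config: TrendConfig | None = None,
               config: DiscoveryConfig | None = None,
               seed: int = 0) -> dict:
    """Full discovery pass on a training cohort.

    Returns the scored rules, comparator statistics, and the matched rule
    (None when nothing beats the floors).
    """
    cfg = (config or DiscoveryConfig()).validate()
    tcfg = (trend_config or TrendConfig()).validate()
    features = build_features(train_cohort, tcfg)
    labels_df = label_risk_days(train_cohort, cfg.horizon_days)
    merged = features[["patient_id", "day_offset"]].merge(
        labels_df, on=["patient_id", "day_offset"], how="left")
    labels = merged["label"].fillna(False).to_numpy(dtype=bool)
    events = event_table(train_cohort)
    forest = train_bootstrap_forest(features, labels, cfg.n_replicates, seed, cfg)
    rules = score_rules(extract_rules(forest, cfg), features, events, cfg.horizon_days)
    comparators = comparator_statistics(features, train_cohort, events, tcfg, cfg.horizon_days)
    matched = match_to_comparators(rules, comparators)
    return {"features": features, "forest": forest, "rules": rules,
            "comparators": comparators, "matched": matched}
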