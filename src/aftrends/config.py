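"""Configuration objects for the simulator, the trend engine, rule discovery
and the end-to-end pipeline.

All knobs that the analysis depends on live here so that a run is fully
described by one :class:`PipelineConfig`, which can be round-tripped through
YAML and hashed for provenance stamping.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

#: minutes in a day; the natural ceiling for any daily-minutes quantity
DAY_MINUTES = 1440.0

#: 23.5 hours in minutes — the device definition of a "persistent" AF day
PERSISTENT_DAY_MIN = 1410.0

#: days after implant used to initialize the moving-average history
INDEX_LAG_DAYS = 21

TREND_STATES = ("A", "B", "C", "D")


class ConfigError(ValueError):
    """Raised when a configuration field violates its documented domain."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimulationConfig:
    """Generator settings for a synthetic ICM cohort.

    The defaults emulate a claims-linked ICM cohort of mixed paroxysmal/
    persistent AF patients monitored for up to two years: 6% persistent phenotype, a
    2-minute device detection floor, sporadic follow-up gaps, a subcohort with
    declining daily activity, and per-day CVH hazard multiplied by the current
    AF-burden trend state.
    """

    n_patients: int = 500
    max_follow_up_days: int = 730
    phenotype_mix: float = 0.06          # fraction persistent
    episode_rate: float = 0.7            # per-day P(>=1 AF episode), paroxysmal
    episode_duration_log_mean: float = 2.6     # ln minutes (~13 min population median)
    episode_duration_log_sd: float = 0.12      # within-patient spread (characteristic duration)
    episode_scale_log_sd: float = 1.2          # between-patient duration scale (cohort skew)
    extra_episode_mean: float = 0.1      # Poisson mean of additional episodes on an episode day
    propensity_rho: float = 0.97         # AR(1) day-to-day correlation of episode propensity
    propensity_sd: float = 0.35          # stationary sd of the log propensity
    activity_mean_min: float = 70.0      # population mean daily activity
    activity_sd_min: float = 20.0        # within-patient day-to-day sd
    activity_between_sd_min: float = 30.0  # between-patient sd of the mean
    activity_decline_fraction: float = 0.5
    activity_decline_min_per_day: float = 0.35   # magnitude of the linear decline
    baseline_hazard: float = 2e-3        # per-day CVH probability on state-A days
    state_multipliers: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 4.49, "C": 8.41, "D": 11.15}
    )
    gap_probability: float = 0.00025     # per-day P(a follow-up gap starts)
    gap_length_mean: float = 7.4         # mean gap length, days
    detection_floor_min: float = 2.0     # device AT/AF detection threshold
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        _check(self.n_patients >= 0, "n_patients must be >= 0")
        _check(self.max_follow_up_days >= 1, "max_follow_up_days must be >= 1")
        for name in ("phenotype_mix", "episode_rate", "gap_probability"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0, 1], got {v}")
        _check(0.0 <= self.baseline_hazard <= 1.0, "baseline_hazard must be in [0, 1]")
        _check(set(self.state_multipliers) == set(TREND_STATES),
               f"state_multipliers must have keys {TREND_STATES}")
        for k, m in self.state_multipliers.items():
            _check(m > 0, f"state_multipliers[{k}] must be > 0")
        _check(self.state_multipliers["A"] == 1.0, "state_multipliers['A'] is fixed at 1")
        worst = self.baseline_hazard * max(self.state_multipliers.values())
        _check(worst <= 1.0,
               f"baseline_hazard x max multiplier = {worst:.3g} exceeds 1")
        _check(self.gap_length_mean >= 1.0, "gap_length_mean must be >= 1 day")
        _check(self.detection_floor_min >= 0, "detection_floor_min must be >= 0")
        _check(0.0 <= self.activity_decline_fraction <= 1.0,
               "activity_decline_fraction must be in [0, 1]")
        _check(abs(self.propensity_rho) < 1.0, "propensity_rho must be in (-1, 1)")
        return self


@dataclass
class TrendConfig:
    """Thresholds and windows for moving-average trend classification.

    ``sinus_cma_threshold`` encodes the "<1% of the day" definition of the
    sinus-rhythm state A (1% of 1440 min = 14.4 min/day).  The two Trend-D
    refinements (historical burden above 8.5 min/day, historical activity
    below 87 min/day) are the machine-learned values frozen for validation.
    """

    sma_windows: tuple[int, ...] = (1, 2, 3, 5, 8, 13, 21)
    sinus_cma_threshold: float = 14.4    # min/day; 1% of a 1440-min day
    trend_d_burden_cma_min: float = 8.5  # min/day
    trend_d_activity_cma_max: float = 87.0  # min/day
    duration_threshold_min: float = 60.0    # continuous AF >= 1 h
    quantity_threshold_min: float = 72.0    # total AT/AF >= 5% of the day

    def validate(self) -> "TrendConfig":
        w = tuple(self.sma_windows)
        _check(len(w) >= 1 and all(x >= 1 for x in w), "windows must be positive")
        _check(all(a < b for a, b in zip(w, w[1:])), "windows must be strictly increasing")
        for name in ("sinus_cma_threshold", "trend_d_burden_cma_min",
                     "trend_d_activity_cma_max", "duration_threshold_min",
                     "quantity_threshold_min"):
            _check(getattr(self, name) > 0, f"{name} must be > 0")
        return self

    @property
    def max_window(self) -> int:
        return max(self.sma_windows)


@dataclass
class DiscoveryConfig:
    """Settings for bootstrap rule mining on trend features."""

    horizon_days: int = 5            # pre-event window labelled "at risk"
    train_fraction: float = 0.7      # patient-level train/holdout split
    n_replicates: int = 200          # bootstrap trees
    bootstrap_fraction: float = 0.7  # per-replicate learning partition
    max_depth: int = 4
    min_leaf_days: int = 50
    balance_classes: bool = True     # weight positives inversely to prevalence
    merge_rel_tol: float = 0.01      # threshold clustering for rule dedup

    def validate(self) -> "DiscoveryConfig":
        _check(self.horizon_days >= 1, "horizon_days must be >= 1")
        _check(0.0 < self.train_fraction <= 1.0, "train_fraction must be in (0, 1]")
        _check(0.0 < self.bootstrap_fraction < 1.0, "bootstrap_fraction must be in (0, 1)")
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(self.max_depth >= 1, "max_depth must be >= 1")
        _check(self.min_leaf_days >= 1, "min_leaf_days must be >= 1")
        return self


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, plus the global seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    trends: TrendConfig = field(default_factory=TrendConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        self.simulation.validate()
        self.trends.validate()
        self.discovery.validate()
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trends"]["sma_windows"] = list(self.trends.sma_windows)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = SimulationConfig(**d.get("simulation", {}))
        tr = d.get("trends", {})
        if "sma_windows" in tr:
            tr = {**tr, "sma_windows": tuple(tr["sma_windows"])}
        cfg = cls(
            simulation=sim,
            trends=TrendConfig(**tr),
            discovery=DiscoveryConfig(**d.get("discovery", {})),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )
        return cfg.validate()

    def config_hash(self) -> str:
        """Short stable digest used to stamp artifacts."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_pipeline_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def with_overrides(cfg: PipelineConfig, **kwargs) -> PipelineConfig:
    """Return a copy of ``cfg`` with top-level fields replaced."""
    return replace(cfg, **kwargs)
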