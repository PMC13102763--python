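"""Configuration objects shared across the pipeline stages.

All tunable knobs live in small dataclasses so that a single YAML file can
describe a full run and be echoed verbatim into the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

#: Vital-sign channels modeled by the trajectory stage, in canonical order.
CHANNELS: tuple[str, ...] = ("HR", "RR", "SBP", "DBP", "MAP", "SpO2")

#: Blood gas parameters examined in the high-risk subgroup, in canonical order.
GAS_PARAMETERS: tuple[str, ...] = (
    "pH",
    "PO2",
    "PCO2",
    "lactate",
    "base_excess",
    "total_co2",
)

#: Units for reporting safe zones.
GAS_UNITS: Mapping[str, str] = {
    "pH": "",
    "PO2": "mmHg",
    "PCO2": "mmHg",
    "lactate": "mmol/L",
    "base_excess": "mEq/L",
    "total_co2": "mEq/L",
}


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class GasParam:
    """Marginal distribution and latent risk geometry of one blood gas parameter.

    The subject-level value is drawn from a normal truncated to
    ``[trunc_lo, trunc_hi]``.  Excess ICU-mortality log-odds are zero inside
    the risk-minimizing interval ``[safe_lo, safe_hi]`` and grow linearly
    with the distance outside it, measured in SD units, at rate ``slope``.
    """

    mean: float
    sd: float
    safe_lo: float
    safe_hi: float
    slope: float
    trunc_lo: float = -np.inf
    trunc_hi: float = np.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigurationError(f"gas SD must be > 0, got {self.sd}")
        if not self.safe_lo < self.safe_hi:
            raise ConfigurationError(
                f"gas risk interval requires lo < hi, got [{self.safe_lo}, {self.safe_hi}]"
            )

    def excess_risk(self, x: np.ndarray) -> np.ndarray:
        """Piecewise-linear excess log-odds of ICU death as a function of x."""
        x = np.asarray(x, dtype=float)
        below = np.clip(self.safe_lo - x, 0.0, None)
        above = np.clip(x - self.safe_hi, 0.0, None)
        return self.slope * (below + above) / self.sd


@dataclass(frozen=True)
class PlausibilityRanges:
    """Inclusive physiological plausibility bounds per vital-sign channel."""

    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "HR": (20.0, 250.0),
            "RR": (4.0, 60.0),
            "SBP": (40.0, 300.0),
            "DBP": (20.0, 200.0),
            "MAP": (30.0, 250.0),
            "SpO2": (50.0, 100.0),
        }
    )

    def __post_init__(self) -> None:
        for ch, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ConfigurationError(f"range for {ch} requires lower < upper")

    def bounds(self, channel: str) -> tuple[float, float]:
        try:
            return self.ranges[channel]
        except KeyError:
            raise ConfigurationError(f"no plausibility range for channel {channel!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic cohort.

    ``traj_coeffs`` has shape (K, n_channels, 4): polynomial coefficients
    (intercept, linear, quadratic, cubic) of the group-mean trajectory in
    native channel units over raw hours 0..11.  ``noise_sd`` has shape
    (K, n_channels).
    """

    n_subjects: int
    mixing: tuple[float, ...]
    traj_coeffs: np.ndarray
    noise_sd: np.ndarray
    missing_rate: float = 0.03
    long_gap_rate: float = 0.04
    outlier_rate: float = 0.003
    obs_per_hour: tuple[int, int] = (2, 4)
    hazard_scale: float = 3000.0
    hazard_shape: float = 0.23
    group_loghr: tuple[float, ...] = (0.0, float(np.log(1.5)), 0.0)
    censor_rate: float = 0.05
    admin_horizon_days: float = 365.0
    icu_logit_base: float = -4.0
    group_logor: tuple[float, ...] = (0.0, 1.1, 0.0)
    gas_params: Mapping[str, GasParam] = field(default_factory=dict)
    plausibility: PlausibilityRanges = field(default_factory=PlausibilityRanges)
    seed: int = 0

    def __post_init__(self) -> None:
        mixing = np.asarray(self.mixing, dtype=float)
        if abs(mixing.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"mixing must sum to 1 within 1e-12, got sum {mixing.sum()!r}"
            )
        if np.any(mixing < 0):
            raise ConfigurationError("mixing proportions must be non-negative")
        coeffs = np.asarray(self.traj_coeffs, dtype=float)
        object.__setattr__(self, "traj_coeffs", coeffs)
        object.__setattr__(
            self, "noise_sd", np.asarray(self.noise_sd, dtype=float)
        )
        K = len(mixing)
        if coeffs.shape[0] != K:
            raise ConfigurationError(
                f"traj_coeffs has {coeffs.shape[0]} groups but mixing has {K}"
            )
        if self.noise_sd.shape != coeffs.shape[:2]:
            raise ConfigurationError("noise_sd shape must match traj_coeffs groups/channels")
        if np.any(self.noise_sd <= 0):
            raise ConfigurationError("all residual SDs must be > 0")
        if self.n_subjects < K:
            raise ConfigurationError("n_subjects must be at least the number of groups")
        for rate_name in ("missing_rate", "long_gap_rate", "outlier_rate", "censor_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{rate_name} must lie in [0, 1], got {rate}")
        if len(self.group_loghr) != K or len(self.group_logor) != K:
            raise ConfigurationError("group effect vectors must have one entry per group")

    @property
    def n_groups(self) -> int:
        return len(self.mixing)

    def mean_trajectory(self, group: int, channel: str, hours: np.ndarray) -> np.ndarray:
        """Group-mean value of ``channel`` at (possibly fractional) hours."""
        c = self.traj_coeffs[group, CHANNELS.index(channel)]
        h = np.asarray(hours, dtype=float)
        return c[0] + c[1] * h + c[2] * h**2 + c[3] * h**3


@dataclass
class PipelineConfig:
    """Stage settings for a full trajectory-to-targets run."""

    n_subjects: int = 600
    seed: int = 0
    k_range: tuple[int, int] = (1, 6)
    n_starts: int = 2
    max_iter: int = 300
    tol: float = 1e-6
    backward_eliminate: bool = True
    column_missing_threshold: float = 0.30
    horizons: tuple[str, ...] = ("icu", "28d", "90d", "365d")
    reference_cluster_rule: str = "lowest_icu_mortality"
    rf_n_estimators: tuple[int, ...] = (200, 500)
    rf_min_samples_leaf: tuple[int, ...] = (5, 20)
    rf_max_features: tuple[str, ...] = ("sqrt", "third")
    cv_folds: int = 5
    pd_grid_size: int = 50
    safe_zone_delta: float = 0.2
    bootstrap_samples: int = 200
    rcs_knots: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.column_missing_threshold <= 1.0:
            raise ConfigurationError("column_missing_threshold must lie in (0, 1]")
        lo, hi = self.k_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("k_range must satisfy 1 <= kmin <= kmax")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("k_range", "horizons", "rf_n_estimators", "rf_min_samples_leaf", "rf_max_features"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def default_gas_params() -> dict[str, GasParam]:
    """Blood gas marginals with clinically plausible centers and U-shaped risk.

    The risk-minimizing intervals are the generator's ground truth against
    which safe-zone recovery is judged; slopes are in excess log-odds of ICU
    death per SD of distance outside the interval.
    """
    return {
        "pH": GasParam(7.38, 0.09, 7.30, 7.48, 2.5, trunc_lo=6.8, trunc_hi=7.8),
        "PO2": GasParam(120.0, 60.0, 60.0, 190.0, 2.5, trunc_lo=20.0, trunc_hi=500.0),
        "PCO2": GasParam(40.0, 12.0, 28.0, 54.0, 2.5, trunc_lo=10.0, trunc_hi=120.0),
        "lactate": GasParam(3.0, 2.2, 0.8, 5.2, 2.5, trunc_lo=0.1, trunc_hi=20.0),
        "base_excess": GasParam(-1.0, 6.0, -8.0, 6.5, 2.5, trunc_lo=-25.0, trunc_hi=25.0),
        "total_co2": GasParam(24.0, 5.5, 18.0, 30.5, 2.5, trunc_lo=5.0, trunc_hi=50.0),
    }
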