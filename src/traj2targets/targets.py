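"""Per-parameter random-forest mortality models, partial dependence and
"safe zone" extraction within the high-risk cluster.

One forest is trained per blood gas parameter (features = clinical
covariates + that parameter), tuned by seeded five-fold cross-validation
on AUROC.  Univariate partial dependence PD(x) = mean_i f(x, z_i) over the
cluster's empirical covariate distribution is evaluated on a grid spanning
the within-cluster 1st-99th percentiles, and the safe zone is the maximal
contiguous run of grid points around the PD minimizer whose PD lies within
delta of the bottom of the PD range.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from traj2targets.config import GAS_PARAMETERS, GAS_UNITS

#: Clinical covariates entering every per-parameter forest.
CLINICAL_FEATURES = ("age", "sex", "sofa", "aps_iii", "invasive_vent", "crrt", "rrt")


class TargetsError(ValueError):
    pass


@dataclass
class RiskModelSpec:
    """Forest and tuning-grid settings for one gas-parameter risk model."""

    clinical_features: tuple[str, ...] = CLINICAL_FEATURES
    n_estimators: tuple[int, ...] = (200, 500)
    min_samples_leaf: tuple[int, ...] = (5, 20)
    max_features: tuple[str, ...] = ("sqrt", "third")
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise TargetsError("cv_folds must be >= 2")
        if not (self.n_estimators and self.min_samples_leaf and self.max_features):
            raise TargetsError("tuning grid must be non-empty")

    def grid(self, n_features: int):
        for ne, leaf, mf in itertools.product(
            self.n_estimators, self.min_samples_leaf, self.max_features
        ):
            mf_val = "sqrt" if mf == "sqrt" else max(1, n_features // 3)
            yield {"n_estimators": ne, "min_samples_leaf": leaf, "max_features": mf_val}


@dataclass
class PDProfile:
    """Partial-dependence curve of predicted ICU-death probability."""

    parameter: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise TargetsError("PD grid must be strictly increasing")
        if np.any((self.values < 0) | (self.values > 1)):
            raise TargetsError("PD values must lie in [0, 1]")


@dataclass
class SafeZone:
    """Lowest-predicted-risk interval of one gas parameter."""

    parameter: str
    lo: float
    hi: float
    delta: float
    pd_at_lo: float
    pd_at_hi: float
    pd_min: float
    pd_max: float

    def format(self) -> str:
        unit = GAS_UNITS.get(self.parameter, "")
        sep = " to " if self.lo < 0 else "–"  # avoid "-7.47–23.00"
        body = f"{self.lo:.2f}{sep}{self.hi:.2f}"
        return f"{self.parameter} {body}{' ' + unit if unit else ''}"

    @property
    def width(self) -> float:
        return self.hi - self.lo


def train_rf(
    records: pd.DataFrame, parameter: str, spec: RiskModelSpec | None = None
) -> tuple[RandomForestClassifier, dict]:
    """CV-tuned forest predicting ICU death from covariates + one gas value.

    Fold assignment and tree growth are fully seeded: the same spec and data
    give identical chosen hyperparameters and predictions.
    """
    spec = spec or RiskModelSpec()
    features = list(spec.clinical_features) + [parameter]
    missing = [f for f in features if f not in records.columns]
    if missing:
        raise TargetsError(f"missing feature column(s): {missing}")
    if len(records) < 50:
        raise TargetsError("need at least 50 records to train a risk model")
    y = records["event_icu"].to_numpy(dtype=int)
    if y.sum() < 5:
        raise TargetsError("need at least 5 ICU-death events")
    if len(np.unique(y)) < 2:
        raise TargetsError("single-class outcome; cannot train a classifier")
    X = records[features].to_numpy(dtype=float)

    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(cv.split(X, y))
    rows = []
    for params in spec.grid(len(features)):
        aucs = []
        for tr, te in folds:
            clf = RandomForestClassifier(random_state=spec.seed, **params)
            clf.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
        rows.append({**params, "cv_auc": float(np.mean(aucs))})
    report = pd.DataFrame(rows).sort_values("cv_auc", ascending=False, kind="mergesort")
    best = report.iloc[0][["n_estimators", "min_samples_leaf", "max_features"]].to_dict()
    best["n_estimators"] = int(best["n_estimators"])
    best["min_samples_leaf"] = int(best["min_samples_leaf"])
    if best["max_features"] != "sqrt":
        best["max_features"] = int(best["max_features"])
    model = RandomForestClassifier(random_state=spec.seed, **best)
    model.fit(X, y)
    model.feature_names_ = features  # for PD lookups
    return model, {"cv_table": report.reset_index(drop=True), "best": best,
                   "cv_auc": float(report.iloc[0]["cv_auc"])}


def _pd_eval(model, X: np.ndarray, col: int, grid: np.ndarray) -> np.ndarray:
    n, m = X.shape
    out = np.empty(len(grid))
    block = X.copy()
    for i, x in enumerate(grid):
        block[:, col] = x
        out[i] = model.predict_proba(block)[:, 1].mean()
    return out


def partial_dependence(
    model,
    records: pd.DataFrame,
    parameter: str,
    grid: np.ndarray | None = None,
    grid_size: int = 50,
) -> PDProfile:
    """Univariate PD of the predicted death probability over a value grid.

    The default grid spans the within-sample 1st-99th percentiles to avoid
    zones driven by extrapolation beyond the observed support.
    """
    features = model.feature_names_
    if parameter not in features:
        raise TargetsError(f"{parameter!r} is not a model feature")
    col = features.index(parameter)
    X = records[features].to_numpy(dtype=float)
    if grid is None:
        lo, hi = np.quantile(X[:, col], [0.01, 0.99])
        grid = np.linspace(lo, hi, grid_size)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < X[:, col].min() or grid.max() > X[:, col].max():
            warnings.warn("PD grid extends outside the observed support")
    return PDProfile(parameter=parameter, grid=grid, values=_pd_eval(model, X, col, grid))


def pd_surface(
    model,
    records: pd.DataFrame,
    parameter: str,
    second: str,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
) -> np.ndarray:
    """Bivariate PD matrix PD(x, y); visualization companion to the 1-D PD."""
    features = model.feature_names_
    for f in (parameter, second):
        if f not in features:
            raise TargetsError(f"{f!r} is not a model feature")
    ci, cj = features.index(parameter), features.index(second)
    X = records[features].to_numpy(dtype=float)
    out = np.empty((len(grid_x), len(grid_y)))
    block = X.copy()
    for i, x in enumerate(grid_x):
        block[:, ci] = x
        for j, yv in enumerate(grid_y):
            block[:, cj] = yv
            out[i, j] = model.predict_proba(block)[:, 1].mean()
    return out


def extract_safe_zone(profile: PDProfile, delta: float = 0.2) -> SafeZone:
    """Maximal contiguous low-PD run containing the global PD minimizer.

    Threshold tau = PDmin + delta * (PDmax - PDmin); endpoints are reported
    at grid resolution; minimizer ties break leftmost.  A flat profile
    yields the full grid span with a warning.
    """
    v = profile.values
    if len(v) < 3:
        raise TargetsError("PD profile needs at least 3 grid points")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        warnings.warn("flat PD profile; safe zone spans the whole grid")
        lo_i, hi_i = 0, len(v) - 1
    else:
        tau = vmin + delta * (vmax - vmin)
        imin = int(np.argmin(v))  # leftmost minimizer
        lo_i = imin
        while lo_i > 0 and v[lo_i - 1] <= tau:
            lo_i -= 1
        hi_i = imin
        while hi_i < len(v) - 1 and v[hi_i + 1] <= tau:
            hi_i += 1
    return SafeZone(
        parameter=profile.parameter,
        lo=float(profile.grid[lo_i]),
        hi=float(profile.grid[hi_i]),
        delta=delta,
        pd_at_lo=float(v[lo_i]),
        pd_at_hi=float(v[hi_i]),
        pd_min=vmin,
        pd_max=vmax,
    )


def safe_zone_report(zones: dict[str, SafeZone], n_used: int | None = None) -> pd.DataFrame:
    """One row per parameter: interval, units, delta, PD range, n."""
    rows = [
        {
            "parameter": name,
            "lo": z.lo,
            "hi": z.hi,
            "units": GAS_UNITS.get(name, ""),
            "delta": z.delta,
            "pd_min": z.pd_min,
            "pd_max": z.pd_max,
            "n": n_used if n_used is not None else np.nan,
            "formatted": z.format(),
        }
        for name, z in zones.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["parameter", "lo", "hi", "units", "delta", "pd_min", "pd_max", "n", "formatted"],
    )


def fit_all_targets(
    records: pd.DataFrame,
    spec: RiskModelSpec | None = None,
    parameters=GAS_PARAMETERS,
    delta: float = 0.2,
    grid_size: int = 50,
):
    """Forest + PD + safe zone for each gas parameter; returns
    (profiles, zones, cv_reports) keyed by parameter."""
    profiles, zones, reports = {}, {}, {}
    for name in parameters:
        model, rep = train_rf(records, name, spec)
        prof = partial_dependence(model, records, name, grid_size=grid_size)
        profiles[name] = prof
        zones[name] = extract_safe_zone(prof, delta)
        reports[name] = rep
    return profiles, zones, reports


def jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Jaccard overlap of two closed intervals."""
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 1.0
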