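"""Restricted cubic spline dose-response between blood gas values and ICU
mortality within the high-risk cluster.

The basis follows the Harrell convention: with knots t_1 < ... < t_k the
design holds the linear term x plus k-2 restricted-cubic terms

    term_j(x) = [ (x-t_j)+^3
                  - (x-t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
                  + (x-t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ] / (t_k - t_1)^2

which are zero below the first knot and exactly linear beyond the last, so
the fitted log hazard is linear in both tails.  Nonlinearity is the joint
Wald test that all k-2 restricted-cubic coefficients vanish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from traj2targets.survival import HORIZON_COLS, fit_cox

#: Default knot quantiles per knot count (Harrell's recommendations).
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


class RCSError(ValueError):
    pass


def rcs_basis(x, knots) -> np.ndarray:
    """Design columns [x, term_1(x), ..., term_{k-2}(x)] for given knots."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise RCSError("need at least 3 knots")
    if len(np.unique(knots)) != k:
        raise RCSError("knots must be distinct")
    knots = np.sort(knots)
    norm = (knots[-1] - knots[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        tj, tkm1, tk = knots[j], knots[-2], knots[-1]
        term = (
            np.clip(x - tj, 0, None) ** 3
            - np.clip(x - tkm1, 0, None) ** 3 * (tk - tj) / (tk - tkm1)
            + np.clip(x - tk, 0, None) ** 3 * (tkm1 - tj) / (tk - tkm1)
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def default_knots(x, k: int = 4) -> np.ndarray:
    """Empirical-quantile knots at the documented per-k positions."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(np.unique(x)) < 20:
        raise RCSError("need at least 20 distinct values to place knots")
    if k not in KNOT_QUANTILES:
        raise RCSError(f"supported knot counts: {sorted(KNOT_QUANTILES)}")
    knots = np.quantile(x, KNOT_QUANTILES[k])
    if len(np.unique(knots)) != k:
        raise RCSError("quantile knots collide; data too discrete for this k")
    return knots


@dataclass
class RCSFit:
    """Spline Cox fit with its HR curve and nonlinearity test."""

    parameter: str
    knots: np.ndarray
    coef: np.ndarray  # spline coefficients (linear first)
    cov: np.ndarray  # covariance of the spline block
    chi2_nonlinear: float
    df_nonlinear: int
    p_nonlinear: float
    x_ref: float
    grid: np.ndarray
    hr: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n: int
    events: int

    @property
    def nonlinear(self) -> bool:
        return bool(self.p_nonlinear < 0.05)


def fit_rcs_cox(
    records: pd.DataFrame,
    parameter: str,
    covariates=("age", "sex", "sofa"),
    horizon: str = "icu",
    knots=None,
    k: int = 4,
    x_ref: float | None = None,
    grid_size: int = 100,
) -> RCSFit:
    """Cox model on the spline basis of one gas parameter plus covariates.

    The HR curve is exp(f(x) - f(x_ref)) with x_ref defaulting to the
    within-sample median, so HR(x_ref) = 1 exactly; its pointwise 95% CI is
    by the delta method on the spline coefficient block.
    """
    x = records[parameter].to_numpy(dtype=float)
    knots = np.asarray(knots, dtype=float) if knots is not None else default_knots(x, k)
    basis = rcs_basis(x, knots)
    n_spline = basis.shape[1]
    cond = np.linalg.cond(basis - basis.mean(axis=0))
    if cond > 1e8:
        raise RCSError(
            f"near-singular spline design (cond {cond:.1e}); try fewer knots"
        )
    names = [f"_rcs{j}" for j in range(n_spline)]
    df = records.copy()
    for j, name in enumerate(names):
        df[name] = basis[:, j]
    res = fit_cox(df, horizon, covariates=tuple(names) + tuple(covariates), reference_cluster=None)
    cph = res._fitter
    full_cov = cph.variance_matrix_.loc[names, names].to_numpy()
    coef = cph.params_.loc[names].to_numpy()

    # joint Wald test of the k-2 restricted-cubic terms
    b_nl = coef[1:]
    v_nl = full_cov[1:, 1:]
    stat = float(b_nl @ np.linalg.solve(v_nl, b_nl)) if len(b_nl) else 0.0
    dof = len(b_nl)
    p = float(chi2.sf(stat, dof)) if dof else 1.0

    ref = float(np.median(x)) if x_ref is None else float(x_ref)
    lo_q, hi_q = np.quantile(x, [0.01, 0.99])
    grid = np.linspace(lo_q, hi_q, grid_size)
    contrast = rcs_basis(grid, knots) - rcs_basis(np.full(grid_size, ref), knots)
    log_hr = contrast @ coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, full_cov, contrast))
    return RCSFit(
        parameter=parameter,
        knots=knots,
        coef=coef,
        cov=full_cov,
        chi2_nonlinear=stat,
        df_nonlinear=dof,
        p_nonlinear=p,
        x_ref=ref,
        grid=grid,
        hr=np.exp(log_hr),
        lo=np.exp(log_hr - 1.96 * se),
        hi=np.exp(log_hr + 1.96 * se),
        n=res.n,
        events=res.events,
    )


def nonlinearity_report(fits: dict[str, RCSFit], alpha: float = 0.05) -> pd.DataFrame:
    """One row per parameter: Wald chi-square, df, p, nonlinear flag.

    No multiplicity correction by default, matching per-parameter
    presentation; pass the table through a Bonferroni step downstream if
    desired.
    """
    rows = [
        {
            "parameter": name,
            "chi2": f.chi2_nonlinear,
            "df": f.df_nonlinear,
            "p": f.p_nonlinear,
            "nonlinear": bool(f.p_nonlinear < alpha),
        }
        for name, f in fits.items()
    ]
    return pd.DataFrame(rows, columns=["parameter", "chi2", "df", "p", "nonlinear"])
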