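"""Group-based multi-trajectory modeling by expectation-maximization.

Model: subject i in latent group g has, for channel v and hour t,

    y_ivt | g  ~  Normal( sum_p beta_{g,v,p} * c(t)^p ,  sigma_{g,v}^2 )

conditionally independent across channels and hours given group, with
c(t) = t - 5.5 the centered hour index (numerical conditioning only; curves
are reported on the raw-hour axis).  The observed-data likelihood of a
subject is the mixture  L_i = sum_g pi_g prod_{v,t} phi(y_ivt), maximized
by EM: the E-step computes posteriors w_ig in log space with a log-sum-exp
guard; the M-step solves one weighted least squares per (group, channel)
and updates sigma^2 as the weighted mean squared residual.

Model selection follows the study protocol: fit K = 1..6, require relative
entropy > 0.7 and every modal group share >= 5%, pick the eligible model
with the lowest BIC, then prune polynomial orders per (group, channel) by
backward elimination of non-significant highest-order terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.cluster import KMeans

N_HOURS = 12
TIME_CENTER = 5.5
VAR_FLOOR = 1e-6


class InputError(ValueError):
    pass


class DegenerateComponentError(RuntimeError):
    """A mixture component lost essentially all posterior weight.

    Usually means K is too large for the data; refit with smaller K.
    """


@dataclass
class TrajectoryModelSpec:
    """Settings for one EM fit."""

    K: int
    orders: np.ndarray | int = 3  # scalar or (K, V) in {1, 2, 3}
    n_starts: int = 2
    max_iter: int = 300
    tol: float = 1e-6
    seed: int = 0

    def orders_array(self, n_channels: int) -> np.ndarray:
        o = np.asarray(self.orders)
        if o.ndim == 0:
            o = np.full((self.K, n_channels), int(o))
        if o.shape != (self.K, n_channels):
            raise InputError("orders must be scalar or shaped (K, n_channels)")
        if not np.isin(o, (1, 2, 3)).all():
            raise InputError("polynomial orders must be in {1, 2, 3}")
        if self.tol <= 0:
            raise InputError("tol must be > 0")
        return o.astype(int)


@dataclass
class GBMTMFit:
    """Fitted mixture: mixing proportions, per-(group, channel) polynomial
    coefficients on the centered-hour basis, residual SDs and posteriors."""

    pi: np.ndarray  # (K,)
    beta: list  # beta[g][v] -> coefficients, length order+1
    sigma: np.ndarray  # (K, V)
    W: np.ndarray  # (N, K) posteriors
    loglik: float
    n_params: int
    converged: bool
    trace: np.ndarray
    orders: np.ndarray  # (K, V)
    coef_se: list  # same layout as beta (WLS covariance of final M-step)

    @property
    def K(self) -> int:
        return len(self.pi)

    def group_curve(self, g: int, v: int, hours: np.ndarray) -> np.ndarray:
        """Group-mean curve on the raw-hour axis (standardized units)."""
        c = np.asarray(hours, dtype=float) - TIME_CENTER
        return np.polyval(self.beta[g][v][::-1], c)


@dataclass
class FitDiagnostics:
    """Model-selection record for one fit."""

    bic: float
    aic: float
    entropy: float
    group_sizes: np.ndarray  # modal proportions
    avepp: np.ndarray
    occ: np.ndarray

    def eligible(
        self, entropy_min: float = 0.7, share_min: float = 0.05
    ) -> bool:
        return bool(self.entropy > entropy_min and self.group_sizes.min() >= share_min)


def _design(order: int) -> np.ndarray:
    t = np.arange(N_HOURS, dtype=float) - TIME_CENTER
    return np.vander(t, order + 1, increasing=True)


def _loglik_matrix(Y: np.ndarray, pi, beta, sigma) -> np.ndarray:
    """(N, K) matrix of log pi_g + log p(y_i | group g)."""
    N, V, T = Y.shape
    K = len(pi)
    out = np.empty((N, K))
    for g in range(K):
        mu = np.stack([
            np.polyval(beta[g][v][::-1], np.arange(T) - TIME_CENTER) for v in range(V)
        ])
        var = np.maximum(sigma[g] ** 2, VAR_FLOOR)
        r2 = ((Y - mu[None]) ** 2 / var[None, :, None]).sum(axis=(1, 2))
        const = -0.5 * T * np.log(2 * np.pi * var).sum()
        out[:, g] = np.log(max(pi[g], 1e-300)) + const - 0.5 * r2
    return out


def observed_loglik(Y: np.ndarray, pi, beta, sigma) -> float:
    """Observed-data log-likelihood at arbitrary parameter values."""
    return float(logsumexp(_loglik_matrix(Y, pi, beta, sigma), axis=1).sum())


def _m_step(Y: np.ndarray, W: np.ndarray, orders: np.ndarray):
    N, V, T = Y.shape
    K = W.shape[1]
    Wg = W.sum(axis=0)
    if Wg.min() < 1e-6:
        raise DegenerateComponentError(
            f"component weight {Wg.min():.2e} ~ 0; try a smaller K"
        )
    pi = Wg / N
    M1 = np.einsum("ik,ivt->kvt", W, Y)
    M2 = np.einsum("ik,ivt->kvt", W, Y**2)
    beta = [[None] * V for _ in range(K)]
    se = [[None] * V for _ in range(K)]
    sigma = np.empty((K, V))
    for g in range(K):
        for v in range(V):
            X = _design(orders[g, v])
            XtX_inv = np.linalg.inv(X.T @ X)
            ybar = M1[g, v] / Wg[g]
            b = XtX_inv @ (X.T @ ybar)
            fit = X @ b
            ss = float(M2[g, v].sum() - 2 * (fit * M1[g, v]).sum() + Wg[g] * (fit**2).sum())
            var = max(ss / (Wg[g] * T), VAR_FLOOR)
            beta[g][v] = b
            sigma[g, v] = np.sqrt(var)
            se[g][v] = np.sqrt(var * np.diag(XtX_inv) / Wg[g])
    return pi, beta, sigma, se


def _em(Y, W0, orders, max_iter, tol):
    trace = []
    W = W0
    pi = beta = sigma = se = None
    loglik = -np.inf
    converged = False
    for _ in range(max_iter):
        pi, beta, sigma, se = _m_step(Y, W, orders)
        ll_mat = _loglik_matrix(Y, pi, beta, sigma)
        ll_i = logsumexp(ll_mat, axis=1)
        new_loglik = float(ll_i.sum())
        W = np.exp(ll_mat - ll_i[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return pi, beta, sigma, se, W, loglik, np.asarray(trace), converged


def _initial_weights(Y, K, rng, start):
    """K-means on flattened grids for start 0; perturbed centers after."""
    N = Y.shape[0]
    flat = Y.reshape(N, -1)
    km = KMeans(
        n_clusters=K,
        n_init=1,
        random_state=int(rng.integers(2**31 - 1)),
    ).fit(flat)
    centers = km.cluster_centers_
    if start > 0:
        scale = 0.5 * flat.std(axis=0).mean()
        centers = centers + rng.normal(0.0, scale, centers.shape)
    labels = np.argmin(
        ((flat[:, None, :] - centers[None]) ** 2).sum(axis=2), axis=1
    )
    # guard: every component needs some weight
    for g in range(K):
        if not (labels == g).any():
            labels[int(rng.integers(N))] = g
    W0 = np.full((N, K), 1e-3)
    W0[np.arange(N), labels] = 1.0
    return W0 / W0.sum(axis=1, keepdims=True)


def fit_em(
    grids,
    spec: TrajectoryModelSpec,
    init_weights: np.ndarray | None = None,
) -> GBMTMFit:
    """Best-of-``n_starts`` EM fit to standardized (N, V, 12) grids.

    ``grids`` may be a GridSet (complete, standardized) or a plain array.
    ``init_weights`` warm-starts from given posteriors (single start).
    """
    Y = np.asarray(getattr(grids, "values", grids), dtype=float)
    if Y.ndim != 3:
        raise InputError("grids must be a (N, V, T) array or GridSet")
    N, V, T = Y.shape
    if N < spec.K:
        raise InputError(f"need at least K={spec.K} subjects, got {N}")
    orders = spec.orders_array(V)
    rng = np.random.default_rng(spec.seed)

    best = None
    starts = 1 if init_weights is not None else max(1, spec.n_starts)
    for s in range(starts):
        W0 = init_weights if init_weights is not None else _initial_weights(Y, spec.K, rng, s)
        pi, beta, sigma, se, W, ll, trace, conv = _em(
            Y, W0, orders, spec.max_iter, spec.tol
        )
        if best is None or ll > best[5]:
            best = (pi, beta, sigma, se, W, ll, trace, conv)
    pi, beta, sigma, se, W, ll, trace, conv = best
    if not conv:
        warnings.warn("EM did not converge within max_iter")
    return GBMTMFit(
        pi=pi,
        beta=beta,
        sigma=sigma,
        W=W,
        loglik=ll,
        n_params=count_params(spec.K, orders),
        converged=conv,
        trace=trace,
        orders=orders,
        coef_se=se,
    )


def count_params(K: int, orders: np.ndarray) -> int:
    """Free parameters: (K-1) mixing + coefficients + one variance per (g, v)."""
    orders = np.asarray(orders)
    V = orders.shape[1]
    return int((K - 1) + (orders + 1).sum() + K * V)


def information_criteria(loglik: float, k: int, N: int) -> tuple[float, float]:
    """(BIC, AIC) with N = number of subjects."""
    if N < 1:
        raise InputError("N must be >= 1")
    return -2.0 * loglik + k * np.log(N), -2.0 * loglik + 2.0 * k


def relative_entropy(W: np.ndarray) -> float:
    """1 - normalized mean posterior Shannon entropy; in [0, 1].

    1 = perfectly crisp classification, 0 = uniform posteriors.  K = 1
    returns 1 by convention (classification is vacuous).
    """
    W = np.asarray(W, dtype=float)
    N, K = W.shape
    if np.abs(W.sum(axis=1) - 1.0).max() > 1e-8:
        raise InputError("posterior rows must sum to 1 within 1e-8")
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(W > 0, -W * np.log(W), 0.0)
    return float(1.0 - h.sum() / (N * np.log(K)))


def assign(W: np.ndarray) -> np.ndarray:
    """Modal group labels 1..K; exact ties go to the lowest group index."""
    return np.argmax(W, axis=1) + 1


def avepp(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Average posterior probability among subjects modally assigned to each group."""
    K = W.shape[1]
    out = np.full(K, np.nan)
    for g in range(K):
        members = labels == g + 1
        if members.any():
            out[g] = W[members, g].mean()
        else:
            warnings.warn(f"group {g + 1} has no modal members; AvePP undefined")
    return out


def occ(avepp_g: float, pi_g: float) -> float:
    """Odds of correct classification: posterior odds over prior odds."""
    if not 0.0 < pi_g < 1.0:
        raise InputError("pi_g must lie strictly inside (0, 1)")
    if not 0.0 < avepp_g <= 1.0:
        raise InputError("AvePP must lie in (0, 1]")
    if avepp_g == 1.0:
        return np.inf
    return (avepp_g / (1.0 - avepp_g)) / (pi_g / (1.0 - pi_g))


def diagnostics(fit: GBMTMFit, N: int | None = None) -> FitDiagnostics:
    N = N if N is not None else fit.W.shape[0]
    bic, aic = information_criteria(fit.loglik, fit.n_params, N)
    labels = assign(fit.W)
    shares = np.bincount(labels - 1, minlength=fit.K) / len(labels)
    ap = avepp(fit.W, labels)
    occs = np.array(
        [
            occ(ap[g], fit.pi[g]) if np.isfinite(ap[g]) and 0 < fit.pi[g] < 1 else np.nan
            for g in range(fit.K)
        ]
    )
    return FitDiagnostics(
        bic=bic,
        aic=aic,
        entropy=relative_entropy(fit.W),
        group_sizes=shares,
        avepp=ap,
        occ=occs,
    )


def select_num_groups(
    grids,
    k_range=(1, 6),
    template: TrajectoryModelSpec | None = None,
    entropy_min: float = 0.7,
    share_min: float = 0.05,
):
    """Fit K over ``k_range`` and apply the entropy/size/BIC selection rule.

    Eligible models have entropy > 0.7 and every modal group share >= 5%;
    among those the lowest BIC wins (ties to smaller K).  If no model is
    eligible the lowest-BIC model overall is returned with a warning flag.
    Returns (selection table as records list, chosen K, {K: (fit, diag)}).
    """
    import pandas as pd

    template = template or TrajectoryModelSpec(K=1)
    fits: dict[int, tuple[GBMTMFit, FitDiagnostics]] = {}
    rows = []
    for K in range(k_range[0], k_range[1] + 1):
        spec = TrajectoryModelSpec(
            K=K,
            orders=template.orders if np.ndim(template.orders) == 0 else 3,
            n_starts=template.n_starts,
            max_iter=template.max_iter,
            tol=template.tol,
            seed=template.seed,
        )
        try:
            fit = fit_em(grids, spec)
        except (DegenerateComponentError, InputError) as err:
            warnings.warn(f"K={K} fit failed: {err}")
            continue
        diag = diagnostics(fit)
        fits[K] = (fit, diag)
        rows.append(
            {
                "K": K,
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "bic": diag.bic,
                "aic": diag.aic,
                "entropy": diag.entropy,
                "min_share": float(diag.group_sizes.min()),
                "min_avepp": float(np.nanmin(diag.avepp)),
                "min_occ": float(np.nanmin(diag.occ)) if not np.isnan(diag.occ).all() else np.nan,
                "eligible": diag.eligible(entropy_min, share_min),
            }
        )
    if not rows:
        raise RuntimeError("no K could be fitted")
    table = pd.DataFrame(rows)
    eligible = table[table["eligible"]]
    pool = eligible if len(eligible) else table
    if not len(eligible):
        warnings.warn("no model met the eligibility criteria; using lowest BIC overall")
    chosen = int(pool.sort_values(["bic", "K"]).iloc[0]["K"])
    return table, chosen, fits


def backward_eliminate_orders(
    grids,
    K: int,
    alpha: float = 0.05,
    template: TrajectoryModelSpec | None = None,
    max_rounds: int = 10,
) -> tuple[TrajectoryModelSpec, GBMTMFit]:
    """Prune polynomial orders per (group, channel) from cubic downward.

    Start with all orders = 3; each round, every (group, channel) whose
    highest-order coefficient has Wald p >= alpha (z from the final M-step
    WLS covariance) is decremented, and the model refit warm-started from
    the previous posteriors so group identities stay aligned.  Stops when
    all retained top terms are significant, everything is linear, or after
    ``max_rounds``.
    """
    Y = np.asarray(getattr(grids, "values", grids), dtype=float)
    template = template or TrajectoryModelSpec(K=K)
    V = Y.shape[1]
    orders = np.full((K, V), 3, dtype=int)
    spec = TrajectoryModelSpec(
        K=K, orders=orders, n_starts=template.n_starts,
        max_iter=template.max_iter, tol=template.tol, seed=template.seed,
    )
    fit = fit_em(Y, spec)
    for _ in range(max_rounds):
        changed = False
        for g in range(K):
            for v in range(V):
                p = orders[g, v]
                if p <= 1:
                    continue
                z = fit.beta[g][v][p] / fit.coef_se[g][v][p]
                pval = 2.0 * norm.sf(abs(z))
                if pval >= alpha:
                    orders[g, v] = p - 1
                    changed = True
        if not changed:
            break
        spec = TrajectoryModelSpec(
            K=K, orders=orders.copy(), n_starts=1,
            max_iter=template.max_iter, tol=template.tol, seed=template.seed,
        )
        fit = fit_em(Y, spec, init_weights=fit.W)
    else:
        warnings.warn("backward elimination stopped after max_rounds")
    return spec, fit


def permutation_accuracy(true_labels: np.ndarray, pred_labels: np.ndarray) -> float:
    """Classification accuracy after the optimal group relabeling."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    K = int(max(true_labels.max(), pred_labels.max()))
    conf = np.zeros((K, K))
    for t, p in zip(true_labels, pred_labels):
        conf[t - 1, p - 1] += 1
    r, c = linear_sum_assignment(-conf)
    return float(conf[r, c].sum() / len(true_labels))
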