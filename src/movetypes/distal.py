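"""Bias-adjusted three-step estimation of typology-outcome associations.

Treating modal (or proportional) typology assignment as if it were the true
class attenuates distal-outcome effects whenever classification is imperfect.
The Bolck-Croon-Hagenaars (BCH) correction inverts the classification-error
matrix D (d[k][s] = P(assigned s | true k)) and re-weights an expanded
subject-by-class pseudo-dataset with w_i = p_i D^{-1}; the weights sum to one
per subject but individual entries may be negative, so the weighted least
squares and its cluster-robust (by subject) sandwich variance are computed
directly.

Also here: the ML three-step comparison of covariates across classes (a
multinomial logit measured through the fixed error matrix), the school
random-intercept screening, and Rubin's rules for pooling across multiple
imputations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lpa import modal_assign

__all__ = [
    "ErrorMatrix",
    "BCHWeights",
    "DistalModelResult",
    "PooledResult",
    "classification_error_matrix",
    "bch_weights",
    "bch_distal_regression",
    "exp_coefficients",
    "covariate_comparison",
    "school_variance_check",
    "pool_rubin",
]


@dataclass(frozen=True)
class ErrorMatrix:
    d: np.ndarray  # K x K, rows: true class, cols: assigned class
    assignment_mode: str

    def __post_init__(self) -> None:
        D = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", D)
        if not np.allclose(D.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("error-matrix rows must sum to 1")


@dataclass(frozen=True)
class BCHWeights:
    w: np.ndarray  # n x K; rows sum to 1, entries may be negative
    assignment_mode: str


@dataclass
class DistalModelResult:
    outcome: str
    log_transformed: bool
    terms: list[str]
    coefficients: np.ndarray
    robust_se: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    p_value: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "outcome": self.outcome,
            "term": self.terms,
            "B": self.coefficients,
            "se": self.robust_se,
            "ci_low": self.ci95_low,
            "ci_high": self.ci95_high,
            "p": self.p_value,
        })
        if self.log_transformed:
            df["exp_b"] = np.exp(df["B"])
        return df


@dataclass(frozen=True)
class PooledResult:
    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    p: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def classification_error_matrix(
    posteriors: np.ndarray, mode: str = "proportional"
) -> ErrorMatrix:
    """D[k, s] = estimated P(assigned class s | true class k).

    ``modal``: assignments are the modal classes; ``proportional``:
    assignment probability mass equals the posterior itself.
    """
    post = np.asarray(posteriors, dtype=float)
    n, K = post.shape
    col_mass = post.sum(axis=0)
    if np.any(col_mass <= 0):
        raise ValueError("a class has zero total posterior mass")
    if mode == "modal":
        assign = np.zeros((n, K))
        assign[np.arange(n), modal_assign(post)] = 1.0
    elif mode == "proportional":
        assign = post
    else:
        raise ValueError(f"unknown mode {mode!r}")
    D = (post.T @ assign) / col_mass[:, None]
    return ErrorMatrix(D, mode)


def bch_weights(posteriors: np.ndarray, err: ErrorMatrix) -> BCHWeights:
    """w_i = p_i @ D^{-1}, with p_i the assignment probability row.

    In modal mode p_i is the one-hot modal assignment; in proportional mode
    it is the posterior row itself.  Rows sum to one because D is row-
    stochastic; entries can be negative when classification is noisy.
    """
    post = np.asarray(posteriors, dtype=float)
    D = err.d
    if np.linalg.cond(D) > 1e8:
        raise np.linalg.LinAlgError(
            "classification-error matrix is ill-conditioned; classes are "
            "poorly separated — consider fewer classes"
        )
    if err.assignment_mode == "modal":
        assign = np.zeros_like(post)
        assign[np.arange(post.shape[0]), modal_assign(post)] = 1.0
    else:
        assign = post
    w = assign @ np.linalg.inv(D)
    return BCHWeights(w, err.assignment_mode)


def _cluster_robust_wls(X, y, w, clusters):
    """WLS point estimates and cluster sandwich covariance.

    Weights may be negative (BCH), so the normal equations are solved as
    plain linear algebra: b = (X'WX)^-1 X'Wy; the meat stacks per-cluster
    score sums.
    """
    XtW = X.T * w
    bread = np.linalg.inv(XtW @ X)
    beta = bread @ (XtW @ y)
    resid = y - X @ beta
    scores = X * (w * resid)[:, None]
    meat = np.zeros((X.shape[1], X.shape[1]))
    order = np.argsort(clusters, kind="stable")
    sorted_clusters = clusters[order]
    boundaries = np.flatnonzero(np.r_[1, np.diff(sorted_clusters)])
    g_sums = np.add.reduceat(scores[order], boundaries, axis=0)
    meat = g_sums.T @ g_sums
    cov = bread @ meat @ bread
    return beta, cov


def bch_distal_regression(
    outcome: np.ndarray,
    weights: BCHWeights,
    covariates: pd.DataFrame | None = None,
    log_outcome: bool = True,
    reference: int = 0,
    class_names: Sequence[str] | None = None,
    interactions: Sequence[tuple[str, str]] = (),
    outcome_name: str = "outcome",
) -> DistalModelResult:
    """Weighted regression of a (log-)outcome on class membership + covariates.

    The data are expanded to n*K pseudo-records (one per subject-class pair)
    carrying the BCH weight for that pair; class indicators use ``reference``
    as the omitted category.  ``interactions`` entries are pairs of column /
    term names; ``("age_c", "class")`` expands to age-by-class terms.
    Standard errors are subject-clustered sandwich estimates; 95% CIs are
    B +/- 1.96 se.
    """
    y = np.asarray(outcome, dtype=float)
    W = weights.w
    n, K = W.shape
    if y.shape != (n,):
        raise ValueError("outcome length must match the weight matrix")
    if log_outcome:
        if np.any(y <= 0):
            raise ValueError("log transform requested but outcome has values <= 0")
        y = np.log(y)
    if class_names is None:
        class_names = [f"class{k + 1}" for k in range(K)]

    cov_arr = None
    cov_names: list[str] = []
    if covariates is not None and covariates.shape[1]:
        cov_names = list(covariates.columns)
        cov_arr = covariates.to_numpy(dtype=float)

    nonref = [k for k in range(K) if k != reference]
    blocks, terms = [], ["intercept"]
    ones = np.ones((n, 1))
    blocks.append(ones)
    for k in nonref:
        terms.append(class_names[k])
    for cname in cov_names:
        terms.append(cname)
    for left, right in interactions:
        if right == "class":
            for k in nonref:
                terms.append(f"{left}:{class_names[k]}")
        else:
            terms.append(f"{left}:{right}")

    # expand: subject blocks repeated per class s
    Xs, ys, ws, cl = [], [], [], []
    for s in range(K):
        cls_dummy = np.zeros((n, len(nonref)))
        for j, k in enumerate(nonref):
            if s == k:
                cls_dummy[:, j] = 1.0
        cols = [ones, cls_dummy]
        if cov_arr is not None:
            cols.append(cov_arr)
        for left, right in interactions:
            lvals = covariates[left].to_numpy(dtype=float)
            if right == "class":
                cols.append(lvals[:, None] * cls_dummy)
            else:
                cols.append((lvals * covariates[right].to_numpy(dtype=float))[:, None])
        Xs.append(np.hstack(cols))
        ys.append(y)
        ws.append(W[:, s])
        cl.append(np.arange(n))
    X = np.vstack(Xs)
    yy = np.concatenate(ys)
    ww = np.concatenate(ws)
    clusters = np.concatenate(cl)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); terms: {terms}"
        )
    beta, cov = _cluster_robust_wls(X, yy, ww, clusters)
    se = np.sqrt(np.diag(cov))
    zstat = beta / se
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    return DistalModelResult(
        outcome=outcome_name, log_transformed=log_outcome, terms=terms,
        coefficients=beta, robust_se=se,
        ci95_low=beta - 1.96 * se, ci95_high=beta + 1.96 * se, p_value=p,
    )


def exp_coefficients(result: DistalModelResult, decimals: int = 2) -> pd.DataFrame:
    """Multiplicative effects exp(B) with exponentiated CI bounds."""
    if not result.log_transformed:
        raise ValueError("outcome was not log-transformed")
    return pd.DataFrame({
        "term": result.terms,
        "exp_b": np.round(np.exp(result.coefficients), decimals),
        "exp_ci_low": np.round(np.exp(result.ci95_low), decimals),
        "exp_ci_high": np.round(np.exp(result.ci95_high), decimals),
    })


def covariate_comparison(
    covariate: np.ndarray,
    posteriors: np.ndarray,
    err: ErrorMatrix | None = None,
    ridge: float = 1e-6,
) -> dict:
    """ML three-step test of whether a covariate differs across classes.

    The true class is modelled as a multinomial logit of the covariate and is
    observed only through the modal assignment, with misclassification rates
    fixed at the error matrix: the log-likelihood of subject i is
    log sum_k P(k | x_i; gamma) * d[k, a_i].  A Wald test of all covariate
    slopes being zero gives the overall p-value.  A tiny L2 penalty keeps the
    optimum finite under separation.
    """
    x = np.asarray(covariate, dtype=float)
    post = np.asarray(posteriors, dtype=float)
    n, K = post.shape
    if err is None:
        err = classification_error_matrix(post, "modal")
    assigned = modal_assign(post)
    d_cols = err.d[:, assigned]  # K x n: d[k, a_i]
    Xd = np.column_stack([np.ones(n), (x - x.mean()) / (x.std() + 1e-12)])
    x_scale = x.std() + 1e-12

    def unpack(theta):
        G = np.zeros((K, 2))
        G[1:] = theta.reshape(K - 1, 2)
        return G

    def neg_loglik_grad(theta):
        G = unpack(theta)
        eta = Xd @ G.T  # n x K
        eta -= eta.max(axis=1, keepdims=True)
        P = np.exp(eta)
        P /= P.sum(axis=1, keepdims=True)  # n x K: P(k | x_i)
        lik = (P * d_cols.T).sum(axis=1)
        nll = -np.log(np.clip(lik, 1e-300, None)).sum() + ridge * (theta**2).sum()
        # dP/deta_j = P_j(delta_jk - P_k); d nll/d eta_ij
        r = (d_cols.T / lik[:, None])  # n x K
        g_eta = -(P * (r - (P * r).sum(axis=1, keepdims=True)))
        grad = (g_eta.T @ Xd)[1:].reshape(-1) + 2 * ridge * theta
        return nll, grad

    theta0 = np.zeros(2 * (K - 1))
    res = optimize.minimize(neg_loglik_grad, theta0, jac=True, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-8})
    theta = res.x
    # numerical Hessian from the analytic gradient
    p_dim = theta.size
    H = np.zeros((p_dim, p_dim))
    h = 1e-5
    for j in range(p_dim):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = neg_loglik_grad(tp)
        _, gm = neg_loglik_grad(tm)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    cov = np.linalg.inv(H)
    slope_idx = np.arange(1, p_dim, 2)  # slopes of each non-reference class
    b = theta[slope_idx]
    Vb = cov[np.ix_(slope_idx, slope_idx)]
    wald = float(b @ np.linalg.solve(Vb, b))
    p = float(stats.chi2.sf(wald, df=len(slope_idx)))

    # implied class-specific covariate means under the fitted model
    G = unpack(theta)
    eta = Xd @ G.T
    eta -= eta.max(axis=1, keepdims=True)
    P = np.exp(eta)
    P /= P.sum(axis=1, keepdims=True)
    lik = (P * d_cols.T).sum(axis=1)
    memb = P * d_cols.T / lik[:, None]  # posterior P(k | x_i, a_i)
    class_means = (memb * x[:, None]).sum(axis=0) / memb.sum(axis=0)
    return {
        "coef": G / np.array([1.0, x_scale]),
        "class_means": class_means,
        "wald": wald,
        "p": p,
        "converged": bool(res.success),
    }


def school_variance_check(outcome: np.ndarray, school_ids: np.ndarray) -> dict:
    """One-way random-intercept screening: ICC and likelihood-ratio p.

    The between-school variance component uses the ANOVA (method-of-moments)
    estimator truncated at zero; the LRT compares a school random-intercept
    model against plain OLS with the usual 50:50 chi-square boundary mixture.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(school_ids)
    groups, counts = np.unique(g, return_counts=True)
    if len(groups) < 2:
        return {"icc": float("nan"), "lrt_p": float("nan"),
                "n_schools": int(len(groups)), "applicable": False}
    N, J = len(y), len(groups)
    overall = y.mean()
    means = np.array([y[g == grp].mean() for grp in groups])
    ssb = float((counts * (means - overall) ** 2).sum())
    ssw = float(sum(((y[g == grp] - means[j]) ** 2).sum()
                    for j, grp in enumerate(groups)))
    msb = ssb / (J - 1)
    msw = ssw / (N - J) if N > J else 0.0
    n0 = (N - (counts**2).sum() / N) / (J - 1)
    var_school = max((msb - msw) / n0, 0.0)
    icc = var_school / (var_school + msw) if (var_school + msw) > 0 else 0.0
    if np.var(y) <= 1e-14:  # constant outcome: nothing to partition
        return {"icc": 0.0, "var_school": 0.0, "var_resid": 0.0,
                "lrt": 0.0, "lrt_p": 1.0, "n_schools": int(J),
                "applicable": True}

    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    # a boundary (zero) school variance is an expected, meaningful outcome
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        mixed = sm.MixedLM(y, np.ones((N, 1)), groups=g).fit(reml=False)
        ll1 = mixed.llf
    resid = y - overall
    sigma2 = float((resid**2).mean())
    ll0 = -0.5 * N * (np.log(2 * np.pi * sigma2) + 1.0)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return {"icc": float(icc), "var_school": var_school, "var_resid": msw,
            "lrt": lrt, "lrt_p": p, "n_schools": int(J), "applicable": True}


def pool_rubin(
    estimates: Sequence[float],
    variances: Sequence[float],
    df_com: float | None = None,
) -> PooledResult:
    """Rubin's rules across m imputations, with Barnard-Rubin small-sample df.

    T = Wbar + (1 + 1/m) B; with one imputation or zero between-imputation
    variance the reference is normal (infinite df).
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    if m == 0:
        raise ValueError("no estimates to pool")
    qbar = float(q.mean())
    wbar = float(u.mean())
    b = float(q.var(ddof=1)) if m > 1 else 0.0
    t = wbar + (1.0 + 1.0 / m) * b
    if b <= 0 or m == 1:
        df = float("inf")
        p = 2.0 * stats.norm.sf(abs(qbar) / np.sqrt(t)) if t > 0 else 1.0
        return PooledResult(qbar, wbar, b, t, df, float(p))
    lam = (1.0 + 1.0 / m) * b / t
    df_old = (m - 1) / lam**2
    if df_com is None or not np.isfinite(df_com):
        df = df_old
    else:
        df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
        df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    p = 2.0 * stats.t.sf(abs(qbar) / np.sqrt(t), df)
    return PooledResult(qbar, wbar, b, t, float(df), float(p))
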