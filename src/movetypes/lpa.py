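"""Latent profile analysis: Gaussian mixtures with a shared covariance.

The typology model is a K-component Gaussian mixture on the (D-1) ilr
coordinates with class-specific means and one pooled within-class covariance
(variances and covariances equal across typologies), fitted by EM from
multiple starts.  Selection diagnostics (BIC, AIC, relative entropy, the
Lo-Mendell-Rubin / bootstrap likelihood-ratio test, minimum class share),
modal assignment, posterior-weighted descriptives, bee-themed profile
labelling, and the model-selection rule live here too.

Parameter count: q = (K-1) + K*(D-1) + (D-1)*D/2 (mixing weights, class
means, and the shared covariance of the D-1 coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .composition import DAY_MINUTES, Composition, compositional_mean

__all__ = [
    "LPAModel",
    "FitDiagnostics",
    "TypologyProfile",
    "SelectionResult",
    "fit_lpa",
    "compute_posteriors",
    "diagnostics",
    "vlmr_test",
    "modal_assign",
    "weighted_descriptives",
    "class_difference_table",
    "label_profiles",
    "select_model",
]

_COND_LIMIT = 1e12


class DegenerateFitError(RuntimeError):
    """Every EM start collapsed onto a degenerate covariance."""


@dataclass
class LPAModel:
    K: int
    mixing: np.ndarray
    means: np.ndarray            # K x d
    shared_cov: np.ndarray       # d x d
    loglik: float
    posteriors: np.ndarray       # n x K
    converged: bool
    n_params: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed_info: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class FitDiagnostics:
    K: int
    loglik: float
    n_params: int
    bic: float
    aic: float
    entropy: float | None
    min_class_share: float
    vlmr_p: float | None = None


@dataclass
class TypologyProfile:
    label: str
    share: float
    compositional_mean: Composition
    weighted_stats: pd.DataFrame | None = None


def _log_mvnorm(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    sol = np.linalg.solve(chol, (X - mean).T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _component_loglikes(X, mixing, means, cov):
    """n x K matrix of log(pi_k) + log phi_k(x_i)."""
    K = means.shape[0]
    out = np.empty((X.shape[0], K))
    for k in range(K):
        out[:, k] = np.log(mixing[k]) + _log_mvnorm(X, means[k], cov)
    return out


def compute_posteriors(
    mixing: np.ndarray, means: np.ndarray, shared_cov: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Posterior class probabilities, log-sum-exp guarded."""
    lw = _component_loglikes(np.asarray(X, float), mixing, means, shared_cov)
    norm = logsumexp(lw, axis=1, keepdims=True)
    if not np.all(np.isfinite(norm)):
        raise FloatingPointError("zero total density for at least one row")
    return np.exp(lw - norm)


def _m_step(X, resp, ridge_on_fail=True):
    n, d = X.shape
    nk = resp.sum(axis=0)
    mixing = nk / n
    means = (resp.T @ X) / nk[:, None]
    cov = np.zeros((d, d))
    for k in range(resp.shape[1]):
        diff = X - means[k]
        cov += (resp[:, k][:, None] * diff).T @ diff
    cov /= n
    cov = 0.5 * (cov + cov.T)
    if ridge_on_fail and (
        not np.all(np.isfinite(cov)) or np.linalg.cond(cov) > _COND_LIMIT
    ):
        cov += 1e-10 * max(np.trace(cov), 1.0) / d * np.eye(d)
    return mixing, means, cov


def _init_resp(X, K, rng, style):
    n = X.shape[0]
    if style == "kmeans++":
        centers, _ = kmeans_plusplus(
            X, n_clusters=K, random_state=int(rng.integers(2**31 - 1))
        )
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        resp = np.zeros((n, K))
        resp[np.arange(n), d2.argmin(axis=1)] = 1.0
        resp = resp * 0.9 + 0.1 / K  # soften so no component starts empty
    else:
        resp = rng.dirichlet(np.ones(K), size=n)
    return resp


def fit_lpa(
    z_matrix: np.ndarray,
    K: int,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LPAModel:
    """Best-of-``n_starts`` EM fit of the shared-covariance Gaussian mixture.

    Starts alternate k-means++ one-hot responsibilities and random Dirichlet
    responsibilities.  The per-iteration log-likelihood is recorded (EM
    guarantees it is nondecreasing) and convergence is declared when its
    relative change drops below ``tol``.  A start whose covariance collapses
    (condition number beyond 1e12 even after ridging) is abandoned.
    """
    X = np.asarray(z_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    n_params = (K - 1) + K * d + d * (d + 1) // 2
    if n <= n_params:
        raise ValueError(f"n={n} too small for q={n_params} parameters")

    if K == 1:
        mean = X.mean(axis=0, keepdims=True)
        cov = np.cov(X.T, bias=True).reshape(d, d)
        loglik = float(_log_mvnorm(X, mean[0], cov).sum())
        return LPAModel(
            K=1, mixing=np.ones(1), means=mean, shared_cov=cov, loglik=loglik,
            posteriors=np.ones((n, 1)), converged=True, n_params=n_params,
            loglik_trace=np.array([loglik]), seed_info={"seed": seed, "closed_form": True},
        )

    rng = np.random.default_rng(seed)
    best = None
    n_collapsed = 0
    for s in range(n_starts):
        style = "kmeans++" if s % 2 == 0 else "random"
        resp = _init_resp(X, K, rng, style)
        try:
            model = _run_em(X, resp, K, tol, max_iter, n_params)
        except np.linalg.LinAlgError:
            n_collapsed += 1
            continue
        if model is None:
            n_collapsed += 1
            continue
        if best is None or model.loglik > best.loglik:
            model.seed_info = {"seed": seed, "start": s, "style": style}
            best = model
    if best is None:
        raise DegenerateFitError(
            f"all {n_starts} starts collapsed (n={n}, K={K})"
        )
    best.seed_info["n_collapsed_starts"] = n_collapsed
    return best


def _run_em(X, resp, K, tol, max_iter, n_params):
    n, d = X.shape
    mixing, means, cov = _m_step(X, resp)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        if np.linalg.cond(cov) > _COND_LIMIT:
            cov = cov + 1e-10 * max(np.trace(cov), 1.0) / d * np.eye(d)
            if np.linalg.cond(cov) > _COND_LIMIT:
                return None
        if np.any(mixing <= 0):
            return None
        lw = _component_loglikes(X, mixing, means, cov)
        norm = logsumexp(lw, axis=1)
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(lw - norm[:, None])
        if loglik - prev < tol * (abs(loglik) + 1e-12) and np.isfinite(prev):
            converged = True
            break
        prev = loglik
        mixing, means, cov = _m_step(X, resp)
    if not converged:
        # max_iter exhausted after an M-step: re-evaluate at the final params
        lw = _component_loglikes(X, mixing, means, cov)
        trace.append(float(logsumexp(lw, axis=1).sum()))
    post = compute_posteriors(mixing, means, cov, X)
    return LPAModel(
        K=K, mixing=mixing, means=means, shared_cov=cov, loglik=trace[-1],
        posteriors=post, converged=converged, n_params=n_params,
        loglik_trace=np.asarray(trace),
    )


def diagnostics(model: LPAModel, n: int | None = None) -> FitDiagnostics:
    """BIC/AIC, relative entropy, minimum class share.

    Relative entropy is 1 - (-sum p log p)/(n log K): 1 for perfectly crisp
    posteriors, 0 for uniform ones; undefined for K=1.
    """
    if n is None:
        n = model.posteriors.shape[0]
    bic = -2.0 * model.loglik + model.n_params * np.log(n)
    aic = -2.0 * model.loglik + 2.0 * model.n_params
    if model.K == 1:
        entropy = None
    else:
        p = np.clip(model.posteriors, 1e-300, 1.0)
        entropy = float(1.0 + (p * np.log(p)).sum() / (n * np.log(model.K)))
    min_share = float(model.posteriors.sum(axis=0).min() / n)
    return FitDiagnostics(
        K=model.K, loglik=model.loglik, n_params=model.n_params,
        bic=float(bic), aic=float(aic), entropy=entropy,
        min_class_share=min_share,
    )


def vlmr_test(
    model_K: LPAModel,
    model_Km1: LPAModel,
    n: int,
    mode: str = "lmr_adjusted",
    z_matrix: np.ndarray | None = None,
    B: int = 99,
    seed: int = 0,
    n_starts: int = 4,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> float:
    """p-value for K classes against K-1 classes.

    ``lmr_adjusted``: the Lo-Mendell-Rubin style correction of the likelihood
    ratio, 2*dl / (1 + 1/(dq * ln n)), referred to a chi-square with dq
    degrees of freedom (dq = parameter difference).  This is an analytic
    approximation; the parametric bootstrap is the calibrated reference.

    ``bootstrap``: draw B datasets of size n from the fitted (K-1)-class
    model, refit both models on each, and return the empirical exceedance
    probability (1 + #{boot >= observed}) / (B + 1).
    """
    if model_K.K != model_Km1.K + 1:
        raise ValueError("models must differ by exactly one class")
    lr = 2.0 * (model_K.loglik - model_Km1.loglik)
    # EM stops within a convergence tolerance of the optimum, so a tiny
    # negative difference is numerical; a substantial one means the larger
    # model's optimisation failed and must be redone
    if lr < -0.05:
        raise RuntimeError(
            "larger model has clearly lower log-likelihood; refit with more starts"
        )
    lr = max(lr, 0.0)
    dq = model_K.n_params - model_Km1.n_params
    if lr == 0.0:
        return 1.0
    if mode == "lmr_adjusted":
        lr_adj = lr / (1.0 + 1.0 / (dq * np.log(n)))
        return float(stats.chi2.sf(lr_adj, df=dq))
    if mode != "bootstrap":
        raise ValueError(f"unknown mode {mode!r}")
    if z_matrix is None:
        raise ValueError("bootstrap mode needs the data matrix")
    rng = np.random.default_rng(seed)
    d = model_Km1.means.shape[1]
    chol = np.linalg.cholesky(model_Km1.shared_cov)
    exceed = 0
    for _ in range(B):
        cls = rng.choice(model_Km1.K, size=n, p=model_Km1.mixing)
        Xb = model_Km1.means[cls] + rng.standard_normal((n, d)) @ chol.T
        sub_seed = int(rng.integers(2**31 - 1))
        m0 = fit_lpa(Xb, model_Km1.K, n_starts=n_starts, seed=sub_seed,
                     tol=tol, max_iter=max_iter)
        m1 = fit_lpa(Xb, model_K.K, n_starts=n_starts, seed=sub_seed + 1,
                     tol=tol, max_iter=max_iter)
        if 2.0 * (m1.loglik - m0.loglik) >= lr:
            exceed += 1
    return float((1 + exceed) / (B + 1))


def modal_assign(posteriors: np.ndarray) -> np.ndarray:
    """Most-probable class per row; ties break toward the lowest class index."""
    return np.argmax(np.asarray(posteriors), axis=1)


def _weighted_mean_sd(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    mean = float((w * x).sum() / sw)
    # reliability-weight variance: posterior weights are precisions, not counts
    denom = sw**2 - (w**2).sum()
    if denom <= 0:
        return mean, float("nan")
    var = sw * float((w * (x - mean) ** 2).sum()) / denom
    return mean, float(np.sqrt(var))


def weighted_descriptives(
    records: pd.DataFrame,
    posteriors: np.ndarray,
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
    composition_cols: Sequence[str] = ("mvpa_min", "lpa_min", "sb_min", "sleep_min"),
) -> list[TypologyProfile]:
    """Posterior-weighted per-class descriptives and compositional means.

    Each subject contributes to every class with weight equal to the posterior
    probability of membership; continuous variables get weighted means and
    SDs, binaries weighted proportions, and the composition a posterior-
    weighted geometric mean.
    """
    post = np.asarray(posteriors, dtype=float)
    if len(records) != post.shape[0]:
        raise ValueError("records and posteriors are misaligned")
    n, K = post.shape
    comp = records[list(composition_cols)].to_numpy(dtype=float)
    profiles = []
    for k in range(K):
        w = post[:, k]
        if w.sum() < 2:
            import warnings

            warnings.warn(f"class {k} has total weight {w.sum():.2f} < 2")
        rows = []
        for col in continuous:
            mean, sd = _weighted_mean_sd(records[col].to_numpy(dtype=float), w)
            rows.append({"variable": col, "kind": "continuous",
                         "mean": mean, "sd": sd})
        for col in binary:
            prop = float((w * records[col].to_numpy(dtype=float)).sum() / w.sum())
            rows.append({"variable": col, "kind": "binary",
                         "mean": prop, "sd": float("nan")})
        cmean = compositional_mean(comp, weights=w, total=DAY_MINUTES,
                                   part_names=tuple(c.removesuffix("_min") for c in composition_cols))
        profiles.append(TypologyProfile(
            label=f"class{k + 1}",
            share=float(w.sum() / n),
            compositional_mean=cmean,
            weighted_stats=pd.DataFrame(rows) if rows else None,
        ))
    return profiles


def label_profiles(profiles: list[TypologyProfile]) -> list[TypologyProfile]:
    """Order by compositional-mean MVPA (descending) and attach bee labels.

    Highest MVPA -> Workers; lowest -> Queens; the middle class of a 3-class
    solution -> Drones.  More than three classes get ordinal labels.  Exact
    MVPA ties break by LPA, descending.
    """
    key = [(-p.compositional_mean.values[0], -p.compositional_mean.values[1])
           for p in profiles]
    order = sorted(range(len(profiles)), key=lambda i: key[i])
    K = len(profiles)
    if K == 1:
        names = ["Workers"]
    elif K == 2:
        names = ["Workers", "Queens"]
    elif K == 3:
        names = ["Workers", "Drones", "Queens"]
    else:
        names = [f"Class{i + 1}" for i in range(K)]
    out = []
    for name, idx in zip(names, order):
        p = profiles[idx]
        out.append(TypologyProfile(name, p.share, p.compositional_mean,
                                   p.weighted_stats))
    return out


def class_difference_table(profiles: list[TypologyProfile]) -> pd.DataFrame:
    """Pairwise differences of compositional means, minutes/day, 0.1 rounding."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    rows = []
    for i, a in enumerate(profiles):
        for j, b in enumerate(profiles):
            if i == j:
                continue
            diff = a.compositional_mean.values - b.compositional_mean.values
            for part, dval in zip(a.compositional_mean.part_names, diff):
                rows.append({
                    "behaviour": part,
                    "profile": a.label,
                    "versus": b.label,
                    "difference_min": round(float(dval), 1),
                })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SelectionResult:
    K: int
    rationale: tuple[str, ...]


def select_model(
    fits: dict[int, FitDiagnostics],
    min_class_share: float = 0.10,
    use_vlmr_gate: bool = False,
    vlmr_alpha: float = 0.05,
) -> SelectionResult:
    """Choose K: drop candidates with a class under ``min_class_share``, then
    take the lowest BIC; optionally require VLMR p < alpha to prefer K over
    K-1 (off by default — substantive interpretability can override the test,
    so the gate is a configurable sensitivity switch, not a hard rule).
    """
    if not fits:
        raise ValueError("no fitted models supplied")
    notes = []
    candidates = {}
    for K in sorted(fits):
        diag = fits[K]
        if K > 1 and diag.min_class_share < min_class_share:
            notes.append(
                f"K={K} excluded: smallest class {diag.min_class_share:.1%}"
                f" < {min_class_share:.0%}"
            )
            continue
        if use_vlmr_gate and K > min(fits) and diag.vlmr_p is not None \
                and diag.vlmr_p >= vlmr_alpha:
            notes.append(f"K={K} excluded: VLMR p={diag.vlmr_p:.3f} >= {vlmr_alpha}")
            continue
        candidates[K] = diag
    if not candidates:
        raise RuntimeError("no candidate model passes the selection rules; " +
                           "; ".join(notes))
    chosen = min(candidates, key=lambda K: candidates[K].bic)
    notes.append(f"K={chosen} selected: lowest BIC "
                 f"({candidates[chosen].bic:.1f}) among passing candidates")
    return SelectionResult(chosen, tuple(notes))
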