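"""Robust multivariate outlier detection in ilr space, plus assignment
agreement between sensitivity fits.

Outlying compositions can destabilise a mixture fit, so subjects whose ilr
coordinates have a large robust Mahalanobis distance — location and scatter
from the minimum covariance determinant (MCD) estimator — are flagged and
excluded before fitting.  Agreement between typology assignments from two
fits (e.g. with and without outliers) is summarised by Cohen's kappa after a
maximum-agreement relabelling, since mixture class labels are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.covariance import MinCovDet
from sklearn.metrics import cohen_kappa_score

__all__ = ["OutlierReport", "detect_outliers", "compare_assignments"]


@dataclass(frozen=True)
class OutlierReport:
    robust_distances: np.ndarray
    threshold: float
    flags: np.ndarray
    n_flagged: int


def detect_outliers(
    z_matrix: np.ndarray,
    quantile: float = 0.975,
    support_fraction: float = 0.75,
    seed: int = 0,
) -> OutlierReport:
    """Flag points whose MCD-based robust distance exceeds the chi-square cut.

    The threshold is sqrt(chi2_{D-1}(quantile)); with the default 0.975
    quantile in 3 dimensions that is sqrt(9.3484) = 3.0575.
    """
    Z = np.asarray(z_matrix, dtype=float)
    if Z.ndim != 2:
        raise ValueError("z_matrix must be 2-dimensional")
    n, d = Z.shape
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    if n <= 5 * d:
        raise ValueError(f"need n > 5*d = {5 * d} points, got {n}")
    if np.linalg.matrix_rank(Z - Z.mean(axis=0)) < d:
        raise ValueError("degenerate data: coordinates lie in a lower-dimensional subspace")
    mcd = MinCovDet(support_fraction=support_fraction, random_state=seed).fit(Z)
    if np.linalg.cond(mcd.covariance_) > 1e12:
        raise ValueError("degenerate data: robust scatter is singular")
    dist = np.sqrt(mcd.mahalanobis(Z))
    threshold = float(np.sqrt(stats.chi2.ppf(quantile, df=d)))
    flags = dist > threshold
    return OutlierReport(dist, threshold, flags, int(flags.sum()))


def compare_assignments(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Cohen's kappa after matching label names by maximum agreement.

    Class labels from two mixture fits are only identified up to permutation;
    the Hungarian algorithm finds the relabelling of ``labels_b`` that
    maximises agreement before kappa is computed.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-d and of equal length")
    cats_a = np.unique(a)
    cats_b = np.unique(b)
    k = max(len(cats_a), len(cats_b))
    ia = np.searchsorted(cats_a, a)
    ib = np.searchsorted(cats_b, b)
    contingency = np.zeros((k, k))
    np.add.at(contingency, (ia, ib), 1)
    _, col = linear_sum_assignment(-contingency)
    remap = np.empty(k, dtype=int)
    remap[col] = np.arange(k)
    return float(cohen_kappa_score(ia, remap[ib]))
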