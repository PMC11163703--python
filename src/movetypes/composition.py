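"""Compositional representation of 24-hour time use.

A day split into MVPA, LPA, SB and sleep carries only relative information:
the four parts are constrained to sum to 1440 minutes, so the natural sample
space is the simplex, not R^4.  This module provides the closure operation,
orthonormal isometric log-ratio (ilr) coordinates that map a D-part
composition to unconstrained R^(D-1), the inverse map, and geometric-mean
(compositional) summaries.  All downstream modelling operates on ilr
coordinates; different orthonormal ilr bases are mutual rotations of each
other, so likelihood-based results are basis-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_PARTS",
    "DAY_MINUTES",
    "Composition",
    "IlrBasis",
    "IlrCoordinates",
    "ZeroPartError",
    "close",
    "build_basis",
    "rotate_basis",
    "ilr_transform",
    "ilr_inverse",
    "ilr_matrix",
    "ilr_inverse_matrix",
    "compositional_mean",
]

DEFAULT_PARTS: tuple[str, ...] = ("mvpa", "lpa", "sb", "sleep")
DAY_MINUTES: float = 1440.0


class ZeroPartError(ValueError):
    """A compositional part is zero or negative.

    Compositions carry ratio information only, so a non-positive part has no
    log-ratio image.  No zero replacement is attempted here: upstream daily
    aggregation is responsible for producing strictly positive parts, and a
    zero reaching this module indicates a data problem worth failing on.
    """


@dataclass(frozen=True)
class Composition:
    """A strictly positive D-part vector closing to ``total`` (minutes/day)."""

    values: np.ndarray
    part_names: tuple[str, ...] = DEFAULT_PARTS
    total: float = DAY_MINUTES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "part_names", tuple(self.part_names))
        if values.ndim != 1 or values.size != len(self.part_names):
            raise ValueError(
                f"expected {len(self.part_names)} parts, got shape {values.shape}"
            )
        if values.size < 2:
            raise ValueError("a composition needs at least 2 parts")
        if np.any(values <= 0):
            bad = [n for n, v in zip(self.part_names, values) if v <= 0]
            raise ZeroPartError(f"non-positive part(s): {', '.join(bad)}")
        if not np.isclose(values.sum(), self.total, rtol=1e-6):
            raise ValueError(
                f"parts sum to {values.sum():.6f}, expected total {self.total}"
            )

    @property
    def D(self) -> int:
        return self.values.size

    @property
    def proportions(self) -> np.ndarray:
        return self.values / self.total

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.part_names, self.values))


def close(
    raw: Sequence[float] | np.ndarray,
    total: float = DAY_MINUTES,
    part_names: tuple[str, ...] = DEFAULT_PARTS,
) -> Composition:
    """Rescale a strictly positive vector so its parts sum to ``total``."""
    raw = np.asarray(raw, dtype=float)
    if total <= 0:
        raise ValueError("total must be positive")
    if np.any(raw <= 0):
        bad = [n for n, v in zip(part_names, raw) if v <= 0]
        raise ZeroPartError(f"non-positive part(s): {', '.join(bad)}")
    return Composition(raw * (total / raw.sum()), part_names, total)


@dataclass(frozen=True)
class IlrBasis:
    """Orthonormal zero-sum contrast matrix defining an ilr coordinate system.

    ``contrast_matrix`` is D x (D-1); its columns are orthonormal and each sums
    to zero, so z = V^T ln(x) is invariant to the closure constant of x.
    """

    contrast_matrix: np.ndarray
    part_names: tuple[str, ...] = DEFAULT_PARTS
    name: str = "pivot"

    def __post_init__(self) -> None:
        V = np.asarray(self.contrast_matrix, dtype=float)
        object.__setattr__(self, "contrast_matrix", V)
        object.__setattr__(self, "part_names", tuple(self.part_names))
        D = V.shape[0]
        if V.shape != (D, D - 1):
            raise ValueError(f"contrast matrix must be D x (D-1), got {V.shape}")
        if not np.allclose(V.T @ V, np.eye(D - 1), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")
        if not np.allclose(V.sum(axis=0), 0.0, atol=1e-10):
            raise ValueError("basis columns must each sum to zero")

    @property
    def D(self) -> int:
        return self.contrast_matrix.shape[0]


@dataclass(frozen=True)
class IlrCoordinates:
    """The R^(D-1) image of one composition under a given basis."""

    values: np.ndarray
    basis: IlrBasis

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.basis.D - 1,):
            raise ValueError("coordinate length must be D-1")
        if not np.all(np.isfinite(values)):
            raise ValueError("ilr coordinates must be finite")


def build_basis(
    D: int | None = None,
    scheme: str = "pivot",
    part_names: tuple[str, ...] | None = None,
) -> IlrBasis:
    """Build the pivot ilr basis for D parts.

    Pivot coordinates contrast each part against the geometric mean of the
    parts after it: z_j = sqrt((D-j)/(D-j+1)) * ln(x_j / gmean(x_{j+1..D})).
    With part order (MVPA, LPA, SB, sleep), z_1 is MVPA against everything
    else, z_2 is LPA against SB and sleep, z_3 is SB against sleep.
    """
    if scheme != "pivot":
        raise ValueError(f"unknown basis scheme: {scheme!r}")
    if part_names is None:
        part_names = DEFAULT_PARTS if D in (None, 4) else tuple(
            f"part{i + 1}" for i in range(D)
        )
    if D is None:
        D = len(part_names)
    if D < 2:
        raise ValueError("D must be >= 2")
    if len(part_names) != D:
        raise ValueError("part_names length must equal D")
    V = np.zeros((D, D - 1))
    for j in range(D - 1):
        r = D - j - 1  # parts after the pivot
        a = np.sqrt(r / (r + 1.0))
        V[j, j] = a
        V[j + 1 :, j] = -a / r
    return IlrBasis(V, part_names, name="pivot")


def rotate_basis(basis: IlrBasis, Q: np.ndarray, name: str = "rotated") -> IlrBasis:
    """Another orthonormal basis V @ Q, with Q an orthogonal (D-1)x(D-1) map."""
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q @ Q.T, np.eye(Q.shape[0]), atol=1e-10):
        raise ValueError("Q must be orthogonal")
    return IlrBasis(basis.contrast_matrix @ Q, basis.part_names, name=name)


def ilr_transform(x: Composition, basis: IlrBasis | None = None) -> IlrCoordinates:
    if basis is None:
        basis = build_basis(x.D, part_names=x.part_names)
    if basis.D != x.D:
        raise ValueError(f"basis is for D={basis.D}, composition has D={x.D}")
    z = basis.contrast_matrix.T @ np.log(x.proportions)
    return IlrCoordinates(z, basis)


def ilr_inverse(
    z: IlrCoordinates | np.ndarray,
    basis: IlrBasis | None = None,
    total: float = DAY_MINUTES,
) -> Composition:
    if isinstance(z, IlrCoordinates):
        basis = z.basis
        z = z.values
    if basis is None:
        raise ValueError("a basis is required when z is a bare vector")
    logx = basis.contrast_matrix @ np.asarray(z, dtype=float)
    x = np.exp(logx - logx.max())  # guard overflow; closure removes the shift
    return close(x, total=total, part_names=basis.part_names)


def ilr_matrix(X: np.ndarray, basis: IlrBasis) -> np.ndarray:
    """Row-wise ilr of an n x D matrix of positive parts (any closure)."""
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ZeroPartError("all parts must be strictly positive")
    return np.log(X) @ basis.contrast_matrix


def ilr_inverse_matrix(
    Z: np.ndarray, basis: IlrBasis, total: float = DAY_MINUTES
) -> np.ndarray:
    """Row-wise inverse ilr of an n x (D-1) matrix, closed to ``total``."""
    Z = np.asarray(Z, dtype=float)
    logx = Z @ basis.contrast_matrix.T
    x = np.exp(logx - logx.max(axis=1, keepdims=True))
    return x * (total / x.sum(axis=1, keepdims=True))


def compositional_mean(
    xs: Iterable[Composition] | np.ndarray,
    weights: Sequence[float] | None = None,
    total: float | None = None,
    part_names: tuple[str, ...] | None = None,
) -> Composition:
    """Per-part (weighted) geometric mean, re-closed.

    Equals the ilr-inverse of the (weighted) arithmetic mean of the ilr
    coordinates, which is how class profile means are computed downstream.
    """
    if isinstance(xs, np.ndarray):
        X = np.asarray(xs, dtype=float)
        if part_names is None:
            part_names = DEFAULT_PARTS if X.shape[1] == 4 else tuple(
                f"part{i + 1}" for i in range(X.shape[1])
            )
        if total is None:
            total = DAY_MINUTES
    else:
        xs = list(xs)
        if not xs:
            raise ValueError("empty collection of compositions")
        X = np.vstack([x.values for x in xs])
        part_names = xs[0].part_names
        if total is None:
            total = xs[0].total
    if X.shape[0] == 0:
        raise ValueError("empty collection of compositions")
    if np.any(X <= 0):
        raise ZeroPartError("all parts must be strictly positive")
    if weights is None:
        w = np.ones(X.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (X.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    logmean = (w[:, None] * np.log(X)).sum(axis=0) / w.sum()
    return close(np.exp(logmean), total=total, part_names=part_names)
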