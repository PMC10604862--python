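"""Regularized canonical correlation analysis via SVD of the whitened
cross-covariance.

Given row-aligned views ``X`` (n x d1) and ``Y`` (n x d2), both standardized
to zero mean and unit variance, CCA finds direction pairs ``(a_i, b_i)``
maximizing ``corr(X a_i, Y b_i)`` subject to unit variance of each variate
and mutual uncorrelatedness with earlier pairs.  The solution used here:

1. covariances ``Sxx``, ``Syy``, ``Sxy`` (sample, n-1 denominator), with an
   optional ridge ``Sxx + eps * tr(Sxx)/d1 * I`` for conditioning;
2. symmetric-eigendecomposition inverse square roots ``Sxx^{-1/2}``,
   ``Syy^{-1/2}``;
3. thin SVD of the whitened cross-covariance
   ``M = Sxx^{-1/2} Sxy Syy^{-1/2} = U S V^T``;
4. projections ``A = Sxx^{-1/2} U``, ``B = Syy^{-1/2} V``; the canonical
   correlations are the singular values ``diag(S)``, descending.

The ridge defaults to ``1e-6`` (scaled by the mean covariance diagonal)
because EEG feature blocks of 60-62 channels fitted on a few hundred epochs
can produce ill-conditioned covariance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import linalg

__all__ = [
    "CCAModel",
    "standardize",
    "apply_standardization",
    "fit_cca",
    "canonical_transform",
    "max_canonical_correlation",
    "save_cca_h5",
    "load_cca_h5",
]

DEFAULT_RIDGE = 1e-6
_EIG_FLOOR = 1e-12


@dataclass
class CCAModel:
    """Fitted CCA: standardization offsets/scales, whitening, SVD factors,
    projection matrices ``A``/``B`` and the canonical-correlation spectrum
    ``rho`` (descending)."""

    mean_x: np.ndarray
    mean_y: np.ndarray
    scale_x: np.ndarray
    scale_y: np.ndarray
    Sxx: np.ndarray
    Syy: np.ndarray
    Sxy: np.ndarray
    Wxx: np.ndarray  # Sxx^{-1/2} (post-ridge)
    Wyy: np.ndarray  # Syy^{-1/2}
    M: np.ndarray
    U: np.ndarray
    V: np.ndarray
    A: np.ndarray
    B: np.ndarray
    rho: np.ndarray
    ridge: float

    @property
    def n_components(self) -> int:
        return len(self.rho)

    @property
    def dim_x(self) -> int:
        return len(self.mean_x)

    @property
    def dim_y(self) -> int:
        return len(self.mean_y)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise zero-mean unit-variance scaling; returns (Z, offsets, scales).

    Scales use the sample (n-1) standard deviation so they match the sample
    covariances used downstream.  Constant columns are an error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardize requires a 2-D matrix with n >= 2 rows")
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at index {bad.tolist()}: cannot standardize")
    return (X - mean) / scale, mean, scale


def apply_standardization(X: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - mean) / scale


def _inv_sqrt_sym(S: np.ndarray, ridged: bool) -> np.ndarray:
    """Inverse square root of a symmetric PSD matrix by eigendecomposition.

    Eigenvalues below ``1e-12 * lambda_max`` are clipped to the floor; on the
    unregularized path that clipping is reported as a warning because it
    silently regularizes a singular covariance.
    """
    w, Q = linalg.eigh(S)
    lam_max = float(w[-1])
    if lam_max <= 0:
        raise ValueError("covariance matrix is not positive semi-definite")
    floor = _EIG_FLOOR * lam_max
    below = w < floor
    if below.any() and not ridged:
        warnings.warn(
            "covariance numerically singular; eigenvalues clipped "
            "(consider a nonzero ridge)",
            RuntimeWarning,
            stacklevel=3,
        )
    w = np.maximum(w, floor)
    return (Q / np.sqrt(w)) @ Q.T


def fit_cca(
    X: np.ndarray,
    Y: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
    k: int | str = "all",
) -> CCAModel:
    """Fit CCA between row-aligned views X (n x d1) and Y (n x d2).

    ``ridge`` adds ``ridge * mean(diag(S)) * I`` to each view's covariance
    before whitening.  ``k`` retains the leading components (default all,
    i.e. ``min(d1, d2)``).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with the same number of rows")
    if X.shape[0] < 2:
        raise ValueError("CCA requires at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in input")
    if ridge < 0:
        raise ValueError("ridge must be non-negative")

    Xs, mean_x, scale_x = standardize(X)
    Ys, mean_y, scale_y = standardize(Y)
    n = X.shape[0]

    Sxx = (Xs.T @ Xs) / (n - 1)
    Syy = (Ys.T @ Ys) / (n - 1)
    Sxy = (Xs.T @ Ys) / (n - 1)

    if ridge > 0:
        Sxx_r = Sxx + ridge * np.mean(np.diag(Sxx)) * np.eye(Sxx.shape[0])
        Syy_r = Syy + ridge * np.mean(np.diag(Syy)) * np.eye(Syy.shape[0])
    else:
        Sxx_r, Syy_r = Sxx, Syy

    Wxx = _inv_sqrt_sym(Sxx_r, ridged=ridge > 0)
    Wyy = _inv_sqrt_sym(Syy_r, ridged=ridge > 0)

    M = Wxx @ Sxy @ Wyy
    U, s, Vt = linalg.svd(M, full_matrices=False)
    V = Vt.T

    # SVD signs are arbitrary: flip each (u_i, v_i) pair jointly so the
    # largest-|.| element of u_i is positive; joint flips keep rho >= 0.
    for i in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]

    n_comp = min(X.shape[1], Y.shape[1])
    if k != "all":
        k = int(k)
        if not (1 <= k <= n_comp):
            raise ValueError(f"k must be in [1, {n_comp}], got {k}")
        n_comp = k
    U, V, s = U[:, :n_comp], V[:, :n_comp], s[:n_comp]

    A = Wxx @ U
    B = Wyy @ V

    return CCAModel(
        mean_x=mean_x, mean_y=mean_y, scale_x=scale_x, scale_y=scale_y,
        Sxx=Sxx, Syy=Syy, Sxy=Sxy, Wxx=Wxx, Wyy=Wyy, M=M,
        U=U, V=V, A=A, B=B, rho=np.clip(s, 0.0, None), ridge=float(ridge),
    )


def canonical_transform(
    model: CCAModel,
    X: np.ndarray | None = None,
    Y: np.ndarray | None = None,
    k: int | None = None,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Project (new) data onto the canonical variates.

    Standardization uses the offsets/scales stored at fit time, so held-out
    epochs are mapped without re-estimating anything.  Returns ``(X', Y')``;
    a view passed as None yields None.  ``k=0`` returns empty matrices.
    """
    if k is None:
        k = model.n_components
    if not (0 <= k <= model.n_components):
        raise ValueError(f"k must be in [0, {model.n_components}]")

    def _proj(Z, mean, scale, P, dim):
        if Z is None:
            return None
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != dim:
            raise ValueError(f"expected {dim} columns, got shape {Z.shape}")
        return apply_standardization(Z, mean, scale) @ P[:, :k]

    return (
        _proj(X, model.mean_x, model.scale_x, model.A, model.dim_x),
        _proj(Y, model.mean_y, model.scale_y, model.B, model.dim_y),
    )


def max_canonical_correlation(model: CCAModel) -> float:
    """The leading canonical correlation (largest singular value of M)."""
    return float(model.rho[0])


_H5_FIELDS = (
    "mean_x", "mean_y", "scale_x", "scale_y", "Sxx", "Syy", "Sxy",
    "Wxx", "Wyy", "M", "U", "V", "A", "B", "rho",
)


def save_cca_h5(model: CCAModel, target: str | h5py.Group) -> None:
    """Serialize all model fields to an HDF5 file or group (bit-stable)."""
    if isinstance(target, (str, bytes)):
        with h5py.File(target, "w") as f:
            save_cca_h5(model, f)
        return
    for name in _H5_FIELDS:
        target.create_dataset(name, data=getattr(model, name))
    target.attrs["ridge"] = model.ridge


def load_cca_h5(source: str | h5py.Group) -> CCAModel:
    if isinstance(source, (str, bytes)):
        with h5py.File(source, "r") as f:
            return load_cca_h5(f)
    kw = {name: source[name][()] for name in _H5_FIELDS}
    return CCAModel(ridge=float(source.attrs["ridge"]), **kw)
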