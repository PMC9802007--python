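"""Log-linear diffusion tensor fit and the voxel-selection rules used to
pick single-fibre, consistent-S0 voxels for the high b-value fit.

The tensor fit supplies the fibre orientation V1 (primary eigenvector)
that the dispersed-stick model holds fixed; it is intended for the low-b
portion of an acquisition (b <= 1 ms/um^2).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .noise import VoxelDataset
from .scheme import AcquisitionScheme

__all__ = ["DiffusionTensor", "dti_fit", "fa_from_eigenvalues", "select_voxels"]


def fa_from_eigenvalues(evals):
    """Fractional anisotropy from tensor eigenvalues (textbook form)."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - md) ** 2, axis=-1)
    den = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, np.clip(fa, 0.0, 1.0), 0.0)


def _design_matrix(scheme: AcquisitionScheme):
    b, g = scheme.b, scheme.g
    return np.column_stack(
        [
            np.ones(len(b)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ]
    )


class DiffusionTensor(BaseEstimator):
    """Log-linear least-squares diffusion tensor estimator.

    fit(X, y): X is the (n_volumes, 4) design [b, gx, gy, gz] (or an
    AcquisitionScheme) restricted to low b; y is one signal vector or an
    (n_voxels, n_volumes) array.

    Attributes
    ----------
    tensor_ : (n_voxels, 3, 3) fitted tensors (um^2/ms)
    evals_ : (n_voxels, 3) eigenvalues, descending
    V1_ : (n_voxels, 3) primary eigenvector (unit, sign arbitrary)
    fa_ : (n_voxels,) fractional anisotropy in [0, 1]
    s0_ : (n_voxels,) extrapolated b=0 signal
    """

    def __init__(self, max_b: float = 1.0):
        self.max_b = max_b

    def fit(self, X, y):
        scheme = X if isinstance(X, AcquisitionScheme) else AcquisitionScheme.from_array(X)
        keep = scheme.b <= self.max_b + 1e-9
        scheme = scheme.subset(keep)
        Y = np.atleast_2d(np.asarray(y, dtype=float))[:, keep]
        if len(scheme) < 7:
            raise ValueError("tensor fit needs >= 7 volumes (6 directions + b0)")
        A = _design_matrix(scheme)
        if np.linalg.matrix_rank(A) < 7:
            raise ValueError("rank-deficient tensor design (too few distinct directions)")
        n_vox = Y.shape[0]
        tensors = np.empty((n_vox, 3, 3))
        s0 = np.empty(n_vox)
        for v in range(n_vox):
            pos = Y[v] > 0
            if pos.sum() < 7 or np.linalg.matrix_rank(A[pos]) < 7:
                raise ValueError("too few positive signals for the log-linear fit")
            coef, *_ = np.linalg.lstsq(A[pos], np.log(Y[v, pos]), rcond=None)
            s0[v] = np.exp(coef[0])
            dxx, dyy, dzz, dxy, dxz, dyz = coef[1:]
            tensors[v] = [[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]]
        evals, evecs = np.linalg.eigh(tensors)
        order = np.argsort(evals, axis=1)[:, ::-1]
        self.evals_ = np.take_along_axis(evals, order, axis=1)
        self.V1_ = np.stack(
            [evecs[v][:, order[v, 0]] for v in range(n_vox)], axis=0
        )
        self.tensor_ = tensors
        self.fa_ = fa_from_eigenvalues(self.evals_)
        self.s0_ = s0
        return self

    def predict(self, X):
        """Model signal at the fitted tensor(s) for design X."""
        scheme = X if isinstance(X, AcquisitionScheme) else AcquisitionScheme.from_array(X)
        A = _design_matrix(scheme)
        out = np.empty((len(self.s0_), len(scheme)))
        for v in range(len(self.s0_)):
            D = self.tensor_[v]
            coef = np.array(
                [np.log(self.s0_[v]), D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]]
            )
            out[v] = np.exp(A @ coef)
        return out[0] if out.shape[0] == 1 else out


def dti_fit(dataset: VoxelDataset, max_b: float = 1.0):
    """Fit the diffusion tensor to the low-b volumes of a dataset.

    Returns (tensor, V1, FA) arrays, one row per voxel.
    """
    est = DiffusionTensor(max_b=max_b).fit(dataset.scheme, dataset.Y)
    return est.tensor_, est.V1_, est.fa_


def select_voxels(fa, s0, mask, fa_threshold: float = 0.7, s0_band: float = 0.1):
    """Indices of single-fibre-like voxels with consistent S0.

    Keeps voxels inside ``mask`` with FA above ``fa_threshold`` and S0
    within +-``s0_band`` (closed interval) of the masked-region mean S0.
    Returned indices are sorted ascending (deterministic).

    Raises
    ------
    ValueError if the mask is empty; returns an empty array (distinct
    outcome) if the mask is non-empty but no voxel passes.
    """
    fa = np.asarray(fa, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if fa.shape != s0.shape or fa.shape != mask.shape:
        raise ValueError("fa, s0 and mask must have matching shapes")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    mean_s0 = s0[mask].mean()
    tol = s0_band * mean_s0 + 1e-12  # closed interval at the band edge
    keep = mask & (fa > fa_threshold) & (np.abs(s0 - mean_s0) <= tol)
    return np.sort(np.flatnonzero(keep))
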