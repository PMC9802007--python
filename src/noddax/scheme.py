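"""Multi-shell acquisition schemes and FSL-style gradient-table IO.

Unit convention used throughout the package: b-values in ms/um^2 and
diffusivities in um^2/ms, so that b*d is dimensionless.  FSL files often
carry b in s/mm^2 (1000x larger); the readers accept either with an
explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "read_bvals_bvecs", "write_bvals_bvecs", "infer_shells"]


def infer_shells(b, tol: float = 0.1):
    """Group b-values into shells by rounding within ``tol`` (ms/um^2).

    Returns an integer shell id per volume; shell 0 is the lowest-b shell.
    """
    b = np.asarray(b, dtype=float)
    order = np.argsort(b)
    shell_id = np.empty(len(b), dtype=int)
    current = 0
    last = None
    for idx in order:
        if last is not None and b[idx] - last > tol:
            current += 1
        shell_id[idx] = current
        last = b[idx]
    return shell_id


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion acquisition: per-volume b-value, gradient direction, shell.

    Parameters
    ----------
    b : (n,) array
        Diffusion weighting in ms/um^2, all >= 0.
    g : (n, 3) array
        Gradient directions; unit norm (1e-6) wherever b > 0.
    shell_id : (n,) int array, optional
        Shell label per volume; inferred from b if omitted.  All volumes
        sharing a shell id must have equal b (1e-9).
    delta_small, delta_big : float, optional
        Pulse duration / separation in ms.  Metadata only; the signal
        models in this package are diffusion-time independent.
    """

    b: np.ndarray
    g: np.ndarray
    shell_id: np.ndarray = None
    delta_small: float | None = None
    delta_big: float | None = None
    shell_tol: float = field(default=0.1, repr=False)

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        g = np.asarray(self.g, dtype=float)
        if g.shape != (len(b), 3):
            raise ValueError("g must have shape (n_volumes, 3)")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        dwi = b > 0
        norms = np.linalg.norm(g[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit norm where b > 0")
        if self.shell_id is None:
            sid = infer_shells(b, tol=self.shell_tol)
        else:
            sid = np.asarray(self.shell_id, dtype=int)
            if sid.shape != b.shape:
                raise ValueError("shell_id must have one entry per volume")
        for s in np.unique(sid):
            bs = b[sid == s]
            if np.ptp(bs) > 1e-9:
                raise ValueError(f"volumes in shell {s} have unequal b-values")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "shell_id", sid)

    def __len__(self):
        return len(self.b)

    @property
    def shells(self):
        """Sorted unique shell ids."""
        return np.unique(self.shell_id)

    @property
    def shell_b(self):
        """Representative b-value per shell id, as a dict."""
        return {int(s): float(self.b[self.shell_id == s][0]) for s in self.shells}

    def shell_mask(self, shell):
        return self.shell_id == shell

    @property
    def weighted(self):
        """Boolean mask of diffusion-weighted (b > 0) volumes."""
        return self.b > 0

    def subset(self, mask):
        """Scheme restricted to the volumes selected by ``mask``."""
        mask = np.asarray(mask)
        return AcquisitionScheme(
            b=self.b[mask],
            g=self.g[mask],
            shell_id=self.shell_id[mask],
            delta_small=self.delta_small,
            delta_big=self.delta_big,
        )

    def with_directions(self, g):
        """Same weighting/shell structure with replaced directions."""
        return AcquisitionScheme(
            b=self.b.copy(),
            g=np.asarray(g, dtype=float),
            shell_id=self.shell_id.copy(),
            delta_small=self.delta_small,
            delta_big=self.delta_big,
        )

    def as_array(self):
        """(n, 4) design array [b, gx, gy, gz] (estimator input format)."""
        return np.column_stack([self.b, self.g])

    @classmethod
    def from_array(cls, X, shell_tol: float = 0.1):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("design array must have shape (n_volumes, 4)")
        return cls(b=X[:, 0], g=X[:, 1:4], shell_tol=shell_tol)


def read_bvals_bvecs(bvals_path, bvecs_path, units: str = "ms/um^2", shell_tol: float = 0.1):
    """Read FSL-style bvals (one row) and bvecs (three rows) text files.

    Parameters
    ----------
    units : {"ms/um^2", "s/mm^2"}
        Units of the bvals file; "s/mm^2" values are divided by 1000.
    """
    b = np.loadtxt(bvals_path, ndmin=1, dtype=float).ravel()
    if units == "s/mm^2":
        b = b / 1000.0
    elif units != "ms/um^2":
        raise ValueError(f"unknown b-value units {units!r}")
    g = np.loadtxt(bvecs_path, ndmin=2, dtype=float)
    if g.shape[0] == 3:
        g = g.T
    if g.shape != (len(b), 3):
        raise ValueError("bvecs shape does not match bvals length")
    # FSL writes zero vectors for b=0 volumes; normalise the rest.
    norms = np.linalg.norm(g, axis=1)
    nz = norms > 0
    g = g.copy()
    g[nz] /= norms[nz, None]
    return AcquisitionScheme(b=b, g=g, shell_tol=shell_tol)


def write_bvals_bvecs(scheme: AcquisitionScheme, bvals_path, bvecs_path, units: str = "ms/um^2"):
    """Write an acquisition scheme as FSL-style bvals/bvecs text files."""
    b = scheme.b
    if units == "s/mm^2":
        b = b * 1000.0
    elif units != "ms/um^2":
        raise ValueError(f"unknown b-value units {units!r}")
    g = np.where(scheme.weighted[:, None], scheme.g, 0.0)
    np.savetxt(bvals_path, b[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, g.T, fmt="%.8f")
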