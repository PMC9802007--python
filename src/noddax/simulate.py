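"""Synthetic high b-value diffusion data with controlled noise structure.

The generator emulates a Connectom-style high-b protocol: three shells at
b = 6.75, 9.85 and 13.5 ms/um^2 with 64 directions each plus interspersed
b=0 volumes.  Ground truth defaults are d_par = 2.2 um^2/ms, ODI = 0.03,
f_in = 0.6 and a signal offset c = 10 at S0 = 100 (only S0/sigma matters;
c = 10 is then 10% of S0).  Per-voxel SNR is SNR_vox = S0/sigma = 16.5.

Noise enters the complex signal: both quadratures receive independent
Gaussian noise of std sigma.  The magnitude channel |z| is then Rician
while the real channel (assuming perfect background-phase removal) is
Gaussian — both extracted from the *same* complex draws so that
real/magnitude comparisons are paired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .noise import VoxelDataset
from .scheme import AcquisitionScheme
from .signal import DispersionIndex, FibreOrientation, WatsonStickParams, predict_signal_full

__all__ = [
    "SimulationConfig",
    "fibonacci_directions",
    "make_scheme",
    "simulate_voxels",
    "simulate_pure_noise",
    "average_voxels",
    "concatenate_with_rotation",
]

_DEFAULT_SHELLS = (6.75, 9.85, 13.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiments."""

    d_par: float = 2.2
    odi: float = 0.03
    f_in: float = 0.6
    c: float = 10.0
    s0: float = 100.0
    snr_vox: float = 16.5
    shells: tuple = _DEFAULT_SHELLS
    n_directions: int = 64
    n_b0: int = 6
    n_voxels: int = 1
    theta: float = 0.0
    phi: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.snr_vox <= 0:
            raise ValueError("snr_vox must be positive")
        if len(self.shells) == 0:
            raise ValueError("at least one shell required")

    @property
    def sigma(self):
        """Std of the Gaussian noise in each complex channel."""
        return self.s0 / self.snr_vox

    @property
    def ground_truth(self) -> WatsonStickParams:
        return WatsonStickParams(
            dispersion=DispersionIndex.from_odi(self.odi),
            d_par=self.d_par,
            orientation=FibreOrientation(self.theta, self.phi),
            F=self.f_in * self.s0,
        )

    def to_json(self):
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["shells"] = list(d["shells"])
        return json.dumps(d, sort_keys=True)


def fibonacci_directions(n: int, rng=None):
    """~Uniform directions on the sphere by the spherical Fibonacci
    lattice, optionally with a random global rotation."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    g = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if rng is not None:
        g = g @ Rotation.random(random_state=rng).as_matrix().T
    return g


def make_scheme(config: SimulationConfig) -> AcquisitionScheme:
    """Build the simulated acquisition: n_b0 b=0 volumes followed by the
    high-b shells, each with an independently rotated Fibonacci lattice.
    Deterministic for a given config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xD1F]))
    b = [np.zeros(config.n_b0)]
    g = [np.tile([0.0, 0.0, 1.0], (config.n_b0, 1))]
    for bval in config.shells:
        b.append(np.full(config.n_directions, float(bval)))
        g.append(fibonacci_directions(config.n_directions, rng))
    return AcquisitionScheme(b=np.concatenate(b), g=np.vstack(g))


def _noiseless_signal(config: SimulationConfig, scheme: AcquisitionScheme):
    """Noise-free measured signal before offset: S0 at b=0 (all water
    contributes), dispersed-stick intra-axonal signal at high b."""
    s = predict_signal_full(config.ground_truth, scheme)
    s[~scheme.weighted] = config.s0
    return s


def simulate_voxels(config: SimulationConfig, scheme: AcquisitionScheme | None = None):
    """Simulate paired real-valued and magnitude datasets.

    Complex noise z = (S + c) + n_re + i n_im with n ~ N(0, sigma^2) is
    drawn once; the magnitude dataset is |z| (Rician) and the real dataset
    Re(z) (Gaussian), so the two share noise draws.

    Returns
    -------
    (real_dataset, magnitude_dataset) : tuple of VoxelDataset
    """
    if scheme is None:
        scheme = make_scheme(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x516]))
    clean = _noiseless_signal(config, scheme) + config.c
    shape = (config.n_voxels, len(scheme))
    re = clean[None, :] + config.sigma * rng.standard_normal(shape)
    im = config.sigma * rng.standard_normal(shape)
    s0 = np.full(config.n_voxels, config.s0)
    mu = config.ground_truth.orientation.mu
    real = VoxelDataset(Y=re, kind="real", S0=s0, scheme=scheme, orientation=mu)
    mag = VoxelDataset(Y=np.hypot(re, im), kind="magnitude", S0=s0, scheme=scheme, orientation=mu)
    return real, mag


def simulate_pure_noise(config: SimulationConfig, n_samples: int, kind: str = "magnitude"):
    """Pure-noise samples (zero diffusion signal, offset + complex noise),
    mimicking ventricle voxels at very high b.  Used to characterise
    (c, eps) a priori."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA11]))
    re = config.c + config.sigma * rng.standard_normal(n_samples)
    if kind == "real":
        return re
    im = config.sigma * rng.standard_normal(n_samples)
    return np.hypot(re, im)


def average_voxels(dataset: VoxelDataset, n: int | None = None) -> VoxelDataset:
    """Average the signal across voxels (they share scheme and fibre
    orientation, so no resampling is needed).  Noise std shrinks by
    sqrt(n).  Note the average of magnitude voxels is *not* the magnitude
    of the averaged complex signal; its Rician floor persists."""
    if dataset.orientation is not None and np.asarray(dataset.orientation).ndim == 2:
        ors = np.asarray(dataset.orientation)
        if np.any(np.abs(np.abs(ors @ ors[0]) - 1.0) > 1e-9):
            raise ValueError("voxels must share a fibre orientation to be averaged")
    n = dataset.n_voxels if n is None else n
    if not 1 <= n <= dataset.n_voxels:
        raise ValueError("n must be between 1 and the number of voxels")
    return VoxelDataset(
        Y=dataset.Y[:n].mean(axis=0, keepdims=True),
        kind=dataset.kind,
        S0=np.array([dataset.S0[:n].mean()]),
        scheme=dataset.scheme,
        orientation=dataset.orientation,
    )


def _rotation_to_z(mu):
    """Rotation matrix mapping unit vector mu onto +z (minimal rotation)."""
    mu = np.asarray(mu, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(mu, z)
    s = np.linalg.norm(v)
    c = float(mu @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1.0 - c) / (s * s))


def concatenate_with_rotation(datasets, orientations, seed: int = 0) -> VoxelDataset:
    """Concatenate voxels after rotating each voxel's *gradient table* so
    its fibre axis maps onto +z with a random azimuthal roll.

    The signals themselves are untouched (no interpolation); only the
    directions are re-expressed in the common frame.  The result is a
    single-voxel dataset whose orientation is +z.
    """
    if len(datasets) != len(orientations):
        raise ValueError("one orientation required per dataset")
    rng = np.random.default_rng(seed)
    kinds = {d.kind for d in datasets}
    if len(kinds) != 1:
        raise ValueError("datasets must share a kind")
    ys, bs, gs, sids = [], [], [], []
    for ds, mu in zip(datasets, orientations):
        mu = np.asarray(mu, dtype=float)
        if abs(np.linalg.norm(mu) - 1.0) > 1e-6:
            raise ValueError("orientations must be unit vectors")
        roll = Rotation.from_euler("z", rng.uniform(0.0, 2.0 * np.pi)).as_matrix()
        R = roll @ _rotation_to_z(mu)
        if ds.n_voxels != 1:
            raise ValueError("concatenate single-voxel datasets (average or index first)")
        ys.append(ds.Y[0])
        bs.append(ds.scheme.b)
        gs.append(ds.scheme.g @ R.T)
        sids.append(ds.scheme.shell_id)
    scheme = AcquisitionScheme(
        b=np.concatenate(bs), g=np.vstack(gs), shell_id=np.concatenate(sids)
    )
    return VoxelDataset(
        Y=np.concatenate(ys)[None, :],
        kind=kinds.pop(),
        S0=np.array([np.mean([ds.S0.mean() for ds in datasets])]),
        scheme=scheme,
        orientation=np.array([0.0, 0.0, 1.0]),
    )
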