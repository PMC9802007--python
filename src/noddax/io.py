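"""Plain-text dataset IO: bvals/bvecs + CSV signal tables, JSON reports.

A dataset written with prefix ``p`` produces ``p.bvals``, ``p.bvecs``
(FSL layout), ``p_signal.csv`` (voxels x volumes, with S0 and kind in a
side-car ``p_meta.json``).  NIfTI export of the signal array is available
when nibabel is installed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .noise import VoxelDataset
from .scheme import read_bvals_bvecs, write_bvals_bvecs

__all__ = ["write_voxel_dataset", "read_voxel_dataset", "write_nifti", "config_hash"]


def config_hash(config_json: str) -> str:
    return hashlib.sha256(config_json.encode()).hexdigest()[:12]


def write_voxel_dataset(dataset: VoxelDataset, prefix, config_json: str | None = None):
    """Write a dataset as bvals/bvecs + signal CSV + JSON metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_bvals_bvecs(dataset.scheme, f"{prefix}.bvals", f"{prefix}.bvecs")
    pd.DataFrame(dataset.Y).to_csv(f"{prefix}_signal.csv", index=False)
    meta = {
        "kind": dataset.kind,
        "S0": dataset.S0.tolist(),
        "orientation": None
        if dataset.orientation is None
        else np.asarray(dataset.orientation).tolist(),
    }
    if config_json is not None:
        meta["config"] = json.loads(config_json)
        meta["config_hash"] = config_hash(config_json)
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def read_voxel_dataset(prefix) -> VoxelDataset:
    prefix = Path(prefix)
    scheme = read_bvals_bvecs(f"{prefix}.bvals", f"{prefix}.bvecs")
    Y = pd.read_csv(f"{prefix}_signal.csv").to_numpy(dtype=float)
    meta = json.loads(Path(f"{prefix}_meta.json").read_text())
    orientation = meta.get("orientation")
    return VoxelDataset(
        Y=Y,
        kind=meta["kind"],
        S0=np.asarray(meta["S0"], dtype=float),
        scheme=scheme,
        orientation=None if orientation is None else np.asarray(orientation, dtype=float),
    )


def write_nifti(dataset: VoxelDataset, path):
    """Optional NIfTI export (voxels laid out along the first axis)."""
    import nibabel as nib

    img = nib.Nifti1Image(
        dataset.Y[:, None, None, :].astype(np.float32), affine=np.eye(4)
    )
    nib.save(img, str(path))
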