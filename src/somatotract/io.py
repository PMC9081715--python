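"""On-disk formats: NIfTI volumes, FSL bval/bvec tables, TrackVis .trk,
model-field stacks with JSON sidecars, and YAML pipeline configs."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import AcquisitionScheme, DwiVolume, FormatError
from .models import ModelField
from .tracking import Streamline, Tractogram

logger = logging.getLogger("somatotract")


# ---------------------------------------------------------------------------
# DWI + gradient tables
# ---------------------------------------------------------------------------

def write_dwi(dwi: DwiVolume, path_nii, path_bval, path_bvec) -> None:
    """Write signal as NIfTI-1 plus FSL-dialect gradient tables.

    bvals: one space-separated row; bvecs: three space-separated rows.
    """
    img = nib.Nifti1Image(dwi.signal.astype(np.float32), dwi.affine)
    nib.save(img, str(path_nii))
    np.savetxt(path_bval, dwi.scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(path_bvec, dwi.scheme.directions.T, fmt="%.8f")


def read_dwi(path_nii, path_bval, path_bvec) -> DwiVolume:
    """Read a 4D NIfTI with its bval/bvec files.

    The affine comes from the NIfTI header; b-values below 50 s/mm^2 are
    treated as b0; non-unit gradient columns are re-normalized with a
    logged warning.
    """
    img = nib.load(str(path_nii))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path_nii}: expected a 4D volume, got {data.ndim}D")
    bvals = np.loadtxt(path_bval, ndmin=1).ravel()
    bvecs = np.loadtxt(path_bvec, ndmin=2)
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:
            bvecs = bvecs.T
        else:
            raise FormatError(f"{path_bvec}: expected 3 rows of directions")
    if len(bvals) != data.shape[3]:
        raise FormatError(
            f"{path_bval}: {len(bvals)} b-values for {data.shape[3]} volumes"
        )
    if bvecs.shape[1] != data.shape[3]:
        raise FormatError(
            f"{path_bvec}: {bvecs.shape[1]} directions for {data.shape[3]} volumes"
        )
    dirs = bvecs.T.copy()
    dwi_rows = bvals >= 50.0
    norms = np.linalg.norm(dirs[dwi_rows], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        logger.warning("%s: non-unit gradient directions re-normalized", path_bvec)
    safe = np.where(norms > 0, norms, 1.0)
    dirs[dwi_rows] = dirs[dwi_rows] / safe[:, None]
    dirs[~dwi_rows] = 0.0
    scheme = AcquisitionScheme(bvals, dirs)
    return DwiVolume(signal=data, affine=img.affine, scheme=scheme)


# ---------------------------------------------------------------------------
# Masks and scalar maps
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine), str(path))


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).astype(np.int16), img.affine


def write_scalar_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# Tractograms (.trk)
# ---------------------------------------------------------------------------

def write_trk(tractogram: Tractogram, path, grid_shape: tuple[int, int, int]) -> None:
    """Write world-space streamlines as TrackVis .trk with a reference header."""
    sls = [sl.points for sl in tractogram]
    t = nib.streamlines.Tractogram(sls, affine_to_rasmm=np.eye(4))
    voxel_sizes = np.linalg.norm(tractogram.affine[:3, :3], axis=0)
    header = {
        nib.streamlines.Field.VOXEL_TO_RASMM: tractogram.affine.astype(np.float32),
        nib.streamlines.Field.VOXEL_SIZES: voxel_sizes.astype(np.float32),
        nib.streamlines.Field.DIMENSIONS: np.array(grid_shape, dtype=np.int16),
    }
    nib.streamlines.save(t, str(path), header=header)


def read_trk(path) -> Tractogram:
    trk = nib.streamlines.load(str(path))
    sls = [
        Streamline(points=np.asarray(p, dtype=float), reasons=("unknown", "unknown"),
                   seed=np.asarray(p[0], dtype=float))
        for p in trk.tractogram.streamlines
    ]
    return Tractogram(
        sls, affine=np.asarray(trk.header["voxel_to_rasmm"], dtype=float)
    )


# ---------------------------------------------------------------------------
# Model field
# ---------------------------------------------------------------------------

def write_model_field(field: ModelField, path_nii, path_json) -> None:
    """Serialize a model field as a stacked multi-volume NIfTI + JSON sidecar.

    Volume layout: [S0, d, f1..f3, v1(xyz), v2(xyz), v3(xyz), mask].
    """
    shape = field.grid_shape
    stack = np.concatenate(
        [
            field.S0[..., None],
            field.d[..., None],
            field.fractions,
            field.orientations.reshape(shape + (9,)),
            field.mask[..., None].astype(float),
        ],
        axis=3,
    )
    nib.save(nib.Nifti1Image(stack.astype(np.float32), field.affine), str(path_nii))
    layout = {
        "volumes": ["S0", "d", "f1", "f2", "f3",
                    "v1x", "v1y", "v1z", "v2x", "v2y", "v2z",
                    "v3x", "v3y", "v3z", "mask"],
        "max_sticks": 3,
    }
    Path(path_json).write_text(json.dumps(layout, indent=2))


def read_model_field(path_nii, path_json) -> ModelField:
    img = nib.load(str(path_nii))
    stack = np.asarray(img.get_fdata(), dtype=float)
    layout = json.loads(Path(path_json).read_text())
    if stack.shape[3] != len(layout["volumes"]):
        raise FormatError(f"{path_nii}: volume count does not match sidecar layout")
    shape = stack.shape[:3]
    return ModelField(
        S0=stack[..., 0],
        d=stack[..., 1],
        fractions=stack[..., 2:5],
        orientations=stack[..., 5:14].reshape(shape + (3, 3)),
        mask=stack[..., 14] > 0.5,
        affine=img.affine,
    )


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def dump_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def dump_json(obj, path) -> None:
    """Canonical JSON writer: sorted keys, fixed float formatting, so
    deterministic inputs give byte-identical files."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
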