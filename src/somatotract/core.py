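"""Shared domain types: acquisition schemes and diffusion-weighted volumes.

World coordinates are RAS millimetres (anterior = +Y, superior = +Z);
voxel indices are 0-based, and a voxel's centre maps through the affine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("somatotract")

#: b-values below this (s/mm^2) are treated as b=0 volumes.
B0_THRESHOLD = 50.0


class InvalidSchemeError(ValueError):
    """Raised when an acquisition scheme cannot support model fitting."""


class GeometryError(ValueError):
    """Raised when phantom geometry does not fit the requested grid."""


class FormatError(ValueError):
    """Raised on malformed or inconsistent on-disk inputs."""


@dataclass
class AcquisitionScheme:
    """A diffusion acquisition: one b-value and one gradient direction per volume.

    Parameters
    ----------
    bvalues : (N,) array of b-values in s/mm^2; 0 (or < ``B0_THRESHOLD``) marks b0.
    directions : (N, 3) array of unit gradient directions; rows for b0 volumes
        are zero vectors.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.ndim != 2 or self.directions.shape[1] != 3:
            raise InvalidSchemeError("directions must be an (N, 3) array")
        if len(self.bvalues) != len(self.directions):
            raise InvalidSchemeError(
                f"bvalues ({len(self.bvalues)}) and directions "
                f"({len(self.directions)}) lengths differ"
            )
        if np.any(self.bvalues < 0):
            raise InvalidSchemeError("b-values must be non-negative")
        norms = np.linalg.norm(self.directions[self.dwi_mask], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidSchemeError("non-b0 directions must have unit norm")

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues < B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique non-zero b-values."""
        return np.unique(self.bvalues[self.dwi_mask])

    def shell_mask(self, b: float, tol: float = 50.0) -> np.ndarray:
        return self.dwi_mask & (np.abs(self.bvalues - b) <= tol)


@dataclass
class DwiVolume:
    """A 4D diffusion-weighted dataset on a regular grid.

    ``signal`` is (X, Y, Z, N) with N matching the scheme; ``affine`` maps
    voxel indices to world mm (RAS).
    """

    signal: np.ndarray
    affine: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (X, Y, Z, N)")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but scheme has "
                f"{len(self.scheme)}"
            )
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (centres) to world mm through ``affine``."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    out = ijk @ affine[:3, :3].T + affine[:3, 3]
    return out if out.shape[0] > 1 else out[0]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map world mm to continuous voxel coordinates."""
    inv = np.linalg.inv(affine)
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    out = xyz @ inv[:3, :3].T + inv[:3, 3]
    return out if out.shape[0] > 1 else out[0]
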