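"""Deterministic multi-fiber streamline tractography between cortex and STN.

Seeding follows the study protocol: seed points are drawn uniformly inside
every voxel of the ROIs dilated by one voxel (6-connectivity), 25 seeds per
voxel.  Propagation is bidirectional fixed-step Euler integration (0.5 mm);
at each step the interpolated stick best aligned with the incoming
direction is followed, and tracks terminate on reaching a stop ROI, turning
by more than 55 degrees in one step, losing every compartment above the
0.05 volume-fraction floor, leaving the brain mask, or hitting the step
cap.  Pathway streamlines are retained only if they intersect all three of
the cortical, internal-capsule and subthalamic masks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._kernels import (
    REASON_ANGLE,
    REASON_LEFT_MASK,
    REASON_LOW_FRACTION,
    REASON_MAX_STEPS,
    REASON_ROI,
    _propagate_half,
)
from .core import voxel_to_world, world_to_voxel
from .interpolation import InterpConfig, _field_arrays
from .models import ModelField

logger = logging.getLogger("somatotract")

REASON_NAMES = {
    REASON_ROI: "roi_reached",
    REASON_ANGLE: "angle",
    REASON_LOW_FRACTION: "low_fraction",
    REASON_LEFT_MASK: "left_mask",
    REASON_MAX_STEPS: "max_steps",
}

_STRUCT_6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class TrackingConfig:
    """Streamline propagation and seeding parameters."""

    step_mm: float = 0.5
    angle_max_deg: float = 55.0
    min_fraction: float = 0.05
    seeds_per_voxel: int = 25
    seed_dilation_voxels: int = 1
    max_steps: int = 400
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not (0 < self.angle_max_deg < 90):
            raise ValueError("angle_max_deg must be in (0, 90)")
        if not (0 < self.min_fraction < 1):
            raise ValueError("min_fraction must be in (0, 1)")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")

    @property
    def cos_angle_max(self) -> float:
        return float(np.cos(np.deg2rad(self.angle_max_deg)))


@dataclass
class Streamline:
    """An ordered set of world-mm points with its termination reasons.

    ``reasons`` holds the termination reason of each end (start, end) of the
    bidirectionally propagated track; ``seed`` is the originating point.
    """

    points: np.ndarray
    reasons: tuple[str, str]
    seed: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Tractogram:
    """A set of streamlines plus the reference affine and provenance."""

    streamlines: list[Streamline]
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def generate_seeds(
    roi_mask: np.ndarray,
    affine: np.ndarray,
    cfg: TrackingConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random seed points inside each voxel of the dilated ROI.

    The ROI is dilated by ``seed_dilation_voxels`` with 6-connectivity;
    voxel order (C order) and the generator state make the result
    deterministic for a given seed.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("seed ROI is empty")
    dil = roi_mask
    if cfg.seed_dilation_voxels > 0:
        dil = ndimage.binary_dilation(
            roi_mask, structure=_STRUCT_6, iterations=cfg.seed_dilation_voxels
        )
    voxels = np.argwhere(dil)
    offs = rng.uniform(-0.5, 0.5, size=(len(voxels), cfg.seeds_per_voxel, 3))
    pts = voxels[:, None, :] + offs
    return voxel_to_world(affine, pts.reshape(-1, 3)).reshape(-1, 3)


def _mask_at(mask: np.ndarray, affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Whether each world point falls inside a mask voxel."""
    v = np.rint(world_to_voxel(affine, points)).astype(int)
    v = np.atleast_2d(v)
    inside = np.all((v >= 0) & (v < np.array(mask.shape)), axis=1)
    out = np.zeros(len(v), dtype=bool)
    out[inside] = mask[tuple(v[inside].T)]
    return out


def propagate(
    seed: np.ndarray,
    field_: ModelField,
    interp_cfg: InterpConfig,
    cfg: TrackingConfig,
    stop_mask: np.ndarray,
    brain_mask: np.ndarray,
) -> Streamline | None:
    """Propagate one seed bidirectionally; returns ``None`` for dead seeds."""
    arrays = _field_arrays(field_)
    return _propagate_one(
        np.asarray(seed, dtype=float), arrays, interp_cfg, cfg,
        np.ascontiguousarray(stop_mask.astype(np.uint8)),
        np.ascontiguousarray(brain_mask.astype(np.uint8)),
    )


def _propagate_one(seed, arrays, interp_cfg, cfg, stop_u8, brain_u8):
    from ._kernels import _interp

    mask_u8, S0, dvol, frac, dirs, aff34, inv34 = arrays
    valid, _, _, fr, dr, ncomp = _interp(
        seed, mask_u8, S0, dvol, frac, dirs, aff34, inv34,
        interp_cfg.bandwidth_mm, interp_cfg.support_radius_mm,
        interp_cfg.cos_cluster, interp_cfg.lambda_select, interp_cfg.max_comps,
    )
    if not valid or ncomp == 0:
        return None
    best = int(np.argmax(fr[:ncomp]))
    if fr[best] < cfg.min_fraction:
        return None
    u0 = dr[best].copy()

    common = (
        mask_u8, S0, dvol, frac, dirs, aff34, inv34,
        interp_cfg.bandwidth_mm, interp_cfg.support_radius_mm,
        interp_cfg.cos_cluster, interp_cfg.lambda_select, interp_cfg.max_comps,
        brain_u8, stop_u8, cfg.step_mm, cfg.cos_angle_max, cfg.min_fraction,
        cfg.max_steps,
    )

    if _mask_at_u8(stop_u8, aff34, inv34, seed):
        # seeded inside a stop ROI: a single step, then immediate stop
        pts, n, reason = _propagate_half(seed, u0, *common)
        points = np.vstack([seed[None, :], pts[: min(n, 1)]])
        name = REASON_NAMES[REASON_ROI]
        return Streamline(points=points, reasons=(name, name), seed=seed)

    pts_n, n_n, r_n = _propagate_half(seed, -u0, *common)
    pts_p, n_p, r_p = _propagate_half(seed, u0, *common)
    if n_n + n_p == 0:
        return None
    points = np.vstack([pts_n[::-1], seed[None, :], pts_p])
    return Streamline(
        points=points,
        reasons=(REASON_NAMES[r_n], REASON_NAMES[r_p]),
        seed=seed,
    )


def _mask_at_u8(mask_u8, aff34, inv34, p) -> bool:
    v = inv34[:, :3] @ p + inv34[:, 3]
    ijk = np.floor(v + 0.5).astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.array(mask_u8.shape)):
        return False
    return bool(mask_u8[ijk[0], ijk[1], ijk[2]])


def _config_hash(interp_cfg: InterpConfig, cfg: TrackingConfig) -> str:
    blob = json.dumps(
        {"interp": vars(interp_cfg), "tracking": vars(cfg)}, sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def reconstruct_pathway(
    field_: ModelField,
    roi_m1: np.ndarray,
    roi_ic: np.ndarray,
    roi_stn: np.ndarray,
    brain_mask: np.ndarray,
    interp_cfg: InterpConfig | None = None,
    cfg: TrackingConfig | None = None,
) -> Tractogram:
    """Reconstruct the cortico-subthalamic pathway by three-ROI retention.

    Seeds are drawn around both the cortical and subthalamic ROIs; both act
    as stop regions.  A streamline is retained only if any of its points
    falls inside each of the M1, IC and STN masks.  Duplicate tracks from
    the symmetric seeding are kept.
    """
    interp_cfg = interp_cfg or InterpConfig()
    cfg = cfg or TrackingConfig()
    roi_m1 = np.asarray(roi_m1, dtype=bool)
    roi_ic = np.asarray(roi_ic, dtype=bool)
    roi_stn = np.asarray(roi_stn, dtype=bool)
    for name, roi in (("M1", roi_m1), ("IC", roi_ic), ("STN", roi_stn)):
        if not roi.any():
            raise ValueError(f"ROI {name} is empty")

    rng = np.random.default_rng(cfg.rng_seed)
    affine = field_.affine
    seeds = np.vstack(
        [
            generate_seeds(roi_m1, affine, cfg, rng),
            generate_seeds(roi_stn, affine, cfg, rng),
        ]
    )
    logger.info("tracking: %d seeds", len(seeds))

    stop_mask = roi_m1 | roi_stn
    arrays = _field_arrays(field_)
    stop_u8 = np.ascontiguousarray(stop_mask.astype(np.uint8))
    brain_u8 = np.ascontiguousarray(brain_mask.astype(np.uint8))

    kept: list[Streamline] = []
    n_propagated = 0
    for seed in seeds:
        sl = _propagate_one(seed, arrays, interp_cfg, cfg, stop_u8, brain_u8)
        if sl is None or len(sl) < 2:
            continue
        n_propagated += 1
        if (
            _mask_at(roi_m1, affine, sl.points).any()
            and _mask_at(roi_ic, affine, sl.points).any()
            and _mask_at(roi_stn, affine, sl.points).any()
        ):
            kept.append(sl)
    logger.info(
        "tracking: %d propagated, %d retained by three-ROI criterion",
        n_propagated, len(kept),
    )
    if not kept:
        logger.warning("tracking produced zero retained streamlines")
    return Tractogram(
        streamlines=kept,
        affine=affine,
        provenance={
            "config_hash": _config_hash(interp_cfg, cfg),
            "rng_seed": cfg.rng_seed,
            "n_seeds": int(len(seeds)),
            "n_propagated": n_propagated,
            "rois": ["M1", "IC", "STN"],
        },
    )
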