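"""Synthetic diffusion phantom of a fan-shaped cortico-subthalamic pathway.

The default phantom mimics the geometry the pipeline is designed for: five
fascicles leave distinct somatotopic patches on a model motor cortex
(medial-to-lateral order trunk, arm, hand, face, tongue), converge into a
compact stem that pierces an internal-capsule slab, and terminate on an
ellipsoidal subthalamic nucleus.  An orthogonal "distractor" bundle crosses
the fan at mid-height, standing in for association fibres such as the
superior longitudinal fasciculus, so crossing-fiber resolution is exercised.

Signals follow the ball-and-stick forward model

    S(b, g) = S0 * [(1 - sum_i f_i) * exp(-b d) + sum_i f_i * exp(-b d (g.v_i)^2)]

with optional Rician noise of scale ``S0 / snr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .core import (
    AcquisitionScheme,
    DwiVolume,
    GeometryError,
    InvalidSchemeError,
    voxel_to_world,
)

logger = logging.getLogger("somatotract")

SUBDIVISIONS = ("trunk", "arm", "hand", "face", "tongue")

# Defaults mirroring a multi-shell human acquisition at desk scale.
DEFAULT_GRID_SHAPE = (48, 56, 48)
DEFAULT_VOXEL_SIZE = 1.25  # mm
DEFAULT_BVALUES = (1000.0, 2000.0, 3000.0)
DEFAULT_S0 = 1000.0
DEFAULT_DIFFUSIVITY = 1.7e-3  # mm^2/s, typical white matter
#: total anisotropic volume fraction inside a bundle voxel
DEFAULT_STICK_FRACTION = 0.7
#: tangents closer than this are treated as the same fiber population
PARALLEL_MERGE_DEG = 15.0
MAX_COMPARTMENTS = 3


# ---------------------------------------------------------------------------
# Acquisition scheme
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, approximately uniform points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_default_scheme(
    n_dirs: int = 90,
    bvalues: tuple[float, ...] = DEFAULT_BVALUES,
    n_b0: int = 6,
    seed: int = 0,
) -> AcquisitionScheme:
    """Build a multi-shell scheme: ``n_b0`` b0 volumes then ``n_dirs`` DWIs
    split evenly over the shells, each shell a seeded random rotation of a
    spherical Fibonacci point set.
    """
    bvalues = tuple(float(b) for b in bvalues)
    n_shells = len(bvalues)
    if n_shells == 0 or n_dirs % n_shells != 0:
        raise InvalidSchemeError(
            f"n_dirs={n_dirs} must divide evenly over {n_shells} shells"
        )
    per_shell = n_dirs // n_shells
    if per_shell < 6:
        raise InvalidSchemeError(
            f"{per_shell} directions per shell; at least 6 are required"
        )
    rng = np.random.default_rng(seed)
    base = _fibonacci_sphere(per_shell)
    bvals = [np.zeros(n_b0)]
    dirs = [np.zeros((n_b0, 3))]
    for b in bvalues:
        # seeded random rotation decorrelates shells while staying uniform
        q = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(q)
        rot *= np.sign(np.linalg.det(rot))
        d = base @ rot.T
        dirs.append(d / np.linalg.norm(d, axis=1, keepdims=True))
        bvals.append(np.full(per_shell, b))
    return AcquisitionScheme(np.concatenate(bvals), np.vstack(dirs))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """One tube of the phantom: a centerline in world mm plus a radius."""

    name: str
    centerline: np.ndarray  # (P, 3) ordered control/through points, world mm
    radius: float
    role: str = "pathway"  # pathway | distractor

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if len(self.centerline) < 2:
            raise GeometryError(f"bundle {self.name}: need >= 2 control points")
        if self.radius <= 0:
            raise GeometryError(f"bundle {self.name}: radius must be positive")


@dataclass
class PhantomTruth:
    """Ground truth for one phantom instance.

    ``fractions``/``orientations`` hold the per-voxel compartment field:
    (X, Y, Z, 3) volume fractions (zero-padded) and (X, Y, Z, 3, 3) unit
    orientations.  Masks share the DWI grid.
    """

    fractions: np.ndarray
    orientations: np.ndarray
    roi_m1_labels: np.ndarray
    roi_ic: np.ndarray
    roi_stn: np.ndarray
    brain_mask: np.ndarray
    gold_streamlines: dict[str, np.ndarray]
    affine: np.ndarray
    bundles: list[BundleSpec] = field(default_factory=list)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[:3]

    def n_compartments(self) -> np.ndarray:
        return (self.fractions > 0).sum(axis=3)


def _resample_polyline(points: np.ndarray, ds: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing ``ds``."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / ds)) + 1, 2)
    t = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(t, s, points[:, k]) for k in range(3)])


def _smooth_centerline(
    upper_pts: np.ndarray, stem_pts: np.ndarray, ds: float = 0.25
) -> np.ndarray:
    """Spline the fan limb down to the merge point, then append the exact
    shared stem so all five pathway bundles have an identical terminal
    segment."""
    seg = np.linalg.norm(np.diff(upper_pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # clamp both end tangents to "straight down" so the stem junction is smooth
    spl = CubicSpline(s, upper_pts, bc_type=((1, (0.0, 0.0, -1.0)), (1, (0.0, 0.0, -1.0))))
    t = np.linspace(0.0, s[-1], max(int(np.ceil(s[-1] / ds)) + 1, 2))
    upper = spl(t)
    stem = _resample_polyline(stem_pts, ds)
    return np.vstack([upper, stem[1:]])


def make_default_geometry(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE,
) -> tuple[list[BundleSpec], dict]:
    """Default fan-plus-crossing geometry scaled to the grid extent.

    Returns the bundle list and a dict of geometric parameters (patch
    centres, STN ellipsoid, IC slab bounds) used by :func:`rasterize_bundles`
    to draw the ROI masks.
    """
    shape = tuple(int(v) for v in grid_shape)
    extent = np.array(shape, dtype=float) * voxel_size_mm
    ex, ey, ez = extent
    s = min(extent) / 60.0  # radius scale relative to the reference extent

    arm_radius = 2.0 * s
    stem_radius = 2.5 * s
    cross_radius = 2.0 * s
    stn_axes = np.array([5.0, 4.0, 3.5]) * s

    # medial->lateral patch order trunk, arm, hand, face, tongue; laterally
    # placed patches sit slightly more anterior (anterolateral fan)
    x_frac = np.array([0.25, 0.375, 0.5, 0.625, 0.75])
    y_frac = np.array([0.43, 0.465, 0.5, 0.535, 0.57])
    z_top = 0.90 * ez
    z_straight = 0.83 * ez
    # snap the stem axis to a voxel centre so the funnel's focus does not
    # straddle a voxel boundary
    ax = (np.round(0.5 * ex / voxel_size_mm - 0.5) + 0.5) * voxel_size_mm
    ay = (np.round(0.5 * ey / voxel_size_mm - 0.5) + 0.5) * voxel_size_mm
    merge = np.array([ax, ay, 0.50 * ez])
    stn_center = np.array([ax, ay, 0.25 * ez])
    stem_bottom = np.array([ax, ay, 0.27 * ez])

    bundles: list[BundleSpec] = []
    for name, fx, fy in zip(SUBDIVISIONS, x_frac, y_frac):
        start = np.array([fx * ex, fy * ey, z_top])
        knee = np.array([fx * ex, fy * ey, z_straight])
        center = _smooth_centerline(
            np.vstack([start, knee, merge]),
            np.vstack([merge, stem_bottom]),
        )
        bundles.append(BundleSpec(name, center, arm_radius, "pathway"))

    crossing = BundleSpec(
        "crossing",
        np.array(
            [[0.08 * ex, 0.5 * ey, 0.78 * ez], [0.92 * ex, 0.5 * ey, 0.78 * ez]]
        ),
        cross_radius,
        "distractor",
    )
    bundles.append(crossing)

    margin = 2.0 * voxel_size_mm
    for b in bundles:
        lo = b.centerline.min(axis=0) - b.radius
        hi = b.centerline.max(axis=0) + b.radius
        if np.any(lo < margin - 1e-9) or np.any(hi > extent - margin + 1e-9):
            raise GeometryError(f"bundle {b.name} exits the grid margin")

    params = {
        "grid_shape": shape,
        "voxel_size_mm": float(voxel_size_mm),
        "patch_centers": {
            name: np.array([fx * ex, fy * ey, z_top])
            for name, fx, fy in zip(SUBDIVISIONS, x_frac, y_frac)
        },
        "patch_half_voxels": (1, 1, 1),
        "stn_center": stn_center,
        "stn_axes": stn_axes,
        "stem_radius": stem_radius,
        "ic_bounds": np.array(
            [[0.40 * ex, 0.60 * ex], [0.42 * ey, 0.58 * ey], [0.37 * ez, 0.43 * ez]]
        ),
        "merge_z": merge[2],
        "stem_axis_xy": merge[:2].copy(),
        # convergence length of the stem's funnel flow: fibres in the
        # compact stem point toward the bundle core, so off-axis offsets
        # decay as exp(-dz / flow_h) on the way down
        "flow_h": 6.0 * s,
        "fan_level_z": 0.86 * ez,
    }
    return bundles, params


def default_affine(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE,
) -> np.ndarray:
    """RAS affine with the voxel (0,0,0) centre at half a voxel from origin."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    aff[:3, 3] = voxel_size_mm / 2.0
    return aff


def _voxel_centers(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return voxel_to_world(affine, idx)


def rasterize_bundles(
    bundles: list[BundleSpec],
    params: dict,
    affine: np.ndarray | None = None,
    stick_fraction: float = DEFAULT_STICK_FRACTION,
) -> PhantomTruth:
    """Rasterize tube bundles into a per-voxel compartment field plus masks.

    Every voxel whose centre lies within a tube's radius receives that
    tube's local tangent as a compartment.  Tangents within
    ``PARALLEL_MERGE_DEG`` of each other (sign-invariant) are merged into a
    single population; if more than three distinct populations remain, the
    three largest are kept and a warning is logged.  The total anisotropic
    fraction of a bundle voxel is ``stick_fraction``, split proportionally
    to membership weight.
    """
    shape = tuple(params["grid_shape"])
    voxel = float(params["voxel_size_mm"])
    if affine is None:
        affine = default_affine(shape, voxel)
    nvox = int(np.prod(shape))
    centers = _voxel_centers(shape, affine)

    max_raw = 8
    raw_w = np.zeros((nvox, max_raw))
    raw_dirs = np.zeros((nvox, max_raw, 3))
    raw_n = np.zeros(nvox, dtype=int)
    stem_r = float(params["stem_radius"])
    merge_z = float(params["merge_z"])
    stem_axis = np.asarray(params.get("stem_axis_xy", (np.nan, np.nan)), dtype=float)
    flow_h = float(params.get("flow_h", 0.0))

    cos_merge = np.cos(np.deg2rad(PARALLEL_MERGE_DEG))
    overflow = 0
    for b in bundles:
        fine = _resample_polyline(b.centerline, 0.25)
        tang = np.gradient(fine, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        tree = cKDTree(fine)
        # stem voxels of pathway bundles use the wider stem radius
        radius = b.radius
        query_r = max(radius, stem_r) if b.role == "pathway" else radius
        cand = tree.query_ball_point(centers, r=query_r, workers=-1)
        for vi, neigh in enumerate(cand):
            if not neigh:
                continue
            dists = np.linalg.norm(fine[neigh] - centers[vi], axis=1)
            j = int(np.argmin(dists))
            pt_r = radius
            in_stem = b.role == "pathway" and fine[neigh[j]][2] <= merge_z + 1e-9
            if in_stem:
                pt_r = stem_r
            if dists[j] > pt_r:
                continue
            t = tang[neigh[j]]
            if in_stem and flow_h > 0 and np.isfinite(stem_axis[0]):
                # funnel flow: stem fibres converge onto the bundle core
                t = np.array(
                    [
                        stem_axis[0] - centers[vi, 0],
                        stem_axis[1] - centers[vi, 1],
                        -flow_h,
                    ]
                )
                t /= np.linalg.norm(t)
            # merge with an existing near-parallel population
            merged = False
            for c in range(raw_n[vi]):
                d0 = raw_dirs[vi, c]
                if abs(np.dot(d0, t)) >= cos_merge:
                    t_al = t if np.dot(d0, t) >= 0 else -t
                    new = raw_w[vi, c] * d0 + t_al
                    raw_dirs[vi, c] = new / np.linalg.norm(new)
                    raw_w[vi, c] += 1.0
                    merged = True
                    break
            if not merged:
                if raw_n[vi] < max_raw:
                    raw_dirs[vi, raw_n[vi]] = t
                    raw_w[vi, raw_n[vi]] = 1.0
                    raw_n[vi] += 1
                else:  # pragma: no cover - geometry never reaches this
                    overflow += 1

    # keep the top-3 populations per voxel, fractions proportional to weight
    fractions = np.zeros((nvox, MAX_COMPARTMENTS))
    orientations = np.zeros((nvox, MAX_COMPARTMENTS, 3))
    n_over = 0
    for vi in np.flatnonzero(raw_n):
        n = raw_n[vi]
        order = np.argsort(raw_w[vi, :n])[::-1]
        if n > MAX_COMPARTMENTS:
            n_over += 1
        keep = order[:MAX_COMPARTMENTS]
        w = raw_w[vi, keep]
        f = stick_fraction * w / w.sum()
        fractions[vi, : len(keep)] = f
        orientations[vi, : len(keep)] = raw_dirs[vi, keep]
    if n_over:
        logger.warning("%d voxels had > %d fiber populations; kept the largest",
                       n_over, MAX_COMPARTMENTS)

    fractions = fractions.reshape(shape + (MAX_COMPARTMENTS,))
    orientations = orientations.reshape(shape + (MAX_COMPARTMENTS, 3))

    # masks -----------------------------------------------------------------
    brain = np.zeros(shape, dtype=bool)
    brain[2:-2, 2:-2, 2:-2] = True

    xyz = centers.reshape(shape + (3,))
    labels = np.zeros(shape, dtype=np.int16)
    half = np.array(params["patch_half_voxels"])
    inv_vox = 1.0 / voxel
    for li, name in enumerate(SUBDIVISIONS, start=1):
        c = params["patch_centers"][name]
        cidx = np.round((c - affine[:3, 3]) * inv_vox).astype(int)
        sl = tuple(
            slice(int(cidx[k] - half[k]), int(cidx[k] + half[k] + 1)) for k in range(3)
        )
        labels[sl] = li

    stn_c = params["stn_center"]
    stn_a = params["stn_axes"]
    stn = (((xyz - stn_c) / stn_a) ** 2).sum(axis=3) <= 1.0

    icb = params["ic_bounds"]
    ic = np.ones(shape, dtype=bool)
    for k in range(3):
        ic &= (xyz[..., k] >= icb[k, 0]) & (xyz[..., k] <= icb[k, 1])

    if np.any(stn & (labels > 0)):
        raise GeometryError("STN and M1 masks overlap")

    gold = {
        b.name: _resample_polyline(b.centerline, 0.5)
        for b in bundles
        if b.role == "pathway"
    }

    return PhantomTruth(
        fractions=fractions,
        orientations=orientations,
        roi_m1_labels=labels,
        roi_ic=ic,
        roi_stn=stn,
        brain_mask=brain,
        gold_streamlines=gold,
        affine=affine,
        bundles=list(bundles),
    )


def make_phantom(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE,
) -> PhantomTruth:
    """Convenience: default geometry rasterized onto the default affine."""
    bundles, params = make_default_geometry(grid_shape, voxel_size_mm)
    return rasterize_bundles(bundles, params)


# ---------------------------------------------------------------------------
# Signal simulation
# ---------------------------------------------------------------------------

def simulate_signal(
    truth: PhantomTruth,
    scheme: AcquisitionScheme,
    S0: float = DEFAULT_S0,
    d: float = DEFAULT_DIFFUSIVITY,
    snr: float = np.inf,
    seed: int = 0,
) -> DwiVolume:
    """Simulate the ball-and-stick forward signal over the phantom.

    Noise is Rician with scale ``sigma = S0 / snr`` (magnitude-MR
    convention); ``snr = inf`` returns the closed-form signal exactly.
    Voxels outside the brain mask are zero.
    """
    if S0 <= 0 or d <= 0:
        raise ValueError("S0 and d must be positive")
    if not (snr > 0):
        raise ValueError("snr must be positive (or inf for noiseless)")
    shape = truth.grid_shape
    n = len(scheme)
    frac = truth.fractions
    dirs = truth.orientations
    ball = 1.0 - frac.sum(axis=3)

    signal = np.empty(shape + (n,), dtype=float)
    for i in range(n):
        b = scheme.bvalues[i]
        g = scheme.directions[i]
        if b < 1e-9 or np.linalg.norm(g) < 1e-12:
            signal[..., i] = S0
            continue
        dot = dirs @ g  # (X, Y, Z, 3)
        att = np.exp(-b * d * dot**2)
        signal[..., i] = S0 * (ball * np.exp(-b * d) + (frac * att).sum(axis=3))

    signal *= truth.brain_mask[..., None]

    if np.isfinite(snr):
        sigma = S0 / snr
        rng = np.random.default_rng(seed)
        n1 = rng.standard_normal(signal.shape)
        n2 = rng.standard_normal(signal.shape)
        signal = np.sqrt((signal + sigma * n1) ** 2 + (sigma * n2) ** 2)
        signal *= truth.brain_mask[..., None]

    return DwiVolume(signal=signal, affine=truth.affine, scheme=scheme)
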