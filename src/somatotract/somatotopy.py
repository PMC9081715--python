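"""Fascicle extraction and spatial-arrangement quantification.

Streamlines of a reconstructed pathway are split into the five somatotopic
fascicles (trunk, arm, hand, face, tongue) by the cortical label at their
M1-side endpoint, voxelized into binary envelopes, and compared through
per-slice Dice overlap tables, contour centroids and anterior-posterior
rank frequencies — the quantities used to characterize how segregated or
intermingled the fascicles are at different depths.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import voxel_to_world, world_to_voxel
from .phantom import SUBDIVISIONS
from .tracking import Streamline, Tractogram

logger = logging.getLogger("somatotract")

#: canonical unordered subdivision pairs, in reporting order
PAIRS: tuple[tuple[str, str], ...] = tuple(itertools.combinations(SUBDIVISIONS, 2))

LABEL_NAMES = {i + 1: name for i, name in enumerate(SUBDIVISIONS)}

#: published group-mean Dice overlap of hyperdirect-pathway fascicle
#: contours from a five-subject HCP analysis, by pair and level (IC =
#: internal capsule, ZI = zona incerta); shipped as reference data for the
#: worked aggregation example.
REFERENCE_DSC_MEANS: dict[str, dict[tuple[str, str], float]] = {
    "IC": dict(zip(PAIRS, (0.80, 0.74, 0.63, 0.47, 0.83, 0.70, 0.49, 0.68, 0.48, 0.49))),
    "ZI": dict(zip(PAIRS, (0.76, 0.71, 0.67, 0.54, 0.81, 0.73, 0.53, 0.68, 0.50, 0.57))),
}
REFERENCE_DSC_STDS: dict[str, dict[tuple[str, str], float]] = {
    "IC": dict(zip(PAIRS, (0.07, 0.03, 0.09, 0.21, 0.08, 0.13, 0.18, 0.14, 0.12, 0.18))),
    "ZI": dict(zip(PAIRS, (0.09, 0.09, 0.13, 0.21, 0.09, 0.14, 0.20, 0.10, 0.21, 0.20))),
}


# ---------------------------------------------------------------------------
# Fascicle extraction and envelopes
# ---------------------------------------------------------------------------

@dataclass
class FascicleSet:
    """Mapping of subdivision name to its tractogram (exclusive assignment)."""

    fascicles: dict[str, Tractogram]

    def __getitem__(self, name: str) -> Tractogram:
        return self.fascicles[name]

    def names(self) -> list[str]:
        return [n for n in SUBDIVISIONS if n in self.fascicles]


@dataclass
class Envelope:
    """Binary voxel mask of a fascicle: 1 where any streamline passes."""

    mask: np.ndarray
    affine: np.ndarray
    name: str = ""

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class EnvelopeStats:
    """Mean / max / std of a scalar map over an envelope's voxels."""

    mean: float
    max: float
    std: float
    n_voxels: int


def extract_fascicles(
    tractogram: Tractogram, m1_labels: np.ndarray, affine: np.ndarray | None = None
) -> FascicleSet:
    """Assign each streamline to the subdivision of its cortical endpoint.

    The endpoint closer (in label distance) to a labeled voxel is taken as
    the cortical one; the label is accepted within a 1-voxel (Chebyshev)
    dilation.  Unassigned streamlines are dropped with a logged count.
    """
    affine = tractogram.affine if affine is None else affine
    m1_labels = np.asarray(m1_labels)
    from scipy import ndimage

    dist, idx = ndimage.distance_transform_edt(m1_labels == 0, return_indices=True)
    shape = np.array(m1_labels.shape)

    def endpoint_label(p: np.ndarray) -> tuple[int, float]:
        v = np.rint(world_to_voxel(affine, p)).astype(int)
        if np.any(v < 0) or np.any(v >= shape):
            return 0, np.inf
        nearest = idx[:, v[0], v[1], v[2]]
        cheb = np.max(np.abs(nearest - v))
        if cheb <= 1:
            return int(m1_labels[tuple(nearest)]), float(cheb)
        return 0, np.inf

    groups: dict[str, list[Streamline]] = {name: [] for name in SUBDIVISIONS}
    dropped = 0
    for sl in tractogram:
        la, da = endpoint_label(sl.points[0])
        lb, db = endpoint_label(sl.points[-1])
        lab = la if da <= db else lb
        if lab in LABEL_NAMES:
            groups[LABEL_NAMES[lab]].append(sl)
        else:
            dropped += 1
    if dropped:
        logger.info("extract_fascicles: dropped %d unassigned streamlines", dropped)
    return FascicleSet(
        {
            name: Tractogram(sls, tractogram.affine, dict(tractogram.provenance))
            for name, sls in groups.items()
        }
    )


def envelope(
    tractogram: Tractogram,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    supersample_mm: float = 0.25,
    name: str = "",
) -> Envelope:
    """Voxelize streamlines into a binary label map.

    Each segment is supersampled at <= ``supersample_mm`` so no traversed
    voxel is skipped at the working resolutions.
    """
    mask = np.zeros(grid_shape, dtype=bool)
    shape = np.array(grid_shape)
    for sl in tractogram:
        pts = sl.points
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] <= 0:
            samples = pts[:1]
        else:
            n = int(np.ceil(s[-1] / supersample_mm)) + 1
            t = np.linspace(0.0, s[-1], n)
            samples = np.column_stack(
                [np.interp(t, s, pts[:, k]) for k in range(3)]
            )
        v = np.rint(world_to_voxel(affine, samples)).astype(int)
        v = np.atleast_2d(v)
        ok = np.all((v >= 0) & (v < shape), axis=1)
        mask[tuple(v[ok].T)] = True
    return Envelope(mask=mask, affine=affine, name=name)


def envelope_stats(env: Envelope, scalar_map: np.ndarray) -> EnvelopeStats:
    """Summary statistics of a scalar map (FA, MD, ...) over an envelope.

    Uses the population std convention (ddof=0); units pass through.
    """
    vals = np.asarray(scalar_map)[env.mask]
    if vals.size == 0:
        raise ValueError("envelope is empty")
    return EnvelopeStats(
        mean=float(vals.mean()),
        max=float(vals.max()),
        std=float(vals.std(ddof=0)),
        n_voxels=int(vals.size),
    )


def slice_mask(env: Envelope, axial_index: int) -> np.ndarray:
    """The envelope's 2D binary mask at one axial (z) index."""
    nz = env.mask.shape[2]
    if not (0 <= axial_index < nz):
        raise IndexError(f"axial index {axial_index} out of range [0, {nz})")
    return env.mask[:, :, axial_index]


# ---------------------------------------------------------------------------
# Overlap and arrangement metrics
# ---------------------------------------------------------------------------

def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 0 if both empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def centroid(
    mask2d: np.ndarray, affine: np.ndarray, axial_index: int
) -> tuple[float, float]:
    """World-mm (x, y) centroid of a 2D slice mask's member voxels."""
    mask2d = np.asarray(mask2d, dtype=bool)
    ij = np.argwhere(mask2d)
    if len(ij) == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    ijk = np.column_stack([ij, np.full(len(ij), axial_index)])
    world = np.atleast_2d(voxel_to_world(affine, ijk))
    return float(world[:, 0].mean()), float(world[:, 1].mean())


def ap_rank(centroids: dict[str, tuple[float, float]]) -> tuple[list[str], bool]:
    """Order names from most anterior (largest +Y) to most posterior.

    Returns (ordering, tie_flag); exact Y ties are broken lexicographically.
    """
    if len(centroids) < 2:
        raise ValueError("need at least two centroids to rank")
    items = sorted(centroids.items(), key=lambda kv: (-kv[1][1], kv[0]))
    ys = [y for _, (_, y) in items]
    ties = len(set(ys)) < len(ys)
    if ties:
        logger.info("ap_rank: tied anterior-posterior coordinates")
    return [name for name, _ in items], ties


def position_frequencies(rankings: list[list[str]]) -> pd.DataFrame:
    """Percent of instances in which each name is most anterior / posterior.

    The denominator (number of instances) is reported explicitly; the
    percentages over names sum to 100 for each position.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    n = len(rankings)
    names = sorted({nm for r in rankings for nm in r})
    first = {nm: 0 for nm in names}
    last = {nm: 0 for nm in names}
    for r in rankings:
        first[r[0]] += 1
        last[r[-1]] += 1
    return pd.DataFrame(
        {
            "pct_most_anterior": [100.0 * first[nm] / n for nm in names],
            "pct_most_posterior": [100.0 * last[nm] / n for nm in names],
            "n_instances": n,
        },
        index=pd.Index(names, name="subdivision"),
    )


# ---------------------------------------------------------------------------
# Dice tables
# ---------------------------------------------------------------------------

@dataclass
class DscTable:
    """Per-instance pairwise Dice values at the two axial levels.

    ``values[level][(a, b)]`` with level in {"IC", "ZI"} and (a, b) one of
    the 10 canonical unordered pairs; pair order is immaterial.
    """

    values: dict[str, dict[tuple[str, str], float]]
    instance: str = ""

    def get(self, level: str, a: str, b: str) -> float:
        pair = (a, b) if (a, b) in self.values[level] else (b, a)
        return self.values[level][pair]


def dsc_table(
    envelopes: dict[str, Envelope],
    levels: dict[str, int],
    instance: str = "",
) -> DscTable:
    """Pairwise slice-level Dice among fascicle envelopes.

    ``levels`` maps level name (e.g. "IC", "ZI") to an axial index; the
    contour at each level is the filled per-slice envelope mask.
    """
    values: dict[str, dict[tuple[str, str], float]] = {}
    for level, zi in levels.items():
        values[level] = {}
        for a, b in itertools.combinations(sorted(envelopes, key=SUBDIVISIONS.index), 2):
            values[level][(a, b)] = dice(
                slice_mask(envelopes[a], zi), slice_mask(envelopes[b], zi)
            )
    return DscTable(values=values, instance=instance)


@dataclass
class DscSummary:
    """Aggregation of Dice tables across instances, per level."""

    per_pair: pd.DataFrame  # index (level, pair_a, pair_b), columns mean/std
    grand_mean: dict[str, float]
    max_pair: dict[str, tuple[tuple[str, str], float]]
    min_pair: dict[str, tuple[tuple[str, str], float]]


def summarize_dsc(tables: list[DscTable]) -> DscSummary:
    """Per-pair mean/std across instances plus per-level grand summaries.

    The grand mean is the unweighted mean of the 10 per-pair means; max and
    min identify the attaining pair.  Cross-instance stds use the sample
    (n-1) convention.
    """
    if not tables:
        raise ValueError("need at least one Dice table")
    levels = list(tables[0].values)
    rows = []
    grand, maxp, minp = {}, {}, {}
    for level in levels:
        pair_means = {}
        for pair in tables[0].values[level]:
            vals = np.array([t.get(level, *pair) for t in tables])
            m = float(vals.mean())
            s = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            pair_means[pair] = m
            rows.append(
                {"level": level, "pair_a": pair[0], "pair_b": pair[1],
                 "mean": m, "std": s, "n": len(vals)}
            )
        grand[level] = float(np.mean(list(pair_means.values())))
        best = max(pair_means.items(), key=lambda kv: kv[1])
        worst = min(pair_means.items(), key=lambda kv: kv[1])
        maxp[level] = (best[0], best[1])
        minp[level] = (worst[0], worst[1])
    per_pair = pd.DataFrame(rows).set_index(["level", "pair_a", "pair_b"])
    return DscSummary(per_pair=per_pair, grand_mean=grand, max_pair=maxp, min_pair=minp)


def reference_dsc_table() -> DscTable:
    """The shipped published group-mean Dice values as a single table."""
    return DscTable(
        values={lvl: dict(v) for lvl, v in REFERENCE_DSC_MEANS.items()},
        instance="published-group-means",
    )


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_fascicle_stats(
    stats: dict[str, dict[str, EnvelopeStats]], out_path: str
) -> None:
    """Bar plots of FA and MD summaries per fascicle (one panel per map)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    maps = sorted({m for per in stats.values() for m in per})
    fig, axes = plt.subplots(len(maps), 1, figsize=(6, 3 * len(maps)), squeeze=False)
    for ax, map_name in zip(axes[:, 0], maps):
        names = [n for n in SUBDIVISIONS if n in stats and map_name in stats[n]]
        means = [stats[n][map_name].mean for n in names]
        errs = [stats[n][map_name].std for n in names]
        ax.bar(names, means, yerr=errs, color="steelblue")
        ax.set_ylabel(map_name)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
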