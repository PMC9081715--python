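"""Data-adaptive kernel-regression interpolation of ball-and-stick fields.

Tracking needs model estimates at arbitrary continuous positions.  Voxel
models in a Gaussian spatial neighborhood are combined by representing each
stick as a dyadic (outer-product) tensor — which makes the combination
invariant to the meaningless sign of a fiber orientation — clustering the
dyadics by orientation proximity, and keeping the heaviest clusters until a
fraction ``lambda_select`` of the stick weight is explained (at most
``max_comps`` compartments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import _interp
from .models import BallStickModel, ModelField


@dataclass
class InterpConfig:
    """Kernel-regression settings.

    bandwidth_mm : Gaussian spatial bandwidth h (default 1.0 mm).
    lambda_select : cumulative stick-weight fraction retained (default 0.9999).
    max_comps : compartment cap, 1-3.
    support_radius_mm : neighborhood cutoff; defaults to 2 * bandwidth,
        beyond which the Gaussian weight is below 2%.
    cluster_angle_deg : greedy clustering threshold (sign-invariant).
    """

    bandwidth_mm: float = 1.0
    lambda_select: float = 0.9999
    max_comps: int = 3
    support_radius_mm: float | None = None
    cluster_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.bandwidth_mm <= 0:
            raise ValueError("bandwidth must be positive")
        if not (0 < self.lambda_select <= 1):
            raise ValueError("lambda_select must be in (0, 1]")
        if self.max_comps not in (1, 2, 3):
            raise ValueError("max_comps must be 1, 2 or 3")
        if self.support_radius_mm is None:
            self.support_radius_mm = 2.0 * self.bandwidth_mm

    @property
    def cos_cluster(self) -> float:
        return float(np.cos(np.deg2rad(self.cluster_angle_deg)))


def _field_arrays(field: ModelField):
    return (
        np.ascontiguousarray(field.mask.astype(np.uint8)),
        np.ascontiguousarray(field.S0),
        np.ascontiguousarray(field.d),
        np.ascontiguousarray(field.fractions),
        np.ascontiguousarray(field.orientations),
        np.ascontiguousarray(field.affine[:3, :]),
        np.ascontiguousarray(np.linalg.inv(field.affine)[:3, :]),
    )


def interpolate(
    field: ModelField, position: np.ndarray, cfg: InterpConfig | None = None
) -> BallStickModel | None:
    """Estimate the ball-and-stick model at a world-mm position.

    Returns ``None`` when no in-mask voxel lies within the support radius
    (the tracker treats this as leaving the data).
    """
    cfg = cfg or InterpConfig()
    arrays = _field_arrays(field)
    p = np.ascontiguousarray(np.asarray(position, dtype=float))
    valid, S0, d, frac, dirs, ncomp = _interp(
        p, *arrays,
        cfg.bandwidth_mm, cfg.support_radius_mm, cfg.cos_cluster,
        cfg.lambda_select, cfg.max_comps,
    )
    if not valid:
        return None
    return BallStickModel(
        S0=S0, d=d, fractions=frac[:ncomp].copy(), orientations=dirs[:ncomp].copy()
    )
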