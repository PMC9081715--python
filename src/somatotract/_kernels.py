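"""Numba kernels for model interpolation and streamline propagation.

These are the inner loops of tracking: a data-adaptive kernel-regression
evaluation of the ball-and-stick field at a continuous world position, and a
fixed-step Euler half-track propagator.  Both operate on the plain arrays of
a ``ModelField`` so they can be jitted; the public API wraps them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# termination reason codes shared with tracking.py
REASON_ROI = 0
REASON_ANGLE = 1
REASON_LOW_FRACTION = 2
REASON_LEFT_MASK = 3
REASON_MAX_STEPS = 4


@njit(cache=True)
def _interp(
    p,
    mask,
    S0,
    dvol,
    frac,
    dirs,
    affine,
    inv_affine,
    bandwidth,
    support,
    cos_cluster,
    lam,
    max_comps,
):
    """Kernel-regression model estimate at world position ``p``.

    Returns (valid, S0, d, out_frac(3,), out_dirs(3,3), n_comp).  Sticks of
    in-mask voxels within ``support`` of ``p`` are weighted by a Gaussian of
    the spatial distance, represented as dyadic tensors, greedily clustered
    by sign-invariant orientation proximity, and the heaviest clusters are
    retained until a fraction ``lam`` of the stick weight is explained (at
    most ``max_comps``).
    """
    out_frac = np.zeros(3)
    out_dirs = np.zeros((3, 3))

    v0 = inv_affine[0, 0] * p[0] + inv_affine[0, 1] * p[1] + inv_affine[0, 2] * p[2] + inv_affine[0, 3]
    v1 = inv_affine[1, 0] * p[0] + inv_affine[1, 1] * p[1] + inv_affine[1, 2] * p[2] + inv_affine[1, 3]
    v2 = inv_affine[2, 0] * p[0] + inv_affine[2, 1] * p[1] + inv_affine[2, 2] * p[2] + inv_affine[2, 3]

    vs0 = np.sqrt(affine[0, 0] ** 2 + affine[1, 0] ** 2 + affine[2, 0] ** 2)
    vs1 = np.sqrt(affine[0, 1] ** 2 + affine[1, 1] ** 2 + affine[2, 1] ** 2)
    vs2 = np.sqrt(affine[0, 2] ** 2 + affine[1, 2] ** 2 + affine[2, 2] ** 2)
    r0 = int(np.ceil(support / vs0))
    r1 = int(np.ceil(support / vs1))
    r2 = int(np.ceil(support / vs2))
    c0 = int(np.floor(v0 + 0.5))
    c1 = int(np.floor(v1 + 0.5))
    c2 = int(np.floor(v2 + 0.5))

    n_max = (2 * r0 + 1) * (2 * r1 + 1) * (2 * r2 + 1) * 3
    cand_w = np.empty(n_max)
    cand_d = np.empty((n_max, 3))
    n_cand = 0
    W = 0.0
    S0_acc = 0.0
    d_acc = 0.0
    sup2 = support * support
    inv_h2 = 1.0 / (bandwidth * bandwidth)

    for i in range(c0 - r0, c0 + r0 + 1):
        if i < 0 or i >= mask.shape[0]:
            continue
        for j in range(c1 - r1, c1 + r1 + 1):
            if j < 0 or j >= mask.shape[1]:
                continue
            for k in range(c2 - r2, c2 + r2 + 1):
                if k < 0 or k >= mask.shape[2]:
                    continue
                if mask[i, j, k] == 0:
                    continue
                cx = affine[0, 0] * i + affine[0, 1] * j + affine[0, 2] * k + affine[0, 3]
                cy = affine[1, 0] * i + affine[1, 1] * j + affine[1, 2] * k + affine[1, 3]
                cz = affine[2, 0] * i + affine[2, 1] * j + affine[2, 2] * k + affine[2, 3]
                d2 = (p[0] - cx) ** 2 + (p[1] - cy) ** 2 + (p[2] - cz) ** 2
                if d2 > sup2:
                    continue
                w = np.exp(-d2 * inv_h2)
                W += w
                S0_acc += w * S0[i, j, k]
                d_acc += w * dvol[i, j, k]
                for s in range(3):
                    fs = frac[i, j, k, s]
                    if fs > 0.0:
                        cand_w[n_cand] = w * fs
                        cand_d[n_cand, 0] = dirs[i, j, k, s, 0]
                        cand_d[n_cand, 1] = dirs[i, j, k, s, 1]
                        cand_d[n_cand, 2] = dirs[i, j, k, s, 2]
                        n_cand += 1

    if W <= 0.0:
        return False, 0.0, 0.0, out_frac, out_dirs, 0

    S0_out = S0_acc / W
    d_out = d_acc / W

    if n_cand == 0:
        return True, S0_out, d_out, out_frac, out_dirs, 0

    # greedy sign-invariant clustering of the dyadics, heaviest first
    order = np.argsort(cand_w[:n_cand])[::-1]
    max_clusters = 32
    cl_w = np.zeros(max_clusters)
    cl_dir = np.zeros((max_clusters, 3))
    cl_dyad = np.zeros((max_clusters, 3, 3))
    n_cl = 0
    for oi in range(n_cand):
        ci = order[oi]
        w = cand_w[ci]
        vx = cand_d[ci, 0]
        vy = cand_d[ci, 1]
        vz = cand_d[ci, 2]
        assigned = -1
        for c in range(n_cl):
            dot = cl_dir[c, 0] * vx + cl_dir[c, 1] * vy + cl_dir[c, 2] * vz
            if np.abs(dot) >= cos_cluster:
                assigned = c
                if dot < 0.0:
                    vx = -vx
                    vy = -vy
                    vz = -vz
                break
        if assigned < 0:
            if n_cl < max_clusters:
                assigned = n_cl
                n_cl += 1
            else:
                assigned = 0  # overflow: fold into the heaviest cluster
        # running weighted mean direction for membership tests
        mx = cl_dir[assigned, 0] * cl_w[assigned] + w * vx
        my = cl_dir[assigned, 1] * cl_w[assigned] + w * vy
        mz = cl_dir[assigned, 2] * cl_w[assigned] + w * vz
        norm = np.sqrt(mx * mx + my * my + mz * mz)
        if norm > 0.0:
            cl_dir[assigned, 0] = mx / norm
            cl_dir[assigned, 1] = my / norm
            cl_dir[assigned, 2] = mz / norm
        cl_w[assigned] += w
        cl_dyad[assigned, 0, 0] += w * vx * vx
        cl_dyad[assigned, 0, 1] += w * vx * vy
        cl_dyad[assigned, 0, 2] += w * vx * vz
        cl_dyad[assigned, 1, 0] += w * vy * vx
        cl_dyad[assigned, 1, 1] += w * vy * vy
        cl_dyad[assigned, 1, 2] += w * vy * vz
        cl_dyad[assigned, 2, 0] += w * vz * vx
        cl_dyad[assigned, 2, 1] += w * vz * vy
        cl_dyad[assigned, 2, 2] += w * vz * vz

    stick_total = 0.0
    for c in range(n_cl):
        stick_total += cl_w[c]
    cl_order = np.argsort(cl_w[:n_cl])[::-1]
    n_keep = 0
    cum = 0.0
    for oi in range(n_cl):
        if n_keep >= max_comps:
            break
        if cum >= lam * stick_total:
            break
        c = cl_order[oi]
        evals, evecs = np.linalg.eigh(cl_dyad[c])
        # principal eigenvector (largest eigenvalue = last column)
        out_dirs[n_keep, 0] = evecs[0, 2]
        out_dirs[n_keep, 1] = evecs[1, 2]
        out_dirs[n_keep, 2] = evecs[2, 2]
        out_frac[n_keep] = cl_w[c] / W
        cum += cl_w[c]
        n_keep += 1

    return True, S0_out, d_out, out_frac, out_dirs, n_keep


@njit(cache=True)
def _propagate_half(
    x0,
    u0,
    mask,
    S0,
    dvol,
    frac,
    dirs,
    affine,
    inv_affine,
    bandwidth,
    support,
    cos_cluster,
    lam,
    max_comps,
    brain_mask,
    stop_mask,
    step,
    cos_angle_max,
    min_fraction,
    max_steps,
):
    """One half-track from a seed: fixed-step Euler integration.

    Returns (points (n, 3), n, reason_code).  At every step the model is
    interpolated at the new point and the stick (fraction >= min_fraction)
    best aligned with the incoming direction is followed, sign-resolved.
    """
    pts = np.empty((max_steps, 3))
    n = 0
    x = x0.copy()
    u = u0.copy()
    reason = REASON_MAX_STEPS
    for _ in range(max_steps):
        xn = x + step * u
        v0 = inv_affine[0, 0] * xn[0] + inv_affine[0, 1] * xn[1] + inv_affine[0, 2] * xn[2] + inv_affine[0, 3]
        v1 = inv_affine[1, 0] * xn[0] + inv_affine[1, 1] * xn[1] + inv_affine[1, 2] * xn[2] + inv_affine[1, 3]
        v2 = inv_affine[2, 0] * xn[0] + inv_affine[2, 1] * xn[1] + inv_affine[2, 2] * xn[2] + inv_affine[2, 3]
        i = int(np.floor(v0 + 0.5))
        j = int(np.floor(v1 + 0.5))
        k = int(np.floor(v2 + 0.5))
        if (
            i < 0 or i >= mask.shape[0]
            or j < 0 or j >= mask.shape[1]
            or k < 0 or k >= mask.shape[2]
            or brain_mask[i, j, k] == 0
        ):
            reason = REASON_LEFT_MASK
            break
        pts[n] = xn
        n += 1
        if stop_mask[i, j, k] != 0:
            reason = REASON_ROI
            break
        valid, _, _, fr, dr, ncomp = _interp(
            xn, mask, S0, dvol, frac, dirs, affine, inv_affine,
            bandwidth, support, cos_cluster, lam, max_comps,
        )
        if not valid:
            reason = REASON_LEFT_MASK
            break
        best = -1
        best_dot = -1.0
        for s in range(ncomp):
            if fr[s] < min_fraction:
                continue
            dot = u[0] * dr[s, 0] + u[1] * dr[s, 1] + u[2] * dr[s, 2]
            if np.abs(dot) > best_dot:
                best_dot = np.abs(dot)
                best = s
        if best < 0:
            reason = REASON_LOW_FRACTION
            break
        if best_dot < cos_angle_max:
            reason = REASON_ANGLE
            break
        sgn = 1.0
        dot = u[0] * dr[best, 0] + u[1] * dr[best, 1] + u[2] * dr[best, 2]
        if dot < 0.0:
            sgn = -1.0
        u[0] = sgn * dr[best, 0]
        u[1] = sgn * dr[best, 1]
        u[2] = sgn * dr[best, 2]
        x = xn
    return pts[:n], n, reason
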