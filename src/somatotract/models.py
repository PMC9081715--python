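"""Per-voxel diffusion models: DTI scalar maps and the ball-and-stick fit.

The tensor fit is the classic log-linear least squares on the lowest shell
(plus b0s), used only to produce FA / MD / direction-encoded colour maps and
an anisotropy gate.  The multi-fiber model is the ball-and-stick
multi-compartment model with a single shared diffusivity,

    S(b, g) = S0 * [f0 * exp(-b d) + sum_i f_i * exp(-b d (g.v_i)^2)],

fitted per voxel by multi-start bounded nonlinear least squares with the
stick count chosen by BIC (fewer sticks preferred when within 2 BIC units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .core import AcquisitionScheme, DwiVolume, InvalidSchemeError

logger = logging.getLogger("somatotract")

MAX_STICKS = 3
_D_BOUNDS = (1e-5, 1e-2)  # mm^2/s


# ---------------------------------------------------------------------------
# Tensor fit and scalar maps
# ---------------------------------------------------------------------------

@dataclass
class TensorFit:
    """Voxel-wise symmetric diffusion tensors plus derived spectra.

    ``tensors`` is (..., 3, 3); ``eigenvalues`` are sorted descending and
    clamped at zero before scalar-map computation; ``flagged`` marks voxels
    with no usable diffusion information (zero tensor substituted).
    """

    tensors: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (..., 3, 3), columns matching eigenvalues
    flagged: np.ndarray

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[..., :, 0]


def fit_dti(dwi: DwiVolume, mask: np.ndarray | None = None) -> TensorFit:
    """Log-linear least-squares tensor fit on the lowest non-zero shell.

    Restricting the fit to the lowest shell keeps the mono-exponential
    tensor model defensible on multi-shell data.
    """
    scheme = dwi.scheme
    shells = scheme.shells
    if len(shells) == 0 or scheme.n_b0 < 1:
        raise InvalidSchemeError("tensor fit needs >= 1 b0 and a non-zero shell")
    sel = scheme.b0_mask | scheme.shell_mask(shells[0])
    if (sel & scheme.dwi_mask).sum() < 6:
        raise InvalidSchemeError("tensor fit needs >= 6 non-b0 directions")

    b = scheme.bvalues[sel]
    g = scheme.directions[sel]
    # design: log S = log S0 - b * (gx^2 Dxx + gy^2 Dyy + gz^2 Dzz
    #                               + 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz)
    X = np.column_stack(
        [
            np.ones(len(b)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )

    shape = dwi.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    sig = dwi.signal[..., sel][mask]
    bad = (sig <= 0).any(axis=1)
    logsig = np.log(np.clip(sig, 1e-12, None))
    coef, *_ = np.linalg.lstsq(X, logsig.T, rcond=None)
    coef = coef.T  # (V, 7)

    V = coef.shape[0]
    D = np.zeros((V, 3, 3))
    D[:, 0, 0] = coef[:, 1]
    D[:, 1, 1] = coef[:, 2]
    D[:, 2, 2] = coef[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = coef[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = coef[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = coef[:, 6]
    D[bad] = 0.0

    evals, evecs = np.linalg.eigh(D)
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    flagged_v = bad | (evals.max(axis=1) <= 1e-12)
    D[flagged_v] = 0.0
    evals[flagged_v] = 0.0
    evals = np.clip(evals, 0.0, None)

    full = lambda a, tail: np.zeros(shape + tail, dtype=float)
    tensors = full(None, (3, 3))
    eigenvalues = full(None, (3,))
    eigenvectors = full(None, (3, 3))
    flagged = np.zeros(shape, dtype=bool)
    tensors[mask] = D
    eigenvalues[mask] = evals
    eigenvectors[mask] = evecs
    flagged[mask] = flagged_v
    return TensorFit(tensors, eigenvalues, eigenvectors, flagged)


def fa(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of one or more eigenvalue triples, in [0, 1].

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||; zero tensors
    give 0 by convention.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5) * num / den
    out = np.where(den > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def md(eigenvalues: np.ndarray) -> np.ndarray:
    """Mean diffusivity (mm^2/s): the eigenvalue average."""
    return np.asarray(eigenvalues, dtype=float).mean(axis=-1)


def dec_map(fit: TensorFit) -> np.ndarray:
    """Direction-encoded colour map: RGB = |principal eigenvector| * FA.

    Red = left-right, green = anterior-posterior, blue = superior-inferior
    (standard convention under an RAS affine).
    """
    f = fa(fit.eigenvalues)
    return np.abs(fit.principal_direction) * f[..., None]


# ---------------------------------------------------------------------------
# Ball-and-stick model
# ---------------------------------------------------------------------------

@dataclass
class BallStickModel:
    """One voxel's ball-and-stick model.

    ``fractions`` (k,) and ``orientations`` (k, 3) describe the sticks;
    the ball fraction is ``f0 = 1 - sum(fractions)``.  Orientations are
    sign-symmetric (v and -v are the same fiber).
    """

    S0: float
    d: float
    fractions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        if np.any(self.fractions < -1e-9) or self.fractions.sum() > 1 + 1e-6:
            raise ValueError("stick fractions must lie in [0, 1] and sum to <= 1")
        n = np.linalg.norm(self.orientations, axis=1)
        if len(n) and np.any(np.abs(n - 1) > 1e-6):
            raise ValueError("stick orientations must be unit vectors")

    @property
    def f0(self) -> float:
        return float(1.0 - self.fractions.sum())

    @property
    def n_sticks(self) -> int:
        return len(self.fractions)


@dataclass
class ModelField:
    """Dense grid of ball-and-stick models inside a brain mask.

    Stored as stacked arrays so tracking kernels can index it directly:
    ``fractions`` (X, Y, Z, 3) zero-padded, ``orientations`` (X, Y, Z, 3, 3).
    """

    S0: np.ndarray
    d: np.ndarray
    fractions: np.ndarray
    orientations: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def model_at(self, ijk: tuple[int, int, int]) -> BallStickModel | None:
        if not self.mask[ijk]:
            return None
        f = self.fractions[ijk]
        keep = f > 0
        return BallStickModel(
            S0=float(self.S0[ijk]),
            d=float(self.d[ijk]),
            fractions=f[keep],
            orientations=self.orientations[ijk][keep],
        )

    def set_voxel(self, ijk: tuple[int, int, int], model: BallStickModel) -> None:
        self.mask[ijk] = True
        self.S0[ijk] = model.S0
        self.d[ijk] = model.d
        self.fractions[ijk] = 0.0
        self.orientations[ijk] = 0.0
        k = model.n_sticks
        self.fractions[ijk][:k] = model.fractions
        self.orientations[ijk][:k] = model.orientations

    @classmethod
    def empty(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "ModelField":
        return cls(
            S0=np.zeros(shape),
            d=np.zeros(shape),
            fractions=np.zeros(shape + (MAX_STICKS,)),
            orientations=np.zeros(shape + (MAX_STICKS, 3)),
            mask=np.zeros(shape, dtype=bool),
            affine=affine,
        )


def predict_ball_stick(model: BallStickModel, scheme: AcquisitionScheme) -> np.ndarray:
    """Closed-form forward signal of a ball-and-stick model."""
    b = scheme.bvalues
    g = scheme.directions
    sig = model.f0 * np.exp(-b * model.d)
    for f, v in zip(model.fractions, model.orientations):
        sig = sig + f * np.exp(-b * model.d * (g @ v) ** 2)
    return model.S0 * sig


def _angles_to_dirs(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _dirs_to_angles(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.atleast_2d(v)
    theta = np.arccos(np.clip(v[:, 2], -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    return theta, phi


def _unpack(x: np.ndarray, k: int) -> tuple[float, float, np.ndarray, np.ndarray]:
    S0, d = x[0], x[1]
    if k == 0:
        return S0, d, np.zeros(0), np.zeros((0, 3))
    s = x[2 : 2 + k]
    ang = x[2 + k :].reshape(k, 2)
    # stick-breaking keeps sum(f) <= 1 under box bounds on s
    f = np.empty(k)
    rem = 1.0
    for i in range(k):
        f[i] = s[i] * rem
        rem -= f[i]
    return S0, d, f, _angles_to_dirs(ang[:, 0], ang[:, 1])


def _residual(x: np.ndarray, y: np.ndarray, b: np.ndarray, g: np.ndarray, k: int):
    S0, d, f, v = _unpack(x, k)
    sig = (1.0 - f.sum()) * np.exp(-b * d)
    for i in range(k):
        sig = sig + f[i] * np.exp(-b * d * (g @ v[i]) ** 2)
    return S0 * sig - y


def _ball_init(y: np.ndarray, scheme: AcquisitionScheme) -> tuple[float, float]:
    S0 = float(y[scheme.b0_mask].mean()) if scheme.n_b0 else float(y.max())
    S0 = max(S0, 1e-6)
    # mono-exponential regression of per-shell mean log signal on b
    bs, means = [0.0], [S0]
    for b in scheme.shells:
        bs.append(b)
        means.append(max(float(y[scheme.shell_mask(b)].mean()), 1e-9 * S0))
    slope = np.polyfit(bs, np.log(means), 1)[0]
    d0 = float(np.clip(-slope, *_D_BOUNDS))
    return S0, d0


def _candidate_directions(
    y: np.ndarray, scheme: AcquisitionScheme, S0: float, d0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rank candidate stick orientations by NNLS weight over a direction
    dictionary built from the outermost shell's gradient set."""
    b_hi = scheme.shells[-1]
    cand = scheme.directions[scheme.shell_mask(b_hi)]
    b = scheme.bvalues
    g = scheme.directions
    atoms = [np.exp(-b * d0)]
    atoms += [np.exp(-b * d0 * (g @ u) ** 2) for u in cand]
    A = np.column_stack(atoms)
    w, _ = nnls(A, y / S0)
    return cand, w[1:]


def _peak_dirs(cand: np.ndarray, w: np.ndarray, k: int, min_sep_deg: float = 30.0):
    """Top-k candidate directions with angular suppression."""
    cos_sep = np.cos(np.deg2rad(min_sep_deg))
    order = np.argsort(w)[::-1]
    peaks: list[np.ndarray] = []
    for j in order:
        u = cand[j]
        if all(abs(u @ p) < cos_sep for p in peaks):
            peaks.append(u)
        if len(peaks) == k:
            break
    while len(peaks) < k:  # degenerate dictionaries: pad with axes
        for ax in np.eye(3):
            if all(abs(ax @ p) < cos_sep for p in peaks):
                peaks.append(ax)
                break
        else:
            peaks.append(np.array([0.0, 0.0, 1.0]))
    return np.array(peaks[:k])


def fit_ball_stick_voxel(
    y: np.ndarray,
    scheme: AcquisitionScheme,
    max_sticks: int = MAX_STICKS,
    seed: int = 0,
    n_starts: int = 2,
) -> BallStickModel:
    """Fit one voxel by multi-start bounded NLLS with BIC stick selection.

    A stick count k is only preferred over a smaller one when its BIC
    improves by more than 2; a residual floor prevents BIC degeneracies on
    noiseless data.  Deterministic for a fixed ``seed``.
    """
    y = np.asarray(y, dtype=float)
    b = scheme.bvalues
    g = scheme.directions
    n = len(y)
    rng = np.random.default_rng(seed)

    S0_init, d_init = _ball_init(y, scheme)
    rss_floor = n * (1e-8 * S0_init) ** 2

    def run(k: int, x0: np.ndarray, lb: np.ndarray, ub: np.ndarray):
        try:
            res = least_squares(
                _residual, x0, bounds=(lb, ub), args=(y, b, g, k),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
            )
            return res.x, float(res.cost * 2.0)
        except Exception:  # pragma: no cover - defensive
            return None, np.inf

    best: dict = {}
    # k = 0: pure ball
    lb0 = np.array([1e-9, _D_BOUNDS[0]])
    ub0 = np.array([10 * max(S0_init, 1.0), _D_BOUNDS[1]])
    x, rss = run(0, np.array([S0_init, d_init]), lb0, ub0)
    best[0] = (x, rss)

    cand, wts = _candidate_directions(y, scheme, S0_init, d_init)
    total_w = wts.sum()
    for k in range(1, max_sticks + 1):
        peaks = _peak_dirs(cand, wts, k)
        theta, phi = _dirs_to_angles(peaks)
        # fractions init: split the NNLS anisotropic weight over the peaks
        f_guess = np.full(k, min(0.8, total_w / (total_w + 1.0) + 0.1) / k)
        starts = []
        s_guess = np.empty(k)
        rem = 1.0
        for i in range(k):
            s_guess[i] = np.clip(f_guess[i] / max(rem, 1e-9), 0.02, 0.98)
            rem -= s_guess[i] * rem
        starts.append(np.concatenate([[S0_init, d_init], s_guess,
                                      np.column_stack([theta, phi]).ravel()]))
        for _ in range(n_starts - 1):
            jitter = rng.normal(scale=0.3, size=2 * k)
            s_j = np.clip(s_guess + rng.normal(scale=0.15, size=k), 0.02, 0.98)
            starts.append(np.concatenate(
                [[S0_init, d_init], s_j,
                 (np.column_stack([theta, phi]).ravel() + jitter)]))
        lb = np.concatenate([[1e-9, _D_BOUNDS[0]], np.zeros(k), np.full(2 * k, -10.0)])
        ub = np.concatenate(
            [[10 * max(S0_init, 1.0), _D_BOUNDS[1]], np.ones(k), np.full(2 * k, 10.0)]
        )
        results = [run(k, x0, lb, ub) for x0 in starts]
        x, rss = min(results, key=lambda r: r[1])
        best[k] = (x, rss)
        if rss < rss_floor:
            break  # residuals at numerical floor; more sticks cannot help

    def bic(k: int) -> float:
        rss = max(best[k][1], rss_floor)
        p = 2 + 3 * k
        return n * np.log(rss / n) + p * np.log(n)

    k_sel = 0
    for k in sorted(best):
        if k == 0:
            continue
        if bic(k) < bic(k_sel) - 2.0:  # prefer fewer sticks within 2 BIC units
            k_sel = k

    x, _ = best[k_sel]
    if x is None:  # pragma: no cover - all starts failed
        logger.warning("ball-and-stick fit failed to converge; using pure ball")
        return BallStickModel(S0_init, d_init, np.zeros(0), np.zeros((0, 3)))
    S0, d, f, v = _unpack(x, k_sel)
    order = np.argsort(f)[::-1]
    f, v = f[order], v[order]
    keep = f > 1e-4
    f, v = f[keep], v[keep]
    v = v / np.linalg.norm(v, axis=1, keepdims=True) if len(v) else v
    return BallStickModel(float(S0), float(d), f, v)


def fit_ball_stick(
    dwi: DwiVolume,
    mask: np.ndarray | None = None,
    max_sticks: int = MAX_STICKS,
    seed: int = 0,
    fa_gate: float = 0.2,
) -> ModelField:
    """Fit the ball-and-stick model over a volume.

    Voxels whose tensor FA falls below ``fa_gate`` are treated as isotropic
    and receive the fast pure-ball fit; set ``fa_gate=0`` to run the full
    multi-compartment fit everywhere.
    """
    if len(dwi.scheme.shells) < 1:
        raise InvalidSchemeError("ball-and-stick fit needs at least one shell")
    shape = dwi.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    field_ = ModelField.empty(shape, dwi.affine)

    if fa_gate > 0:
        tf = fit_dti(dwi, mask)
        fa_map = fa(tf.eigenvalues)
        aniso = mask & (fa_map >= fa_gate) & ~tf.flagged
    else:
        aniso = mask.copy()
    iso = mask & ~aniso

    scheme = dwi.scheme
    # vectorized pure-ball fit for isotropic voxels: log-linear in b
    if iso.any():
        sig = dwi.signal[iso]
        S0v = sig[:, scheme.b0_mask].mean(axis=1)
        ok = S0v > 0
        bvals = scheme.bvalues
        X = np.column_stack([np.ones(len(bvals)), -bvals])
        logs = np.log(np.clip(sig, 1e-12, None))
        coef, *_ = np.linalg.lstsq(X, logs.T, rcond=None)
        S0_fit = np.exp(coef[0])
        d_fit = np.clip(coef[1], *_D_BOUNDS)
        idx = np.argwhere(iso)
        for row, s0i, di, oki in zip(idx, S0_fit, d_fit, ok):
            if not oki:
                continue
            ijk = tuple(row)
            field_.mask[ijk] = True
            field_.S0[ijk] = s0i
            field_.d[ijk] = di

    count = 0
    for ijk in map(tuple, np.argwhere(aniso)):
        model = fit_ball_stick_voxel(
            dwi.signal[ijk], scheme, max_sticks=max_sticks, seed=seed
        )
        field_.set_voxel(ijk, model)
        count += 1
    logger.info(
        "ball-and-stick fit: %d multi-compartment voxels, %d isotropic voxels",
        count, int(iso.sum()),
    )
    return field_
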