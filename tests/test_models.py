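"""Diffusion models: tensor fit, scalar maps, ball-and-stick fit."""

import numpy as np
import pytest

from somatotract import (
    AcquisitionScheme,
    BallStickModel,
    DwiVolume,
    dec_map,
    fa,
    fit_ball_stick,
    fit_ball_stick_voxel,
    fit_dti,
    md,
    make_default_scheme,
    predict_ball_stick,
)


@pytest.fixture(scope="module")
def dti_scheme():
    return make_default_scheme(30, [1000.0], 3, seed=2)


def _tensor_signal(D, scheme, S0=1000.0):
    b = scheme.bvalues
    g = scheme.directions
    q = np.einsum("ni,ij,nj->n", g, D, g)
    return S0 * np.exp(-b * q)


def _volume(signals, scheme):
    """Stack 1-voxel signals into a (N,1,1,n) DwiVolume."""
    sig = np.asarray(signals, dtype=float).reshape(len(signals), 1, 1, -1)
    return DwiVolume(signal=sig, affine=np.eye(4), scheme=scheme)


# ---------------------------------------------------------------------------
# fit_dti
# ---------------------------------------------------------------------------

class TestFitDti:
    def test_isotropic_voxel(self, dti_scheme):
        D = np.eye(3) * 0.7e-3
        dwi = _volume([_tensor_signal(D, dti_scheme)], dti_scheme)
        tf = fit_dti(dwi)
        np.testing.assert_allclose(tf.eigenvalues[0, 0, 0], 0.7e-3, rtol=1e-8)

    def test_anisotropic_round_trip(self, dti_scheme):
        D = np.diag([1.7e-3, 0.2e-3, 0.2e-3])
        dwi = _volume([_tensor_signal(D, dti_scheme)], dti_scheme)
        tf = fit_dti(dwi)
        np.testing.assert_allclose(
            tf.eigenvalues[0, 0, 0], [1.7e-3, 0.2e-3, 0.2e-3], atol=1e-9
        )
        v = tf.eigenvectors[0, 0, 0, :, 0]
        assert abs(v @ [1, 0, 0]) > 1 - 1e-6

    def test_zero_signal_voxel_flagged(self, dti_scheme):
        dwi = _volume([np.zeros(len(dti_scheme))], dti_scheme)
        tf = fit_dti(dwi)
        assert tf.flagged[0, 0, 0]
        np.testing.assert_array_equal(tf.eigenvalues[0, 0, 0], 0.0)

    def test_eigenvalues_sorted_and_clamped(self, dti_scheme):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3)) * 1e-3
        D = A @ A.T / 3 + np.eye(3) * 1e-4
        dwi = _volume([_tensor_signal(D, dti_scheme)], dti_scheme)
        tf = fit_dti(dwi)
        lam = tf.eigenvalues[0, 0, 0]
        assert lam[0] >= lam[1] >= lam[2] >= 0

    def test_rotation_invariance_of_eigenvalues(self, dti_scheme):
        # rotating the gradient set and the tensor jointly leaves the
        # measured signal, hence FA/MD, unchanged
        D = np.diag([1.5e-3, 0.5e-3, 0.3e-3])
        rng = np.random.default_rng(4)
        R, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        rot_scheme = AcquisitionScheme(
            dti_scheme.bvalues, dti_scheme.directions @ R.T
        )
        a = fit_dti(_volume([_tensor_signal(D, dti_scheme)], dti_scheme))
        b = fit_dti(_volume([_tensor_signal(R @ D @ R.T, rot_scheme)], rot_scheme))
        np.testing.assert_allclose(
            a.eigenvalues[0, 0, 0], b.eigenvalues[0, 0, 0], rtol=1e-6
        )
        np.testing.assert_allclose(
            fa(a.eigenvalues), fa(b.eigenvalues), atol=1e-8
        )
        np.testing.assert_allclose(
            md(a.eigenvalues), md(b.eigenvalues), atol=1e-12
        )


# ---------------------------------------------------------------------------
# fa / md / dec_map
# ---------------------------------------------------------------------------

class TestScalars:
    def test_fa_isotropic_zero(self):
        assert fa(np.array([[0.7e-3, 0.7e-3, 0.7e-3]]))[0] == 0.0

    def test_fa_stick_limit_one(self):
        np.testing.assert_allclose(fa(np.array([[1.0, 0.0, 0.0]]))[0], 1.0,
                                   atol=1e-12)

    def test_fa_closed_form(self):
        # sqrt(3/2)*||lam - mean||/||lam|| for (1.7, 0.2, 0.2)e-3
        val = fa(np.array([[1.7e-3, 0.2e-3, 0.2e-3]]))[0]
        np.testing.assert_allclose(val, np.sqrt(2.25 / 2.97), rtol=1e-12)

    def test_fa_zero_eigenvalues_convention(self):
        assert fa(np.array([[0.0, 0.0, 0.0]]))[0] == 0.0

    def test_md_cases(self):
        np.testing.assert_allclose(
            md(np.array([[1.7e-3, 0.2e-3, 0.2e-3]]))[0], 0.7e-3, rtol=1e-12
        )
        assert md(np.array([[0.5, 0.5, 0.5]]))[0] == 0.5
        assert md(np.array([[0.0, 0.0, 0.0]]))[0] == 0.0

    def test_dec_conventions(self, dti_scheme):
        D = np.diag([1.7e-3, 0.2e-3, 0.2e-3])  # principal axis = x
        dwi = _volume(
            [_tensor_signal(D, dti_scheme), np.zeros(len(dti_scheme))], dti_scheme
        )
        tf = fit_dti(dwi)
        rgb = dec_map(tf)
        fa_val = fa(tf.eigenvalues)[0, 0, 0]
        np.testing.assert_allclose(rgb[0, 0, 0], [fa_val, 0.0, 0.0], atol=1e-6)
        np.testing.assert_array_equal(rgb[1, 0, 0], 0.0)  # FA=0 voxel is black


# ---------------------------------------------------------------------------
# predict_ball_stick
# ---------------------------------------------------------------------------

class TestPredict:
    def test_ball_only_closed_form(self):
        s = AcquisitionScheme(np.array([0.0, 2000.0]),
                              np.array([[0.0, 0, 0], [0.0, 0, 1]]))
        m = BallStickModel(S0=500.0, d=1.0e-3, fractions=np.zeros(0),
                          orientations=np.zeros((0, 3)))
        np.testing.assert_allclose(
            predict_ball_stick(m, s), [500.0, 500.0 * np.exp(-2.0)], rtol=1e-12
        )

    def test_mixed_model_closed_form(self):
        g = np.array([0.0, np.sin(np.pi / 3), np.cos(np.pi / 3)])
        s = AcquisitionScheme(np.array([1000.0]), g[None])
        v = np.array([0.0, 0.0, 1.0])
        m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.array([0.7]),
                          orientations=v[None])
        expect = 1000.0 * (
            0.3 * np.exp(-1.7) + 0.7 * np.exp(-1.7 * (g @ v) ** 2)
        )
        np.testing.assert_allclose(predict_ball_stick(m, s), [expect], rtol=1e-12)

    def test_model_invariants_enforced(self):
        with pytest.raises(ValueError):
            BallStickModel(S0=1.0, d=1e-3, fractions=np.array([0.7, 0.7]),
                           orientations=np.array([[0, 0, 1.0], [0, 1.0, 0]]))
        with pytest.raises(ValueError):
            BallStickModel(S0=1.0, d=1e-3, fractions=np.array([0.5]),
                           orientations=np.array([[0, 0, 2.0]]))


# ---------------------------------------------------------------------------
# fit_ball_stick_voxel / fit_ball_stick
# ---------------------------------------------------------------------------

class TestFitBallStick:
    def test_single_stick_recovery(self, scheme):
        m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.array([0.7]),
                          orientations=np.array([[0.0, 0, 1]]))
        fit = fit_ball_stick_voxel(predict_ball_stick(m, scheme), scheme, seed=0)
        assert fit.n_sticks == 1
        assert abs(fit.fractions[0] - 0.7) < 0.02
        ang = np.degrees(np.arccos(min(1.0, abs(fit.orientations[0] @ [0, 0, 1]))))
        assert ang < 2.0

    def test_two_stick_crossing_recovery(self, scheme):
        v = np.array([[1.0, 0, 0], [0.0, 0, 1]])
        m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.array([0.4, 0.4]),
                          orientations=v)
        fit = fit_ball_stick_voxel(predict_ball_stick(m, scheme), scheme, seed=0)
        assert fit.n_sticks == 2
        for true_v in v:
            best = max(abs(fit.orientations @ true_v))
            assert np.degrees(np.arccos(min(1.0, best))) < 5.0

    def test_isotropic_voxel_pure_ball(self, scheme):
        m = BallStickModel(S0=1000.0, d=0.7e-3, fractions=np.zeros(0),
                          orientations=np.zeros((0, 3)))
        fit = fit_ball_stick_voxel(predict_ball_stick(m, scheme), scheme, seed=0)
        assert fit.n_sticks == 0
        assert abs(fit.f0 - 1.0) < 1e-6

    def test_bic_never_overfits_noiseless(self, scheme):
        # model-selection sanity: k sticks never selected when the
        # generating voxel had k-1 at snr = inf
        rng = np.random.default_rng(6)
        for k_true in (0, 1, 2):
            for trial in range(3):
                if k_true == 0:
                    f = np.zeros(0)
                    v = np.zeros((0, 3))
                else:
                    f = np.full(k_true, 0.3)
                    v = np.eye(3)[:k_true] + 0.05 * rng.standard_normal((k_true, 3))
                    v /= np.linalg.norm(v, axis=1, keepdims=True)
                m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=f,
                                  orientations=v)
                fit = fit_ball_stick_voxel(
                    predict_ball_stick(m, scheme), scheme, seed=100 + trial
                )
                assert fit.n_sticks == k_true

    def test_determinism(self, scheme):
        m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.array([0.4, 0.3]),
                          orientations=np.array([[1.0, 0, 0], [0.0, 0.6, 0.8]]))
        y = predict_ball_stick(m, scheme)
        sig = 50.0
        rng = np.random.default_rng(9)
        y = np.hypot(y + sig * rng.standard_normal(len(y)),
                     sig * rng.standard_normal(len(y)))
        a = fit_ball_stick_voxel(y, scheme, seed=3)
        b = fit_ball_stick_voxel(y, scheme, seed=3)
        np.testing.assert_array_equal(a.fractions, b.fractions)
        np.testing.assert_array_equal(a.orientations, b.orientations)

    def test_volume_fit_mixed_voxels(self, scheme):
        stick = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.array([0.7]),
                              orientations=np.array([[0.0, 0, 1]]))
        ball = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.zeros(0),
                             orientations=np.zeros((0, 3)))
        sig = np.zeros((2, 1, 1, len(scheme)))
        sig[0, 0, 0] = predict_ball_stick(stick, scheme)
        sig[1, 0, 0] = predict_ball_stick(ball, scheme)
        dwi = DwiVolume(signal=sig, affine=np.eye(4), scheme=scheme)
        field = fit_ball_stick(dwi, seed=0)
        m0 = field.model_at((0, 0, 0))
        m1 = field.model_at((1, 0, 0))
        assert m0.n_sticks == 1
        assert abs(m0.fractions[0] - 0.7) < 0.02
        assert m1.n_sticks == 0
        assert abs(m1.f0 - 1.0) < 1e-3
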