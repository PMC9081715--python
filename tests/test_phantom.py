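"""Phantom generation: acquisition scheme, geometry, rasterization, signal."""

import logging

import numpy as np
import pytest

from somatotract import (
    AcquisitionScheme,
    BundleSpec,
    make_default_geometry,
    make_default_scheme,
    rasterize_bundles,
    simulate_signal,
)
from somatotract.core import GeometryError, InvalidSchemeError, world_to_voxel
from somatotract.models import predict_ball_stick, BallStickModel
from somatotract.phantom import SUBDIVISIONS, default_affine


# ---------------------------------------------------------------------------
# make_default_scheme
# ---------------------------------------------------------------------------

class TestScheme:
    def test_default_multishell_layout(self):
        s = make_default_scheme(90, [1000, 2000, 3000], 6, seed=1)
        assert len(s) == 96
        assert s.n_b0 == 6
        for b in (1000, 2000, 3000):
            assert s.shell_mask(b).sum() == 30

    def test_minimal_scheme(self):
        s = make_default_scheme(6, [1000], 1, seed=1)
        assert len(s) == 7
        dirs = s.directions[s.dwi_mask]
        assert dirs.shape == (6, 3)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)

    def test_same_shell_directions_spread(self):
        # brute-force check over all same-shell pairs
        s = make_default_scheme(90, [1000, 2000, 3000], 6, seed=1)
        for b in (1000, 2000, 3000):
            d = s.directions[s.shell_mask(b)]
            dots = d @ d.T
            np.fill_diagonal(dots, 0.0)
            assert dots.max() < 0.995

    def test_too_few_directions_rejected(self):
        with pytest.raises(InvalidSchemeError):
            make_default_scheme(3, [1000], 1, seed=0)
        with pytest.raises(InvalidSchemeError):
            make_default_scheme(10, [1000, 2000, 3000], 1, seed=0)

    def test_determinism(self):
        a = make_default_scheme(90, [1000, 2000, 3000], 6, seed=5)
        b = make_default_scheme(90, [1000, 2000, 3000], 6, seed=5)
        c = make_default_scheme(90, [1000, 2000, 3000], 6, seed=6)
        np.testing.assert_array_equal(a.directions, b.directions)
        assert not np.array_equal(a.directions, c.directions)

    def test_scheme_invariants_enforced(self):
        with pytest.raises(InvalidSchemeError):
            AcquisitionScheme(np.array([0.0, 1000.0]),
                              np.array([[0.0, 0, 0], [0, 0, 2.0]]))
        with pytest.raises(InvalidSchemeError):
            AcquisitionScheme(np.array([-5.0]), np.array([[1.0, 0, 0]]))


# ---------------------------------------------------------------------------
# make_default_geometry
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_six_bundles_endpoints(self, phantom):
        assert len(phantom.bundles) == 6
        names = {b.name for b in phantom.bundles}
        assert names == set(SUBDIVISIONS) | {"crossing"}
        truth = phantom.truth
        labels = {name: i + 1 for i, name in enumerate(SUBDIVISIONS)}
        for b in phantom.bundles:
            if b.role != "pathway":
                continue
            start = np.rint(world_to_voxel(truth.affine, b.centerline[0])).astype(int)
            end = np.rint(world_to_voxel(truth.affine, b.centerline[-1])).astype(int)
            assert truth.roi_m1_labels[tuple(start)] == labels[b.name]
            assert truth.roi_stn[tuple(end)]

    def test_stem_pierces_ic_slab(self, phantom):
        truth = phantom.truth
        pathway_field = truth.fractions.sum(axis=3) > 0
        assert (pathway_field & truth.roi_ic).sum() > 0

    def test_m1_patches_pairwise_disjoint(self, phantom):
        # voxel-set intersection oracle
        labels = phantom.truth.roi_m1_labels
        sets = [set(map(tuple, np.argwhere(labels == k))) for k in range(1, 6)]
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (sets[i] & sets[j])

    def test_m1_disjoint_from_stn(self, phantom):
        truth = phantom.truth
        assert not ((truth.roi_m1_labels > 0) & truth.roi_stn).any()

    def test_patch_order_medial_to_lateral(self, phantom):
        labels = phantom.truth.roi_m1_labels
        xs = [np.argwhere(labels == k)[:, 0].mean() for k in range(1, 6)]
        assert xs == sorted(xs)

    def test_grid_too_small_rejected(self):
        with pytest.raises(GeometryError):
            make_default_geometry((6, 6, 6), 1.25)


# ---------------------------------------------------------------------------
# rasterize_bundles
# ---------------------------------------------------------------------------

def _straight_tube(name="tube", z0=5.0, z1=55.0, x=15.0, y=15.0, radius=2.0):
    line = np.array([[x, y, z0], [x, y, (z0 + z1) / 2], [x, y, z1]])
    return BundleSpec(name=name, centerline=line, radius=radius, role="distractor")


def _params(shape=(24, 24, 48), voxel=1.25):
    """Minimal parameter set for rasterizing hand-built tubes: the ROI
    definitions are pushed into corners away from the test tubes."""
    extent = np.array(shape) * voxel
    return {
        "grid_shape": shape,
        "voxel_size_mm": voxel,
        "stem_radius": 1.0,
        "merge_z": -1.0,
        "patch_half_voxels": (0, 0, 0),
        "patch_centers": {
            name: np.array([3.0 + 2.0 * i, 3.0, extent[2] - 4.0])
            for i, name in enumerate(SUBDIVISIONS)
        },
        "stn_center": np.array([3.0, 3.0, 4.0]),
        "stn_axes": np.array([1.0, 1.0, 1.0]),
        "ic_bounds": np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]]),
    }


class TestRasterize:
    def test_single_tube_voxel_has_tube_tangent(self):
        truth = rasterize_bundles([_straight_tube()], _params())
        ijk = np.rint(world_to_voxel(truth.affine, [15.0, 15.0, 30.0])).astype(int)
        n = truth.n_compartments()[tuple(ijk)]
        assert n == 1
        v = truth.orientations[tuple(ijk)][0]
        assert abs(v @ [0, 0, 1]) > 1 - 1e-9

    def test_outside_tube_isotropic(self):
        truth = rasterize_bundles([_straight_tube()], _params())
        ijk = np.rint(world_to_voxel(truth.affine, [25.0, 25.0, 30.0])).astype(int)
        assert truth.n_compartments()[tuple(ijk)] == 0
        assert truth.brain_mask[tuple(ijk)]

    def test_crossing_region_two_distinct_compartments(self, phantom):
        # angle check on the rasterized field in the fan/crossing overlap:
        # the distractor runs along x, so fan/crossing voxels are the
        # 2-compartment voxels holding a near-x population
        truth = phantom.truth
        idx = np.argwhere(truth.n_compartments() == 2)
        min_angle, n_cross = 90.0, 0
        for ijk in idx:
            v1, v2 = truth.orientations[tuple(ijk)][:2]
            if max(abs(v1[0]), abs(v2[0])) < 0.95:
                continue
            n_cross += 1
            ang = np.degrees(np.arccos(min(1.0, abs(float(v1 @ v2)))))
            min_angle = min(min_angle, ang)
        assert n_cross > 0
        assert min_angle >= 45.0

    def test_fraction_invariants(self, phantom):
        frac = phantom.truth.fractions
        assert (frac >= 0).all()
        assert (frac.sum(axis=3) <= 1 + 1e-9).all()
        assert (phantom.truth.n_compartments() <= 3).all()

    def test_more_than_three_populations_trimmed_with_warning(self, caplog):
        # four tubes through the same voxel, pairwise far apart in angle
        c = np.array([15.0, 15.0, 30.0])
        dirs = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1],
             [1 / np.sqrt(3), 1 / np.sqrt(3), 1 / np.sqrt(3)]]
        )
        tubes = [
            BundleSpec(name=f"t{i}", centerline=np.array([c - 8 * d, c, c + 8 * d]),
                       radius=1.5)
            for i, d in enumerate(dirs)
        ]
        with caplog.at_level(logging.WARNING, logger="somatotract"):
            truth = rasterize_bundles(tubes, _params())
        assert (truth.n_compartments() <= 3).all()
        ijk = np.rint(world_to_voxel(truth.affine, c)).astype(int)
        assert truth.n_compartments()[tuple(ijk)] == 3
        assert any("population" in r.getMessage() for r in caplog.records)

    def test_gold_streamlines_consistent_with_field(self, phantom):
        truth = phantom.truth
        has_fiber = truth.n_compartments() > 0
        for name, pts in truth.gold_streamlines.items():
            v = np.rint(world_to_voxel(truth.affine, pts)).astype(int)
            assert has_fiber[tuple(v.T)].mean() > 0.99, name


# ---------------------------------------------------------------------------
# simulate_signal
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_b0_equals_s0(self, phantom, scheme, noiseless_dwi):
        truth = phantom.truth
        b0 = noiseless_dwi.signal[..., scheme.b0_mask]
        inside = truth.brain_mask
        np.testing.assert_allclose(b0[inside], 1000.0, atol=1e-9)

    def test_perpendicular_stick_no_attenuation(self):
        s = AcquisitionScheme(np.array([0.0, 1000.0]),
                              np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.array([1.0]),
                           orientations=np.array([[0.0, 0, 1]]))
        sig = predict_ball_stick(m, s)
        np.testing.assert_allclose(sig, [1000.0, 1000.0], atol=1e-9)

    def test_parallel_stick_closed_form(self):
        s = AcquisitionScheme(np.array([1000.0]), np.array([[0.0, 0, 1]]))
        m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.array([1.0]),
                           orientations=np.array([[0.0, 0, 1]]))
        np.testing.assert_allclose(
            predict_ball_stick(m, s), [1000.0 * np.exp(-1.7)], rtol=1e-12
        )

    def test_noiseless_matches_closed_form_everywhere(self, phantom, scheme,
                                                      noiseless_dwi):
        truth = phantom.truth
        ijk = tuple(np.argwhere(truth.n_compartments() == 1)[0])
        f = truth.fractions[ijk]
        keep = f > 0
        m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=f[keep],
                           orientations=truth.orientations[ijk][keep])
        np.testing.assert_allclose(
            noiseless_dwi.signal[ijk], predict_ball_stick(m, scheme), rtol=1e-12
        )

    def test_noise_reproducible_and_seed_sensitive(self, phantom, scheme):
        a = simulate_signal(phantom.truth, scheme, snr=20.0, seed=4)
        b = simulate_signal(phantom.truth, scheme, snr=20.0, seed=4)
        c = simulate_signal(phantom.truth, scheme, snr=20.0, seed=5)
        np.testing.assert_array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_noiseless_attenuation_monotone_in_b(self):
        g = np.array([0.3, 0.5, np.sqrt(1 - 0.09 - 0.25)])
        bvals = np.array([0.0, 500.0, 1000.0, 2000.0, 3000.0])
        s = AcquisitionScheme(bvals, np.vstack([[0, 0, 0.0]] + [g] * 4))
        m = BallStickModel(S0=1000.0, d=1.7e-3, fractions=np.array([0.4, 0.3]),
                           orientations=np.array([[0.0, 0, 1], [1.0, 0, 0]]))
        sig = predict_ball_stick(m, s)
        assert (np.diff(sig) <= 1e-12).all()

    def test_invalid_parameters_rejected(self, phantom, scheme):
        with pytest.raises(ValueError):
            simulate_signal(phantom.truth, scheme, S0=-1.0)
        with pytest.raises(ValueError):
            simulate_signal(phantom.truth, scheme, d=0.0)
        with pytest.raises(ValueError):
            simulate_signal(phantom.truth, scheme, snr=0.0)
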