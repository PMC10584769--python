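"""Spherical harmonics, direction sampling, and streamline propagation."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

import tractweave as tw
from tractweave.tracking import (DomainError, FodfField, ParameterError,
                                 TrackingError, fibonacci_sphere,
                                 n_coefficients, sh_basis)


def _isotropic_field(amplitude=1.0, shape=(6, 6, 6), order=8):
    coeffs = np.zeros(shape + (n_coefficients(order),))
    coeffs[..., 0] = amplitude * math.sqrt(4 * math.pi)
    return FodfField(coefficients=coeffs, max_order=order, affine=np.eye(4))


def _single_fiber_field(direction, kappa=12.0, shape=(6, 6, 6), order=8):
    """Analytic antipodal lobe projected to SH in every voxel."""
    quad = fibonacci_sphere(400)
    basis = sh_basis(order, quad)
    d = np.asarray(direction, float) / np.linalg.norm(direction)
    f = np.exp(kappa * ((quad @ d) ** 2 - 1.0))
    c = np.linalg.pinv(basis) @ f
    coeffs = np.broadcast_to(c, shape + (len(c),)).copy()
    return FodfField(coefficients=coeffs, max_order=order, affine=np.eye(4))


class TestSphericalHarmonics:
    def test_coefficient_count_follows_even_order_formula(self):
        assert [n_coefficients(o) for o in (0, 2, 4, 6, 8)] == [1, 6, 15, 28, 45]

    def test_basis_is_orthonormal_on_the_sphere(self):
        # Monte-Carlo check of orthonormality under uniform sphere measure
        dirs = fibonacci_sphere(8000)
        B = sh_basis(4, dirs)
        gram = 4 * math.pi * (B.T @ B) / len(dirs)
        assert np.allclose(gram, np.eye(B.shape[1]), atol=0.02)

    def test_isotropic_amplitude_equals_c0_y00(self):
        field = _isotropic_field(amplitude=0.7)
        for d in ([1, 0, 0], [0, 0, 1], [1, 1, 1]):
            amp = tw.fodf_amplitude(field, [2.0, 2.0, 2.0], d)
            assert amp == pytest.approx(0.7, rel=1e-6)

    def test_single_fiber_peaks_along_its_axis(self):
        field = _single_fiber_field([1, 0, 0])
        along = tw.fodf_amplitude(field, [2.0, 2, 2], [1, 0, 0])
        across = tw.fodf_amplitude(field, [2.0, 2, 2], [0, 0, 1])
        assert along > across

    def test_antipodal_symmetry_of_even_order_expansion(self):
        field = _single_fiber_field([1, 1, 0])
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = rng.normal(size=3)
            a1 = tw.fodf_amplitude(field, [2.0, 2, 2], d)
            a2 = tw.fodf_amplitude(field, [2.0, 2, 2], -d)
            assert a1 == pytest.approx(a2, rel=1e-9)

    def test_point_outside_domain_raises(self):
        field = _isotropic_field()
        with pytest.raises(DomainError):
            tw.fodf_amplitude(field, [50.0, 0, 0], [1, 0, 0])


class TestMaxStepAngle:
    def test_published_step_and_radius_give_11_478_degrees(self):
        assert tw.max_step_angle(0.2, 1.0) == \
            pytest.approx(math.degrees(2 * math.asin(0.1)), abs=1e-9)
        assert tw.max_step_angle(0.2, 1.0) == pytest.approx(11.478, abs=1e-3)

    def test_small_step_limit_is_zero(self):
        assert tw.max_step_angle(1e-9, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_step_equal_to_diameter_gives_180(self):
        assert tw.max_step_angle(2.0, 1.0) == pytest.approx(180.0)

    def test_overlong_step_is_a_parameter_error(self):
        with pytest.raises(ParameterError):
            tw.max_step_angle(2.1, 1.0)


class TestSampleDirection:
    def test_isotropic_sampling_is_uniform_over_octants(self):
        field = _isotropic_field()
        rng = np.random.default_rng(7)
        n = 20000
        pts = np.empty((n, 3))
        for i in range(n):
            d = tw.sample_direction(field, [2.5, 2.5, 2.5], None, 0.01, rng)
            pts[i] = d
        octant = (pts[:, 0] > 0) * 4 + (pts[:, 1] > 0) * 2 + (pts[:, 2] > 0)
        counts = np.bincount(octant, minlength=8)
        _, p = chisquare(counts)
        assert p > 1e-3

    def test_everything_below_cutoff_fails(self):
        field = _isotropic_field(amplitude=0.1)
        rng = np.random.default_rng(0)
        assert tw.sample_direction(field, [2.0, 2, 2], None, 0.5, rng) is None

    def test_lobe_with_tight_cone_stays_near_axis(self):
        field = _single_fiber_field([1, 0, 0], kappa=30.0)
        rng = np.random.default_rng(1)
        samples = np.array([
            tw.sample_direction(field, [2.0, 2, 2], np.array([1.0, 0, 0]),
                                0.01, rng, max_angle_deg=30.0)
            for _ in range(500)])
        mean = samples.mean(axis=0)
        mean /= np.linalg.norm(mean)
        assert math.degrees(math.acos(np.clip(mean[0], -1, 1))) < 5.0

    def test_seed_cone_restricts_first_direction(self):
        field = _isotropic_field()
        rng = np.random.default_rng(2)
        axis = np.array([0.0, 1.0, 0.0])
        for _ in range(100):
            d = tw.sample_direction(field, [2.0, 2, 2], None, 0.01, rng,
                                    cone_axis=axis, cone_half_angle_deg=45.0)
            assert d @ axis >= math.cos(math.radians(45.0)) - 1e-9


class TestPropagate:
    def test_straight_bundle_reaches_target_at_expected_length(self, bundle_phantom):
        rng = np.random.default_rng(0)
        params = bundle_phantom["protocol"].tracking_params()
        out = tw.propagate(np.array([0.0, -23.0, 0.0]), bundle_phantom["field"],
                           bundle_phantom["rois"], params, rng)
        assert out.accepted
        length = (len(out.streamline) - 1) * params.step_mm
        # seed near y=-23, target wall begins at y=20: ~43 mm end to end
        assert length == pytest.approx(43.0, rel=0.10)

    def test_exclusion_wall_rejects_crossings(self, bundle_phantom):
        from tractweave.synthetic import make_bundle_phantom
        walled = make_bundle_phantom(with_exclusion_wall=True)
        rng = np.random.default_rng(0)
        params = walled["protocol"].tracking_params()
        reasons = set()
        for _ in range(20):
            out = tw.propagate(np.array([0.0, -23.0, 0.0]), walled["field"],
                               walled["rois"], params, rng)
            assert not out.accepted
            reasons.add(out.reason)
        assert "entered_exclusion" in reasons

    def test_target_adjacent_to_seed_gives_minimal_streamline(self, bundle_phantom):
        rois = dict(bundle_phantom["rois"])
        seed = rois["seed"]
        # target wall immediately anterior of the seed point
        grid = np.zeros(seed.shape, dtype=np.uint8)
        grid[:, 4:, :] = 1      # voxel row just ahead on the 2 mm grid
        rois = {"seed": seed, "targets": [tw.ScalarMap(grid, seed.affine,
                                                       role="binary")],
                "excludes": [], "includes": []}
        rng = np.random.default_rng(0)
        params = bundle_phantom["protocol"].tracking_params()
        out = tw.propagate(np.array([0.0, -21.2, 0.0]), bundle_phantom["field"],
                           rois, params, rng)
        assert out.accepted and len(out.streamline) <= 5

    def test_seed_outside_mask_is_a_contract_error(self, bundle_phantom):
        rng = np.random.default_rng(0)
        params = bundle_phantom["protocol"].tracking_params()
        with pytest.raises(ValueError):
            tw.propagate(np.array([12.0, 27.0, 12.0]), bundle_phantom["field"],
                         bundle_phantom["rois"], params, rng)


class TestTrack:
    def test_exact_streamline_count(self, bundle_tracked):
        assert len(bundle_tracked) == 50
        assert bundle_tracked.meta["n_accepted"] == 50

    def test_fixed_seed_is_bit_identical(self, bundle_phantom):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            outs.append(tw.track(bundle_phantom["protocol"],
                                 bundle_phantom["field"],
                                 bundle_phantom["rois"], rng,
                                 n_streamlines=10))
        for a, b in zip(outs[0].streamlines, outs[1].streamlines):
            assert np.array_equal(a, b)

    def test_accepted_streamlines_satisfy_roi_contract(self, bundle_phantom,
                                                       bundle_tracked):
        rois = bundle_phantom["rois"]
        for sl in bundle_tracked:
            assert rois["seed"].contains(sl[:1])[0]
            assert rois["targets"][0].contains(sl[-1:])[0]

    def test_step_spacing_is_constant(self, bundle_tracked):
        step = bundle_tracked.meta["step_mm"]
        for sl in bundle_tracked.streamlines[:10]:
            seg = np.linalg.norm(np.diff(sl, axis=0), axis=1)
            assert np.allclose(seg, step, atol=1e-6)

    def test_curvature_bound_holds_everywhere(self, bundle_phantom,
                                              bundle_tracked):
        max_angle = math.radians(tw.max_step_angle(0.2, 1.0)) + 1e-9
        for sl in bundle_tracked:
            seg = np.diff(sl, axis=0)
            seg /= np.linalg.norm(seg, axis=1, keepdims=True)
            cosang = np.clip((seg[:-1] * seg[1:]).sum(axis=1), -1, 1)
            assert np.arccos(cosang).max() <= max_angle

    def test_disconnected_target_fails_with_dominant_reason(self):
        from tractweave.synthetic import make_bundle_phantom
        bp = make_bundle_phantom()
        rois = dict(bp["rois"])
        # move the target off the bundle into a dead corner
        grid = np.zeros(rois["seed"].shape, dtype=np.uint8)
        grid[0, 0, 0] = 1
        rois["targets"] = [tw.ScalarMap(grid, rois["seed"].affine,
                                        role="binary")]
        proto = bp["protocol"]
        proto.max_attempts_per_seed = 5
        with pytest.raises(TrackingError, match="no_target|max_length"):
            tw.track(proto, bp["field"], rois,
                     np.random.default_rng(0), n_streamlines=5)

    def test_cutoff_shrinks_admissible_direction_set(self, bundle_phantom):
        # monotonicity of the cutoff: the set of directions admissible at
        # a higher threshold is nested inside the lower-threshold set,
        # and a cutoff above the lobe peak admits nothing
        field = bundle_phantom["field"]
        from tractweave.tracking import _DirectionTable
        table = _DirectionTable.get(field.max_order)
        coefs = field.interpolate_coefficients(np.array([[0.0, 0.0, 0.0]]))[0]
        amp = np.maximum(table.basis @ coefs, 0.0)
        gmax = field.global_max_amplitude()
        admissible = [set(np.flatnonzero(amp >= f * gmax))
                      for f in (0.05, 0.2, 0.5)]
        assert admissible[2] <= admissible[1] <= admissible[0]

    def test_seed_in_sub_cutoff_background_accepts_nothing(self, bundle_phantom):
        # seeds in background-only voxels (isotropic amplitude below the
        # cutoff) can never start: dominant rejection is no_direction
        import copy
        proto = copy.deepcopy(bundle_phantom["protocol"])
        proto.max_attempts_per_seed = 5
        rois = dict(bundle_phantom["rois"])
        grid = np.zeros(rois["seed"].shape, dtype=np.uint8)
        grid[0:2, 0:2, 0:2] = 1       # far corner, off the bundle
        rois["seed"] = tw.ScalarMap(grid, rois["seed"].affine, role="binary")
        with pytest.raises(TrackingError, match="no_direction"):
            tw.track(proto, bundle_phantom["field"], rois,
                     np.random.default_rng(5), n_streamlines=5)

    def test_empty_seed_is_a_tracking_error(self, bundle_phantom):
        rois = dict(bundle_phantom["rois"])
        empty = np.zeros(rois["seed"].shape, dtype=np.uint8)
        rois["seed"] = tw.ScalarMap(empty, rois["seed"].affine, role="binary")
        with pytest.raises(TrackingError):
            tw.track(bundle_phantom["protocol"], bundle_phantom["field"],
                     rois, np.random.default_rng(0))
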