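import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retinosign.fieldsign import (INDETERMINATE, MIRROR, NONMIRROR,
                                  FieldSignMap, GradientField, VectorField,
                                  classify_sign, estimate_gradients,
                                  field_sign_angle, meridian_correct,
                                  sign_at_points)
from retinosign.gridding import GridField
from retinosign.synthetic import sample_penetrations, strip_cortex

from conftest import make_table


def grid_from(fn, lo=0.0, hi=4.0, spacing=0.5):
    ax = np.arange(lo, hi + spacing / 2, spacing)
    xx, yy = np.meshgrid(ax, ax)
    vals = fn(xx, yy)
    return GridField(origin=(lo, lo), spacing=spacing, values=vals,
                     mask=np.ones_like(vals, dtype=bool))


def uniform_gradients(ru, rv, tu, tv, n=5):
    shape = (n, n)
    valid = np.ones(shape, dtype=bool)

    def vf(u, v):
        return VectorField(u=np.full(shape, float(u)),
                           v=np.full(shape, float(v)), valid=valid,
                           step=0.5, origin=(0.0, 0.0), spacing=0.5)

    return GradientField(grad_r=vf(ru, rv), grad_theta=vf(tu, tv))


class TestEstimateGradients:
    def test_linear_field_exact(self):
        g = estimate_gradients(grid_from(lambda x, y: 2.0 * x), step=0.5)
        assert g.valid.any()
        np.testing.assert_allclose(g.u[g.valid], 2.0, atol=1e-12)
        np.testing.assert_allclose(g.v[g.valid], 0.0, atol=1e-12)

    def test_constant_field_zero(self):
        g = estimate_gradients(grid_from(lambda x, y: 0 * x + 3.0), step=0.5)
        np.testing.assert_allclose(g.u[g.valid], 0.0, atol=1e-12)
        np.testing.assert_allclose(g.v[g.valid], 0.0, atol=1e-12)

    def test_quadratic_central_difference_exact(self):
        # central difference of x**2 at x=1 equals 2 for any step h
        field = grid_from(lambda x, y: x ** 2, lo=0.0, hi=2.0, spacing=0.25)
        for step in (0.5, 1.0):
            g = estimate_gradients(field, step=step)
            j = int(round((1.0 - field.origin[0]) / field.spacing))
            i = field.shape[0] // 2
            assert g.valid[i, j]
            assert g.u[i, j] == pytest.approx(2.0, abs=1e-12)

    def test_step_below_spacing_errors(self):
        with pytest.raises(ValueError, match="step"):
            estimate_gradients(grid_from(lambda x, y: x), step=0.1)

    def test_missing_neighbor_excluded(self):
        field = grid_from(lambda x, y: x, spacing=0.5)
        field.mask[4, 4] = False
        field.values[4, 4] = np.nan
        g = estimate_gradients(field, step=1.0)
        # all cells whose stencil touches (4, 4) are invalid
        assert not g.valid[4, 3] and not g.valid[4, 5]
        assert not g.valid[3, 4] and not g.valid[5, 4]
        assert not g.valid[4, 4]

    def test_stencil_rounded_to_whole_cells(self):
        g = estimate_gradients(grid_from(lambda x, y: x, spacing=0.5),
                               step=0.6)
        assert g.step == pytest.approx(1.0)  # one whole cell each way


class TestFieldSignAngle:
    def test_quarter_turn_clockwise_is_nonmirror(self):
        fsm = classify_sign(field_sign_angle(
            uniform_gradients(1, 0, 0, -1)))
        assert np.allclose(fsm.lam[fsm.valid], np.pi / 2)
        assert np.all(fsm.sign_class[fsm.valid] == NONMIRROR)

    def test_quarter_turn_counterclockwise_is_mirror(self):
        fsm = classify_sign(field_sign_angle(
            uniform_gradients(1, 0, 0, 1)))
        assert np.allclose(fsm.lam[fsm.valid], 3 * np.pi / 2)
        assert np.all(fsm.sign_class[fsm.valid] == MIRROR)

    @given(angle=st.floats(0, 2 * math.pi),
           lam=st.floats(0.2, 2 * math.pi - 0.2))
    @settings(max_examples=50, deadline=None)
    def test_joint_rotation_leaves_lambda_unchanged(self, angle, lam):
        # grad_theta at clockwise angle lam from grad_r, both rotated
        ru, rv = math.cos(angle), math.sin(angle)
        tu, tv = math.cos(angle - lam), math.sin(angle - lam)
        fsm = field_sign_angle(uniform_gradients(ru, rv, tu, tv),
                               min_magnitude=0.1)
        assert np.allclose((fsm.lam[fsm.valid] - lam) % (2 * math.pi), 0,
                           atol=1e-9) or np.allclose(
            (fsm.lam[fsm.valid] - lam) % (2 * math.pi), 2 * math.pi,
            atol=1e-9)

    def test_subthreshold_gradient_indeterminate(self):
        fsm = classify_sign(field_sign_angle(
            uniform_gradients(0.1, 0, 0, -5), min_magnitude=0.5))
        assert not fsm.valid.any()
        assert np.all(fsm.sign_class == INDETERMINATE)


class TestClassifySign:
    def test_lambda_90_shades_positive(self):
        fsm = classify_sign(field_sign_angle(uniform_gradients(1, 0, 0, -1)))
        assert np.all(fsm.shade[fsm.valid] > 0.95)

    def test_lambda_270_shades_negative(self):
        fsm = classify_sign(field_sign_angle(uniform_gradients(1, 0, 0, 1)))
        assert np.all(fsm.shade[fsm.valid] < -0.95)

    def test_lambda_0_and_pi_indeterminate(self):
        for tu, tv in ((1.0, 0.0), (-1.0, 0.0)):  # lam = 0 and pi
            fsm = classify_sign(field_sign_angle(
                uniform_gradients(1, 0, tu, tv)))
            assert np.allclose(fsm.shade[fsm.valid], 0.0, atol=1e-12)
            assert np.all(fsm.sign_class == INDETERMINATE)

    def test_shade_is_odd_and_saturates(self):
        lam = np.linspace(0, 2 * np.pi, 101)
        fsm = FieldSignMap(lam=lam.reshape(1, -1),
                           sign_class=np.zeros((1, 101), dtype=np.int8),
                           shade=np.zeros((1, 101)),
                           valid=np.ones((1, 101), dtype=bool),
                           origin=(0.0, 0.0), spacing=0.5)
        out = classify_sign(fsm)
        s = out.shade[0]
        np.testing.assert_allclose(s, -s[::-1], atol=1e-9)  # odd in sin(lam)
        assert s.max() <= 1.0 + 1e-12 and s.min() >= -1.0 - 1e-12


class TestMeridianCorrect:
    def test_beta_zero_identity(self, three_strip_table):
        out = meridian_correct(three_strip_table, 0.0)
        assert out.records == three_strip_table.records

    def test_cap_at_horizontal_meridian(self):
        # center just below the HM with a huge RF: clamped at theta = 0,
        # never pushed through to the vertical meridian
        table = make_table([(0.0, 0.0, 20.0, -5.0, 40.0, 40.0, 0.0)])
        out = meridian_correct(table, 1.0)
        assert out.records[0].theta == pytest.approx(0.0)

    def test_cap_at_vertical_meridian(self):
        table = make_table([(0.0, 0.0, 20.0, 80.0, 40.0, 40.0, 0.0)])
        out = meridian_correct(table, 1.0)
        assert out.records[0].theta == pytest.approx(90.0)

    def test_moves_toward_nearer_meridian(self):
        table = make_table([(0.0, 0.0, 30.0, 20.0, 4.0, 4.0, 0.0),
                            (0.0, 0.0, 30.0, 70.0, 4.0, 4.0, 0.0)])
        out = meridian_correct(table, 0.5)
        assert 0.0 <= out.records[0].theta < 20.0     # toward HM
        assert 70.0 < out.records[1].theta <= 90.0    # toward VM

    def test_invalid_beta(self, three_strip_table):
        with pytest.raises(ValueError):
            meridian_correct(three_strip_table, 1.5)


class TestInvariances:
    """Sign-class invariance under coordinate transforms (grid-free)."""

    @pytest.fixture(scope="class")
    @staticmethod
    def dataset():
        cortex = strip_cortex(n_strips=3, strip_width=2.0, height=6.0,
                              scatter_sd=1.0, seed=11)
        table = sample_penetrations(cortex, 0.5, 0.5, seed=11)
        rng = np.random.default_rng(99)
        probes = np.column_stack([rng.uniform(0.5, 5.5, 150),
                                  rng.uniform(0.5, 5.5, 150)])
        lam, cls = sign_at_points(table.xy, table.r, table.theta, probes,
                                  alpha=1.0, epsilon=0.15)
        return table, probes, lam, cls

    def test_rotation_invariance(self, dataset):
        table, probes, lam0, cls0 = dataset
        rng = np.random.default_rng(7)
        for _ in range(3):
            ang = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(ang), -np.sin(ang)],
                            [np.sin(ang), np.cos(ang)]])
            _, cls = sign_at_points(table.xy @ rot.T, table.r, table.theta,
                                    probes @ rot.T, alpha=1.0, epsilon=0.15,
                                    axes=rot)
            np.testing.assert_array_equal(cls, cls0)

    def test_translation_invariance(self, dataset):
        table, probes, lam0, cls0 = dataset
        shift = np.array([13.25, -4.7])
        _, cls = sign_at_points(table.xy + shift, table.r, table.theta,
                                probes + shift, alpha=1.0, epsilon=0.15)
        np.testing.assert_array_equal(cls, cls0)

    def test_scaling_invariance(self, dataset):
        # scaling cortical mm rescales the unit-bearing parameters with it
        table, probes, lam0, cls0 = dataset
        s = 2.3
        _, cls = sign_at_points(table.xy * s, table.r, table.theta,
                                probes * s, alpha=1.0 / s ** 2, epsilon=0.15,
                                step=0.5 * s, min_magnitude=0.5 / s)
        np.testing.assert_array_equal(cls, cls0)

    def test_theta_offset_invariance(self, dataset):
        table, probes, lam0, cls0 = dataset
        _, cls = sign_at_points(table.xy, table.r, table.theta + 31.0,
                                probes, alpha=1.0, epsilon=0.15)
        np.testing.assert_array_equal(cls, cls0)

    def test_r_scaling_invariance(self, dataset):
        table, probes, lam0, cls0 = dataset
        c = 3.0
        _, cls = sign_at_points(table.xy, table.r * c, table.theta, probes,
                                alpha=1.0, epsilon=0.15,
                                min_magnitude_r=0.5 * c)
        np.testing.assert_array_equal(cls, cls0)

    def test_mirror_swaps_classes(self, dataset):
        table, probes, lam0, cls0 = dataset
        flip = np.diag([-1.0, 1.0])
        lam, cls = sign_at_points(table.xy @ flip, table.r, table.theta,
                                  probes @ flip, alpha=1.0, epsilon=0.15)
        np.testing.assert_array_equal(cls, -cls0)
        ok = ~np.isnan(lam0)
        wrapped = (lam0[ok] + lam[ok]) % (2 * np.pi)
        wrapped = np.minimum(wrapped, 2 * np.pi - wrapped)
        np.testing.assert_allclose(wrapped, 0.0, atol=1e-9)


class TestConformalAnalyticCase:
    def test_nonmirror_lambda_near_90(self, conformal_results):
        from retinosign.gridding import interior_mask
        _, results = conformal_results
        fsm = results["fieldsign"]
        interior = interior_mask(results["eccentricity"], 2.5) & fsm.valid
        lam = np.degrees(fsm.lam[interior])
        assert interior.sum() > 500
        assert np.mean(np.abs(lam - 90.0) <= 1.0) >= 0.99
        assert np.all(fsm.sign_class[interior] == NONMIRROR)
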