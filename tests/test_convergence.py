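"""Finite-difference convergence, equatorial means, strain rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ringflow import convergence as cv
from ringflow import scene
from ringflow.fields import FlowField


class TestConvergenceField:
    def test_uniform_field_has_zero_convergence(self):
        field, _, _ = scene.analytic_flow_field(
            "uniform", {"u0": 0.2, "v0": -0.1}, shape=(5, 7), spacing=2.9)
        c = cv.convergence_field(field)
        assert np.allclose(c.p, 0.0) and np.allclose(c.q, 0.0)

    def test_linear_sink_exact_at_interior_and_boundary(self):
        k1, k2 = 0.004, 0.006
        field, p_true, q_true = scene.analytic_flow_field(
            "linear_sink", {"k1": k1, "k2": k2, "x0": 8.0, "y0": 3.0},
            shape=(6, 6), spacing=2.9)
        c = cv.convergence_field(field)
        # scheme is exact on linear fields everywhere (one-sided stencils
        # are exact on degree-1 polynomials too)
        assert np.abs(c.p - p_true).max() < 1e-6
        assert np.abs(c.q - q_true).max() < 1e-6

    def test_matches_numpy_gradient_oracle(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=(6, 8))
        v = rng.normal(size=(6, 8))
        field = FlowField(u=u, v=v, spacing=2.9)
        c = cv.convergence_field(field)
        assert np.allclose(c.p, -np.gradient(u, 2.9, axis=1))
        assert np.allclose(c.q, -np.gradient(v, 2.9, axis=0))

    @settings(derandomize=True, max_examples=50)
    @given(cu=st.floats(-1, 1), cvv=st.floats(-1, 1))
    def test_constant_offset_invariance(self, cu, cvv):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(5, 5))
        v = rng.normal(size=(5, 5))
        c1 = cv.convergence_field(FlowField(u=u, v=v, spacing=1.0))
        c2 = cv.convergence_field(FlowField(u=u + cu, v=v + cvv,
                                            spacing=1.0))
        assert np.allclose(c1.p, c2.p, atol=1e-12, rtol=0)
        assert np.allclose(c1.q, c2.q, atol=1e-12, rtol=0)

    def test_invalid_vectors_mask_their_stencil(self):
        valid = np.ones((5, 5), bool)
        valid[2, 2] = False
        field = FlowField(u=np.zeros((5, 5)), v=np.zeros((5, 5)),
                          spacing=1.0, valid=valid)
        c = cv.convergence_field(field)
        # along the A-P axis the cells using u[2,2] are (2,1), (2,2), (2,3)
        assert not c.valid_p[2, 1] and not c.valid_p[2, 2] and not c.valid_p[2, 3]
        assert c.valid_p[2, 0]
        assert not c.valid_q[1, 2] and not c.valid_q[2, 2] and not c.valid_q[3, 2]

    def test_single_column_grid_rejected(self):
        field = FlowField(u=np.zeros((3, 1)), v=np.zeros((3, 1)), spacing=1.0)
        with pytest.raises(ValueError, match="A-P"):
            cv.convergence_field(field)


class TestEquatorialMean:
    def _const_conv(self, value, shape=(9, 9), spacing=2.9):
        field = FlowField(u=np.zeros(shape), v=np.zeros(shape),
                          spacing=spacing)
        c = cv.convergence_field(field)
        c.p[:] = value
        c.q[:] = value
        return c

    def test_constant_field_mean_is_constant(self):
        c = self._const_conv(0.007)
        res = cv.equatorial_mean([c], furrow_x=4 * 2.9)
        assert res["mean_p"][0] == pytest.approx(0.007)
        assert res["mean_q"][0] == pytest.approx(0.007)

    def test_linear_sink_block_mean_equals_rate(self):
        k = 0.005
        field, _, _ = scene.analytic_flow_field(
            "linear_sink", {"k1": k, "k2": 0.0, "x0": 10.0},
            shape=(9, 9), spacing=2.9)
        c = cv.convergence_field(field)
        res = cv.equatorial_mean([c], furrow_x=4 * 2.9)
        assert res["mean_p"][0] == pytest.approx(k, abs=1e-9)

    def test_clipped_block_warns(self):
        c = self._const_conv(0.003)
        with pytest.warns(UserWarning, match="clipped"):
            res = cv.equatorial_mean([c], furrow_x=0.0)
        assert res["mean_p"][0] == pytest.approx(0.003)

    def test_all_masked_block_is_nan(self):
        c = self._const_conv(0.003)
        c.valid_p[:] = False
        c.valid_q[:] = False
        res = cv.equatorial_mean([c], furrow_x=4 * 2.9)
        assert np.isnan(res["mean_p"][0]) and np.isnan(res["mean_q"][0])


class TestRelaxationRate:
    def test_linear_fall_between_interval_ends(self):
        t = np.arange(0.0, 61.0, 5.0)
        y = 0.02 - 0.0005 * t  # 0.02 at t=0 -> -0.01 at t=60
        res = cv.relaxation_rate(t, y, t_start=0.0, t_stop=60.0,
                                 smooth_window=1)
        assert not res.censored
        assert res.rate == pytest.approx(-5e-4)
        assert res.t_max == 0.0 and res.t_min == 60.0

    def test_monotone_rise_is_censored(self):
        t = np.arange(0.0, 61.0, 5.0)
        res = cv.relaxation_rate(t, 0.001 * t, t_start=0.0, t_stop=60.0,
                                 smooth_window=1)
        assert res.censored

    def test_noisy_constructed_extrema_within_15pct(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 120.0, 5.6)
        # bump up to a max at 30 s then trough at 90 s
        y = np.interp(t, [0, 30, 90, 120], [0.0, 0.02, -0.01, 0.0])
        true_rate = (-0.01 - 0.02) / (90.0 - 30.0)
        y_noisy = y + rng.normal(0, 0.0005, t.size)
        res = cv.relaxation_rate(t, y_noisy, t_start=0.0, t_stop=120.0)
        assert not res.censored
        assert res.rate == pytest.approx(true_rate, rel=0.15)


class TestLongitudinalStrainRate:
    def test_hand_computed_shrink(self):
        t = np.array([0.0, 27.9])
        d = np.array([10.0, 9.0])
        ts, rates = cv.longitudinal_strain_rate(t, d)
        assert rates[0] == pytest.approx(-1.0 / (10.0 * 27.9))

    def test_stationary_pair_has_zero_rate(self):
        t = np.arange(0.0, 60.0, 5.6)
        ts, rates = cv.longitudinal_strain_rate(t, np.full(t.size, 7.0))
        assert np.allclose(rates, 0.0)

    def test_linear_sink_matches_closed_form(self):
        # pair distance under d' = -k d: d(t) = d0 exp(-k t), so the
        # horizon estimator returns (exp(-k H) - 1) / H exactly
        k, H = 0.005, 27.9
        t = np.arange(0.0, 120.0, 5.58)  # 5 frames = H exactly
        d = 12.0 * np.exp(-k * t)
        ts, rates = cv.longitudinal_strain_rate(t, d, horizon=H)
        expected = (np.exp(-k * H) - 1.0) / H
        assert np.allclose(rates, expected, atol=1e-12)
        assert abs(abs(rates.mean()) - k) / k < 0.25  # small-horizon limit

    def test_unnormalized_flag(self):
        t = np.array([0.0, 27.9])
        d = np.array([10.0, 9.0])
        _, rates = cv.longitudinal_strain_rate(t, d, normalize=False)
        assert rates[0] == pytest.approx(-1.0 / 27.9)

    def test_zero_reference_distance_rejected(self):
        t = np.array([0.0, 27.9])
        with pytest.raises(ValueError, match="zero"):
            cv.longitudinal_strain_rate(t, np.array([0.0, 1.0]))

    def test_insufficient_overlap_rejected(self):
        t = np.array([0.0, 5.6, 11.2])
        with pytest.raises(ValueError, match="horizon"):
            cv.longitudinal_strain_rate(t, np.array([5.0, 5.0, 5.0]),
                                        horizon=27.9)


def test_sink_scene_strain_and_convergence_agree_in_sign():
    """On a circumferential-sink cortex the two compression estimators
    (block-mean convergence, focus-pair strain rate) agree in sign."""
    from ringflow import piv, tracking

    k = 0.005
    cfg = scene.SceneConfig(
        flow_params=scene.FlowParams(ring_amplitude=0.0, circ_rate=k),
        n_frames=12)
    truth = scene.build_scene(cfg)
    stack = scene.render_cortex_stack(truth)
    fields = [piv.filter_vectors(piv.compute_piv(
        stack[i], stack[i + 1], dt=cfg.frame_interval,
        pixel_size=cfg.pixel_size, t=truth.t[i])) for i in range(4)]
    convs = [cv.convergence_field(f) for f in fields]
    res = cv.equatorial_mean(convs, furrow_x=cfg.extent_um[0] / 2)
    assert np.nanmean(res["mean_q"]) > 0

    # strain rate from ground-truth foci spanning the equator
    w, h = cfg.extent_um
    y0 = truth.foci[0, :, 1]
    top = np.argmin(np.abs(y0 - 0.25 * h))
    bot = np.argmin(np.abs(y0 - 0.75 * h))
    d = np.abs(truth.foci[:, top, 1] - truth.foci[:, bot, 1])
    _, rates = cv.longitudinal_strain_rate(truth.t, d)
    assert np.all(rates < 0)
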