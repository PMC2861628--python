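"""K-field coefficients, the analytic information channel, and the
sparsity-threshold relation."""

import dataclasses

import numpy as np
import pytest
from scipy.special import ndtr

from mossyinfo.analytic import (
    AnalyticParams,
    _channel_stats,
    _config_rng,
    _config_signal,
    analytic_channel,
    field_count_coeffs,
    limit_equivalence_check,
    linear_limit_info,
    sample_total_fields,
    single_unit_info,
    sparsity_given_threshold,
    threshold_for_sparsity,
)
from mossyinfo.errors import ParameterError

SMOKE = dict(n_configs=40, grid_points=32, seed=0)


class TestFieldCountCoeffs:
    def test_closed_form_zero_masses(self):
        lam, nu = 1.65, 1.7
        assert field_count_coeffs("C", lam).psi[0] == pytest.approx(np.exp(-lam))
        psi0_a = field_count_coeffs("A", lam, nu).psi[0]
        assert psi0_a == pytest.approx(np.exp(-lam * (1 - np.exp(-nu))), abs=1e-12)

    @pytest.mark.parametrize("model,nu", [("A", 1.7), ("B", 1.7), ("C", None)])
    def test_normalization_and_monte_carlo_agreement(self, model, nu):
        dec = field_count_coeffs(model, 1.65, nu)
        assert dec.tail() < 1e-6
        assert np.all(dec.psi >= 0)
        n = 1_000_000
        draws = sample_total_fields(model, 1.65, nu, n, rng_seed=123)
        hist = np.bincount(draws, minlength=dec.psi.size)[: dec.psi.size] / n
        se = np.sqrt(np.maximum(dec.psi * (1 - dec.psi), 1e-12) / n)
        assert np.all(np.abs(hist - dec.psi) <= 3 * se + 1e-4)

    def test_model_c_is_exactly_poisson(self):
        from scipy.stats import poisson

        dec = field_count_coeffs("C", 1.65)
        np.testing.assert_allclose(
            dec.psi, poisson.pmf(np.arange(dec.psi.size), 1.65), atol=1e-15
        )

    def test_mean_total_fields(self):
        # lambda * nu = 1.65 * 1.7 = 2.805 fields per CA3 unit on average
        dec = field_count_coeffs("A", 1.65, 1.7)
        k = np.arange(dec.psi.size)
        assert dec.psi @ k == pytest.approx(2.805, abs=1e-4)  # truncated tail


class TestSingleFieldLimit:
    def test_discrepancy_small_at_tiny_nu(self):
        assert limit_equivalence_check("A", 1.65, [1e-3])[0] < 1e-3

    def test_discrepancy_order_one_at_standard_nu(self):
        assert limit_equivalence_check("A", 2.805, [1.7])[0] > 0.01

    @pytest.mark.parametrize("model", ["A", "B"])
    def test_monotone_convergence(self, model):
        disc = limit_equivalence_check(model, 1.65, [0.5, 0.1, 0.01]
                                       if model == "A" else [2.0, 1.2, 1.01])
        assert np.all(np.diff(disc) < 0)


class TestChannelStats:
    def test_zero_signal_carries_no_information(self):
        mi, h, eq = _channel_stats(np.zeros(64), 1.0, 1.0, 241)
        assert mi == pytest.approx(0.0, abs=1e-12)
        assert h == pytest.approx(eq)

    def test_histogram_oracle_single_config(self):
        """Quadrature MI for one fixed field configuration agrees with a
        brute-force plug-in estimate from simulated (x, eta) pairs."""
        params = AnalyticParams(n_configs=40, grid_points=16, seed=0)
        u = _config_signal(params, 3, _config_rng(0, 3, 0))
        theta, delta = 1.0, 1.0
        mi, _, _ = _channel_stats(u, theta, delta, 481)

        rng = np.random.default_rng(99)
        reps = 4000  # stratified: every grid point visited equally
        x_idx = np.repeat(np.arange(u.size), reps)
        eta = np.maximum(u[x_idx] - theta + rng.normal(0, delta, x_idx.size), 0.0)
        edges = np.linspace(0, eta.max() + 1e-9, 41)
        sym = np.where(eta == 0.0, 0, 1 + np.digitize(eta, edges))

        def plugin_corrected(sy):
            joint = np.zeros((u.size, sym.max() + 1))
            np.add.at(joint, (x_idx, sy), 1.0)
            pj = joint / joint.sum()
            px = pj.sum(1, keepdims=True)
            pr = pj.sum(0, keepdims=True)
            nz = pj > 0
            mi_hat = float((pj[nz] * np.log2(pj[nz] / (px @ pr)[nz])).sum())
            r_rows = (joint > 0).sum(1)
            bias = (np.sum(r_rows - 1) - ((pr > 0).sum() - 1)) / (
                2 * x_idx.size * np.log(2)
            )
            return mi_hat - bias

        est = plugin_corrected(sym)
        # residual higher-order sampling bias estimated by shuffling
        null = np.mean([plugin_corrected(rng.permutation(sym)) for _ in range(3)])
        assert est - null == pytest.approx(mi, rel=0.05)

    def test_information_decreases_with_noise(self):
        params = AnalyticParams(**SMOKE)
        u = _config_signal(params, 3, _config_rng(0, 3, 1))
        mis = [_channel_stats(u, 1.0, d, 241)[0] for d in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(mis) < 0)

    def test_quadrature_refinement_stable(self):
        params = AnalyticParams(**SMOKE)
        u = _config_signal(params, 4, _config_rng(0, 4, 2))
        coarse = _channel_stats(u, 1.0, 1.0, 241)[0]
        fine = _channel_stats(u, 1.0, 1.0, 481)[0]
        assert fine == pytest.approx(coarse, rel=0.01)


class TestQuenchedChannel:
    def test_no_signal_means_no_information(self):
        res = analytic_channel(AnalyticParams(j_strength=0.0, theta=1.0, **SMOKE))
        assert res.info_bits == pytest.approx(0.0, abs=1e-9)

    def test_entropy_minus_equivocation_is_information(self):
        res = analytic_channel(AnalyticParams(**SMOKE))
        assert res.entropy_bits - res.equivocation_bits == pytest.approx(
            res.info_bits, rel=0.01, abs=1e-4
        )

    def test_linear_limit_reached_at_very_low_threshold(self):
        """As theta -> -inf the rectification never engages and the unit is
        linear; at weak signal the information matches the closed
        signal-to-noise form within 2% (shared center draws)."""
        params = AnalyticParams(j_strength=0.1, theta=-8.0, **SMOKE)
        assert single_unit_info(params) == pytest.approx(
            linear_limit_info(params), rel=0.02
        )

    def test_linear_limit_monotone_in_noise(self):
        vals = [
            linear_limit_info(
                AnalyticParams(j_strength=0.5, theta=-8.0, noise_sd=d, **SMOKE)
            )
            for d in (0.5, 1.0, 2.0)
        ]
        assert np.all(np.diff(vals) < 0)

    def test_c_mf_and_p_active_enter_as_product(self):
        a = analytic_channel(AnalyticParams(c_mf=50.0, p_active=0.033, **SMOKE))
        b = analytic_channel(AnalyticParams(c_mf=100.0, p_active=0.0165, **SMOKE))
        assert a.info_bits == pytest.approx(b.info_bits, rel=1e-6)


class TestSparsityThreshold:
    def test_monotone_decreasing(self):
        params = AnalyticParams(**SMOKE)
        thetas = np.linspace(-2.0, 3.0, 21)
        a = [sparsity_given_threshold(t, params) for t in thetas]
        assert np.all(np.diff(a) < 0)

    def test_inversion_round_trip(self):
        params = AnalyticParams(**SMOKE)
        theta = threshold_for_sparsity(0.1, params)
        assert sparsity_given_threshold(theta, params) == pytest.approx(0.1, abs=1e-3)

    def test_threshold_rises_with_input_strength(self):
        thetas = [
            threshold_for_sparsity(
                0.1, AnalyticParams(j_strength=j, **SMOKE), tol=1e-6
            )
            for j in (0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(thetas) > 0)

    def test_invalid_target(self):
        with pytest.raises(ParameterError):
            threshold_for_sparsity(1.5, AnalyticParams(**SMOKE))

    def test_low_threshold_approaches_linear_value(self):
        # all units effectively above threshold: a -> its theta->-inf plateau
        params = AnalyticParams(**SMOKE)
        a1 = sparsity_given_threshold(-20.0, params)
        a2 = sparsity_given_threshold(-40.0, params)
        assert a1 == pytest.approx(a2, abs=5e-3)
        assert a1 > 0.9

    def test_fixed_theta_simulation_matches_inversion(self):
        """A simulation run at the analytically inverted threshold realizes
        the target sparsity (cross-module consistency)."""
        from mossyinfo.ca3 import CA3Params
        from mossyinfo.dg import DGParams
        from mossyinfo.simulate import SessionParams, run_session

        theta = threshold_for_sparsity(0.1, AnalyticParams(**SMOKE))
        sp = SessionParams(
            dg=DGParams(n_dg=5000),
            ca3=CA3Params(n_ca3=200),
            n_steps=4000,
            threshold_mode="fixed",
            fixed_theta=theta,
        )
        sess = run_session(sp, 77)
        assert sess.mean_sparsity == pytest.approx(0.1, abs=0.02)
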