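"""Kinetic model function, correlation extraction and global fitting."""

import numpy as np
import pytest

import photonflc as pf


def one_component_model(k_u_to_q=2e4, k_q_to_u=1e4, b=(3.0, 1.0)):
    K = np.array([[-k_u_to_q, k_q_to_u], [k_u_to_q, -k_q_to_u]])
    return pf.FLCModel(
        components=[pf.KineticComponent(brightness=np.asarray(b), rate_matrix=K)],
        state_lifetimes_ns=np.array([2.5, 0.5]),
    )


class TestModelCorrelation:
    def test_matches_closed_form_two_state(self):
        comp = pf.two_state_component(k_u_to_q=2e4, k_q_to_u=1e4)
        lags = np.geomspace(1e-6, 1.0, 60)
        oracle = pf.closed_form_two_state_correlation(comp, lags)
        model = pf.FLCModel(
            components=[
                pf.KineticComponent(
                    brightness=comp.state_emission_rates,
                    rate_matrix=comp.transition_rates,
                )
            ]
        )
        got = pf.model_correlation(model, lags)
        np.testing.assert_allclose(got.values, oracle.values, rtol=1e-10)

    def test_all_rates_zero_constant_in_lag(self):
        model = pf.FLCModel(
            components=[
                pf.KineticComponent(
                    brightness=[3.0, 1.0],
                    rate_matrix=np.zeros((2, 2)),
                    populations=[0.4, 0.6],
                )
            ]
        )
        cs = pf.model_correlation(model, np.geomspace(1e-6, 10, 25))
        assert np.ptp(cs.values, axis=0).max() < 1e-14

    def test_two_identical_components_positive_cross_offset(self):
        comp = pf.KineticComponent(
            brightness=[3.0, 1.0],
            rate_matrix=np.array([[-2e4, 1e4], [2e4, -1e4]]),
        )
        comp2 = pf.KineticComponent(
            brightness=[3.0, 1.0],
            rate_matrix=np.array([[-2e4, 1e4], [2e4, -1e4]]),
        )
        model = pf.FLCModel(components=[comp, comp2])
        cs = pf.model_correlation(model, [1e-9])
        assert cs.values[0, 0, 1] > 0.1  # begins above zero

    def test_symmetric_in_state_pair(self):
        model = pf.FLCModel(
            components=[
                pf.KineticComponent(
                    brightness=[5.0, 1.0],
                    rate_matrix=np.array([[-3e4, 0.5e4], [3e4, -0.5e4]]),
                ),
                pf.KineticComponent(
                    brightness=[1.0, 2.0],
                    rate_matrix=np.array([[-1e3, 4e3], [1e3, -4e3]]),
                ),
            ]
        )
        cs = pf.model_correlation(model, np.geomspace(1e-6, 1, 20))
        np.testing.assert_allclose(
            cs.values, np.swapaxes(cs.values, 1, 2), rtol=1e-12
        )

    def test_zero_brightness_component_is_inert(self):
        base = one_component_model()
        ghost = pf.KineticComponent(
            brightness=[0.0, 0.0],
            rate_matrix=np.array([[-1e3, 1e3], [1e3, -1e3]]),
        )
        extended = pf.FLCModel(components=base.components + [ghost])
        lags = np.geomspace(1e-6, 1, 30)
        np.testing.assert_allclose(
            pf.model_correlation(base, lags).values,
            pf.model_correlation(extended, lags).values,
            rtol=1e-12,
        )

    def test_non_generator_matrix_rejected(self):
        with pytest.raises(ValueError, match="generator"):
            pf.KineticComponent(brightness=[1.0, 1.0], rate_matrix=np.eye(2))


class TestGlobalFit:
    def make_noisy_data(self, model, seed=0, rel_noise=0.01):
        lags = np.geomspace(1e-6, 0.1, 50)
        cs = pf.model_correlation(model, lags)
        rng = np.random.default_rng(seed)
        sig = rel_noise * np.abs(cs.values) + 1e-4
        noisy = cs.values + rng.normal(0.0, sig)
        return pf.CorrelationSet(
            lags_s=lags,
            values=noisy,
            sigmas=sig,
            state_photon_fractions=cs.state_photon_fractions,
            state_lifetimes_ns=np.array([2.5, 0.5]),
        )

    def test_self_consistency_recovery(self):
        """1-component model + 1% noise: rates within 10%, populations within 0.05."""
        truth = one_component_model(k_u_to_q=2e4, k_q_to_u=1e4)
        data = self.make_noisy_data(truth, seed=5)
        fit = pf.fit_global_model(data, 1, seed=2, n_starts=8)
        K = fit.components[0].rate_matrix
        assert K[1, 0] == pytest.approx(2e4, rel=0.10)
        assert K[0, 1] == pytest.approx(1e4, rel=0.10)
        np.testing.assert_allclose(
            fit.components[0].populations,
            truth.components[0].populations,
            atol=0.05,
        )

    def test_static_data_rates_at_lower_bound(self):
        lags = np.geomspace(1e-6, 0.1, 40)
        flat = np.ones((40, 2, 2))
        data = pf.CorrelationSet(
            lags_s=lags,
            values=flat,
            sigmas=np.full_like(flat, 0.01),
            state_photon_fractions=np.array([0.5, 0.5]),
        )
        fit = pf.fit_global_model(data, 1, seed=0, n_starts=4)
        pred = pf.model_correlation(fit, lags).values
        assert np.ptp(pred, axis=0).max() < 0.02  # flat model reproduced

    def test_invalid_inputs(self):
        data = self.make_noisy_data(one_component_model())
        with pytest.raises(ValueError):
            pf.fit_global_model(data, 0)
        data.missing[:] = True
        with pytest.raises(ValueError):
            pf.fit_global_model(data, 1)

    def test_residuals_uncorrelated_on_self_generated_data(self):
        """Runs test on fit residuals across lags (5% level)."""
        truth = one_component_model()
        data = self.make_noisy_data(truth, seed=11)
        fit = pf.fit_global_model(data, 1, seed=3, n_starts=8)
        pred = pf.model_correlation(fit, data.lags_s).values
        r = ((data.values - pred) / data.sigmas)[:, 0, 0]
        signs = r > 0
        runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
        n1, n2 = int(signs.sum()), int((~signs).sum())
        mu = 1 + 2 * n1 * n2 / (n1 + n2)
        var = (mu - 1) * (mu - 2) / (n1 + n2 - 1)
        z = (runs - mu) / np.sqrt(max(var, 1e-12))
        assert abs(z) < 1.96


class TestExtractCorrelations:
    def test_static_single_state_flat_autocorrelation(self):
        comp = pf.EmitterComponentSpec(
            state_lifetimes_ns=[2.5],
            state_emission_rates=[2e4],
            transition_rates=np.zeros((1, 1)),
        )
        cfg = pf.SimulationConfig(
            components=[comp], n_molecules=10, trace_duration_s=1.0, seed=6
        )
        streams, _ = pf.simulate_ensemble(cfg)
        dist = pf.mem_ilt_1d(pf.build_decay_histogram(streams))
        states = pf.assign_states(dist)
        assert states.n_states == 1
        stack = pf.build_2dfd(
            streams, lag_edges_s=np.geomspace(1e-5, 0.1, 21), seed=1
        )
        cs = pf.extract_correlations(stack, dist, states)
        g = cs.values[~cs.missing, 0, 0]
        assert np.all(np.abs(g - 1.0) < 0.05)

    def test_two_state_decay_rate_recovered(self):
        """Auto-correlation relaxation within 20% of k12 + k21 = 3e4/s."""
        from scipy.optimize import curve_fit

        comp = pf.two_state_component(k_u_to_q=2e4, k_q_to_u=1e4)
        cfg = pf.SimulationConfig(
            components=[comp], n_molecules=10, trace_duration_s=1.5, seed=19
        )
        streams, _ = pf.simulate_ensemble(cfg)
        dist = pf.mem_ilt_1d(pf.build_decay_histogram(streams))
        states = pf.assign_states(dist)
        stack = pf.build_2dfd(
            streams, lag_edges_s=np.geomspace(1e-5, 0.3, 45), seed=2
        )
        cs = pf.extract_correlations(stack, dist, states)
        keep = ~cs.missing
        lags, g = cs.lags_s[keep], cs.values[keep, 0, 0]

        def model(lag, amp, rate, base):
            return base + amp * np.exp(-rate * lag)

        popt, _ = curve_fit(
            model, lags, g, p0=(1.0, 1e4, 1.0), maxfev=20000
        )
        assert popt[1] == pytest.approx(3e4, rel=0.20)

    def test_empty_lag_bins_flagged_missing(self):
        comp = pf.two_state_component()
        cfg = pf.SimulationConfig(
            components=[comp], n_molecules=3, trace_duration_s=0.05, seed=3
        )
        streams, _ = pf.simulate_ensemble(cfg)
        dist = pf.mem_ilt_1d(pf.build_decay_histogram(streams))
        states = pf.assign_states(dist)
        # last lag bins exceed the trace duration: no pairs possible there
        stack = pf.build_2dfd(streams, lag_edges_s=np.geomspace(1e-4, 10, 26), seed=0)
        cs = pf.extract_correlations(stack, dist, states)
        assert cs.missing[-1]
        assert np.isnan(cs.values[-1]).all()


def test_component_count_selection_one_component():
    """A single-process ensemble is not over-fitted with extra components."""
    comp = pf.two_state_component(k_u_to_q=2e4, k_q_to_u=1e4)
    cfg = pf.SimulationConfig(
        components=[comp], n_molecules=20, trace_duration_s=3.0, seed=21
    )
    streams, _ = pf.simulate_ensemble(cfg)
    dist = pf.mem_ilt_1d(pf.build_decay_histogram(streams))
    states = pf.assign_states(dist)
    stack = pf.build_2dfd(streams, lag_edges_s=np.geomspace(1e-5, 1.0, 51), seed=22)
    cs = pf.extract_correlations(stack, dist, states)
    best, _ = pf.select_component_count(cs, (1, 2), seed=4)
    assert best == 1
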