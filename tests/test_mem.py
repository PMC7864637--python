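"""Maximum-entropy lifetime inversion and 2D decay construction."""

import numpy as np
import pytest

import photonflc as pf
from photonflc.mem import (
    DecayHistogram,
    LifetimeGrid,
    TwoDFDStack,
    assign_states,
    build_2dfd,
    build_decay_histogram,
    decay_kernel,
    mem_ilt_1d,
    mem_ilt_2d,
)
from conftest import make_stream

PERIOD, IRF = 12.5, 0.38


def forward_decay(tau_ns, n_counts, n_bins=250, irf=IRF):
    """Noise-free decay histogram from the continuous forward model."""
    edges = np.linspace(0.0, PERIOD, n_bins + 1)
    grid = LifetimeGrid(np.array([tau_ns * 0.999, tau_ns]))
    p = decay_kernel(grid, edges, irf, PERIOD)[:, 1]
    return DecayHistogram(edges, p / p.sum() * n_counts, irf, PERIOD)


def test_kernel_columns_are_normalized_densities():
    grid = LifetimeGrid.default(20)
    P = decay_kernel(grid, np.linspace(0, PERIOD, 129), IRF, PERIOD)
    assert np.all(P >= 0)
    np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-6)


class TestDecayHistogram:
    def test_single_occupied_bin(self):
        s = make_stream(np.linspace(0, 1, 100), np.full(100, 1.0))
        d = build_decay_histogram([s], bin_width_ns=0.5)
        assert d.counts.sum() == 100
        assert (d.counts > 0).sum() == 1
        assert d.counts.max() == 100

    def test_mean_matches_lifetime_plus_irf_moment(self, two_state_streams):
        """Simulated tau=2.5 ns single state: histogram mean ~ oracle moment."""
        comp = pf.EmitterComponentSpec(
            state_lifetimes_ns=[2.5],
            state_emission_rates=[5000.0],
            transition_rates=np.zeros((1, 1)),
        )
        cfg = pf.SimulationConfig(
            components=[comp], n_molecules=1, trace_duration_s=20.0, seed=2
        )
        streams, _ = pf.simulate_ensemble(cfg)
        d = build_decay_histogram(streams, bin_width_ns=0.05)
        emp_mean = np.sum(d.bin_centers_ns * d.counts) / d.counts.sum()
        oracle = forward_decay(2.5, 1.0)
        oracle_mean = np.sum(oracle.bin_centers_ns * oracle.counts) / oracle.counts.sum()
        assert emp_mean == pytest.approx(oracle_mean, rel=0.01)

    def test_mixed_periods_rejected(self, meta):
        import dataclasses

        other = dataclasses.replace(meta, excitation_period_ns=25.0)
        s1 = make_stream([0.1], [1.0])
        s2 = make_stream([0.1], [1.0], meta=other)
        with pytest.raises(ValueError, match="mixed"):
            build_decay_histogram([s1, s2])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_decay_histogram([])


class TestMem1D:
    def test_noiseless_single_exponential_localizes(self):
        """1e6 counts at tau = 2.5 ns: >=90% of mass within one grid spacing."""
        dist = mem_ilt_1d(forward_decay(2.5, 1e6), chi2_target=0.01)
        grid = dist.grid
        a = dist.normalized()
        near = np.abs(np.log(grid.lifetimes_ns / 2.5)) <= grid.log_spacing * 1.001
        assert a[near].sum() >= 0.90

    def test_equal_mixture_two_separated_peaks(self):
        d1, d2 = forward_decay(0.5, 5e5), forward_decay(2.5, 5e5)
        decay = DecayHistogram(d1.bin_edges_ns, d1.counts + d2.counts, IRF, PERIOD)
        dist = mem_ilt_1d(decay, chi2_target=0.05)
        states = assign_states(dist)
        assert states.n_states == 2
        means = np.sort(states.mean_lifetimes_ns)
        assert means[0] == pytest.approx(0.5, rel=0.15)
        assert means[1] == pytest.approx(2.5, rel=0.15)

    def test_amplitudes_nonnegative_and_chi2_met_on_poisson_data(self):
        # tau = 2.5 at 1e6 counts keeps every bin well-populated, so the
        # Poisson-weighted chi2 target of 1 is attainable
        rng = np.random.default_rng(0)
        d = forward_decay(2.5, 1e6)
        noisy = DecayHistogram(
            d.bin_edges_ns, rng.poisson(d.counts).astype(float), IRF, PERIOD
        )
        dist = mem_ilt_1d(noisy, chi2_target=1.0)
        assert np.all(dist.amplitudes >= 0)
        # the target or, on realizations whose chi2 floor sits above it, the
        # recorded best achievable value (within sampling noise of 1)
        assert dist.chi2_reduced <= 1.05

    def test_empty_decay_rejected(self):
        d = DecayHistogram(np.linspace(0, PERIOD, 11), np.zeros(10), IRF, PERIOD)
        with pytest.raises(ValueError):
            mem_ilt_1d(d)


class TestAssignStates:
    def make_dist(self, amplitudes):
        grid = LifetimeGrid.default(len(amplitudes))
        return pf.LifetimeDistribution(grid, np.asarray(amplitudes, float), 1.0)

    def test_unimodal_single_state(self):
        a = np.exp(-0.5 * (np.arange(60.0) - 30) ** 2 / 9)
        assert assign_states(self.make_dist(a)).n_states == 1

    def test_bimodal_two_states_boundary_between(self):
        x = np.arange(60.0)
        a = np.exp(-0.5 * (x - 25) ** 2 / 4) + np.exp(-0.5 * (x - 45) ** 2 / 4)
        st = assign_states(self.make_dist(a))
        assert st.n_states == 2
        assert 25 < st.boundaries[0] <= 45

    def test_equal_minima_tie_broken_at_lower_index(self):
        a = np.zeros(60)
        a[10] = 1.0
        a[50] = 1.0  # flat zero valley: every interior point ties as minimum
        st = assign_states(self.make_dist(a))
        assert st.n_states == 2
        assert st.boundaries[0] == 11  # first minimum index after the peak

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            assign_states(self.make_dist(np.zeros(60)))

    def test_state_count_stable_under_grid_refinement(self):
        """Bimodal 0.5/2.5 ns fixture: same state count on 60 and 120 points."""
        counts = []
        d1, d2 = forward_decay(0.5, 5e5), forward_decay(2.5, 5e5)
        decay = DecayHistogram(d1.bin_edges_ns, d1.counts + d2.counts, IRF, PERIOD)
        for n in (60, 120):
            dist = mem_ilt_1d(decay, grid=LifetimeGrid.default(n), chi2_target=0.05)
            counts.append(assign_states(dist).n_states)
        assert counts[0] == counts[1] == 2


class TestBuild2DFD:
    def test_matches_brute_force_without_cap(self):
        comp = pf.two_state_component(k_u_to_q=2e4, k_q_to_u=1e4)
        cfg = pf.SimulationConfig(
            components=[comp], n_molecules=6, trace_duration_s=0.04, seed=13
        )
        streams, _ = pf.simulate_ensemble(cfg)
        assert all(s.n_photons <= 1200 for s in streams)
        edges = np.array([1e-4, 1e-3, 1e-2])
        stack = build_2dfd(
            streams,
            lag_edges_s=edges,
            microtime_bins=16,
            max_pairs_per_bin=10**8,
            seed=0,
        )
        for b in range(2):
            oracle = sum(
                pf.brute_force_pair_histogram(
                    s, (edges[b], edges[b + 1]), stack.microtime_edges_ns
                )
                for s in streams
            )
            np.testing.assert_array_equal(stack.matrices[b], oracle)
            assert stack.total_pairs[b] == oracle.sum()

    def test_cross_molecule_pairs_never_counted(self):
        s1 = make_stream([0.0, 1e-3], [1.0, 2.0], molecule_id="a")
        s2 = make_stream([0.5e-3, 1.5e-3], [3.0, 4.0], molecule_id="b")
        stack = build_2dfd(
            [s1, s2], lag_edges_s=np.array([1e-4, 1e-2]), microtime_bins=8, seed=0
        )
        assert stack.total_pairs[0] == 2  # one in-molecule pair each

    def test_subsampling_records_bookkeeping(self, two_state_streams):
        streams, _, _ = two_state_streams
        edges = np.array([1e-3, 1e-2])
        full = build_2dfd(streams, lag_edges_s=edges, microtime_bins=8, seed=0)
        capped = build_2dfd(
            streams, lag_edges_s=edges, microtime_bins=8, max_pairs_per_bin=1000, seed=0
        )
        assert capped.total_pairs[0] == full.total_pairs[0]
        assert capped.used_pairs[0] == 1000
        assert capped.matrices[0].sum() == 1000

    def test_no_pairs_anywhere_rejected(self):
        s = make_stream([0.0, 10.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="no photon pairs"):
            build_2dfd(s and [s], lag_edges_s=np.array([1e-4, 1e-3]), seed=0)

    def test_stationary_matrix_symmetric_within_noise(self, two_state_streams):
        streams, _, _ = two_state_streams
        stack = build_2dfd(
            streams, lag_edges_s=np.array([1e-4, 1e-3]), microtime_bins=8, seed=0
        )
        M = stack.matrices[0].astype(float)
        asym = np.abs(M - M.T)
        sigma = np.sqrt(M + M.T + 1.0)
        assert np.all(asym <= 6.0 * sigma)


class TestMem2D:
    @staticmethod
    def stack_from_matrix(M, edges):
        return TwoDFDStack(
            lag_edges_s=np.array([1e-4, 1e-3]),
            microtime_edges_ns=edges,
            matrices=M[None].astype(np.int64),
            total_pairs=np.array([int(M.sum())]),
            used_pairs=np.array([int(M.sum())]),
            seed=0,
            irf_fwhm_ns=IRF,
            excitation_period_ns=PERIOD,
        )

    def test_separable_input_recovers_unimodal_rank_one(self):
        grid = LifetimeGrid.default(40)
        edges = np.linspace(0, PERIOD, 33)
        P = decay_kernel(grid, edges, IRF, PERIOD)
        k = int(np.argmin(np.abs(grid.lifetimes_ns - 2.5)))
        M = 1e6 * np.outer(P[:, k], P[:, k])
        A0, g = mem_ilt_2d(self.stack_from_matrix(M, edges), grid, chi2_target=0.01)
        a = A0.normalized()
        near = np.abs(np.log(grid.lifetimes_ns / 2.5)) <= 2 * grid.log_spacing
        assert a[near].sum() >= 0.9
        W = np.outer(A0.amplitudes, A0.amplitudes) * g
        sv = np.linalg.svd(W, compute_uv=False)
        assert sv[0] / sv.sum() >= 0.8  # dominant rank-1 structure

    def test_symmetric_input_gives_symmetric_g(self):
        grid = LifetimeGrid.default(30)
        edges = np.linspace(0, PERIOD, 33)
        P = decay_kernel(grid, edges, IRF, PERIOD)
        k1 = int(np.argmin(np.abs(grid.lifetimes_ns - 0.5)))
        k2 = int(np.argmin(np.abs(grid.lifetimes_ns - 2.5)))
        M = 4e5 * (np.outer(P[:, k1], P[:, k2]) + np.outer(P[:, k2], P[:, k1]))
        _, g = mem_ilt_2d(self.stack_from_matrix(M, edges), grid, chi2_target=0.05)
        np.testing.assert_allclose(g, g.T, atol=1e-10)

    def test_static_two_population_diagonal_dominant(self):
        grid = LifetimeGrid.default(40)
        edges = np.linspace(0, PERIOD, 33)
        P = decay_kernel(grid, edges, IRF, PERIOD)
        k1 = int(np.argmin(np.abs(grid.lifetimes_ns - 0.5)))
        k2 = int(np.argmin(np.abs(grid.lifetimes_ns - 2.5)))
        M = 5e5 * np.outer(P[:, k1], P[:, k1]) + 5e5 * np.outer(P[:, k2], P[:, k2])
        A0, g = mem_ilt_2d(self.stack_from_matrix(M, edges), grid, chi2_target=0.01)
        W = np.outer(A0.amplitudes, A0.amplitudes) * g
        short = grid.lifetimes_ns < 1.2
        qq = W[np.ix_(short, short)].sum()
        uu = W[np.ix_(~short, ~short)].sum()
        cross = W.sum() - qq - uu
        assert cross < 0.1 * (qq + uu)
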