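"""Markov gating: rate laws, fixed-step sampler, exact-SSA oracle."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import null_space

from sparkcell import gating
from sparkcell.gating import (LCCChannelState, RyR2ClusterState, RateSet,
                              StepSizeError, gillespie_exact, lcc_rates,
                              luminal_phi, ryr2_rates, step_channels,
                              step_counts, stationary_distribution)


def stationary_oracle(q):
    """Independent stationary solution via the generator's null space."""
    g = q - np.diag(q.sum(axis=1))
    ns = null_space(g.T)
    pi = ns[:, 0]
    return pi / pi.sum()


class TestLuminalPhi:
    def test_slope_free(self):
        for ca in (0.0, 100.0, 2000.0):
            assert luminal_phi(0.0, 0.7, ca) == 0.7

    def test_affine(self):
        phi_m, phi_b, c = 1.5e-3, 0.05, 700.0
        assert luminal_phi(phi_m, phi_b, 2 * c) - luminal_phi(phi_m, phi_b, c) \
            == pytest.approx(phi_m * c)

    def test_mutant_slope_increase(self, params):
        # 90 % larger slope raises Φ by 0.9·phi_m·ca_sr exactly
        phi_m = params.channels.phi_m
        phi_b = params.channels.phi_b
        ca = 1000.0
        delta = luminal_phi(1.9 * phi_m, phi_b, ca) - luminal_phi(phi_m, phi_b, ca)
        assert delta == pytest.approx(0.9 * phi_m * ca)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            luminal_phi(-1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            luminal_phi(1.0, 0.0, -1.0)


class TestRyR2Rates:
    def test_closed_at_zero_subspace_ca(self, params):
        rs = ryr2_rates(RyR2ClusterState.resting(), 0.0, 1000.0,
                        params.channels)
        assert rs.rate(0, 1) == 0.0

    def test_only_diagram_edges(self, params):
        rs = ryr2_rates(RyR2ClusterState.resting(), 10.0, 1000.0,
                        params.channels)
        allowed = {(0, 1), (1, 0), (1, 2), (2, 0)}
        nz = {(i, j) for i in range(3) for j in range(3)
              if i != j and rs.q[i, j] > 0}
        assert nz <= allowed

    def test_open_fraction_increases_with_luminal_ca(self, params):
        # stationary open probability is non-decreasing in ca_jsr
        opens = []
        for ca_jsr in (400.0, 800.0, 1600.0):
            q = gating.ryr2_rate_matrix(5.0, ca_jsr, params.channels)
            opens.append(stationary_oracle(q)[1])
        assert opens[0] < opens[1] < opens[2]

    def test_stationary_matches_long_run_stepper(self, params, rng):
        """Single-channel 3-state chain: analytic stationary distribution vs
        empirical occupancy of the fixed-step engine, within 3 SE."""
        q = gating.ryr2_rate_matrix(8.0, 1000.0, params.channels)
        pi = stationary_oracle(q)
        n_ch, dt, n_steps = 49, 0.05, 4000
        counts = RyR2ClusterState.resting(n_ch).counts()
        occ = np.zeros(3)
        burn = 1000
        for k in range(n_steps):
            counts = step_counts(counts, q, dt, rng)
            if k >= burn:
                occ += counts
        occ /= occ.sum()
        n_eff = n_ch * (n_steps - burn) * dt / 20.0  # crude decorrelation
        se = np.sqrt(pi * (1 - pi) / max(n_eff, 1))
        assert np.all(np.abs(occ - pi) < 3 * se + 0.02)


class TestLCCRates:
    def test_no_ca_inactivation_without_ca(self, params):
        rs = lcc_rates(LCCChannelState.resting(), 0.0, 0.0, params.channels)
        assert rs.rate(1, 3) == 0.0

    def test_ca_inactivation_increasing(self, params):
        rates = [lcc_rates(LCCChannelState.resting(), 0.0, ca,
                           params.channels).rate(1, 3)
                 for ca in (0.0, 10.0, 50.0, 200.0)]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_resting_open_probability_tiny(self, params):
        q = gating.lcc_rate_matrix(-85.0, 0.1, params.channels)
        pi = stationary_oracle(q)
        assert pi[1] + pi[2] < 1e-3

    def test_activation_at_depolarized_v(self, params):
        q_rest = gating.lcc_rate_matrix(-85.0, 0.1, params.channels)
        q_dep = gating.lcc_rate_matrix(10.0, 0.1, params.channels)
        assert q_dep[0, 1] > 100 * q_rest[0, 1]


class TestStepChannels:
    def test_zero_rates_no_change(self, rng):
        state = RyR2ClusterState(n_c1=20, n_o2=20, n_c3=9)
        out = step_channels(state, RateSet(q=np.zeros((3, 3))), 0.05, rng)
        assert out == state

    def test_count_conservation(self, params, rng):
        state = RyR2ClusterState.resting(49)
        rs = ryr2_rates(state, 50.0, 1000.0, params.channels)
        dt = min(0.05, 0.09 / rs.max_exit_rate)
        for _ in range(200):
            state = step_channels(state, rs, dt, rng)
            assert state.n_total == 49
            assert min(state.n_c1, state.n_o2, state.n_c3) >= 0

    def test_lcc_per_channel_conservation(self, params, rng):
        state = LCCChannelState.resting(14)
        rs = lcc_rates(state, 0.0, 20.0, params.channels)
        dt = min(0.05, 0.09 / rs.max_exit_rate)
        for _ in range(200):
            state = step_channels(state, rs, dt, rng)
            assert len(state.states) == 14
            assert state.counts().sum() == 14

    def test_seed_determinism(self, params):
        rs = ryr2_rates(RyR2ClusterState.resting(), 30.0, 1000.0,
                        params.channels)
        dt = min(0.05, 0.09 / rs.max_exit_rate)

        def run(seed):
            rng = np.random.default_rng(seed)
            s = RyR2ClusterState.resting()
            return [step_channels(s, rs, dt, rng) for _ in range(50)]

        assert run(7) == run(7)
        assert run(7) != run(8)

    def test_step_size_cap_enforced(self, rng):
        q = np.zeros((2, 2))
        q[0, 1] = 10.0  # 10/ms exit rate
        with pytest.raises(StepSizeError, match="substep"):
            step_counts(np.array([5, 0]), q, 0.05, rng)

    def test_two_state_occupancy_matches_ssa(self, rng):
        """2-state toy (k12=1/ms, k21=2/ms): fixed-step occupancy matches the
        exact-SSA occupancy by chi-square at p > 0.01."""
        q = np.array([[0.0, 1.0], [2.0, 0.0]])
        dt = 0.05
        n_steps = 100_000
        counts = np.array([1, 0])
        occ = np.zeros(2, dtype=int)
        for _ in range(n_steps):
            counts = step_counts(counts, q, dt, rng)
            occ += counts
        t, traj = gillespie_exact(np.array([1, 0]), q, 5000.0,
                                  np.random.default_rng(99))
        dwell = np.diff(t)
        ssa_occ = np.array([(dwell * traj[:-1][:, s]).sum() for s in (0, 1)])
        p_ssa = ssa_occ / ssa_occ.sum()
        # thin to roughly independent samples before the chi-square
        thin = int(np.ceil(1.0 / dt / (q[0, 1] + q[1, 0]) * 10))
        occ_thin = occ / occ.sum() * (n_steps // thin)
        chi = stats.chisquare(occ_thin, p_ssa * occ_thin.sum())
        assert chi.pvalue > 0.01


class TestGillespieExact:
    def test_absorbing_state(self, rng):
        q = np.array([[0.0, 1.0], [0.0, 0.0]])
        t, traj = gillespie_exact(np.array([3, 0]), q, 1e4, rng)
        assert traj[-1].tolist() == [0, 3]
        # after full absorption nothing changes
        assert (traj[-1] == traj[-2]).all()

    def test_zero_rates_constant(self, rng):
        t, traj = gillespie_exact(np.array([2, 1]), np.zeros((2, 2)), 10.0, rng)
        assert len(traj) == 2 and (traj[0] == traj[1]).all()

    def test_exponential_dwell_mean(self, rng):
        """Single channel, single exit at k = 1/ms → mean dwell 1 ms ± 3 SE."""
        q = np.array([[0.0, 1.0], [0.0, 0.0]])
        n = 10_000
        dwells = []
        for _ in range(n):
            t, traj = gillespie_exact(np.array([1, 0]), q, 1e3, rng)
            dwells.append(t[1])
        m = np.mean(dwells)
        se = np.std(dwells, ddof=1) / np.sqrt(n)
        assert abs(m - 1.0) < 3 * se

    def test_first_opening_time_matches_fine_stepper(self, params):
        """First-opening time of the RyR2 cluster at fixed Ca: fixed-step
        engine at small dt agrees with the exact SSA (KS p > 0.01)."""
        q = gating.ryr2_rate_matrix(1.5, 1000.0, params.channels)
        n = 600
        rng1 = np.random.default_rng(5)
        ssa_times = []
        for _ in range(n):
            t, traj = gillespie_exact(
                RyR2ClusterState.resting().counts(), q, 1e5, rng1)
            opened = np.flatnonzero(traj[:, 1] > 0)
            ssa_times.append(t[opened[0]] if len(opened) else 1e5)
        rng2 = np.random.default_rng(6)
        dt = 0.02
        step_times = []
        for _ in range(n):
            counts = RyR2ClusterState.resting().counts()
            tcur = 0.0
            while counts[1] == 0 and tcur < 1e5:
                counts = step_counts(counts, q, dt, rng2)
                tcur += dt
            step_times.append(tcur)
        ks = stats.ks_2samp(ssa_times, step_times)
        assert ks.pvalue > 0.01


class TestStationaryHelper:
    def test_matches_null_space_oracle(self, params):
        q = gating.lcc_rate_matrix(0.0, 5.0, params.channels)
        assert np.allclose(stationary_distribution(q), stationary_oracle(q),
                           atol=1e-10)
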