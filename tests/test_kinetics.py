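import dataclasses

import numpy as np
import pytest

import vesikin as vk
from vesikin.kinetics import build_rate_components
from vesikin.states import N_STATES
from vesikin.transient import CaTransient


def constant_transient(ca, t_last=1.0):
    """Degenerate transient pinned at a constant concentration."""
    return CaTransient(
        ap_onsets=(0.0,),
        amplitude_ap=0.0,
        gauss_mean=1.5e-3,
        gauss_sd=0.2e-3,
        amplitude_residual=0.0,
        tau_residual=0.2,
        km_smooth=1e-4,
        t0_offset=1.6e-3,
        ca_rest=ca,
    )


class TestElementaryRates:
    def test_fusion_rate_basal(self, params):
        assert vk.fusion_rate(0, 0, params) == pytest.approx(3.5e-4)

    def test_fusion_rate_per_ion_factors(self, params):
        assert vk.fusion_rate(1, 0, params) / vk.fusion_rate(0, 0, params) == pytest.approx(16.0)
        assert vk.fusion_rate(0, 1, params) / vk.fusion_rate(0, 0, params) == pytest.approx(27.98)
        assert vk.fusion_rate(2, 3, params) == pytest.approx(
            params.l_plus * 27.98**3 * 16.0**2
        )

    def test_fusion_rate_bounds(self, params):
        with pytest.raises(ValueError):
            vk.fusion_rate(3, 0, params)
        with pytest.raises(ValueError):
            vk.fusion_rate(0, 6, params)

    def test_docking_rates_catalysis(self, params):
        assert vk.docking_rates((1, 0, 0), params) == pytest.approx((5.0, 5.0))
        assert vk.docking_rates((0, 0, 1), params) == pytest.approx((500.0, 500.0))
        ko = params.with_genotype("syt7_ko")
        for S in [(1, 0, 0), (0.2, 0.5, 0.3), (0, 0, 1)]:
            assert vk.docking_rates(S, ko) == pytest.approx((5.0, 5.0))

    def test_docking_rates_require_distribution(self, params):
        with pytest.raises(ValueError):
            vk.docking_rates((0.5, 0.2, 0.2), params)

    def test_ca_binding_examples(self, params):
        # Doc2α double-bound empty site: off-rate 2·k2−·b2 = 42 s⁻¹
        _, off = vk.ca_binding_rates("doc2", 2, None, 0.0, params)
        assert off == pytest.approx(2 * 42.0 * 0.5)
        # syt1 on a docked site with the five-ion budget exhausted
        on, _ = vk.ca_binding_rates("syt1", 3, (2, 3), 10.0, params)
        assert on == 0.0
        # syt7 single remaining slot at rest
        on, _ = vk.ca_binding_rates("syt7", 1, None, 0.05, params)
        assert on == pytest.approx(1 * 28.0 * 0.05)

    def test_budget_clamps_doc2_on_docked(self, params):
        on, _ = vk.ca_binding_rates("doc2", 0, (0, 4), 1.0, params)
        assert on == pytest.approx(1 * 28.0)  # only one slot left of two
        on, _ = vk.ca_binding_rates("doc2", 0, (0, 5), 1.0, params)
        assert on == 0.0


class TestIntensityMatrix:
    def test_generator_structure(self, params, state_space):
        S = vk.syt7_steady_state(0.05, params)
        Q = vk.build_intensity_matrix(0.05, S, params)
        off = Q - np.diag(np.diag(Q))
        assert (off >= 0).all()
        assert np.abs(Q.sum(axis=1)).max() <= 1e-10 * np.abs(Q).max()

    def test_no_inbound_into_budget_violating_states(self, params, state_space):
        Q = vk.build_intensity_matrix(50.0, (0, 0, 1), params)
        forbidden = state_space.forbidden_mask
        inbound = Q[~forbidden][:, forbidden]
        assert np.abs(inbound).max() == 0.0

    def test_zero_calcium_kills_on_rates(self, params, state_space):
        Q = vk.build_intensity_matrix(0.0, (1, 0, 0), params)
        # Doc2α binding E[0]→E[1] requires calcium
        assert Q[state_space.empty_index(0), state_space.empty_index(1)] == 0.0
        # docking still runs at the basal rate
        assert Q[state_space.tethered_index(1), state_space.docked_index(1, 0)] == pytest.approx(5.0)

    def test_docking_enters_syt1_unbound_only(self, params, state_space):
        Q = vk.build_intensity_matrix(0.05, (1, 0, 0), params)
        t1 = state_space.tethered_index(1)
        for s1 in range(1, 6):
            assert Q[t1, state_space.docked_index(1, s1)] == 0.0

    def test_fusion_preserves_doc2_state(self, params, state_space):
        Q = vk.build_intensity_matrix(0.0, (1, 0, 0), params)
        i = state_space.docked_index(2, 1)
        assert Q[i, state_space.empty_index(2)] == pytest.approx(
            vk.fusion_rate(2, 1, params)
        )
        assert Q[i, state_space.empty_index(0)] == 0.0


class TestSteadyState:
    def test_zero_calcium(self, params, state_space):
        pi, S = vk.steady_state(params, 0.0)
        assert S == pytest.approx([1.0, 0.0, 0.0])
        bound = [i for i in range(N_STATES) if state_space.label(i)
                 not in ("E[0]", "T[0]", "D[0,0]")]
        assert np.abs(pi[bound]).max() <= 1e-9 * params.n_sites

    def test_syt7_detailed_balance_at_rest(self, params):
        S = vk.syt7_steady_state(0.05, params)
        assert S[1] / S[0] == pytest.approx(2 * 0.05 * 28.0 / 42.0, rel=1e-12)
        assert S[2] / S[1] == pytest.approx(0.05 * 28.0 / (2 * 0.5 * 42.0), rel=1e-12)

    def test_nullspace_agrees_with_matrix_exponential(self, params):
        pi_ns, _ = vk.steady_state(params)
        pi_expm = vk.steady_state_expm(params)
        assert np.abs(pi_ns - pi_expm).max() <= 1e-6 * params.n_sites

    def test_conserves_site_count(self, params):
        for ca in (0.0, 0.05, 1.0, 30.0):
            pi, _ = vk.steady_state(params, ca)
            assert pi.sum() == pytest.approx(params.n_sites, rel=1e-9)
            assert (pi >= 0).all()

    def test_syt1_occupancies_follow_detailed_balance(self, state_space):
        # isolate the syt1 binding chain: fusion off, Doc2α off, and a
        # vanishing docking/undocking exchange (the uniform undocking sink
        # plus the s1=0 docking source would otherwise perturb the chain by
        # ~k_docking/k1−); the conditional docked distribution then follows
        # the birth–death closed form exactly
        p = dataclasses.replace(
            vk.default_parameters(),
            l_plus=1e-12,
            k_docking=1e-6,
            k_undocking=1e-6,
        ).with_genotype("doc2_ko")
        ca = 1.0
        pi, _ = vk.steady_state(p, ca)
        for s1 in range(0, 5):
            lo = pi[state_space.docked_index(0, s1)]
            hi = pi[state_space.docked_index(0, s1 + 1)]
            on = (p.syt1.n - s1) * p.syt1.k_plus * ca
            off = (s1 + 1) * p.syt1.k_minus * p.syt1.b**s1
            assert hi / lo == pytest.approx(on / off, rel=1e-6)

    def test_syt7_is_catalyst_not_equilibrium_shift(self, state_space):
        # docking and undocking scale together, so the equilibrium docked
        # fraction is independent of f7 once fusion flux is negligible
        base = dataclasses.replace(vk.default_parameters(), l_plus=1e-12)
        ko = base.with_genotype("syt7_ko")
        for ca in (0.05, 1.0):
            pi_wt, _ = vk.steady_state(base, ca)
            pi_ko, _ = vk.steady_state(ko, ca)
            dw = pi_wt[state_space.docked_mask].sum()
            dk = pi_ko[state_space.docked_mask].sum()
            assert dw == pytest.approx(dk, rel=1e-9)

    def test_catalyst_neutrality_with_default_fusion(self, params, state_space):
        pi_wt, _ = vk.steady_state(params, 0.05)
        pi_ko, _ = vk.steady_state(params.with_genotype("syt7_ko"), 0.05)
        assert pi_wt[state_space.docked_mask].sum() == pytest.approx(
            pi_ko[state_space.docked_mask].sum(), rel=1e-3
        )


class TestSimulate:
    def test_stationary_under_resting_calcium(self, params):
        tr = constant_transient(params.ca_rest)
        traj = vk.simulate(params, transient=tr, t_end=1.0, max_step=1e-3)
        pi, _ = vk.steady_state(params)
        drift = np.abs(traj.occupancies - pi).max()
        assert drift <= 1e-4 * params.n_sites

    def test_conservation_and_monotone_fusion(self, wt_traj, params):
        total = wt_traj.occupancies.sum(axis=1)
        assert np.abs(total - params.n_sites).max() <= 1e-6 * params.n_sites
        assert (np.diff(wt_traj.fused) >= -1e-9).all()
        assert wt_traj.fused[0] == 0.0
        assert np.abs(wt_traj.syt7.sum(axis=1) - 1.0).max() <= 1e-9

    def test_budget_violating_states_stay_empty(self, wt_traj, params, state_space):
        assert wt_traj.occupancies[:, state_space.forbidden_mask].max() \
            <= 1e-12 * params.n_sites

    def test_docked_pool_dips_and_recovers(self, wt_traj):
        onsets = wt_traj.ap_onsets
        for o in onsets[:3]:
            pre = wt_traj.docked_at(o)
            trough = wt_traj.docked[(wt_traj.t > o) & (wt_traj.t < o + 0.01)].min()
            late = wt_traj.docked_at(o + 0.045)
            assert trough < pre - 1.0
            assert late > trough + 1.0

    def test_release_rate_non_negative(self, wt_traj):
        assert (wt_traj.release_rate() >= 0).all()

    def test_solver_tolerance_independence(self, params, wt_traj):
        tight = vk.simulate(
            params, genotype="wt", rtol=5e-6, atol=5e-6
        )
        assert tight.fused[-1] == pytest.approx(wt_traj.fused[-1], rel=1e-3)

    def test_genotype_unknown_rejected(self, params):
        with pytest.raises(ValueError):
            vk.simulate(params, genotype="nonsense")
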