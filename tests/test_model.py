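"""Rate laws, right-hand side and simulation of the mating ODE model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matefit import (
    GeneralParameters,
    GrowthKinetics,
    LoadingSchedule,
    TransferKinetics,
    get_variant,
    growth_rate,
    rhs,
    simulate,
    transfer_rate,
)

from .conftest import TABLE2_TRUTH


def _plain_growth(psi_max, **kw):
    return GrowthKinetics(psi_max=psi_max, **kw)


class TestGrowthRate:
    @pytest.mark.parametrize("kin, t_eff, C, expected", [
        # lag and Monod factors both saturate to 1
        (GrowthKinetics(psi_max=0.05, K_L=0, n=1, K_G=0), 100.0, 1.0, 0.05),
        # lag factor vanishes at t = 0 when K_L > 0
        (GrowthKinetics(psi_max=0.05, K_L=10, n=1, K_G=0), 0.0, 1.0, 0.0),
        # half-lag, linear-resource form at the published recipient kinetics
        (GrowthKinetics(psi_max=0.0571, K_L=145, n=1,
                        resource_form="linear"), 145.0, 0.5, 0.0142750),
    ])
    def test_values(self, kin, t_eff, C, expected):
        assert growth_rate(kin, t_eff, C) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_k_l_zero_lag_factor_is_one_even_at_t0(self):
        kin = GrowthKinetics(psi_max=1.0, K_L=0.0, n=2.0, K_G=0.0)
        assert growth_rate(kin, 0.0, 1.0) == 1.0

    def test_negative_inputs_rejected(self):
        kin = GrowthKinetics(psi_max=0.05)
        with pytest.raises(ValueError):
            growth_rate(kin, -1.0, 1.0)
        with pytest.raises(ValueError):
            growth_rate(kin, 1.0, -0.5)
        with pytest.raises(ValueError):
            GrowthKinetics(psi_max=-0.05)


class TestTransferRate:
    @pytest.mark.parametrize("kin, C, expected", [
        (TransferKinetics(gamma_max=3e-10, K_T=0), 1.0, 3e-10),
        (TransferKinetics(gamma_max=1.27e-10, resource_form="linear"),
         0.0, 0.0),
        # half saturation at C = K_T
        (TransferKinetics(gamma_max=2e-10, K_T=1.0), 1.0, 1e-10),
    ])
    def test_values(self, kin, C, expected):
        assert transfer_rate(kin, C) == pytest.approx(expected, rel=1e-12)

    def test_negative_resource_rejected(self):
        with pytest.raises(ValueError):
            transfer_rate(TransferKinetics(gamma_max=1e-10), -1.0)


def _exponential_params(psi_d, psi_r, psi_t, gamma=0.0):
    """No lag, no resource dependence, no depletion: pure exponentials."""
    growth = {p: GrowthKinetics(psi_max=v, K_L=0, n=1, lag_form="none",
                                resource_form="none", e=0.0)
              for p, v in zip("DRT", (psi_d, psi_r, psi_t))}
    transfer = {j: TransferKinetics(gamma_max=gamma, resource_form="none")
                for j in "DT"}
    return GeneralParameters(growth=growth, transfer=transfer)


class TestRhs:
    def test_pure_exponential_limit(self):
        params = _exponential_params(0.01, 0.02, 0.03)
        sched = LoadingSchedule(donor_density=1e6, recipient_density=2e6)
        d = rhs(50.0, [1e6, 2e6, 3e6, 1.0], params, sched)
        assert d[0] == pytest.approx(0.01 * 1e6)
        assert d[1] == pytest.approx(0.02 * 2e6)
        assert d[2] == pytest.approx(0.03 * 3e6)
        assert d[3] == 0.0

    def test_conjugation_conserves_recipients_plus_transconjugants(self):
        # zero growth: the conjugation flux moves density from R to T only
        params = _exponential_params(0.0, 0.0, 0.0, gamma=1e-9)
        sched = LoadingSchedule(donor_density=1e6, recipient_density=2e6)
        d = rhs(10.0, [1e6, 2e6, 5e5, 1.0], params, sched)
        assert d[0] == 0.0
        assert d[1] + d[2] == pytest.approx(0.0, abs=1e-6)
        assert d[2] > 0

    def test_selected_model_transconjugants_have_no_growth_term(self, v15):
        # dT/dt = R * gamma * C * (D + T) exactly: no psi_T T contribution
        params = v15.resolve(TABLE2_TRUTH)
        sched = LoadingSchedule(donor_density=1e6, recipient_density=1e6)
        D, R, T, C = 1e6, 2e6, 5e6, 0.7
        d = rhs(100.0, [D, R, T, C], params, sched)
        gamma = TABLE2_TRUTH[3]
        assert d[2] == pytest.approx(R * gamma * C * (D + T), rel=1e-12)

    def test_unloaded_population_contributes_nothing(self, v15):
        params = v15.resolve(TABLE2_TRUTH)
        sched = LoadingSchedule(donor_time=120.0, donor_density=1e7,
                                recipient_density=1e6)
        d = rhs(60.0, [0.0, 1e6, 0.0, 1.0], params, sched)
        assert d[0] == 0.0  # donors absent before their load time
        assert d[2] == 0.0  # no plasmid-bearing cells, no transfer


class TestSimulate:
    def test_exponential_closed_form(self):
        params = _exponential_params(0.01, 0.0, 0.0)
        sched = LoadingSchedule(donor_density=1e6)
        traj = simulate(params, sched, [0.0, 100.0], rtol=1e-10)
        assert traj.D[-1] == pytest.approx(1e6 * np.e, rel=1e-6)

    def test_first_state_is_initial_condition(self, v15):
        params = v15.resolve(TABLE2_TRUTH)
        sched = LoadingSchedule(donor_density=1.5e6, recipient_density=2.5e6)
        traj = simulate(params, sched, np.arange(0, 201, 40.0))
        assert traj.D[0] == 1.5e6
        assert traj.R[0] == 2.5e6
        assert traj.T[0] == 0.0
        assert traj.C[0] == 1.0

    def test_no_transfer_means_no_transconjugants(self, v15):
        vec = TABLE2_TRUTH.copy()
        vec[3] = 0.0  # gamma_max
        traj = simulate(v15.resolve(vec),
                        LoadingSchedule(donor_density=1e6,
                                        recipient_density=1e6),
                        np.arange(0, 361, 40.0))
        assert np.all(traj.T == 0.0)

    def test_staggered_lag_clock_runs_from_load_time(self, v15):
        # with no recipients, a donor loaded at 120 min sees untouched
        # resource, so its trajectory is the simultaneous one shifted by 120
        params = v15.resolve(TABLE2_TRUTH)
        late = simulate(params,
                        LoadingSchedule(donor_time=120.0, donor_density=2e6),
                        np.array([0.0, 120.0, 200.0, 320.0]))
        early = simulate(params, LoadingSchedule(donor_density=2e6),
                         np.array([0.0, 80.0, 200.0]))
        assert late.D[0] == 0.0
        assert late.D[1] == 2e6
        assert late.D[2] == pytest.approx(early.D[1], rel=1e-6)
        assert late.D[3] == pytest.approx(early.D[2], rel=1e-6)

    def test_times_must_increase(self, v15):
        params = v15.resolve(TABLE2_TRUTH)
        with pytest.raises(ValueError):
            simulate(params, LoadingSchedule(donor_density=1e6),
                     [0.0, 40.0, 40.0])


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=500.0),
                min_size=19, max_size=19))
def test_nonnegativity_and_resource_monotonicity(free19):
    """Trajectories from nonnegative states stay nonnegative and C never
    increases, for arbitrary full-model parameters in [0, 500]."""
    v0 = get_variant("V0")
    # rates in [0, 500] 1/min explode numerically; scale them to realistic
    # magnitudes while keeping the draw's structure
    vec = np.array(free19)
    names = v0.free_names
    # steep Hill switches (n in the hundreds) stall any stiff solver on the
    # near-discontinuity at t = K_L, so the Hill draw is scaled down too
    scale = {"psi_max": 1e-4, "gamma_max": 1e-12, "e": 1e-11, "n_": 0.02}
    for i, name in enumerate(names):
        for prefix, s in scale.items():
            if name.startswith(prefix):
                vec[i] *= s
    params = v0.resolve(vec)
    traj = simulate(params,
                    LoadingSchedule(donor_density=1e6, recipient_density=1e6),
                    np.arange(0, 361, 40.0), rtol=1e-6)
    for pop in (traj.D, traj.R, traj.T):
        assert np.all(pop >= 0.0)
    assert np.all(traj.C >= -1e-9)
    assert np.all(np.diff(traj.C) <= 1e-9)
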