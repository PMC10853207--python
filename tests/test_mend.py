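"""Mechanistic simulator: kinetics, conservation, isotope tracing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilprime.mend import (Forcing, MendParams, MendState, add_litter,
                            constant_forcing, default_lab_state,
                            env_scalars, mend_derivatives, simulate_mend,
                            spin_up)


class TestEnvScalars:
    def test_reference_conditions_give_unity(self):
        p = MendParams()
        f_t, f_w, f_ph = env_scalars(p.t_ref, p.theta_ref, p.ph_opt, p)
        assert (f_t, f_w, f_ph) == (1.0, 1.0, 1.0)

    def test_q10_definition(self):
        p = MendParams(q10=2.0)
        f_t, _, _ = env_scalars(p.t_ref + 10.0, p.theta_ref, p.ph_opt, p)
        assert f_t == 2.0

    def test_moisture_and_ph_bounded_by_one(self):
        p = MendParams()
        for theta in (0.05, 0.3, 0.9):
            for ph in (4.0, 7.0, 9.0):
                _, f_w, f_ph = env_scalars(25.0, theta, ph, p)
                assert 0 < f_w <= 1 and 0 < f_ph <= 1


class TestDerivatives:
    def test_all_zero_state_is_stationary(self):
        d = mend_derivatives(np.zeros((2, 9)), MendParams(), 25, 0.3, 7.0)
        assert np.all(d == 0)

    def test_no_enzymes_no_polymer_decomposition(self):
        s = MendState.from_totals(p_o=5, p_h=5, m=10, e_o=0, e_h=0)
        d = mend_derivatives(s.pools, MendParams(), 25, 0.3, 7.0)
        assert np.all(d[:, :3] == 0)  # P_O, P_H, M untouched

    @given(st.integers(0, 999))
    @settings(max_examples=200, deadline=None)
    def test_mass_balance_closes_for_random_states(self, seed):
        rng = np.random.default_rng(seed)
        pools = rng.uniform(0, 5, (2, 9))
        lit = float(rng.uniform(0, 0.01))
        p = MendParams()
        d = mend_derivatives(pools, p, float(rng.uniform(0, 35)),
                             float(rng.uniform(0.05, 0.6)),
                             float(rng.uniform(4, 9)), litter_rate=lit,
                             litter_atom13=float(rng.uniform(0, 1)))
        assert d.sum() == pytest.approx(lit, abs=1e-12)


class TestAddLitter:
    def test_isotope_split_arithmetic(self):
        s = MendState.from_totals(d=1.0)
        out = add_litter(s, 2.0, atom13=0.751)
        assert out.pools[1].sum() == pytest.approx(1.502)
        assert out.pools[0].sum() - s.pools[0].sum() == pytest.approx(0.498)

    def test_unlabeled_litter_leaves_labeled_channel(self):
        s = MendState.from_totals(d=1.0, atom13=0.2)
        out = add_litter(s, 3.0, atom13=0.0)
        assert np.allclose(out.pools[1], s.pools[1])

    def test_zero_duration_simulation_preserves_addition(self):
        p = MendParams()
        s = add_litter(default_lab_state(), 10.0, 0.751)
        f = constant_forcing(24.0, params=p)
        traj = simulate_mend(s, p, f, duration_h=0.0, output_every_h=1.0)
        assert np.allclose(traj["pools"][0], s.pools)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            add_litter(default_lab_state(), -1.0, 0.5)


class TestSimulate:
    def test_empty_soil_stays_constant(self):
        p = MendParams()
        s = MendState.from_totals(p_o=3.0, p_h=2.0, m=5.0)  # no biomass
        f = constant_forcing(48.0, params=p)
        traj = simulate_mend(s, p, f, step_h=1.0)
        assert np.allclose(traj["pools"][-1], traj["pools"][0])

    def test_mass_conservation_multi_year(self):
        p = MendParams()
        s = default_lab_state()
        f = constant_forcing(2 * 8760.0, temp_c=20, litter_rate=4e-4,
                             litter_atom13=0.2, params=p)
        traj = simulate_mend(s, p, f, step_h=6.0, output_every_h=24.0)
        inputs = 4e-4 * 2 * 8760.0
        drift = traj["total_c"][-1] - s.total_c - inputs
        assert abs(drift) / s.total_c < 1e-8

    def test_isotope_channels_sum_to_combined_run(self):
        p = MendParams()
        s_dual = default_lab_state(atom13=0.3)
        f = constant_forcing(7 * 24.0, litter_rate=1e-3, litter_atom13=0.751,
                             params=p)
        dual = simulate_mend(s_dual, p, f, step_h=1.0)
        s_comb = MendState(np.vstack([s_dual.pools.sum(axis=0), np.zeros(9)]))
        comb = simulate_mend(s_comb, p, f, step_h=1.0)
        a = dual["pools"].sum(axis=1)
        b = comb["pools"].sum(axis=1)
        assert np.max(np.abs(a - b)) / np.max(b) < 1e-8

    def test_q10_monotonicity_above_reference(self):
        s = default_lab_state()
        f = constant_forcing(7 * 24.0, temp_c=30.0)
        co2 = []
        for q10 in (1.5, 2.0, 2.5, 3.0):
            p = MendParams(q10=q10)
            co2.append(simulate_mend(s, p, f, step_h=1.0)["co2_cum"][-1])
        assert np.all(np.diff(co2) >= 0)

    def test_priming_emerges_at_default_parameters(self):
        """Labeled litter raises cumulative *unlabeled* CO2 vs a twin."""
        p = MendParams()
        f = constant_forcing(7 * 24.0, params=p)
        bare = simulate_mend(default_lab_state(), p, f, step_h=1.0)
        amended = simulate_mend(add_litter(default_lab_state(), 10.0, 0.751),
                                p, f, step_h=1.0)
        assert (amended["co2_cum_unlabeled"][-1]
                > bare["co2_cum_unlabeled"][-1])

    def test_nonfinite_initial_state_rejected(self):
        p = MendParams()
        s = MendState(np.full((2, 9), np.nan))
        f = constant_forcing(24.0, params=p)
        with pytest.raises(ValueError):
            simulate_mend(s, p, f)


class TestCompiledKernel:
    def test_kernel_matches_python_reference_exactly(self):
        """The compiled integrator reproduces the pure-Python RK4 path
        bit for bit on a labeled-litter incubation."""
        p = MendParams()
        s = default_lab_state(atom13=0.3)
        f = constant_forcing(7 * 24.0, temp_c=25.0, litter_rate=1e-3,
                             litter_atom13=0.751, params=p)
        a = simulate_mend(s, p, f, step_h=1.0)
        b = simulate_mend(s, p, f, step_h=1.0, use_kernel=False)
        assert np.array_equal(a["pools"], b["pools"])

    def test_kernel_matches_python_under_varying_forcing(self):
        rng = np.random.default_rng(9)
        n = 30
        f = Forcing(dt=24.0, temp_c=rng.uniform(5, 30, n),
                    moisture=rng.uniform(0.1, 0.5, n),
                    ph=rng.uniform(5, 8, n),
                    litter_rate=rng.uniform(0, 1e-3, n),
                    litter_atom13=rng.uniform(0, 1, n))
        p = MendParams()
        s = default_lab_state(atom13=0.1)
        a = simulate_mend(s, p, f, step_h=6.0, output_every_h=24.0)
        b = simulate_mend(s, p, f, step_h=6.0, output_every_h=24.0,
                          use_kernel=False)
        assert np.array_equal(a["pools"], b["pools"])


class TestSpinUp:
    def test_equilibrium_drift_below_tenth_percent_per_year(self):
        p = MendParams()
        f = constant_forcing(8760.0, temp_c=15.0, litter_rate=4e-4, params=p)
        eq = spin_up(p, f, years=50.0, step_h=24.0)
        after = simulate_mend(eq, p, f, step_h=24.0, output_every_h=8760.0)
        stock0 = eq.pools[:, :8].sum()
        stock1 = after["pools"][-1][:, :8].sum()
        assert abs(stock1 - stock0) / stock0 < 1e-3
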