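"""Half-sarcomere mechanics: thin-filament kinetics, myosin cycling,
stress laws, conservation and independent-solver oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from cardioloop import _core
from cardioloop.half_sarcomere import (MyosinState, SarcomereParams,
                                       ThinFilamentState, active_stress,
                                       myosin_step, overlap_fraction,
                                       passive_stress, recruitment_rate,
                                       run_twitch, thin_filament_step)


@pytest.fixture(scope="module")
def params():
    return SarcomereParams()


class TestPassiveStress:
    def test_zero_at_slack(self, params):
        assert passive_stress(params.L_slack, params) == 0.0

    def test_zero_below_slack(self, params):
        assert passive_stress(0.8 * params.L_slack, params) == 0.0

    def test_closed_form_one_length_constant_above_slack(self, params):
        s = passive_stress(params.L_slack + params.L, params)
        assert s == pytest.approx(params.sigma * (np.e - 1.0), rel=1e-12)

    @given(st.floats(min_value=901.0, max_value=1400.0),
           st.floats(min_value=1.0, max_value=400.0))
    def test_strictly_increasing_above_slack(self, hsl, dl):
        p = SarcomereParams()
        assert passive_stress(hsl + dl, p) > passive_stress(hsl, p)

    def test_rejects_nonpositive_length(self, params):
        with pytest.raises(ValueError):
            passive_stress(0.0, params)


class TestRecruitmentRate:
    def test_intercept_is_k1(self, params):
        assert recruitment_rate(0.0, params) == params.k_1

    def test_linear_in_force(self, params):
        inc1 = recruitment_rate(1e4, params) - params.k_1
        inc2 = recruitment_rate(2e4, params) - params.k_1
        assert inc2 == pytest.approx(2 * inc1, rel=1e-12)

    def test_negative_force_treated_as_zero(self, params):
        assert recruitment_rate(-5e3, params) == params.k_1

    def test_force_independent_when_coupling_off(self):
        p = SarcomereParams(k_force=1e-30)
        assert recruitment_rate(3e4, p) == pytest.approx(p.k_1, rel=1e-6)


class TestActiveStress:
    def test_zero_without_bound_heads(self, params):
        assert active_stress(MyosinState.resting(params), params) == 0.0

    def test_zero_when_all_heads_at_minus_powerstroke(self, params):
        m = MyosinState.resting(params)
        i = int(np.argmin(np.abs(m.x + params.x_ps)))
        assert m.x[i] == pytest.approx(-params.x_ps)  # -4.5 is on the grid
        m.M_FG[i] = 0.5 / m.dx
        m.M_OFF = 0.5
        assert active_stress(m, params) == pytest.approx(0.0, abs=1e-9)

    def test_zero_for_symmetric_distribution_about_minus_powerstroke(self):
        p = SarcomereParams(x_ps=5.0)
        m = MyosinState.resting(p)
        # narrow gaussian centered at -x_ps; grid truncation negligible
        m.M_FG = np.exp(-0.5 * ((m.x + p.x_ps) / 1.0) ** 2)
        m.M_OFF = 0.0
        m.M_ON = 1.0 - m.bound_fraction
        full = p.N_0 * p.k_cb * p.x_ps * 1e-9  # stress scale of the model
        assert abs(active_stress(m, p)) < 1e-5 * full


class TestOverlap:
    def test_shape(self, params):
        assert overlap_fraction(params.hsl_zero_overlap, params) == 0.0
        assert overlap_fraction(600.0, params) == 0.0
        assert overlap_fraction(params.hsl_full_overlap, params) == 1.0
        assert overlap_fraction(1050.0, params) == 1.0
        assert overlap_fraction(params.hsl_desc_end, params) == 0.0
        mid = 0.5 * (params.hsl_desc_start + params.hsl_desc_end)
        assert overlap_fraction(mid, params) == pytest.approx(0.5)

    @given(st.floats(min_value=740.0, max_value=995.0),
           st.floats(min_value=1.0, max_value=30.0))
    def test_ascending_limb_monotone(self, hsl, dl):
        p = SarcomereParams()
        assert overlap_fraction(hsl + dl, p) >= overlap_fraction(hsl, p)


class TestThinFilament:
    def test_no_activation_without_calcium(self, params):
        thin = ThinFilamentState()
        for _ in range(100):
            thin = thin_filament_step(thin, 0.0, 950.0, params, 1.0)
        assert thin.N_on == 0.0

    def test_saturating_calcium_drives_full_overlap_occupancy(self, params):
        thin = ThinFilamentState()
        nov = overlap_fraction(950.0, params)
        for _ in range(20000):
            thin = thin_filament_step(thin, 10.0, 950.0, params, 0.01)
        assert thin.N_on > 0.95 * nov

    def test_fixed_point_matches_algebraic_root(self, params):
        """Steady activation at pCa 6 equals the closed-form fixed point of
        the rate equation (independent root-finding oracle)."""
        Ca = 1.0e-3  # mM, i.e. 1 uM
        hsl = 950.0
        nov = overlap_fraction(hsl, params)

        def rate(n):
            return (params.k_on * Ca * (nov - n) * (1 + params.k_coop * n)
                    - params.k_off * n * (1 + params.k_coop * (nov - n)))

        expected = brentq(rate, 0.0, nov)
        thin = ThinFilamentState()
        for _ in range(100000):
            thin = thin_filament_step(thin, Ca, hsl, params, 0.05)
        assert thin.N_on == pytest.approx(expected, rel=1e-6)

    def test_rejects_negative_calcium(self, params):
        with pytest.raises(ValueError):
            thin_filament_step(ThinFilamentState(), -1.0, 950.0, params, 1.0)

    def test_n_on_cannot_fall_below_bound_fraction(self, params):
        thin = ThinFilamentState(N_on=0.3, N_bound=0.3)
        out = thin_filament_step(thin, 0.0, 950.0, params, 50.0)
        assert out.N_on >= out.N_bound


class TestMyosin:
    def test_conservation_under_isometric_activation(self, params):
        my = MyosinState.resting(params)
        thin = ThinFilamentState(N_on=0.6)
        for _ in range(500):
            my, thin, _ = myosin_step(my, thin, params, 1.0, 0.0, 950.0,
                                      n_substeps=2)
            thin = ThinFilamentState(N_on=0.6, N_bound=my.bound_fraction)
            assert abs(my.total() - 1.0) < 1e-6

    def test_no_binding_sites_leaves_off_on_exchange_only(self, params):
        my = MyosinState.resting(params)
        thin = ThinFilamentState(N_on=0.0)
        # below slack length: no passive force, so J1 reduces to k_1
        for _ in range(4000):
            my, thin, _ = myosin_step(my, thin, params, 1.0, 0.0, 880.0)
            thin = ThinFilamentState(N_on=0.0, N_bound=my.bound_fraction)
        assert my.bound_fraction == 0.0
        expected_on = params.k_1 / (params.k_1 + params.k_2)
        assert my.M_ON == pytest.approx(expected_on, rel=1e-3)

    def test_matches_independent_master_equation_solver(self):
        """Isometric cycling at fixed activation agrees with an adaptive
        dense solver run on an independently coded master equation."""
        p = SarcomereParams(k_force=0.0)
        x = p.strain_grid()
        dx = p.dx
        n_on = 0.5
        wfac = p.k_cb * 1e-18 / (2 * _core.KB_T)

        def rhs(t, yv):
            m_off, m_on, fg = yv[0], yv[1], yv[2:]
            avail = max(n_on - fg.sum() * dx, 0.0)
            att = p.k_3 * np.exp(-wfac * x ** 2) * avail * m_on
            det = (p.k_4_0 + p.k_4_1 * x ** 4) * fg
            d = np.empty_like(yv)
            d[0] = p.k_2 * m_on - p.k_1 * m_off
            d[1] = (p.k_1 * m_off - p.k_2 * m_on
                    + det.sum() * dx - att.sum() * dx)
            d[2:] = att - det
            return d

        sol = solve_ivp(rhs, (0.0, 0.2), np.r_[1.0, 0.0, np.zeros_like(x)],
                        method="LSODA", rtol=1e-10, atol=1e-12)
        ref = sol.y[:, -1]

        my = MyosinState.resting(p)
        thin = ThinFilamentState(N_on=n_on)
        for _ in range(10000):
            my, thin, _ = myosin_step(my, thin, p, 0.02, 0.0, 950.0)
            thin = ThinFilamentState(N_on=n_on, N_bound=my.bound_fraction)
        assert abs(my.M_OFF - ref[0]) < 2e-3
        assert abs(my.M_ON - ref[1]) < 2e-3
        assert np.max(np.abs(my.M_FG - ref[2:])) < 2e-3

    def test_equilibrium_matches_algebraic_balance(self):
        """With force coupling off and constant activation the subsystem
        converges to the unique flux-balance equilibrium (independent
        nonlinear-solve oracle)."""
        p = SarcomereParams(k_force=0.0)
        x = p.strain_grid()
        dx = p.dx
        n_on = 0.4
        wfac = p.k_cb * 1e-18 / (2 * _core.KB_T)
        g = p.k_3 * np.exp(-wfac * x ** 2)
        k4 = p.k_4_0 + p.k_4_1 * x ** 4

        # equilibrium: fg(x) = g(x) avail m_on / k4(x); off/on from J1=J2
        def residual(m_on):
            # solve bound fraction consistent with avail = n_on - nb
            b_per_avail = (g / k4).sum() * dx * m_on
            nb = n_on * b_per_avail / (1.0 + b_per_avail)
            m_off = (p.k_2 / p.k_1) * m_on
            return m_off + m_on + nb - 1.0

        m_on_eq = brentq(residual, 1e-9, 1.0)
        b_per_avail = (g / k4).sum() * dx * m_on_eq
        nb_eq = n_on * b_per_avail / (1.0 + b_per_avail)

        # the OFF pool relaxes on the slow 1/k_1 ~ 1 s timescale, so the
        # run must span several seconds to reach the fixed point
        my = MyosinState.resting(p)
        thin = ThinFilamentState(N_on=n_on)
        for _ in range(50000):
            my, thin, _ = myosin_step(my, thin, p, 0.2, 0.0, 950.0)
            thin = ThinFilamentState(N_on=n_on, N_bound=my.bound_fraction)
        assert my.M_ON == pytest.approx(m_on_eq, rel=2e-3)
        assert my.bound_fraction == pytest.approx(nb_eq, rel=2e-3)

    def test_atp_counts_detachment_flux_exactly(self, params):
        """The ATP counter equals the time-integrated detachment flux
        (discrete bookkeeping identity, checked against a manual tally)."""
        p = SarcomereParams(k_force=0.0)
        x = p.strain_grid()
        dx = p.dx
        wfac = p.k_cb * 1e-18 / (2 * _core.KB_T)
        k4 = p.k_4_0 + p.k_4_1 * x ** 4
        my = MyosinState.resting(p)
        thin = ThinFilamentState(N_on=0.5)
        total_atp = 0.0
        manual = 0.0
        dt_s = 0.05e-3
        for _ in range(2000):
            manual += (k4 * my.M_FG).sum() * dx * dt_s
            my, thin, atp = myosin_step(my, thin, p, 0.05, 0.0, 950.0)
            thin = ThinFilamentState(N_on=0.5, N_bound=my.bound_fraction)
            total_atp += atp
        assert total_atp == pytest.approx(manual, rel=1e-9)


class TestAdvection:
    @given(st.floats(min_value=-3.0, max_value=3.0))
    def test_mass_within_grid_conserved(self, shift):
        p = SarcomereParams()
        x = p.strain_grid()
        fg = np.exp(-0.5 * (x / 2.0) ** 2)
        out, lost = _core.advect_fg(fg, x, p.dx, shift)
        assert out.sum() * p.dx + lost == pytest.approx(fg.sum() * p.dx,
                                                        abs=1e-12)
        assert np.all(out >= 0.0)

    def test_shift_moves_distribution(self):
        p = SarcomereParams()
        x = p.strain_grid()
        fg = np.zeros_like(x)
        fg[20] = 1.0  # delta at x = 0
        out, lost = _core.advect_fg(fg, x, p.dx, 1.0)  # stretch by 1 nm
        assert out[22] == pytest.approx(1.0)  # +1 nm = 2 bins of 0.5 nm
        assert lost == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def ca_transient():
    t = np.arange(800.0)
    ca = 6.5e-5 + 9e-4 * (np.exp(-t / 150.0) - np.exp(-t / 15.0))
    return np.clip(ca, 0.0, None)


class TestTwitchRunner:

    def test_twitch_rises_and_relaxes(self, params, ca_transient):
        hsl = np.full_like(ca_transient, 950.0)
        df = run_twitch(ca_transient, hsl, params)
        peak = df.active_stress.max()
        assert peak > 10 * df.active_stress.iloc[-1]
        assert df.active_stress.iloc[0] < 1e-2 * peak

    def test_isometric_twitch_force_increases_with_length(self, params,
                                                          ca_transient):
        """Length-dependent activation: peak twitch stress grows with
        half-sarcomere length across the physiological range."""
        peaks = []
        for hsl0 in (880.0, 930.0, 980.0):
            hsl = np.full_like(ca_transient, hsl0)
            df = run_twitch(ca_transient, hsl, params)
            peaks.append(df.active_stress.max())
        assert peaks[0] < peaks[1] < peaks[2]

    def test_trace_length_mismatch_rejected(self, params):
        with pytest.raises(ValueError):
            run_twitch(np.zeros(10), np.zeros(9), params)
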