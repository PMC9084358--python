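"""Forward box model: difference equations, conventions, conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ch4iso.boxmodel import (HemisphericForcing, IsotopeState, SinkParameters,
                             run_forward, step_forward, to_delta)
from ch4iso.units import R_VPDB, DeltaConvention, UnitConvention

CONV = DeltaConvention()
UNITS = UnitConvention()


def make_state(m12_n, m12_s, ratio=R_VPDB, year=2000):
    return IsotopeState(year, m12_n, m12_s, ratio * m12_n, ratio * m12_s)


def constant_forcing(years, s12_n=0.0, s12_s=0.0, s13_n=0.0, s13_s=0.0):
    n = len(years)
    return HemisphericForcing(years, np.full(n, s12_n), np.full(n, s12_s),
                              np.full(n, s13_n), np.full(n, s13_s))


class TestStepForward:
    def test_equal_boxes_no_sources_no_sinks_are_a_fixed_point(self):
        state = make_state(2000.0, 2000.0)
        sinks = SinkParameters(k_oh=0.0, epsilon_total=0.0, tau_ex=1.0)
        out = step_forward(state, 0, 0, 0, 0, sinks)
        assert out.m12_n == pytest.approx(state.m12_n, rel=1e-15)
        assert out.m13_s == pytest.approx(state.m13_s, rel=1e-15)
        assert out.year == state.year + 1

    def test_exchange_moves_half_the_gradient_and_conserves_totals(self):
        # boxes 2 and 1 Tg, tau_ex = 1, dt = 1: exchange term is
        # -(1/2)*2 + (1/2)*1 = -0.5 for the north box, +0.5 for the south
        state = make_state(2.0, 1.0)
        sinks = SinkParameters(k_oh=0.0, epsilon_total=0.0, tau_ex=1.0)
        out = step_forward(state, 0, 0, 0, 0, sinks)
        assert out.m12_n == pytest.approx(1.5, abs=1e-15)
        assert out.m12_s == pytest.approx(1.5, abs=1e-15)
        assert out.total12() == pytest.approx(state.total12(), rel=1e-15)
        assert out.total13() == pytest.approx(state.total13(), rel=1e-15)

    def test_constant_source_converges_to_s_over_k(self):
        k = 0.1
        s_global = 500.0
        state = make_state(100.0, 100.0)
        sinks = SinkParameters(k_oh=k, epsilon_total=0.0, tau_ex=1.0)
        for _ in range(400):
            state = step_forward(state, s_global / 2, s_global / 2, 1e-9, 1e-9,
                                 sinks)
        assert state.total12() == pytest.approx(s_global / k, rel=1e-9)

    def test_rejects_nonfinite_flux_and_unphysical_forcing(self):
        state = make_state(10.0, 10.0)
        sinks = SinkParameters(k_oh=0.1, epsilon_total=-6.0)
        with pytest.raises(ValueError, match="non-finite"):
            step_forward(state, np.nan, 0, 0, 0, sinks)
        with pytest.raises(ValueError, match="non-positive mass"):
            # removing far more than the box holds
            step_forward(state, -100.0, 0, 0, 0, sinks)


class TestConservation:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        m_n=st.floats(1.0, 1e4), m_s=st.floats(1.0, 1e4),
        r_n=st.floats(0.9 * R_VPDB, 1.1 * R_VPDB),
        r_s=st.floats(0.9 * R_VPDB, 1.1 * R_VPDB),
        # tau_ex >= dt/2 keeps the explicit exchange step stable
        tau=st.floats(0.5, 5.0), steps=st.integers(1, 40),
    )
    def test_zero_sinks_conserve_both_isotopologues(self, m_n, m_s, r_n, r_s,
                                                    tau, steps):
        state = IsotopeState(2000, m_n, m_s, r_n * m_n, r_s * m_s)
        sinks = SinkParameters(k_oh=0.0, epsilon_total=0.0, tau_ex=tau)
        t12, t13 = state.total12(), state.total13()
        for _ in range(steps):
            state = step_forward(state, 0, 0, 0, 0, sinks)
        assert state.total12() == pytest.approx(t12, rel=1e-12)
        assert state.total13() == pytest.approx(t13, rel=1e-12)

    def test_exchange_never_changes_global_totals_with_sources_and_sinks(self):
        state = IsotopeState(2000, 3000.0, 1500.0, R_VPDB * 3000, R_VPDB * 1500)
        sinks_fast = SinkParameters(k_oh=0.08, epsilon_total=-6.0, tau_ex=0.5)
        sinks_off = SinkParameters(k_oh=0.08, epsilon_total=-6.0, tau_ex=1e12)
        a = step_forward(state, 200, 50, 2, 0.5, sinks_fast)
        b = step_forward(state, 200, 50, 2, 0.5, sinks_off)
        assert a.total12() == pytest.approx(b.total12(), rel=1e-12)
        assert a.total13() == pytest.approx(b.total13(), rel=1e-12)


class TestDeltaConversion:
    def test_reference_ratio_gives_zero_permil(self):
        state = make_state(100.0, 50.0, ratio=R_VPDB)
        d_n, d_s, d_g = to_delta(state, CONV)
        assert d_n == pytest.approx(0.0, abs=1e-12)
        assert d_g == pytest.approx(0.0, abs=1e-12)

    def test_one_percent_depletion_is_minus_ten_permil(self):
        state = make_state(100.0, 100.0, ratio=0.99 * R_VPDB)
        _, _, d_g = to_delta(state, CONV)
        assert d_g == pytest.approx(-10.0, abs=1e-10)

    def test_default_reference_is_vpdb(self):
        assert CONV.r_std == pytest.approx(0.0112372)

    def test_global_delta_uses_summed_masses_not_averaged_deltas(self):
        state = IsotopeState(2000, 100.0, 300.0, 0.99 * R_VPDB * 100,
                             1.01 * R_VPDB * 300)
        d_n, d_s, d_g = to_delta(state, CONV)
        mass_weighted_ratio = (state.total13() / state.total12())
        assert d_g == pytest.approx(CONV.delta(mass_weighted_ratio), abs=1e-12)
        assert d_g != pytest.approx((d_n + d_s) / 2, abs=1e-3)

    def test_zero_m12_is_rejected(self):
        with pytest.raises(ValueError, match="m12 must be positive"):
            CONV.delta_from_masses(1.0, 0.0)


class TestUnits:
    def test_zero_and_round_trip(self):
        assert UNITS.ppb_to_tg(0.0) == 0.0
        ppb = 1890.0
        assert UNITS.tg_to_ppb(UNITS.ppb_to_tg(ppb)) == pytest.approx(ppb, rel=1e-12)

    def test_default_factor_and_hemispheric_split(self):
        assert UNITS.ppb_to_tg(1.0) == pytest.approx(2.767)
        # equal mixing ratio -> each box carries half the global mass
        assert 2 * UNITS.box_mass(1800.0) == pytest.approx(UNITS.ppb_to_tg(1800.0))


class TestRunForward:
    def test_deterministic_and_correct_length(self):
        years = np.arange(2000, 2010)
        forcing = constant_forcing(years, 250, 250, 2.8, 2.8)
        sinks = SinkParameters(k_oh=0.1, epsilon_total=-6.9)
        init = make_state(2400.0, 2400.0, year=2000)
        t1 = run_forward(forcing, sinks, init)
        t2 = run_forward(forcing, sinks, init)
        assert t1.years.size == years.size + 1
        np.testing.assert_array_equal(t1.delta_global(), t2.delta_global())

    def test_year_mismatch_rejected(self):
        forcing = constant_forcing(np.arange(2001, 2005), 100, 100, 1, 1)
        init = make_state(2000.0, 2000.0, year=2000)
        with pytest.raises(ValueError, match="init year"):
            run_forward(forcing, SinkParameters(k_oh=0.1, epsilon_total=-6.9), init)

    def test_delta_invariant_under_common_scaling(self):
        # doubling all isotopologue sources and the initial burdens leaves
        # every ratio, hence the delta series, unchanged
        years = np.arange(2000, 2015)
        sinks = SinkParameters(k_oh=0.09, epsilon_total=-6.9)
        f1 = constant_forcing(years, 240, 260, 2.6, 2.9)
        f2 = constant_forcing(years, 480, 520, 5.2, 5.8)
        init1 = IsotopeState(2000, 2300.0, 2400.0, 26.0, 27.0)
        init2 = IsotopeState(2000, 4600.0, 4800.0, 52.0, 54.0)
        d1 = run_forward(f1, sinks, init1).delta_global()
        d2 = run_forward(f2, sinks, init2).delta_global()
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_trajectory_is_affine_in_sources(self):
        # superposition: traj(f1 + f2) = traj(f1) + traj(f2) - traj(0)
        years = np.arange(2000, 2012)
        sinks = SinkParameters(k_oh=0.11, epsilon_total=-5.5, tau_ex=0.8)
        init = IsotopeState(2000, 2500.0, 2300.0, 28.0, 26.0)
        f1 = constant_forcing(years, 150, 100, 1.7, 1.1)
        f2 = constant_forcing(years, 80, 120, 0.9, 1.3)
        f0 = constant_forcing(years)
        t_sum = run_forward(f1 + f2, sinks, init)
        t1 = run_forward(f1, sinks, init)
        t2 = run_forward(f2, sinks, init)
        t0 = run_forward(f0, sinks, init)
        np.testing.assert_allclose(
            t_sum.m12_n, t1.m12_n + t2.m12_n - t0.m12_n, rtol=1e-12)
        np.testing.assert_allclose(
            t_sum.m13_s, t1.m13_s + t2.m13_s - t0.m13_s, rtol=1e-12)

    def test_steady_state_isotope_closed_form(self):
        # (1 + delta_atm/1000) * (1 + eps/1000) = (1 + delta_src/1000)
        eps = -6.9
        delta_src = -54.0
        years = np.arange(2000, 2400)
        r_src = CONV.ratio(delta_src)
        s = 550.0
        s13 = s * r_src / (1 + r_src)
        forcing = constant_forcing(years, (s - s13) / 2, (s - s13) / 2,
                                   s13 / 2, s13 / 2)
        sinks = SinkParameters(k_oh=0.1, epsilon_total=eps)
        init = make_state(2500.0, 2500.0, year=2000)
        d_final = run_forward(forcing, sinks, init).delta_global()[-1]
        lhs = (1 + d_final / 1000) * (1 + eps / 1000)
        assert lhs == pytest.approx(1 + delta_src / 1000, abs=1e-9)

    def test_output_table_schema(self):
        years = np.arange(2000, 2005)
        forcing = constant_forcing(years, 250, 250, 2.8, 2.8)
        frame = run_forward(forcing, SinkParameters(k_oh=0.1, epsilon_total=-6.9),
                            make_state(2400.0, 2400.0, year=2000)).to_frame()
        assert list(frame.columns) == [
            "year", "ch4_ppb_global", "ch4_ppb_nh", "ch4_ppb_sh",
            "d13c_global", "d13c_nh", "d13c_sh", "lifetime_yr"]
        assert frame["lifetime_yr"].iloc[0] == pytest.approx(10.0)
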