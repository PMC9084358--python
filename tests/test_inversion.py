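"""Inverse solvers: OH rate recovery, ε optimization, idealized wetlands."""

import numpy as np
import pandas as pd
import pytest

from ch4iso.boxmodel import SinkParameters, run_forward
from ch4iso.ensemble import (EnsembleConfig, _effective_global_delta,
                             build_forcing, scenario_category_deltas)
from ch4iso.inversion import (ObservationRecord, epsilon_residual, fit_epsilon,
                              fit_epsilon_vector, invert_oh, invert_wetland,
                              summarize_oh)
from ch4iso.model import IsotopeBudgetModel, WetlandInversionModel
from ch4iso.signatures import build_sector_signature_draws
from ch4iso.synthetic import TruthConfig, generate_world
from ch4iso.units import DeltaConvention, UnitConvention, isotopologue_split

CONV = DeltaConvention()
UNITS = UnitConvention()
CFG = EnsembleConfig()


def truth_forcing(world):
    scen = world.truth_scenario()
    years_step = world.observations.years[:-1]
    draws = build_sector_signature_draws(world.signature_specs(), 1,
                                         world.config.seed, sigma_scale=0.0)
    cat_delta = {c: a[0] for c, a in
                 scenario_category_deltas(scen, draws, years_step).items()}
    forcing, _ = build_forcing(scen, cat_delta, years_step, CONV)
    return scen, cat_delta, forcing


class TestInvertOh:
    def test_recovers_known_oh_series_to_machine_precision(self, nf_world):
        _, _, forcing = truth_forcing(nf_world)
        sol = invert_oh(forcing, nf_world.observations, nf_world.truth["epsilon"])
        truth = nf_world.truth["k_oh"].loc[sol.years].to_numpy()
        np.testing.assert_allclose(sol.k_oh, truth, rtol=1e-9)
        assert sol.all_feasible

    def test_constant_record_gives_steady_balance_rate(self):
        # constant burden M and constant source S: the balance collapses to
        # k = S / (M12 + alpha*M13), which is S/M up to the permil-level
        # isotope weighting of the removal term
        ppb, delta, s = 1800.0, -47.3, 520.0
        years = np.arange(2000, 2011)
        obs = ObservationRecord(pd.DataFrame(
            {"ch4_ppb": ppb, "d13c_permil": delta}, index=years))
        s12, s13 = isotopologue_split(s, -54.0, CONV)
        from ch4iso.boxmodel import HemisphericForcing
        n = years.size - 1
        forcing = HemisphericForcing(years[:-1],
                                     np.full(n, s12 / 2), np.full(n, s12 / 2),
                                     np.full(n, s13 / 2), np.full(n, s13 / 2))
        eps = -6.9
        sol = invert_oh(forcing, obs, eps)
        init = obs.initial_state()
        alpha = 1 + eps / 1000
        expected = s / (init.total12() + alpha * init.total13())
        assert sol.k_oh[0] == pytest.approx(expected, rel=1e-12)
        assert sol.k_oh[0] == pytest.approx(s / UNITS.ppb_to_tg(ppb), rel=2e-4)

    def test_forward_rerun_reproduces_the_record(self, noisy_world):
        # the solver and the forward model must agree step for step, so a
        # fresh forward run with the recovered rates hits every observation
        _, _, forcing = truth_forcing(noisy_world)
        obs = noisy_world.observations
        sol = invert_oh(forcing, obs, -6.9)
        sinks = SinkParameters(k_oh=pd.Series(sol.k_oh, index=sol.years),
                               epsilon_total=-6.9)
        traj = run_forward(forcing, sinks, obs.initial_state())
        err = np.abs(traj.ppb_global() - obs.ch4_ppb)
        assert err.max() < 1e-6

    def test_unachievable_growth_is_flagged_infeasible(self, nf_world):
        _, _, forcing = truth_forcing(nf_world)
        obs = nf_world.observations
        boosted = obs.data.copy()
        boosted.loc[boosted.index[5]:, "ch4_ppb"] += 400.0  # impossible jump
        sol = invert_oh(forcing, ObservationRecord(boosted), -6.9)
        assert not sol.feasible[4]
        assert not sol.all_feasible


class TestFitEpsilon:
    def test_recovers_true_fractionation(self, nf_world):
        _, _, forcing = truth_forcing(nf_world)
        eps = fit_epsilon(forcing, nf_world.observations)
        assert eps == pytest.approx(nf_world.truth["epsilon"], abs=0.01)

    def test_residual_is_monotone_decreasing_in_epsilon(self, nf_world):
        _, _, forcing = truth_forcing(nf_world)
        grid = np.linspace(-12.0, -1.0, 12)
        res = [float(epsilon_residual(e, forcing, nf_world.observations))
               for e in grid]
        assert np.all(np.diff(res) < 0)

    def test_vector_bisection_matches_scalar_brentq(self, noisy_world, noisy_draws):
        scen = noisy_world.observations, noisy_world.truth_scenario()
        obs, scenario = scen
        years_step = obs.years[:-1]
        cat_delta = scenario_category_deltas(scenario, noisy_draws, years_step)
        forcing, _ = build_forcing(scenario, cat_delta, years_step, CONV)
        eps_vec, failed = fit_epsilon_vector(forcing, obs)
        assert not failed.any()
        for i in range(noisy_draws.n_draws):
            cat_i = {c: a[i] for c, a in cat_delta.items()}
            forcing_i, _ = build_forcing(scenario, cat_i, years_step, CONV)
            eps_i = fit_epsilon(forcing_i, obs)
            assert eps_vec[i] == pytest.approx(eps_i, abs=1e-8)

    def test_no_sign_change_reports_residual_curve(self, nf_world):
        _, _, forcing = truth_forcing(nf_world)
        with pytest.raises(ValueError, match="no sign change"):
            fit_epsilon(forcing, nf_world.observations, bracket=(-0.2, -0.1))


class TestInvertWetland:
    def test_recovers_linear_wetland_truth_and_oh(self):
        world = generate_world(
            TruthConfig(seed=21).with_wetland_trend(2.0).noise_free())
        draws = build_sector_signature_draws(world.signature_specs(), 1, 21,
                                             sigma_scale=0.0)
        res = WetlandInversionModel(world.observations, world.truth_scenario(),
                                    draws, 0).fit()
        truth_wet = world.truth["category_flux"]["WET"].sum(axis=1)
        truth_k = world.truth["k_oh"]
        np.testing.assert_allclose(
            res.wet_flux.to_numpy(),
            truth_wet.loc[res.wet_flux.index].to_numpy(), rtol=1e-3)
        np.testing.assert_allclose(
            res.k_oh.to_numpy(), truth_k.loc[res.k_oh.index].to_numpy(),
            rtol=1e-3)
        # and far tighter in practice: the solve is algebraically exact
        assert np.abs(res.wet_flux.to_numpy()
                      / truth_wet.loc[res.wet_flux.index].to_numpy() - 1).max() < 1e-9

    def test_reduces_to_oh_inversion_when_obs_match_the_scenario(self, nf_world):
        # observations generated with wetlands inside the scenario: the
        # idealized wetland increment must vanish and k_oh must match
        scen, cat_delta, forcing = truth_forcing(nf_world)
        obs = nf_world.observations
        sol_oh = invert_oh(forcing, obs, nf_world.truth["epsilon"])
        other, _ = build_forcing(scen, cat_delta, obs.years[:-1], CONV,
                                 exclude=("WET",))
        wet_flux = scen.category_flux("WET").reindex(obs.years[:-1]).to_numpy()
        wet_delta = _effective_global_delta(wet_flux, cat_delta["WET"], CONV)
        sol = invert_wetland(other, wet_delta, obs, nf_world.truth["epsilon"])
        np.testing.assert_allclose(sol.wet_flux, wet_flux.sum(axis=1), rtol=1e-9)
        np.testing.assert_allclose(sol.k_oh, sol_oh.k_oh, rtol=1e-9)

    def test_linear_solve_matches_brute_force_grid_minimum(self, nf_world):
        scen, cat_delta, _ = truth_forcing(nf_world)
        obs = nf_world.observations
        other, _ = build_forcing(scen, cat_delta, obs.years[:-1], CONV,
                                 exclude=("WET",))
        wet_flux = scen.category_flux("WET").reindex(obs.years[:-1]).to_numpy()
        wet_delta = _effective_global_delta(wet_flux, cat_delta["WET"], CONV)
        eps = nf_world.truth["epsilon"]
        sol = invert_wetland(other, wet_delta, obs, eps)

        # year 0 misfit surface on a (W, k) grid around the solution
        alpha = 1 + eps / 1000
        init = obs.initial_state()
        m12, m13 = init.total12(), init.total13()
        m12_obs, m13_obs = obs.isotopologue_masses()
        r = CONV.ratio(wet_delta[0])
        f13 = r / (1 + r)
        s12o = other.s12_n[0] + other.s12_s[0]
        s13o = other.s13_n[0] + other.s13_s[0]

        def misfit(w, k):
            p12 = m12 + s12o + w * (1 - f13) - k * m12
            p13 = m13 + s13o + w * f13 - alpha * k * m13
            return (p12 - m12_obs[1]) ** 2 + (p13 - m13_obs[1]) ** 2

        ws = np.linspace(sol.wet_flux[0] - 20, sol.wet_flux[0] + 20, 81)
        ks = np.linspace(sol.k_oh[0] * 0.98, sol.k_oh[0] * 1.02, 81)
        surface = misfit(ws[:, None], ks[None, :])
        i, j = np.unravel_index(np.argmin(surface), surface.shape)
        assert ws[i] == pytest.approx(sol.wet_flux[0], abs=(ws[1] - ws[0]))
        assert ks[j] == pytest.approx(sol.k_oh[0], abs=(ks[1] - ks[0]))
        assert misfit(sol.wet_flux[0], sol.k_oh[0]) < 1e-16

    def test_near_singular_year_is_flagged_not_fatal(self, nf_world):
        scen, cat_delta, _ = truth_forcing(nf_world)
        obs = nf_world.observations
        other, _ = build_forcing(scen, cat_delta, obs.years[:-1], CONV,
                                 exclude=("WET",))
        n = obs.years.size - 1
        # a wetland delta equal to the removal-adjusted atmosphere makes the
        # two balances collinear
        d_atm = obs.d13c[0]
        eps = -6.9
        degenerate = ((1 + d_atm / 1000) * (1 + eps / 1000) - 1) * 1000
        sol = invert_wetland(other, np.full(n, degenerate), obs, eps,
                             det_tol=1e-2)
        assert sol.flags["singular"].iloc[0]


class TestSummarizeOh:
    def test_constant_rate_has_zero_anomaly(self, nf_world):
        _, _, forcing = truth_forcing(nf_world)
        sol = invert_oh(forcing, nf_world.observations, -6.9)
        sol.k_oh[:] = 0.1
        out = summarize_oh(sol)
        np.testing.assert_allclose(out["frac_anomaly"], 0.0, atol=1e-14)
        np.testing.assert_allclose(out["lifetime_yr"], 10.0, rtol=1e-12)

    def test_uniform_scaling_shows_up_linearly_against_a_fixed_reference(
            self, nf_world):
        _, _, forcing = truth_forcing(nf_world)
        sol = invert_oh(forcing, nf_world.observations, -6.9)
        ref = sol.k_oh.mean()
        sol.k_oh[:] = sol.k_oh * 1.01
        out = summarize_oh(sol, ref=ref)
        base = summarize_oh(sol, ref=ref * 1.01)
        np.testing.assert_allclose(
            out["frac_anomaly"], 1.01 * (base["frac_anomaly"] + 1) - 1,
            atol=1e-12)
        # the 1e5 molec/cm3 scaling is 10x the fractional anomaly
        np.testing.assert_allclose(out["oh_anomaly_1e5_molec_cm3"],
                                   10 * out["frac_anomaly"], atol=1e-14)

    def test_synthetic_default_lifetime_in_plausible_band(self, nf_world, nf_draws):
        res = IsotopeBudgetModel(nf_world.observations, nf_world.truth_scenario(),
                                 nf_draws, 0).fit()
        assert 7.0 < res.lifetime.mean() < 11.0


class TestOhSmoothing:
    def test_reporting_smoother_preserves_a_linear_rate_trend(self, nf_world):
        _, _, forcing = truth_forcing(nf_world)
        sol = invert_oh(forcing, nf_world.observations, -6.9)
        sol.k_oh[:] = 0.1 + 0.001 * np.arange(sol.k_oh.size)
        out = summarize_oh(sol, smooth=5)
        interior = out["k_oh"].iloc[2:-2].to_numpy()
        np.testing.assert_allclose(np.diff(interior), 0.001, rtol=1e-9)
        with pytest.raises(ValueError, match="odd"):
            summarize_oh(sol, smooth=4)
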