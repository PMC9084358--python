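"""Period deltas, contribution shares, 13CH4 mass accounting, trends."""

import numpy as np
import pandas as pd
import pytest

from ch4iso.attribution import (DEFAULT_PERIODS, PeriodSet, c13_mass_share,
                                contribution_shares, linear_trend,
                                moving_anomaly, period_delta)

YEARS = pd.Index(range(1993, 2018), name="year")


class TestPeriodDelta:
    def test_constant_series_has_zero_deltas(self):
        out = period_delta(pd.Series(42.0, index=YEARS))
        assert (out.abs() < 1e-12).all()

    def test_identity_series_delta_is_difference_of_period_midpoints(self):
        out = period_delta(pd.Series(YEARS.to_numpy(float), index=YEARS))
        # mean(2007..2012) - mean(2000..2006) = 2009.5 - 2003
        assert out["renewed_growth"] == pytest.approx(6.5)
        assert out["accelerated_growth"] == pytest.approx(2015.0 - 2003.0)

    def test_step_increase_at_2007_shows_up_in_the_composite(self):
        series = pd.Series(150.0, index=YEARS) + 7.3 * (YEARS >= 2007)
        out = period_delta(series)
        assert out["post2007"] == pytest.approx(7.3)
        assert out["decreased_growth"] == pytest.approx(0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.uniform(0, 10, len(YEARS)), index=YEARS)
        y = pd.Series(rng.uniform(0, 10, len(YEARS)), index=YEARS)
        combo = period_delta(2.0 * x + 3.0 * y)
        parts = 2.0 * period_delta(x) + 3.0 * period_delta(y)
        pd.testing.assert_series_equal(combo, parts, check_names=False)

    def test_missing_years_rejected(self):
        short = pd.Series(1.0, index=pd.Index(range(2000, 2010), name="year"))
        with pytest.raises(ValueError, match="missing"):
            period_delta(short)

    def test_overlapping_periods_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PeriodSet(periods={"a": (1993, 2000), "b": (2000, 2006)},
                      reference="a")


class TestContributionShares:
    def test_single_changing_category_takes_all(self):
        deltas = pd.DataFrame({"IFF": [0.0, 0.0], "AGW": [10.0, 12.0],
                               "WET": [0.0, 0.0]})
        out = contribution_shares(deltas)
        assert out["mean"]["AGW"] == pytest.approx(100.0)
        assert out["mean"]["IFF"] == pytest.approx(0.0)

    def test_headline_arithmetic(self):
        deltas = pd.DataFrame([[13.7, 21.0, 5.3]], columns=["IFF", "AGW", "WET"])
        out = contribution_shares(deltas)
        assert out["mean"]["IFF"] == pytest.approx(100 * 13.7 / 40.0, rel=1e-6)
        assert out["mean"]["AGW"] == pytest.approx(100 * 21.0 / 40.0, rel=1e-6)
        assert out["mean"]["WET"] == pytest.approx(100 * 5.3 / 40.0, rel=1e-6)

    def test_shares_sum_to_100_per_run_when_all_positive(self):
        rng = np.random.default_rng(4)
        deltas = pd.DataFrame(rng.uniform(1, 20, (50, 3)),
                              columns=["IFF", "AGW", "WET"])
        out = contribution_shares(deltas)
        np.testing.assert_allclose(out["shares"].sum(axis=1), 100.0, rtol=1e-9)
        assert out["mean"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_near_zero_total_runs_are_excluded_and_counted(self):
        deltas = pd.DataFrame([[5.0, 5.0, -10.0], [10.0, 5.0, 5.0]],
                              columns=["IFF", "AGW", "WET"])
        out = contribution_shares(deltas)
        assert out["n_excluded"] == 1
        assert len(out["shares"]) == 1


class TestC13MassShare:
    def flux(self, value):
        return pd.DataFrame({"N": value / 2, "S": value / 2},
                            index=YEARS, dtype=float)

    def test_equal_flux_equal_delta_split_evenly(self):
        flux = {"A": self.flux(np.full(len(YEARS), 100.0)),
                "B": self.flux(np.full(len(YEARS), 100.0))}
        delta = {k: np.full((len(YEARS), 2), -50.0) for k in flux}
        shares = c13_mass_share(flux, delta, YEARS.to_numpy())
        np.testing.assert_allclose(shares.to_numpy(), 50.0, rtol=1e-12)

    def test_heavier_source_carries_more_c13(self):
        flux = {"heavy": self.flux(np.full(len(YEARS), 100.0)),
                "light": self.flux(np.full(len(YEARS), 100.0))}
        delta = {"heavy": np.full((len(YEARS), 2), -40.0),
                 "light": np.full((len(YEARS), 2), -60.0)}
        shares = c13_mass_share(flux, delta, YEARS.to_numpy())
        assert (shares["heavy"] > 50.0).all()

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(6)
        flux = {k: self.flux(rng.uniform(20, 200, len(YEARS)))
                for k in ("A", "B", "C")}
        delta = {k: rng.uniform(-70, -25, (len(YEARS), 2)) for k in flux}
        shares = c13_mass_share(flux, delta, YEARS.to_numpy())
        np.testing.assert_allclose(shares.sum(axis=1), 100.0, atol=1e-9)

    def test_period_changes_relative_to_plateau(self):
        flux = {"A": self.flux(100.0 + 20.0 * (YEARS >= 2007)),
                "B": self.flux(np.full(len(YEARS), 100.0))}
        delta = {k: np.full((len(YEARS), 2), -50.0) for k in flux}
        shares, changes = c13_mass_share(flux, delta, YEARS.to_numpy(),
                                         periods=DEFAULT_PERIODS)
        assert changes.loc["post2007", "A"] > 0
        assert changes.loc["post2007", "B"] < 0


class TestMovingAnomaly:
    def test_constant_series_gives_zeros(self):
        out = moving_anomaly(pd.Series(5.0, index=YEARS), window=7, ref_year=2001)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_series_keeps_its_slope_away_from_edges(self):
        series = pd.Series(3.0 * (YEARS - 2000), index=YEARS, dtype=float)
        out = moving_anomaly(series, window=7, ref_year=2001)
        interior = out.loc[1996:2014]
        np.testing.assert_allclose(np.diff(interior), 3.0, rtol=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_anomaly(pd.Series(1.0, index=YEARS), window=6)

    def test_window_longer_than_series_rejected(self):
        short = pd.Series(1.0, index=pd.Index(range(2000, 2003), name="year"))
        with pytest.raises(ValueError, match="exceeds"):
            moving_anomaly(short, window=7, ref_year=2001)


class TestLinearTrend:
    def test_exact_linear_series(self):
        series = pd.Series(2.0 * (YEARS - 2000), index=YEARS, dtype=float)
        tr = linear_trend(series)
        assert tr.slope == pytest.approx(2.0, rel=1e-12)
        assert tr.significant

    def test_constant_series_convention(self):
        tr = linear_trend(pd.Series(7.0, index=YEARS))
        assert tr.slope == 0.0
        assert tr.pvalue == 1.0
        assert not tr.significant

    def test_window_restricts_the_fit(self):
        series = pd.Series(np.where(YEARS < 2005, 0.0, 5.0 * (YEARS - 2005)),
                           index=YEARS)
        tr = linear_trend(series, window=(2006, 2017))
        assert tr.slope == pytest.approx(5.0, rel=1e-12)

    def test_type_one_error_rate_is_about_five_percent(self):
        # white noise has no trend: the 95% test should flag ~5% of replicates
        rng = np.random.default_rng(12)
        years = pd.Index(range(2000, 2018), name="year")
        n_rep = 1000
        flags = 0
        for _ in range(n_rep):
            series = pd.Series(rng.standard_normal(len(years)), index=years)
            flags += linear_trend(series).significant
        rate = flags / n_rep
        assert 0.03 <= rate <= 0.07


class TestSigmaAcrossScenarios:
    def test_scenario_mean_spread_option(self, nf_world, nf_catalogue):
        from ch4iso.attribution import attribute_most_likely
        from ch4iso.ensemble import EnsembleConfig, run_ensemble
        from ch4iso.signatures import build_sector_signature_draws

        draws = build_sector_signature_draws(nf_world.signature_specs(), 3, 11,
                                             sigma_scale=0.0)
        res = run_ensemble(nf_catalogue, draws, nf_world.observations,
                           EnsembleConfig(n_draws=3))
        by_runs = attribute_most_likely(res, percentile=5.0)
        by_scen = attribute_most_likely(res, percentile=5.0,
                                        sigma_across="scenarios")
        # manual recomputation: average per-run shares within scenarios,
        # then take mean/std across the distinct scenario means
        shares = by_runs["shares"]["shares"].copy()
        sid = by_runs["selected"].set_index("run_id")["scenario_id"]
        shares["scenario_id"] = sid.loc[shares.index]
        by_hand = shares.groupby("scenario_id").mean()
        pd.testing.assert_series_equal(by_scen["shares"]["mean"],
                                       by_hand.mean(axis=0),
                                       check_names=False, rtol=1e-9)
        pd.testing.assert_series_equal(by_scen["shares"]["sigma"],
                                       by_hand.std(axis=0, ddof=1),
                                       check_names=False, rtol=1e-9)
        with pytest.raises(ValueError, match="sigma_across"):
            attribute_most_likely(res, percentile=5.0, sigma_across="draws")
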