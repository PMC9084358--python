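"""Model/Results interface over the inverse solvers.

Two estimator classes in the statsmodels idiom: construct from data, call
``fit()``, get a Results object carrying estimates, diagnostics and a
``summary()`` table.

* :class:`IsotopeBudgetModel` — one emission scenario under one Monte
  Carlo signature draw, fitted against the observed CH4 and δ13C records:
  ``fit()`` estimates ε (onset-window match) and the per-year OH removal
  rate (exact CH4 mass balance), then scores the simulated δ13C.
* :class:`WetlandInversionModel` — the idealized-wetland variant: per-year
  joint solve for wetland flux and OH rate reproducing both records, with
  the anomaly and trend diagnostics used to judge wetland hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .attribution import TrendResult, linear_trend, moving_anomaly
from .ensemble import EnsembleConfig, build_forcing, scenario_category_deltas, \
    _effective_global_delta
from .evaluation import EvaluationResult, score_run
from .inversion import (ObservationRecord, OhSolution, WetlandSolution,
                        fit_epsilon, invert_oh, invert_wetland, summarize_oh)
from .scenarios import EmissionScenario
from .signatures import SectorSignatureDraws

__all__ = [
    "IsotopeBudgetModel",
    "IsotopeBudgetResults",
    "WetlandInversionModel",
    "WetlandInversionResults",
]


def _rule(title: str, width: int = 62) -> str:
    pad = width - len(title) - 2
    return "=" * (pad // 2) + f" {title} " + "=" * (pad - pad // 2)


class IsotopeBudgetModel:
    """Two-box isotope budget of one scenario, fitted to observations.

    Parameters
    ----------
    obs
        Observed annual global CH4 and δ13C record.
    scenario
        One emission scenario (candidate per category plus OTH and soil).
    draws
        Monte Carlo signature ensemble; ``draw_index`` picks the
        realization this model uses.
    config
        Solver settings (ε bracket, onset window, τ_ex, unit/δ conventions).
    """

    def __init__(
        self,
        obs: ObservationRecord,
        scenario: EmissionScenario,
        draws: SectorSignatureDraws,
        draw_index: int = 0,
        config: EnsembleConfig = EnsembleConfig(),
    ) -> None:
        self.obs = obs
        self.scenario = scenario
        self.draws = draws
        self.draw_index = int(draw_index)
        self.config = config
        self.years_step = obs.years[:-1]
        cat_delta = scenario_category_deltas(scenario, draws, self.years_step)
        self.cat_delta = {c: a[self.draw_index] for c, a in cat_delta.items()}
        self.forcing, self._mean_source_delta = build_forcing(
            scenario, self.cat_delta, self.years_step, config.conv,
            soil_delta=config.soil_delta)

    def fit(self) -> "IsotopeBudgetResults":
        cfg = self.config
        init = self.obs.initial_state(cfg.units, cfg.conv)
        eps = fit_epsilon(self.forcing, self.obs, init,
                          bracket=cfg.epsilon_bracket, onset_years=cfg.onset_years,
                          k_minor=cfg.k_minor, tau_ex=cfg.tau_ex,
                          units=cfg.units, conv=cfg.conv)
        sol = invert_oh(self.forcing, self.obs, eps, init,
                        k_minor=cfg.k_minor, tau_ex=cfg.tau_ex,
                        units=cfg.units, conv=cfg.conv)
        d_sim = sol.trajectory.delta_global()
        run_id = f"{self.scenario.scenario_id}/d{self.draw_index:04d}"
        ev = score_run(d_sim, self.obs.d13c, run_id=run_id,
                       scenario_id=self.scenario.scenario_id, draw=self.draw_index,
                       mean_source_delta=float(self._mean_source_delta))
        return IsotopeBudgetResults(self, eps, sol, ev)


@dataclass
class IsotopeBudgetResults:
    """Estimates and diagnostics of a fitted :class:`IsotopeBudgetModel`."""

    model: IsotopeBudgetModel
    epsilon: float
    oh_solution: OhSolution
    evaluation: EvaluationResult

    @property
    def params(self) -> pd.Series:
        return pd.Series({"epsilon_permil": self.epsilon,
                          "mean_k_oh": float(self.oh_solution.k_oh.mean())})

    @property
    def k_oh(self) -> pd.Series:
        return self.oh_solution.series()

    @property
    def lifetime(self) -> pd.Series:
        return self.oh_solution.lifetime()

    @property
    def delta_sim(self) -> pd.Series:
        traj = self.oh_solution.trajectory
        return pd.Series(traj.delta_global(), index=traj.years, name="d13c_sim")

    @property
    def feasible(self) -> bool:
        return self.oh_solution.all_feasible

    def oh_anomaly(self, ref_period: Optional[tuple] = None) -> pd.DataFrame:
        return summarize_oh(self.oh_solution, ref_period)

    def simulate(self) -> pd.DataFrame:
        """Forward trajectory table of the fitted run."""
        return self.oh_solution.trajectory.to_frame()

    def summary(self) -> str:
        ev = self.evaluation
        lines = [
            _rule("Isotope budget fit"),
            f"scenario:        {self.model.scenario.scenario_id}"
            f"   draw: {self.model.draw_index}",
            f"years:           {self.model.obs.years[0]}-{self.model.obs.years[-1]}",
            f"epsilon:         {self.epsilon:8.3f} permil",
            f"mean lifetime:   {self.lifetime.mean():8.2f} yr",
            f"mean source d13C:{ev.mean_source_delta:8.2f} permil",
            f"feasible:        {self.feasible}",
            _rule("delta13C agreement"),
            f"RMSE:   {ev.rmse:9.4f} permil    MSD:    {ev.msd:9.6f} permil^2",
            f"r:      {ev.r:9.4f}           cRMSE:  {ev.crmse:9.4f} permil",
            f"SD sim: {ev.sd_sim:9.4f} permil    SD obs: {ev.sd_obs:9.4f} permil",
            "=" * 62,
        ]
        return "\n".join(lines)


class WetlandInversionModel:
    """Idealized wetland flux + OH rate jointly fitted to both tracers."""

    def __init__(
        self,
        obs: ObservationRecord,
        scenario: EmissionScenario,
        draws: SectorSignatureDraws,
        draw_index: int = 0,
        config: EnsembleConfig = EnsembleConfig(),
        epsilon: Optional[float] = None,
    ) -> None:
        self.obs = obs
        self.scenario = scenario
        self.draws = draws
        self.draw_index = int(draw_index)
        self.config = config
        self.epsilon = epsilon
        self.years_step = obs.years[:-1]
        cat_delta = scenario_category_deltas(scenario, draws, self.years_step)
        self.cat_delta = {c: a[self.draw_index] for c, a in cat_delta.items()}

    def fit(self) -> "WetlandInversionResults":
        cfg = self.config
        init = self.obs.initial_state(cfg.units, cfg.conv)
        eps = self.epsilon
        if eps is None:
            full, _ = build_forcing(self.scenario, self.cat_delta,
                                    self.years_step, cfg.conv,
                                    soil_delta=cfg.soil_delta)
            eps = fit_epsilon(full, self.obs, init, bracket=cfg.epsilon_bracket,
                              onset_years=cfg.onset_years, k_minor=cfg.k_minor,
                              tau_ex=cfg.tau_ex, units=cfg.units, conv=cfg.conv)
        other, _ = build_forcing(self.scenario, self.cat_delta, self.years_step,
                                 cfg.conv, exclude=("WET",),
                                 soil_delta=cfg.soil_delta)
        wet_flux = self.scenario.category_flux("WET") \
            .reindex(self.years_step).to_numpy(dtype=float)
        wet_delta = _effective_global_delta(wet_flux, self.cat_delta["WET"],
                                            cfg.conv)
        share_n = wet_flux[:, 0].sum() / wet_flux.sum()
        sol = invert_wetland(other, wet_delta, self.obs, eps, init,
                             wet_split=(share_n, 1.0 - share_n),
                             k_minor=cfg.k_minor, tau_ex=cfg.tau_ex,
                             units=cfg.units, conv=cfg.conv)
        return WetlandInversionResults(self, eps, sol)


@dataclass
class WetlandInversionResults:
    """Idealized wetland series with anomaly and trend diagnostics."""

    model: WetlandInversionModel
    epsilon: float
    solution: WetlandSolution

    @property
    def wet_flux(self) -> pd.Series:
        return pd.Series(self.solution.wet_flux,
                         index=pd.Index(self.solution.years, name="year"),
                         name="wet_flux_tg")

    @property
    def k_oh(self) -> pd.Series:
        return pd.Series(self.solution.k_oh,
                         index=pd.Index(self.solution.years, name="year"),
                         name="k_oh")

    def anomaly(self, window: int = 7, ref_year: int = 2001) -> pd.Series:
        """Moving-window wetland anomaly relative to a reference year."""
        return moving_anomaly(self.wet_flux, window=window, ref_year=ref_year)

    def trend(self, window: tuple = (2000, 2016)) -> TrendResult:
        """OLS wetland trend (Tg yr^-1 yr^-1) with 95% significance flag."""
        return linear_trend(self.wet_flux, window=window)

    def summary(self) -> str:
        tr = self.trend()
        flagged = int(self.solution.flags.to_numpy().sum())
        star = " *" if tr.significant else ""
        lines = [
            _rule("Idealized wetland inversion"),
            f"scenario:       {self.model.scenario.scenario_id}"
            f"   draw: {self.model.draw_index}",
            f"epsilon:        {self.epsilon:8.3f} permil",
            f"mean WET flux:  {self.wet_flux.mean():8.2f} Tg/yr",
            f"trend:          {tr.slope:8.3f} +/- {tr.stderr:.3f} Tg/yr/yr"
            f" (p={tr.pvalue:.3g}){star}",
            f"flagged years:  {flagged}",
            "=" * 62,
        ]
        return "\n".join(lines)
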