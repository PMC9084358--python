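"""Scoring of simulated δ13C-CH4 series and most-likely-scenario selection.

Each ensemble run is summarized by the statistics of a Taylor diagram —
Pearson correlation, series standard deviation, centered RMSE — plus the
plain RMSE and the mean squared difference (MSD), which is the selection
criterion: the "most likely" subset is the first percentile of runs with
the lowest MSD against the observed record (960 of 96 000 at the default
ensemble size).  Statistics are unweighted; the observational 1-σ can be
used as an inverse-variance weight but is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["EvaluationResult", "score_run", "score_runs", "select_most_likely"]


@dataclass(frozen=True)
class EvaluationResult:
    """Agreement statistics of one run against the observed δ13C series.

    Satisfies ``msd == rmse**2`` and the Taylor identity
    ``crmse**2 == sd_sim**2 + sd_obs**2 - 2 sd_sim sd_obs r``
    (standard deviations are population, ddof=0).
    """

    run_id: str
    scenario_id: str
    draw: int
    rmse: float
    msd: float
    r: float
    sd_sim: float
    sd_obs: float
    crmse: float
    bias: float
    mean_source_delta: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def _stats(sim: np.ndarray, obs: np.ndarray, weights: Optional[np.ndarray]):
    """Vectorized over leading axes of ``sim``; obs is 1-D along the last axis."""
    if weights is None:
        w = np.ones_like(obs)
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    diff = sim - obs
    msd = (w * diff**2).sum(axis=-1)
    rmse = np.sqrt(msd)
    bias = (w * diff).sum(axis=-1)
    sim_c = sim - (w * sim).sum(axis=-1, keepdims=True)
    obs_c = obs - (w * obs).sum()
    sd_sim = np.sqrt((w * sim_c**2).sum(axis=-1))
    sd_obs = np.sqrt((w * obs_c**2).sum())
    cov = (w * sim_c * obs_c).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sd_sim * sd_obs)
    crmse = np.sqrt(np.maximum((w * (sim_c - obs_c) ** 2).sum(axis=-1), 0.0))
    return rmse, msd, r, sd_sim, sd_obs, crmse, bias


def score_run(
    sim: np.ndarray,
    obs: np.ndarray,
    run_id: str = "run",
    scenario_id: str = "",
    draw: int = 0,
    mean_source_delta: Optional[float] = None,
    weights: Optional[np.ndarray] = None,
) -> EvaluationResult:
    """Score one simulated δ13C series against aligned observations.

    Series must be aligned on the same years; fewer than 3 points leave the
    correlation undefined and are rejected.
    """
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"sim shape {sim.shape} != obs shape {obs.shape}")
    if sim.size < 3:
        raise ValueError("need at least 3 aligned years (correlation undefined)")
    rmse, msd, r, sd_sim, sd_obs, crmse, bias = _stats(sim, obs, weights)
    return EvaluationResult(run_id, scenario_id, draw,
                            float(rmse), float(msd), float(r), float(sd_sim),
                            float(sd_obs), float(crmse), float(bias),
                            mean_source_delta)


def score_runs(
    sim: np.ndarray,
    obs: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Vectorized scoring: ``sim`` has shape (n_runs, n_years)."""
    sim = np.atleast_2d(np.asarray(sim, dtype=float))
    obs = np.asarray(obs, dtype=float)
    if sim.shape[-1] != obs.size:
        raise ValueError("sim and obs year axes differ")
    if obs.size < 3:
        raise ValueError("need at least 3 aligned years (correlation undefined)")
    rmse, msd, r, sd_sim, sd_obs, crmse, bias = _stats(sim, obs, weights)
    return pd.DataFrame({
        "rmse": rmse, "msd": msd, "r": r, "sd_sim": sd_sim,
        "sd_obs": np.full(sim.shape[0], sd_obs), "crmse": crmse, "bias": bias,
    })


def select_most_likely(
    results: Union[pd.DataFrame, Sequence[EvaluationResult]],
    percentile: float = 1.0,
):
    """Keep the ``floor(percentile/100 * n)`` runs with the lowest MSD.

    Failed runs must be excluded beforehand.  The sort is ascending in MSD
    with ties broken by the stable input (run id) order, so selection is
    reproducible and independent of execution order.  Returns the subset in
    the same form as the input (DataFrame or list).
    """
    if not (0.0 < percentile <= 100.0):
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    as_frame = isinstance(results, pd.DataFrame)
    if as_frame:
        msd = results["msd"].to_numpy(dtype=float)
    else:
        results = list(results)
        msd = np.array([r.msd for r in results], dtype=float)
    n = msd.size
    if n == 0:
        raise ValueError("no results to select from")
    if np.any(~np.isfinite(msd)):
        raise ValueError("non-finite MSD present; exclude failed runs first")
    k = math.floor(percentile / 100.0 * n)
    order = np.argsort(msd, kind="stable")[:k]
    order = np.sort(order)  # preserve stable run-id order within the subset
    if as_frame:
        return results.iloc[order]
    return [results[i] for i in order]
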