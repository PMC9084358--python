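"""Period-based attribution of the CH4 rise over the most-likely subset.

The study window splits into named growth regimes — decreased growth
1993–1999, the plateau 2000–2006, renewed growth 2007–2012, accelerated
growth 2013–2017, and the post-2007 composite 2007–2017 — and every change
is measured as a period-mean flux difference against the plateau.  Shares
of the total change use the three headline categories (IFF, AGW, WET) as
the denominator; runs where the deltas are mixed-sign keep their raw
shares (they can be negative or exceed 100%), and the ensemble spread is
the 1-σ across the per-run raw shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scenarios import CATEGORIES
from .units import DEFAULT_DELTA, DeltaConvention, isotopologue_split

__all__ = [
    "PeriodSet",
    "DEFAULT_PERIODS",
    "TrendResult",
    "period_delta",
    "contribution_shares",
    "c13_mass_share",
    "moving_anomaly",
    "linear_trend",
    "attribute_most_likely",
]

#: Categories in the share denominator of the headline attribution.
SHARE_CATEGORIES = ("IFF", "AGW", "WET")


@dataclass(frozen=True)
class PeriodSet:
    """Named year intervals (inclusive) with a reference (plateau) period."""

    periods: dict = field(default_factory=lambda: {
        "decreased_growth": (1993, 1999),
        "stabilization": (2000, 2006),
        "renewed_growth": (2007, 2012),
        "accelerated_growth": (2013, 2017),
        "post2007": (2007, 2017),      # renewed + accelerated composite
    })
    reference: str = "stabilization"

    def __post_init__(self) -> None:
        if self.reference not in self.periods:
            raise ValueError(f"reference period {self.reference!r} not defined")
        core = {k: v for k, v in self.periods.items() if k != "post2007"}
        spans = sorted(core.values())
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c <= b:
                raise ValueError(f"periods overlap: ({a},{b}) and ({c},{d})")

    def years(self, name: str) -> np.ndarray:
        lo, hi = self.periods[name]
        return np.arange(lo, hi + 1)


DEFAULT_PERIODS = PeriodSet()


def period_delta(series: pd.Series, periods: PeriodSet = DEFAULT_PERIODS) -> pd.Series:
    """Period-mean changes relative to the plateau: mean(period) − mean(ref)."""
    series = series.astype(float)
    out = {}
    ref_years = periods.years(periods.reference)
    missing = [int(y) for y in ref_years if y not in series.index]
    if missing:
        raise ValueError(f"series missing reference years {missing}")
    ref = series.loc[ref_years].mean()
    for name in periods.periods:
        yrs = periods.years(name)
        missing = [int(y) for y in yrs if y not in series.index]
        if missing:
            raise ValueError(f"series missing years {missing} for period {name!r}")
        out[name] = series.loc[yrs].mean() - ref
    return pd.Series(out, name=series.name)


def contribution_shares(deltas: pd.DataFrame) -> dict:
    """Percent share of each category in the summed change, per run.

    ``deltas`` has one row per run and one column per category (normally
    the IFF/AGW/WET headline set).  Runs whose summed delta is ~0 have
    undefined shares and are excluded (counted).  Returns per-run shares
    and the ensemble mean ± 1-σ per category, in percent.
    """
    total = deltas.sum(axis=1)
    ok = np.abs(total.to_numpy()) > 1e-12 * max(1.0, np.abs(deltas.to_numpy()).max())
    shares = deltas.loc[ok].div(total.loc[ok], axis=0) * 100.0
    return {
        "shares": shares,
        "mean": shares.mean(axis=0),
        "sigma": shares.std(axis=0, ddof=1) if len(shares) > 1
        else pd.Series(0.0, index=deltas.columns),
        "n_excluded": int((~ok).sum()),
    }


def c13_mass_share(
    category_flux: dict,
    category_delta: dict,
    years: np.ndarray,
    conv: DeltaConvention = DEFAULT_DELTA,
    periods: Optional[PeriodSet] = None,
):
    """Per-category share of the annual total source 13CH4 mass (percent).

    ``category_flux`` maps category -> year-indexed (N, S) DataFrame and
    ``category_delta`` maps category -> δ13C array of shape (n_years, 2)
    for one Monte Carlo draw.  Shares sum to 100% each year.  If a
    ``periods`` set is given, also returns each category's change in
    period-mean share relative to the plateau (percentage points).
    """
    years = np.asarray(years, dtype=int)
    s13 = {}
    for cat, frame in category_flux.items():
        flux = frame.reindex(years).to_numpy(dtype=float)
        _, f13 = isotopologue_split(flux, np.asarray(category_delta[cat]), conv)
        s13[cat] = f13.sum(axis=-1)
    table = pd.DataFrame(s13, index=pd.Index(years, name="year"))
    total = table.sum(axis=1)
    if np.any(total.to_numpy() <= 0):
        raise ValueError("zero total source 13CH4 mass in some year")
    shares = table.div(total, axis=0) * 100.0
    if periods is None:
        return shares
    changes = shares.apply(lambda col: period_delta(col, periods))
    return shares, changes


def moving_anomaly(series: pd.Series, window: int = 7,
                   ref_year: int = 2001) -> pd.Series:
    """Centered moving average (edge-truncated) minus its value at ``ref_year``."""
    if window % 2 != 1:
        raise ValueError("window must be odd (centered average)")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    if ref_year not in series.index:
        raise ValueError(f"reference year {ref_year} not in series")
    smooth = series.astype(float).rolling(window, center=True, min_periods=1).mean()
    return smooth - smooth.loc[ref_year]


@dataclass(frozen=True)
class TrendResult:
    """OLS slope with a two-sided t-test at the 95% level."""

    slope: float
    stderr: float
    intercept: float
    pvalue: float
    n: int

    @property
    def significant(self) -> bool:
        return self.pvalue < 0.05


def linear_trend(series: pd.Series, window: Optional[tuple] = None) -> TrendResult:
    """Least-squares linear trend of an annual series (units yr^-1).

    ``window = (start, end)`` restricts the fit years.  A constant series
    returns slope 0 with p = 1 by convention.
    """
    s = series.astype(float)
    if window is not None:
        lo, hi = window
        s = s.loc[(s.index >= lo) & (s.index <= hi)]
    if len(s) < 3:
        raise ValueError("need at least 3 points for a trend")
    x = s.index.to_numpy(dtype=float)
    y = s.to_numpy()
    if np.allclose(y, y[0]):
        return TrendResult(0.0, 0.0, float(y[0]), 1.0, len(s))
    fit = sps.linregress(x, y)
    return TrendResult(float(fit.slope), float(fit.stderr),
                       float(fit.intercept), float(fit.pvalue), len(s))


def attribute_most_likely(
    result,
    periods: PeriodSet = DEFAULT_PERIODS,
    percentile: Optional[float] = None,
    sigma_across: str = "runs",
) -> dict:
    """Attribution report over the most-likely subset of an ensemble.

    For every selected run, the per-category period-mean flux changes
    relative to the plateau are computed from the run's scenario; the
    headline shares use the post-2007 composite and the IFF/AGW/WET
    denominator.  Returns period tables (mean ± 1-σ across runs) and the
    share statistics.

    ``sigma_across`` chooses the population behind the share spread:
    ``"runs"`` (default, the 1-σ across all selected runs) or
    ``"scenarios"`` (shares first averaged per scenario, spread across the
    distinct scenario means).
    """
    if sigma_across not in ("runs", "scenarios"):
        raise ValueError(f"sigma_across must be 'runs' or 'scenarios', "
                         f"got {sigma_across!r}")
    chosen = result.select(percentile)
    if len(chosen) == 0:
        raise ValueError("selection is empty; lower the ensemble size or raise percentile")
    deltas_by_scenario = {}
    for sid in chosen["scenario_id"].unique():
        scen = result.scenario_by_id(sid)
        deltas_by_scenario[sid] = {
            cat: period_delta(scen.category_flux(cat).sum(axis=1), periods)
            for cat in CATEGORIES
        }
    rows = {}
    for cat in CATEGORIES:
        per_run = pd.DataFrame(
            [deltas_by_scenario[sid][cat] for sid in chosen["scenario_id"]],
            index=chosen["run_id"].to_list())
        rows[cat] = per_run
    period_tables = {}
    for name in periods.periods:
        tab = pd.DataFrame({
            cat: {"delta_mean": rows[cat][name].mean(),
                  "delta_sigma": rows[cat][name].std(ddof=1) if len(rows[cat]) > 1 else 0.0}
            for cat in CATEGORIES
        }).T
        period_tables[name] = tab
    headline = pd.DataFrame({cat: rows[cat]["post2007"] for cat in SHARE_CATEGORIES})
    shares = contribution_shares(headline)
    if sigma_across == "scenarios":
        per_run = shares["shares"].copy()
        per_run["scenario_id"] = chosen.set_index("run_id").loc[
            per_run.index, "scenario_id"]
        by_scen = per_run.groupby("scenario_id").mean()
        shares["mean"] = by_scen.mean(axis=0)
        shares["sigma"] = (by_scen.std(axis=0, ddof=1) if len(by_scen) > 1
                           else pd.Series(0.0, index=by_scen.columns))
    return {
        "n_selected": int(len(chosen)),
        "period_deltas": period_tables,
        "headline_deltas": headline,
        "shares": shares,
        "selected": chosen,
    }
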