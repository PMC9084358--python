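"""Inverse-mode solvers for the two-box CH4 isotope budget.

Three solvers share one algebraic backbone — the explicit annual update of
:mod:`ch4iso.boxmodel`, which is linear in the removal rate and in any one
source flux given the start-of-year state:

* :func:`invert_oh` — per-year OH removal rate ``k_oh(t)`` such that the
  simulated global CH4 burden matches the observed record *exactly* at
  every year end (the global balance is linear in k).
* :func:`fit_epsilon` — the sink-weighted fractionation ε that makes the
  simulated δ13C match the observed mean over the onset window of the
  study period, with the OH inversion nested inside (ε outer, OH inner).
* :func:`invert_wetland` — the idealized-wetland mode: per year, a 2x2
  linear solve for (wetland flux, k_oh) from the 12CH4 and 13CH4 balances
  so the forward model reproduces both observed CH4 and δ13C.

Because the inverse solvers use the same stepping as the forward model, a
forward re-run of any solution reproduces the observations to rounding.
All marches accept a leading ensemble dimension on the forcing and on ε,
which the ensemble engine uses to process all Monte Carlo draws at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .boxmodel import HemisphericForcing, IsotopeState, Trajectory, _step
from .units import DEFAULT_DELTA, DEFAULT_UNITS, DeltaConvention, UnitConvention

__all__ = [
    "ObservationRecord",
    "OhSolution",
    "WetlandSolution",
    "invert_oh",
    "fit_epsilon",
    "fit_epsilon_vector",
    "epsilon_residual",
    "invert_wetland",
    "summarize_oh",
]

#: Default 1-σ of the observed global δ13C record (per mil).
D13C_SIGMA_DEFAULT = 0.04

#: Default ε bracket for the onset optimization (per mil).
EPSILON_BRACKET = (-12.0, -1.0)


@dataclass
class ObservationRecord:
    """Annual global CH4 (ppb) and δ13C (per mil) observations with 1-σ."""

    data: pd.DataFrame   # index: year; columns ch4_ppb, ch4_sigma, d13c_permil, d13c_sigma

    def __post_init__(self) -> None:
        d = self.data.copy()
        if "ch4_ppb" not in d.columns or "d13c_permil" not in d.columns:
            raise ValueError("observations need ch4_ppb and d13c_permil columns")
        if "ch4_sigma" not in d.columns:
            d["ch4_sigma"] = 0.0
        if "d13c_sigma" not in d.columns:
            d["d13c_sigma"] = D13C_SIGMA_DEFAULT
        d.index = d.index.astype(int)
        d.index.name = "year"
        if np.any(np.diff(d.index.to_numpy()) != 1):
            raise ValueError("observation years must be contiguous")
        if np.any(d["ch4_ppb"].to_numpy() <= 0):
            raise ValueError("ch4_ppb must be positive")
        self.data = d

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def ch4_ppb(self) -> np.ndarray:
        return self.data["ch4_ppb"].to_numpy(dtype=float)

    @property
    def d13c(self) -> np.ndarray:
        return self.data["d13c_permil"].to_numpy(dtype=float)

    def masses(self, units: UnitConvention = DEFAULT_UNITS) -> np.ndarray:
        """Observed total atmospheric CH4 mass per year (Tg)."""
        return units.ppb_to_tg(self.ch4_ppb)

    def isotopologue_masses(self, units: UnitConvention = DEFAULT_UNITS,
                            conv: DeltaConvention = DEFAULT_DELTA):
        """Observed (M12, M13) targets per year from CH4 and δ13C (Tg)."""
        total = self.masses(units)
        r = conv.ratio(self.d13c)
        m13 = total * r / (1.0 + r)
        return total - m13, m13

    def initial_state(self, units: UnitConvention = DEFAULT_UNITS,
                      conv: DeltaConvention = DEFAULT_DELTA) -> IsotopeState:
        return IsotopeState.from_observation(
            int(self.years[0]), float(self.ch4_ppb[0]), float(self.d13c[0]), units, conv)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ObservationRecord":
        return cls(pd.read_csv(path, index_col="year"))


def _init_arrays(init: IsotopeState):
    return (np.asarray(init.m12_n, float), np.asarray(init.m12_s, float),
            np.asarray(init.m13_n, float), np.asarray(init.m13_s, float))


def _march_inverse(forcing: HemisphericForcing, m_obs_total: np.ndarray,
                   init: IsotopeState, alpha, k_minor: float, tau_ex: float):
    """March the budget forward, solving k each year to hit the observed mass.

    Returns ``(k_oh, m12_n, m12_s, m13_n, m13_s)`` with time as the last
    axis (k has n entries, states n+1).  ``alpha`` may carry a leading
    ensemble dimension matching the forcing.
    """
    n = forcing.years.size
    if m_obs_total.shape[-1] != n + 1:
        raise ValueError("observed masses must cover n_years + 1 points")
    ex = 1.0 / (2.0 * tau_ex)
    alpha = np.asarray(alpha, dtype=float)
    m12n, m12s, m13n, m13s = _init_arrays(init)
    ks, t12n, t12s, t13n, t13s = [], [m12n], [m12s], [m13n], [m13s]
    for t in range(n):
        s12n = forcing.s12_n[..., t]
        s12s = forcing.s12_s[..., t]
        s13n = forcing.s13_n[..., t]
        s13s = forcing.s13_s[..., t]
        m12 = m12n + m12s
        m13 = m13n + m13s
        s_tot = s12n + s12s + s13n + s13s
        # Global balance: M(t+1) = M + S - kappa*(M12 + alpha*M13); solve kappa.
        kappa = (m12 + m13 + s_tot - m_obs_total[t + 1]) / (m12 + alpha * m13)
        m12n, m12s, m13n, m13s = _step(m12n, m12s, m13n, m13s,
                                       s12n, s12s, s13n, s13s,
                                       kappa, alpha * kappa, ex, 1.0)
        ks.append(kappa - k_minor)
        t12n.append(m12n); t12s.append(m12s); t13n.append(m13n); t13s.append(m13s)
    stack = lambda xs: np.stack(np.broadcast_arrays(*xs), axis=-1)
    return stack(ks), stack(t12n), stack(t12s), stack(t13n), stack(t13s)


@dataclass
class OhSolution:
    """Per-year OH removal rates reproducing the observed CH4 record."""

    years: np.ndarray                # step years (n,)
    k_oh: np.ndarray                 # (n,)
    epsilon: float
    k_minor: float
    feasible: np.ndarray             # (n,) bool; False where implied k_oh <= 0
    trajectory: Trajectory

    @property
    def all_feasible(self) -> bool:
        return bool(np.all(self.feasible))

    def series(self) -> pd.Series:
        return pd.Series(self.k_oh, index=self.years, name="k_oh")

    def lifetime(self) -> pd.Series:
        """Annual CH4 lifetime 1/(k_oh + k_minor), yr."""
        return pd.Series(1.0 / (self.k_oh + self.k_minor), index=self.years,
                         name="lifetime_yr")

    def to_frame(self) -> pd.DataFrame:
        out = summarize_oh(self)
        out["feasible"] = self.feasible
        return out


def invert_oh(
    forcing: HemisphericForcing,
    obs: ObservationRecord,
    eps: float,
    init: Optional[IsotopeState] = None,
    k_minor: float = 0.0,
    tau_ex: float = 1.0,
    units: UnitConvention = DEFAULT_UNITS,
    conv: DeltaConvention = DEFAULT_DELTA,
) -> OhSolution:
    """Solve k_oh(t) so the simulated global CH4 equals the observations.

    The forcing must cover ``obs.years[:-1]`` (the source labelled year t
    drives the step to t+1).  Years with implied ``k_oh <= 0`` (sources too
    small against the observed growth) are flagged infeasible; the march
    continues so the full diagnostic series is returned.
    """
    if not np.array_equal(forcing.years, obs.years[:-1]):
        raise ValueError("forcing years must equal observation years[:-1]")
    if init is None:
        init = obs.initial_state(units, conv)
    alpha = 1.0 + eps / 1000.0
    m_obs = obs.masses(units)
    k, m12n, m12s, m13n, m13s = _march_inverse(forcing, m_obs, init, alpha,
                                               k_minor, tau_ex)
    traj = Trajectory(np.append(forcing.years, forcing.years[-1] + 1),
                      m12n, m12s, m13n, m13s, k_oh=k, k_minor=k_minor,
                      units=units, conv=conv)
    return OhSolution(forcing.years.copy(), np.asarray(k, float), eps, k_minor,
                      feasible=np.asarray(k, float) > 0, trajectory=traj)


def epsilon_residual(
    eps,
    forcing: HemisphericForcing,
    obs: ObservationRecord,
    init: Optional[IsotopeState] = None,
    onset_years: int = 3,
    k_minor: float = 0.0,
    tau_ex: float = 1.0,
    units: UnitConvention = DEFAULT_UNITS,
    conv: DeltaConvention = DEFAULT_DELTA,
):
    """Onset-window misfit δ_sim − δ_obs (per mil) as a function of ε.

    A more negative ε leaves the simulated atmosphere isotopically heavier,
    so the residual decreases monotonically in ε.  ``eps`` may be an array
    with a leading ensemble dimension.
    """
    if init is None:
        init = obs.initial_state(units, conv)
    alpha = 1.0 + np.asarray(eps, dtype=float) / 1000.0
    m_obs = obs.masses(units)
    _, m12n, m12s, m13n, m13s = _march_inverse(forcing, m_obs, init,
                                               alpha, k_minor, tau_ex)
    d_sim = conv.delta((m13n + m13s) / (m12n + m12s))
    d_obs = obs.d13c
    w = int(onset_years)
    return d_sim[..., :w].mean(axis=-1) - d_obs[:w].mean()


def fit_epsilon(
    forcing: HemisphericForcing,
    obs: ObservationRecord,
    init: Optional[IsotopeState] = None,
    bracket: tuple = EPSILON_BRACKET,
    onset_years: int = 3,
    k_minor: float = 0.0,
    tau_ex: float = 1.0,
    units: UnitConvention = DEFAULT_UNITS,
    conv: DeltaConvention = DEFAULT_DELTA,
    xtol: float = 1e-10,
) -> float:
    """Fit ε by bracketed root-finding on the onset-window δ13C misfit.

    The onset window (default: mean over the first three observation
    years) damps single-year observation noise.  Raises with the residual
    curve if the bracket does not straddle a root.
    """
    def resid(e):
        return float(epsilon_residual(e, forcing, obs, init, onset_years,
                                      k_minor, tau_ex, units, conv))

    lo, hi = bracket
    r_lo, r_hi = resid(lo), resid(hi)
    if np.sign(r_lo) == np.sign(r_hi):
        grid = np.linspace(lo, hi, 12)
        curve = ", ".join(f"{e:.1f}:{resid(e):+.3f}" for e in grid)
        raise ValueError(
            f"no sign change for epsilon in [{lo}, {hi}] permil; residual curve {curve}")
    return float(brentq(resid, lo, hi, xtol=xtol))


def fit_epsilon_vector(
    forcing: HemisphericForcing,
    obs: ObservationRecord,
    init: Optional[IsotopeState] = None,
    bracket: tuple = EPSILON_BRACKET,
    onset_years: int = 3,
    k_minor: float = 0.0,
    tau_ex: float = 1.0,
    units: UnitConvention = DEFAULT_UNITS,
    conv: DeltaConvention = DEFAULT_DELTA,
    iterations: int = 60,
):
    """Vectorized ε fit by bisection over an ensemble of forcings.

    Returns ``(eps, failed)``: ε per ensemble member and a mask of members
    whose residual does not change sign on the bracket (ε set to NaN).
    The residual is monotone in ε, so bisection converges to the same root
    :func:`fit_epsilon` finds; 60 halvings of an 11-permil bracket reach
    ~5e-18 permil, far below solver noise.
    """
    lead = forcing.s12_n.shape[:-1]
    lo = np.full(lead or (), bracket[0], dtype=float)
    hi = np.full(lead or (), bracket[1], dtype=float)
    kw = dict(onset_years=onset_years, k_minor=k_minor, tau_ex=tau_ex,
              units=units, conv=conv)
    r_lo = epsilon_residual(lo, forcing, obs, init, **kw)
    r_hi = epsilon_residual(hi, forcing, obs, init, **kw)
    failed = np.sign(r_lo) == np.sign(r_hi)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        r_mid = epsilon_residual(mid, forcing, obs, init, **kw)
        same = np.sign(r_mid) == np.sign(r_lo)
        lo = np.where(same, mid, lo)
        r_lo = np.where(same, r_mid, r_lo)
        hi = np.where(same, hi, mid)
    eps = 0.5 * (lo + hi)
    return np.where(failed, np.nan, eps), failed


@dataclass
class WetlandSolution:
    """Joint per-year (wetland flux, k_oh) reproducing CH4 and δ13C."""

    years: np.ndarray                # step years (n,)
    wet_flux: np.ndarray             # (n,) Tg yr^-1
    k_oh: np.ndarray                 # (n,)
    epsilon: float
    k_minor: float
    det: np.ndarray                  # (n,) 2x2 system determinant
    flags: pd.DataFrame = field(repr=False)   # singular / negative_wetland per year
    trajectory: Trajectory = field(repr=False, default=None)

    def series(self) -> pd.DataFrame:
        out = pd.DataFrame({"wet_flux_tg": self.wet_flux, "k_oh": self.k_oh,
                            "det": self.det}, index=pd.Index(self.years, name="year"))
        return out.join(self.flags)


def invert_wetland(
    other_forcing: HemisphericForcing,
    wet_delta: np.ndarray,
    obs: ObservationRecord,
    eps: float,
    init: Optional[IsotopeState] = None,
    wet_split: tuple = (0.5, 0.5),
    k_minor: float = 0.0,
    tau_ex: float = 1.0,
    det_tol: float = 1e-10,
    units: UnitConvention = DEFAULT_UNITS,
    conv: DeltaConvention = DEFAULT_DELTA,
) -> WetlandSolution:
    """Idealized wetland inversion: per-year 2x2 linear solve.

    ``other_forcing`` is the net isotopologue source of everything except
    wetlands (soil uptake already subtracted); ``wet_delta`` the effective
    global wetland δ13C per step year (per mil).  Both observed tracers are
    converted to isotopologue mass targets, making each year's 12CH4 and
    13CH4 balances linear in the unknowns (W, k_oh).  The wetland flux is
    split into hemispheres by ``wet_split`` (N, S), which affects only the
    hemispheric distribution, never the global match.

    Years where the system is near singular (wetland δ isotopically
    indistinguishable from the removal-adjusted atmosphere, |det| below
    ``det_tol`` relative) are flagged; negative wetland fluxes are flagged
    and retained.
    """
    if not np.array_equal(other_forcing.years, obs.years[:-1]):
        raise ValueError("forcing years must equal observation years[:-1]")
    wet_delta = np.asarray(wet_delta, dtype=float)
    if wet_delta.shape != other_forcing.years.shape:
        raise ValueError("wet_delta must provide one value per step year")
    if not np.isclose(sum(wet_split), 1.0):
        raise ValueError("wet_split fractions must sum to 1")
    if init is None:
        init = obs.initial_state(units, conv)
    alpha = 1.0 + eps / 1000.0
    ex = 1.0 / (2.0 * tau_ex)
    m12_obs, m13_obs = obs.isotopologue_masses(units, conv)

    r_w = conv.ratio(wet_delta)
    f13 = r_w / (1.0 + r_w)          # 13C share of the wetland flux
    f12 = 1.0 - f13

    n = other_forcing.years.size
    m12n, m12s, m13n, m13s = _init_arrays(init)
    W = np.empty(n); K = np.empty(n); det = np.empty(n)
    singular = np.zeros(n, dtype=bool); negative = np.zeros(n, dtype=bool)
    t12n, t12s, t13n, t13s = [m12n], [m12s], [m13n], [m13s]
    for t in range(n):
        s12 = other_forcing.s12_n[..., t] + other_forcing.s12_s[..., t]
        s13 = other_forcing.s13_n[..., t] + other_forcing.s13_s[..., t]
        m12 = m12n + m12s
        m13 = m13n + m13s
        b1 = m12_obs[t + 1] - m12 - s12
        b2 = m13_obs[t + 1] - m13 - s13
        # [f12  -m12      ] [W    ]   [b1]
        # [f13  -alpha*m13] [kappa] = [b2]
        d = -f12[t] * alpha * m13 + m12 * f13[t]
        det[t] = d
        scale = max(abs(f12[t] * alpha * m13), abs(m12 * f13[t]), 1.0)
        if abs(d) < det_tol * scale:
            # Wetland delta isotopically indistinguishable from the
            # removal-adjusted atmosphere: fall back to the CH4-only balance
            # (W = 0) so the march can continue; the year stays flagged and
            # callers score the run as failed.
            singular[t] = True
            w = 0.0
            kappa = (m12 + m13 + s12 + s13 - (m12_obs[t + 1] + m13_obs[t + 1])) \
                / (m12 + alpha * m13)
        else:
            w = (-alpha * m13 * b1 + m12 * b2) / d
            kappa = (-f13[t] * b1 + f12[t] * b2) / d
        W[t] = w
        K[t] = kappa - k_minor
        if w < 0:
            negative[t] = True
        m12n, m12s, m13n, m13s = _step(
            m12n, m12s, m13n, m13s,
            other_forcing.s12_n[..., t] + w * f12[t] * wet_split[0],
            other_forcing.s12_s[..., t] + w * f12[t] * wet_split[1],
            other_forcing.s13_n[..., t] + w * f13[t] * wet_split[0],
            other_forcing.s13_s[..., t] + w * f13[t] * wet_split[1],
            kappa, alpha * kappa, ex, 1.0)
        t12n.append(m12n); t12s.append(m12s); t13n.append(m13n); t13s.append(m13s)

    if np.any(negative):
        import warnings
        years_neg = other_forcing.years[negative].tolist()
        warnings.warn(f"negative idealized wetland flux in years {years_neg}")
    stack = lambda xs: np.stack(np.broadcast_arrays(*xs), axis=-1)
    traj = Trajectory(np.append(other_forcing.years, other_forcing.years[-1] + 1),
                      stack(t12n), stack(t12s), stack(t13n), stack(t13s),
                      k_oh=K, k_minor=k_minor, units=units, conv=conv)
    flags = pd.DataFrame({"singular": singular, "negative_wetland": negative},
                         index=pd.Index(other_forcing.years, name="year"))
    return WetlandSolution(other_forcing.years.copy(), W, K, eps, k_minor,
                           det, flags, traj)


def summarize_oh(sol: OhSolution, ref=None, smooth: Optional[int] = None) -> pd.DataFrame:
    """OH anomaly diagnostics relative to a reference removal rate.

    ``ref`` is a (start, end) year tuple (reference = mean rate over that
    period), an explicit rate in yr^-1, or None (mean over all years).
    ``smooth`` applies a centered odd-window moving average *for reporting
    only* — the scoring pipeline always consumes the unsmoothed solution.
    Columns: the rate itself, the fractional anomaly, the anomaly scaled
    to an assumed global mean OH of 1e6 molec cm^-3 (reported in 1e5
    molec cm^-3 units), and the annual lifetime.
    """
    years = sol.years
    k_oh = sol.k_oh
    if smooth is not None:
        if smooth % 2 != 1:
            raise ValueError("smoothing window must be odd")
        k_oh = (pd.Series(k_oh).rolling(smooth, center=True, min_periods=1)
                .mean().to_numpy())
    if ref is None:
        ref = k_oh.mean()
    elif isinstance(ref, tuple):
        lo, hi = ref
        mask = (years >= lo) & (years <= hi)
        if not mask.any():
            raise ValueError(f"reference period {ref} outside {years[0]}..{years[-1]}")
        ref = k_oh[mask].mean()
    else:
        ref = float(ref)
        if ref <= 0:
            raise ValueError("reference rate must be positive")
    frac = k_oh / ref - 1.0
    return pd.DataFrame({
        "k_oh": k_oh,
        "frac_anomaly": frac,
        "oh_anomaly_1e5_molec_cm3": frac * 10.0,   # 1e6 reference, 1e5 units
        "lifetime_yr": 1.0 / (k_oh + sol.k_minor),
    }, index=pd.Index(years, name="year"))
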