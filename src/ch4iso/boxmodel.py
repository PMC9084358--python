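"""Two-hemisphere 12CH4/13CH4 tropospheric box model.

The troposphere is represented as two perfectly mixed boxes (northern and
southern hemisphere).  Each isotopologue obeys an explicit annual difference
equation: source addition, first-order removal, and symmetric
interhemispheric exchange with timescale ``tau_ex``::

    m(t+dt) = m(t) + (S - k*m - (m - m_other) / (2*tau_ex)) * dt

Removal of 12CH4 uses the rate ``k_oh + k_minor``; removal of 13CH4 uses
``alpha * (k_oh + k_minor)`` with ``alpha = 1 + epsilon/1000``, where
``epsilon`` (negative, per mil) is the sink-weighted kinetic fractionation.
The 12C rate applies to 12CH4 in both hemispheres (the rate is hemisphere
symmetric by construction).  Integration is the explicit annual step itself,
not a continuous ODE solve: the budget is formulated on annual data and the
inverse solvers in :mod:`ch4iso.inversion` rely on the update being exactly
this linear recursion.

State and forcing fields may be scalars or numpy arrays with a leading
ensemble dimension; all operations broadcast, which is what makes the
96 x 1000 Monte Carlo ensemble cheap.

Stability: the explicit step requires ``tau_ex >= dt/2`` (otherwise the
exchange term overshoots the gradient); with the annual step and the
standard ``tau_ex = 1`` yr this is always satisfied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .units import DEFAULT_DELTA, DEFAULT_UNITS, DeltaConvention, UnitConvention

__all__ = [
    "IsotopeState",
    "SinkParameters",
    "HemisphericForcing",
    "Trajectory",
    "step_forward",
    "run_forward",
    "to_delta",
]

ArrayLike = Union[float, np.ndarray]


@dataclass
class IsotopeState:
    """Per-hemisphere isotopologue burdens (Tg) at one time point."""

    year: float
    m12_n: ArrayLike
    m12_s: ArrayLike
    m13_n: ArrayLike
    m13_s: ArrayLike

    @classmethod
    def from_observation(
        cls,
        year: float,
        ch4_ppb: float,
        d13c_permil: float,
        units: UnitConvention = DEFAULT_UNITS,
        conv: DeltaConvention = DEFAULT_DELTA,
    ) -> "IsotopeState":
        """Build a state with both boxes at the observed global values.

        The observed records used here are global means; absent a stated
        interhemispheric gradient both boxes start at the global mixing
        ratio and δ13C.
        """
        total = units.ppb_to_tg(ch4_ppb)
        r = conv.ratio(d13c_permil)
        m13 = total * r / (1.0 + r)
        m12 = total - m13
        return cls(year=year, m12_n=m12 / 2.0, m12_s=m12 / 2.0,
                   m13_n=m13 / 2.0, m13_s=m13 / 2.0)

    # -- aggregates ---------------------------------------------------------
    def total12(self):
        return self.m12_n + self.m12_s

    def total13(self):
        return self.m13_n + self.m13_s

    def total(self):
        """Total CH4 mass (both isotopologues, both boxes), Tg."""
        return self.total12() + self.total13()

    def delta(self, conv: DeltaConvention = DEFAULT_DELTA):
        """(δ_N, δ_S, δ_global) in per mil; global from summed masses."""
        d_n = conv.delta_from_masses(self.m13_n, self.m12_n)
        d_s = conv.delta_from_masses(self.m13_s, self.m12_s)
        d_g = conv.delta_from_masses(self.total13(), self.total12())
        return d_n, d_s, d_g

    def ppb(self, units: UnitConvention = DEFAULT_UNITS):
        """(ppb_N, ppb_S, ppb_global)."""
        p_n = units.box_ppb(self.m12_n + self.m13_n)
        p_s = units.box_ppb(self.m12_s + self.m13_s)
        return p_n, p_s, units.tg_to_ppb(self.total())

    def validate(self) -> None:
        for name in ("m12_n", "m12_s", "m13_n", "m13_s"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(~np.isfinite(v)):
                raise ValueError(f"non-finite mass in {name}")
            if np.any(v <= 0):
                raise ValueError(f"non-positive mass in {name}")


@dataclass(frozen=True)
class SinkParameters:
    """First-order sink description.

    Parameters
    ----------
    k_oh
        OH-driven removal rate (yr^-1): scalar, array aligned with the
        forcing years, or a year-indexed :class:`pandas.Series`.
    epsilon_total
        Sink-weighted fractionation ε (per mil, negative).
    k_minor
        Constant lumped rate for non-OH sinks (yr^-1).  Default 0: the soil
        sink enters the budget as a flux and Cl/stratospheric losses are
        folded into ε, which keeps OH the sole driver of rate variability.
    tau_ex
        Interhemispheric exchange time (yr); default 1.
    """

    k_oh: Union[float, np.ndarray, pd.Series]
    epsilon_total: float
    k_minor: float = 0.0
    tau_ex: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_ex > 0):
            raise ValueError("tau_ex must be positive")
        alpha = self.alpha
        if not (0.9 < alpha <= 1.0):
            raise ValueError(
                f"alpha = 1 + epsilon/1000 = {alpha} outside (0.9, 1.0]; "
                "epsilon_total should be a small non-positive per-mil value"
            )
        if self.k_minor < 0:
            raise ValueError("k_minor must be non-negative")

    @property
    def alpha(self) -> float:
        """Isotope rate multiplier for 13CH4 removal."""
        return 1.0 + self.epsilon_total / 1000.0

    def oh_rates_for(self, years: np.ndarray) -> np.ndarray:
        """k_oh resolved to an array aligned with ``years``."""
        years = np.asarray(years)
        if isinstance(self.k_oh, pd.Series):
            missing = [int(y) for y in years if y not in self.k_oh.index]
            if missing:
                raise ValueError(f"k_oh series missing years {missing}")
            rates = self.k_oh.loc[years].to_numpy(dtype=float)
        else:
            rates = np.broadcast_to(np.asarray(self.k_oh, dtype=float),
                                    years.shape).copy()
        if np.any(rates < 0):
            raise ValueError("k_oh must be non-negative for every year")
        return rates


@dataclass
class HemisphericForcing:
    """Per-year net isotopologue source fluxes (Tg yr^-1) per hemisphere.

    Arrays are indexed ``[..., t]`` with an optional leading ensemble
    dimension; ``years[t]`` labels the step from year t to t+1.  Soil uptake
    is already subtracted (net source).
    """

    years: np.ndarray
    s12_n: np.ndarray
    s12_s: np.ndarray
    s13_n: np.ndarray
    s13_s: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        n = self.years.size
        for name in ("s12_n", "s12_s", "s13_n", "s13_s"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape[-1] != n:
                raise ValueError(f"{name} last axis ({a.shape[-1]}) != n years ({n})")
            if np.any(~np.isfinite(a)):
                raise ValueError(f"non-finite flux in {name}")
            setattr(self, name, a)

    def __add__(self, other: "HemisphericForcing") -> "HemisphericForcing":
        if not np.array_equal(self.years, other.years):
            raise ValueError("forcings cover different years")
        return HemisphericForcing(
            self.years,
            self.s12_n + other.s12_n, self.s12_s + other.s12_s,
            self.s13_n + other.s13_n, self.s13_s + other.s13_s,
        )


def _step(m12_n, m12_s, m13_n, m13_s, s12_n, s12_s, s13_n, s13_s,
          k12, k13, ex, dt):
    """One explicit step of the four difference equations (no validation)."""
    n12_n = m12_n + (s12_n - k12 * m12_n - ex * (m12_n - m12_s)) * dt
    n12_s = m12_s + (s12_s - k12 * m12_s - ex * (m12_s - m12_n)) * dt
    n13_n = m13_n + (s13_n - k13 * m13_n - ex * (m13_n - m13_s)) * dt
    n13_s = m13_s + (s13_s - k13 * m13_s - ex * (m13_s - m13_n)) * dt
    return n12_n, n12_s, n13_n, n13_s


def step_forward(
    state: IsotopeState,
    src12_n: ArrayLike,
    src12_s: ArrayLike,
    src13_n: ArrayLike,
    src13_s: ArrayLike,
    sinks: SinkParameters,
    dt: float = 1.0,
) -> IsotopeState:
    """Advance the state by ``dt`` years under the given net sources.

    Sources are net fluxes for the step (soil uptake already subtracted).
    ``sinks.k_oh`` must resolve for ``state.year``.  Raises if the forcing
    or state is non-finite, or if any resulting mass is non-positive
    (unphysical forcing).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    state.validate()
    for name, v in (("src12_n", src12_n), ("src12_s", src12_s),
                    ("src13_n", src13_n), ("src13_s", src13_s)):
        if np.any(~np.isfinite(np.asarray(v, dtype=float))):
            raise ValueError(f"non-finite flux {name}")
    k_oh = sinks.oh_rates_for(np.asarray([state.year]))[0] \
        if isinstance(sinks.k_oh, pd.Series) else np.asarray(sinks.k_oh, dtype=float)
    if np.ndim(k_oh) > 0 and np.size(k_oh) != 1 and not isinstance(sinks.k_oh, pd.Series):
        raise ValueError("step_forward needs a scalar or year-indexed k_oh")
    k12 = k_oh + sinks.k_minor
    k13 = sinks.alpha * k12
    ex = 1.0 / (2.0 * sinks.tau_ex)
    out = _step(state.m12_n, state.m12_s, state.m13_n, state.m13_s,
                src12_n, src12_s, src13_n, src13_s, k12, k13, ex, dt)
    new = IsotopeState(state.year + dt, *out)
    if any(np.any(np.asarray(m) <= 0) for m in out):
        raise ValueError("step produced a non-positive mass (unphysical forcing)")
    return new


def to_delta(state: IsotopeState, conv: DeltaConvention = DEFAULT_DELTA):
    """δ13C of a state: (δ_N, δ_S, δ_global) in per mil.

    The global value is computed from summed hemispheric isotopologue
    masses, never by averaging the hemispheric deltas.
    """
    return state.delta(conv)


@dataclass
class Trajectory:
    """Year-indexed box-model trajectory plus the removal rates applied."""

    years: np.ndarray                      # (n+1,)
    m12_n: np.ndarray                      # (..., n+1)
    m12_s: np.ndarray
    m13_n: np.ndarray
    m13_s: np.ndarray
    k_oh: np.ndarray                       # (..., n)
    k_minor: float = 0.0
    units: UnitConvention = field(default_factory=UnitConvention)
    conv: DeltaConvention = field(default_factory=DeltaConvention)

    def state(self, i: int) -> IsotopeState:
        return IsotopeState(self.years[i], self.m12_n[..., i], self.m12_s[..., i],
                            self.m13_n[..., i], self.m13_s[..., i])

    def delta_global(self) -> np.ndarray:
        m12 = self.m12_n + self.m12_s
        m13 = self.m13_n + self.m13_s
        return self.conv.delta(m13 / m12)

    def delta_nh(self) -> np.ndarray:
        return self.conv.delta(self.m13_n / self.m12_n)

    def delta_sh(self) -> np.ndarray:
        return self.conv.delta(self.m13_s / self.m12_s)

    def ppb_global(self) -> np.ndarray:
        return self.units.tg_to_ppb(self.m12_n + self.m12_s + self.m13_n + self.m13_s)

    def lifetime(self) -> np.ndarray:
        """Annual atmospheric lifetime 1/(k_oh + k_minor), yr."""
        return 1.0 / (self.k_oh + self.k_minor)

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as the standard output table (scalar trajectories only)."""
        if np.ndim(self.m12_n) != 1:
            raise ValueError("to_frame supports scalar (non-ensemble) trajectories")
        life = np.append(self.lifetime(), np.nan)  # no step labelled at last year
        return pd.DataFrame({
            "year": self.years,
            "ch4_ppb_global": self.ppb_global(),
            "ch4_ppb_nh": self.units.box_ppb(self.m12_n + self.m13_n),
            "ch4_ppb_sh": self.units.box_ppb(self.m12_s + self.m13_s),
            "d13c_global": self.delta_global(),
            "d13c_nh": self.delta_nh(),
            "d13c_sh": self.delta_sh(),
            "lifetime_yr": life,
        })


def run_forward(
    forcing: HemisphericForcing,
    sinks: SinkParameters,
    init: IsotopeState,
    units: UnitConvention = DEFAULT_UNITS,
    conv: DeltaConvention = DEFAULT_DELTA,
) -> Trajectory:
    """Integrate the box model over the forcing years.

    ``init.year`` must equal the first forcing year; the trajectory spans
    ``n_years + 1`` points (initial state plus one per annual step) and is
    fully deterministic given its inputs.
    """
    years = forcing.years
    if int(init.year) != int(years[0]):
        raise ValueError(f"init year {init.year} != first forcing year {years[0]}")
    if years.size and np.any(np.diff(years) != 1):
        raise ValueError("forcing years must be contiguous annual steps")
    init.validate()
    k_oh = sinks.oh_rates_for(years)
    k13 = sinks.alpha * (k_oh + sinks.k_minor)
    ex = 1.0 / (2.0 * sinks.tau_ex)

    shape = np.broadcast_shapes(
        np.shape(init.m12_n), forcing.s12_n.shape[:-1], np.shape(sinks.epsilon_total)
    )
    n = years.size
    m12_n = [np.broadcast_to(np.asarray(init.m12_n, float), shape)]
    m12_s = [np.broadcast_to(np.asarray(init.m12_s, float), shape)]
    m13_n = [np.broadcast_to(np.asarray(init.m13_n, float), shape)]
    m13_s = [np.broadcast_to(np.asarray(init.m13_s, float), shape)]
    for t in range(n):
        out = _step(m12_n[-1], m12_s[-1], m13_n[-1], m13_s[-1],
                    forcing.s12_n[..., t], forcing.s12_s[..., t],
                    forcing.s13_n[..., t], forcing.s13_s[..., t],
                    k_oh[t] + sinks.k_minor, k13[t], ex, 1.0)
        m12_n.append(out[0]); m12_s.append(out[1])
        m13_n.append(out[2]); m13_s.append(out[3])

    stack = lambda xs: np.stack(np.broadcast_arrays(*xs), axis=-1)
    k_arr = np.broadcast_to(k_oh, shape + (n,)).copy() if shape else k_oh
    return Trajectory(
        years=np.append(years, years[-1] + 1),
        m12_n=stack(m12_n), m12_s=stack(m12_s),
        m13_n=stack(m13_n), m13_s=stack(m13_s),
        k_oh=k_arr, k_minor=sinks.k_minor, units=units, conv=conv,
    )
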