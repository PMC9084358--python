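"""Isotope-ratio and unit conventions shared across the package.

All isotope arithmetic in the package goes through :class:`DeltaConvention`
so that the VPDB reference ratio lives in exactly one place, and through the
exact two-isotopologue split (``s12 + s13 = flux``) rather than the common
first-order approximation ``s13 = R * flux``, which carries a ~1% bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_VPDB",
    "TG_PER_PPB",
    "DeltaConvention",
    "UnitConvention",
    "isotopologue_split",
    "delta_from_split",
]

#: 13C/12C ratio of the Vienna Pee Dee Belemnite reference material
#: (1.12372%, dimensionless).
R_VPDB = 0.0112372

#: Whole-atmosphere conversion between a global mean CH4 mixing ratio and
#: total atmospheric CH4 mass.  2.767 Tg ppb^-1 corresponds to an atmosphere
#: of ~1.725e20 mol of air (2.767e12 g / 16.043 g mol^-1 / 1e-9), i.e. a dry
#: air mass of ~5.0e18 kg at 28.97 g mol^-1 -- the conventional factor used
#: in global CH4 budgeting.  It is a configurable constant, not physics.
TG_PER_PPB = 2.767


@dataclass(frozen=True)
class DeltaConvention:
    """δ13C reporting convention (reference ratio + per-mil scaling).

    Parameters
    ----------
    r_std
        13C/12C ratio of the reference material.  Default is VPDB.
    """

    r_std: float = R_VPDB

    def __post_init__(self) -> None:
        if not (self.r_std > 0):
            raise ValueError(f"r_std must be positive, got {self.r_std}")

    def ratio(self, delta_permil):
        """13C/12C ratio implied by a δ13C value in per mil."""
        delta_permil = np.asarray(delta_permil, dtype=float)
        if np.any(delta_permil <= -1000.0):
            raise ValueError("delta below -1000 permil implies a negative isotope ratio")
        return self.r_std * (1.0 + delta_permil / 1000.0)

    def delta(self, ratio):
        """δ13C (per mil) of a 13C/12C ratio."""
        return (np.asarray(ratio, dtype=float) / self.r_std - 1.0) * 1000.0

    def delta_from_masses(self, m13, m12):
        """δ13C (per mil) from isotopologue masses; ``m12`` must be positive."""
        m12 = np.asarray(m12, dtype=float)
        if np.any(m12 <= 0):
            raise ValueError("m12 must be positive to form an isotope ratio")
        return self.delta(np.asarray(m13, dtype=float) / m12)


DEFAULT_DELTA = DeltaConvention()


def isotopologue_split(flux, delta_permil, conv: DeltaConvention = DEFAULT_DELTA):
    """Split a CH4 flux into (12CH4, 13CH4) parts with ratio set by δ13C.

    Exact bookkeeping: ``s13 / s12 = r_std * (1 + δ/1000)`` and
    ``s12 + s13 = flux``.  Works elementwise on arrays; broadcasting between
    ``flux`` and ``delta_permil`` follows numpy rules.
    """
    flux = np.asarray(flux, dtype=float)
    r = conv.ratio(delta_permil)
    s13 = flux * r / (1.0 + r)
    return flux - s13, s13


def delta_from_split(s12, s13, conv: DeltaConvention = DEFAULT_DELTA):
    """Recover δ13C (per mil) from an isotopologue pair."""
    s12 = np.asarray(s12, dtype=float)
    if np.any(s12 <= 0):
        raise ValueError("12C part must be positive to form a ratio")
    return conv.delta(np.asarray(s13, dtype=float) / s12)


@dataclass(frozen=True)
class UnitConvention:
    """ppb ↔ Tg conversion and the hemispheric mass split.

    The two tropospheric boxes are taken to hold equal air masses, so at an
    equal mixing ratio each box carries half the global CH4 mass.
    """

    tg_per_ppb: float = TG_PER_PPB

    def __post_init__(self) -> None:
        if not (self.tg_per_ppb > 0):
            raise ValueError(f"tg_per_ppb must be positive, got {self.tg_per_ppb}")

    def ppb_to_tg(self, ppb):
        """Global mean mixing ratio (ppb) → total atmospheric CH4 mass (Tg)."""
        ppb = np.asarray(ppb, dtype=float)
        if np.any(~np.isfinite(ppb)):
            raise ValueError("non-finite mixing ratio")
        return ppb * self.tg_per_ppb

    def tg_to_ppb(self, tg):
        """Total atmospheric CH4 mass (Tg) → global mean mixing ratio (ppb)."""
        tg = np.asarray(tg, dtype=float)
        if np.any(~np.isfinite(tg)):
            raise ValueError("non-finite mass")
        return tg / self.tg_per_ppb

    def box_mass(self, ppb):
        """Per-hemisphere CH4 mass (Tg) at a given box mixing ratio (ppb)."""
        return np.asarray(ppb, dtype=float) * (self.tg_per_ppb / 2.0)

    def box_ppb(self, tg):
        """Box mixing ratio (ppb) of a per-hemisphere CH4 mass (Tg)."""
        return np.asarray(tg, dtype=float) / (self.tg_per_ppb / 2.0)


DEFAULT_UNITS = UnitConvention()
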