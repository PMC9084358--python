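"""Emission-weighted δ13C source signatures and their Monte Carlo sampling.

Spatially resolved source categories carry a gridded flux pattern and a
gridded δ13C map with a per-cell 1-σ layer; sectors without maps carry a
scalar mean ± σ.  A Monte Carlo *draw* perturbs every map cell (or scalar)
independently with Gaussian noise, clips to physically plausible bounds,
and reduces each sector to one emission-weighted δ13C per hemisphere.
Category signatures then follow by flux-weighting the member sectors year
by year, so a shifting sector mix (e.g. growing coal share) moves the
category δ13C even though each sector's map is fixed.

Reproducibility: draw ``i`` of sector ``s`` uses the dedicated substream
``default_rng([master_seed, crc32(s), i])`` — ensembles are reproducible
and independent of evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .units import DEFAULT_DELTA, DeltaConvention, isotopologue_split

__all__ = [
    "DELTA_BOUNDS",
    "GriddedField",
    "SectorSignatureSpec",
    "SignatureDraw",
    "SectorSignatureDraws",
    "weighted_signature",
    "sample_signature_maps",
    "scalar_signature",
    "source_isotopologue_split",
    "build_sector_signature_draws",
    "category_delta_series",
]

#: Clipping bounds for perturbed δ13C values (per mil); guards unphysical
#: Gaussian tails.  Configurable at call sites.
DELTA_BOUNDS = (-120.0, 10.0)


def _substream(master_seed: int, tag: str, index: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), zlib.crc32(tag.encode()), int(index)])


@dataclass
class GriddedField:
    """A regular lat/lon field (flux per cell, or δ13C with optional 1-σ)."""

    lat: np.ndarray                  # (nlat,) cell-center latitudes, ascending
    lon: np.ndarray                  # (nlon,) cell-center longitudes
    values: np.ndarray               # (nlat, nlon)
    sigma: Optional[np.ndarray] = None  # (nlat, nlon), >= 0

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lat.size, self.lon.size):
            raise ValueError(
                f"values shape {self.values.shape} != (nlat={self.lat.size}, nlon={self.lon.size})")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.values.shape:
                raise ValueError("sigma layer not congruent with values")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")

    def congruent(self, other: "GriddedField") -> bool:
        return (np.array_equal(self.lat, other.lat)
                and np.array_equal(self.lon, other.lon))

    def hemisphere_mask(self, region: str) -> np.ndarray:
        """Boolean cell mask; cells are assigned by center latitude (>= 0 -> N)."""
        if region in ("global", "G"):
            return np.ones_like(self.values, dtype=bool)
        if region == "N":
            return np.broadcast_to((self.lat >= 0)[:, None], self.values.shape)
        if region == "S":
            return np.broadcast_to((self.lat < 0)[:, None], self.values.shape)
        raise ValueError(f"unknown region {region!r} (use 'N', 'S' or 'global')")

    # -- I/O ---------------------------------------------------------------
    def to_dataset(self):
        import xarray as xr

        data = {"value": (("lat", "lon"), self.values)}
        if self.sigma is not None:
            data["sigma"] = (("lat", "lon"), self.sigma)
        return xr.Dataset(data, coords={"lat": self.lat, "lon": self.lon})

    def to_netcdf(self, path) -> None:
        # NetCDF-3 via the scipy backend keeps the dependency footprint small.
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "GriddedField":
        import xarray as xr

        with xr.open_dataset(path, engine="scipy") as ds:
            sigma = ds["sigma"].values.copy() if "sigma" in ds else None
            return cls(ds["lat"].values.copy(), ds["lon"].values.copy(),
                       ds["value"].values.copy(), sigma)

    def to_csv(self, path) -> None:
        lat2, lon2 = np.meshgrid(self.lat, self.lon, indexing="ij")
        frame = pd.DataFrame({
            "lat": lat2.ravel(), "lon": lon2.ravel(), "value": self.values.ravel()})
        if self.sigma is not None:
            frame["sigma"] = self.sigma.ravel()
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GriddedField":
        frame = pd.read_csv(path)
        lat = np.unique(frame["lat"].to_numpy())
        lon = np.unique(frame["lon"].to_numpy())
        pv = frame.pivot_table(index="lat", columns="lon", values="value")
        values = pv.reindex(index=lat, columns=lon).to_numpy()
        sigma = None
        if "sigma" in frame.columns:
            sigma = (frame.pivot_table(index="lat", columns="lon", values="sigma")
                     .reindex(index=lat, columns=lon).to_numpy())
        return cls(lat, lon, values, sigma)


def weighted_signature(flux: GriddedField, sig: GriddedField, region: str = "global") -> float:
    """Flux-weighted mean δ13C over a region: Σ(F_c δ_c)/Σ F_c.

    Raises if the grids are not congruent or the regional flux total is zero
    (undefined weights).
    """
    if not flux.congruent(sig):
        raise ValueError("flux and signature grids are not congruent")
    mask = flux.hemisphere_mask(region)
    w = np.where(mask, flux.values, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"zero total flux in region {region!r}: weights undefined")
    return float((w * sig.values).sum() / total)


def sample_signature_maps(
    sig: GriddedField,
    n: int,
    seed: int,
    tag: str = "map",
    bounds: tuple = DELTA_BOUNDS,
    sigma_scale: float = 1.0,
    mode: str = "cellwise",
) -> np.ndarray:
    """``n`` Gaussian perturbations of a signature map.

    Returns an array of shape ``(n, nlat, nlon)``; draw ``i`` depends only
    on ``(seed, tag, i)``.  Values are clipped to ``bounds``.  A zero sigma
    layer (or ``sigma_scale=0``) reproduces the mean map in every draw.

    ``mode="cellwise"`` (the default) perturbs every cell independently;
    ``mode="offset"`` applies one shared standard-normal deviate per draw
    to the whole map (scaled by the cell σ), a sensitivity variant that
    treats the map uncertainty as fully correlated.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if sig.sigma is None:
        raise ValueError("signature field has no sigma layer")
    if mode not in ("cellwise", "offset"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    out = np.empty((n,) + sig.values.shape)
    scaled = sig.sigma * sigma_scale
    for i in range(n):
        rng = _substream(seed, tag, i)
        z = (rng.standard_normal(sig.values.shape) if mode == "cellwise"
             else rng.standard_normal())
        out[i] = np.clip(sig.values + scaled * z, *bounds)
    return out


def scalar_signature(
    category: str,
    mean: float,
    sigma: float,
    n: int,
    seed: int,
    bounds: tuple = DELTA_BOUNDS,
    sigma_scale: float = 1.0,
) -> np.ndarray:
    """``n`` Gaussian draws of a globally averaged signature (clipped).

    ``n = 0`` returns an explicit empty array.  Draw ``i`` depends only on
    ``(seed, category, i)``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 0:
        raise ValueError("n must be >= 0")
    out = np.empty(n)
    for i in range(n):
        z = _substream(seed, f"scalar:{category}", i).standard_normal()
        out[i] = mean + sigma * sigma_scale * z
    return np.clip(out, *bounds)


def source_isotopologue_split(flux, delta_permil, conv: DeltaConvention = DEFAULT_DELTA):
    """Split a source flux into (12S, 13S) Tg yr^-1 (exact bookkeeping).

    ``13S/12S = r_std (1 + δ/1000)`` and ``12S + 13S = flux``.
    """
    return isotopologue_split(flux, delta_permil, conv)


@dataclass
class SectorSignatureSpec:
    """What is needed to draw one sector's hemispheric signatures.

    ``pattern`` (flux weights) and a map-valued ``signature`` for spatially
    resolved sectors; ``signature = (mean, sigma)`` for scalar sectors
    (applied identically in both hemispheres).
    """

    name: str
    category: str
    signature: Union[GriddedField, tuple]
    pattern: Optional[GriddedField] = None

    def __post_init__(self) -> None:
        if isinstance(self.signature, GriddedField):
            if self.pattern is None:
                raise ValueError(f"sector {self.name!r}: gridded signature needs a flux pattern")
            if not self.pattern.congruent(self.signature):
                raise ValueError(f"sector {self.name!r}: pattern/signature grids differ")
        else:
            mean, sigma = self.signature
            if sigma < 0:
                raise ValueError(f"sector {self.name!r}: negative sigma")

    @property
    def gridded(self) -> bool:
        return isinstance(self.signature, GriddedField)


@dataclass
class SignatureDraw:
    """One Monte Carlo realization of per-sector hemispheric δ13C values."""

    index: int
    delta: pd.DataFrame              # index: sector name, columns: N, S

    def sector_delta(self, name: str, hemisphere: str) -> float:
        return float(self.delta.loc[name, hemisphere])


@dataclass
class SectorSignatureDraws:
    """The full Monte Carlo ensemble of sector signatures.

    ``delta`` has shape ``(n_draws, n_sectors, 2)`` with the last axis over
    (N, S); sector order is ``names``.
    """

    names: list
    categories: dict                 # sector name -> category
    delta: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.delta.shape[0]

    def draw(self, i: int) -> SignatureDraw:
        frame = pd.DataFrame(self.delta[i], index=list(self.names), columns=["N", "S"])
        return SignatureDraw(i, frame)


def build_sector_signature_draws(
    specs: Sequence[SectorSignatureSpec],
    n_draws: int,
    seed: int,
    bounds: tuple = DELTA_BOUNDS,
    sigma_scale: float = 1.0,
    mode: str = "cellwise",
) -> SectorSignatureDraws:
    """Draw hemispheric emission-weighted δ13C for every sector.

    Gridded sectors: each draw perturbs the map cell-wise, then reduces to
    one flux-weighted value per hemisphere (a hemisphere with zero pattern
    flux gets NaN — it then carries zero flux weight downstream).  Scalar
    sectors: one Gaussian value per draw, used in both hemispheres.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sector names")
    delta = np.full((n_draws, len(specs), 2), np.nan)
    for j, spec in enumerate(specs):
        if spec.gridded:
            maps = sample_signature_maps(spec.signature, n_draws, seed,
                                         tag=f"map:{spec.name}", bounds=bounds,
                                         sigma_scale=sigma_scale, mode=mode)
            for h, region in enumerate(("N", "S")):
                mask = spec.pattern.hemisphere_mask(region)
                w = np.where(mask, spec.pattern.values, 0.0)
                total = w.sum()
                if total > 0:
                    delta[:, j, h] = (maps * w).sum(axis=(1, 2)) / total
        else:
            mean, sigma = spec.signature
            vals = scalar_signature(spec.name, mean, sigma, n_draws, seed,
                                    bounds=bounds, sigma_scale=sigma_scale)
            delta[:, j, 0] = vals
            delta[:, j, 1] = vals
    return SectorSignatureDraws(names, {s.name: s.category for s in specs}, delta)


def category_delta_series(
    sector_fluxes: dict,
    draws: SectorSignatureDraws,
    years: np.ndarray,
) -> np.ndarray:
    """Emission-weighted category δ13C per draw, year and hemisphere.

    ``sector_fluxes`` maps sector name -> year-indexed DataFrame (N, S) for
    the sectors of *one* category candidate.  Returns an array of shape
    ``(n_draws, n_years, 2)``.  Years/hemispheres where the candidate has
    zero total flux get δ = 0 (they contribute zero isotopologue flux, so
    the placeholder value is inert).
    """
    years = np.asarray(years, dtype=int)
    num = np.zeros((draws.n_draws, years.size, 2))
    den = np.zeros((years.size, 2))
    for name, frame in sector_fluxes.items():
        if name not in draws.names:
            raise KeyError(f"no signature draws for sector {name!r}")
        j = draws.names.index(name)
        flux = frame.reindex(years).to_numpy(dtype=float)       # (n_years, 2)
        if np.any(~np.isfinite(flux)):
            raise ValueError(f"sector {name!r} missing years in {years[0]}..{years[-1]}")
        d = draws.delta[:, j, :]                                 # (n_draws, 2)
        undefined = ~np.isfinite(d[0])                           # same cells in every draw
        if np.any((flux > 0) & undefined[None, :]):
            raise ValueError(
                f"sector {name!r} carries flux in a hemisphere with no signature")
        contrib = flux[None, :, :] * np.nan_to_num(d[:, None, :])
        num += contrib
        den += flux
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den[None, :, :] > 0, num / den[None, :, :], 0.0)
    return out
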