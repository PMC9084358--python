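"""Synthetic world generator: every input the pipeline needs, from a seed.

The generator emulates the study's data situation without any download:
per-sector annual emissions with configurable trends, steps and
interannual variability (IAV); stylized gridded flux patterns and δ13C
signature maps with per-cell 1-σ; scalar signatures for sectors without
maps; and pseudo-observations produced by running the forward box model on
the known truth (prescribed ε and OH series) plus Gaussian observation
noise.  Sector placement is deliberately schematic — tropical + boreal
wetland bands, mid-latitude northern fossil sources — enough to create
hemispheric and band contrast, with no claim to inventory realism.

Default magnitudes are chosen to look like the 1993–2017 methane budget:
~550 Tg yr^-1 gross source, a ~9.3 yr lifetime, a +7.3 Tg step in tropical
wetland emissions at 2007, signature means per the compiled source-
signature tables (coal −45.8‰, oil & gas −43.8‰, livestock −65.4‰,
wetlands −59.6‰ flux-weighted from tropical −56.7 / boreal −67.8‰,
biomass burning −23.9‰), ε = −6.9‰, and a 0.04‰ observed-δ13C 1-σ.
The same seed always reproduces the same world, byte for byte.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .boxmodel import IsotopeState, SinkParameters, run_forward
from .ensemble import build_forcing, scenario_category_deltas
from .inversion import ObservationRecord
from .scenarios import (CATEGORIES, FACTORIAL_CATEGORIES, CategoryCandidate,
                        EmissionScenario, ScenarioCatalogue, SectorSeries)
from .signatures import GriddedField, SectorSignatureSpec, build_sector_signature_draws
from .units import DEFAULT_DELTA, DEFAULT_UNITS, DeltaConvention, UnitConvention

__all__ = [
    "SectorSpec",
    "TruthConfig",
    "SyntheticWorld",
    "generate_world",
    "make_scenario_catalogue",
    "wetland_signature_map",
]


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(tag.encode())])


@dataclass(frozen=True)
class SectorSpec:
    """One synthetic sector: flux shape, placement and δ13C signature."""

    name: str
    category: str
    base: float                       # global flux in the first year, Tg yr^-1
    trend: float = 0.0                # Tg yr^-1 per year
    step: Optional[tuple] = None      # (year, magnitude Tg yr^-1)
    iav_sigma: float = 0.0            # 1-σ interannual noise, Tg yr^-1
    sig_mean: float = -60.0           # δ13C mean, permil
    sig_sigma: float = 0.0            # per-cell (or scalar) 1-σ, permil
    pattern: Optional[str] = None     # band name; None -> scalar signature
    nh_share: Optional[float] = None  # hemispheric split for scalar sectors


def _default_sectors() -> tuple:
    return (
        SectorSpec("coal", "IFF", base=38.0, trend=0.45,
                   sig_mean=-45.8, sig_sigma=2.57, pattern="nh_midlat"),
        SectorSpec("oil_gas", "IFF", base=80.0, trend=0.20,
                   sig_mean=-43.8, sig_sigma=0.93, pattern="nh_midlat"),
        SectorSpec("livestock", "AGW", base=100.0, trend=0.55,
                   sig_mean=-65.4, sig_sigma=0.86, pattern="nh_broad"),
        SectorSpec("rice", "AGW", base=30.0, sig_mean=-63.0, sig_sigma=1.0,
                   nh_share=0.9),
        SectorSpec("landfill_waste", "AGW", base=62.0, trend=0.35,
                   sig_mean=-55.0, sig_sigma=1.5, nh_share=0.9),
        SectorSpec("wetlands_tropical", "WET", base=110.0, step=(2007, 7.3),
                   iav_sigma=3.0, sig_mean=-56.7, sig_sigma=0.20,
                   pattern="tropics"),
        SectorSpec("wetlands_boreal", "WET", base=40.0, iav_sigma=1.0,
                   sig_mean=-67.8, sig_sigma=0.20, pattern="boreal"),
        SectorSpec("biomass_burning", "BB", base=32.0, trend=-0.25,
                   iav_sigma=2.0, sig_mean=-23.9, sig_sigma=0.14,
                   pattern="tropics"),
        SectorSpec("geological", "GEO", base=15.0, sig_mean=-49.0,
                   sig_sigma=1.0, nh_share=0.7),
        SectorSpec("other_natural", "OTH", base=40.0, sig_mean=-61.0,
                   sig_sigma=1.5, nh_share=0.6),
    )


@dataclass(frozen=True)
class TruthConfig:
    """Full description of the synthetic truth; the seed fixes everything."""

    years: tuple = (1993, 2017)
    sectors: tuple = field(default_factory=_default_sectors)
    soil_uptake: float = 30.0         # Tg yr^-1, constant climatology
    soil_nh_share: float = 2.0 / 3.0
    epsilon: float = -6.9             # permil, sink-weighted fractionation
    init_ch4_ppb: float = 1735.0
    oh_anomaly_amplitude: float = 0.005   # fractional IAV of k_oh
    oh_anomaly_period: float = 15.0       # yr
    oh_anomaly_phase_year: float = 1998.0
    ch4_obs_sigma: float = 0.5        # ppb
    d13c_obs_sigma: float = 0.04      # permil
    seed: int = 0
    nlat: int = 18
    nlon: int = 36

    def noise_free(self) -> "TruthConfig":
        """Same truth with zero IAV and zero observation noise."""
        quiet = tuple(replace(s, iav_sigma=0.0) for s in self.sectors)
        return replace(self, sectors=quiet, ch4_obs_sigma=0.0, d13c_obs_sigma=0.0)

    def with_wetland_trend(self, slope: float) -> "TruthConfig":
        """Replace the tropical-wetland step with a linear trend (Tg yr^-2)."""
        sectors = tuple(
            replace(s, step=None, trend=slope, iav_sigma=0.0)
            if s.name == "wetlands_tropical" else s
            for s in self.sectors)
        return replace(self, sectors=sectors)


_BANDS = {
    "nh_midlat": lambda lat: (lat >= 30) & (lat <= 60),
    "nh_broad": lambda lat: (lat >= -35) & (lat <= 60),
    "tropics": lambda lat: np.abs(lat) <= 20,
    "boreal": lambda lat: (lat >= 50) & (lat <= 70),
}


def _grid(cfg: TruthConfig):
    dlat = 180.0 / cfg.nlat
    dlon = 360.0 / cfg.nlon
    lat = -90.0 + dlat / 2.0 + dlat * np.arange(cfg.nlat)
    lon = -180.0 + dlon / 2.0 + dlon * np.arange(cfg.nlon)
    return lat, lon


def _band_pattern(kind: str, lat: np.ndarray, lon: np.ndarray) -> GriddedField:
    if kind not in _BANDS:
        raise ValueError(f"unknown pattern kind {kind!r}")
    mask = _BANDS[kind](lat)
    values = np.repeat(mask[:, None].astype(float), lon.size, axis=1)
    if values.sum() == 0:
        raise ValueError(f"pattern {kind!r} selects no cells on this grid")
    return GriddedField(lat, lon, values / values.sum())


def wetland_signature_map(lat: np.ndarray, lon: np.ndarray,
                          tropical_mean: float = -56.7,
                          boreal_mean: float = -67.8,
                          sigma: float = 0.20) -> GriddedField:
    """One wetland δ13C map: enriched tropical band, depleted boreal band.

    Cells outside both bands take the latitude-interpolated value; the two
    wetland flux patterns (tropical, boreal) select their own band, so the
    emission-weighted wetland δ13C always lies between the band means and
    moves toward the tropical value as the tropical flux share grows.
    """
    per_lat = np.where(np.abs(lat) <= 20, tropical_mean,
                       np.where(lat >= 50, boreal_mean,
                                np.interp(np.abs(lat), [20.0, 50.0],
                                          [tropical_mean, boreal_mean])))
    values = np.repeat(per_lat[:, None], lon.size, axis=1)
    return GriddedField(lat, lon, values, np.full_like(values, sigma))


def _sector_series(spec: SectorSpec, years: np.ndarray, nh_share: float,
                   seed: int) -> SectorSeries:
    y0 = years[0]
    flux = spec.base + spec.trend * (years - y0)
    if spec.step is not None:
        sy, mag = spec.step
        flux = flux + mag * (years >= sy)
    if spec.iav_sigma > 0:
        flux = flux + spec.iav_sigma * _rng(seed, f"series:{spec.name}") \
            .standard_normal(years.size)
    flux = np.maximum(flux, 0.0)
    frame = pd.DataFrame({"N": flux * nh_share, "S": flux * (1.0 - nh_share)},
                         index=pd.Index(years, name="year"))
    return SectorSeries(spec.name, spec.category, "TRUTH", frame)


@dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, plus the truth ledger."""

    config: TruthConfig
    lat: np.ndarray
    lon: np.ndarray
    patterns: dict                    # sector -> GriddedField (flux weights)
    signature_maps: dict              # sector -> GriddedField (with sigma)
    scalar_signatures: dict           # sector -> (mean, sigma)
    sector_series: dict               # sector -> SectorSeries
    observations: ObservationRecord
    truth: dict                       # epsilon, k_oh, init, category tables

    def signature_specs(self) -> list:
        specs = []
        for spec in self.config.sectors:
            if spec.pattern is not None:
                specs.append(SectorSignatureSpec(
                    spec.name, spec.category,
                    signature=self.signature_maps[spec.name],
                    pattern=self.patterns[spec.name]))
            else:
                specs.append(SectorSignatureSpec(
                    spec.name, spec.category,
                    signature=self.scalar_signatures[spec.name]))
        return specs

    def soil_series(self) -> SectorSeries:
        years = np.arange(self.config.years[0], self.config.years[1] + 1)
        cfg = self.config
        frame = pd.DataFrame(
            {"N": np.full(years.size, cfg.soil_uptake * cfg.soil_nh_share),
             "S": np.full(years.size, cfg.soil_uptake * (1 - cfg.soil_nh_share))},
            index=pd.Index(years, name="year"))
        return SectorSeries("soil", "SOIL", "TRUTH", frame)

    def truth_candidates(self) -> dict:
        """One TRUTH candidate per category (members = the truth sectors)."""
        by_cat: dict = {}
        for name, series in self.sector_series.items():
            by_cat.setdefault(series.category, []).append(series)
        return {cat: CategoryCandidate(cat, "TRUTH", members)
                for cat, members in by_cat.items()}

    def truth_scenario(self) -> EmissionScenario:
        cands = self.truth_candidates()
        members = {cat: cands[cat] for cat in CATEGORIES}
        sid = "-".join(f"{cat}0" for cat in FACTORIAL_CATEGORIES)
        return EmissionScenario(sid, members, self.soil_series())


def generate_world(cfg: TruthConfig = TruthConfig(),
                   units: UnitConvention = DEFAULT_UNITS,
                   conv: DeltaConvention = DEFAULT_DELTA) -> SyntheticWorld:
    """Build grids, series, signatures and pseudo-observations from a truth.

    Observations are the forward box-model run of the truth (prescribed
    OH-rate series and ε) plus Gaussian noise; the truth ledger records
    everything needed for recovery tests.  Raises if the configured
    sources cannot cover the soil uptake.
    """
    y0, y1 = cfg.years
    years = np.arange(y0, y1 + 1)
    lat, lon = _grid(cfg)

    patterns, signature_maps, scalar_signatures, sector_series = {}, {}, {}, {}
    wet_map = wetland_signature_map(lat, lon)
    for spec in cfg.sectors:
        if spec.pattern is not None:
            pat = _band_pattern(spec.pattern, lat, lon)
            patterns[spec.name] = pat
            if spec.category == "WET":
                signature_maps[spec.name] = dataclasses.replace(
                    wet_map, sigma=np.full_like(wet_map.values, spec.sig_sigma))
            else:
                signature_maps[spec.name] = GriddedField(
                    lat, lon, np.full((lat.size, lon.size), spec.sig_mean),
                    np.full((lat.size, lon.size), spec.sig_sigma))
            nh_share = float(np.clip(
                pat.values[lat >= 0, :].sum() / pat.values.sum(), 0.0, 1.0))
        else:
            if spec.nh_share is None:
                raise ValueError(f"scalar sector {spec.name!r} needs nh_share")
            scalar_signatures[spec.name] = (spec.sig_mean, spec.sig_sigma)
            nh_share = spec.nh_share
        sector_series[spec.name] = _sector_series(spec, years, nh_share, cfg.seed)

    world = SyntheticWorld(cfg, lat, lon, patterns, signature_maps,
                           scalar_signatures, sector_series,
                           observations=None, truth=None)

    # --- truth forcing at the exact (unperturbed) signatures --------------
    scen = world.truth_scenario()
    total = scen.total()  # raises on negative net source
    mean_draws = build_sector_signature_draws(world.signature_specs(), 1,
                                              cfg.seed, sigma_scale=0.0)
    years_step = years[:-1]
    cat_delta = {c: a[0] for c, a in
                 scenario_category_deltas(scen, mean_draws, years_step).items()}
    forcing, mean_source_delta = build_forcing(scen, cat_delta, years_step, conv)

    # --- prescribed sinks and initial state -------------------------------
    m_init = units.ppb_to_tg(cfg.init_ch4_ppb)
    k0 = float(total.loc[y0].sum()) / m_init        # steady start: k = S/M
    k_oh = pd.Series(
        k0 * (1.0 + cfg.oh_anomaly_amplitude
              * np.sin(2 * np.pi * (years - cfg.oh_anomaly_phase_year)
                       / cfg.oh_anomaly_period)),
        index=pd.Index(years, name="year"), name="k_oh")
    alpha = 1.0 + cfg.epsilon / 1000.0
    # steady-state isotope ratio: R_atm = R_src / alpha
    delta_src0 = _first_year_source_delta(forcing, conv)
    d_init = ((1.0 + delta_src0 / 1000.0) / alpha - 1.0) * 1000.0
    init = IsotopeState.from_observation(int(y0), cfg.init_ch4_ppb, d_init,
                                         units, conv)

    sinks = SinkParameters(k_oh=k_oh, epsilon_total=cfg.epsilon, tau_ex=1.0)
    traj = run_forward(forcing, sinks, init, units, conv)

    ppb = traj.ppb_global()
    d13 = traj.delta_global()
    if cfg.ch4_obs_sigma > 0:
        ppb = ppb + cfg.ch4_obs_sigma * _rng(cfg.seed, "obs:ch4") \
            .standard_normal(ppb.size)
    if cfg.d13c_obs_sigma > 0:
        d13 = d13 + cfg.d13c_obs_sigma * _rng(cfg.seed, "obs:d13c") \
            .standard_normal(d13.size)
    obs = ObservationRecord(pd.DataFrame({
        "ch4_ppb": ppb,
        "ch4_sigma": cfg.ch4_obs_sigma,
        "d13c_permil": d13,
        "d13c_sigma": cfg.d13c_obs_sigma,
    }, index=pd.Index(traj.years, name="year")))

    world.observations = obs
    world.truth = {
        "epsilon": cfg.epsilon,
        "k_oh": k_oh.loc[years_step],
        "init": init,
        "trajectory": traj,
        "category_flux": {c: scen.category_flux(c) for c in CATEGORIES},
        "category_delta": cat_delta,
        "mean_source_delta": float(np.asarray(mean_source_delta)),
        "net_total": total,
    }
    return world


def _first_year_source_delta(forcing, conv) -> float:
    s12 = forcing.s12_n[..., 0] + forcing.s12_s[..., 0]
    s13 = forcing.s13_n[..., 0] + forcing.s13_s[..., 0]
    return float(conv.delta(np.asarray(s13) / np.asarray(s12)))


def _transform(members: list, label: str, fn) -> CategoryCandidate:
    """Apply fn(name, DataFrame) -> DataFrame to every member series."""
    out = []
    for m in members:
        data = fn(m.name, m.data.copy())
        out.append(SectorSeries(m.name, m.category, label, data))
    return CategoryCandidate(out[0].category, label, out)


def make_scenario_catalogue(
    world: SyntheticWorld,
    counts: tuple = (4, 3, 2, 2, 2),
) -> ScenarioCatalogue:
    """Factorial catalogue of candidate estimates around the truth.

    Candidate 0 of every category is the truth; the remaining candidates
    emulate the systematic disagreements between bottom-up products —
    steeper or flatter trends, magnitude biases, a step-free wetland
    estimate, a flat biomass-burning series, and a geological source at
    52 instead of 15 Tg yr^-1.  ``counts`` truncates the candidate lists
    (the default (4, 3, 2, 2, 2) enumerates to 96 scenarios).
    """
    truth = world.truth_candidates()
    years = np.arange(world.config.years[0], world.config.years[1] + 1)
    ramp = (years - years[0]).astype(float)

    def trend_on(sector_name, slope):
        def fn(name, data):
            if name == sector_name:
                total0 = data.sum(axis=1).to_numpy()
                scale = (total0 + slope * ramp) / np.where(total0 > 0, total0, 1.0)
                data = data.mul(np.maximum(scale, 0.0), axis=0)
            return data
        return fn

    def scale_all(factor):
        return lambda name, data: data * factor

    def flatten(offset=0.0):
        def fn(name, data):
            mean = data.mean(axis=0)
            flat = pd.DataFrame({c: np.full(len(data), mean[c]) for c in data},
                                index=data.index)
            total = flat.sum(axis=1)
            return flat.mul((total + offset) / total, axis=0)
        return fn

    def remove_step(sector_name, step):
        sy, mag = step
        def fn(name, data):
            if name == sector_name:
                total0 = data.sum(axis=1).to_numpy()
                adj = total0 - mag * (data.index.to_numpy() >= sy)
                data = data.mul(adj / np.where(total0 > 0, total0, 1.0), axis=0)
            return data
        return fn

    def constant_at(value):
        def fn(name, data):
            share = data.div(data.sum(axis=1), axis=0)
            return share.mul(value, axis=0)
        return fn

    iff, agw, wet, bb, geo = (truth[c] for c in FACTORIAL_CATEGORIES)
    wet_step = next((s.step for s in world.config.sectors
                     if s.name == "wetlands_tropical" and s.step is not None), None)
    if wet_step is not None:
        no_step = _transform(wet.members, "NOSTEP",
                             remove_step("wetlands_tropical", wet_step))
    else:
        no_step = _transform(wet.members, "FLAT", flatten())
    variants = {
        "IFF": [iff,
                _transform(iff.members, "HIGHTREND", trend_on("coal", 0.7)),
                _transform(iff.members, "LOWBIAS", scale_all(0.92)),
                _transform(iff.members, "FLAT", flatten(offset=8.0))],
        "AGW": [agw,
                _transform(agw.members, "HIGHTREND", trend_on("livestock", 0.5)),
                _transform(agw.members, "LOWTREND", trend_on("livestock", -0.4))],
        "WET": [wet, no_step],
        "BB": [bb, _transform(bb.members, "FLAT", flatten())],
        "GEO": [geo, _transform(geo.members, "HIGH52", constant_at(52.0))],
    }
    if len(counts) != len(FACTORIAL_CATEGORIES):
        raise ValueError("counts must have one entry per factorial category")
    candidates = {}
    for cat, n in zip(FACTORIAL_CATEGORIES, counts):
        avail = variants[cat]
        if not (1 <= n <= len(avail)):
            raise ValueError(f"{cat}: requested {n} candidates, have {len(avail)}")
        candidates[cat] = avail[:n]
    return ScenarioCatalogue(candidates, other=truth["OTH"],
                             soil=world.soil_series())
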