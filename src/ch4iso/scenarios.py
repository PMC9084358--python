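"""Emission-scenario catalogue: sector→category mapping and the factorial.

The net annual CH4 source of one scenario is

    S_tot = S_IFF + S_AGW + S_WET + S_BB + S_GEO + S_OTH - S_soil

per year and hemisphere, where the five leading categories each come from a
catalogue of candidate bottom-up estimates (e.g. 4 industrial-fossil-fuel
candidates x 3 agriculture/waste x 2 wetland x 2 biomass-burning x 2
geological = 96 scenarios), OTH is a single shared natural-source series and
S_soil a constant climatological soil uptake.

Candidates keep their member *sector* series (coal, oil & gas, ...) because
the emission-weighted δ13C of a category depends on the sector mix, not only
on the category total.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CATEGORIES",
    "FACTORIAL_CATEGORIES",
    "SectorSeries",
    "CategoryCandidate",
    "ScenarioCatalogue",
    "EmissionScenario",
    "load_sector_mapping",
    "map_sectors",
    "enumerate_scenarios",
    "combine_total",
]

#: Source categories of the budget (SOIL is the uptake term, kept separate).
CATEGORIES = ("IFF", "AGW", "WET", "BB", "GEO", "OTH")

#: Categories that vary across the factorial ensemble, in enumeration order.
FACTORIAL_CATEGORIES = ("IFF", "AGW", "WET", "BB", "GEO")

HEMISPHERES = ("N", "S")


def load_sector_mapping(path=None) -> dict:
    """Sector-name → category mapping (editable YAML shipped with the package)."""
    if path is None:
        text = resources.files("ch4iso.data").joinpath("sector_categories.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    mapping = yaml.safe_load(text)
    bad = {s: c for s, c in mapping.items() if c not in CATEGORIES + ("SOIL",)}
    if bad:
        raise ValueError(f"mapping assigns unknown categories: {bad}")
    return mapping


def _check_frame(data: pd.DataFrame, name: str, uptake: bool = False) -> pd.DataFrame:
    data = data.copy()
    if list(data.columns) != list(HEMISPHERES):
        raise ValueError(f"{name}: columns must be {HEMISPHERES}, got {list(data.columns)}")
    if len(data) and np.any(np.diff(data.index.to_numpy()) != 1):
        raise ValueError(f"{name}: years must be contiguous")
    if np.any(data.to_numpy() < 0):
        kind = "uptake magnitude" if uptake else "flux"
        raise ValueError(f"{name}: negative {kind}")
    data.index = data.index.astype(int)
    data.index.name = "year"
    return data


@dataclass
class SectorSeries:
    """One sector's hemispheric flux series (Tg CH4 yr^-1).

    ``data`` is year-indexed with columns N and S.  For the SOIL category
    the values are a non-negative uptake magnitude.
    """

    name: str
    category: str
    dataset: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES + ("SOIL",):
            raise ValueError(f"unknown category {self.category!r}")
        self.data = _check_frame(self.data, self.name, uptake=self.category == "SOIL")

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def total(self) -> pd.Series:
        """Global (N+S) series."""
        return self.data.sum(axis=1)


@dataclass
class CategoryCandidate:
    """One candidate estimate for a category: a bundle of sector series."""

    category: str
    label: str
    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"candidate {self.label!r} has no member sectors")
        years = self.members[0].years
        for m in self.members:
            if m.category != self.category:
                raise ValueError(
                    f"member {m.name!r} has category {m.category}, expected {self.category}")
            if not np.array_equal(m.years, years):
                raise ValueError(f"member {m.name!r} years differ within candidate {self.label!r}")

    @property
    def data(self) -> pd.DataFrame:
        """Aggregated hemispheric category series."""
        out = self.members[0].data.copy()
        for m in self.members[1:]:
            out = out + m.data
        return out

    @property
    def years(self) -> np.ndarray:
        return self.members[0].years

    def sector_fluxes(self) -> dict:
        return {m.name: m.data for m in self.members}


def map_sectors(table: pd.DataFrame, mapping: dict | None = None) -> dict:
    """Aggregate an inventory table into per-category candidates.

    ``table`` has columns dataset, sector, year, hemisphere, flux_tg and
    optionally an explicit category column (which wins over the mapping).
    Unmapped sectors fall into OTH with a warning; negative fluxes are
    rejected.  An empty table returns an empty dict — an explicit
    zero-length result, not a frame of zeros.
    """
    required = {"dataset", "sector", "year", "hemisphere", "flux_tg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"inventory table missing columns {sorted(missing)}")
    if len(table) == 0:
        return {}
    if np.any(table["flux_tg"].to_numpy() < 0):
        raise ValueError("negative flux rows in inventory table")
    if mapping is None:
        mapping = load_sector_mapping()

    def categorize(row) -> str:
        if "category" in table.columns and isinstance(row.get("category"), str) and row["category"]:
            return row["category"]
        sector = str(row["sector"]).lower()
        if sector in mapping:
            return mapping[sector]
        warnings.warn(f"sector {row['sector']!r} not in mapping; assigned to OTH")
        return "OTH"

    table = table.copy()
    table["_cat"] = table.apply(categorize, axis=1)
    out: dict = {}
    for (cat, dataset), grp in table.groupby(["_cat", "dataset"], sort=True):
        members = []
        for sector, sg in grp.groupby("sector", sort=True):
            wide = (sg.pivot_table(index="year", columns="hemisphere",
                                   values="flux_tg", aggfunc="sum")
                      .reindex(columns=list(HEMISPHERES), fill_value=0.0)
                      .fillna(0.0))
            wide.columns = list(HEMISPHERES)
            members.append(SectorSeries(str(sector), cat, str(dataset), wide))
        cand = CategoryCandidate(cat, str(dataset), members)
        out.setdefault(cat, []).append(cand)
    return out


@dataclass
class ScenarioCatalogue:
    """Ordered candidate lists per factorial category plus shared OTH/soil."""

    candidates: dict                 # category -> list[CategoryCandidate]
    other: CategoryCandidate         # OTH, shared by every scenario
    soil: SectorSeries               # uptake magnitude, shared

    def __post_init__(self) -> None:
        for cat in FACTORIAL_CATEGORIES:
            if not self.candidates.get(cat):
                raise ValueError(f"category {cat} has no candidates")
        years = self.candidates[FACTORIAL_CATEGORIES[0]][0].years
        for cat in FACTORIAL_CATEGORIES:
            for cand in self.candidates[cat]:
                if not np.array_equal(cand.years, years):
                    raise ValueError(f"candidate {cand.label!r} ({cat}) year range differs")
        for extra in (self.other.years, self.soil.years):
            if not np.array_equal(extra, years):
                raise ValueError("OTH/soil year range differs from candidates")

    @property
    def years(self) -> np.ndarray:
        return self.candidates[FACTORIAL_CATEGORIES[0]][0].years

    @property
    def counts(self) -> tuple:
        return tuple(len(self.candidates[c]) for c in FACTORIAL_CATEGORIES)

    def n_scenarios(self) -> int:
        return int(np.prod(self.counts))


@dataclass
class EmissionScenario:
    """One factorial combination with a stable id and a derived net total."""

    scenario_id: str
    members: dict                    # category -> CategoryCandidate (incl. OTH)
    soil: SectorSeries

    def category_flux(self, category: str) -> pd.DataFrame:
        if category == "SOIL":
            return self.soil.data
        return self.members[category].data

    def total(self) -> pd.DataFrame:
        """Net hemispheric source per year (sources minus soil uptake).

        Raises if the net source is negative in any year/hemisphere.
        """
        out = None
        for cat in CATEGORIES:
            d = self.members[cat].data
            out = d.copy() if out is None else out + d
        out = out - self.soil.data
        if np.any(out.to_numpy() < 0):
            bad = out.index[(out < 0).any(axis=1)].tolist()
            raise ValueError(f"negative net source in years {bad}")
        return out


def enumerate_scenarios(catalogue: ScenarioCatalogue) -> list:
    """Cartesian product of candidates, lexicographic in (IFF, AGW, WET, BB, GEO).

    Scenario ids encode the candidate indices (``IFF0-AGW2-...``) and are
    stable across re-runs.
    """
    lists = [catalogue.candidates[c] for c in FACTORIAL_CATEGORIES]
    out = []
    for indices in itertools.product(*(range(len(l)) for l in lists)):
        members = {cat: lists[k][i] for k, (cat, i) in
                   enumerate(zip(FACTORIAL_CATEGORIES, indices))}
        members["OTH"] = catalogue.other
        sid = "-".join(f"{cat}{i}" for cat, i in zip(FACTORIAL_CATEGORIES, indices))
        out.append(EmissionScenario(sid, members, catalogue.soil))
    return out


def combine_total(scenario: EmissionScenario) -> pd.DataFrame:
    """Net hemispheric S_tot series of a scenario (soil uptake subtracted)."""
    return scenario.total()
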