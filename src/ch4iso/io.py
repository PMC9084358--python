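"""Readers/writers for the pipeline's on-disk schemas.

A *world directory* holds everything one analysis needs, all in plain
text: ``observations.csv`` (year, ch4_ppb, ch4_sigma, d13c_permil,
d13c_sigma), ``inventory.csv`` (dataset, sector, category, year,
hemisphere, flux_tg — one dataset string per category candidate),
``catalogue.yaml`` (candidate order per category), ``grids/`` (CSV rasters
lat, lon, value[, sigma] per gridded sector), ``signature_meta.yaml``
(sector → category / kind / scalar mean ± σ) and ``truth.json`` (the
synthetic truth ledger, absent for real data).  NetCDF grids are accepted
interchangeably with the CSV rasters.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inversion import ObservationRecord
from .scenarios import (CATEGORIES, FACTORIAL_CATEGORIES, ScenarioCatalogue,
                        SectorSeries, map_sectors)
from .signatures import GriddedField, SectorSignatureSpec

__all__ = [
    "write_world",
    "load_observations",
    "load_catalogue",
    "load_signature_specs",
    "load_truth",
    "config_digest",
]


def config_digest(payload: dict) -> str:
    """Stable short hash of a configuration mapping (for run logs)."""
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _inventory_rows(candidate, dataset: str) -> pd.DataFrame:
    rows = []
    for member in candidate.members:
        for hemi in ("N", "S"):
            rows.append(pd.DataFrame({
                "dataset": dataset,
                "sector": member.name,
                "category": member.category,
                "year": member.data.index,
                "hemisphere": hemi,
                "flux_tg": member.data[hemi].to_numpy(),
            }))
    return pd.concat(rows, ignore_index=True)


def write_world(world, catalogue: ScenarioCatalogue, path) -> Path:
    """Write a synthetic world + catalogue as a world directory."""
    path = Path(path)
    (path / "grids").mkdir(parents=True, exist_ok=True)
    world.observations.to_csv(path / "observations.csv")

    inv = []
    order = {}
    for cat in FACTORIAL_CATEGORIES:
        order[cat] = []
        for cand in catalogue.candidates[cat]:
            dataset = f"{cat}:{cand.label}"
            order[cat].append(dataset)
            inv.append(_inventory_rows(cand, dataset))
    inv.append(_inventory_rows(catalogue.other, f"OTH:{catalogue.other.label}"))
    soil = catalogue.soil
    inv.append(pd.DataFrame({
        "dataset": "SOIL:TRUTH", "sector": soil.name, "category": "SOIL",
        "year": np.tile(soil.data.index, 2),
        "hemisphere": np.repeat(["N", "S"], len(soil.data)),
        "flux_tg": np.concatenate([soil.data["N"], soil.data["S"]]),
    }))
    pd.concat(inv, ignore_index=True).to_csv(path / "inventory.csv", index=False)

    order["OTH"] = f"OTH:{catalogue.other.label}"
    order["SOIL"] = "SOIL:TRUTH"
    with open(path / "catalogue.yaml", "w") as fh:
        yaml.safe_dump(order, fh)

    meta = {}
    for spec in world.config.sectors:
        if spec.pattern is not None:
            meta[spec.name] = {"category": spec.category, "kind": "gridded"}
            world.patterns[spec.name].to_csv(path / "grids" / f"{spec.name}_pattern.csv")
            world.signature_maps[spec.name].to_csv(
                path / "grids" / f"{spec.name}_signature.csv")
        else:
            mean, sigma = world.scalar_signatures[spec.name]
            meta[spec.name] = {"category": spec.category, "kind": "scalar",
                               "mean": float(mean), "sigma": float(sigma)}
    with open(path / "signature_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)

    truth = {
        "epsilon": world.truth["epsilon"],
        "k_oh": {int(y): float(v) for y, v in world.truth["k_oh"].items()},
        "mean_source_delta": world.truth["mean_source_delta"],
        "seed": world.config.seed,
    }
    with open(path / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return path


def load_observations(path) -> ObservationRecord:
    return ObservationRecord.from_csv(Path(path) / "observations.csv")


def load_catalogue(path) -> ScenarioCatalogue:
    path = Path(path)
    table = pd.read_csv(path / "inventory.csv")
    with open(path / "catalogue.yaml") as fh:
        order = yaml.safe_load(fh)
    by_cat = map_sectors(table)
    candidates = {}
    for cat in FACTORIAL_CATEGORIES:
        by_label = {c.label: c for c in by_cat.get(cat, [])}
        missing = [d for d in order[cat] if d not in by_label]
        if missing:
            raise ValueError(f"catalogue.yaml names unknown datasets {missing}")
        candidates[cat] = [by_label[d] for d in order[cat]]
    other = {c.label: c for c in by_cat["OTH"]}[order["OTH"]]
    soil_cand = {c.label: c for c in by_cat["SOIL"]}[order["SOIL"]]
    soil = SectorSeries("soil", "SOIL", soil_cand.label, soil_cand.data)
    return ScenarioCatalogue(candidates, other=other, soil=soil)


def load_signature_specs(path) -> list:
    path = Path(path)
    with open(path / "signature_meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    specs = []
    for name, info in meta.items():
        if info["kind"] == "gridded":
            pattern = _load_grid(path / "grids" / f"{name}_pattern")
            signature = _load_grid(path / "grids" / f"{name}_signature")
            specs.append(SectorSignatureSpec(name, info["category"],
                                             signature=signature, pattern=pattern))
        else:
            specs.append(SectorSignatureSpec(
                name, info["category"],
                signature=(float(info["mean"]), float(info["sigma"]))))
    return specs


def _load_grid(stem: Path) -> GriddedField:
    if stem.with_suffix(".csv").exists():
        return GriddedField.from_csv(stem.with_suffix(".csv"))
    if stem.with_suffix(".nc").exists():
        return GriddedField.from_netcdf(stem.with_suffix(".nc"))
    raise FileNotFoundError(f"no grid file for {stem}")


def load_truth(path) -> dict:
    with open(Path(path) / "truth.json") as fh:
        truth = json.load(fh)
    truth["k_oh"] = pd.Series({int(y): v for y, v in truth["k_oh"].items()},
                              name="k_oh")
    return truth
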