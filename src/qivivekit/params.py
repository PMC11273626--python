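"""Loaders for the shipped species/compound parameter files."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from qivivekit.exposure import ExposureScenario
from qivivekit.kinetics import EnzymeKinetics
from qivivekit.pbk import CompoundParams, PBKModel, SpeciesPhysiology, build_pbk
from qivivekit.qivive import RPFTable

__all__ = [
    "data_path",
    "load_physiology",
    "load_compounds",
    "load_model",
    "load_rpf_table",
    "load_scenarios",
]

SPECIES = ("rat", "human")


def data_path(name: str) -> Path:
    """Path of a shipped data file."""
    return Path(str(resources.files("qivivekit").joinpath("data", name)))


def _read_yaml(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_physiology(species: str, path: str | Path | None = None) -> SpeciesPhysiology:
    if path is None:
        if species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        path = data_path(f"physiology_{species}.yaml")
    d = _read_yaml(Path(path))
    return SpeciesPhysiology(
        species=d["species"],
        body_weight=float(d["body_weight"]),
        volume_fractions={k: float(v) for k, v in d["volume_fractions"].items()},
        flow_fractions={k: float(v) for k, v in d["flow_fractions"].items()},
        cardiac_output=float(d["cardiac_output"]),
        gfr=float(d["gfr"]),
    )


def _compound_from_dict(d: dict, species: str, absorption_set: str = "default") -> CompoundParams:
    ka = float(d.get("ka", 0.0))
    fa = float(d.get("fa", 0.0))
    if absorption_set == "alt":
        alt = d.get("absorption_alt")
        if alt is None:
            raise ValueError(f"no alternative absorption set shipped for {d['name']!r}")
        ka, fa = float(alt["ka"]), float(alt["fa"])
    elif absorption_set != "default":
        raise ValueError("absorption_set must be 'default' or 'alt'")
    pathways = [
        EnzymeKinetics(
            vmax_unscaled=float(p["vmax_unscaled"]),
            km=float(p["km"]),
            pathway=p["pathway"],
            species=species,
            vmax_scaled=float(p["vmax_scaled"]),
        )
        for p in d.get("pathways", [])
    ]
    return CompoundParams(
        name=d["name"],
        molar_mass=float(d["molar_mass"]),
        partition={k: float(v) for k, v in d["partition"].items()},
        bpr=float(d["bpr"]),
        fup=float(d["fup"]),
        ka=ka,
        fa=fa,
        kb=float(d.get("kb", 0.0)),
        pathways=pathways,
        clint=float(d.get("clint", 0.0)),
    )


def load_compounds(
    species: str, path: str | Path | None = None, absorption_set: str = "default"
) -> tuple[CompoundParams, CompoundParams]:
    """(parent, metabolite) parameter sets for one species."""
    if path is None:
        if species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        path = data_path(f"compounds_{species}.yaml")
    d = _read_yaml(Path(path))
    parent = _compound_from_dict(d["parent"], species, absorption_set)
    metabolite = _compound_from_dict(d["metabolite"], species)
    return parent, metabolite


def load_model(
    species: str,
    physiology_path: str | Path | None = None,
    compounds_path: str | Path | None = None,
    absorption_set: str = "default",
) -> PBKModel:
    """Assembled PBK model from the shipped (or given) parameter files."""
    physiology = load_physiology(species, physiology_path)
    parent, metabolite = load_compounds(species, compounds_path, absorption_set)
    return build_pbk(physiology, parent, metabolite)


def load_rpf_table(path: str | Path | None = None) -> RPFTable:
    if path is None:
        path = data_path("rpf_bmcl.csv")
    df = pd.read_csv(path, comment="#")
    required = {"endpoint", "bmcl10_parent_uM", "bmcl10_metabolite_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"RPF table missing columns: {sorted(missing)}")
    entries = {}
    for _, row in df.iterrows():
        entries[str(row["endpoint"])] = {
            "bmcl_parent": float(row["bmcl10_parent_uM"]),
            "bmcl_metabolite": float(row["bmcl10_metabolite_uM"]),
            "bmcu_parent": float(row.get("bmcu10_parent_uM", float("nan"))),
            "bmcu_metabolite": float(row.get("bmcu10_metabolite_uM", float("nan"))),
            "rpf_reported": float(row["rpf_reported"]) if "rpf_reported" in row else None,
        }
    return RPFTable(entries=entries)


def load_scenarios(path: str | Path | None = None) -> list[ExposureScenario]:
    if path is None:
        path = data_path("scenarios_fixture.csv")
    df = pd.read_csv(path, comment="#")
    return [
        ExposureScenario(
            product=str(row["product"]),
            category=str(row["category"]),
            content=float(row["content_mg_per_g"]),
            daily_amount=float(row["daily_amount_g"]),
            body_weight=float(row.get("body_weight_kg", 60.0)),
        )
        for _, row in df.iterrows()
    ]
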