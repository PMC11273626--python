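"""File formats, configuration and pipeline orchestration.

All tabular formats are plain CSV with one header line, dot decimal
separator and units encoded in the column names.  Dataset-level metadata
(direction, units, labels) travels in leading ``# key=value`` comment lines.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import qivivekit
from qivivekit import params as _params
from qivivekit.bmd import benchmark_dose
from qivivekit.datasets import DepletionDataset, DoseResponseCurve, KineticDataset
from qivivekit.exposure import compute_edi, margin_of_exposure, summarize_exposure
from qivivekit.kinetics import (
    ScalingFactors,
    clint_from_depletion,
    fit_michaelis_menten,
    scale_clint,
)
from qivivekit.pbk import SimulationOutput, TISSUES, build_pbk
from qivivekit.qivive import ENDPOINT_ORGANS, ReverseDosimetry, convert_curve

__all__ = [
    "load_curve",
    "write_curve",
    "load_kinetic_dataset",
    "write_kinetic_dataset",
    "load_depletion_dataset",
    "write_depletion_dataset",
    "write_simulation",
    "load_config",
    "run_pipeline",
    "PipelineError",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# CSV with '# key=value' metadata header
# ---------------------------------------------------------------------------

def _write_meta_csv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def _read_meta_csv(path: Path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    return df, meta


def write_curve(path: str | Path, curve: DoseResponseCurve) -> None:
    df = pd.DataFrame(
        {
            f"dose_{curve.dose_units}": curve.doses,
            f"response_{curve.response_units}": curve.responses,
            "replicate": curve.replicate,
            "censored": curve.censored.astype(int),
        }
    )
    meta = {
        "direction": curve.direction,
        "dose_units": curve.dose_units,
        "response_units": curve.response_units,
    }
    meta.update({k: v for k, v in curve.meta.items() if np.isscalar(v)})
    _write_meta_csv(Path(path), df, meta)


def load_curve(path: str | Path) -> DoseResponseCurve:
    """Read and validate a dose-response curve CSV.

    Requires dose/response columns (units suffix in the name), non-negative
    doses and a dose-0 control row.
    """
    path = Path(path)
    df, meta = _read_meta_csv(path)
    dose_cols = [c for c in df.columns if c.startswith("dose")]
    resp_cols = [c for c in df.columns if c.startswith("response")]
    if not dose_cols or not resp_cols:
        raise ValueError(f"{path}: need 'dose_<units>' and 'response_<units>' columns")
    dose_col, resp_col = dose_cols[0], resp_cols[0]
    dose_units = meta.get("dose_units") or dose_col.partition("_")[2] or "uM"
    resp_units = meta.get("response_units") or resp_col.partition("_")[2] or "response"
    doses = pd.to_numeric(df[dose_col], errors="coerce")
    responses = pd.to_numeric(df[resp_col], errors="coerce")
    if doses.isna().any() or responses.isna().any():
        raise ValueError(f"{path}: malformed numbers in dose/response columns")
    if (doses < 0).any():
        raise ValueError(f"{path}: negative doses are not allowed")
    censored = (
        df["censored"].astype(bool).to_numpy() if "censored" in df.columns else None
    )
    curve = DoseResponseCurve(
        doses=doses.to_numpy(),
        responses=responses.to_numpy(),
        replicate=df["replicate"].to_numpy() if "replicate" in df.columns else None,
        direction=meta.get("direction", "decreasing"),
        dose_units=dose_units,
        response_units=resp_units,
        censored=censored,
    )
    if not curve.has_control:
        raise ValueError(f"{path}: a dose-0 control row is required")
    return curve


def write_kinetic_dataset(path: str | Path, data: KineticDataset) -> None:
    df = pd.DataFrame(
        {
            "concentration_uM": data.concentrations,
            "velocity_nmol_per_min_per_mg": data.velocities,
            "replicate": data.replicate,
            "series": data.series,
        }
    )
    meta = {
        "protein_source": data.protein_source,
        "species": data.species,
        "pathway": data.pathway,
    }
    _write_meta_csv(Path(path), df, meta)


def load_kinetic_dataset(path: str | Path) -> KineticDataset:
    df, meta = _read_meta_csv(Path(path))
    return KineticDataset(
        concentrations=df["concentration_uM"].to_numpy(),
        velocities=df["velocity_nmol_per_min_per_mg"].to_numpy(),
        replicate=df["replicate"].to_numpy() if "replicate" in df.columns else None,
        series=df["series"].to_numpy() if "series" in df.columns else None,
        protein_source=meta.get("protein_source", "microsomes"),
        species=meta.get("species", "rat"),
        pathway=meta.get("pathway", "rhein_formation"),
    )


def write_depletion_dataset(path: str | Path, data: DepletionDataset) -> None:
    df = pd.DataFrame(
        {
            "time_min": data.times,
            "concentration_uM": data.concentrations,
            "replicate": data.replicate,
            "series": data.series,
        }
    )
    meta = {"cell_density_1e6_per_mL": data.cell_density, "species": data.species}
    _write_meta_csv(Path(path), df, meta)


def load_depletion_dataset(path: str | Path) -> DepletionDataset:
    df, meta = _read_meta_csv(Path(path))
    return DepletionDataset(
        times=df["time_min"].to_numpy(),
        concentrations=df["concentration_uM"].to_numpy(),
        cell_density=float(meta["cell_density_1e6_per_mL"]),
        replicate=df["replicate"].to_numpy() if "replicate" in df.columns else None,
        series=df["series"].to_numpy() if "series" in df.columns else None,
        species=meta.get("species", "rat"),
    )


def write_simulation(path: str | Path, out: SimulationOutput) -> None:
    """Tidy CSV: time, compound, compartment, amount; blood in uM and ug/mL."""
    rows = []
    model = out.model
    for label, name in (("parent", model.parent.name), ("metabolite", model.metabolite.name)):
        off = 1 if label == "parent" else None
        for tissue in TISSUES:
            series = out.tissue_venous_conc(label, tissue)
            amounts = (
                series * model._V[TISSUES.index(tissue)] *
                (model._Pp if label == "parent" else model._Pm)[TISSUES.index(tissue)]
            )
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": out.time,
                        "compound": name,
                        "compartment": tissue,
                        "amount_umol": amounts,
                        "conc_uM": np.nan,
                        "conc_ug_per_mL": np.nan,
                    }
                )
            )
        blood_um = out.blood_conc(label, "uM")
        rows.append(
            pd.DataFrame(
                {
                    "time_h": out.time,
                    "compound": name,
                    "compartment": "blood",
                    "amount_umol": blood_um * model._Vb,
                    "conc_uM": blood_um,
                    "conc_ug_per_mL": out.blood_conc(label, "ug_per_mL"),
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    meta = {
        "species": model.physiology.species,
        "route": out.regimen.route,
        "dose_mg_per_kg": out.regimen.dose,
        "dose_umol": out.dose_umol,
        "unabsorbed_umol": out.unabsorbed_umol,
    }
    _write_meta_csv(Path(path), df, meta)


# ---------------------------------------------------------------------------
# configuration + pipeline
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS = {
    "bmd": {"family": "hill", "bmr": 0.10, "n_boot": 200, "seed": 0},
    "reverse_dosimetry": {"duration": 72.0, "dose_cap": 10_000.0, "rtol": 1e-7, "atol": 1e-9},
}


def load_config(path: str | Path) -> dict:
    """Load and validate a pipeline configuration (YAML or JSON dialect)."""
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return validate_config(config, base_dir=path.parent)


def validate_config(config: dict, base_dir: str | Path = ".") -> dict:
    base = Path(base_dir)
    cfg = dict(config)
    if "species" not in cfg:
        raise ValueError("config: 'species' is required")
    if cfg["species"] not in ("rat", "human"):
        raise ValueError("config: species must be 'rat' or 'human'")
    cfg.setdefault("seed", 0)
    for section, defaults in _CONFIG_DEFAULTS.items():
        merged = dict(defaults)
        merged.update(cfg.get(section, {}))
        cfg[section] = merged
    cfg["bmd"].setdefault("seed", cfg["seed"])
    if "endpoints" not in cfg or not cfg["endpoints"]:
        raise ValueError("config: at least one endpoint with a curve file is required")
    for name, spec in cfg["endpoints"].items():
        if "curve" not in spec:
            raise ValueError(f"config: endpoint {name!r} is missing a 'curve' path")
        curve_path = base / spec["curve"]
        if not curve_path.exists():
            raise ValueError(f"config: curve file for endpoint {name!r} not found: {curve_path}")
        spec["curve"] = str(curve_path)
        spec.setdefault("fbs_percent", 10.0)
        spec.setdefault("organs", list(ENDPOINT_ORGANS.get(name, ("liver",))))
    for key in ("rpf_table", "scenarios", "compounds", "physiology"):
        if key in cfg and cfg[key] is not None:
            p = base / cfg[key]
            if not p.exists():
                raise ValueError(f"config: {key} file not found: {p}")
            cfg[key] = str(p)
    for key in ("microsomes", "depletion"):
        kin = cfg.get("kinetics") or {}
        if key in kin:
            p = base / kin[key]
            if not p.exists():
                raise ValueError(f"config: kinetics.{key} file not found: {p}")
            kin[key] = str(p)
        cfg["kinetics"] = kin
    return cfg


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run fit-kinetics -> PBK -> QIVIVE -> BMD -> exposure comparison.

    Every artifact is written under ``outdir``; a provenance log records the
    config hash, seed and package version.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = config["species"]
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config["seed"],
        "version": qivivekit.__version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    report: dict = {"species": species, "endpoints": {}, "exposure": None}

    # stage 1: in-vitro kinetics (optional refit of model parameters)
    physiology = _params.load_physiology(species, config.get("physiology"))
    parent, metabolite = _params.load_compounds(species, config.get("compounds"))
    try:
        kin = config.get("kinetics") or {}
        fitted = {}
        scaling = ScalingFactors.for_species(species, liver_mass_g=physiology.liver_mass_g)
        if "microsomes" in kin:
            data = load_kinetic_dataset(kin["microsomes"])
            ek = fit_michaelis_menten(data).scaled(
                scaling.protein_content(data.protein_source), scaling.liver_mass_g
            )
            fitted["conversion"] = ek
            parent.pathways = [p for p in parent.pathways if p.pathway != ek.pathway] + [ek]
        if "depletion" in kin:
            data = load_depletion_dataset(kin["depletion"])
            ce = clint_from_depletion(data)
            ce.clint_invivo = scale_clint(
                ce.clint_invitro, scaling.hepatocellularity, scaling.liver_mass_g / 1000.0
            )
            fitted["clearance"] = ce
            metabolite.clint = ce.clint_invivo
        if fitted:
            with open(outdir / "kinetic_fits.json", "w") as fh:
                json.dump(
                    {
                        k: (v.__dict__ if not hasattr(v, "params") else v)
                        for k, v in fitted.items()
                    },
                    fh,
                    indent=2,
                    default=lambda o: float(o) if np.isscalar(o) else str(o),
                )
        provenance["stages"].append("fit-kinetics")
    except Exception as exc:
        raise PipelineError(f"stage fit-kinetics failed: {exc}") from exc

    # stage 2: PBK model
    try:
        model = build_pbk(physiology, parent, metabolite)
        provenance["stages"].append("build-pbk")
    except Exception as exc:
        raise PipelineError(f"stage build-pbk failed: {exc}") from exc

    # stage 3+4: QIVIVE conversion and BMD per endpoint/organ
    rpf_table = _params.load_rpf_table(config.get("rpf_table"))
    bmd_cfg = config["bmd"]
    rd_cfg = config["reverse_dosimetry"]
    for endpoint, spec in config["endpoints"].items():
        try:
            curve = load_curve(spec["curve"])
            report["endpoints"][endpoint] = {}
            for organ in spec["organs"]:
                rd = ReverseDosimetry(
                    model,
                    rpf_table,
                    endpoint,
                    organ=organ,
                    duration=rd_cfg["duration"],
                    dose_cap=rd_cfg["dose_cap"],
                    rtol=rd_cfg["rtol"],
                    atol=rd_cfg["atol"],
                )
                invivo = convert_curve(curve, spec["fbs_percent"], rd)
                write_curve(outdir / f"invivo_{endpoint}_{organ}.csv", invivo)
                result = benchmark_dose(
                    invivo,
                    family=bmd_cfg["family"],
                    bmr=bmd_cfg["bmr"],
                    n_boot=bmd_cfg["n_boot"],
                    seed=bmd_cfg["seed"],
                )
                with open(outdir / f"bmd_{endpoint}_{organ}.json", "w") as fh:
                    json.dump(result.to_dict(), fh, indent=2)
                report["endpoints"][endpoint][organ] = result.to_dict()
        except Exception as exc:
            raise PipelineError(f"stage qivive/bmd failed for endpoint {endpoint!r}: {exc}") from exc
    provenance["stages"].append("qivive-bmd")

    # stage 5: exposure comparison
    try:
        scenarios = _params.load_scenarios(config.get("scenarios"))
        summary = summarize_exposure(scenarios)
        margins = {}
        for endpoint, organs in report["endpoints"].items():
            for organ, res in organs.items():
                margins[f"{endpoint}_{organ}"] = margin_of_exposure(res["bmdl"], summary.p95)
        exposure_rows = pd.DataFrame(
            {
                "product": [s.product for s in scenarios],
                "category": [s.category for s in scenarios],
                "edi_mg_per_kg_per_day": [compute_edi(s) for s in scenarios],
            }
        )
        exposure_rows.to_csv(outdir / "exposure_edi.csv", index=False)
        report["exposure"] = {
            "geometric_mean": summary.geometric_mean,
            "p95": summary.p95,
            "range": list(summary.range),
            "margins_vs_p95": margins,
        }
        provenance["stages"].append("exposure")
    except Exception as exc:
        raise PipelineError(f"stage exposure failed: {exc}") from exc

    report["provenance"] = provenance
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("pipeline finished: %s", outdir / "report.json")
    return report
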