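"""Configuration files, fixtures, scenario runner and CSV round-tripping.

Drug models, regimens and scenarios are plain YAML with a strict schema:
unknown keys are rejected and declared units must match the package's fixed
unit system (time h, amounts mg, volumes L, clearances L/h, concentrations
ng/mL), so a file written for another convention fails loudly instead of
silently mis-scaling.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import pandas as pd
import yaml

from .drugs import DrugModel
from .pk import ConcentrationProfile, Regimen, nca, simulate

__all__ = [
    "SchemaError",
    "load_drug_model",
    "save_drug_model",
    "load_builtin_drug",
    "builtin_regimen",
    "load_regimen",
    "load_genotype_clearances",
    "write_profile_csv",
    "read_profile_csv",
    "run_scenario",
    "write_bundle",
]

log = logging.getLogger("sippk")

PathLike = Union[str, Path]

EXPECTED_UNITS = {
    "ka": "1/h",
    "v": "L/kg",
    "cl": "L/h",
    "body_weight": "kg",
    "mw": "g/mol",
    "ki": "uM",
}

_DRUG_TOP_KEYS = {"name", "mw", "parameters", "units", "fm", "ki"}
_DRUG_PARAM_KEYS = {"ka", "v", "cl", "fu", "fa", "fg", "body_weight", "blood_to_plasma"}


class SchemaError(ValueError):
    """A configuration file violates the expected schema."""


def _data_root():
    return importlib.resources.files("sippk") / "data"


def _check_units(units: Mapping[str, str], source: str) -> None:
    for field_name, unit in units.items():
        expected = EXPECTED_UNITS.get(field_name)
        if expected is None:
            raise SchemaError(f"{source}: unit declared for unknown field {field_name!r}")
        if unit != expected:
            raise SchemaError(
                f"{source}: field {field_name!r} declares unit {unit!r}; "
                f"this package works in {expected!r}"
            )


def _parse_drug(doc: dict, source: str) -> DrugModel:
    if not isinstance(doc, dict):
        raise SchemaError(f"{source}: drug model must be a mapping")
    unknown = set(doc) - _DRUG_TOP_KEYS
    if unknown:
        raise SchemaError(f"{source}: unknown keys {sorted(unknown)}")
    for required in ("name", "mw", "parameters"):
        if required not in doc:
            raise SchemaError(f"{source}: missing required key {required!r}")
    params = doc["parameters"]
    unknown = set(params) - _DRUG_PARAM_KEYS
    if unknown:
        raise SchemaError(f"{source}: unknown parameters {sorted(unknown)}")
    _check_units(doc.get("units", {}), source)
    try:
        return DrugModel(
            name=str(doc["name"]),
            mw=float(doc["mw"]),
            fm={str(k): float(v) for k, v in (doc.get("fm") or {}).items()},
            ki={str(k): float(v) for k, v in (doc.get("ki") or {}).items()},
            **{k: float(v) for k, v in params.items()},
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{source}: {exc}") from exc


def load_drug_model(path: PathLike) -> DrugModel:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_drug(doc, str(path))


def load_builtin_drug(name: str) -> DrugModel:
    resource = _data_root() / f"{name}.yaml"
    if not resource.is_file():
        raise FileNotFoundError(f"no builtin drug model named {name!r}")
    doc = yaml.safe_load(resource.read_text())
    return _parse_drug(doc, f"builtin:{name}")


def save_drug_model(model: DrugModel, path: PathLike) -> None:
    doc = {
        "name": model.name,
        "mw": model.mw,
        "parameters": {
            "ka": model.ka,
            "v": model.v,
            "cl": model.cl,
            "fu": model.fu,
            "fa": model.fa,
            "fg": model.fg,
            "body_weight": model.body_weight,
            "blood_to_plasma": model.blood_to_plasma,
        },
        "units": {"ka": "1/h", "v": "L/kg", "cl": "L/h", "body_weight": "kg",
                  "mw": "g/mol", "ki": "uM"},
        "fm": dict(model.fm),
        "ki": dict(model.ki),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# regimens
# ---------------------------------------------------------------------------


def _parse_dose_block(block: dict, source: str) -> Regimen:
    pattern = block.get("pattern")
    if pattern == "single":
        return Regimen.single(float(block["amount_mg"]), float(block.get("time_h", 0.0)))
    if pattern == "qd":
        return Regimen.qd(
            float(block["amount_mg"]), int(block["n_days"]), float(block.get("start_h", 0.0))
        )
    if pattern == "bid":
        return Regimen.bid(
            float(block["amount_mg"]), int(block["n_days"]), float(block.get("start_h", 0.0))
        )
    raise SchemaError(f"{source}: unknown dose pattern {pattern!r}")


def _parse_regimen(doc: dict, source: str) -> Regimen:
    if isinstance(doc, dict) and "pattern" in doc:
        return _parse_dose_block(doc, source)
    if not isinstance(doc, dict) or "doses" not in doc:
        raise SchemaError(f"{source}: regimen file needs a 'doses' list or a dose block")
    blocks = doc["doses"]
    regimen = _parse_dose_block(blocks[0], source)
    for block in blocks[1:]:
        regimen = regimen + _parse_dose_block(block, source)
    return regimen


def load_regimen(path: PathLike) -> Regimen:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_regimen(doc, str(path))


def builtin_regimen(name: str) -> Regimen:
    resource = _data_root() / "regimens" / f"{name}.yaml"
    if not resource.is_file():
        raise FileNotFoundError(f"no builtin regimen named {name!r}")
    return _parse_regimen(yaml.safe_load(resource.read_text()), f"builtin:{name}")


def load_genotype_clearances() -> pd.Series:
    """Per-genotype apparent oral clearances (L/h) shipped as a fixture."""
    resource = _data_root() / "genotype_clf.csv"
    df = pd.read_csv(resource.open())  # type: ignore[arg-type]
    return df.set_index("genotype")["cl_f_l_per_h"]


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def write_profile_csv(profile: ConcentrationProfile, path: PathLike) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_profile_csv(path: PathLike) -> ConcentrationProfile:
    df = pd.read_csv(path)
    for col in ("time_h", "conc_ng_per_ml"):
        if col not in df.columns:
            raise SchemaError(f"{path}: profile CSV missing column {col!r}")
    meta_cols = [c for c in df.columns if c not in ("time_h", "conc_ng_per_ml")]
    metadata = {c: df[c].iloc[0] for c in meta_cols}
    return ConcentrationProfile(
        df["time_h"].to_numpy(), df["conc_ng_per_ml"].to_numpy(), metadata
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _resolve_drug(ref, base_dir: Path, source: str) -> DrugModel:
    if isinstance(ref, dict):
        return _parse_drug(ref, source)
    candidate = base_dir / str(ref)
    if candidate.is_file():
        return load_drug_model(candidate)
    return load_builtin_drug(str(ref))


def run_scenario(config_path: PathLike, seed: Optional[int] = None) -> Dict:
    """Execute one simulation scenario described by a YAML config.

    The bundle returned carries the profile, its NCA summary, the optional
    population table and a provenance block (package version, seed, config
    hash) sufficient to reproduce the run bit-for-bit.
    """
    from . import __version__

    config_path = Path(config_path)
    text = config_path.read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"{config_path}: scenario must be a mapping")
    unknown = set(doc) - {"name", "drug", "override", "regimen", "seed", "grid", "population"}
    if unknown:
        raise SchemaError(f"{config_path}: unknown keys {sorted(unknown)}")

    model = _resolve_drug(doc["drug"], config_path.parent, str(config_path))
    for param, value in (doc.get("override") or {}).items():
        if param not in ("cl", "ka", "v"):
            raise SchemaError(f"{config_path}: cannot override {param!r}")
        from dataclasses import replace

        model = replace(model, **{param: float(value)})

    regimen_ref = doc["regimen"]
    if isinstance(regimen_ref, (dict,)):
        regimen = _parse_regimen(regimen_ref, str(config_path))
    else:
        reg_path = config_path.parent / str(regimen_ref)
        regimen = load_regimen(reg_path) if reg_path.is_file() else builtin_regimen(str(regimen_ref))

    grid_cfg = doc.get("grid") or {}
    dt = float(grid_cfg.get("dt_h", 0.25))
    n_half = float(grid_cfg.get("n_half_lives", 10.0))
    run_seed = int(seed if seed is not None else doc.get("seed", 0))

    log.info("scenario %s: drug=%s config_sha=%s", doc.get("name"), model.name,
             _sha256(text)[:12])
    profile = simulate(model, regimen, dt=dt, n_half_lives=n_half,
                       metadata={"scenario": doc.get("name", config_path.stem)})
    summary = nca(profile)
    bundle: Dict = {
        "name": doc.get("name", config_path.stem),
        "profile": profile,
        "nca": summary,
        "provenance": {
            "package_version": __version__,
            "seed": run_seed,
            "config_sha256": _sha256(text),
            "drug": model.name,
        },
    }

    pop_cfg = doc.get("population")
    if pop_cfg:
        from .population import PopulationSpec, run_population, summarize

        spec = PopulationSpec(
            n=int(pop_cfg["n"]), cv={"cl": float(pop_cfg.get("cv_cl", 0.5))}, seed=run_seed
        )
        table = run_population(model, regimen, spec, dt=dt, n_half_lives=n_half)
        bundle["population"] = table
        bundle["population_summary"] = {
            metric: summarize(table[metric].to_numpy())
            for metric in ("auc_last", "auc_inf", "cmax")
        }
    return bundle


def write_bundle(bundle: Dict, out_dir: PathLike) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_profile_csv(bundle["profile"], out / "profile.csv")
    nca_summary = bundle["nca"]
    pd.DataFrame([vars(nca_summary)]).to_csv(out / "nca.csv", index=False)
    if "population" in bundle:
        bundle["population"].to_csv(out / "population.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle["provenance"], fh, indent=2)
    log.info("bundle %s written to %s", bundle["name"], out)
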