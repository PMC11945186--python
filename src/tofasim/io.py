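"""Configuration schema and tabular I/O.

Run configurations are human-editable YAML (JSON is a YAML subset and is
accepted interchangeably) with a versioned ``schema`` key; unknown keys are
rejected with an explicit message.  Observed concentration tables are CSV
with columns ``study_id, time_h, conc_ng_ml`` (plus an optional ``arm``);
concentrations may be numeric or the string ``BLQ`` for values below the
quantification limit.  All concentrations at the I/O boundary are ng/mL.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .compound import FORMULATIONS, CompoundModel, Formulation, tofacitinib
from .engine import DosingRegimen, FAST_SOLVER, DEFAULT_SOLVER, SolverSettings
from .physiology import PopulationSpec

__all__ = [
    "RunConfig",
    "load_config",
    "read_observed_csv",
    "write_profile_csv",
    "write_json_report",
]

SCHEMA_VERSION = 1

_TOP_LEVEL_KEYS = {
    "schema", "compound", "formulation", "regimen", "population",
    "impairment", "perpetrator", "solver", "seed", "output_dir", "fast",
}
_REGIMEN_KEYS = {"dose_mg", "schedule", "n_doses", "route"}
_POPULATION_KEYS = {"n", "age_range", "female_fraction", "variability"}
_IMPAIRMENT_KEYS = {"hepatic", "renal"}
_SOLVER_KEYS = {"method", "rtol", "atol", "output_dt"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _reject_unknown(block: Mapping[str, Any], allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


@dataclass
class RunConfig:
    """Validated run configuration."""

    compound: CompoundModel
    formulation: Formulation
    regimen: DosingRegimen
    population: Optional[PopulationSpec] = None
    impairment: Dict[str, str] = field(default_factory=dict)
    perpetrator: Optional[str] = None
    solver: SolverSettings = DEFAULT_SOLVER
    seed: int = 0
    output_dir: Path = Path(".")


def load_config(path: str | Path, fast: bool = False) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    _reject_unknown(raw, _TOP_LEVEL_KEYS, str(path))
    if raw.get("schema", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema version {raw.get('schema')!r}")

    compound = tofacitinib()
    comp_block = raw.get("compound", {})
    valid_fields = set(CompoundModel.__dataclass_fields__)
    _reject_unknown(comp_block, valid_fields, "compound block")
    if comp_block:
        compound = compound.with_params(**comp_block)

    form_block = raw.get("formulation", "IR")
    if isinstance(form_block, str):
        if form_block not in FORMULATIONS:
            raise ConfigError(
                f"unknown formulation {form_block!r}; known: {sorted(FORMULATIONS)}"
            )
        formulation = FORMULATIONS[form_block]
    else:
        _reject_unknown(form_block, {"kind", "t50", "shape"}, "formulation block")
        formulation = Formulation(**form_block)

    reg_block = dict(raw.get("regimen", {}))
    _reject_unknown(reg_block, _REGIMEN_KEYS, "regimen block")
    reg_block.setdefault("dose_mg", 5.0)
    regimen = DosingRegimen(formulation=formulation, **reg_block)

    population = None
    if "population" in raw:
        pop_block = dict(raw["population"])
        _reject_unknown(pop_block, _POPULATION_KEYS, "population block")
        if "age_range" in pop_block:
            pop_block["age_range"] = tuple(pop_block["age_range"])
        pop_block.setdefault("n", 200)
        if fast:
            pop_block["n"] = min(pop_block["n"], 100)
        population = PopulationSpec(seed=int(raw.get("seed", 0)), **pop_block)

    impairment = dict(raw.get("impairment", {}))
    _reject_unknown(impairment, _IMPAIRMENT_KEYS, "impairment block")

    solver = FAST_SOLVER if fast else DEFAULT_SOLVER
    if "solver" in raw:
        sol_block = dict(raw["solver"])
        _reject_unknown(sol_block, _SOLVER_KEYS, "solver block")
        solver = SolverSettings(**{**solver.__dict__, **sol_block})

    return RunConfig(
        compound=compound,
        formulation=formulation,
        regimen=regimen,
        population=population,
        impairment=impairment,
        perpetrator=raw.get("perpetrator"),
        solver=solver,
        seed=int(raw.get("seed", 0)),
        output_dir=Path(raw.get("output_dir", ".")),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_observed_csv(path: str | Path) -> pd.DataFrame:
    """Read an observed concentration table.

    Returns a frame with ``study_id, arm, time_h, conc_ng_ml, censored``;
    BLQ rows carry ``conc_ng_ml = NaN`` and ``censored = True``.  Raises on
    missing columns or non-monotone times within an arm, naming the row.
    """
    df = pd.read_csv(path, dtype={"conc_ng_ml": str})
    required = {"study_id", "time_h", "conc_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "arm" not in df.columns:
        df["arm"] = ""
    times = pd.to_numeric(df["time_h"], errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax())
        raise ValueError(f"{path}: non-numeric time at row {row + 2}")
    df["time_h"] = times
    raw = df["conc_ng_ml"].str.strip()
    censored = raw.str.upper() == "BLQ"
    conc = pd.to_numeric(raw.where(~censored), errors="coerce")
    bad = conc.isna() & ~censored
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{path}: concentration at row {row + 2} is neither numeric nor 'BLQ'"
        )
    df["conc_ng_ml"] = conc
    df["censored"] = censored
    for (study, arm), sub in df.groupby(["study_id", "arm"], sort=False):
        dt = np.diff(sub["time_h"].to_numpy())
        if np.any(dt <= 0):
            k = int(np.argmax(dt <= 0))
            row = int(sub.index[k + 1])
            raise ValueError(
                f"{path}: non-monotone times within arm {study!r}/{arm!r} "
                f"at row {row + 2}"
            )
    return df[["study_id", "arm", "time_h", "conc_ng_ml", "censored"]]


def write_observed_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observed table (inverse of :func:`read_observed_csv`)."""
    out = df.copy()
    if "censored" in out.columns:
        conc = out["conc_ng_ml"].astype(object)
        conc[out["censored"]] = "BLQ"
        out["conc_ng_ml"] = conc
        out = out.drop(columns=["censored"])
    out.to_csv(path, index=False, float_format="%.10g")


def write_profile_csv(result, path: str | Path) -> None:
    """Write a simulated profile as time_h, conc_ng_ml."""
    pd.DataFrame(
        {"time_h": result.time, "conc_ng_ml": result.plasma_conc}
    ).to_csv(path, index=False, float_format="%.10g")


def _round_floats(obj: Any) -> Any:
    """Round all floats to 10 significant digits for reproducible reports."""
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json_report(payload: Mapping[str, Any], path: str | Path) -> None:
    """Deterministic JSON output (floats fixed to 10 significant digits)."""
    Path(path).write_text(json.dumps(_round_floats(dict(payload)), indent=2) + "\n")
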