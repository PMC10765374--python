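"""Configuration, CSV/JSON file exchange and provenance stamping.

CSV dialect: comma-separated, period decimal, UTF-8, mandatory header.
Writers prepend a ``#``-prefixed provenance block (package version, config
hash, seed, optional timestamp) which pandas readers skip via
``comment='#'``.  Configs are TOML or JSON and validate through pydantic,
so every failure names the offending field.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .core import Direction, ParameterError, PhospholipidSpecies, ProteinLigand
from .datasets import membrane_preset, protein_preset
from .fitting import ActivityDataset, FitResult
from .isotherm import (
    MW_CHOLESTEROL,
    MW_PHOSPHOLIPID,
    Isotherm,
    wt_percent_to_mol_percent,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "read_activity_csv",
    "write_activity_csv",
    "write_isotherm_csv",
    "write_fit_json",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class _LipidCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    k_assoc: float = Field(gt=0)
    r: int = Field(ge=1)
    amount: float = Field(ge=0)


class _MembraneCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Optional[str] = None
    lipids: Optional[List[_LipidCfg]] = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.preset is None) == (self.lipids is None):
            raise ValueError(
                "membrane: exactly one of 'preset' or 'lipids' must be given"
            )
        return self


class _ProteinCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Optional[str] = None
    name: str = "protein"
    k_subunit: Optional[float] = Field(default=None, gt=0)
    n: int = Field(default=1, ge=1)
    amount: float = Field(default=1e-3, ge=0)
    direction: Literal["increasing", "decreasing"] = "increasing"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.preset is None) == (self.k_subunit is None):
            raise ValueError(
                "protein: exactly one of 'preset' or 'k_subunit' must be given"
            )
        return self


class _GridCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: float = Field(default=0.0, ge=0, lt=100)
    stop: float = Field(default=60.0, gt=0, lt=100)
    count: int = Field(default=121, ge=2)


class _FitCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_values: List[int] = Field(default_factory=lambda: [1, 2, 3, 4, 5])
    fit_baseline: bool = True
    log10_k_bounds: Tuple[float, float] = (-2.0, 16.0)


class _NoiseCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    model: Literal["none", "additive", "multiplicative"] = "multiplicative"
    sd: float = Field(default=0.02, ge=0)
    n_points: int = Field(default=12, ge=3)
    baseline: float = 0.0
    amplitude: float = 1.0


class RunConfig(BaseModel):
    """Validated run description for the command-line pipeline."""

    model_config = ConfigDict(extra="forbid")
    membrane: _MembraneCfg
    protein: Optional[_ProteinCfg] = None
    grid: _GridCfg = Field(default_factory=_GridCfg)
    fit: _FitCfg = Field(default_factory=_FitCfg)
    noise: _NoiseCfg = Field(default_factory=_NoiseCfg)
    seed: Optional[int] = None
    temperature_k: float = Field(default=298.0, gt=0)

    @model_validator(mode="after")
    def _seed_when_stochastic(self):
        if self.noise.model != "none" and self.noise.sd > 0 and self.seed is None:
            raise ValueError("seed: required whenever a stochastic noise model is active")
        return self

    def resolve_lipids(self) -> Tuple[PhospholipidSpecies, ...]:
        if self.membrane.preset is not None:
            return membrane_preset(self.membrane.preset)
        return tuple(
            PhospholipidSpecies(c.name, c.k_assoc, c.r, c.amount)
            for c in self.membrane.lipids
        )

    def resolve_protein(self) -> Optional[ProteinLigand]:
        if self.protein is None:
            return None
        if self.protein.preset is not None:
            return protein_preset(self.protein.preset)
        return ProteinLigand(
            self.protein.name,
            self.protein.k_subunit,
            self.protein.n,
            self.protein.amount,
            self.protein.direction,
        )

    def config_hash(self) -> str:
        digest = hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        )
        return digest.hexdigest()[:12]


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
        else:
            raw = tomllib.loads(path.read_text())
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "(root)"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError(f"invalid config {path}: " + "; ".join(lines)) from exc


def _provenance_lines(
    config_hash: str = "", seed: Optional[int] = None, timestamp: bool = True
) -> List[str]:
    lines = [f"# sterolbind {__version__}"]
    if config_hash:
        lines.append(f"# config_hash: {config_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if timestamp:
        lines.append(f"# written: {datetime.now(timezone.utc).isoformat()}")
    return lines


def read_activity_csv(
    path: Union[str, Path],
    units: str = "mol_percent",
    direction: Union[Direction, str] = Direction.INCREASING,
    mw_chol: float = MW_CHOLESTEROL,
    mw_pl: float = MW_PHOSPHOLIPID,
    name: str = "",
) -> ActivityDataset:
    """Read a two-column (cholesterol, activity) CSV into a dataset.

    ``units="wt_percent"`` converts the cholesterol column to mol % using
    the supplied molecular weights.  Non-numeric cells are reported with
    their row numbers; duplicate abscissae are rejected.
    """
    path = Path(path)
    if units not in ("mol_percent", "wt_percent"):
        raise ParameterError(f"units must be 'mol_percent' or 'wt_percent', got {units!r}")
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParameterError(f"{path}: file is empty or has no header row") from None
    cols = {c.strip().lower(): c for c in frame.columns}
    if "cholesterol" not in cols or "activity" not in cols:
        raise ParameterError(
            f"{path}: need columns 'cholesterol' and 'activity', found {list(frame.columns)}"
        )
    chol = pd.to_numeric(frame[cols["cholesterol"]], errors="coerce")
    act = pd.to_numeric(frame[cols["activity"]], errors="coerce")
    bad = frame.index[chol.isna() | act.isna()].tolist()
    if bad:
        rows = ", ".join(str(i + 2) for i in bad)  # header is line 1
        raise ParameterError(f"{path}: non-numeric or missing cells at file line(s) {rows}")
    chol_vals = chol.to_numpy(dtype=float)
    if units == "wt_percent":
        chol_vals = np.array(
            [wt_percent_to_mol_percent(w, mw_chol, mw_pl) for w in chol_vals]
        )
    return ActivityDataset(
        mol_percent=tuple(chol_vals),
        activity=tuple(act.to_numpy(dtype=float)),
        direction=direction,
        name=name or path.stem,
        provenance={"source": str(path), "units": units},
    )


def write_activity_csv(
    dataset: ActivityDataset,
    path: Union[str, Path],
    config_hash: str = "",
    seed: Optional[int] = None,
    timestamp: bool = True,
) -> None:
    path = Path(path)
    lines = _provenance_lines(config_hash, seed, timestamp)
    body = dataset.to_frame().to_csv(index=False, float_format="%.12g")
    path.write_text("\n".join(lines) + "\n" + body)


def write_isotherm_csv(
    iso: Isotherm,
    path: Union[str, Path],
    config_hash: str = "",
    seed: Optional[int] = None,
    timestamp: bool = True,
) -> None:
    """Write an isotherm in the standard column order with provenance."""
    path = Path(path)
    cols = ["mol_percent", "occupancy", "frac_free_chol", "free_per_phospholipid"]
    cols += [f"bound_frac_{sp.name}" for sp in iso.lipids]
    lines = _provenance_lines(config_hash, seed, timestamp)
    body = iso.table[cols].to_csv(index=False, float_format="%.12g")
    path.write_text("\n".join(lines) + "\n" + body)


def write_fit_json(
    result: Union[FitResult, Sequence[FitResult]],
    path: Union[str, Path],
    config_hash: str = "",
    seed: Optional[int] = None,
    timestamp: bool = True,
) -> None:
    """Write one fit (or a ranked stoichiometry scan) as full-precision JSON."""
    path = Path(path)
    if isinstance(result, FitResult):
        payload = result.to_dict()
    else:
        payload = [r.to_dict() for r in result]
    doc = {
        "sterolbind_version": __version__,
        "config_hash": config_hash or None,
        "seed": seed,
        "result": payload,
    }
    if timestamp:
        doc["written"] = datetime.now(timezone.utc).isoformat()
    path.write_text(json.dumps(doc, indent=2) + "\n")
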