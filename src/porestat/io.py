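"""Configuration and tabular I/O.

All unit conversion lives here: files speak the lab dialect (mV, pA, mM,
Å), everything past this boundary is SI plus kT.  Config files are TOML
with sections ``energy``, ``sites``, ``bath`` and ``geometry``; an empty
file yields the canonical default parameter set (the fitted site potentials,
Uc = 10 kT, nf = -2.5, the homology-model geometry).  Unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from importlib import resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CONCENTRATION_CLAMP, DEFAULT_SOLVENT_MOLARITY, DEFAULT_TEMPERATURE
from .ensemble import BathState, EnergyParams, SiteParams
from .transport import PoreGeometry

__all__ = [
    "ConfigError",
    "MissingConfigFileError",
    "UnknownConfigKeyError",
    "ConfigValueError",
    "TableSchemaError",
    "RunConfig",
    "ExperimentTable",
    "default_config",
    "load_config",
    "save_config",
    "read_table",
    "write_table",
    "TABLE_SCHEMAS",
]

log = logging.getLogger("porestat")


class ConfigError(Exception):
    """Base class for configuration problems."""

    code = 1


class MissingConfigFileError(ConfigError):
    code = 2


class UnknownConfigKeyError(ConfigError):
    code = 3


class ConfigValueError(ConfigError):
    code = 4


class TableSchemaError(ValueError):
    """A tabular file does not match its declared schema."""


@dataclass
class RunConfig:
    """Validated run parameters: energetics, site properties, bath
    conditions, geometry and the global seed."""

    energy: EnergyParams = field(default_factory=EnergyParams)
    sites: SiteParams = field(default_factory=SiteParams)
    bath_c: float = 0.14
    cw: float = DEFAULT_SOLVENT_MOLARITY
    T: float = DEFAULT_TEMPERATURE
    clamp: float = CONCENTRATION_CLAMP
    geometry: PoreGeometry = field(default_factory=PoreGeometry)
    seed: int = 0

    def bath(self, c: float | None = None) -> BathState:
        return BathState(self.bath_c if c is None else c, cw=self.cw, T=self.T)


_KNOWN_KEYS = {
    "energy": {"Uc", "nf", "z"},
    "sites": {"dmu", "D"},
    "bath": {"c", "cw", "T", "clamp"},
    "geometry": {"radius", "length", "area", "volume", "Lc"},
}
_KNOWN_TOP = set(_KNOWN_KEYS) | {"seed"}


def _check_keys(section: str, table: dict) -> None:
    unknown = set(table) - _KNOWN_KEYS[section]
    if unknown:
        raise UnknownConfigKeyError(
            f"unknown key(s) {sorted(unknown)} in [{section}]"
        )


def default_config() -> RunConfig:
    """The packaged canonical parameter set (fitted site potentials,
    Uc = 10 kT, nf = -2.5, homology-model geometry)."""
    with resources.as_file(
        resources.files("porestat.data") / "default_params.toml"
    ) as p:
        return load_config(p)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML parameter file; defaults fill absent keys."""
    path = Path(path)
    if not path.exists():
        raise MissingConfigFileError(f"config file not found: {path}")
    raw_bytes = path.read_bytes()
    log.debug("loading config %s (sha256 %s)", path, hashlib.sha256(raw_bytes).hexdigest()[:12])
    try:
        raw = tomllib.loads(raw_bytes.decode())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigValueError(f"cannot parse {path}: {exc}") from exc
    unknown = set(raw) - _KNOWN_TOP
    if unknown:
        raise UnknownConfigKeyError(f"unknown top-level key(s) {sorted(unknown)}")
    cfg = RunConfig()
    try:
        if "energy" in raw:
            _check_keys("energy", raw["energy"])
            d = {"Uc": cfg.energy.Uc, "nf": cfg.energy.nf, "z": cfg.energy.z}
            d.update(raw["energy"])
            cfg.energy = EnergyParams(**d)
        if "sites" in raw:
            _check_keys("sites", raw["sites"])
            d = {"dmu": cfg.sites.dmu, "D": cfg.sites.D}
            d.update(raw["sites"])
            if np.isscalar(d["D"]):
                d["D"] = (float(d["D"]),) * len(d["dmu"])
            cfg.sites = SiteParams(dmu=tuple(d["dmu"]), D=tuple(d["D"]))
        if "bath" in raw:
            _check_keys("bath", raw["bath"])
            b = raw["bath"]
            cfg.bath_c = float(b.get("c", cfg.bath_c))
            cfg.cw = float(b.get("cw", cfg.cw))
            cfg.T = float(b.get("T", cfg.T))
            cfg.clamp = float(b.get("clamp", cfg.clamp))
            if cfg.bath_c <= 0 or cfg.cw <= 0 or cfg.T <= 0 or cfg.clamp <= 0:
                raise ConfigValueError("bath parameters must be positive")
            BathState(cfg.bath_c, cw=cfg.cw, T=cfg.T)  # range check
        if "geometry" in raw:
            _check_keys("geometry", raw["geometry"])
            g = raw["geometry"]
            base = cfg.geometry
            cfg.geometry = PoreGeometry(
                radius=tuple(g.get("radius", base.radius)),
                length=tuple(g.get("length", base.length)),
                area=tuple(g.get("area", base.area)),
                volume=tuple(g.get("volume", base.volume)),
                Lc=float(g.get("Lc", base.Lc)),
            )
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigValueError(str(exc)) from exc
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return repr(float(v))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as TOML; ``load_config(save_config(c)) == c``."""
    lines = [
        f"seed = {int(cfg.seed)}",
        "",
        "[energy]",
        f"Uc = {_toml_value(cfg.energy.Uc)}",
        f"nf = {_toml_value(cfg.energy.nf)}",
        f"z = {_toml_value(cfg.energy.z)}",
        "",
        "[sites]",
        f"dmu = {_toml_value(cfg.sites.dmu)}",
        f"D = {_toml_value(cfg.sites.D)}",
        "",
        "[bath]",
        f"c = {_toml_value(cfg.bath_c)}",
        f"cw = {_toml_value(cfg.cw)}",
        f"T = {_toml_value(cfg.T)}",
        f"clamp = {_toml_value(cfg.clamp)}",
        "",
        "[geometry]",
        f"radius = {_toml_value(cfg.geometry.radius)}",
        f"length = {_toml_value(cfg.geometry.length)}",
        f"area = {_toml_value(cfg.geometry.area)}",
        f"volume = {_toml_value(cfg.geometry.volume)}",
        f"Lc = {_toml_value(cfg.geometry.Lc)}",
        "",
    ]
    Path(path).write_text("\n".join(lines))


# file column -> (internal column, scale factor file->internal)
TABLE_SCHEMAS: dict[str, dict[str, tuple[str, float]]] = {
    "iv": {
        "voltage_mV": ("voltage", 1e-3),
        "current_pA": ("current", 1e-12),
        "bath_L_M": ("bath_c_L", 1.0),
        "bath_R_M": ("bath_c_R", 1.0),
    },
    "occupancy": {
        "site": ("site", 1.0),
        "occupancy": ("mean_occupancy", 1.0),
        "se": ("se", 1.0),
        "bath_M": ("bath_c", 1.0),
    },
    "wholecell": {
        "bath_Na_mM": ("bath_Na", 1e-3),
        "pipette_Na_mM": ("pipette_Na", 1e-3),
        "voltage_mV": ("voltage", 1e-3),
        "normalized_current": ("normalized_current", 1.0),
        "sem": ("sem", 1.0),
    },
}


@dataclass
class ExperimentTable:
    """A typed experimental table in internal (SI) units."""

    schema: str
    df: pd.DataFrame


def read_table(path: str | Path, schema: str) -> ExperimentTable:
    """Read a CSV against a declared schema, converting units inward.

    A header-only file is an empty table, not an error; a missing column or
    a non-numeric cell raises :class:`TableSchemaError` naming the row and
    column.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; one of {sorted(TABLE_SCHEMAS)}")
    mapping = TABLE_SCHEMAS[schema]
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = set(mapping) - set(raw.columns)
    if missing:
        raise TableSchemaError(
            f"{path}: missing column(s) {sorted(missing)} for schema {schema!r}"
        )
    out = {}
    for file_col, (name, scale) in mapping.items():
        vals = pd.to_numeric(raw[file_col], errors="coerce")
        bad = vals.isna() & raw[file_col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableSchemaError(
                f"{path}: non-numeric value {raw[file_col][row]!r} "
                f"in column {file_col!r}, row {row}"
            )
        out[name] = vals * scale
    df = pd.DataFrame(out)
    if schema == "occupancy" and len(df):
        df["site"] = df["site"].astype(int)
    return ExperimentTable(schema=schema, df=df)


def write_table(table: ExperimentTable, path: str | Path) -> None:
    """Write a table back to CSV in display units, 6 significant digits,
    fixed column order; deterministic bytes for deterministic input."""
    mapping = TABLE_SCHEMAS[table.schema]
    cols = {}
    for file_col, (name, scale) in mapping.items():
        if name not in table.df.columns:
            raise TableSchemaError(f"table lacks column {name!r} for schema {table.schema!r}")
        cols[file_col] = table.df[name] / scale
    out = pd.DataFrame(cols)
    extra = [c for c in table.df.columns if c not in {n for n, _ in mapping.values()}]
    for c in extra:
        out[c] = table.df[c]
    out.to_csv(path, index=False, float_format="%.6g")
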