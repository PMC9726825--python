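"""Validated CSV / YAML reading and writing, unit conversion, run manifests.

Tables are CSV with a header row, UTF-8, decimal point; time columns carry
explicit unit suffixes (``t_h``, ``t_day``, ``t_s``).  Every CLI run
writes a JSON manifest tying its outputs to (inputs, config, seed,
package version) so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .core_model import CalibrationAnchors
from .errors import SchemaError
from .synthetic import ScenarioConfig
from .units import hours, kelvin

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "load_config",
    "load_anchors",
    "RunManifest",
]

#: Required numeric columns per table kind (extra columns are allowed).
SCHEMAS = {
    "tracks": ["cell_id", "time_h", "size_au", "ros_au", "bud_flag", "birth_flag",
               "death_flag", "censored_flag"],
    "traces": ["cell_id", "time_h", "whi5_ratio", "dna_copy", "bud_flag", "division_flag"],
    "population": ["condition_id", "temperature_C", "t_day", "density_per_ml",
                   "initial_density_per_ml", "carrying_capacity_per_ml"],
    "viability": ["condition_id", "t_day", "live_per_ml", "dead_per_ml"],
    "labeling": ["temperature_C", "t_h", "labeled_copies_per_cell", "replicate"],
    "induction": ["temperature_C", "t_h", "signal_au", "replicate"],
    "anchors": ["gene", "tpm", "fish_copies_per_cell"],
    "rates": ["temperature_C", "rate"],
    "oxidation": ["condition", "t_s", "signal_au"],
}

_ID_COLUMNS = {"cell_id", "condition_id", "gene", "condition", "replicate"}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Raises :class:`SchemaError` naming missing columns, or naming the
    column and 1-based data row of the first non-numeric cell.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for schema {schema!r}")
    for col in SCHEMAS[schema]:
        if col in _ID_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    return data


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario config from a YAML file on disk."""
    return ScenarioConfig.from_dict(load_config(path))


def load_anchors(path: str | Path) -> CalibrationAnchors:
    """Load calibration anchors from YAML, converting degC / days to K / hours.

    Expected keys: ``t_days`` (mapping temperature_C -> days, 2 entries),
    ``tau_max_days`` (mapping with one entry), ``ros_threshold``, and
    optionally ``alpha`` and ``s_ros``.
    """
    data = load_config(path)
    for key in ("t_days", "tau_max_days", "ros_threshold"):
        if key not in data:
            raise SchemaError(f"{path}: anchors config is missing {key!r}")
    t_anchors = {kelvin(float(tc)): hours(float(d)) for tc, d in data["t_days"].items()}
    ((tm_c, tm_d),) = data["tau_max_days"].items()
    return CalibrationAnchors(
        t_anchors=t_anchors,
        tau_max_anchor=(kelvin(float(tm_c)), hours(float(tm_d))),
        ros_threshold=float(data["ros_threshold"]),
        alpha=float(data.get("alpha", 0.77)),
        s_ros=float(data.get("s_ros", 1000.0)),
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    seed: int | None = None
    config: dict | None = None
    inputs: dict = dataclasses.field(default_factory=dict)
    extra: dict = dataclasses.field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _digest(p)

    def write(self, path: str | Path) -> None:
        from . import __version__

        record = {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "config_hash": (
                hashlib.sha256(
                    json.dumps(self.config, sort_keys=True, default=str).encode()
                ).hexdigest()[:16]
                if self.config is not None
                else None
            ),
            "inputs": self.inputs,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            **self.extra,
        }
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(record, indent=2, default=str) + "\n")
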