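"""Delimited-text I/O with schema validation and provenance headers.

All tables are UTF-8 comma-separated files with a header row and decimal
points. Output files carry ``#``-prefixed provenance comment lines (seed,
config hash, package version) that pandas skips on read via
``comment="#"``. Write-then-read round-trips the in-memory table; unknown
columns are preserved.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import reference as ref
from .exceptions import SchemaError
from .gait_metrics import STEP_COLUMNS

SUBJECT_REQUIRED: tuple[str, ...] = ("subject_id", "group") + ref.GAIT_VARIABLES


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# pdgait {__version__}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
    return path


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#", encoding="utf-8")
    except (pd.errors.ParserError, UnicodeDecodeError) as err:
        raise SchemaError(f"cannot parse {path}: {err}") from err


def _validate_stages(df: pd.DataFrame) -> None:
    if "stage" not in df.columns:
        return
    stages = pd.to_numeric(df["stage"], errors="coerce").dropna().unique()
    bad = [s for s in stages if s not in ref.VALID_STAGES]
    if bad:
        raise SchemaError(
            f"invalid modified H&Y stage(s) {sorted(bad)}: allowed stages are "
            f"{list(ref.VALID_STAGES)} (stage 5 subjects are excluded by design)"
        )


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Subject-level table: id, group, optional stage, eight variables."""
    df = _read_csv(path)
    missing = [c for c in SUBJECT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"subject table missing required column(s): {missing}")
    for v in ref.GAIT_VARIABLES:
        df[v] = pd.to_numeric(df[v], errors="raise")
    _validate_stages(df)
    return df


def read_step_table(path: str | Path) -> pd.DataFrame:
    """Step-level walkway table (one row per footfall interval)."""
    df = _read_csv(path)
    missing = [c for c in STEP_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"step table missing required column(s): {missing}")
    feet = set(df["foot"].unique()) - {"left", "right"}
    if feet:
        raise SchemaError(f"foot must be 'left' or 'right', found {sorted(feet)}")
    _validate_stages(df)
    return df


def load_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return data


def save_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, (pd.Series, np.ndarray)):
            return list(o)
        return str(o)

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n", encoding="utf-8")
    return path
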