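"""CSV/JSON readers and writers for the observation and tracked tables.

Tables are UTF-8, comma-delimited, "." decimal, with one header line.
Writers prepend a single ``#``-prefixed metadata comment embedding the
tool version, a config hash and the seed, so every artefact is traceable
to the run that produced it; readers skip comment lines.  Unknown extra
columns survive a round-trip untouched and are ignored by the analysis
stages.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import DataFormatError

FLOW_COLUMNS = ["t", "k", "n_out", "n_in", "width", "q", "experiment_id"]
TRACKED_COLUMNS = ["direction", "k_local", "C", "T", "uturn"]

__all__ = [
    "read_flow_density",
    "write_flow_density",
    "read_tracked",
    "write_tracked",
    "write_json",
    "metadata_line",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable config echo."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_line(seed: int | None = None, config=None) -> str:
    parts = [f"anttraffic={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return "# " + " ".join(parts)


def _read_table(path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{what} file {path} is empty", stacklevel=3)
        return pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{what} file {path} is missing column(s): {', '.join(missing)}"
        )
    return df


def _write_table(df: pd.DataFrame, path, seed, config) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(metadata_line(seed, config) + "\n")
        df.to_csv(fh, index=False)


def read_flow_density(path) -> pd.DataFrame:
    """Read a per-second flow/density observation table."""
    df = _read_table(path, FLOW_COLUMNS, "flow-density")
    for col in ("k", "q", "width"):
        if len(df) and not pd.api.types.is_numeric_dtype(df[col]):
            raise DataFormatError(f"flow-density column {col!r} is not numeric")
    return df


def write_flow_density(df: pd.DataFrame, path, seed=None, config=None) -> None:
    _write_table(df, path, seed, config)


def read_tracked(path) -> pd.DataFrame:
    """Read an individually tracked ant table."""
    df = _read_table(path, TRACKED_COLUMNS, "tracked-ant")
    for col in ("k_local", "C", "T"):
        if len(df) and not pd.api.types.is_numeric_dtype(df[col]):
            raise DataFormatError(f"tracked-ant column {col!r} is not numeric")
    return df


def write_tracked(df: pd.DataFrame, path, seed=None, config=None) -> None:
    _write_table(df, path, seed, config)


def write_json(obj: dict, path, seed=None, config=None) -> None:
    """Write a JSON report with embedded provenance metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    payload["_meta"] = {
        "tool": "anttraffic",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
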