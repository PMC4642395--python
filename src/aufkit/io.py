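"""Readers, writers and seed plumbing shared by the library and the CLI.

CSV record tables, JSON summaries/reports and YAML/JSON configs all go
through here.  Numbers are serialized at full precision; any rounding
happens only when a report is rendered for display.  Every CLI run also
writes a provenance record (config + seed + package version) beside its
outputs so results can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError
from .metric import DEFAULT_WINDOW_DAYS

RECORD_COLUMNS = ("app_id", "active_users", "daily_uses")


def child_seed(root_seed: int, stream: str) -> int:
    """Derive a per-module seed from the root seed and a stream name.

    A named-stream derivation keeps each module's draws independent of
    the others, so adding a module never perturbs existing output.
    The result is a 31-bit integer.
    """
    mix = np.random.SeedSequence([int(root_seed), zlib.crc32(stream.encode("utf-8"))])
    return int(mix.generate_state(1, dtype=np.uint64)[0] % (2**31))


def read_usage_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a usage-record CSV.

    Expected header: ``app_id,active_users,daily_uses[,window_days]``.
    A missing ``window_days`` column defaults to 30.  Rows with
    non-numeric or negative values are reported with their 1-based file
    line numbers in a :class:`~aufkit.errors.ParseError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"app_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    if "window_days" not in df.columns:
        df["window_days"] = DEFAULT_WINDOW_DAYS

    bad_lines: list[int] = []
    for col in ("active_users", "daily_uses", "window_days"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        invalid = numeric.isna() | (numeric < 0)
        bad_lines.extend(int(i) + 2 for i in df.index[invalid])  # +2: header is line 1
        df[col] = numeric
    if bad_lines:
        lines = tuple(sorted(set(bad_lines)))
        raise ParseError(
            f"{path}: {len(lines)} row(s) failed validation "
            f"(non-numeric or negative values) at line(s) {list(lines)}",
            lines=lines,
        )
    df["window_days"] = df["window_days"].astype(int)
    return df[list(RECORD_COLUMNS) + ["window_days"]]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_summary(summary: Any, path: str | Path) -> None:
    """Serialize a summary/report dataclass (or dict) to JSON with stable key order."""
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"cannot write summary to directory {path}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_summary(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def load_config_document(path: str | Path, allowed_keys: set[str]) -> dict:
    """Load a YAML/JSON config mapping, rejecting unknown keys by name."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    unknown = set(doc) - allowed_keys
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown config key(s) {sorted(unknown)}; allowed: {sorted(allowed_keys)}"
        )
    return doc


def write_provenance(out_dir: str | Path, subcommand: str, config: dict, seed: int | None) -> None:
    """Record what produced the outputs in a directory: config, seed, version."""
    from . import __version__

    doc = {
        "tool": "auf",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "config": _jsonable(config),
    }
    write_summary(doc, Path(out_dir) / "provenance.json")
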