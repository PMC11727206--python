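"""File I/O: covariate tables, assignment files, configs, run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ._validation import check_assignment

__all__ = [
    "read_covariates",
    "write_assignment",
    "read_assignment",
    "load_config",
    "RunManifest",
]


def read_covariates(path, delimiter: Optional[str] = None, header: bool = True):
    """Read an n x p numeric covariate table from CSV/TSV.

    Row order defines the unit index (0-based). Returns (values, column_names);
    non-numeric cells raise a parse error naming the offending coordinates.
    """
    path = Path(path)
    sep = delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, header=0 if header else None,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty or has no parseable rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or converted.isna().any():
            i = int(np.argmax(converted.isna().values))
            raise ValueError(
                f"{path}: non-numeric or missing value at row {i}, column {col!r}: "
                f"{df[col].iloc[i]!r}"
            )
        values[:, j] = converted.values
    names = [str(c) for c in df.columns] if header else None
    return values, names


@dataclass
class RunManifest:
    """Provenance record written next to every output file."""

    command: str
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    package: str = "modesign"

    def to_dict(self) -> dict:
        from . import __version__

        blob = json.dumps(self.config, sort_keys=True, default=str)
        return {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "package": self.package,
            "version": __version__,
            "python": sys.version.split()[0],
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def write_assignment(path, T, manifest: Optional[RunManifest] = None) -> None:
    """Write an assignment as CSV (unit_index, treatment); if a manifest is
    given it is written alongside as ``<path>.manifest.json``."""
    t = check_assignment(T)
    pd.DataFrame({"unit_index": np.arange(t.size), "treatment": t}).to_csv(
        path, index=False)
    if manifest is not None:
        manifest.write(str(path) + ".manifest.json")


def read_assignment(path) -> np.ndarray:
    """Read an assignment CSV written by :func:`write_assignment`."""
    df = pd.read_csv(path)
    if "treatment" not in df.columns:
        raise ValueError(f"{path}: missing 'treatment' column")
    if "unit_index" in df.columns:
        df = df.sort_values("unit_index")
    return check_assignment(df["treatment"].to_numpy())


def load_config(path) -> dict:
    """Load a simulation config from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)
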