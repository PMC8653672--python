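"""Flat-file formats: sample tables (CSV), reports (JSON), run manifests."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .simulate import SAMPLE_COLUMNS

REQUIRED_SAMPLE_COLUMNS = ["sample_id", "analyte", "rlu", "cohort"]


@dataclass
class RunManifest:
    """Provenance of one pipeline step, embedded in every output."""

    command: str
    panel: str = "default"
    seed: Optional[int] = None
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    overrides: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "panel": self.panel,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "overrides": self.overrides,
            "version": self.version,
            "timestamp": self.timestamp,
        }


def write_samples(records: pd.DataFrame, path: str | Path,
                  manifest: RunManifest | None = None) -> None:
    """Write a sample table as CSV; deterministic bytes for equal tables.

    The run manifest, which carries a wall-clock timestamp, goes to a
    sidecar ``<path>.manifest.json`` so the table itself stays
    byte-reproducible.
    """
    path = Path(path)
    cols = [c for c in SAMPLE_COLUMNS if c in records.columns]
    records.to_csv(path, index=False, columns=cols)
    if manifest is not None:
        Path(f"{path}.manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2) + "\n"
        )


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and schema-check a sample table CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse sample table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} lacks columns: {missing}")
    if df.empty:
        raise ValueError(f"sample table {path} is empty")
    if not pd.api.types.is_numeric_dtype(df["rlu"]):
        raise ValueError(f"sample table {path}: rlu column is not numeric")
    return df


def write_json(payload: dict | str, path: str | Path) -> None:
    text = payload if isinstance(payload, str) else json.dumps(payload, indent=2)
    Path(path).write_text(text + ("" if text.endswith("\n") else "\n"))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
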