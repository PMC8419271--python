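"""File I/O and run configuration.

Time series travel as delimited text (TSV canonical, CSV accepted): rows
are time points, columns are ROIs, with an optional single header row of
ROI names and no index column.  Adjacency matrices are written as full
square TSVs at 17 significant digits (lossless for doubles) with a JSON
sidecar carrying the order and convergence metadata.  Scan collections
are described by a manifest CSV with columns ``scan_path, subject_id,
label``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .bfn import AdjacencyMatrix, ROITimeSeries, ValidationError
from .classify import DEFAULT_LAMBDA_GRID, DEFAULT_P_GRID

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_adjacency",
    "read_adjacency",
    "read_manifest",
    "RunConfig",
]

_FLOAT_FMT = "%.17g"


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _is_numeric_row(tokens: list[str]) -> bool:
    try:
        [float(t) for t in tokens]
        return True
    except ValueError:
        return False


def read_timeseries(
    path,
    scan_id: Optional[str] = None,
    subject_id: str = "",
    label: Optional[str] = None,
) -> ROITimeSeries:
    """Read one scan's M x N signal matrix from delimited text."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValidationError(f"{path}: empty file")
    delim = _sniff_delimiter(first)
    tokens = [t.strip() for t in first.rstrip("\n").split(delim)]
    has_header = not _is_numeric_row(tokens)
    try:
        df = pd.read_csv(
            path, sep=delim, header=0 if has_header else None, dtype=float,
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: not a rectangular numeric table ({exc})") from exc
    if df.isna().to_numpy().any():
        raise ValidationError(f"{path}: ragged rows or non-numeric cells")
    names = tuple(str(c) for c in df.columns) if has_header else None
    return ROITimeSeries(
        values=df.to_numpy(dtype=float),
        scan_id=scan_id or path.stem,
        subject_id=subject_id,
        label=label,
        roi_names=names,
    )


def write_timeseries(ts: ROITimeSeries, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(ts.roi_names) if ts.roi_names else ""
    np.savetxt(path, ts.values, fmt=_FLOAT_FMT, delimiter="\t",
               header=header, comments="")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_adjacency(R: AdjacencyMatrix, path, extra: Optional[dict] = None) -> None:
    """Write a full square TSV plus a JSON sidecar (order, degenerate
    nodes, and any ``extra`` metadata such as tol / n_converged)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, R.values, fmt=_FLOAT_FMT, delimiter="\t")
    meta = {
        "order": R.order,
        "degenerate_nodes": sorted(R.degenerate_nodes),
    }
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_adjacency(path) -> AdjacencyMatrix:
    """Read an adjacency TSV back, validating the matrix invariants."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{path}: cannot parse adjacency TSV ({exc})") from exc
    order = 1
    degenerate: frozenset = frozenset()
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        order = int(meta.get("order", 1))
        degenerate = frozenset(meta.get("degenerate_nodes", []))
    return AdjacencyMatrix(values=values, order=order, degenerate_nodes=degenerate)


def read_manifest(path) -> pd.DataFrame:
    """Manifest CSV with columns ``scan_path, subject_id, label``; scan
    paths are resolved relative to the manifest's directory."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str)
    required = {"scan_path", "subject_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")
    if df[sorted(required)].isna().any().any():
        raise ValidationError("manifest has empty cells in required columns")
    df["scan_path"] = [
        str((path.parent / p)) if not Path(p).is_absolute() else p
        for p in df["scan_path"]
    ]
    return df


@dataclass
class RunConfig:
    """All tunables in one place, serializable to/from YAML.

    Unknown keys in a config file are rejected rather than ignored.
    """

    tol: float = 1e-6
    max_iter: int = 30
    policy: str = "error"
    rank_rel_tol: float = 1e-8
    k: int = 5
    inner_k: int = 5
    seed: int = 7
    C: float = 1.0
    p_grid: tuple = tuple(DEFAULT_P_GRID)
    lambda_grid: tuple = tuple(DEFAULT_LAMBDA_GRID)
    orders: tuple = (1, 2, 3, 4, "conv")
    mode: str = "single"
    selection_scope: str = "fold"
    equal_var: bool = True

    def __post_init__(self):
        if not self.tol > 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.mode not in ("single", "fusion"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.selection_scope not in ("fold", "global"):
            raise ValidationError(f"unknown selection_scope {self.selection_scope!r}")
        self.p_grid = tuple(float(p) for p in self.p_grid)
        self.lambda_grid = tuple(float(l) for l in self.lambda_grid)
        self.orders = tuple(
            o if o == "conv" else int(o) for o in self.orders
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["p_grid"] = list(self.p_grid)
        d["lambda_grid"] = list(self.lambda_grid)
        d["orders"] = list(self.orders)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
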