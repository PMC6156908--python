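"""Sample, reference-state and parameter-table I/O.

A sample set is a table of conformations projected onto the top two principal
components of experimentally known structures (PC1, PC2) together with a
force-field potential energy per conformation. Energies are carried through as
opaque reals; no unit conversion is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class SampleSet:
    """Energy-evaluated samples in PC1-PC2 projection space."""

    points: np.ndarray          # (n, 2) float
    energies: np.ndarray        # (n,) float
    variant_label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.energies.shape != (self.points.shape[0],):
            raise ValueError("points and energies must have equal length")
        if len(self.points) == 0:
            raise ValueError("sample set is empty")
        if not (np.isfinite(self.points).all() and np.isfinite(self.energies).all()):
            raise ValueError("sample set contains non-finite values")
        if len(self.points) < 3:
            raise ValueError("at least 3 samples are required")
        # a 2D alpha-shape needs three non-collinear points
        centered = self.points - self.points.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-12 * max(1.0, np.abs(centered).max())) < 2:
            raise ValueError("all sample points are collinear")

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pc1": self.points[:, 0], "pc2": self.points[:, 1], "energy": self.energies}
        )


@dataclass(frozen=True)
class ReferenceState:
    """An experimentally known conformational state projected into PC space."""

    label: str
    location: tuple[float, float]
    energy: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("reference state label must be nonempty")
        if not np.all(np.isfinite(self.location)) or not np.isfinite(self.energy):
            raise ValueError(f"reference state {self.label!r} has non-finite fields")


def _resolve_column(df: pd.DataFrame, key, what: str):
    if isinstance(key, int):
        if key >= df.shape[1]:
            raise ValueError(f"column index {key} for {what} out of range")
        return df.columns[key]
    if key not in df.columns:
        raise ValueError(f"column {key!r} for {what} not found in {list(df.columns)}")
    return key


def _read_table(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with header autodetection.

    Floats are parsed in round-trip mode so written values re-read exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    head = pd.read_csv(path, sep=sep, nrows=5, header=None,
                       float_precision="round_trip")
    # header autodetection: if the first row is entirely non-numeric strings
    # while the second parses as numbers, treat row 0 as a header
    def _numericish(row) -> bool:
        return pd.to_numeric(row, errors="coerce").notna().any()

    has_header = len(head) > 1 and not _numericish(head.iloc[0]) and _numericish(head.iloc[1])
    return pd.read_csv(path, sep=sep, header=0 if has_header else None,
                       float_precision="round_trip")


def read_samples(path, column_spec: dict | None = None, variant_label: str | None = None) -> SampleSet:
    """Read a sample table (CSV/TSV) into a :class:`SampleSet`.

    ``column_spec`` maps the roles ``pc1``/``pc2``/``energy`` to column names
    or positional indices; by default the first three columns are used (or the
    columns named pc1/pc2/energy when present). Rows with non-finite fields
    are dropped with a logged count.
    """
    df = _read_table(path)
    if df.shape[0] < 3:
        raise ValueError(f"{path}: need at least 3 data rows, found {df.shape[0]}")
    if column_spec is None:
        lower = {str(c).lower(): c for c in df.columns}
        if {"pc1", "pc2", "energy"} <= set(lower):
            column_spec = {k: lower[k] for k in ("pc1", "pc2", "energy")}
        else:
            column_spec = {"pc1": 0, "pc2": 1, "energy": 2}
    cols = [_resolve_column(df, column_spec[k], k) for k in ("pc1", "pc2", "energy")]
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    bad_cells = sub.isna() & df[cols].notna()
    if bad_cells.any().any():
        row = int(bad_cells.any(axis=1).idxmax())
        raise ValueError(f"{path}: non-numeric cell in data row {row}")
    keep = np.isfinite(sub.to_numpy()).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.warning("%s: dropped %d rows with non-finite fields", path, dropped)
    sub = sub[keep]
    if sub.shape[0] < 3:
        raise ValueError(f"{path}: fewer than 3 usable rows after filtering")
    label = variant_label if variant_label is not None else Path(path).stem
    return SampleSet(sub.iloc[:, :2].to_numpy(float), sub.iloc[:, 2].to_numpy(float), label)


def write_samples(samples: SampleSet, path) -> None:
    """Write a sample set as a headered CSV (pc1, pc2, energy).

    Floats are written with 17 significant digits so values round-trip
    bit-exactly through read_samples."""
    samples.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_states(path) -> list[ReferenceState]:
    """Read a reference-state table with columns label, pc1, pc2, energy."""
    df = _read_table(path)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: state table needs columns label,pc1,pc2,energy")
    out = []
    for _, row in df.iterrows():
        vals = pd.to_numeric(row.iloc[1:4], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"{path}: non-numeric state row for label {row.iloc[0]!r}")
        out.append(ReferenceState(str(row.iloc[0]), (float(vals.iloc[0]), float(vals.iloc[1])),
                                  float(vals.iloc[2])))
    return out


def read_parameter_table(path) -> pd.DataFrame:
    """Read a per-variant biochemical parameter table (variant x parameter).

    First column holds variant labels (index); the remaining columns are
    numeric parameters. Missing cells are allowed (NaN).
    """
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicated variant labels {dupes}")
    return df.apply(pd.to_numeric, errors="coerce")
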