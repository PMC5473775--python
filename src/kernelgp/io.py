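"""Readers and writers for the package's delimited-text and HDF5 formats.

* Phenotypes: long format with header ``line,env,trait,value``; unbalance
  is implicit (absent rows).
* Marker matrix: first column line id, header row of marker ids, missing
  as ``NA`` or empty; comma or tab auto-detected.  An HDF5 container with
  datasets ``dosages``, ``line_ids``, ``marker_ids`` is supported for
  large matrices.
* Kernel: full square matrix with id header row and id first column;
  symmetry validated on read.
* Cross table: header ``hybrid,parent1,parent2``.

Values are written with %.17g so text round trips are bit-identical for
float64.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import PhenotypeRecords
from .kernels import SYM_TOL, KernelMatrix
from .markers import CrossTable, MarkerMatrix

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_kernel",
    "write_kernel",
    "read_cross_table",
    "write_cross_table",
    "config_hash",
]

_FMT = "%.17g"  # shortest guaranteed round-trip precision for float64


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration dict, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_phenotypes(path: str | Path) -> PhenotypeRecords:
    """Read long-format phenotype records; errors name the offending row."""
    path = Path(path)
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed phenotype file {path}: {exc}") from exc
    expected = {"line", "env", "trait", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(expected)}, found {list(df.columns)}"
        )
    bad = df.index[~np.isfinite(pd.to_numeric(df["value"], errors="coerce"))]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: non-numeric value at line(s) {[i + 2 for i in bad]}")
    try:
        return PhenotypeRecords(df[["line", "env", "trait", "value"]])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_phenotypes(records: PhenotypeRecords, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("line,env,trait,value\n")
        for row in records.df.itertuples(index=False):
            fh.write(f"{row.line},{row.env},{row.trait},{_FMT % row.value}\n")


def read_marker_matrix(path: str | Path) -> MarkerMatrix:
    """Read a dosage matrix from delimited text or HDF5 (by extension)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            return MarkerMatrix(
                f["dosages"][()],
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["line_ids"][()]],
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["marker_ids"][()]],
            )
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                     na_values=["NA", ""], keep_default_na=False,
                     float_precision="round_trip")
    values = df.to_numpy(dtype=float)  # raises on non-numeric cells
    return MarkerMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_marker_matrix(markers: MarkerMatrix, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("dosages", data=markers.dosages)
            f.create_dataset("line_ids", data=np.array(markers.line_ids, dtype="S"))
            f.create_dataset("marker_ids", data=np.array(markers.marker_ids, dtype="S"))
        return
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("line," + ",".join(markers.marker_ids) + "\n")
        for lid, row in zip(markers.line_ids, markers.dosages):
            cells = ("NA" if np.isnan(v) else _FMT % v for v in row)
            fh.write(lid + "," + ",".join(cells) + "\n")


def read_kernel(path: str | Path, method_tag: str = "GB") -> KernelMatrix:
    """Read a square kernel file; validates symmetry to 1e-8."""
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                     float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    ids = [str(i) for i in df.index]
    if list(map(str, df.columns)) != ids:
        raise ValueError(f"{path}: row and column ids disagree")
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: kernel not square: {values.shape}")
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym > 1e-8:
        raise ValueError(f"{path}: kernel asymmetric (max |K - K'| = {asym:.3g})")
    K = KernelMatrix((values + values.T) / 2.0, ids, method_tag=method_tag)
    try:
        K.validate()
    except ValueError as exc:
        import warnings

        warnings.warn(f"{path}: {exc}", UserWarning, stacklevel=2)
    return K


def write_kernel(K: KernelMatrix, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("id," + ",".join(K.line_ids) + "\n")
        for lid, row in zip(K.line_ids, K.values):
            fh.write(lid + "," + ",".join(_FMT % v for v in row) + "\n")


def read_cross_table(path: str | Path) -> CrossTable:
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    expected = {"hybrid", "parent1", "parent2"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    return CrossTable(
        df["hybrid"].astype(str).tolist(),
        df["parent1"].astype(str).tolist(),
        df["parent2"].astype(str).tolist(),
    )


def write_cross_table(crosses: CrossTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("hybrid,parent1,parent2\n")
        for h, p1, p2 in zip(crosses.hybrid_ids, crosses.parent1_ids, crosses.parent2_ids):
            fh.write(f"{h},{p1},{p2}\n")
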