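"""Readers and writers for the on-disk formats.

Canonical formats:

* count matrices — UTF-8 TSV, first header cell literally ``feature_id``
  (bulk, features x samples) or ``cell_id`` (single cell, cells x genes);
  MatrixMarket triplets (with two companion id lists) are accepted for
  single-cell matrices only.
* fragment end counts — bedgraph, 0-based half-open intervals on disk;
  every in-memory coordinate is a 1-based nucleotide index.
* gene sets — one id per line, ``#`` comments allowed.
* references — FASTA.

Every writer accepts optional header comment lines (used by the CLI to
embed the run config); every reader skips ``#`` comment lines, so writer
output always round-trips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .containers import CellMatrix, EndCountProfile, ExpressionMatrix

FEATURES_BY_SAMPLES = "features_by_samples"
CELLS_BY_GENES = "cells_by_genes"


class ParseError(ValueError):
    """Malformed file content, with the offending coordinates in the message."""


# ---------------------------------------------------------------------------
# Count matrices (TSV)
# ---------------------------------------------------------------------------

_HEADER_CELL = {FEATURES_BY_SAMPLES: "feature_id", CELLS_BY_GENES: "cell_id"}


def _read_table(path: str | Path, orientation: str) -> pd.DataFrame:
    expected = _HEADER_CELL.get(orientation)
    if expected is None:
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != expected:
        raise ParseError(
            f"{path}: first header cell must be {expected!r}, got {header[0]!r}"
        )
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        raise ParseError(f"{path}: duplicate column ids")
    row_ids: list[str] = []
    data = np.empty((len(lines) - 1, len(col_ids)), dtype=np.int64)
    for r, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(col_ids) + 1:
            raise ParseError(f"{path}: line {r}: expected {len(col_ids) + 1} fields")
        row_ids.append(fields[0])
        for c, tok in enumerate(fields[1:]):
            try:
                data[r - 2, c] = int(tok)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at row {fields[0]!r}, "
                    f"column {col_ids[c]!r}"
                ) from exc
    if len(set(row_ids)) != len(row_ids):
        dup = sorted({x for x in row_ids if row_ids.count(x) > 1})[:3]
        raise ParseError(f"{path}: duplicate row ids: {dup}")
    df = pd.DataFrame(data, index=pd.Index(row_ids, name=expected), columns=col_ids)
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def read_counts(path: str | Path, orientation: str = FEATURES_BY_SAMPLES):
    """Read an integer count matrix.

    ``orientation='features_by_samples'`` returns an ``ExpressionMatrix``
    (unit counts); ``'cells_by_genes'`` returns a ``CellMatrix`` whose
    mitochondrial genes are those whose id starts with ``mt-`` (case
    insensitive).
    """
    df = _read_table(path, orientation)
    if orientation == FEATURES_BY_SAMPLES:
        return ExpressionMatrix(df, unit="counts")
    mito = {g for g in df.columns if g.lower().startswith("mt-")}
    return CellMatrix(df, mito_genes=mito)


def write_counts(
    matrix: ExpressionMatrix | CellMatrix | pd.DataFrame,
    path: str | Path,
    orientation: str | None = None,
    header_lines: list[str] | None = None,
) -> None:
    """Write a count matrix in the canonical TSV dialect.

    Integer values are written as integers; for the canonical dialect
    (no ``header_lines``) a read/write round trip is byte-identical.
    """
    if isinstance(matrix, ExpressionMatrix):
        df, orientation = matrix.values, orientation or FEATURES_BY_SAMPLES
    elif isinstance(matrix, CellMatrix):
        df, orientation = matrix.counts, orientation or CELLS_BY_GENES
    else:
        df = matrix
        if orientation is None:
            raise ValueError("orientation required for a bare DataFrame")
    first = _HEADER_CELL[orientation]
    arr = df.to_numpy()
    integral = arr.size == 0 or np.allclose(arr, np.rint(arr))
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(line if line.startswith("#") else "# " + line)
            fh.write("\n")
        fh.write(first + "\t" + "\t".join(map(str, df.columns)) + "\n")
        for rid, row in zip(df.index, arr):
            if integral:
                cells = (str(int(round(v))) for v in row)
            else:
                cells = (format(v, ".6g") for v in row)
            fh.write(str(rid) + "\t" + "\t".join(cells) + "\n")


def read_counts_mtx(
    mtx_path: str | Path,
    row_ids_path: str | Path,
    col_ids_path: str | Path,
) -> CellMatrix:
    """Read a single-cell matrix from MatrixMarket plus two id lists
    (rows = cells, columns = genes)."""
    mat = coo_matrix(mmread(mtx_path))
    rows = read_id_list(row_ids_path)
    cols = read_id_list(col_ids_path)
    if mat.shape != (len(rows), len(cols)):
        raise ParseError(
            f"{mtx_path}: shape {mat.shape} does not match id lists "
            f"({len(rows)} x {len(cols)})"
        )
    dense = np.asarray(mat.todense()).astype(np.int64)
    df = pd.DataFrame(dense, index=pd.Index(rows, name="cell_id"), columns=cols)
    mito = {g for g in cols if g.lower().startswith("mt-")}
    return CellMatrix(df, mito_genes=mito)


def write_counts_mtx(
    cells: CellMatrix,
    mtx_path: str | Path,
    row_ids_path: str | Path,
    col_ids_path: str | Path,
) -> None:
    sparse = coo_matrix(cells.counts.to_numpy())
    mmwrite(str(mtx_path), sparse, field="integer")
    write_id_list(cells.cell_ids, row_ids_path)
    write_id_list(cells.gene_ids, col_ids_path)


# ---------------------------------------------------------------------------
# Gene sets / id lists
# ---------------------------------------------------------------------------

def read_id_list(path: str | Path) -> list[str]:
    """One id per line; ``#`` comments and blank lines skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


read_gene_set = read_id_list


def write_id_list(ids, path: str | Path, header_lines: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(line if line.startswith("#") else "# " + line)
            fh.write("\n")
        for i in ids:
            fh.write(str(i) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning {record id: sequence}."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif name is None:
                raise ParseError(f"{path}: sequence before first header")
            else:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# End counts (bedgraph)
# ---------------------------------------------------------------------------

def read_bedgraph_ends(path: str | Path, reference_id: str, length: int) -> np.ndarray:
    """Read per-nucleotide end counts from a bedgraph.

    Intervals are 0-based half-open on disk; the returned vector is indexed
    by 1-based nucleotide position (entry 0 = nucleotide 1).  An interval
    ``[s, e)`` with count ``v`` adds ``v`` at nucleotides ``s+1 .. e``.
    Empty files give an all-zero vector.
    """
    counts = np.zeros(length, dtype=np.int64)
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: line {ln}: expected 4 bedgraph fields")
            ref, s, e, v = fields
            if ref != reference_id:
                raise ParseError(
                    f"{path}: line {ln}: reference {ref!r} != {reference_id!r}"
                )
            try:
                s, e, v = int(s), int(e), int(v)
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: non-integer field") from exc
            if v < 0:
                raise ParseError(f"{path}: line {ln}: negative count")
            if s < 0 or e > length or s >= e:
                raise ParseError(
                    f"{path}: line {ln}: interval [{s}, {e}) outside [0, {length})"
                )
            counts[s:e] += v
    return counts


def write_bedgraph_ends(
    counts: np.ndarray,
    path: str | Path,
    reference_id: str,
    header_lines: list[str] | None = None,
) -> None:
    """Write per-nucleotide end counts as one bedgraph line per nonzero
    position."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(line if line.startswith("#") else "# " + line)
            fh.write("\n")
        for i, v in enumerate(np.asarray(counts)):
            if v:
                fh.write(f"{reference_id}\t{i}\t{i + 1}\t{int(v)}\n")


def read_endcounts(
    path_5p: str | Path,
    path_3p: str | Path,
    reference_id: str,
    length: int,
) -> EndCountProfile:
    """Read paired 5'/3' end-count bedgraphs and combine them into the
    per-bond cleavage profile (length L-1)."""
    c5 = read_bedgraph_ends(path_5p, reference_id, length)
    c3 = read_bedgraph_ends(path_3p, reference_id, length)
    return EndCountProfile.from_end_counts(reference_id, length, c5, c3)


def read_endcounts_table(path: str | Path, reference_id: str, length: int) -> EndCountProfile:
    """4-column TSV alternative: ref, 1-based position, count5p, count3p."""
    c5 = np.zeros(length, dtype=np.int64)
    c3 = np.zeros(length, dtype=np.int64)
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}: line {ln}: expected 4 fields")
            ref, pos, v5, v3 = fields
            if ref != reference_id:
                raise ParseError(f"{path}: line {ln}: reference {ref!r}")
            pos, v5, v3 = int(pos), int(v5), int(v3)
            if not 1 <= pos <= length:
                raise ParseError(f"{path}: line {ln}: position {pos} outside [1, {length}]")
            if v5 < 0 or v3 < 0:
                raise ParseError(f"{path}: line {ln}: negative count")
            c5[pos - 1] += v5
            c3[pos - 1] += v3
    return EndCountProfile.from_end_counts(reference_id, length, c5, c3)


# ---------------------------------------------------------------------------
# Generic tables, manifests
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a result table as TSV with optional comment header; floats use
    a fixed 6-significant-digit format so identical runs are byte-identical."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(line if line.startswith("#") else "# " + line)
            fh.write("\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", lineterminator="\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    command: str,
    config: dict,
    inputs: dict[str, str | Path],
    outputs: list[str],
) -> None:
    """Record what a run did: command, config (incl. seed), input digests,
    package version.  Deliberately timestamp-free so identical runs produce
    identical manifests."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "inputs": {str(k): file_digest(v) for k, v in inputs.items()},
        "outputs": sorted(Path(o).name for o in outputs),
        "version": __version__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
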