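"""Single-cell QC filtering and per-cell gene-set scoring.

QC drops genes detected in too few cells and cells with too few UMIs or too
high a mitochondrial fraction.  Gene-set scores (ERV families, ribosomal
protein genes) are per-cell means of counts-per-10k, log2(1 + x) normalized
expression over the set, and their cross-cell correlation is the readout
for the anti-correlation between the 2C-like ERV program and ribosome
production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import rankstats
from .containers import CellMatrix

CP10K = 1e4


@dataclass
class QCReport:
    dropped_genes: pd.Series  # gene id -> reason
    dropped_cells: pd.Series  # cell id -> reason
    empty_after_filtering: bool

    def as_frame(self) -> pd.DataFrame:
        rows = [("gene", g, r) for g, r in self.dropped_genes.items()]
        rows += [("cell", c, r) for c, r in self.dropped_cells.items()]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def qc_filter(
    cells: CellMatrix,
    min_cells_per_gene: int = 3,
    min_umi: int = 500,
    max_mito_fraction: float = 0.2,
) -> tuple[CellMatrix, QCReport]:
    """Apply the standard droplet QC filters.

    Genes expressed (count > 0) in fewer than ``min_cells_per_gene`` cells
    are dropped, with detection evaluated on the *pre-filter* cell set; then
    cells with ``nUMI < min_umi`` or ``mito_fraction > max_mito_fraction``
    are dropped (thresholds are strict in those directions: nUMI exactly at
    the minimum survives, as does a mito fraction exactly at the maximum).
    One pass each, gene filter first; the filters are not re-iterated.

    An empty result is reported in the QC report, not raised.
    """
    detected_in = (cells.counts > 0).sum(axis=0)
    keep_genes = detected_in >= min_cells_per_gene

    n_umi = cells.n_umi
    mito = cells.mito_fraction
    low_umi = n_umi < min_umi
    high_mito = mito > max_mito_fraction
    keep_cells = ~(low_umi | high_mito)

    reasons_g = pd.Series(
        f"detected in < {min_cells_per_gene} cells",
        index=cells.gene_ids[~keep_genes],
    )
    reason_c = np.where(
        low_umi & high_mito,
        "low nUMI; high mito fraction",
        np.where(low_umi, f"nUMI < {min_umi}", f"mito fraction > {max_mito_fraction}"),
    )
    reasons_c = pd.Series(reason_c[~keep_cells.to_numpy()], index=cells.cell_ids[~keep_cells])

    filtered = CellMatrix(
        cells.counts.loc[keep_cells, keep_genes],
        mito_genes=cells.mito_genes,
    )
    report = QCReport(
        dropped_genes=reasons_g,
        dropped_cells=reasons_c,
        empty_after_filtering=filtered.counts.size == 0,
    )
    return filtered, report


def normalize_cp10k_log2(cells: CellMatrix) -> pd.DataFrame:
    """Counts-per-10k depth normalization followed by log2(1 + x)."""
    depth = cells.n_umi.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cp10k = np.where(
            depth[:, None] > 0,
            cells.counts.to_numpy(dtype=float) / depth[:, None] * CP10K,
            0.0,
        )
    return pd.DataFrame(np.log2(1.0 + cp10k), index=cells.cell_ids, columns=cells.gene_ids)


def geneset_score(
    cells: CellMatrix,
    gene_set: list[str],
    normalization: str = "cp10k_log2",
    detect_min_umi: int = 1,
) -> pd.DataFrame:
    """Per-cell averaged expression of a gene set.

    The score is the mean normalized expression over the set's genes present
    in the matrix; ``normalization`` is ``cp10k_log2`` (default) or
    ``raw_mean`` (mean of raw counts, kept for sensitivity analysis).
    ``detectable`` flags cells with at least ``detect_min_umi`` raw UMIs in
    the set.

    Returns a DataFrame with columns score, set_umi, detectable.
    """
    present = [g for g in dict.fromkeys(gene_set) if g in cells.gene_ids]
    if not present:
        missing = list(gene_set)[:5]
        raise ValueError(f"no gene-set members in the matrix (looked for {missing} ...)")
    set_umi = cells.counts[present].sum(axis=1)
    if normalization == "cp10k_log2":
        norm = normalize_cp10k_log2(cells)
        score = norm[present].mean(axis=1)
    elif normalization == "raw_mean":
        score = cells.counts[present].mean(axis=1).astype(float)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return pd.DataFrame(
        {
            "score": score,
            "set_umi": set_umi,
            "detectable": set_umi >= detect_min_umi,
        },
        index=cells.cell_ids,
    )


def erv_rp_correlation(
    erv_scores: pd.DataFrame,
    rp_scores: pd.DataFrame,
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between per-cell ERV and RP scores.

    Restricted to cells with detectable ERV expression (each dot of the
    scatter is a single cell with >= 1 ERV UMI); needs at least 3 such
    cells.  Returns ``(r, table)`` where the table holds the per-cell
    (erv_score, rp_score) pairs used.
    """
    if not erv_scores.index.equals(rp_scores.index):
        raise ValueError("score tables cover different cells")
    keep = erv_scores.index[erv_scores["detectable"]]
    if len(keep) < 3:
        raise ValueError(f"only {len(keep)} cells with detectable ERV expression; need >= 3")
    table = pd.DataFrame(
        {
            "erv_score": erv_scores.loc[keep, "score"],
            "rp_score": rp_scores.loc[keep, "score"],
        },
        index=keep,
    )
    r = rankstats.pearson_r(table["erv_score"].to_numpy(), table["rp_score"].to_numpy())
    return r, table
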