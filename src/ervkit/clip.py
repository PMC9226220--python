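"""CLIP-over-control enrichment scoring.

Per-transcript enrichment is the log2 ratio of the feature's TPM in the
CLIP library over its TPM in the control RNA-seq library (with a
pseudocount), summarized per annotation category (snoRNA, rRNA, repeat
families, ...).  A small read-assignment contract mirrors the rDNA-first
alignment convention: reads matching the ribosomal DNA repeating unit count
toward rRNA with priority, everything else counts only if it maps to a
unique genome feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RRNA_FEATURE = "rRNA"


def clip_enrich(
    pair: pd.DataFrame,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score CLIP enrichment per feature and summarize per category.

    ``pair`` is a feature-indexed DataFrame with columns ``tpm_clip``,
    ``tpm_control`` and ``category``.  Enrichment is
    ``log2((tpm_clip + a) / (tpm_control + a))``.

    Returns ``(per_feature, per_category)``: the feature table gains an
    ``enrichment`` column; the category table has mean, median and member
    count.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    required = {"tpm_clip", "tpm_control", "category"}
    missing = required - set(pair.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    if (pair["category"].astype(str) == "").any():
        raise ValueError("every feature needs a nonempty category")
    if (pair[["tpm_clip", "tpm_control"]] < 0).to_numpy().any():
        raise ValueError("TPM values must be nonnegative")

    per_feature = pair.copy()
    per_feature["enrichment"] = np.log2(
        (pair["tpm_clip"] + pseudocount) / (pair["tpm_control"] + pseudocount)
    )
    per_category = (
        per_feature.groupby("category")["enrichment"]
        .agg(mean="mean", median="median", n_members="size")
        .sort_index()
    )
    return per_feature, per_category


def priority_assign(hits: pd.DataFrame) -> pd.Series:
    """Count reads to features under the rDNA-first, unique-mapper contract.

    ``hits`` has one row per candidate alignment with columns ``read_id``
    and ``target``; a target equal to ``"rDNA"`` marks a hit to the
    ribosomal DNA repeating unit.  Rules, in order:

    1. any read with an rDNA hit is counted to ``rRNA`` and removed;
    2. remaining reads hitting exactly one genome feature count to it;
    3. reads hitting multiple genome features are discarded.

    Returns per-feature read counts (including the ``rRNA`` bucket when
    populated).  Empty input gives empty counts.
    """
    required = {"read_id", "target"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    if hits.empty:
        return pd.Series(dtype=int, name="count")

    is_rdna = hits["target"] == "rDNA"
    rdna_reads = set(hits.loc[is_rdna, "read_id"])
    counts: dict[str, int] = {}
    if rdna_reads:
        counts[RRNA_FEATURE] = len(rdna_reads)

    rest = hits[~hits["read_id"].isin(rdna_reads)]
    per_read = rest.groupby("read_id")["target"].agg(["nunique", "first"])
    unique_hits = per_read[per_read["nunique"] == 1]["first"]
    for target, n in unique_hits.value_counts().items():
        counts[target] = counts.get(target, 0) + int(n)

    out = pd.Series(counts, dtype=int, name="count").sort_index()
    out.index.name = "feature_id"
    return out
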