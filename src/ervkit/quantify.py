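"""Bulk expression quantification.

TPM conversion, repeat-family aggregation, per-feature 0-1 normalization,
KO-vs-WT fold changes, and a simple two-group differential-expression
caller (Welch's t on log2(TPM + 1) with the conventional
|log2FC| > 1, p < 0.05 call thresholds).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    COUNTS,
    GENE,
    NORMALIZED01,
    REPEAT,
    TPM_UNIT,
    ExpressionMatrix,
    FeatureTable,
)

TPM_SCALE = 1e6


def tpm(counts: ExpressionMatrix, features: FeatureTable) -> ExpressionMatrix:
    """Convert raw counts to transcripts-per-million.

    Per sample: each feature's count is divided by its effective length (nt)
    to a rate, and rates are rescaled to sum to 1e6.  All-zero samples stay
    all-zero.
    """
    if counts.unit != COUNTS:
        raise ValueError(f"tpm() expects counts, got unit {counts.unit!r}")
    missing = counts.feature_ids.difference(features.ids())
    if len(missing):
        raise ValueError(f"features missing a length: {missing[:5].tolist()}")
    lengths = features.lengths.loc[counts.feature_ids].to_numpy(dtype=float)
    rates = counts.values.to_numpy(dtype=float) / lengths[:, None]
    colsum = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(colsum > 0, rates / colsum * TPM_SCALE, 0.0)
    out = pd.DataFrame(vals, index=counts.feature_ids, columns=counts.sample_ids)
    return ExpressionMatrix(out, unit=TPM_UNIT)


def aggregate_family(
    expr: ExpressionMatrix,
    features: FeatureTable,
    level: str = "family",
    *,
    keep_genes: bool = False,
) -> ExpressionMatrix:
    """Sum repeat-member values into per-family (or per-class) rows.

    ``level`` selects the grouping column: ``family`` uses the repeat family
    label as-is; ``class`` is an alias for the same column here since family
    labels already carry the class naming used throughout (e.g. ``ERVL``).
    Gene rows are dropped unless ``keep_genes`` passes them through
    untouched.
    """
    if level not in ("family", "class"):
        raise ValueError("level must be 'family' or 'class'")
    ann = features.table.loc[expr.feature_ids]
    is_repeat = ann["feature_class"] == REPEAT
    fam = ann.loc[is_repeat, "family"]
    if (fam.fillna("") == "").any():
        raise ValueError("repeat feature without a family label")
    grouped = expr.values.loc[is_repeat].groupby(fam, sort=True).sum()
    grouped.index.name = expr.values.index.name
    if keep_genes:
        genes = expr.values.loc[ann.index[ann["feature_class"] == GENE]]
        grouped = pd.concat([grouped, genes])
    return ExpressionMatrix(grouped, unit=expr.unit)


def minmax_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Linearly rescale each feature row to [0, 1] across samples.

    Constant rows map to all zeros, keeping downstream rank tests total.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("min-max normalization needs at least 2 samples")
    vals = expr.values.to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (vals - lo) / span, 0.0)
    df = pd.DataFrame(out, index=expr.feature_ids, columns=expr.sample_ids)
    return ExpressionMatrix(df, unit=NORMALIZED01)


def _group_columns(expr: ExpressionMatrix, group: list[str], name: str) -> pd.DataFrame:
    if len(group) == 0:
        raise ValueError(f"{name} sample group is empty")
    missing = [s for s in group if s not in expr.sample_ids]
    if missing:
        raise ValueError(f"{name} samples not in matrix: {missing}")
    return expr.values[group]


def log2fc(
    expr: ExpressionMatrix,
    wt_samples: list[str],
    ko_samples: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-feature log2((mean_KO + c) / (mean_WT + c))."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    wt = _group_columns(expr, wt_samples, "WT").mean(axis=1)
    ko = _group_columns(expr, ko_samples, "KO").mean(axis=1)
    lfc = np.log2((ko + pseudocount) / (wt + pseudocount))
    lfc.name = "log2fc"
    return lfc


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def simple_de(
    expr: ExpressionMatrix,
    wt_samples: list[str],
    ko_samples: list[str],
    *,
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Call differential features between two replicate groups.

    Welch's t-test on log2(TPM + c) per feature, a documented lightweight
    stand-in for a count-model fit; a feature is ``called`` when
    ``|log2fc| > lfc_threshold`` and ``p_value < p_threshold`` (raw p; a
    Benjamini-Hochberg column is provided alongside).

    Returns a DataFrame with columns log2fc, p_value, p_adj, called.
    """
    if expr.unit != TPM_UNIT:
        raise ValueError("simple_de expects a TPM matrix")
    wt = _group_columns(expr, wt_samples, "WT")
    ko = _group_columns(expr, ko_samples, "KO")
    if wt.shape[1] < 2 or ko.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicates")

    lfc = log2fc(expr, wt_samples, ko_samples, pseudocount)
    lwt = np.log2(wt.to_numpy(dtype=float) + pseudocount)
    lko = np.log2(ko.to_numpy(dtype=float) + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant features trigger scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(lko, lwt, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # Welch is undefined when both groups are constant: identical constants
    # are a perfect null (p=1), different constants a perfect separation.
    zero_var = (lwt.var(axis=1) == 0) & (lko.var(axis=1) == 0)
    same_mean = np.isclose(lwt.mean(axis=1), lko.mean(axis=1))
    p = np.where(zero_var & same_mean, 1.0, p)
    p = np.where(zero_var & ~same_mean, 0.0, p)
    p = np.nan_to_num(p, nan=1.0)

    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "p_value": p,
            "p_adj": _bh_adjust(p),
        },
        index=expr.feature_ids,
    )
    out["called"] = (out["log2fc"].abs() > lfc_threshold) & (out["p_value"] < p_threshold)
    return out
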