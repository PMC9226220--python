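"""Embryo stage-specificity scoring and staging clusters.

A gene's stage profile (mean TPM per ordered developmental stage) is scored
with an entropy-based specificity measure: the profile is normalized to a
probability vector ``p`` and, for each stage ``s``,

    JSsp_s = 1 - sqrt(JSD(p, e_s))

where ``e_s`` is the point mass at stage ``s`` and JSD the Jensen-Shannon
divergence in bits.  The score is the maximum over stages; it is 1 exactly
when the gene is expressed at a single stage and falls toward 0 as
expression spreads.  Genes above a score threshold are clustered with
K-means on max-scaled profiles into ordered stage clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import rankstats
from .containers import ExpressionMatrix, SampleSheet


def stage_profiles(
    expr: ExpressionMatrix,
    samples: SampleSheet,
    stages: list[str] | None = None,
    condition: str | None = "WT",
) -> pd.DataFrame:
    """Per-gene mean expression across ordered stages (genes x stages).

    ``stages`` fixes the stage order; by default stages appear in sample
    sheet order of first occurrence.  ``condition`` restricts the averaged
    samples (stage profiles are built from wild-type samples unless told
    otherwise); pass ``None`` to use all samples.
    """
    tab = samples.table.loc[[s for s in expr.sample_ids if s in samples.table.index]]
    if condition is not None:
        tab = tab[tab["condition"] == condition]
    if stages is None:
        stages = list(dict.fromkeys(tab["stage"].astype(str)))
    cols = {}
    for st in stages:
        ids = tab.index[tab["stage"].astype(str) == str(st)].tolist()
        if not ids:
            raise ValueError(f"no samples for stage {st!r}")
        cols[str(st)] = expr.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def _entropy_term(x: np.ndarray) -> np.ndarray:
    """Elementwise -x*log2(x) with 0*log(0) = 0."""
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = -x[pos] * np.log2(x[pos])
    return out


def specificity_score(profile: np.ndarray) -> tuple[float, int]:
    """Specificity score and 0-based argmax stage of one profile.

    Raises on an all-zero profile (such genes are flagged and excluded
    upstream).  Ties in the per-stage score resolve to the earliest stage.
    """
    scores = specificity_scores(np.asarray(profile, dtype=float)[None, :])
    return float(scores["score"][0]), int(scores["argmax_stage"][0])


def specificity_scores(profiles: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized specificity scoring of a genes x stages array.

    Returns arrays ``score`` (max over stages of 1 - sqrt(JSD)) and
    ``argmax_stage`` (0-based, earliest stage on ties).

    The per-stage JSD against the point mass ``e_s`` reduces to
    ``H(m_s) - H(p)/2`` with ``m_s = (p + e_s)/2``, and ``H(m_s)`` differs
    from ``H(p/2)``'s sum only in stage ``s``'s term, giving an O(G*S)
    evaluation.
    """
    p = np.asarray(profiles, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("profiles must be a 2-D array with >= 2 stages")
    if (p < 0).any():
        raise ValueError("profiles must be nonnegative")
    row_sum = p.sum(axis=1)
    if (row_sum == 0).any():
        raise ValueError("all-zero profile cannot be scored")
    p = p / row_sum[:, None]

    h_p = _entropy_term(p).sum(axis=1)  # H(p), bits
    half_terms = _entropy_term(p / 2.0)  # -p_j/2 * log2(p_j/2)
    base = half_terms.sum(axis=1)
    # H(m_s) = base - term_s(p_s/2) + term((p_s + 1)/2)
    h_m = base[:, None] - half_terms + _entropy_term((p + 1.0) / 2.0)
    jsd = h_m - h_p[:, None] / 2.0
    jsd = np.clip(jsd, 0.0, 1.0)
    per_stage = 1.0 - np.sqrt(jsd)
    return {
        "score": per_stage.max(axis=1),
        "argmax_stage": per_stage.argmax(axis=1),  # argmax -> first max
    }


def score_profiles(profiles: pd.DataFrame, log_transform: bool = False) -> pd.DataFrame:
    """Score every gene profile; all-zero genes are flagged, not scored.

    ``log_transform`` applies log2(x + 1) to the profile before scoring
    (a softer variant; the default scores the raw stage means).

    Returns a DataFrame with columns score, argmax_stage, scored.
    """
    vals = profiles.to_numpy(dtype=float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    nonzero = vals.sum(axis=1) > 0
    score = np.full(len(profiles), np.nan)
    argmax = np.full(len(profiles), "", dtype=object)
    if nonzero.any():
        res = specificity_scores(vals[nonzero])
        score[nonzero] = res["score"]
        stage_labels = np.asarray(profiles.columns, dtype=object)
        argmax[nonzero] = stage_labels[res["argmax_stage"]]
    return pd.DataFrame(
        {"score": score, "argmax_stage": argmax, "scored": nonzero},
        index=profiles.index,
    )


@dataclass
class StageClustering:
    """Per-gene specificity score, best stage and K-means cluster label
    (1..K for genes above the threshold, 0 for unassigned)."""

    table: pd.DataFrame  # columns: score, argmax_stage, cluster
    centroids: pd.DataFrame  # cluster x stage centroid matrix (max-scaled units)


def cluster_stage_genes(
    profiles: pd.DataFrame,
    scores: pd.DataFrame,
    *,
    threshold: float = 0.2,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
) -> StageClustering:
    """K-means staging of genes whose specificity score passes ``threshold``.

    Passing genes' profiles are row-rescaled to max = 1 and clustered with
    Euclidean K-means (``n_restarts`` initializations, best inertia kept).
    Clusters are relabeled 1..K by the stage index at their centroid's
    maximum, ascending, so labels are deterministic given the seed.
    """
    passing = scores.index[(scores["scored"]) & (scores["score"] > threshold)]
    if len(passing) < k:
        raise ValueError(f"only {len(passing)} genes pass the threshold; need >= {k}")
    mat = profiles.loc[passing].to_numpy(dtype=float)
    mat = mat / mat.max(axis=1, keepdims=True)

    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(mat)

    centroid_peak = km.cluster_centers_.argmax(axis=1)
    order = np.lexsort((np.arange(k), centroid_peak))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw_labels]

    table = scores.copy()
    table["cluster"] = 0
    table.loc[passing, "cluster"] = labels
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=np.arange(1, k + 1), columns=profiles.columns
    )
    centroids.index.name = "cluster"
    return StageClustering(table=table, centroids=centroids)


def cluster_fc_analysis(
    clustering: StageClustering,
    lfc: pd.Series,
    side: str = rankstats.TWO_SIDED,
) -> pd.DataFrame:
    """Per-cluster fold-change summary and Mann-Whitney test.

    Each cluster's member log2 fold changes are summarized (quartiles) and
    compared against the fold changes of all *other* clustered genes with a
    two-sample Mann-Whitney U test (the complement convention).  Clusters
    with < 2 members with a defined lfc are reported with NA statistics.
    """
    tab = clustering.table
    clustered = tab.index[tab["cluster"] > 0]
    lfc = lfc.reindex(clustered).dropna()
    rows = []
    for c in sorted(tab.loc[clustered, "cluster"].unique()):
        members = lfc.index.intersection(tab.index[tab["cluster"] == c])
        others = lfc.index.difference(members)
        vals = lfc.loc[members]
        row = {
            "cluster": int(c),
            "n_genes": len(members),
            "q1": vals.quantile(0.25) if len(members) else np.nan,
            "median_lfc": vals.median() if len(members) else np.nan,
            "q3": vals.quantile(0.75) if len(members) else np.nan,
        }
        if len(members) >= 2 and len(others) >= 1:
            res = rankstats.mann_whitney_u(vals.to_numpy(), lfc.loc[others].to_numpy(), side)
            row["u_statistic"] = res.statistic
            row["p_value"] = res.p_value
        else:
            row["u_statistic"] = np.nan
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def ltr_class_test(
    norm: ExpressionMatrix,
    families: pd.Series,
    samples: SampleSheet,
    *,
    wt_condition: str = "WT",
    ko_condition: str = "KO",
    side: str = rankstats.TWO_SIDED,
) -> pd.DataFrame:
    """Per repeat family/class paired test of KO vs WT expression.

    For each member feature the KO-sample mean is paired with its WT-sample
    mean (on the normalized 0-1 values), and members of a family form the
    pairs of a Wilcoxon signed-rank test.  ``side='greater'`` tests for
    up-regulation in KO.
    """
    wt_ids = samples.samples_where(condition=wt_condition)
    ko_ids = samples.samples_where(condition=ko_condition)
    if not wt_ids or not ko_ids:
        raise ValueError("both conditions need samples")
    missing = [s for s in wt_ids + ko_ids if s not in norm.sample_ids]
    if missing:
        raise ValueError(f"samples missing from matrix: {missing}")
    fam = families.reindex(norm.feature_ids)
    if fam.isna().any():
        raise ValueError("every member feature needs a family label")
    wt_mean = norm.values[wt_ids].mean(axis=1)
    ko_mean = norm.values[ko_ids].mean(axis=1)
    rows = []
    for family, members in fam.groupby(fam).groups.items():
        if len(members) < 2:
            raise ValueError(f"family {family!r} has < 2 members")
        res = rankstats.wilcoxon_signed_rank(
            ko_mean.loc[members].to_numpy(), wt_mean.loc[members].to_numpy(), side
        )
        rows.append(
            {
                "family": family,
                "n_members": len(members),
                "mean_delta": float((ko_mean.loc[members] - wt_mean.loc[members]).mean()),
                "w_statistic": res.statistic,
                "p_value": res.p_value,
                "n_effective": res.n_effective,
            }
        )
    return pd.DataFrame(rows).set_index("family")
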