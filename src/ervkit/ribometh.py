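"""RiboMeth-seq 2'-O-methylation quantification.

In a RiboMeth-seq library, alkaline/metal-ion fragmentation cleaves the RNA
backbone at random phosphodiester bonds, but a 2'-O-methylated ribose
protects the bond immediately 3' of it.  Counting fragment ends per bond
therefore yields a cleavage profile with dips at methylated positions.  The
MethScore at bond ``i`` contrasts the bond's combined end count ``n(i)``
with weighted averages of its flanking bonds:

    score(i) = max(0, 1 - 2 * n(i) / (Lbar + Rbar))

where ``Lbar``/``Rbar`` are weighted means of up to ``w`` bonds to the left
and right (linearly decreasing weights by default, truncated at profile
edges).  A fully protected bond scores 1; uniform cleavage scores 0.

The score at bond ``i`` is reported at nucleotide position ``i`` — the
methylated ribose protecting the bond 3' of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import rankstats
from .containers import EndCountProfile


def default_weights(window: int) -> np.ndarray:
    """Linearly decreasing flank weights: weight_d = (w - d + 1)/w for
    offset d = 1..w."""
    if window < 1:
        raise ValueError("window must be >= 1")
    return (window - np.arange(window)) / window


def methscore(
    profile: EndCountProfile,
    window: int = 6,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bond MethScore track.

    Returns a DataFrame indexed by 1-based position (bond i, reported at
    nucleotide i) with columns ``n`` (combined end count), ``score_raw``
    (may be negative), ``score`` (floored at 0) and ``coverage_ok``
    (False where the score is undefined: no flanking bonds on one side, or
    zero flanking coverage).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if weights is None:
        weights = default_weights(window)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (window,) or (weights <= 0).any():
        raise ValueError("weights must be positive with one entry per offset")

    n = profile.n.astype(float)
    n_bonds = len(n)
    lbar = np.full(n_bonds, np.nan)
    rbar = np.full(n_bonds, np.nan)
    for i in range(n_bonds):
        left_d = np.arange(1, min(window, i) + 1)
        right_d = np.arange(1, min(window, n_bonds - 1 - i) + 1)
        if len(left_d):
            wl = weights[left_d - 1]
            lbar[i] = (wl * n[i - left_d]).sum() / wl.sum()
        if len(right_d):
            wr = weights[right_d - 1]
            rbar[i] = (wr * n[i + right_d]).sum() / wr.sum()

    denom = lbar + rbar
    defined = np.isfinite(denom) & (denom > 0)
    raw = np.full(n_bonds, np.nan)
    raw[defined] = 1.0 - 2.0 * n[defined] / denom[defined]
    score = np.where(defined, np.maximum(raw, 0.0), np.nan)

    return pd.DataFrame(
        {
            "n": profile.n,
            "score_raw": raw,
            "score": score,
            "coverage_ok": defined,
        },
        index=pd.RangeIndex(1, profile.length, name="position"),
    )


def compare_methscores(
    wt: pd.DataFrame,
    ko: pd.DataFrame,
    sites: list[int] | None = None,
    side: str = rankstats.TWO_SIDED,
) -> tuple[rankstats.TestResult, pd.DataFrame]:
    """Paired Wilcoxon signed-rank comparison of two MethScore tracks.

    Tracks must come from the same reference (equal positions).  The test
    pairs the per-position scores over all positions defined in both tracks
    (or over ``sites`` if supplied); ``side='greater'`` tests for higher
    scores in WT (i.e. methylation loss in KO).  Also returns the per-site
    table with columns score_wt, score_ko and delta = score_ko - score_wt.
    """
    if not wt.index.equals(ko.index):
        raise ValueError("tracks come from different references (positions differ)")
    both = wt.index[(wt["coverage_ok"] & ko["coverage_ok"])]
    if sites is not None:
        sites_idx = pd.Index(sites)
        missing = sites_idx.difference(both)
        if len(missing):
            raise ValueError(f"sites undefined in one of the tracks: {missing.tolist()[:5]}")
        both = sites_idx
    table = pd.DataFrame(
        {
            "score_wt": wt.loc[both, "score"],
            "score_ko": ko.loc[both, "score"],
        },
        index=both,
    )
    table["delta"] = table["score_ko"] - table["score_wt"]
    res = rankstats.wilcoxon_signed_rank(
        table["score_wt"].to_numpy(), table["score_ko"].to_numpy(), side
    )
    return res, table


def detect_sites(track: pd.DataFrame, k: int) -> list[int]:
    """Positions of the k highest MethScores (ties to the lower position)."""
    defined = track[track["coverage_ok"]]
    if k > len(defined):
        raise ValueError(f"k={k} exceeds the {len(defined)} defined positions")
    # Index is the 1-based position and is ascending; a stable sort by
    # descending score therefore breaks ties toward the lower position.
    order = defined.sort_values("score", ascending=False, kind="mergesort")
    return order.index[:k].tolist()
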