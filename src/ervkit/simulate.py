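"""Synthetic data generators for every stage of the analysis stack.

Each generator emits inputs with the statistical structure the downstream
method assumes, together with a machine-readable truth table, so recovery
can be tested without any sequencing download:

* ``simulate_bulk`` — negative-binomial bulk counts over embryo stages and
  WT/KO conditions, with planted stage-specific gene clusters (contiguous
  stage blocks), repeat families, a KO-up 2C/ERV program and a KO-down
  ribosomal-protein program.
* ``simulate_sc`` — a two-subpopulation (ES-like / 2C-like) cell x gene UMI
  matrix with anti-correlated ERV and ribosomal-protein expression.
* ``simulate_fragments`` — alkaline-fragmentation molecules with per-bond
  Bernoulli cleavage and protection at methylated bonds, size-selected and
  tallied into 5'/3' end counts.
* ``simulate_clip`` — paired CLIP/control Poisson libraries with planted
  per-category enrichment folds.

All draws flow from a single seeded ``numpy.random.Generator`` per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CellMatrix,
    EndCountProfile,
    ExpressionMatrix,
    FeatureTable,
    SampleSheet,
)

# ---------------------------------------------------------------------------
# Bulk RNA-seq
# ---------------------------------------------------------------------------

#: Repeat family names carried by the simulated annotation; the first two
#: are the 2C-stage ERV families that respond to the knockout.
REPEAT_FAMILIES = ("MERVL-int", "MT2_Mm", "ERVL", "ERVK", "ERV1", "MaLR", "L1", "B1")


@dataclass
class BulkSimSpec:
    """Design of the simulated bulk experiment.

    Samples span ``n_stages`` ordered embryo stages x {WT, KO} x
    ``replicates``.  Five contiguous-stage-block gene clusters are planted
    (cluster k elevated in stages 2k-1..2k for the default 10 stages);
    cluster 1 is the 2C cluster and carries ``ko_lfc_2c``, the last cluster
    doubles as the ribosomal-protein set and carries ``ko_lfc_ribo``.  The
    2C ERV repeat families (MERVL-int, MT2_Mm) share the 2C stage block and
    KO effect.
    """

    n_stages: int = 10
    n_clusters: int = 5
    genes_per_cluster: int = 200
    n_background_genes: int = 2000
    n_repeat_families: int = 8
    members_per_family: int = 50
    base_mean: float = 50.0
    cluster_fold: float = 10.0  # elevation of a cluster gene in its stages
    nb_dispersion: float = 0.1
    ko_lfc_2c: float = 2.0
    ko_lfc_ribo: float = -1.0
    replicates: int = 3
    noiseless: bool = False  # emit rounded expected means instead of NB draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("need at least 2 stages")
        if self.n_clusters < 1 or self.n_clusters > self.n_stages:
            raise ValueError("n_clusters must be in [1, n_stages]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.base_mean <= 0 or self.cluster_fold <= 0:
            raise ValueError("means and folds must be positive")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.n_repeat_families < 1 or self.n_repeat_families > len(REPEAT_FAMILIES):
            raise ValueError(
                f"n_repeat_families must be in [1, {len(REPEAT_FAMILIES)}]"
            )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2 (Poisson when
    the dispersion is 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion  # gamma shape
    # NB as a gamma-Poisson mixture keeps the parameterization explicit.
    lam = rng.gamma(shape=size_param, scale=mean * dispersion)
    return rng.poisson(lam)


def _stage_blocks(n_stages: int, n_clusters: int) -> list[np.ndarray]:
    """Contiguous, near-equal blocks of stage indices, one per cluster."""
    bounds = np.linspace(0, n_stages, n_clusters + 1).round().astype(int)
    return [np.arange(bounds[k], bounds[k + 1]) for k in range(n_clusters)]


def simulate_bulk(
    spec: BulkSimSpec,
) -> tuple[ExpressionMatrix, FeatureTable, SampleSheet, pd.DataFrame]:
    """Draw the bulk count matrix, annotation, sample sheet and truth table.

    The truth table is feature-indexed with columns ``kind`` (cluster /
    background / repeat), ``cluster`` (1..K or 0), ``family``, ``gene_set``
    (``2C`` / ``ribosomal_protein`` / empty) and ``ko_lfc``.
    """
    rng = np.random.default_rng(spec.seed)
    S, K = spec.n_stages, spec.n_clusters
    blocks = _stage_blocks(S, K)

    feature_ids: list[str] = []
    rows_class: list[str] = []
    rows_family: list[str] = []
    lengths: list[int] = []
    truth_rows: list[dict] = []
    profiles: list[np.ndarray] = []  # per-stage relative mean (x base_mean)
    ko_lfc: list[float] = []

    def add_feature(fid, fclass, family, profile, lfc, kind, cluster, gene_set):
        feature_ids.append(fid)
        rows_class.append(fclass)
        rows_family.append(family)
        lengths.append(int(rng.integers(500, 5000)))
        profiles.append(profile)
        ko_lfc.append(lfc)
        truth_rows.append(
            {
                "feature_id": fid,
                "kind": kind,
                "cluster": cluster,
                "family": family,
                "gene_set": gene_set,
                "ko_lfc": lfc,
            }
        )

    flat = np.ones(S)
    for k in range(K):
        profile = np.ones(S)
        profile[blocks[k]] = spec.cluster_fold
        if k == 0:
            lfc, gene_set = spec.ko_lfc_2c, "2C"
        elif k == K - 1:
            lfc, gene_set = spec.ko_lfc_ribo, "ribosomal_protein"
        else:
            lfc, gene_set = 0.0, ""
        for g in range(spec.genes_per_cluster):
            add_feature(f"cluster{k + 1}_gene{g + 1}", "gene", "", profile, lfc,
                        "cluster", k + 1, gene_set)
    for g in range(spec.n_background_genes):
        add_feature(f"bg_gene{g + 1}", "gene", "", flat, 0.0, "background", 0, "")

    erv_profile = np.ones(S)
    erv_profile[blocks[0]] = spec.cluster_fold
    for f in range(spec.n_repeat_families):
        family = REPEAT_FAMILIES[f]
        is_2c_erv = family in ("MERVL-int", "MT2_Mm")
        profile = erv_profile if is_2c_erv else flat
        lfc = spec.ko_lfc_2c if is_2c_erv else 0.0
        for m in range(spec.members_per_family):
            add_feature(f"{family}_m{m + 1}", "repeat", family, profile, lfc,
                        "repeat", 0, "2C" if is_2c_erv else "")

    sample_ids, conds, stages, reps = [], [], [], []
    for st in range(1, S + 1):
        for cond in ("WT", "KO"):
            for r in range(1, spec.replicates + 1):
                sample_ids.append(f"{cond}_s{st:02d}_r{r}")
                conds.append(cond)
                stages.append(f"s{st:02d}")
                reps.append(r)
    sheet = pd.DataFrame(
        {"condition": conds, "stage": stages, "replicate": reps},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    prof = np.asarray(profiles)  # features x stages
    lfc_arr = np.asarray(ko_lfc)
    stage_idx = np.array([int(s[1:]) - 1 for s in stages])
    is_ko = np.array([c == "KO" for c in conds])
    mu = spec.base_mean * prof[:, stage_idx]
    mu = mu * np.where(is_ko[None, :], 2.0 ** lfc_arr[:, None], 1.0)

    if spec.noiseless:
        counts = np.rint(mu).astype(int)
    else:
        counts = _nb_draw(rng, mu, spec.nb_dispersion)

    values = pd.DataFrame(
        counts, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids
    )
    features = FeatureTable(
        pd.DataFrame(
            {"feature_class": rows_class, "family": rows_family, "length": lengths},
            index=pd.Index(feature_ids, name="feature_id"),
        )
    )
    truth = pd.DataFrame(truth_rows).set_index("feature_id")
    return ExpressionMatrix(values, unit="counts"), features, SampleSheet(sheet), truth


# ---------------------------------------------------------------------------
# Single-cell RNA-seq
# ---------------------------------------------------------------------------

@dataclass
class ScSimSpec:
    """Two-subpopulation single-cell design.

    ES-like cells put ``f_rp_es`` of their transcript mass in the ribosomal
    protein set and ``f_erv_es`` in the ERV set; 2C-like cells raise the
    ERV fraction to ``f_erv_2c`` and scale the RP fraction down by
    ``1 - anticorr_strength`` (the lost mass is absorbed by the background
    genes, so at ``anticorr_strength = 0`` the RP program is untouched).
    """

    n_cells_es: int = 400
    n_cells_2c: int = 60
    n_erv_genes: int = 50
    n_rp_genes: int = 100
    n_other_genes: int = 1000
    n_mito_genes: int = 10
    depth_mean: float = 3000.0
    mito_fraction_range: tuple[float, float] = (0.02, 0.10)
    f_erv_es: float = 0.002
    f_erv_2c: float = 0.05
    f_rp_es: float = 0.30
    anticorr_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_es + self.n_cells_2c < 1:
            raise ValueError("need at least one cell")
        if min(self.n_erv_genes, self.n_rp_genes, self.n_other_genes) < 1:
            raise ValueError("each gene group needs at least one gene")
        if not 0.0 <= self.anticorr_strength <= 1.0:
            raise ValueError("anticorr_strength must be in [0, 1]")
        lo, hi = self.mito_fraction_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


def simulate_sc(spec: ScSimSpec) -> tuple[CellMatrix, dict[str, list[str]], pd.Series]:
    """Draw the UMI matrix, the ERV / RP gene sets and true cell labels.

    Per cell, a depth is drawn Poisson around ``depth_mean`` and UMIs are
    distributed multinomially over gene weights set by the cell's
    subpopulation; within each gene group, relative weights are a fixed
    lognormal draw shared across cells.
    """
    rng = np.random.default_rng(spec.seed)
    erv_genes = [f"ERV_{i + 1}" for i in range(spec.n_erv_genes)]
    rp_genes = [f"Rp_{i + 1}" for i in range(spec.n_rp_genes)]
    mito_genes = [f"mt-{i + 1}" for i in range(spec.n_mito_genes)]
    other_genes = [f"Gene_{i + 1}" for i in range(spec.n_other_genes)]
    genes = erv_genes + rp_genes + mito_genes + other_genes

    def group_weights(n):
        w = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        return w / w.sum()

    w_erv = group_weights(spec.n_erv_genes)
    w_rp = group_weights(spec.n_rp_genes)
    w_mito = group_weights(spec.n_mito_genes)
    w_other = group_weights(spec.n_other_genes)

    labels = ["ES"] * spec.n_cells_es + ["2C"] * spec.n_cells_2c
    cell_ids = [f"cell_{i + 1}" for i in range(len(labels))]
    rng.shuffle(labels)

    counts = np.zeros((len(labels), len(genes)), dtype=int)
    lo, hi = spec.mito_fraction_range
    for i, lab in enumerate(labels):
        f_mito = rng.uniform(lo, hi)
        f_erv = spec.f_erv_2c if lab == "2C" else spec.f_erv_es
        f_rp = spec.f_rp_es * (1.0 - (spec.anticorr_strength if lab == "2C" else 0.0))
        f_other = 1.0 - f_mito - f_erv - f_rp
        if f_other <= 0:
            raise ValueError("gene-set fractions exceed 1; reduce set fractions")
        p = np.concatenate(
            [f_erv * w_erv, f_rp * w_rp, f_mito * w_mito, f_other * w_other]
        )
        depth = rng.poisson(spec.depth_mean)
        if depth > 0:
            counts[i] = rng.multinomial(depth, p)

    matrix = CellMatrix(
        pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell_id"), columns=genes),
        mito_genes=set(mito_genes),
    )
    gene_sets = {"ERV": erv_genes, "ribosomal_protein": rp_genes}
    truth = pd.Series(labels, index=matrix.cell_ids, name="population")
    return matrix, gene_sets, truth


# ---------------------------------------------------------------------------
# RiboMeth-seq fragments
# ---------------------------------------------------------------------------

@dataclass
class RiboSimSpec:
    """Alkaline-fragmentation design for one rRNA-like reference.

    Each molecule is cleaved independently at every internucleotide bond
    with probability ``cleavage_rate``, reduced to ``cleavage_rate *
    protection`` at bonds 3' of a methylated nucleotide (``protection`` is
    the fraction of baseline cleavage retained: 0 = full protection,
    1 = no methylation effect).  Maximal uncut intervals are the fragments;
    only those with length in [size_min, size_max] survive size selection,
    matching the 30-200 nt library range.
    """

    ref_length: int = 4000
    n_sites: int = 20
    methylated_sites: list[int] | None = None  # 1-based nucleotide positions
    cleavage_rate: float = 0.01
    protection: float = 0.2
    n_molecules: int = 50_000
    size_min: int = 30
    size_max: int = 200
    site_margin: int = 7  # keep planted sites this far from both ends
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref_length < 10:
            raise ValueError("reference too short")
        if not 0.0 <= self.protection <= 1.0:
            raise ValueError("protection must be in [0, 1]")
        if not 0.0 < self.cleavage_rate < 1.0:
            raise ValueError("cleavage_rate must be in (0, 1)")
        if self.size_min < 1 or self.size_max < self.size_min:
            raise ValueError("invalid size-selection window")
        if self.methylated_sites is not None:
            lo, hi = self.site_margin, self.ref_length - 1 - self.site_margin
            bad = [s for s in self.methylated_sites if not lo <= s <= hi]
            if bad:
                raise ValueError(f"methylated sites outside interior margin: {bad[:5]}")


@dataclass
class FragmentSimResult:
    sites: list[int]  # planted methylated nucleotide positions (1-based)
    counts_5p: np.ndarray  # per-nucleotide 5' fragment-end counts, 1-based
    counts_3p: np.ndarray
    raw_counts_5p: np.ndarray  # before size selection
    raw_counts_3p: np.ndarray
    n_fragments_total: int  # before size selection
    n_fragments_kept: int

    def profile(self, reference_id: str = "rRNA_synthetic") -> EndCountProfile:
        length = len(self.counts_5p)
        return EndCountProfile.from_end_counts(
            reference_id, length, self.counts_5p, self.counts_3p
        )


def simulate_fragments(spec: RiboSimSpec) -> FragmentSimResult:
    """Simulate fragmentation and tally 5'/3' fragment ends per nucleotide.

    Before size selection the number of fragments equals both the total 5'
    and total 3' end counts (every fragment has one of each).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.ref_length
    if spec.methylated_sites is None:
        lo, hi = spec.site_margin, L - 1 - spec.site_margin
        sites = sorted(rng.choice(np.arange(lo, hi + 1), size=spec.n_sites, replace=False))
        sites = [int(s) for s in sites]
    else:
        sites = sorted(int(s) for s in spec.methylated_sites)

    # Bond b (1-based, 1..L-1) sits 3' of nucleotide b; methylation at
    # nucleotide s protects bond s.
    p_bond = np.full(L - 1, spec.cleavage_rate)
    p_bond[np.asarray(sites) - 1] *= spec.protection

    c5 = np.zeros(L, dtype=np.int64)
    c3 = np.zeros(L, dtype=np.int64)
    raw5 = np.zeros(L, dtype=np.int64)
    raw3 = np.zeros(L, dtype=np.int64)
    n_total = 0
    n_kept = 0

    chunk = 2000
    for start in range(0, spec.n_molecules, chunk):
        m = min(chunk, spec.n_molecules - start)
        cuts = rng.random((m, L - 1)) < p_bond
        for row in cuts:
            cut_bonds = np.flatnonzero(row) + 1  # bond index = left nucleotide
            starts = np.concatenate(([1], cut_bonds + 1))
            ends = np.concatenate((cut_bonds, [L]))
            n_total += len(starts)
            np.add.at(raw5, starts - 1, 1)
            np.add.at(raw3, ends - 1, 1)
            lengths = ends - starts + 1
            keep = (lengths >= spec.size_min) & (lengths <= spec.size_max)
            n_kept += int(keep.sum())
            np.add.at(c5, starts[keep] - 1, 1)
            np.add.at(c3, ends[keep] - 1, 1)

    return FragmentSimResult(
        sites=sites,
        counts_5p=c5,
        counts_3p=c3,
        raw_counts_5p=raw5,
        raw_counts_3p=raw3,
        n_fragments_total=n_total,
        n_fragments_kept=n_kept,
    )


# ---------------------------------------------------------------------------
# CLIP / control library pair
# ---------------------------------------------------------------------------

def _default_clip_folds() -> dict[str, float]:
    return {
        "snoRNA": 8.0,
        "rRNA": 4.0,
        "pre_let7": 2.0,
        "protein_coding": 1.0,
        "MERVL-int": 1.0,
        "MT2_Mm": 1.0,
        "ERVL": 1.0,
    }


@dataclass
class ClipSimSpec:
    """Paired CLIP/control Poisson libraries with planted category folds.

    Baseline (control) abundances are lognormal per feature; the categories
    carrying an enrichment fold are given a small share
    (``enriched_fraction`` each) of the baseline library so that rescaling
    the CLIP library to the common depth barely shifts unenriched
    categories.
    """

    category_enrichment: dict[str, float] = field(default_factory=_default_clip_folds)
    n_features_per_category: int = 50
    library_depth: int = 1_000_000
    enriched_fraction: float = 0.004
    feature_length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.category_enrichment:
            raise ValueError("need at least one category")
        if any(f <= 0 for f in self.category_enrichment.values()):
            raise ValueError("enrichment folds must be positive")
        if self.n_features_per_category < 1:
            raise ValueError("need at least one feature per category")
        if self.library_depth < 1:
            raise ValueError("library depth must be positive")
        n_enriched = sum(1 for f in self.category_enrichment.values() if f != 1.0)
        if n_enriched * self.enriched_fraction >= 0.5:
            raise ValueError("enriched_fraction too large for this many categories")


def simulate_clip(
    spec: ClipSimSpec,
) -> tuple[pd.DataFrame, FeatureTable, pd.Series]:
    """Draw the CLIP/control count pair, annotation, and true folds.

    Returns ``(counts, features, truth)``: counts is a feature x
    {clip, control} integer DataFrame plus a ``category`` column; truth maps
    category -> planted fold.
    """
    rng = np.random.default_rng(spec.seed)
    cats = list(spec.category_enrichment)
    folds = np.array([spec.category_enrichment[c] for c in cats])
    enriched = folds != 1.0
    n_enriched = int(enriched.sum())
    n_flat = len(cats) - n_enriched
    flat_fraction = (
        (1.0 - n_enriched * spec.enriched_fraction) / n_flat if n_flat else 1.0 / len(cats)
    )

    feature_ids, categories, base = [], [], []
    for ci, cat in enumerate(cats):
        frac = spec.enriched_fraction if enriched[ci] else flat_fraction
        w = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_features_per_category)
        w = w / w.sum() * frac
        for fi in range(spec.n_features_per_category):
            feature_ids.append(f"{cat}_{fi + 1}")
            categories.append(cat)
            base.append(w[fi])
    base = np.asarray(base)
    base = base / base.sum()

    fold_per_feature = np.array([spec.category_enrichment[c] for c in categories])
    clip_mean = base * fold_per_feature
    clip_mean = clip_mean / clip_mean.sum()

    control = rng.poisson(base * spec.library_depth)
    clip = rng.poisson(clip_mean * spec.library_depth)

    counts = pd.DataFrame(
        {"clip": clip, "control": control, "category": categories},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    features = FeatureTable(
        pd.DataFrame(
            {
                "feature_class": "repeat",
                "family": categories,
                "length": spec.feature_length,
            },
            index=pd.Index(feature_ids, name="feature_id"),
        )
    )
    truth = pd.Series(spec.category_enrichment, name="fold")
    truth.index.name = "category"
    return counts, features, truth
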