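# Methods

This note documents the models, parameter choices and numerical
conventions behind `ervkit`, and what the synthetic-data generators do and
do not emulate.

## Quantification

**TPM.** Per sample, counts are divided by feature length (nt) to a rate
and rates rescaled to sum to 1e6; all-zero samples stay zero. Because TPM
is a compositional unit, a strong planted up-shift in one gene group
slightly deflates every other feature's TPM in that condition — visible in
simulated knockouts as a small negative background log2 fold change. The
pipeline order is fixed as TPM-then-aggregate: summing member TPMs gives
family abundances on the same per-sample scale, whereas aggregating counts
first and then length-normalizing would need an effective family length
that is not well defined for heterogeneous members.

**0-1 normalization.** Per feature row, (x − min)/(max − min) across all
samples; constant rows map to zeros rather than NaN so downstream rank
tests stay total. Normalization is applied at whatever aggregation level
the caller passes in (member level by default).

**Fold change and DE.** log2((mean_KO + c)/(mean_WT + c)) with pseudocount
c = 1 TPM (configurable; no published value exists for it). The simple DE
caller runs Welch's t on log2(TPM + c) across replicates — an explicit
lightweight stand-in for a count-model fit, not a reimplementation of one
— and calls features at |log2FC| > 1 and raw p < 0.05 (Benjamini-Hochberg
adjusted values are emitted alongside; the call thresholds use raw p by
convention). When both groups are constant the t statistic is undefined:
equal constants are reported as p = 1, unequal constants as p = 0.

## Stage specificity and staging clusters

The specificity score follows the entropy-based measure for tissue/stage
specificity: with p the normalized profile over S ordered stages and e_s
the point mass at stage s,

    JSsp_s = 1 − sqrt(JSD(p, e_s)),   score = max_s JSsp_s,

JSD in bits (log base 2, 0·log 0 ≡ 0), ties in the argmax resolved to the
earliest stage. The score is 1 exactly for single-stage profiles and
decreases as expression spreads; a uniform profile scores 0.322, 0.259,
0.219, 0.129 at S = 3, 4, 5, 10 — the 0.2 staging threshold excludes
uniform profiles only from S = 6 on, which is comfortably true for the
10-stage design used here. Scoring runs on raw stage-mean TPM by default;
a log2(TPM+1) variant is available (`score_profiles(log_transform=True)`).
Implementation note: JSD(p, e_s) reduces to H(m_s) − H(p)/2 with
m_s = (p + e_s)/2, and H(m_s) differs from the row-wise half-entropy sum
in a single term, giving an O(genes × stages) vectorized evaluation;
negative rounding residue is clipped at 0.

K-means (Euclidean, 10 restarts, fixed seed) runs on profiles row-rescaled
to max = 1 (mirroring per-gene heat-map scaling) for genes above the
threshold. Fitted clusters are relabeled 1..K by the stage index of their
centroid's maximum, ascending, so cluster labels are deterministic and
ordered along development.

Per-cluster fold-change statistics compare each cluster's member log2 fold
changes against those of **all other clustered genes** (two-sample
Mann-Whitney). The comparison set was a genuinely open choice (cluster vs
complement, vs all genes, or one-sample vs zero); the complement
convention matches the two-sample test named in the source analyses and is
the default, switchable via the `side`/caller arguments.

Per-family LTR tests pair each repeat member's KO-sample mean with its
WT-sample mean on the 0-1 normalized values and run a Wilcoxon signed-rank
across members. On compositional (TPM-derived) data, unshifted families
inherit a small negative KO-WT delta when another family is strongly
up-shifted; directional (one-sided "greater") testing is therefore the
meaningful form for up-regulation claims.

## Rank statistics

Mann-Whitney U and Wilcoxon signed-rank are implemented from first
principles. Tie-free inputs with total n ≤ 12 use exact enumeration of
the permutation (resp. sign-flip) null; otherwise a normal approximation
with midranks, tie correction and a ±0.5 continuity correction
(switchable) is used. Two-sided p-values are min(1, 2·min(tail p)).
Zero differences are dropped before signed-ranking; the all-zero case is
reported as p = 1 with n_effective = 0 rather than an error. The exact
path is verified in the test suite against independent
generating-function nulls; the approximation is accurate to 0.02 only for
reasonably balanced designs (e.g. 5 vs 5), which is why enumeration is
the default whenever it is feasible. Empirical type-I error at α = 0.05
is ~0.045 for both tests over 10,000 null simulations.

## CLIP enrichment

Enrichment is computed on TPM (library-size and length normalized), never
raw counts: log2((TPM_CLIP + a)/(TPM_control + a)), a = 1 TPM by default.
Per-category summaries are means/medians over member features. The
read-assignment contract mirrors the rDNA-first alignment convention:
reads hitting the ribosomal DNA repeating unit count toward rRNA with
priority; remaining reads count only when they map to a single genome
feature; multi-feature reads are discarded. Alignment itself is out of
scope — the contract operates on an abstract per-read hit table.

## RiboMeth-seq MethScore

The per-bond cleavage profile combines both end tallies:
n(b) = (3' ends at nucleotide b) + (5' ends at nucleotide b+1), bond b
being the phosphodiester bond between nucleotides b and b+1 (all in-memory
coordinates 1-based; bedgraph files on disk are 0-based half-open).
Methylation at nucleotide i protects bond i, and the score at bond i is
reported at nucleotide position i.

Several MethScore variants exist in the literature; this package computes
the weighted-flanking form

    score(i) = max(0, 1 − 2 n(i) / (L̄_i + R̄_i)),

with L̄/R̄ weighted averages over up to w flanking bonds per side, default
w = 6 with linearly decreasing weights (w−d+1)/w, truncated at profile
edges. Window and weights are configurable and recorded in output
headers. Scores are undefined (coverage_ok = False) at bonds lacking any
flanking bond on one side or with zero flanking coverage; negative raw
scores are floored at 0 with the raw value kept as a diagnostics column.
The score is invariant under uniform scaling of the profile and
non-increasing in n(i) at fixed flanks.

WT/KO comparison pairs per-position scores (all positions defined in both
tracks, or a supplied site list) in a Wilcoxon signed-rank test;
`side="greater"` tests for methylation loss in the second track.
Candidate sites are the top-k scores, ties to the lower position.

## Synthetic data generators

The generators define the study conditions; their defaults are fixed and
are not tuned per analysis.

**Bulk** (`BulkSimSpec`): 10 embryo stages × {WT, KO} × 3 replicates.
Five planted gene clusters of 200 genes occupy contiguous two-stage
blocks at 10× the base mean (50 counts) — block profiles give K-means a
recoverable truth — over 2,000 flat background genes. Counts are negative
binomial parameterized by mean and dispersion α (variance μ + αμ²,
α = 0.1, a typical RNA-seq replicate dispersion), drawn as a gamma-Poisson
mixture; α = 0 gives Poisson, and `noiseless=True` emits rounded expected
means for exactness checks. Cluster 1 doubles as the 2C program
(KO log2FC +2), cluster 5 as the ribosomal-protein set (KO log2FC −1).
Eight repeat families × 50 members carry RepeatMasker-style names; the
two 2C ERV families (MERVL-int, MT2_Mm) share the 2C stage block and KO
up-shift. A truth table (cluster, family, gene set, KO effect per
feature) is emitted alongside.

**Single cell** (`ScSimSpec`): 400 ES-like + 60 2C-like cells (the 2C-like
state is a minority state), Poisson depth around 3,000 UMIs, multinomial
UMI allocation over fixed lognormal within-group gene weights. ES-like
cells put 30% of mass in 100 RP genes and 0.2% in 50 ERV genes; 2C-like
cells raise the ERV fraction to 5% and scale the RP fraction by
(1 − anticorr_strength), default 0.8. The lost/gained mass is absorbed by
the 1,000 background genes, so at anticorr_strength = 0 the RP program is
genuinely untouched and the ERV-vs-RP correlation is a clean null.
Ten mt- genes with per-cell mito weight uniform in [0.02, 0.10] support
the QC path.

**Fragments** (`RiboSimSpec`): per molecule, every bond is cleaved
independently with probability 0.01, reduced by the protection factor
(default 0.2 = 20% of baseline cleavage retained) at the 20 planted
sites; fragments are maximal uncut intervals, and only those in the
30-200 nt library window are counted. The per-molecule Bernoulli model is
exact — no Poisson-process shortcut — so the protection semantics are
literal and Σ5' = Σ3' = fragment count holds before size selection.

**CLIP** (`ClipSimSpec`): Poisson libraries at depth 1e6; control means
proportional to lognormal baseline abundances, CLIP means to baseline ×
category fold (defaults snoRNA 8×, rRNA 4×, pre-let7 2×, others 1×).
Enriched categories get a small baseline share (0.4% each) so that
rescaling the CLIP library to common depth shifts unenriched categories by
only ~0.06 log2 units — the fold-recovery tolerance of ±0.3 covers this
compositional bias.

What the generators do **not** emulate: read-level sequencing (no FASTQ,
no sequencing error, no UMI collisions, no mapping ambiguity), batch or
library-preparation effects, gene-length bias beyond the TPM model,
overdispersion in single-cell data beyond multinomial sampling, and any
real locus structure. Passing recovery tests therefore demonstrates the
correctness and calibration of the statistical machinery under its own
assumptions, not performance on real sequencing data.

## Single-cell QC

Genes detected (count > 0) in fewer than 3 cells are dropped, with
detection evaluated on the pre-filter cell set; then cells with
nUMI < 500 or mitochondrial fraction > 0.2 are dropped (both thresholds
strict in those directions: nUMI exactly 500 and mito exactly 0.2
survive). One pass each, in that order, with no re-iteration. This order
makes the filter idempotent whenever surviving genes remain detected in
enough surviving cells — true for realistic matrices — but an adversarial
matrix whose boundary cell depends on a dropped gene's counts can shift on
a second application; re-iterating to a fixed point was deliberately not
adopted, matching the single-pass convention of standard droplet QC.

The "averaged expression" gene-set score is mean per-cell CP10K,
log2(1 + x)-normalized expression over the set's genes present in the
matrix (the exact scaling behind published per-cell color scales is not
stated anywhere; CP10K-log is the common droplet convention, and a
raw-mean mode is kept for sensitivity analysis). "Detectable ERV
expression" is ≥ 1 raw UMI in the set (configurable); correlations are
computed over detectable cells only.

## Determinism and outputs

All randomness flows from a single seeded `numpy.random.Generator` per
generator call; K-means restarts use a fixed seed; cluster labels are
ordered deterministically. CLI outputs embed the full run config in
comment headers, write a timestamp-free manifest (config, input SHA-256
digests, package version), and are byte-identical across reruns with the
same seed and inputs. Floats in TSV outputs use a fixed 6-significant-
digit format for that reason.

## Problem sizes

The default simulation sizes (3,400 bulk features × 60 samples; 460 cells
× 1,160 genes; 50,000 fragmented molecules on a 4,000-nt reference; 350
CLIP features at depth 1e6) were chosen as the smallest designs at which
each recovery target is comfortably identifiable — e.g. ~500 expected
cleavage events per unprotected bond, ~100 per protected bond — while a
full pipeline run stays in the tens of seconds on a laptop.
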