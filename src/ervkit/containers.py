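"""In-memory containers shared across the package.

The backbone tables are plain pandas objects wrapped with just enough
metadata to keep units and identities honest:

* ``FeatureTable`` — one row per quantified feature (gene or repeat copy)
  with its class, repeat family and effective length.
* ``ExpressionMatrix`` — features x samples values plus a unit tag
  (``counts`` / ``TPM`` / ``normalized01``).
* ``SampleSheet`` — sample condition (WT/KO), embryo stage and replicate.
* ``CellMatrix`` — cells x genes UMI counts with mitochondrial flags.
* ``EndCountProfile`` — per-bond cleavage counts along an rRNA reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE = "gene"
REPEAT = "repeat"


@dataclass
class FeatureTable:
    """Feature annotation: index = feature_id; columns feature_class,
    family (repeat family/class name, empty for genes), length (nt),
    and an optional free-form gene_set tag."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"feature_class", "family", "length"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"FeatureTable missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            dup = self.table.index[self.table.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        if (self.table["length"] < 1).any():
            raise ValueError("feature lengths must be >= 1")
        bad = ~self.table["feature_class"].isin([GENE, REPEAT])
        if bad.any():
            raise ValueError(
                f"unknown feature_class values: "
                f"{sorted(self.table.loc[bad, 'feature_class'].unique())}"
            )
        genes = self.table["feature_class"] == GENE
        if (self.table.loc[genes, "family"].fillna("") != "").any():
            raise ValueError("gene features must have an empty repeat family")
        if (self.table.loc[~genes, "family"].fillna("") == "").any():
            raise ValueError("repeat features must carry a family label")

    @property
    def lengths(self) -> pd.Series:
        return self.table["length"]

    @property
    def families(self) -> pd.Series:
        return self.table["family"]

    def ids(self) -> pd.Index:
        return self.table.index


@dataclass
class SampleSheet:
    """Sample annotation: index = sample_id; columns condition, stage,
    replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"condition", "stage", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"SampleSheet missing columns: {sorted(missing)}")
        if not self.table.index.is_unique:
            raise ValueError("duplicate sample ids")
        if (self.table["replicate"] < 1).any():
            raise ValueError("replicate numbers must be >= 1")

    def samples_where(self, condition: str | None = None, stage: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if stage is not None:
            mask &= self.table["stage"].astype(str) == str(stage)
        return self.table.index[mask].tolist()


COUNTS = "counts"
TPM_UNIT = "TPM"
NORMALIZED01 = "normalized01"
_UNITS = (COUNTS, TPM_UNIT, NORMALIZED01)


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with a unit tag."""

    values: pd.DataFrame
    unit: str = COUNTS

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {_UNITS}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate feature ids in expression matrix")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if arr.size and np.asarray(arr < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.unit == NORMALIZED01 and arr.size and np.asarray(arr > 1).any():
            raise ValueError("normalized01 values must lie in [0, 1]")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[features], unit=self.unit)


@dataclass
class CellMatrix:
    """Cells x genes UMI counts; ``mito_genes`` flags mitochondrial genes."""

    counts: pd.DataFrame
    mito_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("duplicate cell ids")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate gene ids")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("UMI counts must be nonnegative")
        self.mito_genes = set(self.mito_genes) & set(self.counts.columns)

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_umi(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def mito_fraction(self) -> pd.Series:
        total = self.n_umi.astype(float)
        mito_cols = sorted(self.mito_genes)
        mito = self.counts[mito_cols].sum(axis=1) if mito_cols else pd.Series(0.0, index=self.counts.index)
        frac = mito / total.replace(0, np.nan)
        return frac.fillna(0.0)


@dataclass
class EndCountProfile:
    """Combined 5'/3' cleavage-end counts per internucleotide bond.

    Bond ``b`` (1-based, ``b in [1, L-1]``) is the phosphodiester bond
    between nucleotides ``b`` and ``b+1``.  The combined count is

        n(b) = (# 3' fragment ends at nucleotide b)
             + (# 5' fragment ends at nucleotide b+1)

    so each internal cleavage whose two flanking fragments are both
    observed contributes 2 to its bond.
    """

    reference_id: str
    length: int
    n: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        if self.length < 2:
            raise ValueError("reference length must be >= 2")
        if self.n.shape != (self.length - 1,):
            raise ValueError(
                f"profile for length {self.length} needs {self.length - 1} bonds, "
                f"got {self.n.shape}"
            )
        if (self.n < 0).any():
            raise ValueError("bond counts must be nonnegative")

    @classmethod
    def from_end_counts(
        cls, reference_id: str, length: int, counts_5p: np.ndarray, counts_3p: np.ndarray
    ) -> "EndCountProfile":
        """Combine per-nucleotide 5' and 3' end counts (1-based arrays of
        length L) into the per-bond profile."""
        c5 = np.asarray(counts_5p)
        c3 = np.asarray(counts_3p)
        if c5.shape != (length,) or c3.shape != (length,):
            raise ValueError("end-count vectors must have one entry per nucleotide")
        if (c5 < 0).any() or (c3 < 0).any():
            raise ValueError("end counts must be nonnegative")
        n = c3[:-1] + c5[1:]
        return cls(reference_id=reference_id, length=length, n=n)
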