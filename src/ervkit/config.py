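"""Run configuration shared by the command-line pipeline and the library.

All tunable thresholds of the analysis stack live in one flat record so that
every output can embed the exact settings it was produced under.  Values are
read from a TOML file and individually overridable from the command line.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """Flat bag of pipeline parameters.

    Attributes
    ----------
    seed:
        Seed for every random draw in a run.
    pseudocount_tpm:
        Pseudocount (TPM units) added before log2 ratios.
    specificity_threshold:
        Minimum stage-specificity score for a gene to enter K-means staging.
    k_clusters:
        Number of stage clusters fitted by K-means.
    methscore_window:
        Number of flanking bonds (each side) in the MethScore local average.
    min_cells_per_gene, min_umi, max_mito_fraction:
        Single-cell QC thresholds: a gene must be detected in at least
        ``min_cells_per_gene`` cells; a cell needs ``nUMI >= min_umi`` and a
        mitochondrial fraction ``<= max_mito_fraction``.
    de_lfc, de_p:
        Differential-expression call thresholds: ``|log2FC| > de_lfc`` and
        ``p < de_p``.
    """

    seed: int = 0
    pseudocount_tpm: float = 1.0
    specificity_threshold: float = 0.2
    k_clusters: int = 5
    methscore_window: int = 6
    min_cells_per_gene: int = 3
    min_umi: int = 500
    max_mito_fraction: float = 0.2
    de_lfc: float = 1.0
    de_p: float = 0.05

    def __post_init__(self) -> None:
        if self.pseudocount_tpm <= 0:
            raise ValueError("pseudocount_tpm must be positive")
        if not 0.0 <= self.specificity_threshold <= 1.0:
            raise ValueError("specificity_threshold must be in [0, 1]")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.methscore_window < 1:
            raise ValueError("methscore_window must be >= 1")
        if self.min_cells_per_gene < 0 or self.min_umi < 0:
            raise ValueError("QC count thresholds must be nonnegative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.de_lfc < 0:
            raise ValueError("de_lfc must be nonnegative")
        if not 0.0 <= self.de_p <= 1.0:
            raise ValueError("de_p must be in [0, 1]")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True)

    def header_line(self) -> str:
        """One-line comment embedding the full config, for output headers."""
        return "# config " + self.to_json()

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
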