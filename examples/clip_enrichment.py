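"""CLIP-over-control enrichment with planted category folds.

Simulates a paired CLIP / control RNA-seq library (Poisson counts, depth
1e6) in which snoRNA is enriched 8-fold, rRNA 4-fold and a pre-miRNA
category 2-fold, then recovers the folds as per-category mean
log2(TPM_clip / TPM_control) enrichments.
"""

import numpy as np
import pandas as pd

from ervkit import ClipSimSpec, ExpressionMatrix, clip_enrich, simulate_clip, tpm

counts, features, truth = simulate_clip(ClipSimSpec(seed=1))
expr = tpm(ExpressionMatrix(counts[["clip", "control"]]), features)
pair = pd.DataFrame(
    {
        "tpm_clip": expr.values["clip"],
        "tpm_control": expr.values["control"],
        "category": counts["category"],
    }
)
per_feature, per_category = clip_enrich(pair, pseudocount=1.0)

table = per_category[["mean", "median", "n_members"]].copy()
table["planted_log2_fold"] = np.log2(truth.reindex(table.index))
print("per-category CLIP enrichment (log2 units):")
print(table.to_string(float_format="%.3f"))
print("\nthe mean enrichment of each category recovers its planted "
      "log2 fold within sampling noise; fold-1 categories sit near 0.")
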