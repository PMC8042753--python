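"""Expression similarity (Re) and the age-normalised Re/KS feature.

Builds a small expression matrix, computes the Spearman correlation of
two paralogs' profiles and joins it with KA/KS into model features.
"""

import numpy as np
import pandas as pd

from dupdiverge.expr_similarity import ExpressionMatrix, build_features, spearman_re

rng = np.random.default_rng(0)
base = rng.normal(6, 1.5, 50)
mat = ExpressionMatrix(
    pd.DataFrame(
        {
            "dup_a": base,
            "dup_b": base + rng.normal(0, 0.8, 50),  # correlated paralog
            "other": rng.normal(6, 1.5, 50),  # unrelated gene
        }
    ).T
)

print(f"Re(dup_a, dup_b) = {spearman_re(mat, 'dup_a', 'dup_b'):.3f}")
print(f"Re(dup_a, other) = {spearman_re(mat, 'dup_a', 'other'):.3f}")

div = pd.DataFrame(
    [{"gene_a": "dup_a", "gene_b": "dup_b", "ka": 0.05, "ks": 0.4}]
)
feats, _ = build_features(div, mat)
f = feats[0]
print(f"features: KA/KS = {f.ka_ks:.3f}, Re = {f.re:.3f}, Re/KS = {f.re_ks:.3f}")
# high Re/KS means the pair kept similar expression for its age —
# evidence for low functional divergence.
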