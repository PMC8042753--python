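"""Expression similarity of paralogs.

Re is the Spearman rank correlation of two genes' expression profiles
across many conditions (634 in the reference compendium). Dividing Re by
KS normalises expression similarity by duplication age, giving the
Re/KS feature used alongside KA/KS by the divergence model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "PairFeatures",
    "spearman_re",
    "build_features",
    "expression_breadth",
]


@dataclass
class ExpressionMatrix:
    """Gene x condition expression values (log-scale); NaN = missing."""

    data: pd.DataFrame  # index: gene ids, columns: condition ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 conditions")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t")


@dataclass(frozen=True)
class PairFeatures:
    """Model features for one duplicate pair."""

    pair_id: str
    ka_ks: float
    re: float
    ks: float
    re_ks: float
    label: str = "unknown"  # high / low / unknown


def spearman_re(mat: ExpressionMatrix, gene_a: str, gene_b: str) -> float | None:
    """Spearman correlation of two genes' profiles (pairwise-complete).

    Average ranks for ties. Returns None when fewer than 3 complete
    condition pairs remain.
    """
    for g in (gene_a, gene_b):
        if g not in mat.data.index:
            raise KeyError(f"gene {g} absent from expression matrix")
    x = mat.data.loc[gene_a].to_numpy(dtype=float)
    y = mat.data.loc[gene_b].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return None
    rho = stats.spearmanr(x[ok], y[ok]).statistic
    return float(rho)


def build_features(
    divergence: pd.DataFrame, mat: ExpressionMatrix | None = None
) -> tuple[list[PairFeatures], list[dict]]:
    """Join KA/KS and Re/KS into per-pair features.

    ``divergence`` needs columns gene_a, gene_b, ka, ks (or a
    precomputed ka_ks) and optionally re and label. When ``mat`` is
    given and re is absent, Re is computed from the matrix. Pairs with
    KS <= 0, undefined KA/KS or undefined Re go to the exclusion list
    with a reason.
    """
    feats: list[PairFeatures] = []
    excluded: list[dict] = []
    for _, row in divergence.iterrows():
        pid = f"{row['gene_a']}|{row['gene_b']}"
        label = str(row.get("label", "unknown"))
        ks = row.get("ks")
        ka_ks = row.get("ka_ks")
        if ka_ks is None or (isinstance(ka_ks, float) and np.isnan(ka_ks)):
            ka = row.get("ka")
            if ka is not None and ks is not None and not np.isnan(ka) and ks > 0:
                ka_ks = ka / ks
            else:
                ka_ks = None
        re = row.get("re")
        if (re is None or (isinstance(re, float) and np.isnan(re))) and mat is not None:
            try:
                re = spearman_re(mat, row["gene_a"], row["gene_b"])
            except KeyError:
                re = None
        if ks is None or np.isnan(ks) or ks <= 0 or ka_ks is None:
            excluded.append({"pair": pid, "reason": "undefined_feature"})
            continue
        if re is None or (isinstance(re, float) and np.isnan(re)):
            excluded.append({"pair": pid, "reason": "undefined_re"})
            continue
        feats.append(
            PairFeatures(pid, float(ka_ks), float(re), float(ks), float(re) / float(ks), label)
        )
    return feats, excluded


def expression_breadth(
    mat: ExpressionMatrix,
    expressed_threshold: float | None = None,
    broad_frac: float = 0.95,
    specific_frac: float = 0.05,
) -> pd.Series:
    """Classify each gene as broadly / specifically expressed or neither.

    A gene counts as expressed in a condition when its value is at least
    ``expressed_threshold`` (default: the matrix-wide 60th percentile).
    Broad: expressed in >= broad_frac of conditions. Specific: expressed
    in <= specific_frac of conditions (but in at least one). Otherwise
    "neither".
    """
    values = mat.data.to_numpy(dtype=float)
    if expressed_threshold is None:
        expressed_threshold = float(np.nanpercentile(values, 60))
    n_cond = values.shape[1]
    expressed = np.nansum(values >= expressed_threshold, axis=1)
    calls = np.where(
        expressed >= broad_frac * n_cond,
        "broad",
        np.where(
            (expressed >= 1) & (expressed <= specific_frac * n_cond),
            "specific",
            "neither",
        ),
    )
    out = pd.Series(calls, index=mat.data.index, name="breadth")
    out.attrs["expressed_threshold"] = expressed_threshold
    out.attrs["broad_frac"] = broad_frac
    out.attrs["specific_frac"] = specific_frac
    return out


def features_to_frame(feats: list[PairFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": f.pair_id,
                "ka_ks": f.ka_ks,
                "re": f.re,
                "ks": f.ks,
                "re_ks": f.re_ks,
                "label": f.label,
            }
            for f in feats
        ]
    )
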