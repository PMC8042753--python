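"""Functional-bias analyses and the supporting statistical tests.

High and low diversified duplicates differ systematically in annotation:
low diversified pairs are enriched for core (highly conserved) genes,
carry more protein–protein interactions, are broadly expressed and
derive predominantly from whole-genome duplication, whereas high
diversified pairs skew toward tandem duplicates with specific
expression. This module assembles those contingency tables and group
comparisons and runs the corresponding tests (chi-square with optional
Yates correction, Wilcoxon rank-sum, t/F/Kolmogorov–Smirnov,
hypergeometric enrichment with Benjamini–Hochberg control).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSets",
    "shared_set_proportion",
    "chi2_2x2",
    "wilcoxon_rank_sum",
    "phenotype_tests",
    "enrich_terms",
    "bias_report",
]

MECHANISMS = ("tandem", "wgd", "other")


@dataclass
class AnnotationSets:
    """Per-gene annotations used by the bias analyses."""

    go: dict[str, frozenset] = field(default_factory=dict)
    domains: dict[str, frozenset] = field(default_factory=dict)
    ppi_degree: dict[str, int] = field(default_factory=dict)
    core: dict[str, bool] = field(default_factory=dict)
    mechanism: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, d in self.ppi_degree.items():
            if d < 0:
                raise ValueError(f"negative PPI degree for {g}")
        for g, m in self.mechanism.items():
            if m not in MECHANISMS:
                raise ValueError(f"unknown mechanism {m!r} for {g}")

    @classmethod
    def from_tsv(cls, path) -> "AnnotationSets":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        def split(col, row):
            v = row.get(col)
            if pd.isna(v) or v == "":
                return frozenset()
            return frozenset(str(v).split(";"))
        go, dom, ppi, core, mech = {}, {}, {}, {}, {}
        for _, row in df.iterrows():
            g = row["gene"]
            go[g] = split("go", row)
            dom[g] = split("domains", row)
            if "ppi_degree" in df.columns and not pd.isna(row["ppi_degree"]):
                ppi[g] = int(row["ppi_degree"])
            if "core" in df.columns and not pd.isna(row["core"]):
                core[g] = bool(int(row["core"]))
            if "mechanism" in df.columns and not pd.isna(row["mechanism"]):
                mech[g] = str(row["mechanism"])
        return cls(go, dom, ppi, core, mech)


def shared_set_proportion(set_a, set_b, mode: str = "jaccard") -> float | None:
    """Proportion of annotation terms shared by two genes.

    Jaccard |A∩B|/|A∪B| by default; ``mode='min'`` divides by the
    smaller set instead. Returns None when both sets are empty.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    if not a and not b:
        return None
    inter = len(a & b)
    if mode == "jaccard":
        return inter / len(a | b)
    if mode == "min":
        denom = min(len(a), len(b))
        return inter / denom if denom else 0.0
    raise ValueError(f"unknown mode {mode!r}")


def chi2_2x2(table, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = stats.chi2_contingency(t, correction=yates)
    return float(stat), float(p)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact Mann–Whitney p by enumerating all group splits.

    Handles ties (works on the pooled values directly). Feasible for
    combined n up to ~14.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))
    ranks = stats.rankdata(pooled)
    u_null = []
    for comb in itertools.combinations(idx, n1):
        r1 = ranks[list(comb)].sum()
        u_null.append(r1 - n1 * (n1 + 1) / 2.0)
    u_null = np.asarray(u_null)
    mu = len(x) * len(y) / 2.0
    dev = abs(u_obs - mu)
    return float(np.mean(np.abs(u_null - mu) >= dev - 1e-12))


def wilcoxon_rank_sum(x, y, exact_cutoff: int = 12) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when the combined sample size is at most
    ``exact_cutoff``; otherwise the normal approximation with tie and
    continuity corrections. Returns (U of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    u = float(res.statistic)
    if len(x) + len(y) <= exact_cutoff:
        return u, _exact_rank_sum_p(x, y, u)
    return u, float(res.pvalue)


def phenotype_tests(groups: dict[str, tuple]) -> pd.DataFrame:
    """Per-trait phenotype comparisons for transgenic-line data.

    ``groups`` maps a trait name to (control, treatment) replicate
    arrays. For each trait: a Kolmogorov–Smirnov normality check of each
    sample against its fitted normal, a two-tailed equal-variance
    Student t-test, and a two-tailed variance-ratio F-test.
    """
    rows = []
    for trait, (control, treated) in groups.items():
        c = np.asarray(control, dtype=float)
        t = np.asarray(treated, dtype=float)
        if len(c) < 2 or len(t) < 2:
            raise ValueError(f"trait {trait}: need >=2 replicates per group")

        def ks_norm(sample):
            sd = sample.std(ddof=1)
            if sd == 0:
                return np.nan
            return stats.kstest(sample, "norm", args=(sample.mean(), sd)).pvalue

        t_stat, t_p = stats.ttest_ind(c, t, equal_var=True)
        vc, vt = c.var(ddof=1), t.var(ddof=1)
        if vt == 0:
            f_ratio, f_p = np.nan, np.nan
        else:
            f_ratio = vc / vt
            cdf = stats.f.cdf(f_ratio, len(c) - 1, len(t) - 1)
            f_p = 2 * min(cdf, 1 - cdf)
        rows.append(
            {
                "trait": trait,
                "ks_normal_p_control": ks_norm(c),
                "ks_normal_p_treated": ks_norm(t),
                "t_stat": float(t_stat),
                "t_p": float(t_p),
                "f_ratio": float(f_ratio) if np.isfinite(f_ratio) else np.nan,
                "f_p": float(f_p) if np.isfinite(f_p) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def enrich_terms(
    foreground, background, term_map: dict[str, frozenset], alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment with BH-FDR control.

    ``term_map`` maps gene -> set of terms. A term is enriched when its
    BH-adjusted p is below ``alpha`` and its foreground fold is above 1.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    if not fg:
        return pd.DataFrame(
            columns=["term", "k_fg", "n_fg", "k_bg", "n_bg", "fold", "p", "fdr", "enriched"]
        )
    term_fg: dict[str, int] = {}
    term_bg: dict[str, int] = {}
    for g in bg:
        for term in term_map.get(g, ()):  # genes without terms contribute nothing
            term_bg[term] = term_bg.get(term, 0) + 1
            if g in fg:
                term_fg[term] = term_fg.get(term, 0) + 1
    rows = []
    M, n = len(bg), len(fg)
    for term, K in sorted(term_bg.items()):
        k = term_fg.get(term, 0)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        fold = (k / n) / (K / M)
        rows.append({"term": term, "k_fg": k, "n_fg": n, "k_bg": K, "n_bg": M,
                     "fold": fold, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["fdr"] = []
        df["enriched"] = []
        return df
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["enriched"] = (df["fdr"] < alpha) & (df["fold"] > 1)
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def bias_report(
    gene_calls: pd.DataFrame,
    ann: AnnotationSets,
    breadth: pd.Series | None = None,
    yates: bool = True,
) -> dict:
    """Assemble the functional-bias comparisons between call classes.

    ``gene_calls`` has columns gene, call (high/low/unclassified); only
    high/low genes enter the comparisons. Produces: core-gene
    contingency and proportions, PPI-degree Wilcoxon, broad/specific
    expression contingency, and the tandem/WGD mechanism table with
    per-class ratios. Genes lacking an annotation are skipped and
    counted.
    """
    hl = gene_calls[gene_calls["call"].isin(["high", "low"])]
    high_genes = hl.loc[hl["call"] == "high", "gene"].tolist()
    low_genes = hl.loc[hl["call"] == "low", "gene"].tolist()
    report: dict = {"n_high_genes": len(high_genes), "n_low_genes": len(low_genes),
                    "skipped": {}}

    # core genes
    if ann.core:
        def core_counts(genes):
            have = [g for g in genes if g in ann.core]
            return sum(ann.core[g] for g in have), len(have)
        ch, nh = core_counts(high_genes)
        cl, nl = core_counts(low_genes)
        report["skipped"]["core"] = len(high_genes) + len(low_genes) - nh - nl
        if nh and nl:
            table = [[ch, nh - ch], [cl, nl - cl]]
            stat, p = chi2_2x2(table, yates=yates)
            report["core"] = {
                "prop_high": ch / nh, "prop_low": cl / nl,
                "table": table, "chi2": stat, "p": p,
            }

    # PPI degrees
    deg_h = [ann.ppi_degree[g] for g in high_genes if g in ann.ppi_degree]
    deg_l = [ann.ppi_degree[g] for g in low_genes if g in ann.ppi_degree]
    report["skipped"]["ppi"] = (
        len(high_genes) + len(low_genes) - len(deg_h) - len(deg_l)
    )
    if deg_h and deg_l:
        u, p = wilcoxon_rank_sum(deg_h, deg_l)
        report["ppi"] = {
            "median_high": float(np.median(deg_h)),
            "median_low": float(np.median(deg_l)),
            "U": u, "p": p,
        }

    # expression breadth: specific vs broad by class
    if breadth is not None:
        b = breadth.reindex(hl["gene"])
        calls = hl.set_index("gene")["call"]
        def cell(kind, cls):
            return int(((b == kind) & (calls == cls)).sum())
        table = [[cell("specific", "high"), cell("specific", "low")],
                 [cell("broad", "high"), cell("broad", "low")]]
        if min(sum(r) for r in table) > 0 and min(sum(c) for c in zip(*table)) > 0:
            stat, p = chi2_2x2(table, yates=yates)
            report["breadth"] = {"table": table, "chi2": stat, "p": p}

    # duplication mechanism
    if ann.mechanism:
        def mech_counts(genes):
            td = sum(1 for g in genes if ann.mechanism.get(g) == "tandem")
            wg = sum(1 for g in genes if ann.mechanism.get(g) == "wgd")
            return td, wg
        th, wh = mech_counts(high_genes)
        tl, wl = mech_counts(low_genes)
        if (th + wh) and (tl + wl):
            table = [[th, wh], [tl, wl]]
            stat, p = chi2_2x2(table, yates=yates)
            report["mechanism"] = {
                "table": table,
                "ratio_high": th / wh if wh else np.inf,
                "ratio_low": tl / wl if wl else np.inf,
                "chi2": stat, "p": p,
            }

    # shared-annotation proportions need pair structure, handled upstream
    return report


def report_to_text(report: dict) -> str:
    lines = [
        f"high-call genes: {report['n_high_genes']}",
        f"low-call genes:  {report['n_low_genes']}",
    ]
    if "core" in report:
        c = report["core"]
        lines.append(
            f"core-gene proportion: high {c['prop_high']:.3f} vs "
            f"low {c['prop_low']:.3f} (chi2 p = {c['p']:.3g})"
        )
    if "ppi" in report:
        p = report["ppi"]
        lines.append(
            f"PPI degree median: high {p['median_high']:.1f} vs "
            f"low {p['median_low']:.1f} (Wilcoxon p = {p['p']:.3g})"
        )
    if "breadth" in report:
        b = report["breadth"]
        lines.append(f"specific/broad table {b['table']} (chi2 p = {b['p']:.3g})")
    if "mechanism" in report:
        m = report["mechanism"]
        lines.append(
            f"tandem/WGD ratio: high {m['ratio_high']:.2f} vs "
            f"low {m['ratio_low']:.2f} (chi2 p = {m['p']:.3g})"
        )
    return "\n".join(lines)
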