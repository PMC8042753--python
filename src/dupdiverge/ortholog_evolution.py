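"""Ortholog retention and branch-specific selection for duplicate pairs.

For each A. thaliana duplicate we ask whether an ortholog survives in
A. lyrata and B. rapa (retention), and, where the three sequences are
all present, estimate KA and KS on the two lineage-specific branches of
the unrooted three-taxon tree:

    AS2 ---- Br
     \
      AS1 --- Al
       \
        At

AS1 is the (At, Al) ancestor and AS2 the (At, Al, Br) ancestor. Branch
lengths come from the additive decomposition of the three pairwise
distances, computed separately for KA and KS:

    b(Al) = (d(At,Al) + d(Al,Br) - d(At,Br)) / 2   # AS1 -> Al
    b(Br) = (d(At,Br) + d(Al,Br) - d(At,Al)) / 2   # AS2 -> Br

Negative decompositions (non-additive noise) are truncated to zero and
flagged. Selection on a branch is called by a two-sided Fisher exact
test of branch-allocated nonsynonymous/synonymous difference counts
against the nonsynonymous/synonymous site totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bias_stats import chi2_2x2, wilcoxon_rank_sum
from .seq_divergence import CodonAlignment, DivergenceEstimate, ng86_ka_ks

__all__ = [
    "OrthologTriplet",
    "BranchEstimate",
    "retention_analysis",
    "branch_ka_ks",
    "selection_call",
    "selection_proportions",
    "bootstrap_support",
]


@dataclass
class OrthologTriplet:
    """One A. thaliana gene with its (possibly absent) Al/Br orthologs."""

    at_gene: str
    al_gene: str | None
    br_gene: str | None
    pair_class: str  # high / low
    mechanism: str  # tandem / wgd / other
    aln_at_al: CodonAlignment | None = None
    aln_at_br: CodonAlignment | None = None
    aln_al_br: CodonAlignment | None = None

    @property
    def complete(self) -> bool:
        return (
            self.al_gene is not None
            and self.br_gene is not None
            and self.aln_at_al is not None
            and self.aln_at_br is not None
            and self.aln_al_br is not None
        )


@dataclass
class BranchEstimate:
    branch: str  # "AS1->Al" or "AS2->Br"
    ka: float | None
    ks: float | None
    ka_ks: float | None
    truncated: bool = False
    selection: str = "undetermined"  # positive/purifying/neutral/undetermined
    p: float | None = None


def retention_analysis(triplets, yates: bool = True) -> dict:
    """Ortholog retention rates by class and mechanism, with chi-square
    comparisons between classes (overall and within each mechanism)."""
    rows = []
    for t in triplets:
        rows.append(
            {
                "class": t.pair_class,
                "mechanism": t.mechanism,
                "al": t.al_gene is not None,
                "br": t.br_gene is not None,
            }
        )
    df = pd.DataFrame(rows)
    out: dict = {"rates": {}, "comparisons": {}, "notes": []}
    if df.empty:
        out["notes"].append("no triplets")
        return out
    for species in ("al", "br"):
        for (cls, mech), grp in df.groupby(["class", "mechanism"]):
            out["rates"][(species, cls, mech)] = float(grp[species].mean())
        for cls, grp in df.groupby("class"):
            out["rates"][(species, cls, "all")] = float(grp[species].mean())

        def compare(key, sub):
            h = sub[sub["class"] == "high"][species]
            l = sub[sub["class"] == "low"][species]
            if len(h) == 0 or len(l) == 0:
                out["notes"].append(f"{species}/{key}: empty stratum")
                return
            table = [[int(h.sum()), int(len(h) - h.sum())],
                     [int(l.sum()), int(len(l) - l.sum())]]
            if min(sum(r) for r in table) == 0 or min(sum(c) for c in zip(*table)) == 0:
                out["notes"].append(f"{species}/{key}: degenerate table")
                return
            stat, p = chi2_2x2(table, yates=yates)
            out["comparisons"][(species, key)] = {
                "rate_high": float(h.mean()), "rate_low": float(l.mean()),
                "table": table, "chi2": stat, "p": p,
            }

        compare("all", df)
        for mech, sub in df.groupby("mechanism"):
            compare(mech, sub)
    return out


def _decompose(d_at_al: float, d_at_br: float, d_al_br: float) -> tuple[float, float, bool]:
    b_al = (d_at_al + d_al_br - d_at_br) / 2.0
    b_br = (d_at_br + d_al_br - d_at_al) / 2.0
    truncated = b_al < 0 or b_br < 0
    return max(b_al, 0.0), max(b_br, 0.0), truncated


def branch_ka_ks(triplet: OrthologTriplet) -> tuple[BranchEstimate, BranchEstimate, dict]:
    """Branch-specific KA and KS for AS1->Al and AS2->Br.

    Returns the two branch estimates plus the pairwise NG86 estimates
    used (for downstream difference-count allocation). Branches are
    undetermined when any pairwise estimate is undefined.
    """
    und = (
        BranchEstimate("AS1->Al", None, None, None),
        BranchEstimate("AS2->Br", None, None, None),
    )
    if not triplet.complete:
        return (*und, {})
    est: dict[str, DivergenceEstimate] = {}
    try:
        est["at_al"] = ng86_ka_ks(triplet.aln_at_al)
        est["at_br"] = ng86_ka_ks(triplet.aln_at_br)
        est["al_br"] = ng86_ka_ks(triplet.aln_al_br)
    except ValueError:
        return (*und, {})
    if any(e.ka is None or e.ks is None for e in est.values()):
        return (*und, est)
    ka_al, ka_br, trunc_ka = _decompose(
        est["at_al"].ka, est["at_br"].ka, est["al_br"].ka
    )
    ks_al, ks_br, trunc_ks = _decompose(
        est["at_al"].ks, est["at_br"].ks, est["al_br"].ks
    )
    def mk(branch, ka, ks, trunc):
        ratio = ka / ks if ks > 0 else None
        return BranchEstimate(branch, ka, ks, ratio, truncated=trunc)
    return (
        mk("AS1->Al", ka_al, ks_al, trunc_ka or trunc_ks),
        mk("AS2->Br", ka_br, ks_br, trunc_ka or trunc_ks),
        est,
    )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def selection_call(
    branch: BranchEstimate, pair_est: DivergenceEstimate, alpha: float = 0.05
) -> BranchEstimate:
    """Call positive/purifying/neutral selection on a branch.

    The pairwise NG86 difference counts are scaled down by the
    branch-to-pairwise distance ratio (rounded half-up) and tested
    against the site totals in a two-sided Fisher exact test. Positive:
    p < alpha and branch KA/KS > 1; purifying: p < alpha and KA/KS < 1;
    otherwise neutral. Zero allocated differences -> neutral, flagged
    through p = None.
    """
    if branch.ka is None or branch.ks is None:
        branch.selection = "undetermined"
        return branch
    frac_n = branch.ka / pair_est.ka if pair_est.ka and pair_est.ka > 0 else 0.0
    frac_s = branch.ks / pair_est.ks if pair_est.ks and pair_est.ks > 0 else 0.0
    nd = _round_half_up(pair_est.Nd * min(frac_n, 1.0))
    sd = _round_half_up(pair_est.Sd * min(frac_s, 1.0))
    if nd + sd == 0:
        branch.selection = "neutral"
        branch.p = None
        return branch
    table = [[nd, sd], [_round_half_up(pair_est.N), _round_half_up(pair_est.S)]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    branch.p = float(p)
    if p < alpha and branch.ka_ks is not None and branch.ka_ks > 1:
        branch.selection = "positive"
    elif p < alpha and branch.ka_ks is not None and branch.ka_ks < 1:
        branch.selection = "purifying"
    else:
        branch.selection = "neutral"
    return branch


def call_triplet_selection(triplet: OrthologTriplet, alpha: float = 0.05):
    """Branch estimates with selection calls for one complete triplet.

    AS1->Al allocates the At–Al pairwise counts; AS2->Br the At–Br
    counts (the branch lies on that pairwise path).
    """
    b_al, b_br, est = branch_ka_ks(triplet)
    if est and b_al.ka is not None:
        selection_call(b_al, est["at_al"], alpha)
        selection_call(b_br, est["at_br"], alpha)
    return b_al, b_br


def selection_proportions(
    branch_calls: pd.DataFrame,
    singleton_ka_ks: dict[str, np.ndarray] | None = None,
    yates: bool = True,
) -> dict:
    """Positive/purifying proportions per class x mechanism group.

    ``branch_calls`` columns: branch, class, mechanism, ka_ks,
    selection. Each group's proportion is chi-square-compared against
    the all-genes average for that branch; when singleton control KA/KS
    distributions are supplied, a Wilcoxon rank-sum compares each
    group's branch KA/KS against them.
    """
    out: dict = {"groups": {}, "notes": []}
    for branch, bdf in branch_calls.groupby("branch"):
        det = bdf[bdf["selection"] != "undetermined"]
        n_all = len(det)
        if n_all == 0:
            out["notes"].append(f"{branch}: no determined calls")
            continue
        avg_pos = float((det["selection"] == "positive").mean())
        avg_pur = float((det["selection"] == "purifying").mean())
        out["groups"][(branch, "all", "all")] = {
            "n": n_all, "prop_positive": avg_pos, "prop_purifying": avg_pur,
        }
        for (cls, mech), grp in det.groupby(["class", "mechanism"]):
            n = len(grp)
            if n == 0:
                continue
            pos = int((grp["selection"] == "positive").sum())
            pur = int((grp["selection"] == "purifying").sum())
            entry = {
                "n": n,
                "prop_positive": pos / n,
                "prop_purifying": pur / n,
            }
            rest = det.drop(grp.index)
            for kind, k in (("positive", pos), ("purifying", pur)):
                k_rest = int((rest["selection"] == kind).sum())
                table = [[k, n - k], [k_rest, len(rest) - k_rest]]
                if (
                    len(rest)
                    and min(sum(r) for r in table) > 0
                    and min(sum(c) for c in zip(*table)) > 0
                ):
                    _, p = chi2_2x2(table, yates=yates)
                    entry[f"chi2_p_{kind}"] = p
            if singleton_ka_ks is not None and branch in singleton_ka_ks:
                vals = grp["ka_ks"].dropna().to_numpy()
                ctrl = np.asarray(singleton_ka_ks[branch], dtype=float)
                if len(vals) and len(ctrl):
                    _, wp = wilcoxon_rank_sum(vals, ctrl)
                    entry["wilcoxon_vs_singletons_p"] = wp
            out["groups"][(branch, cls, mech)] = entry
    return out


def bootstrap_support(
    triplets, predicate, n_boot: int = 100, seed: int = 0
) -> float:
    """Fraction of bootstrap resamples on which ``predicate`` holds.

    ``predicate`` receives a list of triplets (a resample with
    replacement) and returns a bool. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    triplets = list(triplets)
    n = len(triplets)
    if n == 0 or n_boot == 0:
        return float("nan")
    hits = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if predicate([triplets[i] for i in idx]):
            hits += 1
    return hits / n_boot
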