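"""Retention rates, three-taxon branch decomposition and selection calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from dupdiverge.ortholog_evolution import (
    BranchEstimate,
    OrthologTriplet,
    _decompose,
    bootstrap_support,
    branch_ka_ks,
    call_triplet_selection,
    retention_analysis,
    selection_call,
    selection_proportions,
)
from dupdiverge.seq_divergence import DivergenceEstimate
from dupdiverge.synthetic_data import (
    SimConfig,
    simulate_selection_groups,
    simulate_triplets,
)


def _trip(cls, mech, al=True, br=True):
    return OrthologTriplet(
        "at", "al" if al else None, "br" if br else None, cls, mech
    )


# --- retention -------------------------------------------------------------


def test_retention_all_present():
    trips = [_trip("high", "tandem")] * 5 + [_trip("low", "wgd")] * 5
    res = retention_analysis(trips)
    assert res["rates"][("al", "high", "all")] == 1.0
    assert res["rates"][("br", "low", "all")] == 1.0


def test_retention_toy_counts_and_chi2():
    trips = (
        [_trip("high", "wgd", al=True)] * 2 + [_trip("high", "wgd", al=False)] * 8
        + [_trip("low", "wgd", al=True)] * 8 + [_trip("low", "wgd", al=False)] * 2
    )
    res = retention_analysis(trips)
    cmp_all = res["comparisons"][("al", "all")]
    assert cmp_all["rate_high"] == pytest.approx(0.2)
    assert cmp_all["rate_low"] == pytest.approx(0.8)
    assert cmp_all["table"] == [[2, 8], [8, 2]]
    # oracle: same table through scipy directly
    from scipy.stats import chi2_contingency

    assert cmp_all["p"] == pytest.approx(
        chi2_contingency([[2, 8], [8, 2]], correction=True)[1]
    )


def test_retention_recovers_planted_probabilities():
    cfg = SimConfig(n_high=500, n_low=500)
    trips = simulate_triplets(cfg, seed=21)
    res = retention_analysis(trips)
    assert res["rates"][("al", "low", "all")] == pytest.approx(0.67, abs=0.05)
    assert res["rates"][("al", "high", "all")] == pytest.approx(0.41, abs=0.05)


# --- branch decomposition --------------------------------------------------


def test_decomposition_equidistant():
    b_al, b_br, trunc = _decompose(0.4, 0.4, 0.4)
    assert b_al == pytest.approx(0.2) and b_br == pytest.approx(0.2)
    assert not trunc


def test_decomposition_additive_toy():
    b_al, b_br, trunc = _decompose(0.2, 0.5, 0.5)
    assert b_al == pytest.approx(0.1)
    assert b_br == pytest.approx(0.4)
    assert not trunc


def test_decomposition_negative_truncated():
    b_al, b_br, trunc = _decompose(0.5, 0.1, 0.1)
    assert b_al == pytest.approx(0.25)
    assert b_br == 0.0 and trunc


def test_decomposition_consistency_when_additive(rng):
    """Branch sums reproduce the pairwise distances for additive triples."""
    for _ in range(20):
        x_at, x_al, x_br = rng.uniform(0.01, 0.5, 3)
        d_at_al, d_at_br, d_al_br = x_at + x_al, x_at + x_br, x_al + x_br
        b_al, b_br, trunc = _decompose(d_at_al, d_at_br, d_al_br)
        b_at = d_at_al - b_al
        assert not trunc
        assert b_at + b_br == pytest.approx(d_at_br)
        assert b_al + b_br == pytest.approx(d_al_br)


def test_incomplete_triplet_undetermined():
    b_al, b_br, est = branch_ka_ks(_trip("high", "tandem", br=False))
    assert b_al.ka is None and b_br.selection == "undetermined"


# --- selection calls -------------------------------------------------------


def _pair_est(S, N, Sd, Nd, ks, ka):
    ratio = ka / ks if ks else None
    return DivergenceEstimate(S, N, Sd, Nd, ks, ka, ratio, n_codons=int((S + N) / 3))


def test_selection_purifying_oracle():
    est = _pair_est(S=300, N=600, Sd=20, Nd=0, ks=0.07, ka=0.0)
    b = BranchEstimate("AS2->Br", ka=0.0, ks=0.07, ka_ks=0.0)
    selection_call(b, est)
    assert b.selection == "purifying"
    assert b.p == pytest.approx(fisher_exact([[0, 20], [600, 300]])[1])


def test_selection_positive_oracle():
    est = _pair_est(S=300, N=600, Sd=2, Nd=40, ks=0.0067, ka=0.069)
    b = BranchEstimate("AS2->Br", ka=0.069, ks=0.0067, ka_ks=10.3)
    selection_call(b, est)
    assert b.selection == "positive"
    assert b.p == pytest.approx(fisher_exact([[40, 2], [600, 300]])[1])


def test_selection_proportional_counts_neutral():
    # Nd/Sd exactly at the site ratio: no signal
    est = _pair_est(S=300, N=600, Sd=15, Nd=30, ks=0.05, ka=0.05)
    b = BranchEstimate("AS1->Al", ka=0.05, ks=0.05, ka_ks=1.0)
    selection_call(b, est)
    assert b.selection == "neutral"


def test_selection_zero_differences_neutral_flagged():
    est = _pair_est(S=300, N=600, Sd=0, Nd=0, ks=0.0, ka=0.0)
    b = BranchEstimate("AS1->Al", ka=0.0, ks=0.0, ka_ks=None)
    selection_call(b, est)
    assert b.selection == "neutral" and b.p is None


def test_branch_omega_recovery():
    """Median branch KA/KS tracks the planted omega within ±25%."""
    cfg = SimConfig(n_codons=300)
    trips = simulate_selection_groups(
        cfg, n_per_group={("low", "wgd"): 40}, seed=5
    )
    vals = []
    for t in trips:
        _, b_br, _ = branch_ka_ks(t)
        if b_br.ka_ks is not None:
            vals.append(b_br.ka_ks)
    assert np.median(vals) == pytest.approx(0.2, rel=0.25)


def test_group_counts_partition():
    cfg = SimConfig(n_codons=120)
    trips = simulate_selection_groups(cfg, n_per_group=8, seed=2)
    rows = []
    for t in trips:
        for b in call_triplet_selection(t):
            rows.append({"branch": b.branch, "class": t.pair_class,
                         "mechanism": t.mechanism, "ka_ks": b.ka_ks,
                         "selection": b.selection})
    df = pd.DataFrame(rows)
    res = selection_proportions(df)
    for (branch, cls, mech), entry in res["groups"].items():
        if cls == "all":
            continue
        grp = df[(df["branch"] == branch) & (df["class"] == cls)
                 & (df["mechanism"] == mech)
                 & (df["selection"] != "undetermined")]
        assert entry["n"] == len(grp)


def test_selection_ordering_matches_planting():
    cfg = SimConfig()
    trips = simulate_selection_groups(
        cfg,
        n_per_group={("high", "tandem"): 50, ("high", "wgd"): 25,
                     ("low", "tandem"): 15, ("low", "wgd"): 50},
        seed=17,
    )
    rows = []
    for t in trips:
        for b in call_triplet_selection(t):
            rows.append({"class": t.pair_class, "mechanism": t.mechanism,
                         "selection": b.selection})
    df = pd.DataFrame(rows)
    ht = df[(df["class"] == "high") & (df["mechanism"] == "tandem")]
    lw = df[(df["class"] == "low") & (df["mechanism"] == "wgd")]
    assert (ht["selection"] == "positive").mean() > (
        df["selection"] == "positive"
    ).mean()
    assert (lw["selection"] == "purifying").mean() > (
        df["selection"] == "purifying"
    ).mean()


# --- bootstrap -------------------------------------------------------------


def test_bootstrap_deterministic_and_extremes():
    trips = [_trip("high", "tandem")] * 10 + [_trip("low", "wgd", al=False)] * 10

    def pred(sample):
        h = [t for t in sample if t.pair_class == "high"]
        l = [t for t in sample if t.pair_class == "low"]
        if not h or not l:
            return False
        rh = np.mean([t.al_gene is not None for t in h])
        rl = np.mean([t.al_gene is not None for t in l])
        return rh > rl

    s1 = bootstrap_support(trips, pred, n_boot=50, seed=4)
    s2 = bootstrap_support(trips, pred, n_boot=50, seed=4)
    assert s1 == s2
    assert s1 > 0.9  # deterministic large effect


def test_bootstrap_null_support_centered(rng):
    trips = [_trip("high", "tandem", al=bool(i % 2)) for i in range(40)] + [
        _trip("low", "wgd", al=bool(i % 2)) for i in range(40)
    ]

    def pred(sample):
        h = [t.al_gene is not None for t in sample if t.pair_class == "high"]
        l = [t.al_gene is not None for t in sample if t.pair_class == "low"]
        return bool(h) and bool(l) and np.mean(h) > np.mean(l)

    supports = [
        bootstrap_support(trips, pred, n_boot=40, seed=s) for s in range(10)
    ]
    assert 0.2 < np.mean(supports) < 0.8  # no planted effect
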