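"""Logistic DFD model: fit, score, thresholds, classification, metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dupdiverge.dfd_model import (
    DFDModel,
    calibrate_thresholds,
    classification_counts,
    classify,
    cross_validate,
    dfd_score,
    fit_lr,
    pr_auc,
    relative_importance,
    roc_auc,
    single_variable_models,
)
from dupdiverge.expr_similarity import PairFeatures
from dupdiverge.synthetic_data import (
    SimConfig,
    simulate_lr_features,
    simulate_pair_features,
)

PRINTED = DFDModel(beta0=-0.1228, beta_kaks=10.3044, beta_reks=-1.4177)


def feats_from_frame(df):
    return [
        PairFeatures(r.pair, r.ka_ks, getattr(r, "re", 0.0),
                     getattr(r, "ks", 1.0), r.re_ks, r.label)
        for r in df.itertuples()
    ]


# --- scoring ---------------------------------------------------------------


def test_score_closed_form_at_origin():
    assert dfd_score(PRINTED, 0.0, 0.0) == pytest.approx(expit(-0.1228))
    assert dfd_score(PRINTED, 0.0, 0.0) == pytest.approx(0.4693, abs=1e-4)


def test_score_closed_form_unit_kaks():
    assert dfd_score(PRINTED, 1.0, 0.0) == pytest.approx(expit(10.1816))
    assert dfd_score(PRINTED, 1.0, 0.0) == pytest.approx(0.99996, abs=1e-5)


def test_score_monotone_and_bounded(rng):
    ka = np.sort(rng.uniform(0, 2, 50))
    scores = dfd_score(PRINTED, ka, np.zeros(50))
    assert np.all(np.diff(scores) > 0)  # increasing in ka_ks
    re_ks = np.sort(rng.uniform(-2, 5, 50))
    scores2 = dfd_score(PRINTED, np.ones(50), re_ks)
    assert np.all(np.diff(scores2) < 0)  # decreasing in re_ks
    assert np.all((scores > 0) & (scores < 1))


# --- fitting ---------------------------------------------------------------


def test_fit_recovers_generating_coefficients_within_3se():
    beta_true = (-0.5, 3.0, -1.0)
    df = simulate_lr_features(beta_true, n=5000, seed=11)
    model = fit_lr(feats_from_frame(df))
    # independent oracle: statsmodels GLM gives both estimates and SEs
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(df)), df["ka_ks"], df["re_ks"]])
    y = (df["label"] == "high").astype(float)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert model.beta == pytest.approx(ref.params.to_numpy(), rel=1e-6)
    for est, true, se in zip(model.beta, beta_true, ref.bse.to_numpy()):
        assert abs(est - true) < 3 * se


def test_fit_requires_two_per_class():
    df = simulate_lr_features((-0.5, 3.0, -1.0), n=20, seed=1)
    df["label"] = "high"
    with pytest.raises(ValueError):
        fit_lr(feats_from_frame(df))


def test_fit_separated_data_uses_ridge_or_raises():
    rows = []
    for i in range(20):
        rows.append({"pair": f"h{i}", "ka_ks": 2.0 + i / 10, "re_ks": 0.0,
                     "label": "high"})
        rows.append({"pair": f"l{i}", "ka_ks": 0.1 + i / 100, "re_ks": 0.0,
                     "label": "low"})
    feats = feats_from_frame(pd.DataFrame(rows))
    model = fit_lr(feats, ridge_fallback=True)
    assert model.ridge
    from dupdiverge.dfd_model import SeparationError

    with pytest.raises(SeparationError):
        fit_lr(feats, ridge_fallback=False)


# --- thresholds & classification -------------------------------------------


def test_threshold_percentile_interpolation():
    # identity-score model: DFD equals logistic(ka_ks), so planting
    # ka_ks = logit(s) makes the scores exactly s
    scores = np.arange(0.05, 1.0001, 0.05)  # 20 true-high scores
    logit = lambda s: 50.0 if s >= 1 else float(np.log(s / (1 - s)))
    feats = [
        PairFeatures(f"p{i}", logit(s), 0.0, 1.0, 0.0, "high")
        for i, s in enumerate(scores)
    ] + [PairFeatures(f"l{i}", -50.0, 0.0, 1.0, 0.0, "low") for i in range(2)]
    model = DFDModel(beta0=0.0, beta_kaks=1.0, beta_reks=0.0)
    calibrate_thresholds(model, feats)
    # 5th percentile of {0.05, ..., 1.00} by linear interpolation
    assert model.thr_low == pytest.approx(0.0975, abs=1e-9)


def test_three_way_calls_and_partition():
    model = DFDModel(0.0, 1.0, 0.0, thr_low=0.54, thr_high=0.91)
    def feat(s):
        return PairFeatures(f"p{s}", float(np.log(s / (1 - s))), 0.0, 1.0, 0.0)
    calls = classify(model, [feat(0.95), feat(0.40), feat(0.70)])
    assert [c.call for c in calls] == ["high", "low", "unclassified"]
    # a score exactly at the threshold stays unclassified (strict inequality)
    boundary = feat(0.5)
    model_b = DFDModel(0.0, 1.0, 0.0, thr_low=0.2,
                       thr_high=dfd_score(model, boundary.ka_ks, 0.0))
    assert classify(model_b, [boundary])[0].call == "unclassified"
    counts = classification_counts(calls)
    assert sum(counts.values()) == 3


def test_perfect_separation_crosses_thresholds_and_flags():
    # highs all score ~1 and lows ~0, so thr_low (5th pct of highs) ends up
    # above thr_high (95th pct of lows): returned as-is but flagged
    feats = [PairFeatures("h", 50.0, 0, 1, 0.0, "high"),
             PairFeatures("h2", 50.0, 0, 1, 0.0, "high"),
             PairFeatures("l", -50.0, 0, 1, 0.0, "low"),
             PairFeatures("l2", -50.0, 0, 1, 0.0, "low")]
    model = DFDModel(0.0, 1.0, 0.0)
    calibrate_thresholds(model, feats)
    assert model.thr_low > model.thr_high
    assert model.non_separating


# --- AUCs ------------------------------------------------------------------


def test_roc_auc_perfect_and_ties():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], ["high", "high", "low", "low"]) == 1.0
    assert roc_auc([0.5] * 6, ["high"] * 3 + ["low"] * 3) == 0.5


def test_roc_auc_equals_pairwise_oracle(rng):
    scores = rng.normal(size=40)
    labels = ["high" if v else "low" for v in rng.random(40) < 0.4]
    y = np.array([l == "high" for l in labels])
    pos, neg = scores[y], scores[~y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert roc_auc(scores, labels) == pytest.approx(wins / (len(pos) * len(neg)))


def test_roc_auc_complement_under_negation(rng):
    scores = rng.normal(size=30)  # tie-free
    labels = ["high"] * 10 + ["low"] * 20
    assert roc_auc(scores, labels) == pytest.approx(
        1 - roc_auc(-scores, labels)
    )


def test_aucs_match_sklearn(rng):
    from sklearn.metrics import average_precision_score, roc_auc_score

    scores = rng.normal(size=200)
    y = (rng.random(200) < 0.6).astype(int)
    labels = ["high" if v else "low" for v in y]
    assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(y, scores))
    assert pr_auc(scores, labels) == pytest.approx(
        average_precision_score(y, scores)
    )


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], ["high", "high"])


# --- cross-validation ------------------------------------------------------


def test_cross_validation_deterministic_and_calibrated():
    cfg = SimConfig(n_high=500, n_low=500)
    feats = feats_from_frame(simulate_pair_features(cfg, seed=3))
    cv1 = cross_validate(feats, n_rounds=25, seed=9)
    cv2 = cross_validate(feats, n_rounds=25, seed=9)
    pd.testing.assert_frame_equal(cv1, cv2)
    assert cv1["test_fpr_high_call"].mean() <= 0.07
    assert cv1["test_fpr_low_call"].mean() <= 0.07


def test_cross_validation_zero_rounds():
    cfg = SimConfig(n_high=20, n_low=20)
    feats = feats_from_frame(simulate_pair_features(cfg, seed=3))
    assert cross_validate(feats, n_rounds=0).empty


# --- variable importance ---------------------------------------------------


def test_informative_variable_ranks_first(rng):
    n = 500
    x = rng.normal(size=n)
    noise = rng.normal(size=n)
    y = np.where(rng.random(n) < expit(3 * x), "high", "low")
    table = pd.DataFrame({"signal": x, "noise": noise, "label": y})
    imp = relative_importance(table)
    assert imp.iloc[0]["variable"] == "signal"
    assert imp.iloc[0]["deviance_drop"] > imp.iloc[1]["deviance_drop"]


def test_duplicate_variables_tie_broken_by_name(rng):
    n = 200
    x = rng.normal(size=n)
    y = np.where(rng.random(n) < expit(2 * x), "high", "low")
    table = pd.DataFrame({"b_copy": x, "a_copy": x, "label": y})
    imp = relative_importance(table)
    # identical columns tie exactly; deterministic alphabetical order
    assert list(imp["variable"]) == ["a_copy", "b_copy"]


def test_single_variable_models_noise_is_chance(rng):
    n = 10000
    table = pd.DataFrame(
        {
            "noise": rng.normal(size=n),
            "label": np.where(rng.random(n) < 0.5, "high", "low"),
        }
    )
    res = single_variable_models(table)
    assert res.loc[res["variable"] == "noise", "roc_auc"].iloc[0] == pytest.approx(
        0.5, abs=0.02
    )


def test_model_round_trip(tmp_path):
    m = DFDModel(-0.1, 2.0, -0.5, thr_low=0.4, thr_high=0.8, n=100)
    p = tmp_path / "model.txt"
    m.save(p)
    m2 = DFDModel.load(p)
    assert m2.beta == pytest.approx(m.beta)
    assert (m2.thr_low, m2.thr_high, m2.n) == (0.4, 0.8, 100)
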