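"""Logistic model of the degree of functional divergence (DFD).

A duplicate pair's DFD is the fitted probability that the pair is
"high diversified" (each single knockout already shows an abnormal
phenotype), modelled as

    logit(DFD) = b0 + b1 * KA/KS + b2 * Re/KS

with high = 1. Decision thresholds are calibrated so that each call
type has at most a 5% false-positive rate on the training data: a pair
is called low when its DFD falls below the 5th percentile of the
true-high scores, high when above the 95th percentile of the true-low
scores, and is otherwise left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "DFDModel",
    "Classification",
    "SeparationError",
    "fit_lr",
    "dfd_score",
    "calibrate_thresholds",
    "classify",
    "roc_auc",
    "pr_auc",
    "cross_validate",
    "relative_importance",
    "single_variable_models",
]

LABEL_CODES = {"high": 1, "low": 0}


class SeparationError(RuntimeError):
    """Perfect separation: the ML logistic fit diverges.

    Refit with ``ridge_fallback=True`` (L2 penalty, lambda = 1e-6).
    """


@dataclass
class DFDModel:
    beta0: float
    beta_kaks: float
    beta_reks: float
    thr_low: float | None = None
    thr_high: float | None = None
    n: int = 0
    converged: bool = True
    log_likelihood: float = float("nan")
    ridge: bool = False
    non_separating: bool = False
    method: str = "irls-logit"

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_kaks, self.beta_reks])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}\t{v}\n")

    @classmethod
    def load(cls, path) -> "DFDModel":
        kv: dict = {}
        with open(path) as fh:
            for line in fh:
                k, v = line.rstrip("\n").split("\t")
                kv[k] = v
        conv = {
            "beta0": float, "beta_kaks": float, "beta_reks": float,
            "thr_low": lambda s: None if s == "None" else float(s),
            "thr_high": lambda s: None if s == "None" else float(s),
            "n": int,
            "converged": lambda s: s == "True",
            "log_likelihood": float,
            "ridge": lambda s: s == "True",
            "non_separating": lambda s: s == "True",
            "method": str,
        }
        return cls(**{k: conv[k](v) for k, v in kv.items() if k in conv})


@dataclass(frozen=True)
class Classification:
    pair_id: str
    dfd: float
    call: str  # high / low / unclassified


def _encode(labels) -> np.ndarray:
    y = np.asarray([LABEL_CODES[l] for l in labels], dtype=float)
    return y


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool, float]:
    """Iteratively reweighted least squares for a logit-link binomial GLM.

    Converges when the largest coefficient update falls below ``tol``.
    An optional L2 penalty (not applied to the intercept) stabilises
    separated data.
    """
    n, p = X.shape
    beta = np.zeros(p)
    penalty = np.full(p, ridge_lambda)
    penalty[0] = 0.0
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        A = X.T @ (w[:, None] * X) + np.diag(penalty)
        beta_new = np.linalg.solve(A, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta, -700, 700)
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    if ridge_lambda > 0:
        loglik_pen = loglik  # penalty negligible at 1e-6; report unpenalised
        loglik = loglik_pen
    return beta, converged, loglik


def _design(features) -> tuple[np.ndarray, np.ndarray, list[str]]:
    ka_ks = np.asarray([f.ka_ks for f in features], dtype=float)
    re_ks = np.asarray([f.re_ks for f in features], dtype=float)
    labels = [f.label for f in features]
    X = np.column_stack([np.ones_like(ka_ks), ka_ks, re_ks])
    return X, _encode(labels), labels


def fit_lr(features, labels=None, ridge_fallback: bool = True) -> DFDModel:
    """Maximum-likelihood logistic fit of DFD on KA/KS and Re/KS.

    ``features`` is a list of PairFeatures (labels taken from each
    feature unless ``labels`` is passed). Outcome coding: high = 1.
    Requires at least two pairs of each class. On perfect separation the
    fit is redone with an L2 penalty of 1e-6 (``ridge_fallback``) or a
    :class:`SeparationError` is raised.
    """
    X, y, _ = _design(features)
    if labels is not None:
        y = _encode(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    n_high, n_low = int(y.sum()), int((1 - y).sum())
    if n_high < 2 or n_low < 2:
        raise ValueError(
            f"need >=2 pairs per class, got high={n_high}, low={n_low}"
        )
    try:
        beta, converged, loglik = _irls(X, y)
        separated = (not converged) or np.max(np.abs(beta)) > 1e3
    except np.linalg.LinAlgError:  # weights collapse under separation
        separated = True
    ridge = False
    if separated:
        if not ridge_fallback:
            raise SeparationError(
                "logistic fit did not converge (likely perfect separation); "
                "use ridge_fallback=True"
            )
        beta, converged, loglik = _irls(X, y, ridge_lambda=1e-6)
        ridge = True
    return DFDModel(
        beta0=float(beta[0]),
        beta_kaks=float(beta[1]),
        beta_reks=float(beta[2]),
        n=len(y),
        converged=converged,
        log_likelihood=loglik,
        ridge=ridge,
    )


def dfd_score(model: DFDModel, ka_ks, re_ks) -> np.ndarray | float:
    """DFD = logistic(b0 + b1*KA/KS + b2*Re/KS); always in (0, 1)."""
    score = expit(model.beta0 + model.beta_kaks * np.asarray(ka_ks)
                  + model.beta_reks * np.asarray(re_ks))
    if np.ndim(ka_ks) == 0:
        return float(score)
    return score


def _scores_for(model: DFDModel, features) -> np.ndarray:
    return np.asarray(
        [dfd_score(model, f.ka_ks, f.re_ks) for f in features], dtype=float
    )


def calibrate_thresholds(
    model: DFDModel, features, labels=None, fpr: float = 0.05
) -> DFDModel:
    """Set the low/high decision thresholds at a given false-positive rate.

    thr_low is the ``fpr`` quantile of DFD among true-high pairs (so at
    most that share of highs would be miscalled low); thr_high is the
    ``1 - fpr`` quantile among true-low pairs. Quantiles use linear
    interpolation. When the classes overlap so much that thr_low >
    thr_high, both are still returned and the model is flagged
    ``non_separating``.
    """
    scores = _scores_for(model, features)
    y = _encode(labels) if labels is not None else _encode([f.label for f in features])
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise ValueError("both classes required for threshold calibration")
    thr_low = float(np.percentile(scores[y == 1], 100 * fpr))
    thr_high = float(np.percentile(scores[y == 0], 100 * (1 - fpr)))
    model.thr_low = thr_low
    model.thr_high = thr_high
    model.non_separating = thr_low > thr_high
    return model


def classify(model: DFDModel, features) -> list[Classification]:
    """Three-way call per pair: high (DFD > thr_high), low (< thr_low),
    else unclassified. Boundary scores are unclassified."""
    if model.thr_low is None or model.thr_high is None:
        raise ValueError("model has no calibrated thresholds")
    out = []
    for f in features:
        d = dfd_score(model, f.ka_ks, f.re_ks)
        if d > model.thr_high:
            call = "high"
        elif d < model.thr_low:
            call = "low"
        else:
            call = "unclassified"
        out.append(Classification(f.pair_id, d, call))
    return out


def classification_counts(calls: list[Classification]) -> dict[str, int]:
    counts = {"high": 0, "low": 0, "unclassified": 0}
    for c in calls:
        counts[c.call] += 1
    return counts


def roc_auc(scores, labels) -> float:
    """ROC AUC via the Mann–Whitney U identity (average ranks for ties).

    Positive class = high.
    """
    y = _encode(labels) if not isinstance(labels, np.ndarray) else labels
    scores = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC AUC")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def pr_auc(scores, labels) -> float:
    """Precision–recall AUC by step-wise interpolation over descending
    score thresholds (positive class = high)."""
    y = _encode(labels) if not isinstance(labels, np.ndarray) else labels
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("both classes required for PR AUC")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # evaluate only at distinct-threshold boundaries
    boundary = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[boundary], fp[boundary]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum(precision * (recall - prev_recall)))


def cross_validate(
    features, n_rounds: int = 100, fpr: float = 0.05, seed: int = 0,
    test_frac: float = 0.2,
) -> pd.DataFrame:
    """Repeated stratified random 80/20 splits.

    Per round: fit on the training split, calibrate thresholds on the
    training split, then measure on the held-out split the realised
    false-positive rate of each call type and the ROC AUC. Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    y = _encode([f.label for f in features])
    idx_high = np.flatnonzero(y == 1)
    idx_low = np.flatnonzero(y == 0)
    rows = []
    for rnd in range(n_rounds):
        test = set()
        for idx in (idx_high, idx_low):
            perm = rng.permutation(idx)
            n_test = max(1, int(round(test_frac * len(idx))))
            test.update(perm[:n_test].tolist())
        train_f = [f for i, f in enumerate(features) if i not in test]
        test_f = [f for i, f in enumerate(features) if i in test]
        model = fit_lr(train_f)
        calibrate_thresholds(model, train_f, fpr=fpr)
        calls = classify(model, test_f)
        yt = _encode([f.label for f in test_f])
        calls_arr = np.array([c.call for c in calls])
        n_low_true = int((yt == 0).sum())
        n_high_true = int((yt == 1).sum())
        fpr_high = float((calls_arr[yt == 0] == "high").sum() / n_low_true)
        fpr_low = float((calls_arr[yt == 1] == "low").sum() / n_high_true)
        auc = roc_auc([c.dfd for c in calls], [f.label for f in test_f])
        rows.append(
            {
                "round": rnd,
                "thr_low": model.thr_low,
                "thr_high": model.thr_high,
                "test_fpr_high_call": fpr_high,
                "test_fpr_low_call": fpr_low,
                "test_roc_auc": auc,
            }
        )
    return pd.DataFrame(rows)


# --- generic multi-variable fits (relative importance, single-variable) ----


def _fit_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    try:
        beta, converged, loglik = _irls(X, y)
    except np.linalg.LinAlgError:  # collinear design
        beta, converged, loglik = _irls(X, y, ridge_lambda=1e-6)
        return beta, loglik, True
    if (not converged) or np.max(np.abs(beta)) > 1e3:
        beta, converged, loglik = _irls(X, y, ridge_lambda=1e-6)
        return beta, loglik, True
    return beta, loglik, False


def relative_importance(
    table: pd.DataFrame, label_col: str = "label", variables=None
) -> pd.DataFrame:
    """Rank explanatory variables by drop-in-deviance.

    A variable's importance is the increase in residual deviance when it
    is removed from the full logistic model (2 * (loglik_full -
    loglik_reduced)). Ties are broken deterministically by variable
    name.
    """
    if variables is None:
        variables = [c for c in table.columns if c != label_col]
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    y = _encode(table[label_col].tolist())
    X_full = np.column_stack(
        [np.ones(len(table))] + [table[v].to_numpy(dtype=float) for v in variables]
    )
    _, ll_full, ridge_full = _fit_design(X_full, y)
    rows = []
    for v in variables:
        keep = [w for w in variables if w != v]
        X_red = np.column_stack(
            [np.ones(len(table))] + [table[w].to_numpy(dtype=float) for w in keep]
        )
        _, ll_red, ridge_red = _fit_design(X_red, y)
        rows.append(
            {
                "variable": v,
                "deviance_drop": 2.0 * (ll_full - ll_red),
                "ridge_flag": ridge_full or ridge_red,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["deviance_drop", "variable"], ascending=[False, True], kind="stable"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def single_variable_models(
    table: pd.DataFrame, label_col: str = "label", variables=None
) -> pd.DataFrame:
    """One logistic fit per variable; report each model's ROC and PR AUC."""
    if variables is None:
        variables = [c for c in table.columns if c != label_col]
    y = _encode(table[label_col].tolist())
    labels = table[label_col].tolist()
    rows = []
    for v in variables:
        x = table[v].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        beta, _, _ = _fit_design(X, y)
        scores = expit(X @ beta)
        rows.append(
            {
                "variable": v,
                "roc_auc": roc_auc(scores, labels),
                "pr_auc": pr_auc(scores, labels),
            }
        )
    return pd.DataFrame(rows)
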