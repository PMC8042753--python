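"""End-to-end orchestration of the duplicate-divergence analysis.

Stage order: sequence divergence -> expression similarity -> model
training (or loading) -> classification -> functional-bias report ->
ortholog/branch analyses. Every stage writes TSV outputs into the run
directory and appends its row counts to a manifest; a failure aborts
with a stage-named error, preserving the partial outputs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias_stats, dfd_model, expr_similarity, seq_divergence
from .expr_similarity import ExpressionMatrix, build_features, features_to_frame
from .ortholog_evolution import call_triplet_selection, retention_analysis

__all__ = ["RunConfig", "StageError", "run_full_pipeline", "paper_mode",
           "divergence_table"]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs, outputs and knobs for one pipeline run."""

    cds_fasta: str = ""
    pep_fasta: str = ""
    pairs_tsv: str = ""
    expression_tsv: str = ""
    annotations_tsv: str = ""
    triplets_tsv: str = ""
    out_dir: str = "run"
    min_identity: float = 0.30
    min_coverage: float = 0.50
    max_ks: float = 3.0
    fpr: float = 0.05
    seed: int = 0
    yates: bool = True
    shared_mode: str = "jaccard"
    exact_wilcoxon_cutoff: int = 12

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_coverage <= 1):
            raise ValueError("identity/coverage thresholds must be in [0, 1]")
        if not 0 < self.fpr < 1:
            raise ValueError("fpr must be in (0, 1)")
        if self.max_ks <= 0:
            raise ValueError("max_ks must be positive")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def divergence_table(
    records: dict[str, seq_divergence.GeneRecord],
    pairs: pd.DataFrame,
    min_identity: float = 0.30,
    min_coverage: float = 0.50,
    max_ks: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every pair (align, back-translate, NG86) and filter.

    Pair-table rows with precomputed ``ka``/``ks`` (e.g. from an
    external estimator) are used as-is and skip alignment. Returns
    (kept, rejected) frames; kept carries gene_a, gene_b, label,
    identity, coverage, ka, ks, ka_ks.
    """
    scored = []
    for _, row in pairs.iterrows():
        entry = {
            "gene_a": row["gene_a"],
            "gene_b": row["gene_b"],
            "label": row.get("label", "unknown"),
        }
        if "ks" in row and pd.notna(row.get("ks")) and pd.notna(row.get("ka")):
            entry.update(
                identity=1.0, coverage=1.0,
                ka=float(row["ka"]), ks=float(row["ks"]),
            )
            scored.append(entry)
            continue
        rec_a = records.get(row["gene_a"])
        rec_b = records.get(row["gene_b"])
        if rec_a is None or rec_b is None:
            entry["error"] = "missing_sequence"
            scored.append(entry)
            continue
        aln, est = seq_divergence.pair_divergence(rec_a, rec_b)
        entry.update(
            identity=aln.identity, coverage=aln.coverage,
            ka=est.ka if est.ka is not None else np.nan,
            ks=est.ks,
        )
        scored.append(entry)
    result = seq_divergence.filter_pairs(
        scored, min_identity, min_coverage, max_ks
    )
    kept = pd.DataFrame(result.kept)
    if not kept.empty:
        kept["ka_ks"] = np.where(kept["ks"] > 0, kept["ka"] / kept["ks"], np.nan)
    rejected = pd.DataFrame(
        result.rejected,
        columns=["gene_a", "gene_b", "label", "identity", "coverage", "ka",
                 "ks", "reasons"] if not result.rejected else None,
    )
    return kept, rejected


def run_full_pipeline(config: RunConfig) -> Path:
    """Run every stage on the configured inputs; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def log(stage: str, n_in: int, n_out: int, t0: float) -> None:
        manifest.append(
            {"stage": stage, "rows_in": n_in, "rows_out": n_out,
             "elapsed_s": round(time.monotonic() - t0, 3)}
        )

    for name in ("cds_fasta", "pep_fasta", "pairs_tsv", "expression_tsv"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise StageError("inputs", f"missing input {name}={path!r}")

    # divergence
    t0 = time.monotonic()
    try:
        cds = seq_divergence.read_fasta(config.cds_fasta)
        pep = seq_divergence.read_fasta(config.pep_fasta)
        records = seq_divergence.build_gene_records(cds, pep)
        pairs = pd.read_csv(config.pairs_tsv, sep="\t")
        kept, rejected = divergence_table(
            records, pairs, config.min_identity, config.min_coverage,
            config.max_ks,
        )
        kept.to_csv(out / "divergence.tsv", sep="\t", index=False)
        rejected.to_csv(out / "rejected.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("divergence", str(exc)) from exc
    log("divergence", len(pairs), len(kept), t0)

    # expression features
    t0 = time.monotonic()
    try:
        mat = ExpressionMatrix.from_tsv(config.expression_tsv)
        feats, excluded = build_features(kept, mat)
        fdf = features_to_frame(feats)
        fdf.to_csv(out / "features.tsv", sep="\t", index=False)
        pd.DataFrame(excluded, columns=["pair", "reason"]).to_csv(
            out / "excluded.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise StageError("expression", str(exc)) from exc
    log("expression", len(kept), len(feats), t0)

    # train + classify
    t0 = time.monotonic()
    try:
        labelled = [f for f in feats if f.label in ("high", "low")]
        model = dfd_model.fit_lr(labelled)
        dfd_model.calibrate_thresholds(model, labelled, fpr=config.fpr)
        model.save(out / "model.txt")
        calls = dfd_model.classify(model, feats)
        calls_df = pd.DataFrame(
            [{"pair": c.pair_id, "dfd": c.dfd, "call": c.call} for c in calls]
        )
        calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
        counts = dfd_model.classification_counts(calls)
    except Exception as exc:
        raise StageError("model", str(exc)) from exc
    log("model", len(feats), sum(counts.values()), t0)

    # bias report
    t0 = time.monotonic()
    n_bias = 0
    if config.annotations_tsv and Path(config.annotations_tsv).exists():
        try:
            ann = bias_stats.AnnotationSets.from_tsv(config.annotations_tsv)
            gene_calls = _gene_level_calls(calls_df)
            breadth = expr_similarity.expression_breadth(mat)
            report = bias_stats.bias_report(
                gene_calls, ann, breadth, yates=config.yates
            )
            (out / "bias_report.txt").write_text(
                bias_stats.report_to_text(report) + "\n"
            )
            n_bias = len(gene_calls)
        except Exception as exc:
            raise StageError("bias", str(exc)) from exc
    log("bias", len(calls_df), n_bias, t0)

    pd.DataFrame(manifest).to_csv(out / "manifest.tsv", sep="\t", index=False)
    cfg_path = out / "config.yaml"
    config.save(cfg_path)
    return out


def _gene_level_calls(calls_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, row in calls_df.iterrows():
        ga, gb = row["pair"].split("|", 1)
        for g in (ga, gb):
            rows.append({"gene": g, "call": row["call"]})
    return pd.DataFrame(rows)


def paper_mode(features: pd.DataFrame, fpr: float = 0.05) -> dict:
    """Fit, calibrate and evaluate on a precomputed feature table.

    ``features`` must carry ka_ks, re_ks and label (high/low) columns —
    the reproduction path for an externally supplied training table.
    Returns the fitted model, thresholds and ROC/PR AUCs.
    """
    for col in ("ka_ks", "re_ks", "label"):
        if col not in features.columns:
            raise ValueError(f"feature table lacks required column {col!r}")
    feats = [
        expr_similarity.PairFeatures(
            str(row.get("pair", i)), float(row["ka_ks"]), float("nan"),
            float(row.get("ks", np.nan)), float(row["re_ks"]),
            str(row["label"]),
        )
        for i, row in features.iterrows()
    ]
    model = dfd_model.fit_lr(feats)
    dfd_model.calibrate_thresholds(model, feats, fpr=fpr)
    scores = [dfd_model.dfd_score(model, f.ka_ks, f.re_ks) for f in feats]
    labels = [f.label for f in feats]
    return {
        "model": model,
        "beta": (model.beta0, model.beta_kaks, model.beta_reks),
        "thr_low": model.thr_low,
        "thr_high": model.thr_high,
        "roc_auc": dfd_model.roc_auc(scores, labels),
        "pr_auc": dfd_model.pr_auc(scores, labels),
        "n": len(feats),
    }


def ortholog_report(triplets, yates: bool = True) -> dict:
    """Retention rates plus per-branch selection calls for complete triplets."""
    retention = retention_analysis(triplets, yates=yates)
    rows = []
    for t in triplets:
        if not t.complete:
            continue
        b_al, b_br = call_triplet_selection(t)
        for b in (b_al, b_br):
            rows.append(
                {
                    "at_gene": t.at_gene,
                    "branch": b.branch,
                    "class": t.pair_class,
                    "mechanism": t.mechanism,
                    "ka": b.ka,
                    "ks": b.ks,
                    "ka_ks": b.ka_ks,
                    "selection": b.selection,
                }
            )
    return {"retention": retention, "branches": pd.DataFrame(rows)}
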