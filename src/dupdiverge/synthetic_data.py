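"""Synthetic inputs with the statistical structure the pipeline assumes.

Generates every input the analysis consumes — codon sequences evolved
under a chosen nonsynonymous/synonymous rate ratio (omega), expression
profiles with a chosen Spearman correlation, class-labelled pair
tables, per-gene annotations with planted biases, and ortholog triplets
with class-dependent retention — so every stage is testable without any
database downloads.

Planted contrasts (all configurable, defaults chosen once to mirror the
qualitative structure of real duplicate-pair data):

* high diversified pairs draw omega from a lognormal with mean ~0.8,
  low diversified pairs ~0.15 (protein divergence contrast);
* expression Spearman targets ~0.2 (high) vs ~0.7 (low);
* ortholog retention 0.41 (high) vs 0.67 (low) in A. lyrata and
  0.26 vs 0.38 in B. rapa;
* tandem/WGD mechanism mix 0.67 tandem (high) vs 0.27 (low);
* branch omegas 1.5 for high-tandem vs 0.2 for low-WGD.

The codon mutation process is a simplified accept/reject scheme, not a
full codon rate matrix: point mutations arrive as a Poisson process,
proposals creating stop codons are rejected, nonsynonymous proposals
are accepted with probability min(1, omega) (for omega > 1 the proposal
intensity is scaled up and synonymous acceptance scaled down, so the
nonsynonymous/synonymous rate ratio is omega while the expected
synonymous divergence stays calibrated). All randomness derives from a
single seed; generation is byte-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expr_similarity import ExpressionMatrix
from .ortholog_evolution import OrthologTriplet
from .seq_divergence import (
    CODON_TABLE,
    SENSE_CODONS,
    CodonAlignment,
    GeneRecord,
)

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_codon_pair",
    "simulate_expression_pair",
    "simulate_pair_features",
    "simulate_lr_features",
    "simulate_triplets",
    "simulate_selection_groups",
    "simulate_singleton_controls",
    "simulate_dataset",
    "write_bundle",
]

_NUCS = "ACGT"


@dataclass
class SimConfig:
    """Generative parameters for a full synthetic input bundle."""

    n_high: int = 500
    n_low: int = 500
    # lognormal omega distributions: (mean omega, sigma of log-omega)
    omega_high: tuple[float, float] = (0.8, 0.8)
    omega_low: tuple[float, float] = (0.15, 0.8)
    # pairwise synonymous divergence (KS target) range
    t_range: tuple[float, float] = (0.1, 2.5)
    # expression Spearman targets: (mean rho, sd)
    rho_high: tuple[float, float] = (0.2, 0.25)
    rho_low: tuple[float, float] = (0.7, 0.25)
    n_conditions: int = 634
    n_codons: int = 300
    # ortholog retention probabilities by class
    retention_al: dict = field(default_factory=lambda: {"high": 0.41, "low": 0.67})
    retention_br: dict = field(default_factory=lambda: {"high": 0.26, "low": 0.38})
    # P(tandem) by class; remainder is WGD
    tandem_frac: dict = field(default_factory=lambda: {"high": 0.67, "low": 0.27})
    # branch omega by (class, mechanism) for the ortholog tree
    omega_branch: dict = field(
        default_factory=lambda: {
            ("high", "tandem"): 1.5,
            ("high", "wgd"): 0.8,
            ("low", "tandem"): 0.4,
            ("low", "wgd"): 0.2,
        }
    )
    omega_singleton: float = 0.4
    # branch synonymous divergences of the 3-taxon tree
    t_branch_at: float = 0.075
    t_branch_al: float = 0.075
    t_branch_as: float = 0.175  # AS2 -> AS1
    t_branch_br: float = 0.25
    # planted annotation biases
    ppi_mean: dict = field(default_factory=lambda: {"high": 3.0, "low": 9.0})
    core_frac: dict = field(default_factory=lambda: {"high": 0.02, "low": 0.14})
    go_terms_per_gene: int = 5
    go_share_prob: dict = field(default_factory=lambda: {"high": 0.3, "low": 0.8})
    n_go_terms: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.retention_al, self.retention_br, self.tandem_frac):
            for v in d.values():
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must be in [0, 1]")
        if self.n_conditions < 3:
            raise ValueError("need at least 3 conditions")


def _lognormal_omega(rng, mean_omega: float, sigma: float) -> float:
    mu = math.log(mean_omega) - sigma**2 / 2.0
    return float(rng.lognormal(mu, sigma))


def _random_cds(rng, n_codons: int) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def _translate(cds: str) -> str:
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def _evolve(cds: str, t: float, omega: float, rng) -> str:
    """Evolve a CDS along one branch of expected synonymous divergence t.

    Proposal intensity and acceptance probabilities are set so the
    expected number of synonymous substitutions per synonymous site is t
    and the nonsynonymous/synonymous rate ratio is omega.
    """
    if t <= 0:
        return cds
    seq = list(cds)
    n_sites = len(seq)
    if omega <= 1:
        a_syn, a_non = 1.0, omega
    else:
        a_syn, a_non = 1.0 / omega, 1.0
    n_prop = rng.poisson(n_sites * t / a_syn)
    for _ in range(n_prop):
        site = int(rng.integers(0, n_sites))
        old = seq[site]
        alt = _NUCS.replace(old, "")[int(rng.integers(0, 3))]
        c0 = 3 * (site // 3)
        codon = "".join(seq[c0 : c0 + 3])
        new_codon = codon[: site - c0] + alt + codon[site - c0 + 1 :]
        aa_old, aa_new = CODON_TABLE[codon], CODON_TABLE[new_codon]
        if aa_new == "*":
            continue
        accept = a_syn if aa_new == aa_old else a_non
        if accept >= 1.0 or rng.random() < accept:
            seq[site] = alt
    return "".join(seq)


def simulate_codon_pair(
    length: int, t: float, omega: float, seed: int | np.random.Generator = 0
) -> tuple[str, str, dict]:
    """Two coding sequences diverged from a random ancestor.

    ``t`` is the expected pairwise synonymous divergence (each lineage
    evolves t/2). Returns (cds_a, cds_b, true-parameter dict).
    """
    if length < 1 or t < 0 or omega < 0:
        raise ValueError("length >= 1, t >= 0, omega >= 0 required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = _random_cds(rng, length)
    a = _evolve(anc, t / 2.0, omega, rng)
    b = _evolve(anc, t / 2.0, omega, rng)
    return a, b, {"t": t, "omega": omega, "length": length}


def simulate_expression_pair(
    n_conditions: int, target_rho: float, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two expression profiles with population Spearman = target_rho.

    Bivariate normal through a Gaussian copula with Pearson
    r = 2 sin(pi * rho / 6), exponentiated to an intensity-like scale.
    """
    if n_conditions < 3 or not -1 <= target_rho <= 1:
        raise ValueError("n_conditions >= 3 and rho in [-1, 1] required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = 2.0 * math.sin(math.pi * target_rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_conditions,
                                method="cholesky")
    x = np.exp(6.0 + 1.5 * z[:, 0])
    y = np.exp(6.0 + 1.5 * z[:, 1])
    return x, y


def simulate_pair_features(
    config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Class-conditional pair features without sequence simulation.

    Draws KA/KS directly from the class omega distributions, KS from
    ``t_range`` and Re from the class rho distributions, for fast
    model-level studies (fitting, calibration, cross-validation).
    Columns: pair, ka_ks, re, ks, re_ks, label.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for label, n, (om_mean, om_sig), (rho_mean, rho_sd) in (
        ("high", config.n_high, config.omega_high, config.rho_high),
        ("low", config.n_low, config.omega_low, config.rho_low),
    ):
        for i in range(n):
            ka_ks = _lognormal_omega(rng, om_mean, om_sig)
            ks = float(rng.uniform(*config.t_range))
            re = float(np.clip(rng.normal(rho_mean, rho_sd), -1.0, 1.0))
            rows.append(
                {
                    "pair": f"{label}_{i}",
                    "ka_ks": ka_ks,
                    "re": re,
                    "ks": ks,
                    "re_ks": re / ks,
                    "label": label,
                }
            )
    return pd.DataFrame(rows)


def simulate_lr_features(
    beta: tuple[float, float, float], n: int, seed: int = 0
) -> pd.DataFrame:
    """Features and labels drawn from a known logistic model.

    Covariates: ka_ks lognormal, re_ks normal; the label is Bernoulli
    with P(high) = logistic(b0 + b1*ka_ks + b2*re_ks). Used for
    coefficient-recovery checks.
    """
    rng = np.random.default_rng(seed)
    ka_ks = rng.lognormal(-1.0, 0.8, size=n)
    re_ks = rng.normal(0.5, 1.0, size=n)
    eta = beta[0] + beta[1] * ka_ks + beta[2] * re_ks
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(
        {
            "pair": [f"p{i}" for i in range(n)],
            "ka_ks": ka_ks,
            "re_ks": re_ks,
            "label": np.where(y, "high", "low"),
        }
    )


def _self_alignment(cds_a: str, cds_b: str) -> CodonAlignment:
    """Codon alignment of two equal-length, indel-free CDS."""
    cols = tuple(
        (cds_a[i : i + 3], cds_b[i : i + 3]) for i in range(0, len(cds_a), 3)
    )
    return CodonAlignment(cols)


def simulate_triplets(
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
    sequences: bool = True,
) -> list[OrthologTriplet]:
    """Ortholog triplets with class-dependent retention and branch omegas.

    Topology: ancestor AS2 splits into the B. rapa branch and AS1; AS1
    splits into the A. thaliana and A. lyrata branches. Sequences are
    simulated only when both orthologs are retained (the branch analysis
    needs all three taxa); retention itself is Bernoulli per species
    with the class-specific probability.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    triplets = []
    for label, n in (("high", config.n_high), ("low", config.n_low)):
        for i in range(n):
            mech = "tandem" if rng.random() < config.tandem_frac[label] else "wgd"
            has_al = rng.random() < config.retention_al[label]
            has_br = rng.random() < config.retention_br[label]
            at_gene = f"At_{label}_{i}"
            trip = OrthologTriplet(
                at_gene=at_gene,
                al_gene=f"Al_{label}_{i}" if has_al else None,
                br_gene=f"Br_{label}_{i}" if has_br else None,
                pair_class=label,
                mechanism=mech,
            )
            if has_al and has_br and sequences:
                omega = config.omega_branch[(label, mech)]
                anc = _random_cds(rng, config.n_codons)
                seq_br = _evolve(anc, config.t_branch_br, omega, rng)
                as1 = _evolve(anc, config.t_branch_as, omega, rng)
                seq_at = _evolve(as1, config.t_branch_at, omega, rng)
                seq_al = _evolve(as1, config.t_branch_al, omega, rng)
                trip.aln_at_al = _self_alignment(seq_at, seq_al)
                trip.aln_at_br = _self_alignment(seq_at, seq_br)
                trip.aln_al_br = _self_alignment(seq_al, seq_br)
            triplets.append(trip)
    return triplets


def simulate_selection_groups(
    config: SimConfig,
    n_per_group: dict | int = 50,
    seed: int | np.random.Generator | None = None,
) -> list[OrthologTriplet]:
    """Complete (three-taxon) triplets for each class x mechanism group.

    Used for selection-proportion studies, where only triplets with both
    orthologs retained are informative; each group's branches evolve at
    its ``omega_branch`` rate. ``n_per_group`` may be a single count or
    a {(class, mechanism): count} mapping.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    out = []
    for (label, mech), omega in sorted(config.omega_branch.items()):
        n = n_per_group if isinstance(n_per_group, int) else n_per_group.get(
            (label, mech), 0
        )
        for i in range(n):
            anc = _random_cds(rng, config.n_codons)
            seq_br = _evolve(anc, config.t_branch_br, omega, rng)
            as1 = _evolve(anc, config.t_branch_as, omega, rng)
            seq_at = _evolve(as1, config.t_branch_at, omega, rng)
            seq_al = _evolve(as1, config.t_branch_al, omega, rng)
            out.append(
                OrthologTriplet(
                    at_gene=f"At_{label}_{mech}_{i}",
                    al_gene=f"Al_{label}_{mech}_{i}",
                    br_gene=f"Br_{label}_{mech}_{i}",
                    pair_class=label,
                    mechanism=mech,
                    aln_at_al=_self_alignment(seq_at, seq_al),
                    aln_at_br=_self_alignment(seq_at, seq_br),
                    aln_al_br=_self_alignment(seq_al, seq_br),
                )
            )
    return out


def simulate_singleton_controls(
    config: SimConfig, n: int = 200, seed: int | np.random.Generator | None = None
) -> list[OrthologTriplet]:
    """One-to-one ortholog controls evolved at the singleton omega."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    out = []
    for i in range(n):
        anc = _random_cds(rng, config.n_codons)
        omega = config.omega_singleton
        seq_br = _evolve(anc, config.t_branch_br, omega, rng)
        as1 = _evolve(anc, config.t_branch_as, omega, rng)
        seq_at = _evolve(as1, config.t_branch_at, omega, rng)
        seq_al = _evolve(as1, config.t_branch_al, omega, rng)
        out.append(
            OrthologTriplet(
                at_gene=f"At_single_{i}",
                al_gene=f"Al_single_{i}",
                br_gene=f"Br_single_{i}",
                pair_class="singleton",
                mechanism="other",
                aln_at_al=_self_alignment(seq_at, seq_al),
                aln_at_br=_self_alignment(seq_at, seq_br),
                aln_al_br=_self_alignment(seq_al, seq_br),
            )
        )
    return out


@dataclass
class SimBundle:
    """A complete synthetic input set plus its true-parameter manifest."""

    records: dict[str, GeneRecord]
    pairs: pd.DataFrame  # gene_a, gene_b, label
    expression: ExpressionMatrix
    annotations: pd.DataFrame  # gene, go, domains, ppi_degree, core, mechanism
    triplets: list[OrthologTriplet]
    manifest: dict


def simulate_dataset(config: SimConfig, sequences: bool = True) -> SimBundle:
    """Generate the full input bundle for an end-to-end run.

    High-class pairs draw omega from ``omega_high`` and Spearman targets
    from ``rho_high``; low-class the reverse. Annotations are planted
    with the class-dependent PPI/core/GO/mechanism biases; ortholog
    triplets follow the retention probabilities. ``sequences=False``
    skips CDS simulation (feature tables only, much faster).
    """
    rng = np.random.default_rng(config.seed)
    records: dict[str, GeneRecord] = {}
    pair_rows, ann_rows, truth = [], [], []
    expr_profiles: dict[str, np.ndarray] = {}
    go_pool = [f"GO:{i:07d}" for i in range(config.n_go_terms)]
    dom_pool = [f"PF{i:05d}" for i in range(config.n_go_terms // 4)]

    for label, n, om_cfg, rho_cfg in (
        ("high", config.n_high, config.omega_high, config.rho_high),
        ("low", config.n_low, config.omega_low, config.rho_low),
    ):
        for i in range(n):
            ga, gb = f"{label}{i}a", f"{label}{i}b"
            omega = _lognormal_omega(rng, *om_cfg)
            t = float(rng.uniform(*config.t_range))
            rho = float(np.clip(rng.normal(*rho_cfg), -1.0, 1.0))
            if sequences:
                cds_a, cds_b, _ = simulate_codon_pair(
                    config.n_codons, t, omega, rng
                )
                records[ga] = GeneRecord(ga, cds_a, _translate(cds_a))
                records[gb] = GeneRecord(gb, cds_b, _translate(cds_b))
            xa, xb = simulate_expression_pair(config.n_conditions, rho, rng)
            expr_profiles[ga], expr_profiles[gb] = xa, xb
            pair_rows.append({"gene_a": ga, "gene_b": gb, "label": label})
            truth.append(
                {"gene_a": ga, "gene_b": gb, "label": label,
                 "true_omega": omega, "true_t": t, "true_rho": rho}
            )
            mech = "tandem" if rng.random() < config.tandem_frac[label] else "wgd"
            shared_go = [
                term for term in rng.choice(go_pool, config.go_terms_per_gene,
                                            replace=False)
                if rng.random() < config.go_share_prob[label]
            ]
            for g in (ga, gb):
                own_go = list(
                    rng.choice(go_pool, config.go_terms_per_gene, replace=False)
                )
                go = sorted(set(shared_go + own_go[: config.go_terms_per_gene
                                                   - len(shared_go)]))
                domains = sorted(
                    rng.choice(dom_pool, 2, replace=False).tolist()
                )
                ann_rows.append(
                    {
                        "gene": g,
                        "go": ";".join(go),
                        "domains": ";".join(domains),
                        "ppi_degree": int(rng.poisson(config.ppi_mean[label])),
                        "core": int(rng.random() < config.core_frac[label]),
                        "mechanism": mech,
                    }
                )

    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "label"])
    annotations = pd.DataFrame(
        ann_rows,
        columns=["gene", "go", "domains", "ppi_degree", "core", "mechanism"],
    )
    cond_ids = [f"cond{j}" for j in range(config.n_conditions)]
    if expr_profiles:
        expr = ExpressionMatrix(
            pd.DataFrame.from_dict(expr_profiles, orient="index",
                                   columns=cond_ids)
        )
    else:
        expr = ExpressionMatrix(
            pd.DataFrame(np.empty((0, config.n_conditions)), columns=cond_ids)
        )
    triplets = simulate_triplets(config, rng) if sequences else []
    manifest = {
        "config": {k: str(v) for k, v in vars(config).items()},
        "truth": truth,
    }
    return SimBundle(records, pairs, expr, annotations, triplets, manifest)


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write a bundle in the formats the pipeline reads (FASTA + TSV)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "cds.fa", "w") as cds_fh, open(out / "pep.fa", "w") as pep_fh:
        for gid in sorted(bundle.records):
            rec = bundle.records[gid]
            cds_fh.write(f">{gid}\n{rec.cds}\n")
            pep_fh.write(f">{gid}\n{rec.protein}\n")
    bundle.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    bundle.expression.to_tsv(out / "expression.tsv")
    bundle.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    trip_rows = [
        {
            "at_gene": t.at_gene,
            "al_gene": t.al_gene or "-",
            "br_gene": t.br_gene or "-",
            "class": t.pair_class,
            "mechanism": t.mechanism,
        }
        for t in bundle.triplets
    ]
    pd.DataFrame(
        trip_rows, columns=["at_gene", "al_gene", "br_gene", "class", "mechanism"]
    ).to_csv(out / "triplets.tsv", sep="\t", index=False)
    with open(out / "manifest.tsv", "w") as fh:
        for k, v in bundle.manifest["config"].items():
            fh.write(f"{k}\t{v}\n")
    pd.DataFrame(bundle.manifest["truth"]).to_csv(
        out / "truth.tsv", sep="\t", index=False
    )
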