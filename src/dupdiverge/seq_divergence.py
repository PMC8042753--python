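"""Sequence divergence of duplicate gene pairs.

This module turns a pair of coding genes into a KA/KS estimate:

1. read CDS + protein FASTA files (longest-isoform representatives),
2. globally align the two proteins (BLOSUM62, affine gaps),
3. back-translate the protein alignment onto the coding sequences,
4. count synonymous/nonsynonymous sites and differences with the
   Nei–Gojobori (1986) method and apply the Jukes–Cantor correction,
5. filter pairs on alignment identity, coverage and KS.

KA is the number of nonsynonymous substitutions per nonsynonymous site,
KS the number of synonymous substitutions per synonymous site; their
ratio measures the selection pressure on the protein sequence and, for a
duplicate pair, the protein-level divergence rate at a given duplication
age.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "GeneRecord",
    "ProteinAlignment",
    "CodonAlignment",
    "DivergenceEstimate",
    "FastaError",
    "read_fasta",
    "build_gene_records",
    "align_pair",
    "import_alignment",
    "identity_coverage",
    "backtranslate",
    "ng86_ka_ks",
    "filter_pairs",
    "pair_divergence",
]

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))
_NUCS = "ACGT"
GAP_CODON = "---"


class FastaError(ValueError):
    """Malformed FASTA input or CDS/protein inconsistency."""


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene: id, CDS and its (longest-isoform) protein.

    The terminal stop codon, if present, is stripped from the CDS on
    construction, so ``len(cds) == 3 * len(protein)`` always holds.
    """

    gene_id: str
    cds: str
    protein: str

    def __post_init__(self) -> None:
        if len(self.cds) != 3 * len(self.protein):
            raise FastaError(
                f"gene {self.gene_id}: CDS length {len(self.cds)} is not "
                f"3 x protein length {len(self.protein)}"
            )


@dataclass(frozen=True)
class ProteinAlignment:
    """A pairwise global protein alignment with identity and coverage."""

    row_a: str
    row_b: str
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        if any(a == "-" == b for a, b in zip(self.row_a, self.row_b)):
            raise ValueError("alignment contains a gap-in-both column")


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon columns; each cell is a 3-nt codon or '---'."""

    columns: tuple[tuple[str, str], ...]

    @property
    def n_codons(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class DivergenceEstimate:
    """NG86 site/difference counts and Jukes–Cantor corrected KA, KS.

    ``ka_ks`` is None when KS is zero or either correction diverges
    (proportion of differences >= 3/4).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    ks: float | None
    ka: float | None
    ka_ks: float | None
    n_codons: int
    method: str = "NG86+JC"


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping.

    Ids are the header token up to the first whitespace.
    """
    seqs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq).upper()
    except ValueError as exc:  # biopython parse failure
        raise FastaError(f"malformed FASTA {path}: {exc}") from exc
    if not seqs:
        raise FastaError(f"no FASTA records in {path}")
    return seqs


def build_gene_records(
    cds_seqs: dict[str, str], protein_seqs: dict[str, str]
) -> dict[str, GeneRecord]:
    """Pair CDS and protein sequences into :class:`GeneRecord` objects.

    A terminal stop codon on the CDS is stripped. Genes present in only
    one of the inputs are skipped. A length mismatch after stop-stripping
    raises :class:`FastaError` naming the gene.
    """
    records: dict[str, GeneRecord] = {}
    for gid, cds in cds_seqs.items():
        prot = protein_seqs.get(gid)
        if prot is None:
            continue
        prot = prot.rstrip("*")
        if len(cds) == 3 * len(prot) + 3 and CODON_TABLE.get(cds[-3:]) == "*":
            cds = cds[:-3]
        records[gid] = GeneRecord(gid, cds, prot)
    return records


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA_ALPHABET = set(str(_BLOSUM62.alphabet))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _sanitize_protein(seq: str) -> str:
    return "".join(c if c in _AA_ALPHABET and c != "*" else "X" for c in seq.upper())


def align_pair(a: str, b: str) -> ProteinAlignment:
    """Globally align two protein sequences (BLOSUM62, affine gaps).

    Deterministic: the highest-scoring alignment in the aligner's fixed
    internal traceback order is returned. Non-standard residues are
    treated as X.
    """
    if not a or not b:
        raise ValueError("cannot align an empty protein sequence")
    aligner = _make_aligner()
    aln = aligner.align(_sanitize_protein(a), _sanitize_protein(b))[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ident, cov = _identity_coverage(row_a, row_b, len(a), len(b))
    return ProteinAlignment(row_a, row_b, ident, cov)


def import_alignment(row_a: str, row_b: str) -> ProteinAlignment:
    """Accept externally computed gapped rows verbatim (e.g. from MAFFT)."""
    ungapped_a = row_a.replace("-", "")
    ungapped_b = row_b.replace("-", "")
    ident, cov = _identity_coverage(row_a, row_b, len(ungapped_a), len(ungapped_b))
    return ProteinAlignment(row_a, row_b, ident, cov)


def _identity_coverage(
    row_a: str, row_b: str, len_a: int, len_b: int
) -> tuple[float, float]:
    both = sum(1 for x, y in zip(row_a, row_b) if x != "-" and y != "-")
    if both == 0:
        raise ValueError("alignment has no column where both rows are non-gap")
    same = sum(1 for x, y in zip(row_a, row_b) if x != "-" and y != "-" and x == y)
    return same / both, both / max(len_a, len_b)


def identity_coverage(aln: ProteinAlignment) -> tuple[float, float]:
    """Identity over dually-aligned columns; coverage over the longer sequence."""
    return aln.identity, aln.coverage


def backtranslate(aln: ProteinAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Map a protein alignment onto codons of the two CDS.

    Each amino-acid column becomes one codon column; protein gaps become
    '---'. Raises if a codon does not translate to the aligned residue
    (X residues are exempt).
    """
    for row, cds, name in ((aln.row_a, cds_a, "a"), (aln.row_b, cds_b, "b")):
        n_res = len(row) - row.count("-")
        if len(cds) != 3 * n_res:
            raise ValueError(
                f"side {name}: CDS length {len(cds)} does not match "
                f"{n_res} aligned residues"
            )

    def codons_for(row: str, cds: str, name: str) -> list[str]:
        out, i = [], 0
        for col, aa in enumerate(row):
            if aa == "-":
                out.append(GAP_CODON)
                continue
            codon = cds[3 * i : 3 * i + 3]
            trans = CODON_TABLE.get(codon)
            if aa != "X" and trans is not None and trans != aa:
                raise ValueError(
                    f"side {name}, codon {i + 1}: {codon} translates to "
                    f"{trans}, alignment row has {aa}"
                )
            out.append(codon)
            i += 1
        return out

    cols = tuple(
        zip(codons_for(aln.row_a, cds_a, "a"), codons_for(aln.row_b, cds_b, "b"))
    )
    return CodonAlignment(cols)


# --- NG86 counting ---------------------------------------------------------


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Synonymous site count of a sense codon (NG86).

    For each position, the fraction of the three possible point changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for nuc in _NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1 :]
            if CODON_TABLE[alt] == aa:
                s += 1 / 3
    return s


@lru_cache(maxsize=None)
def codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal substitution paths; paths passing through a
    stop codon are excluded (unless every path does, in which case all
    paths are used).
    """
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(pos):
        cur = c1
        sd = nd = 0.0
        ok = True
        for step, i in enumerate(order):
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if CODON_TABLE[nxt] == "*" and step < len(order) - 1:
                ok = False
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (paths if ok else blocked).append((sd, nd))
    use = paths or blocked
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction; None when it diverges."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - (4.0 / 3.0) * p) + 0.0


def _usable_codon(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(n in _NUCS for n in codon)
        and CODON_TABLE.get(codon) != "*"
    )


def ng86_ka_ks(
    caln: CodonAlignment, on_bad_codon: str = "warn"
) -> DivergenceEstimate:
    """Nei–Gojobori (1986) KA/KS from an aligned codon pair.

    Synonymous site counts are averaged over the two sequences; per-column
    differences are averaged over all minimal substitution paths. The
    Jukes–Cantor correction is applied separately to the synonymous and
    nonsynonymous difference proportions.

    Columns with a gap, an ambiguous base or a stop codon are skipped
    (``on_bad_codon='warn'``, the default) or raise (``'error'``).
    """
    s_a = s_b = sd = nd = 0.0
    n_used = 0
    for idx, (ca, cb) in enumerate(caln.columns):
        if ca == GAP_CODON or cb == GAP_CODON:
            continue
        if not (_usable_codon(ca) and _usable_codon(cb)):
            if on_bad_codon == "error":
                raise ValueError(
                    f"column {idx + 1}: unusable codon pair ({ca}, {cb})"
                )
            warnings.warn(
                f"column {idx + 1}: codon pair ({ca}, {cb}) skipped",
                stacklevel=2,
            )
            continue
        s_a += syn_sites(ca)
        s_b += syn_sites(cb)
        d_s, d_n = codon_diffs(ca, cb)
        sd += d_s
        nd += d_n
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable codon columns for KA/KS estimation")
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_used - S
    ks = _jc_correct(sd / S) if S > 0 else None
    ka = _jc_correct(nd / N) if N > 0 else None
    ka_ks = None
    if ks is not None and ka is not None and ks > 0:
        ka_ks = ka / ks
    return DivergenceEstimate(S, N, sd, nd, ks, ka, ka_ks, n_used)


def pair_divergence(rec_a: GeneRecord, rec_b: GeneRecord) -> tuple[
    ProteinAlignment, DivergenceEstimate
]:
    """Align two genes' proteins and estimate KA/KS from their CDS."""
    aln = align_pair(rec_a.protein, rec_b.protein)
    caln = backtranslate(aln, rec_a.cds, rec_b.cds)
    return aln, ng86_ka_ks(caln)


# --- pair filtering --------------------------------------------------------


@dataclass
class FilterResult:
    kept: list[dict]
    rejected: list[dict] = field(default_factory=list)


def filter_pairs(
    pairs: Iterable[dict],
    min_identity: float = 0.30,
    min_coverage: float = 0.50,
    max_ks: float = 3.0,
) -> FilterResult:
    """Filter scored pairs on identity, coverage and KS.

    Each pair dict must carry ``identity``, ``coverage`` and ``ks`` (ks
    may be None, rejected as undefined). Boundary values are kept: a
    pair is rejected only when identity < min_identity, coverage <
    min_coverage or ks > max_ks. The rejection report lists every
    failing reason per pair. Idempotent and order-independent.
    """
    kept: list[dict] = []
    rejected: list[dict] = []
    for pair in pairs:
        reasons = []
        if pair.get("error"):
            reasons.append("missing_sequence")
        else:
            if pair["identity"] < min_identity:
                reasons.append("identity")
            if pair["coverage"] < min_coverage:
                reasons.append("coverage")
            if pair["ks"] is None:
                reasons.append("undefined_ks")
            elif pair["ks"] > max_ks:
                reasons.append("ks")
        if reasons:
            rejected.append({**pair, "reasons": ";".join(reasons)})
        else:
            kept.append(pair)
    return FilterResult(kept, rejected)
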