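"""Independent brute-force oracles shared across test modules.

These deliberately avoid the package's own counting code: codon
translation goes through Bio.Seq and every path/site enumeration is
explicit.
"""

import itertools

from Bio.Seq import Seq

NUCS = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


SENSE = [
    "".join(c) for c in itertools.product(NUCS, repeat=3) if aa("".join(c)) != "*"
]


def oracle_syn_sites(codon: str) -> float:
    """Fraction-of-3 synonymous changes per position, stops nonsynonymous."""
    total = 0.0
    for pos, base in enumerate(codon):
        for alt in NUCS:
            if alt == base:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if aa(mutant) == aa(codon):
                total += 1.0
    return total / 3.0


def oracle_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (syn, nonsyn) differences over minimal substitution paths,
    excluding paths through stop codons (all paths if every one is blocked)."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    clean, blocked = [], []
    for order in itertools.permutations(pos):
        cur, sd, nd, ok = c1, 0, 0, True
        for step_no, i in enumerate(order):
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if aa(nxt) == "*" and step_no < len(order) - 1:
                ok = False
            if aa(nxt) == aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (clean if ok else blocked).append((sd, nd))
    use = clean or blocked
    return (
        sum(s for s, _ in use) / len(use),
        sum(n for _, n in use) / len(use),
    )


def oracle_ka_ks(codons_a, codons_b):
    """Site and difference totals for an aligned (gap-free) codon pair."""
    s_a = sum(oracle_syn_sites(c) for c in codons_a)
    s_b = sum(oracle_syn_sites(c) for c in codons_b)
    S = (s_a + s_b) / 2
    N = 3 * len(codons_a) - S
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d_s, d_n = oracle_diffs(ca, cb)
        sd += d_s
        nd += d_n
    return S, N, sd, nd
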