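"""KA/KS of one duplicate pair from raw coding sequences.

Aligns the two proteins, maps the alignment back onto codons and counts
synonymous/nonsynonymous sites and differences (Nei–Gojobori 1986 with
Jukes–Cantor correction).
"""

from dupdiverge.seq_divergence import GeneRecord, pair_divergence

# a 12-codon toy gene and a diverged copy (2 synonymous + 1
# nonsynonymous change)
rec_a = GeneRecord(
    "dup_a",
    "ATGGCTAAAGTTCCGGAAGGGTTTCTTAGCCATTGGTAC",
    "MAKVPEGFLSHWY",
)
rec_b = GeneRecord(
    "dup_b",
    "ATGGCCAAAGTTCCGGAGGGGTTTATTAGCCATTGGTAC",
    "MAKVPEGFISHWY",
)

aln, est = pair_divergence(rec_a, rec_b)
print(f"identity {aln.identity:.2f}, coverage {aln.coverage:.2f}")
print(f"S = {est.S:.2f} synonymous sites, N = {est.N:.2f} nonsynonymous sites")
print(f"Sd = {est.Sd:.2f}, Nd = {est.Nd:.2f} differences")
print(f"KS = {est.ks:.4f}, KA = {est.ka:.4f}, KA/KS = {est.ka_ks:.3f}")
# KA/KS well below 1 indicates purifying selection on the protein; for
# duplicate pairs it doubles as the protein-divergence-rate feature.
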