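"""Nc-plot analysis of the published flavivirus codon-usage table.

Reconstructs an ORF realizing the bundled published codon counts (3419
sense codons), recomputes GC3, Wright's effective number of codons and the
ENCobs/ENCexp ratio, and prints selected synonymous-family statistics.
"""

from rnasig import codon_counts, enc_expected, enc_observed, enc_ratio, family_proportions, family_ranking, gc3
from rnasig import reference as ref
from rnasig.codon_usage import classify_enc_ratio

codons = []
for codon, count in sorted(ref.ORF_CODON_COUNTS.items()):
    codons.extend([codon] * count)
codons.remove("AUG")
table = codon_counts("AUG" + "".join(codons) + "UGA")

s = gc3(table)
obs = enc_observed(table)
exp = enc_expected(s)
ratio = enc_ratio(obs, exp)
print(f"codons: {table.n_codons}")
print(f"GC3 {s:.3f} | ENCobs {obs:.2f} | ENCexp {exp:.2f} | ratio {ratio:.3f}")
print(f"-> {classify_enc_ratio(ratio)}")

props = family_proportions(table)
print(f"\nAsn: AAU {props['AAU']:.2f} / AAC {props['AAC']:.2f}")
print(f"Pro ranking: {family_ranking(table, 'P')}")
print(f"Phe ranking: {family_ranking(table, 'F')}")
print("\nA ratio near 1 says the codon choices mostly follow the genome's "
      "nucleotide bias rather than translational selection.")
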