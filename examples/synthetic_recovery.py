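"""Round trip: generate biased synthetic data, recover the parameters.

Each generator is paired with the statistic that should recover its
parameter: mononucleotide frequencies from an i.i.d. genome, dinucleotide
suppression ratios from a tuned Markov genome, and the ENC limits from
codon-frequency-driven ORFs.
"""

from rnasig import codon_counts, count_dinucleotides, count_nucleotides, dinucleotide_ratio, enc_observed
from rnasig.synthetic import (
    SyntheticSpec,
    generate_iid_genome,
    generate_markov_genome,
    generate_orf,
    implied_dinucleotide_ratio,
    single_codon_per_family_freqs,
    tuned_suppression_matrix,
    uniform_codon_freqs,
)

spec = SyntheticSpec(seed=5)
genome = generate_iid_genome(spec)
fr = count_nucleotides(genome.sequence).fractions
print("mono freqs  target -> measured")
for nt, p in zip("AUCG", spec.mono_freqs):
    print(f"  {nt}: {p:.3f} -> {fr[nt]:.3f}")

m = tuned_suppression_matrix(gpc_cpg=2.17, apu_upa=1.86)
markov = generate_markov_genome(SyntheticSpec(seed=5, length=50_000, transition_matrix=m))
d = count_dinucleotides(markov.sequence)
print(f"\nGpC/CpG  implied {implied_dinucleotide_ratio(m, 'GC', 'CG'):.2f} -> "
      f"measured {dinucleotide_ratio(d, 'GC', 'CG'):.2f}")
print(f"ApU/UpA  implied {implied_dinucleotide_ratio(m, 'AU', 'UA'):.2f} -> "
      f"measured {dinucleotide_ratio(d, 'AU', 'UA'):.2f}")

enc_hi = enc_observed(codon_counts(generate_orf(uniform_codon_freqs(), 5000, seed=5)))
enc_lo = enc_observed(codon_counts(generate_orf(single_codon_per_family_freqs(), 5000, seed=5)))
print(f"\nENC of a uniform-usage ORF: {enc_hi:.2f} (limit 61)")
print(f"ENC of a one-codon-per-family ORF: {enc_lo:.2f} (limit 20)")
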