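"""Per-region nucleotide composition and purine bias of a genome.

Builds a small flavivirus-like genome (UTRs flanking one long ORF), locates
the ORF, and prints a composition table: counts, percentages and the Pu/Py
ratio per region.  A Pu/Py ratio well above 1 marks a purine-rich genome.
"""

from rnasig import (
    GenomeRecord,
    count_dinucleotides,
    count_nucleotides,
    dinucleotide_ratio,
    find_polyprotein_orf,
    slice_regions,
)
from rnasig.composition import composition_table
from rnasig.synthetic import SyntheticSpec, generate_iid_genome, generate_orf, uniform_codon_freqs

orf = generate_orf(uniform_codon_freqs(), 600, seed=1)
utr5 = generate_iid_genome(SyntheticSpec(seed=2, length=106)).sequence
utr3 = generate_iid_genome(SyntheticSpec(seed=3, length=428)).sequence
record = GenomeRecord(id="demo", sequence=utr5 + orf + utr3)

ann = find_polyprotein_orf(record)
u5, orf_seq, u3 = slice_regions(record, ann)
table = composition_table(
    {
        "complete": count_nucleotides(record.sequence),
        "utr5": count_nucleotides(u5),
        "orf": count_nucleotides(orf_seq),
        "utr3": count_nucleotides(u3),
    }
)
print(table.to_string())

dinucs = count_dinucleotides(record.sequence)
print(f"\nGpC/CpG: {dinucleotide_ratio(dinucs, 'GC', 'CG'):.2f}   "
      f"ApU/UpA: {dinucleotide_ratio(dinucs, 'AU', 'UA'):.2f}")
print("Ratios near 1 are expected here: this demo genome has no dinucleotide "
      "suppression; real flavivirus genomes run near 2.")
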