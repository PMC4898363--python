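"""Published composition and codon-usage counts for the ZIKV MR-766 genome.

These are the printed counts from the original compositional survey of the
Zika virus prototype strain (GenBank NC_012532, 10794 nt): whole-genome and
UTR nucleotide counts, the ss/ds partition of the MFold-folded genome, and
the codon usage of the single polyprotein ORF (3419 sense codons).  They
serve as inputs for reproducing the published summary statistics and as
cross-checks for the counting code; the sequence itself is not bundled and
can be fetched with scripts/fetch_zikv.py.
"""

from __future__ import annotations

from .codon_usage import CodonUsageTable
from .composition import CompositionProfile

GENOME_LENGTH = 10794
UTR5_LENGTH = 106
UTR3_LENGTH = 428
POLYPROTEIN_AA = 3419

#: whole-genome and region nucleotide counts (A, U, C, G)
REGION_NT_COUNTS: dict[str, dict[str, int]] = {
    "complete": {"A": 2991, "U": 2305, "C": 2359, "G": 3139},
    "utr5": {"A": 29, "U": 31, "C": 16, "G": 30},
    "utr3": {"A": 113, "U": 72, "C": 118, "G": 125},
    "utr5+utr3": {"A": 142, "U": 103, "C": 134, "G": 155},
}

#: nucleotide counts of the ss/ds position sets of the folded genome
PARTITION_NT_COUNTS: dict[str, dict[str, int]] = {
    "all": {"A": 2991, "U": 2305, "C": 2359, "G": 3139},
    "ds": {"A": 1154, "U": 1604, "C": 1758, "G": 2171},
    "ss": {"A": 1837, "U": 701, "C": 601, "G": 968},
}

#: sense-codon counts of the polyprotein ORF (sums to 3419)
ORF_CODON_COUNTS: dict[str, int] = {
    # Ala
    "GCG": 30, "GCA": 80, "GCU": 77, "GCC": 96,
    # Pro
    "CCG": 11, "CCA": 65, "CCU": 28, "CCC": 38,
    # Asn
    "AAU": 36, "AAC": 68,
    # Cys
    "UGU": 35, "UGC": 29,
    # Asp
    "GAU": 61, "GAC": 93,
    # Gln
    "CAG": 38, "CAA": 38,
    # Glu
    "GAG": 115, "GAA": 107,
    # Arg
    "AGG": 57, "AGA": 93, "CGG": 21, "CGA": 11, "CGU": 14, "CGC": 24,
    # Phe
    "UUU": 45, "UUC": 46,
    # Gly
    "GGG": 67, "GGA": 150, "GGU": 40, "GGC": 51,
    # Ser
    "AGU": 36, "AGC": 38, "UCG": 18, "UCA": 50, "UCU": 29, "UCC": 28,
    # His
    "CAU": 34, "CAC": 40,
    # Ile
    "AUA": 51, "AUU": 46, "AUC": 78,
    # Thr
    "ACG": 20, "ACA": 91, "ACU": 53, "ACC": 62,
    # Lys
    "AAG": 111, "AAA": 77,
    # Leu
    "UUG": 69, "UUA": 20, "CUG": 94, "CUA": 31, "CUU": 46, "CUC": 53,
    # Val
    "GUG": 115, "GUA": 31, "GUU": 55, "GUC": 70,
    # Trp / Met
    "UGG": 92, "AUG": 130,
    # Tyr
    "UAU": 38, "UAC": 49,
}

#: published summary values derivable from the counts above
PUBLISHED = {
    "pu_py_ratio": 1.31,
    "purine_percent": 56.8,
    "ds_percent": 62.0,
    "ss_a_percent": 44.7,
    "ss_purine_percent": 68.3,
    "gpc_cpg_ratio": 2.17,
    "apu_upa_ratio": 1.86,
    "gc3": 0.53,
    "enc_ratio_floor": 0.88,
}


def region_profile(region: str) -> CompositionProfile:
    return CompositionProfile(REGION_NT_COUNTS[region])


def partition_profile(compartment: str) -> CompositionProfile:
    return CompositionProfile(PARTITION_NT_COUNTS[compartment])


def published_codon_usage() -> CodonUsageTable:
    return CodonUsageTable(ORF_CODON_COUNTS)
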