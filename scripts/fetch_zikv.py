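#!/usr/bin/env python
"""Opt-in, network-requiring reproduction on the real prototype genome.

Downloads the ZIKV MR-766 prototype genome (GenBank NC_012532) from NCBI
E-utilities, then recomputes the sequence-level published values that the
offline suite cannot reach: exact nucleotide counts (A=2991, U=2305,
C=2359, G=3139), the 106/428-nt UTRs around the 3419-amino-acid polyprotein
ORF, the GpC/CpG (2.17) and ApU/UpA (1.86) count ratios, and the codon-level
statistics from the actual ORF.

Never run by the test suite.  Usage:

    python scripts/fetch_zikv.py [--accession NC_012532] [--out zikv.fasta]
"""

from __future__ import annotations

import argparse
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch_fasta(accession: str, out: Path) -> Path:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=60) as response:
        out.write_bytes(response.read())
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--accession", default="NC_012532")
    parser.add_argument("--out", type=Path, default=Path("scratch/zikv.fasta"))
    args = parser.parse_args()

    args.out.parent.mkdir(parents=True, exist_ok=True)
    fetch_fasta(args.accession, args.out)

    from rnasig import (
        count_dinucleotides,
        dinucleotide_ratio,
        find_polyprotein_orf,
        read_fasta,
        run_analysis,
        slice_regions,
    )

    record = read_fasta(args.out)[0]
    ann = find_polyprotein_orf(record)
    utr5, orf, utr3 = slice_regions(record, ann)
    print(f"{record.id}: {record.length} nt")
    print(f"5'UTR {len(utr5)} nt | ORF {len(orf) // 3 - 1} aa + stop | 3'UTR {len(utr3)} nt")

    report = run_analysis({"fasta": str(args.out)})
    profile = report.region_profiles["complete"]
    for nt in "AUCG":
        print(f"{nt}: {profile.counts[nt]} ({100 * profile.fractions[nt]:.1f} %)")
    print(f"Pu/Py: {profile.pu_py_ratio:.2f}")
    dinucs = count_dinucleotides(record.sequence)
    print(f"GpC/CpG: {dinucleotide_ratio(dinucs, 'GC', 'CG'):.2f}")
    print(f"ApU/UpA: {dinucleotide_ratio(dinucs, 'AU', 'UA'):.2f}")
    stats = report.codon_stats
    print(
        f"GC3 {stats['gc3']:.2f} | ENCobs {stats['enc_obs']:.2f} | "
        f"ENCexp {stats['enc_exp']:.2f} | ratio {stats['enc_ratio']:.3f}"
    )


if __name__ == "__main__":
    main()
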