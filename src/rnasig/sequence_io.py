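"""Sequence input/output and region handling for positive-strand RNA genomes.

Flavivirus-style genomes carry a single long polyprotein ORF flanked by short
untranslated regions.  This module reads and writes FASTA, normalizes raw
sequences to the RNA alphabet {A, C, G, U}, locates the polyprotein ORF and
slices a genome into 5'UTR / ORF / 3'UTR.

All coordinates are 0-based, half-open intervals on the plus strand.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
START_CODON = "AUG"
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


class SequenceError(ValueError):
    """Raised for malformed sequences, files or annotations."""


@dataclass(frozen=True)
class GenomeRecord:
    """A single genome sequence, normalized to uppercase RNA.

    Attributes
    ----------
    id : str
        Sequence identifier (FASTA header up to the first whitespace).
    description : str
        Full FASTA description line (without the leading ``>``).
    sequence : str
        Uppercase RNA sequence over {A, C, G, U}.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: non-RNA characters {sorted(bad)}; "
                "normalize with normalize_rna() first"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """5'UTR / ORF / 3'UTR intervals jointly covering a genome.

    Intervals are 0-based half-open ``(start, end)`` tuples, ordered
    utr5 < orf < utr3 and contiguous.  The stop codon is part of the ORF
    interval.
    """

    utr5: tuple[int, int]
    orf: tuple[int, int]
    utr3: tuple[int, int]

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1), (c0, c1) = self.utr5, self.orf, self.utr3
        if not (0 <= a0 <= a1 == b0 <= b1 == c0 <= c1):
            raise SequenceError(
                f"regions must be contiguous and ordered: {self.utr5}, {self.orf}, {self.utr3}"
            )
        if (b1 - b0) % 3 != 0:
            raise SequenceError(f"ORF length {b1 - b0} is not a multiple of 3")

    @property
    def length(self) -> int:
        return self.utr3[1]

    def validate_against(self, record: GenomeRecord) -> None:
        """Check interval bounds and codon content against a sequence."""
        if self.length != record.length:
            raise SequenceError(
                f"annotation covers [0, {self.length}) but record has length {record.length}"
            )
        b0, b1 = self.orf
        orf = record.sequence[b0:b1]
        if orf[:3] != START_CODON:
            raise SequenceError(f"ORF does not start with AUG at {b0}")
        if orf[-3:] not in STOP_CODONS:
            raise SequenceError(f"ORF does not end with a stop codon at {b1 - 3}")


def normalize_rna(raw: str, *, skip_ambiguous: bool = False) -> str:
    """Normalize a raw sequence to uppercase RNA.

    Uppercases, maps T to U (DNA input is accepted) and strips whitespace.
    In strict mode (default) any residual character outside {A, C, G, U} —
    e.g. IUPAC ambiguity codes N, R, Y — raises :class:`SequenceError`
    listing the offending 1-based positions.  With ``skip_ambiguous=True``
    such characters are dropped with a logged warning, so downstream counts
    use the effective length.
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = "".join(raw.split()).upper().replace("T", "U")
    bad_positions = [i + 1 for i, c in enumerate(seq) if c not in RNA_ALPHABET]
    if bad_positions:
        if not skip_ambiguous:
            shown = ", ".join(map(str, bad_positions[:10]))
            more = "" if len(bad_positions) <= 10 else f" (+{len(bad_positions) - 10} more)"
            raise SequenceError(
                f"non-RNA characters at positions {shown}{more}; "
                "pass skip_ambiguous=True to drop them"
            )
        logger.warning("dropping %d ambiguous characters", len(bad_positions))
        seq = "".join(c for c in seq if c in RNA_ALPHABET)
    return seq


def read_fasta(path: str | Path, *, skip_ambiguous: bool = False) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into normalized :class:`GenomeRecord` s.

    Order is preserved.  Wrapped and unwrapped sequence lines, lowercase and
    DNA alphabets are all accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_rna(str(rec.seq), skip_ambiguous=skip_ambiguous)
        except SequenceError as exc:
            raise SequenceError(f"{path}: entry {rec.id!r}: {exc}") from exc
        records.append(GenomeRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, *, width: int = 70) -> None:
    """Write records as FASTA (fixed line width, default 70)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def find_polyprotein_orf(record: GenomeRecord) -> RegionAnnotation:
    """Locate the longest AUG-initiated, stop-terminated ORF on the plus strand.

    The flanking remainders become the 5'UTR and 3'UTR; the stop codon is
    included in the ORF interval.  Ties on length break toward the earliest
    start.  Raises :class:`SequenceError` if no AUG-initiated ORF with an
    in-frame stop exists.
    """
    seq = record.sequence
    n = len(seq)
    if n < 6:
        raise SequenceError(f"record {record.id!r}: too short ({n} nt) to contain an ORF")

    # per-frame sorted stop positions, then next-stop lookup per AUG via bisect
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(n - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)

    best: tuple[int, int] | None = None  # (-length, start)
    best_interval: tuple[int, int] | None = None
    start = seq.find(START_CODON)
    while start != -1:
        stops = stops_by_frame[start % 3]
        j = bisect_left(stops, start + 3)
        if j < len(stops):
            stop = stops[j]
            length = stop + 3 - start
            key = (-length, start)
            if best is None or key < best:
                best = key
                best_interval = (start, stop + 3)
        start = seq.find(START_CODON, start + 1)

    if best_interval is None:
        raise SequenceError(f"record {record.id!r}: no AUG-initiated ORF with in-frame stop")
    b0, b1 = best_interval
    return RegionAnnotation(utr5=(0, b0), orf=(b0, b1), utr3=(b1, n))


def slice_regions(record: GenomeRecord, ann: RegionAnnotation) -> tuple[str, str, str]:
    """Return the (utr5, orf, utr3) subsequences; their concatenation is the genome."""
    ann.validate_against(record)
    s = record.sequence
    return (s[slice(*ann.utr5)], s[slice(*ann.orf)], s[slice(*ann.utr3)])


def read_region_annotation(path: str | Path) -> RegionAnnotation:
    """Read a 3-line TSV region annotation: ``region<TAB>start<TAB>end``.

    Regions must be named utr5, orf, utr3 (any order in the file); coordinates
    are 0-based half-open.
    """
    fields: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SequenceError(f"{path}:{lineno}: expected 'region<TAB>start<TAB>end'")
            name, start, end = parts
            fields[name.strip().lower()] = (int(start), int(end))
    missing = {"utr5", "orf", "utr3"} - fields.keys()
    if missing:
        raise SequenceError(f"{path}: missing regions {sorted(missing)}")
    return RegionAnnotation(utr5=fields["utr5"], orf=fields["orf"], utr3=fields["utr3"])


def write_region_annotation(ann: RegionAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, iv in (("utr5", ann.utr5), ("orf", ann.orf), ("utr3", ann.utr3)):
            fh.write(f"{name}\t{iv[0]}\t{iv[1]}\n")
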