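"""Single-/double-stranded partitioning of a folded genome from ss-count data.

Structure-ensemble folding tools (MFold and kin) report, for each position,
the number of predicted structures in which that position is unpaired — the
ss-count.  A position is scored single-stranded ("ss") when it is unpaired in
at least half of the structures, double-stranded ("ds") otherwise; the
threshold is inclusive and is applied to possibly non-integer averaged counts
without rounding.  Genomes too long for one folding job are folded as two
fragments with a fixed overlap whose ss-counts are arithmetically averaged
before ss/ds discrimination.

Single-structure inputs (dot-bracket, CT) degenerate to an ensemble of one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import GenomeRecord

SS = "ss"
DS = "ds"


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class PairingProfile:
    """Per-position unpaired-structure counts from a folding ensemble.

    ``ss_count`` is float-valued because fragment merging averages counts;
    raw parsed profiles hold integers.
    """

    ss_count: np.ndarray
    n_structures: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.ss_count, dtype=float)
        object.__setattr__(self, "ss_count", arr)
        if self.n_structures <= 0:
            raise StructureError(f"n_structures must be positive, got {self.n_structures}")
        if arr.size and (arr.min() < 0 or arr.max() > self.n_structures):
            raise StructureError(
                f"ss-counts must lie in [0, {self.n_structures}]; "
                f"found range [{arr.min()}, {arr.max()}]"
            )

    @property
    def length(self) -> int:
        return int(self.ss_count.size)

    @property
    def labels(self) -> np.ndarray:
        """Per-position 'ss'/'ds' labels under the at-least-half rule."""
        return np.where(classify_ss_ds(self), SS, DS)


def read_sscount(path: str | Path, n_structures: int | None = None) -> PairingProfile:
    """Parse an MFold-style ss-count file.

    Dialect: optional comment lines (#), then either a single-token header
    giving the structure count followed by ``position  count`` lines
    (1-based, contiguous), or a headerless two-column body, in which case
    ``n_structures`` must be supplied.
    """
    path = Path(path)
    rows: list[tuple[int, int]] = []
    header: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split("#", 1)[0].split()
            if not tokens:
                continue
            if header is None and not rows and len(tokens) == 1:
                header = int(tokens[0])
                continue
            if len(tokens) != 2:
                raise StructureError(f"{path}:{lineno}: expected 'position count'")
            rows.append((int(tokens[0]), int(tokens[1])))
    if header is None:
        if n_structures is None:
            raise StructureError(
                f"{path}: headerless ss-count file requires an explicit n_structures"
            )
        header = n_structures
    if not rows:
        raise StructureError(f"{path}: no ss-count data lines")
    positions = [p for p, _ in rows]
    if positions != list(range(1, len(rows) + 1)):
        raise StructureError(
            f"{path}: position index must be contiguous 1..{len(rows)} "
            "without gaps or duplicates"
        )
    counts = np.array([c for _, c in rows], dtype=float)
    if counts.max() > header:
        raise StructureError(
            f"{path}: ss-count {int(counts.max())} exceeds structure count {header}"
        )
    return PairingProfile(ss_count=counts, n_structures=header)


def write_sscount(profile: PairingProfile, path: str | Path) -> None:
    """Write the header + ``position count`` dialect (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(f"{int(profile.n_structures)}\n")
        for i, c in enumerate(profile.ss_count, 1):
            fh.write(f"{i} {int(c) if float(c).is_integer() else c}\n")


def read_dotbracket(path: str | Path) -> PairingProfile:
    """Single dot-bracket structure as a degenerate ensemble (n_structures=1).

    Accepts an optional FASTA-style header line and an optional sequence line
    before the structure line; pseudoknot bracket tiers ``[]{}<>`` are
    understood.
    """
    structure = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            if set(line) <= set(".()[]{}<>,_-"):
                structure = line
                break
    if structure is None:
        raise StructureError(f"{path}: no dot-bracket line found")
    return dotbracket_profile(structure)


def dotbracket_profile(structure: str) -> PairingProfile:
    pairs = {"(": ")", "[": "]", "{": "}", "<": ">"}
    closers = {v: k for k, v in pairs.items()}
    stacks: dict[str, list[int]] = {k: [] for k in pairs}
    unpaired = np.ones(len(structure), dtype=float)
    for i, c in enumerate(structure):
        if c in pairs:
            stacks[c].append(i)
            unpaired[i] = 0.0
        elif c in closers:
            opener = closers[c]
            if not stacks[opener]:
                raise StructureError(f"unbalanced {c!r} at position {i + 1}")
            stacks[opener].pop()
            unpaired[i] = 0.0
        elif c not in ".,_-":
            raise StructureError(f"invalid dot-bracket character {c!r} at position {i + 1}")
    leftovers = sum(len(s) for s in stacks.values())
    if leftovers:
        raise StructureError(f"{leftovers} unclosed bracket(s)")
    return PairingProfile(ss_count=unpaired, n_structures=1)


def read_ct(path: str | Path) -> PairingProfile:
    """Single CT-format structure as a degenerate ensemble (n_structures=1).

    The CT header's declared length must match the body; pairing must be
    symmetric (i paired to j implies j paired to i).
    """
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln and not ln.startswith("#")]
    if not lines:
        raise StructureError(f"{path}: empty CT file")
    try:
        declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureError(f"{path}: malformed CT header {lines[0]!r}") from None
    body = lines[1 : 1 + declared]
    if len(body) != declared:
        raise StructureError(
            f"{path}: header declares {declared} positions, body has {len(body)}"
        )
    partner = np.zeros(declared, dtype=int)
    for ln in body:
        tokens = ln.split()
        if len(tokens) < 5:
            raise StructureError(f"{path}: malformed CT line {ln!r}")
        idx, pair = int(tokens[0]), int(tokens[4])
        if not (1 <= idx <= declared) or not (0 <= pair <= declared):
            raise StructureError(f"{path}: CT indices out of range in {ln!r}")
        partner[idx - 1] = pair
    for i, j in enumerate(partner, 1):
        if j and partner[j - 1] != i:
            raise StructureError(f"{path}: asymmetric pairing {i}-{j}")
    return PairingProfile(ss_count=(partner == 0).astype(float), n_structures=1)


def merge_fragment_profiles(
    p1: PairingProfile, p2: PairingProfile, overlap: int = 1000
) -> PairingProfile:
    """Merge two fragment profiles sharing ``overlap`` genomic positions.

    In the overlap (tail of p1 = head of p2) the ss-counts are arithmetically
    averaged and kept unrounded; outside it they are copied.  Averaging
    happens before ss/ds discrimination, so a merged count of e.g. 24.5 with
    50 structures classifies ds (24.5 < 25).
    """
    if p1.n_structures != p2.n_structures:
        raise StructureError(
            f"fragments disagree on n_structures: {p1.n_structures} vs {p2.n_structures}"
        )
    if overlap < 0 or overlap > min(p1.length, p2.length):
        raise StructureError(
            f"overlap {overlap} exceeds a fragment length ({p1.length}, {p2.length})"
        )
    if overlap == 0:
        merged = np.concatenate([p1.ss_count, p2.ss_count])
    else:
        averaged = (p1.ss_count[p1.length - overlap :] + p2.ss_count[:overlap]) / 2.0
        merged = np.concatenate(
            [p1.ss_count[: p1.length - overlap], averaged, p2.ss_count[overlap:]]
        )
    return PairingProfile(ss_count=merged, n_structures=p1.n_structures)


def classify_ss_ds(profile: PairingProfile) -> np.ndarray:
    """Boolean mask, True where a position is single-stranded.

    A position is ss iff its ss-count is at least half the number of
    structures (inclusive, real-valued comparison).
    """
    return profile.ss_count >= profile.n_structures / 2.0


def partition_positions(
    record: GenomeRecord, labels: Sequence[str] | np.ndarray
) -> tuple[str, str]:
    """Split a genome into its ss and ds subsequences, genomic order kept.

    ``labels`` is either the string labels from :attr:`PairingProfile.labels`
    or a boolean ss-mask.  Every nucleotide lands in exactly one of the two
    outputs, so their multiset union equals the genome.
    """
    labels = np.asarray(labels)
    if labels.size != record.length:
        raise StructureError(
            f"labels length {labels.size} != genome length {record.length}"
        )
    mask = labels if labels.dtype == bool else labels == SS
    arr = np.frombuffer(record.sequence.encode("ascii"), dtype="S1")
    ss_seq = b"".join(arr[mask]).decode("ascii")
    ds_seq = b"".join(arr[~mask]).decode("ascii")
    return ss_seq, ds_seq


def split_into_fragments(
    record: GenomeRecord, max_fragment: int = 9000, overlap: int = 1000
) -> list[tuple[int, int]]:
    """Fragment intervals for folding genomes longer than one job allows.

    Genomes over ``max_fragment`` nt are split into two halves sharing
    ``overlap`` positions; short genomes come back whole.
    """
    n = record.length
    if n <= max_fragment:
        return [(0, n)]
    mid = (n + overlap) // 2
    return [(0, mid), (mid - overlap, n)]
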