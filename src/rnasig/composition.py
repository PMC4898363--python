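"""Mono- and dinucleotide composition statistics.

Purine/pyrimidine bias is summarized by the Pu/Py ratio (A+G over U+C) and
dinucleotide suppression by plain count ratios between a dinucleotide and its
mirror (GpC/CpG, ApU/UpA).  The expectation-normalized odds ratio commonly
used elsewhere in the literature is provided separately as
:func:`dinucleotide_odds_ratio` and is not used in the table-style reports.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping

import pandas as pd

NUCLEOTIDES = ("A", "U", "C", "G")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("UC")
DINUCLEOTIDES = tuple(a + b for a, b in product("AUCG", repeat=2))


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionProfile:
    """Nucleotide counts and purine/pyrimidine summary for any multiset of bases."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {n: int(self.counts.get(n, 0)) for n in NUCLEOTIDES}
        )
        if any(v < 0 for v in self.counts.values()):
            raise CompositionError("negative nucleotide count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {n: float("nan") for n in NUCLEOTIDES}
        return {n: c / t for n, c in self.counts.items()}

    @property
    def purines(self) -> int:
        return self.counts["A"] + self.counts["G"]

    @property
    def pyrimidines(self) -> int:
        return self.counts["U"] + self.counts["C"]

    @property
    def pu_py_ratio(self) -> float | None:
        """(A+G)/(U+C); None when undefined (no pyrimidines)."""
        if self.pyrimidines == 0:
            return None
        return self.purines / self.pyrimidines

    @property
    def purine_fraction(self) -> float:
        return self.purines / self.total

    def __add__(self, other: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            {n: self.counts[n] + other.counts[n] for n in NUCLEOTIDES}
        )

    def as_row(self) -> dict[str, object]:
        """One report row: length, per-base 'count (pct)' strings, Pu/Py at 2 dp."""
        row: dict[str, object] = {"nts": self.total}
        fr = self.fractions
        for n in NUCLEOTIDES:
            pct = f"{100 * fr[n]:.1f}" if self.total else "-"
            row[n] = f"{self.counts[n]} ({pct} %)"
        ratio = self.pu_py_ratio
        row["Pu/Py"] = f"{ratio:.2f}" if ratio is not None else "-"
        return row


@dataclass(frozen=True)
class DinucleotideCounts:
    """Overlapping ordered dinucleotide counts (no wraparound)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {d: int(self.counts.get(d, 0)) for d in DINUCLEOTIDES}
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _check_alphabet(symbols: Iterable[str]) -> Counter:
    c = Counter(symbols)
    bad = set(c) - set(NUCLEOTIDES)
    if bad:
        raise CompositionError(f"non-RNA symbols {sorted(bad)}")
    return c


def count_nucleotides(seq: str) -> CompositionProfile:
    """Exact nucleotide counts of a contiguous RNA sequence.

    An empty sequence yields a profile with total 0 and an undefined Pu/Py
    ratio rather than an error.
    """
    return CompositionProfile(_check_alphabet(seq))


def count_nucleotides_multiset(positions: Iterable[str]) -> CompositionProfile:
    """Nucleotide counts of an arbitrary (non-contiguous) collection of bases.

    Same contract as :func:`count_nucleotides` but with no adjacency
    semantics — used for the single- and double-stranded position sets of a
    folded genome.
    """
    return CompositionProfile(_check_alphabet(positions))


def count_dinucleotides(seq: str) -> DinucleotideCounts:
    """Overlapping dinucleotide counts over a contiguous sequence.

    Windows of width 2 advance by 1; no wraparound, so total = len(seq) - 1.
    """
    if len(seq) < 2:
        raise CompositionError(f"sequence of length {len(seq)} has no dinucleotides")
    _check_alphabet(seq)
    return DinucleotideCounts(Counter(seq[i : i + 2] for i in range(len(seq) - 1)))


def dinucleotide_ratio(
    counts: DinucleotideCounts, numerator: str, denominator: str
) -> float | None:
    """Plain count ratio of two dinucleotides, e.g. GpC/CpG.

    Returns None (flagged undefined) when the denominator count is 0.  This
    is the raw count ratio, not an observed/expected odds ratio.
    """
    for d in (numerator, denominator):
        if d not in counts.counts:
            raise CompositionError(f"unknown dinucleotide {d!r}")
    den = counts.counts[denominator]
    if den == 0:
        return None
    return counts.counts[numerator] / den


def dinucleotide_odds_ratio(seq: str, dinucleotide: str) -> float | None:
    """Observed/expected odds ratio f(XY) / (f(X)·f(Y)) for one dinucleotide.

    Expectation under independent mononucleotide frequencies; the standard
    suppression statistic in the dinucleotide-bias literature, offered as an
    extra alongside the plain count ratios.
    """
    mono = count_nucleotides(seq).fractions
    di = count_dinucleotides(seq)
    x, y = dinucleotide[0], dinucleotide[1]
    expected = mono[x] * mono[y]
    if expected == 0:
        return None
    observed = di.counts[dinucleotide] / di.total
    return observed / expected


def composition_table(profiles: Mapping[str, CompositionProfile]) -> pd.DataFrame:
    """Human-readable composition report, one named row per nucleotide set.

    Percentages at 1 dp and Pu/Py at 2 dp, matching the conventions of
    published genome-composition tables.
    """
    return pd.DataFrame(
        {name: prof.as_row() for name, prof in profiles.items()}
    ).T.rename_axis("region")
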