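"""Codon-usage analysis: synonymous-family counts, GC3, Wright's ENC, Nc-plot.

The effective number of codons (ENC, also Nc) measures how evenly an ORF uses
synonymous codons, from 20 (one codon per amino acid) to 61 (uniform usage).
For a synonymous family with total count n and within-family proportions p_i,
the family homozygosity is

    F = (n * sum(p_i^2) - 1) / (n - 1)

and ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where Fk is the mean F over the
families of degeneracy k (2-fold: 9 families, 3-fold: Ile, 4-fold: 5
families, 6-fold: Leu/Ser/Arg); Met and Trp contribute the constant 2.

The expected ENC under random codon usage constrained only by GC3 (the G+C
fraction at the third, synonymously variable codon positions) is

    ENCexp(s) = 2 + s + 29 / (s^2 + (1 - s)^2)

and the ratio ENCobs/ENCexp quantifies codon selection beyond composition:
1 means no bias; 0.8-1.0 very weak or virtually absent bias.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _CodonTable

from .sequence_io import START_CODON, STOP_CODONS


class CodonError(ValueError):
    pass


def _standard_code() -> dict[str, str]:
    table = _CodonTable.unambiguous_rna_by_id[1]
    return dict(table.forward_table)  # sense codons only; stops excluded


#: codon -> one-letter amino acid, standard genetic code, RNA alphabet
GENETIC_CODE: dict[str, str] = _standard_code()
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

#: amino acid -> its synonymous codons (family sizes 1, 2, 3, 4 and 6)
FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in sorted(set(GENETIC_CODE.values()))
}
SINGLE_CODON_AAS = frozenset(aa for aa, cs in FAMILIES.items() if len(cs) == 1)  # M, W

#: degeneracy class -> amino acids (2: 9 families, 3: Ile, 4: 5, 6: 3)
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(aa for aa, cs in FAMILIES.items() if len(cs) == k) for k in (2, 3, 4, 6)
}
_ENC_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}

#: Codon boxes for third-position ranking strings: groups of synonymous
#: codons sharing their first two positions.  Six-fold families split into
#: their 4-codon and 2-codon boxes (e.g. Leu -> CUN and UUR).
CODON_BOXES: dict[str, tuple[str, ...]] = {}
for _aa, _codons in FAMILIES.items():
    _by_prefix: dict[str, list[str]] = {}
    for _c in _codons:
        _by_prefix.setdefault(_c[:2], []).append(_c)
    if len(_by_prefix) == 1:
        CODON_BOXES[_aa] = tuple(_codons)
    else:
        for _prefix, _cs in _by_prefix.items():
            CODON_BOXES[f"{_aa}:{_prefix}"] = tuple(sorted(_cs))


@dataclass(frozen=True)
class CodonUsageTable:
    """Counts over the 61 sense codons of a single ORF (stop excluded)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise CodonError(f"not sense codons: {sorted(bad)}")
        object.__setattr__(
            self, "counts", {c: int(self.counts.get(c, 0)) for c in SENSE_CODONS}
        )

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def family_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in FAMILIES[aa])


def codon_counts(orf_seq: str) -> CodonUsageTable:
    """Count sense codons of an ORF (AUG ... stop; stop excluded from counts).

    The ORF must have length a multiple of 3, start with AUG and contain
    exactly one stop codon, in frame at the very end.
    """
    if len(orf_seq) % 3 != 0:
        raise CodonError(f"ORF length {len(orf_seq)} is not a multiple of 3")
    if len(orf_seq) < 6:
        raise CodonError("ORF must contain at least a start and a stop codon")
    codons = [orf_seq[i : i + 3] for i in range(0, len(orf_seq), 3)]
    if codons[0] != START_CODON:
        raise CodonError(f"ORF starts with {codons[0]}, expected AUG")
    if codons[-1] not in STOP_CODONS:
        raise CodonError(f"ORF ends with {codons[-1]}, expected a stop codon")
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise CodonError(f"internal stop codon {c} at codon {i + 1} (nt {3 * i + 1})")
        if c not in GENETIC_CODE:
            raise CodonError(f"invalid codon {c!r} at codon {i + 1}")
    return CodonUsageTable(Counter(codons[:-1]))


def family_proportions(table: CodonUsageTable) -> dict[str, float]:
    """Within-family proportion of each codon; NaN where the family is absent."""
    out: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        total = table.family_total(aa)
        for c in codons:
            out[c] = table.counts[c] / total if total else float("nan")
    return out


_TIE_PRIORITY = {n: i for i, n in enumerate("GACU")}


def family_ranking(
    table: CodonUsageTable, box: str, tie_delta: float = 0.02
) -> str:
    """Third-position ranking string for one codon box, e.g. ``"A > C > U > G"``.

    ``box`` is a key of :data:`CODON_BOXES` (an amino acid, or ``"Leu:CU"``
    style for the sub-boxes of six-fold families).  Third-position
    nucleotides are ordered by descending within-family proportion; adjacent
    nucleotides whose 2-dp proportions differ by at most ``tie_delta`` are
    joined with ``=`` instead of ``>``.
    """
    codons = CODON_BOXES.get(box)
    if codons is None:
        raise CodonError(f"unknown codon box {box!r}; keys: {sorted(CODON_BOXES)}")
    if len(codons) < 2:
        raise CodonError(f"box {box!r} has a single codon; no ranking")
    if table.family_total(GENETIC_CODE[codons[0]]) == 0:
        return ""  # family absent from the ORF; proportions undefined
    props = family_proportions(table)
    entries = sorted(
        ((round(props[c], 2), c[2]) for c in codons),
        key=lambda pc: (-pc[0], _TIE_PRIORITY[pc[1]]),
    )
    parts = [entries[0][1]]
    for (prev_p, _), (p, nt) in zip(entries, entries[1:]):
        parts.append("=" if prev_p - p <= tie_delta + 1e-12 else ">")
        parts.append(nt)
    return " ".join(parts)


def gc3(
    source: str | CodonUsageTable, *, synonymous_only: bool = False
) -> float:
    """G+C fraction at third codon positions of an ORF or codon table.

    By default every sense codon counts (stops excluded).  With
    ``synonymous_only=True`` the non-degenerate Met and Trp codons are also
    excluded, restricting the statistic to third positions free to vary
    without changing the protein.
    """
    table = source if isinstance(source, CodonUsageTable) else codon_counts(source)
    gc = total = 0
    for codon, count in table.counts.items():
        if synonymous_only and GENETIC_CODE[codon] in SINGLE_CODON_AAS:
            continue
        total += count
        if codon[2] in "GC":
            gc += count
    if total == 0:
        raise CodonError("no synonymously variable codons; GC3 undefined")
    return gc / total


def _family_homozygosity(table: CodonUsageTable, aa: str) -> float | None:
    """Wright's F for one family; None when n < 2 or F is degenerate (<= 0)."""
    counts = np.array([table.counts[c] for c in FAMILIES[aa]], dtype=float)
    n = counts.sum()
    if n < 2:
        return None
    p = counts / n
    f = (n * float(p @ p) - 1.0) / (n - 1.0)
    if f <= 0:
        return None
    return f


def enc_observed(table: CodonUsageTable, *, cap: bool = True) -> float:
    """Wright's effective number of codons of one codon-usage table.

    Families with fewer than 2 codons counted, or a non-positive
    homozygosity, drop out of their degeneracy-class average.  An empty
    3-fold class (Ile unused) falls back to the mean of the 2- and 4-fold
    averages; an empty 2-, 4- or 6-fold class is an error (does not occur
    for real ORFs of more than a few hundred codons).  The value is capped
    at 61 unless ``cap=False``.
    """
    if table.n_codons < 60:
        warnings.warn(
            f"ENC on only {table.n_codons} codons is unstable", stacklevel=2
        )
    class_means: dict[int, float | None] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = [f for aa in aas if (f := _family_homozygosity(table, aa)) is not None]
        class_means[k] = float(np.mean(fs)) if fs else None
    if class_means[3] is None:
        if class_means[2] is None or class_means[4] is None:
            raise CodonError("cannot estimate 3-fold homozygosity: 2- or 4-fold class empty")
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    empty = [k for k in (2, 4, 6) if class_means[k] is None]
    if empty:
        raise CodonError(f"no computable family in degeneracy class(es) {empty}")
    enc = 2.0 + sum(_ENC_WEIGHTS[k] / class_means[k] for k in (2, 3, 4, 6))
    return min(enc, 61.0) if cap else enc


def enc_expected(s: float) -> float:
    """Expected ENC for random codon usage at GC3 = ``s`` (0 < s < 1)."""
    if not 0.0 < s < 1.0:
        raise CodonError(f"GC3 must lie strictly in (0, 1), got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_ratio(enc_obs: float, enc_exp: float) -> float:
    """ENCobs/ENCexp: 1 = zero codon bias; 0.8-1.0 very weak or absent bias."""
    if enc_exp <= 0:
        raise CodonError("expected ENC must be positive")
    return enc_obs / enc_exp


def classify_enc_ratio(ratio: float) -> str:
    if ratio >= 0.8:
        return "very weak or virtually absent codon bias"
    if ratio >= 0.6:
        return "weak codon bias"
    return "strong codon bias"


def nc_plot_data(
    tables: Sequence[CodonUsageTable],
    labels: Sequence[str] | None = None,
    curve_points: int = 99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nc-plot coordinates: one point per table, plus the sampled ENCexp curve.

    Returns ``(points, curve)``: points has columns label/gc3/enc_obs/
    enc_exp/ratio, the curve samples ENCexp(s) for s in 0.01..0.99.
    """
    if not tables:
        raise CodonError("need at least one codon-usage table")
    if labels is None:
        labels = [f"orf{i + 1}" for i in range(len(tables))]
    rows = []
    for label, table in zip(labels, tables):
        s = gc3(table)
        obs = enc_observed(table)
        exp = enc_expected(s)
        rows.append(
            {"label": label, "gc3": s, "enc_obs": obs, "enc_exp": exp,
             "ratio": enc_ratio(obs, exp)}
        )
    grid = np.linspace(0.01, 0.99, curve_points)
    curve = pd.DataFrame({"gc3": grid, "enc_exp": [enc_expected(s) for s in grid]})
    return pd.DataFrame(rows), curve


def codon_usage_report(table: CodonUsageTable, tie_delta: float = 0.02) -> pd.DataFrame:
    """Long-format codon report: AA, codon, count, proportion, box ranking."""
    props = family_proportions(table)
    box_of: dict[str, str] = {}
    rankings: dict[str, str] = {}
    for box, codons in CODON_BOXES.items():
        for c in codons:
            box_of[c] = box
        if len(codons) >= 2 and table.n_codons:
            rankings[box] = family_ranking(table, box, tie_delta)
    rows = []
    for aa, codons in FAMILIES.items():
        for c in codons:
            rows.append(
                {
                    "aa": aa,
                    "codon": c,
                    "count": table.counts[c],
                    "proportion": round(props[c], 2) if not np.isnan(props[c]) else None,
                    "box": box_of[c],
                    "ranking": rankings.get(box_of[c], ""),
                }
            )
    return pd.DataFrame(rows)
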