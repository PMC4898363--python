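"""Windowed and cumulative nucleotide skew along a sequence.

The skew between nucleotides N1 and N2 in a window is
(N1 - N2)/(N1 + N2); a positive value means N1 exceeds N2.  Cumulative skew
diagrams (Grigoriev-style) plot the running sum of per-window skews over
overlapping windows: the window is ~1 % of the sequence length and the step
20 % of the window, giving about 500 data points per track regardless of
sequence length.  Monotone trends in the cumulative track expose steady
compositional bias; a flat track means the two bases are balanced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import NUCLEOTIDES

#: Track orientations used for the six unordered base pairs: first-named
#: minus second-named, purine/pyrimidine comparisons written Py last.
PAIR_LABELS = ("GA", "CA", "UA", "CG", "UG", "UC")


class SkewError(ValueError):
    pass


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SkewTrack:
    """Per-window and cumulative skew values for one ordered nucleotide pair."""

    pair: tuple[str, str]
    windows: list[tuple[int, int]]
    window_skews: np.ndarray  # undefined windows hold 0.0 and are flagged
    undefined: np.ndarray  # bool mask: True where N1+N2 was 0 in the window
    window_size: int
    step: int

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.window_skews)

    @property
    def label(self) -> str:
        return "".join(self.pair)

    def to_frame(self) -> pd.DataFrame:
        starts, ends = zip(*self.windows) if self.windows else ((), ())
        return pd.DataFrame(
            {
                "window_start": starts,
                "window_end": ends,
                "skew": self.window_skews,
                "cumulative": self.cumulative,
                "undefined": self.undefined,
            }
        )


def make_windows(
    length: int, window_frac: float = 0.01, step_frac: float = 0.2
) -> tuple[list[tuple[int, int]], int, int]:
    """Overlapping analysis windows over ``[0, length)``.

    window_size = round(window_frac * length) and step = round(step_frac *
    window_size), both rounded half-away-from-zero and clamped to >= 1.
    Windows advance by ``step``; the last window is the last one fully
    contained in the sequence (no partial or wrapped windows).  With the
    defaults this yields ~500 windows for any length much larger than 100.
    """
    if window_frac <= 0 or step_frac <= 0:
        raise SkewError("window_frac and step_frac must be positive")
    if length < 10:
        raise SkewError(f"sequence of length {length} too short for windowing")
    window_size = max(1, _round_half_away(window_frac * length))
    step = max(1, _round_half_away(step_frac * window_size))
    starts = range(0, length - window_size + 1, step)
    return [(s, s + window_size) for s in starts], window_size, step


def window_skew(seq: str, window: tuple[int, int], pair: tuple[str, str]) -> float | None:
    """Skew (N1 - N2)/(N1 + N2) of one window; None when both counts are 0."""
    start, end = window
    if not (0 <= start <= end <= len(seq)):
        raise SkewError(f"window {window} outside sequence of length {len(seq)}")
    sub = seq[start:end]
    n1, n2 = sub.count(pair[0]), sub.count(pair[1])
    if n1 + n2 == 0:
        return None
    return (n1 - n2) / (n1 + n2)


def _window_counts(seq: str, windows: list[tuple[int, int]]) -> dict[str, np.ndarray]:
    """Per-window nucleotide counts via prefix sums (fast path)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    starts = np.array([w[0] for w in windows], dtype=np.intp)
    ends = np.array([w[1] for w in windows], dtype=np.intp)
    out = {}
    for n in NUCLEOTIDES:
        prefix = np.concatenate(([0], np.cumsum(arr == ord(n))))
        out[n] = prefix[ends] - prefix[starts]
    return out


def cumulative_skew_track(
    seq: str,
    pair: tuple[str, str],
    window_frac: float = 0.01,
    step_frac: float = 0.2,
) -> SkewTrack:
    """Cumulative skew track of one ordered pair over a whole sequence.

    Windows where both counts are zero are flagged undefined and contribute
    0 to the running sum (keeps all tracks the same length).
    """
    windows, wsize, step = make_windows(len(seq), window_frac, step_frac)
    counts = _window_counts(seq, windows)
    n1, n2 = counts[pair[0]].astype(float), counts[pair[1]].astype(float)
    denom = n1 + n2
    undefined = denom == 0
    skews = np.zeros_like(denom)
    np.divide(n1 - n2, denom, out=skews, where=~undefined)
    return SkewTrack(
        pair=tuple(pair),
        windows=windows,
        window_skews=skews,
        undefined=undefined,
        window_size=wsize,
        step=step,
    )


def all_pairwise_skews(
    seq: str, window_frac: float = 0.01, step_frac: float = 0.2
) -> dict[str, SkewTrack]:
    """The six skew tracks GA, CA, UA, CG, UG, UC (first minus second)."""
    return {
        label: cumulative_skew_track(seq, (label[0], label[1]), window_frac, step_frac)
        for label in PAIR_LABELS
    }


def skew_panel(
    tracks_by_compartment: dict[str, dict[str, SkewTrack]], path: str
) -> None:
    """Plot cumulative skew tracks, one panel per compartment (all/ds/ss).

    Shared y-axis across panels so compositional signatures of different
    genome parts are directly comparable.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(tracks_by_compartment)
    fig, axes = plt.subplots(
        1, len(names), figsize=(4.2 * len(names), 3.6), sharey=True, squeeze=False
    )
    for ax, name in zip(axes[0], names):
        for label, track in tracks_by_compartment[name].items():
            ax.plot(track.cumulative, label=label, lw=1.2)
        ax.axhline(0, color="0.6", lw=0.6)
        ax.set_title(f"{name} nts")
        ax.set_xlabel("window index")
    axes[0][0].set_ylabel("cumulative skew")
    axes[0][-1].legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
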