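"""Bond-order cutoff selection.

The number of distinct species found in a trajectory depends on the
bond-order threshold: too low, and vibrationally stretched contacts fuse
molecules into unphysical aggregates; too high, and intact molecules
fragment.  Both extremes inflate the distinct-species count, so the curve of
distinct species versus cutoff has a minimum in a mid-range band and the
operating cutoff is taken at that minimum (0.5 in practice for C/H/O systems).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph import DEFAULT_CUTOFF, frame_census
from .io import BondFrame


@dataclass(frozen=True)
class CutoffCurve:
    """Distinct-species count as a function of bond-order cutoff.

    ``mean_distinct``/``sd_distinct`` are the mean and standard deviation
    across replicates of the number of unique formulas seen in the sampled
    frames of each replicate.
    """

    cutoffs: tuple[float, ...]
    mean_distinct: tuple[float, ...]
    sd_distinct: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoff grid must be strictly increasing")
        if any(s < 0 for s in self.sd_distinct):
            raise ValueError("sd_distinct must be non-negative")


def distinct_species_curve(
    replicates: Sequence[Sequence[BondFrame]],
    cutoffs: Sequence[float],
    frame_stride: int = 10,
) -> CutoffCurve:
    """Evaluate the distinct-species curve over a cutoff grid.

    For each replicate, every ``frame_stride``-th frame is analysed and the
    number of unique formulas pooled over those frames is recorded per
    cutoff; the curve reports mean +/- sd across replicates.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    cutoffs = sorted(float(c) for c in cutoffs)
    if any(c <= 0 or c >= 2 for c in cutoffs):
        raise ValueError("cutoffs must lie in (0, 2)")
    per_replicate = np.zeros((len(replicates), len(cutoffs)))
    for r, frames in enumerate(replicates):
        sampled = list(frames)[::frame_stride]
        if not sampled:
            raise ValueError(f"replicate {r} has no frames")
        for c, cutoff in enumerate(cutoffs):
            formulas: set[str] = set()
            for frame in sampled:
                formulas.update(frame_census(frame, cutoff))
            per_replicate[r, c] = len(formulas)
    mean = per_replicate.mean(axis=0)
    sd = per_replicate.std(axis=0, ddof=1) if len(replicates) > 1 else np.zeros(len(cutoffs))
    return CutoffCurve(
        cutoffs=tuple(cutoffs),
        mean_distinct=tuple(float(m) for m in mean),
        sd_distinct=tuple(float(s) for s in sd),
    )


def select_cutoff(curve: CutoffCurve) -> float:
    """Grid point minimising the mean distinct-species count.

    Ties are broken toward the smallest cutoff.  This count-based rule can be
    overridden by the caller; chemical plausibility of the species at the
    chosen cutoff is left to inspection.
    """
    if not curve.cutoffs:
        raise ValueError("empty curve")
    best = int(np.argmin(curve.mean_distinct))  # argmin returns first minimum
    return curve.cutoffs[best]


def curve_records(curve: CutoffCurve) -> list[dict]:
    """Rows for the cutoff CSV table."""
    return [
        {"cutoff": c, "mean_distinct": m, "sd_distinct": s}
        for c, m, s in zip(curve.cutoffs, curve.mean_distinct, curve.sd_distinct)
    ]


DEFAULT_GRID = tuple(np.round(np.arange(0.2, 1.35, 0.1), 2))

__all__ = [
    "CutoffCurve",
    "distinct_species_curve",
    "select_cutoff",
    "curve_records",
    "DEFAULT_CUTOFF",
    "DEFAULT_GRID",
]
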