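"""Species timelines, lifetime filtering, product ranking and intermediates.

A species *instance* is an exact atom-id set; its cumulative lifetime is the
number of frames in which that exact set occurs as a species, times the frame
interval.  Short-lived instances ("flicker" species produced by bond-order
fluctuation around the cutoff) are removed with a lifetime threshold of
12.5 ps (50 frames at the 250 fs dump interval) before any reporting.

Reaction products are ranked by their mean instance count over the trailing
window of the run (100 ps by default), averaged across replicates.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .graph import DEFAULT_CUTOFF, frame_species
from .io import BondFrame, TrajectoryMeta

#: minimum cumulative lifetime (ps) for a species to be considered real
DEFAULT_LIFETIME_PS = 12.5
#: trailing window (ps) over which product prevalence is averaged
DEFAULT_WINDOW_PS = 100.0
#: number of most-abundant species reported
DEFAULT_TOP_K = 10


@dataclass
class SpeciesTimeline:
    """Per-frame history of one formula.

    ``counts[k]`` is the instance count in frame ``k``; ``instances[k]`` the
    atom-id sets present in frame ``k``; ``cumulative_lifetimes`` maps each
    atom-id set ever seen to its total occupancy time in ps.
    """

    formula: str
    counts: np.ndarray
    instances: list[tuple[frozenset[int], ...]]
    cumulative_lifetimes: dict[frozenset[int], float] = field(default_factory=dict)

    @property
    def max_lifetime_ps(self) -> float:
        return max(self.cumulative_lifetimes.values(), default=0.0)

    @property
    def longest_run_frames(self) -> dict[frozenset[int], int]:
        """Longest contiguous run (frames) of each atom set."""
        runs: dict[frozenset[int], int] = {}
        current: dict[frozenset[int], int] = {}
        for frame_sets in self.instances:
            present = set(frame_sets)
            for s in present:
                current[s] = current.get(s, 0) + 1
                runs[s] = max(runs.get(s, 0), current[s])
            for s in list(current):
                if s not in present:
                    del current[s]
        return runs


def build_timelines(
    frames: Sequence[BondFrame],
    cutoff: float = DEFAULT_CUTOFF,
    meta: TrajectoryMeta | None = None,
    frame_interval_ps: float | None = None,
) -> dict[str, SpeciesTimeline]:
    """Assemble per-formula timelines from per-frame species partitions.

    The frame interval (ps) used to convert occupancy counts to lifetimes is
    taken from ``meta`` or ``frame_interval_ps``; it defaults to 0.25 ps.
    """
    if not frames:
        raise ValueError("need at least one frame")
    n_atoms = frames[0].n_atoms
    for k, frame in enumerate(frames):
        if frame.n_atoms != n_atoms:
            raise ValueError(
                f"frame {k} has {frame.n_atoms} atoms, expected {n_atoms}: "
                "atoms are conserved in a closed box"
            )
    if frame_interval_ps is None:
        frame_interval_ps = meta.frame_interval_ps if meta is not None else 0.25
    n = len(frames)
    counts: dict[str, np.ndarray] = {}
    instances: dict[str, list[tuple[frozenset[int], ...]]] = {}
    occupancy: dict[str, Counter] = defaultdict(Counter)
    for k, frame in enumerate(frames):
        per_formula: dict[str, list[frozenset[int]]] = defaultdict(list)
        for inst in frame_species(frame, cutoff):
            per_formula[inst.formula].append(inst.atom_ids)
        for formula, sets in per_formula.items():
            if formula not in counts:
                counts[formula] = np.zeros(n, dtype=np.int64)
                instances[formula] = [()] * n
            counts[formula][k] = len(sets)
            instances[formula][k] = tuple(sets)
            occupancy[formula].update(sets)
    return {
        formula: SpeciesTimeline(
            formula=formula,
            counts=counts[formula],
            instances=instances[formula],
            cumulative_lifetimes={
                s: c * frame_interval_ps for s, c in occupancy[formula].items()
            },
        )
        for formula in counts
    }


def lifetime_filter(
    timelines: Mapping[str, SpeciesTimeline],
    threshold_ps: float = DEFAULT_LIFETIME_PS,
    contiguous: bool = False,
    frame_interval_ps: float = 0.25,
) -> dict[str, SpeciesTimeline]:
    """Drop formulas whose every instance lived less than ``threshold_ps``.

    A formula survives iff at least one of its atom-set instances has
    cumulative occupancy >= the threshold (closed bound: exactly the
    threshold is retained).  With ``contiguous=True`` the longest contiguous
    run is used instead of cumulative occupancy.
    """
    if threshold_ps < 0:
        raise ValueError("threshold must be non-negative")
    kept: dict[str, SpeciesTimeline] = {}
    for formula, tl in timelines.items():
        if contiguous:
            best = max(tl.longest_run_frames.values(), default=0) * frame_interval_ps
        else:
            best = tl.max_lifetime_ps
        if best >= threshold_ps:
            kept[formula] = tl
    return kept


@dataclass(frozen=True)
class ProductRanking:
    """Formulas ranked by mean trailing-window count across replicates."""

    window_ps: float
    entries: tuple[tuple[str, float], ...]

    def top(self, k: int = DEFAULT_TOP_K) -> tuple[tuple[str, float], ...]:
        return self.entries[:k]

    def formulas(self, k: int = DEFAULT_TOP_K) -> list[str]:
        return [f for f, _ in self.entries[:k]]


def rank_products(
    replicate_timelines: Sequence[Mapping[str, SpeciesTimeline]],
    window_ps: float = DEFAULT_WINDOW_PS,
    frame_interval_ps: float = 0.25,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> ProductRanking:
    """Rank species by mean count over the last ``window_ps`` of each run.

    The trailing-window mean is computed per replicate and then averaged
    across replicates (a formula absent from a replicate contributes 0).
    Ties are broken lexicographically by formula.  ``exclude`` removes feed
    species (reactant, O2) when a product-only report is wanted.
    """
    if window_ps <= 0:
        raise ValueError("window must be positive")
    if not replicate_timelines:
        raise ValueError("need at least one replicate")
    window_frames = int(round(window_ps / frame_interval_ps))
    sums: dict[str, float] = defaultdict(float)
    n_rep = len(replicate_timelines)
    for timelines in replicate_timelines:
        if not timelines:
            raise ValueError("replicate has no timelines")
        n_frames = len(next(iter(timelines.values())).counts)
        if window_frames > n_frames:
            raise ValueError(
                f"window of {window_frames} frames exceeds trajectory length {n_frames}"
            )
        for formula, tl in timelines.items():
            if formula in exclude:
                continue
            sums[formula] += float(tl.counts[n_frames - window_frames:].mean())
    entries = sorted(
        ((f, s / n_rep) for f, s in sums.items()),
        key=lambda e: (-e[1], e[0]),
    )
    return ProductRanking(window_ps=window_ps, entries=tuple(entries))


@dataclass(frozen=True)
class IntermediateReport:
    """A species that shared atoms with a product, with its time span."""

    formula: str
    first_ps: float
    last_ps: float


def find_intermediates(
    timelines: Mapping[str, SpeciesTimeline],
    product_formula: str,
    threshold_ps: float = DEFAULT_LIFETIME_PS,
    frame_interval_ps: float = 0.25,
) -> dict[str, IntermediateReport]:
    """All species that ever shared an atom with a final product instance.

    For each instance of ``product_formula`` in the final frame, every
    species instance (in any frame) whose atom set intersects the product's
    atoms is collected.  The lifetime filter is applied, and the result is
    deduplicated by formula with first/last appearance times.
    """
    if product_formula not in timelines:
        raise ValueError(f"product {product_formula!r} not present in timelines")
    product_tl = timelines[product_formula]
    final = product_tl.instances[-1]
    if not final:
        raise ValueError(f"product {product_formula!r} absent at trajectory end")
    product_atoms: set[int] = set()
    for inst in final:
        product_atoms.update(inst)
    surviving = lifetime_filter(timelines, threshold_ps, frame_interval_ps=frame_interval_ps)
    out: dict[str, IntermediateReport] = {}
    for formula, tl in surviving.items():
        first = last = None
        for k, frame_sets in enumerate(tl.instances):
            if any(not product_atoms.isdisjoint(s) for s in frame_sets):
                if first is None:
                    first = k
                last = k
        if first is not None:
            out[formula] = IntermediateReport(
                formula=formula,
                first_ps=first * frame_interval_ps,
                last_ps=last * frame_interval_ps,
            )
    return out


def census_records(
    timelines: Mapping[str, SpeciesTimeline],
    replicate: str = "r0",
    frame_interval_ps: float = 0.25,
) -> list[dict]:
    """Rows for the census CSV (one row per frame x formula with count > 0)."""
    rows = []
    for formula in sorted(timelines):
        tl = timelines[formula]
        for k in np.nonzero(tl.counts)[0]:
            rows.append(
                {
                    "replicate": replicate,
                    "frame": int(k),
                    "time_ps": k * frame_interval_ps,
                    "formula": formula,
                    "count": int(tl.counts[k]),
                }
            )
    return rows
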