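"""Reaction-pathway reconstruction.

Once the dominant products of a run are known, each final product instance is
traced backwards: for every atom of the product, the species containing it is
recorded in every frame, and all committed bond events touching any traced
atom form that instance's event sequence.  Sequences from many molecule
copies (and replicates) are aggregated into a single dominant pathway by
ordering event descriptors by their median event time and reporting, for each
step, the fraction of instances in which it occurred; where pairwise
precedence majorities conflict with the median order, the conflict is
reported rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

from .events import BondEvent
from .graph import DEFAULT_CUTOFF, SpeciesInstance, frame_species
from .io import BondFrame


def frame_partitions(
    frames: Sequence[BondFrame], cutoff: float = DEFAULT_CUTOFF
) -> list[list[SpeciesInstance]]:
    """Species partition of every frame."""
    return [frame_species(f, cutoff) for f in frames]


def product_atom_trace(
    product_atoms: frozenset[int],
    partitions: Sequence[Sequence[SpeciesInstance]],
) -> dict[int, list[SpeciesInstance]]:
    """For each atom of a product, its containing species in every frame.

    Raises if any atom is missing from any frame (atoms are conserved, so a
    gap means the inputs are inconsistent).
    """
    trace: dict[int, list[SpeciesInstance]] = {a: [] for a in sorted(product_atoms)}
    for k, partition in enumerate(partitions):
        by_atom: dict[int, SpeciesInstance] = {}
        for inst in partition:
            if not product_atoms.isdisjoint(inst.atom_ids):
                for a in inst.atom_ids:
                    by_atom[a] = inst
        for a in trace:
            if a not in by_atom:
                raise ValueError(f"atom {a} missing from frame {k}: atom conservation violated")
            trace[a].append(by_atom[a])
    return trace


def traced_atoms(trace: Mapping[int, Sequence[SpeciesInstance]]) -> frozenset[int]:
    """Union of all atoms that ever shared a species with the product's atoms."""
    atoms: set[int] = set()
    for insts in trace.values():
        for inst in insts:
            atoms.update(inst.atom_ids)
    return frozenset(atoms)


def event_sequence(
    product_atoms: frozenset[int],
    events: Sequence[BondEvent],
    trace: Mapping[int, Sequence[SpeciesInstance]],
) -> list[BondEvent]:
    """Committed events along one product instance's history, time-ordered.

    An event belongs to the sequence when its atom pair intersects the traced
    atom set — which includes transient partners such as an H atom that was
    eliminated early and captured later.  Ties in time are broken by
    descriptor, lexicographically.
    """
    atoms = traced_atoms(trace) | product_atoms
    selected = [
        e for e in events
        if e.atom_pair[0] in atoms or e.atom_pair[1] in atoms
    ]
    selected.sort(key=lambda e: (e.time_ps, e.descriptor))
    return selected


@dataclass(frozen=True)
class PathwayStep:
    """One aggregated step of a pathway."""

    descriptor: str
    event_type: str
    median_time_ps: float
    support: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.descriptor, self.event_type)


@dataclass(frozen=True)
class PathwaySummary:
    """Dominant pathway to one product, aggregated over instances."""

    product_formula: str
    steps: tuple[PathwayStep, ...]
    n_instances: int
    precedence_conflicts: tuple[tuple[tuple[str, str], tuple[str, str], float], ...] = ()

    def step_keys(self) -> list[tuple[str, str]]:
        return [s.key for s in self.steps]

    def descriptors(self) -> list[str]:
        return [s.descriptor for s in self.steps]


def dominant_pathway(
    sequences: Sequence[Sequence[BondEvent]],
    product_formula: str,
    min_support: float = 0.0,
) -> PathwaySummary:
    """Aggregate per-instance event sequences into one canonical pathway.

    Steps are event descriptors (label or element pair, plus event type);
    each step's time is the median over the instances that contain it, and
    its support is the fraction of instances containing it.  Steps are
    ordered by median time.  For every pair of steps the majority pairwise
    precedence is computed from instances containing both; pairs whose
    majority order contradicts the median-time order are reported in
    ``precedence_conflicts`` as ``(earlier_key, later_key, fraction)`` where
    the fraction supports the *contradicting* order.
    """
    if not sequences:
        raise ValueError("need at least one event sequence")
    n = len(sequences)
    times: dict[tuple[str, str], list[float]] = {}
    presence: dict[tuple[str, str], int] = {}
    for seq in sequences:
        seen: dict[tuple[str, str], float] = {}
        for e in seq:
            key = (e.descriptor, e.event_type)
            if key not in seen:  # first occurrence defines the step time
                seen[key] = e.time_ps
        for key, t in seen.items():
            times.setdefault(key, []).append(t)
            presence[key] = presence.get(key, 0) + 1
    steps = [
        PathwayStep(
            descriptor=key[0],
            event_type=key[1],
            median_time_ps=float(median(ts)),
            support=presence[key] / n,
        )
        for key, ts in times.items()
        if presence[key] / n >= min_support
    ]
    steps.sort(key=lambda s: (s.median_time_ps, s.descriptor))
    # pairwise precedence vs median order
    conflicts = []
    for a_idx in range(len(steps)):
        for b_idx in range(a_idx + 1, len(steps)):
            a, b = steps[a_idx], steps[b_idx]
            before = after = 0
            for seq in sequences:
                seen = {}
                for e in seq:
                    key = (e.descriptor, e.event_type)
                    if key not in seen:
                        seen[key] = e.time_ps
                if a.key in seen and b.key in seen:
                    if seen[a.key] < seen[b.key]:
                        before += 1
                    elif seen[b.key] < seen[a.key]:
                        after += 1
            total = before + after
            if total and after > before:
                conflicts.append((a.key, b.key, after / total))
    return PathwaySummary(
        product_formula=product_formula,
        steps=tuple(steps),
        n_instances=n,
        precedence_conflicts=tuple(conflicts),
    )


def pathway_for_product(
    frames: Sequence[BondFrame],
    events: Sequence[BondEvent],
    product_formula: str,
    cutoff: float = DEFAULT_CUTOFF,
    min_support: float = 0.0,
) -> PathwaySummary:
    """End-to-end: trace every final instance of a product and aggregate.

    ``events`` should contain all committed labeled-bond and new-bond events
    of the trajectory (from :mod:`reaxtrack.events`).
    """
    partitions = frame_partitions(frames, cutoff)
    finals = [inst for inst in partitions[-1] if inst.formula == product_formula]
    if not finals:
        raise ValueError(f"product {product_formula!r} absent in final frame")
    sequences = []
    for inst in finals:
        trace = product_atom_trace(inst.atom_ids, partitions)
        sequences.append(event_sequence(inst.atom_ids, events, trace))
    return dominant_pathway(sequences, product_formula, min_support)


def pathway_records(summary: PathwaySummary) -> list[dict]:
    """Rows for the pathway CSV/JSON report."""
    return [
        {
            "product": summary.product_formula,
            "step": k,
            "descriptor": s.descriptor,
            "event_type": s.event_type,
            "median_time_ps": s.median_time_ps,
            "support": s.support,
        }
        for k, s in enumerate(summary.steps)
    ]
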