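"""Labeled-bond tracking and bond-event detection.

Every copy of the reactant template present in the initial frame is located
by element-labeled graph matching, which binds each labeled template bond
(1A, 3B', ...) to a concrete atom-id pair.  The order of each such bond is
then followed through all frames and discretised into three states:

    absent  (order < 0.5), single (0.5 <= order < 1.5), double (order >= 1.5)

The thresholds are the midpoints between the nominal orders 0, 1 and 2, and
the lower one coincides with the operating species cutoff.  A state change
only counts as a chemical event once the new state has persisted for a
minimum number of consecutive frames (50 by default, mirroring the 12.5 ps
species lifetime filter); this hysteresis keeps bond-order vibration from
being counted as reaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .graph import DEFAULT_CUTOFF, frame_species
from .io import BondFrame, MoleculeTemplate

logger = logging.getLogger(__name__)

#: state-classification thresholds (midpoints of nominal orders 0/1/2)
ABSENT_SINGLE_THRESHOLD = 0.5
SINGLE_DOUBLE_THRESHOLD = 1.5
#: frames a new state must persist before the transition is committed
DEFAULT_PERSISTENCE_FRAMES = 50

STATE_ABSENT, STATE_SINGLE, STATE_DOUBLE = 0, 1, 2

EVENT_TYPES = ("dissociation", "formation", "single_to_double", "double_to_single")

_TRANSITIONS = {
    (STATE_SINGLE, STATE_ABSENT): "dissociation",
    (STATE_DOUBLE, STATE_ABSENT): "dissociation",
    (STATE_ABSENT, STATE_SINGLE): "formation",
    (STATE_ABSENT, STATE_DOUBLE): "formation",
    (STATE_SINGLE, STATE_DOUBLE): "single_to_double",
    (STATE_DOUBLE, STATE_SINGLE): "double_to_single",
}


@dataclass
class LabeledBondInstance:
    """One labeled template bond in one molecule copy."""

    label: str
    molecule_index: int
    atom_pair: tuple[int, int]
    order_series: np.ndarray

    def __post_init__(self) -> None:
        i, j = self.atom_pair
        if i >= j:
            self.atom_pair = (j, i)


@dataclass(frozen=True)
class BondEvent:
    """A committed state change of a bond."""

    descriptor: str
    molecule_index: int
    event_type: str
    time_ps: float
    frame: int
    atom_pair: tuple[int, int]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")


def template_graph(template: MoleculeTemplate) -> nx.Graph:
    """Element-labeled graph of a molecule template (nominal orders as edge data)."""
    g = nx.Graph()
    for idx, el in template.atoms:
        g.add_node(idx, element=el)
    for i, j, order, label in template.bonds:
        g.add_edge(i, j, order=order, label=label)
    return g


def _component_graph(frame: BondFrame, atom_ids: frozenset[int], cutoff: float) -> nx.Graph:
    g = nx.Graph()
    for a in sorted(atom_ids):
        g.add_node(a, element=frame.atoms[a])
    for (i, j), bo in frame.bonds.items():
        if bo >= cutoff and i in atom_ids and j in atom_ids:
            g.add_edge(i, j)
    return g


def _element_match(n1: Mapping, n2: Mapping) -> bool:
    return n1["element"] == n2["element"]


def match_template(
    frame: BondFrame,
    atom_ids: frozenset[int],
    template: MoleculeTemplate,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[int, int] | None:
    """Map template local indices onto a frame component, or None if not a copy.

    When the template has automorphisms (e.g. the two rings of a symmetric
    dimer, or methyl hydrogens) several isomorphisms exist; the one produced
    by matching with all nodes visited in ascending-id order is used, which
    is deterministic for a given frame.
    """
    if len(atom_ids) != template.n_atoms:
        return None
    comp = _component_graph(frame, atom_ids, cutoff)
    tg = template_graph(template)
    gm = nx.isomorphism.GraphMatcher(tg, comp, node_match=_element_match)
    for mapping in gm.isomorphisms_iter():
        return dict(mapping)
    return None


def map_labeled_bonds(
    frame: BondFrame,
    template: MoleculeTemplate,
    cutoff: float = DEFAULT_CUTOFF,
    expected_copies: int | None = None,
) -> list[LabeledBondInstance]:
    """Bind every labeled bond of every intact template copy in a frame.

    Copies are numbered 0, 1, ... in order of their smallest atom id.
    Components that are not isomorphic to the template (already-reacted
    molecules, O2, fragments) are skipped; a warning is logged if the number
    of copies found differs from ``expected_copies``.
    """
    instances: list[LabeledBondInstance] = []
    n_copies = 0
    for inst in frame_species(frame, cutoff):
        if inst.formula != template.formula:
            continue
        mapping = match_template(frame, inst.atom_ids, template, cutoff)
        if mapping is None:
            continue
        for label, (i, j) in sorted(template.labeled_bonds.items()):
            instances.append(
                LabeledBondInstance(
                    label=label,
                    molecule_index=n_copies,
                    atom_pair=(mapping[i], mapping[j]),
                    order_series=np.empty(0),
                )
            )
        n_copies += 1
    if expected_copies is not None and n_copies != expected_copies:
        logger.warning(
            "expected %d intact copies of %s, found %d",
            expected_copies, template.name, n_copies,
        )
    return instances


def attach_order_series(
    instances: Sequence[LabeledBondInstance],
    frames: Sequence[BondFrame],
) -> None:
    """Fill each instance's per-frame bond-order series from the frames.

    A pair not listed in a frame's bond table has order 0.
    """
    n = len(frames)
    for inst in instances:
        series = np.zeros(n)
        pair = inst.atom_pair
        for k, frame in enumerate(frames):
            series[k] = frame.bonds.get(pair, 0.0)
        inst.order_series = series


def track_labeled_bonds(
    frames: Sequence[BondFrame],
    template: MoleculeTemplate,
    cutoff: float = DEFAULT_CUTOFF,
    expected_copies: int | None = None,
) -> list[LabeledBondInstance]:
    """Convenience: match on the first frame, then extract all order series."""
    if not frames:
        raise ValueError("need at least one frame")
    instances = map_labeled_bonds(frames[0], template, cutoff, expected_copies)
    attach_order_series(instances, frames)
    return instances


def classify_state_series(order_series: np.ndarray) -> np.ndarray:
    """Discretise a bond-order series into absent/single/double states."""
    series = np.asarray(order_series)
    if series.size == 0:
        raise ValueError("empty order series")
    states = np.zeros(series.shape, dtype=np.int8)
    states[series >= ABSENT_SINGLE_THRESHOLD] = STATE_SINGLE
    states[series >= SINGLE_DOUBLE_THRESHOLD] = STATE_DOUBLE
    return states


def _run_lengths(states: np.ndarray) -> list[tuple[int, int, int]]:
    """(state, start_frame, length) runs of a state series."""
    runs = []
    start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[start]:
            runs.append((int(states[start]), start, k - start))
            start = k
    return runs


def detect_state_events(
    states: np.ndarray,
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
) -> list[tuple[int, int, int]]:
    """Committed transitions ``(old_state, new_state, frame)`` of a state series.

    A transition is committed only when the new state holds for at least
    ``persistence_frames`` consecutive frames; shorter excursions (flickers)
    are ignored.  The event frame is the first frame of the new state's run.
    """
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    runs = _run_lengths(states)
    committed = runs[0][0]
    out = []
    for state, start, length in runs[1:]:
        if length >= persistence_frames and state != committed:
            out.append((committed, state, start))
            committed = state
    return out


def detect_events(
    instance: LabeledBondInstance,
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
    frame_interval_ps: float = 0.25,
) -> list[BondEvent]:
    """Committed bond events of one labeled bond."""
    states = classify_state_series(instance.order_series)
    return [
        BondEvent(
            descriptor=instance.label,
            molecule_index=instance.molecule_index,
            event_type=_TRANSITIONS[(old, new)],
            time_ps=frame * frame_interval_ps,
            frame=frame,
            atom_pair=instance.atom_pair,
        )
        for old, new, frame in detect_state_events(states, persistence_frames)
    ]


def detect_all_events(
    instances: Sequence[LabeledBondInstance],
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
    frame_interval_ps: float = 0.25,
) -> list[BondEvent]:
    events: list[BondEvent] = []
    for inst in instances:
        events.extend(detect_events(inst, persistence_frames, frame_interval_ps))
    events.sort(key=lambda e: (e.time_ps, e.descriptor))
    return events


def bond_count_series(
    instances: Sequence[LabeledBondInstance],
    merge_primes: bool = False,
) -> dict[str, np.ndarray]:
    """Per-frame count of instances in a bonded state (single or double), per label.

    With ``merge_primes=True`` the primed/unprimed label pairs of a symmetric
    molecule (1B and 1B') are aggregated under the unprimed name.
    """
    out: dict[str, np.ndarray] = {}
    for inst in instances:
        label = inst.label.rstrip("'") if merge_primes else inst.label
        bonded = (classify_state_series(inst.order_series) != STATE_ABSENT).astype(np.int64)
        if label in out:
            out[label] = out[label] + bonded
        else:
            out[label] = bonded
    return out


def detect_new_bonds(
    frames: Sequence[BondFrame],
    known_pairs: Iterable[tuple[int, int]],
    watch: Iterable[frozenset[str]] | None = None,
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
    frame_interval_ps: float = 0.25,
) -> list[BondEvent]:
    """Formation events of bonds that are not part of any template copy.

    ``known_pairs`` are the atom pairs already bound to template bonds (plus
    any other pairs to ignore, e.g. the O2 bonds of the feed).  ``watch``
    optionally restricts the report to unordered element pairs, e.g.
    ``[frozenset({"C", "O"}), frozenset({"H", "O"})]``.  The same persistence
    rule as for labeled bonds applies.
    """
    if not frames:
        raise ValueError("need at least one frame")
    known = {tuple(sorted(p)) for p in known_pairs}
    watch_set = {frozenset(w) for w in watch} if watch is not None else None
    candidates: set[tuple[int, int]] = set()
    for frame in frames:
        for pair, bo in frame.bonds.items():
            if bo >= ABSENT_SINGLE_THRESHOLD and pair not in known:
                candidates.add(pair)
    elements = frames[0].atoms
    events: list[BondEvent] = []
    n = len(frames)
    for pair in sorted(candidates):
        pair_elements = frozenset({elements[pair[0]], elements[pair[1]]})
        if watch_set is not None and pair_elements not in watch_set:
            continue
        series = np.fromiter(
            (frame.bonds.get(pair, 0.0) for frame in frames), dtype=float, count=n
        )
        states = classify_state_series(series)
        descriptor = "-".join(sorted({elements[pair[0]], elements[pair[1]]}) if
                              elements[pair[0]] != elements[pair[1]] else
                              [elements[pair[0]], elements[pair[1]]])
        for old, new, frame_k in detect_state_events(states, persistence_frames):
            if _TRANSITIONS[(old, new)] != "formation":
                continue
            events.append(
                BondEvent(
                    descriptor=descriptor,
                    molecule_index=-1,
                    event_type="formation",
                    time_ps=frame_k * frame_interval_ps,
                    frame=frame_k,
                    atom_pair=pair,
                )
            )
    events.sort(key=lambda e: (e.time_ps, e.descriptor, e.atom_pair))
    return events


def event_records(events: Sequence[BondEvent], replicate: str = "r0") -> list[dict]:
    """Rows for the events CSV table."""
    return [
        {
            "replicate": replicate,
            "molecule_index": e.molecule_index,
            "bond_label_or_pair": e.descriptor if e.molecule_index >= 0
            else f"{e.descriptor}({e.atom_pair[0]},{e.atom_pair[1]})",
            "event_type": e.event_type,
            "time_ps": e.time_ps,
        }
        for e in events
    ]
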