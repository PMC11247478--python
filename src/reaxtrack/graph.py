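"""Chemical species detection from one bond-order frame.

A frame becomes a molecular graph by thresholding bond orders at a cutoff
(a pair is bonded iff its order is >= the cutoff; the default 0.5 separates
"no bond" from "single bond").  Species are the connected components of that
graph, named by their canonical Hill formula.  Structural isomers with the
same composition are therefore counted together; the atom-id sets are kept
so individual instances can still be followed through time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io import BondFrame

#: operating bond-order cutoff used throughout unless overridden
DEFAULT_CUTOFF = 0.5


@dataclass(frozen=True)
class SpeciesInstance:
    """A connected set of atoms in one frame."""

    atom_ids: frozenset[int]
    formula: str
    frame: int = 0

    def __post_init__(self) -> None:
        if not self.atom_ids:
            raise ValueError("species instance must contain at least one atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def min_atom_id(self) -> int:
        return min(self.atom_ids)


def hill_formula(elements: Iterable[str]) -> str:
    """Canonical Hill formula of an element multiset.

    Carbon first, hydrogen second, remaining elements alphabetical; with no
    carbon present, all elements purely alphabetical (H2O, not OH2).  Count
    suffix omitted when 1.
    """
    counts = Counter(elements)
    if not counts:
        raise ValueError("empty element multiset")
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else [])
        order += sorted(el for el in counts if el not in ("C", "H"))
    else:
        order = sorted(counts)
    return "".join(
        f"{el}{counts[el]}" if counts[el] > 1 else el for el in order
    )


def apply_cutoff(frame: BondFrame, cutoff: float = DEFAULT_CUTOFF) -> dict[tuple[int, int], float]:
    """Edges of the molecular graph: bonds with order >= cutoff.

    The bound is closed so that boundary orders count as bonded; raising the
    cutoff can only remove edges.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return {pair: bo for pair, bo in frame.bonds.items() if bo >= cutoff}


def connected_species(
    adjacency: Mapping[tuple[int, int], float] | Iterable[tuple[int, int]],
    frame: BondFrame,
) -> list[SpeciesInstance]:
    """Partition the frame's atoms into species along the given edges.

    Components are found by sparse-graph traversal (the classic BFS
    flood-fill).  Output is ordered by each species' smallest atom id, so the
    partition is deterministic; every atom belongs to exactly one instance.
    """
    atom_ids = sorted(frame.atoms)
    if not atom_ids:
        return []
    index = {a: k for k, a in enumerate(atom_ids)}
    edges = list(adjacency)
    if edges:
        rows = np.fromiter((index[i] for i, j in edges), dtype=np.intp, count=len(edges))
        cols = np.fromiter((index[j] for i, j in edges), dtype=np.intp, count=len(edges))
        data = np.ones(len(edges), dtype=np.int8)
        mat = coo_matrix((data, (rows, cols)), shape=(len(atom_ids), len(atom_ids)))
        _, labels = connected_components(mat, directed=False)
    else:
        labels = np.arange(len(atom_ids))
    groups: dict[int, list[int]] = {}
    for atom, lab in zip(atom_ids, labels):
        groups.setdefault(int(lab), []).append(atom)
    instances = [
        SpeciesInstance(
            atom_ids=frozenset(members),
            formula=hill_formula(frame.atoms[a] for a in members),
            frame=frame.timestep,
        )
        for members in groups.values()
    ]
    instances.sort(key=lambda s: s.min_atom_id)
    return instances


def frame_species(frame: BondFrame, cutoff: float = DEFAULT_CUTOFF) -> list[SpeciesInstance]:
    """Convenience: threshold then partition in one call."""
    return connected_species(apply_cutoff(frame, cutoff), frame)


def frame_census(frame: BondFrame, cutoff: float = DEFAULT_CUTOFF) -> dict[str, int]:
    """Count species instances per formula in one frame."""
    census: Counter[str] = Counter(s.formula for s in frame_species(frame, cutoff))
    return dict(census)
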