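"""Shared fixtures: packaged templates and scripted scenario trajectories.

Scenario fixtures are session-scoped because generating and analysing them
is the dominant cost of the suite; all tests treat them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from reaxtrack.io import BondFrame, packaged_template
from reaxtrack.synth import (
    generate_trajectory,
    preset_molecule_a,
    preset_molecule_b,
)


@pytest.fixture(scope="session")
def template_a():
    return packaged_template("A")


@pytest.fixture(scope="session")
def template_b():
    return packaged_template("B")


@pytest.fixture(scope="session")
def template_o2():
    return packaged_template("O2")


@pytest.fixture(scope="session")
def scenario_a_noiseless():
    """Monomer preset, no noise, no flicker: frames, log, layout, meta."""
    initial, layout, script, meta = preset_molecule_a(noise_sd=0.0, seed=101)
    frames, log = generate_trajectory(initial, layout, script, meta)
    return frames, log, layout, meta


@pytest.fixture(scope="session")
def scenario_a_noisy():
    """Monomer preset with default noise and flicker species."""
    initial, layout, script, meta = preset_molecule_a(
        noise_sd=0.05, flicker_rate=0.3, seed=202
    )
    frames, log = generate_trajectory(initial, layout, script, meta)
    return frames, log, layout, meta


@pytest.fixture(scope="session")
def scenario_b_noiseless():
    """Dimer preset, no noise: frames, log, layout, meta."""
    initial, layout, script, meta = preset_molecule_b(noise_sd=0.0, seed=303)
    frames, log = generate_trajectory(initial, layout, script, meta)
    return frames, log, layout, meta


def random_frame(rng: np.random.Generator, max_atoms: int = 60) -> BondFrame:
    """A random small frame for oracle-equivalence checks."""
    n = int(rng.integers(1, max_atoms + 1))
    elements = rng.choice(["C", "H", "O"], size=n)
    atoms = {i + 1: str(el) for i, el in enumerate(elements)}
    bonds = {}
    n_edges = int(rng.integers(0, 2 * n))
    for _ in range(n_edges):
        i, j = rng.integers(1, n + 1, size=2)
        if i != j:
            bonds[(min(i, j), max(i, j))] = float(rng.uniform(0.0, 2.0))
    return BondFrame(timestep=0, time_fs=0.0, atoms=atoms, bonds=bonds)


def oracle_partition(frame: BondFrame, cutoff: float) -> set[frozenset[int]]:
    """Brute-force species partition via boolean transitive closure.

    Independent of the package's traversal: builds the full adjacency
    matrix and closes it by repeated boolean multiplication.
    """
    ids = sorted(frame.atoms)
    idx = {a: k for k, a in enumerate(ids)}
    n = len(ids)
    reach = np.eye(n, dtype=bool)
    for (i, j), bo in frame.bonds.items():
        if bo >= cutoff:
            reach[idx[i], idx[j]] = reach[idx[j], idx[i]] = True
    while True:
        nxt = reach | (reach @ reach)
        if np.array_equal(nxt, reach):
            break
        reach = nxt
    groups = {}
    for k, a in enumerate(ids):
        key = tuple(np.nonzero(reach[k])[0])
        groups.setdefault(key, set()).add(a)
    return {frozenset(g) for g in groups.values()}
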