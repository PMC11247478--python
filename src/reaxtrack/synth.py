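"""Synthetic bond-order trajectories with ground-truth annotation.

The generator emulates the systems the analysis modules are built for — a
periodic box of 50 reactant molecules plus 300 O2, dumped every 250 fs over
1 ns — without running any molecular dynamics.  Bond orders evolve as step
functions at scripted reaction events, decorated with Gaussian noise around
the nominal orders (sd 0.05 by default) and, optionally, short-lived
"flicker" bonds in the 0.5-0.7 order range that briefly fuse species and
must be removed by the lifetime filter downstream.

Everything the generator does is recorded in a :class:`GroundTruthLog`
(species intervals, committed events, flicker insertions), so census, event
detection and pathway reconstruction can be checked against exact truth.
Scripted mechanism presets for the two reactants' headline products
(CO2 and ethyl hydroperoxide from the monomer; water from the dimer) ship as
regression scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .graph import hill_formula
from .io import (
    BondFrame,
    MoleculeTemplate,
    TrajectoryMeta,
    RAMP_RATE_K_PER_PS,
    RAMP_T_END_K,
    RAMP_T_START_K,
    packaged_template,
)
from .onset import RampSeries

DEFAULT_NOISE_SD = 0.05
FLICKER_ORDER_RANGE = (0.5, 0.7)
FLICKER_LIFETIME_FRAMES = (1, 5)
WEAK_CONTACT_ORDER_RANGE = (0.1, 0.45)


@dataclass(frozen=True)
class MoleculePlacement:
    """One molecule copy's atom-id block in the box."""

    template_name: str
    molecule_index: int
    local_to_atom: dict[int, int]
    label_pairs: dict[str, tuple[int, int]]

    def atom_ids(self) -> frozenset[int]:
        return frozenset(self.local_to_atom.values())


@dataclass
class BoxLayout:
    """Atom-id bookkeeping of a generated box."""

    molecules: list[MoleculePlacement]
    o2_pairs: list[tuple[int, int]]
    n_atoms: int

    def labeled_pair(self, molecule_index: int, label: str) -> tuple[int, int]:
        return self.molecules[molecule_index].label_pairs[label]

    def all_template_pairs(self) -> set[tuple[int, int]]:
        pairs: set[tuple[int, int]] = set()
        for mol in self.molecules:
            pairs.update(mol.label_pairs.values())
        return pairs


def generate_box(
    template: MoleculeTemplate,
    n_molecules: int,
    n_O2: int,
    o2_template: MoleculeTemplate | None = None,
) -> tuple[BondFrame, BoxLayout]:
    """Initial frame of a box: template copies then O2, in disjoint id blocks.

    All bonds start at their nominal orders.  Total atoms =
    ``n_molecules * template_size + 2 * n_O2``.
    """
    if n_molecules < 0 or n_O2 < 0:
        raise ValueError("counts must be non-negative")
    if o2_template is None and n_O2 > 0:
        o2_template = packaged_template("O2")
    atoms: dict[int, str] = {}
    bonds: dict[tuple[int, int], float] = {}
    molecules: list[MoleculePlacement] = []
    next_id = 1
    for m in range(n_molecules):
        local_to_atom = {}
        for local, el in template.atoms:
            local_to_atom[local] = next_id
            atoms[next_id] = el
            next_id += 1
        for i, j, order, _ in template.bonds:
            a, b = local_to_atom[i], local_to_atom[j]
            bonds[(min(a, b), max(a, b))] = float(order)
        label_pairs = {}
        for label, (i, j) in template.labeled_bonds.items():
            a, b = local_to_atom[i], local_to_atom[j]
            label_pairs[label] = (min(a, b), max(a, b))
        molecules.append(
            MoleculePlacement(
                template_name=template.name,
                molecule_index=m,
                local_to_atom=local_to_atom,
                label_pairs=label_pairs,
            )
        )
    o2_pairs: list[tuple[int, int]] = []
    for _ in range(n_O2):
        a, b = next_id, next_id + 1
        atoms[a] = atoms[b] = "O"
        bonds[(a, b)] = 2.0
        o2_pairs.append((a, b))
        next_id += 2
    frame = BondFrame(timestep=0, time_fs=0.0, atoms=atoms, bonds=bonds)
    layout = BoxLayout(molecules=molecules, o2_pairs=o2_pairs, n_atoms=len(atoms))
    return frame, layout


# ---------------------------------------------------------------------------
# reaction scripts
# ---------------------------------------------------------------------------

_NOMINAL_AFTER = {
    "dissociation": 0.0,
    "formation": 1.0,
    "single_to_double": 2.0,
    "double_to_single": 1.0,
}


@dataclass(frozen=True)
class ScriptedEvent:
    """One scheduled (or rate-sampled) bond event.

    Either ``label`` + ``molecule_index`` (a labeled template bond) or an
    explicit ``atom_pair`` identifies the bond.  ``frame`` schedules the
    event directly; alternatively ``rate`` gives a per-frame probability and
    the frame is sampled when the trajectory is generated.
    """

    event_type: str
    frame: int | None = None
    rate: float | None = None
    label: str | None = None
    molecule_index: int | None = None
    atom_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.event_type not in _NOMINAL_AFTER:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if (self.frame is None) == (self.rate is None):
            raise ValueError("exactly one of frame/rate must be given")
        if self.rate is not None and not (0 <= self.rate <= 1):
            raise ValueError("rate must be a per-frame probability in [0, 1]")
        if self.atom_pair is None and (self.label is None or self.molecule_index is None):
            raise ValueError("give either atom_pair or label+molecule_index")


@dataclass
class ReactionScript:
    """A set of scripted events plus noise/flicker settings."""

    events: list[ScriptedEvent] = field(default_factory=list)
    noise_sd: float = DEFAULT_NOISE_SD
    flicker_rate: float = 0.0
    weak_contact_rate: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class LoggedEvent:
    descriptor: str
    molecule_index: int
    event_type: str
    frame: int
    atom_pair: tuple[int, int]


@dataclass(frozen=True)
class SpeciesInterval:
    atom_ids: frozenset[int]
    formula: str
    first_frame: int
    last_frame: int

    @property
    def n_frames(self) -> int:
        return self.last_frame - self.first_frame + 1


@dataclass
class GroundTruthLog:
    """Exact record of what the generator did."""

    species_intervals: list[SpeciesInterval] = field(default_factory=list)
    events: list[LoggedEvent] = field(default_factory=list)
    flickers: list[tuple[tuple[int, int], int, int]] = field(default_factory=list)
    n_frames: int = 0

    def census_at(self, frame: int) -> dict[str, int]:
        """Species counts per formula at one frame (flickers excluded)."""
        out: dict[str, int] = {}
        for iv in self.species_intervals:
            if iv.first_frame <= frame <= iv.last_frame:
                out[iv.formula] = out.get(iv.formula, 0) + 1
        return out

    def containing_species(self, atom: int, frame: int) -> frozenset[int]:
        for iv in self.species_intervals:
            if iv.first_frame <= frame <= iv.last_frame and atom in iv.atom_ids:
                return iv.atom_ids
        raise KeyError(f"atom {atom} not covered at frame {frame}")

    def occupancy_frames(self) -> dict[tuple[frozenset[int], str], int]:
        """Total frames of existence per (atom set, formula)."""
        out: dict[tuple[frozenset[int], str], int] = {}
        for iv in self.species_intervals:
            key = (iv.atom_ids, iv.formula)
            out[key] = out.get(key, 0) + iv.n_frames
        return out


def _components(atoms: dict[int, str], edges: set[tuple[int, int]]) -> list[frozenset[int]]:
    """Connected components by union-find (generator-side bookkeeping)."""
    parent = {a: a for a in atoms}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for a in atoms:
        groups.setdefault(find(a), set()).add(a)
    return [frozenset(g) for g in groups.values()]


def generate_trajectory(
    initial: BondFrame,
    layout: BoxLayout,
    script: ReactionScript,
    meta: TrajectoryMeta,
) -> tuple[list[BondFrame], GroundTruthLog]:
    """Evolve the box's bond orders per the script and emit dump frames.

    Bond orders are step functions at event frames plus clipped Gaussian
    noise; flicker bonds appear at ``flicker_rate`` per frame between two
    random atoms of different species and live 1-5 frames with orders in
    [0.5, 0.7].  The returned log is exact by construction.  The same seed
    always yields identical frames and log.
    """
    rng = np.random.default_rng(script.seed)
    n_frames = meta.n_frames
    # resolve bond pairs and event frames
    resolved: list[tuple[int, tuple[int, int], str, str, int]] = []
    for ev in script.events:
        if ev.atom_pair is not None:
            pair = (min(ev.atom_pair), max(ev.atom_pair))
            if pair[0] not in initial.atoms or pair[1] not in initial.atoms:
                raise ValueError(f"event references unknown atom in pair {pair}")
            descriptor = "-".join(sorted((initial.atoms[pair[0]], initial.atoms[pair[1]])))
            mol_idx = -1 if ev.molecule_index is None else ev.molecule_index
        else:
            pair = layout.labeled_pair(ev.molecule_index, ev.label)
            descriptor = ev.label
            mol_idx = ev.molecule_index
        if ev.frame is not None:
            frame = ev.frame
        else:
            frame = int(rng.geometric(ev.rate)) if ev.rate > 0 else n_frames
            if frame >= n_frames:
                continue
        if not (0 <= frame < n_frames):
            raise ValueError(f"event at frame {frame} outside trajectory of {n_frames}")
        resolved.append((frame, pair, ev.event_type, descriptor, mol_idx))
    resolved.sort(key=lambda r: r[0])
    nominal: dict[tuple[int, int], float] = dict(initial.bonds)
    log = GroundTruthLog(n_frames=n_frames)
    by_frame: dict[int, list[tuple[tuple[int, int], str, str, int]]] = {}
    for frame, pair, etype, desc, mol in resolved:
        by_frame.setdefault(frame, []).append((pair, etype, desc, mol))

    def bonded_edges() -> set[tuple[int, int]]:
        return {p for p, o in nominal.items() if o > 0}

    open_intervals: dict[frozenset[int], int] = {}
    for comp in _components(initial.atoms, bonded_edges()):
        open_intervals[comp] = 0

    def reconcile(frame_k: int) -> None:
        new_comps = set(_components(initial.atoms, bonded_edges()))
        for comp in list(open_intervals):
            if comp not in new_comps:
                log.species_intervals.append(
                    SpeciesInterval(
                        atom_ids=comp,
                        formula=hill_formula(initial.atoms[a] for a in comp),
                        first_frame=open_intervals.pop(comp),
                        last_frame=frame_k - 1,
                    )
                )
        for comp in new_comps:
            if comp not in open_intervals:
                open_intervals[comp] = frame_k

    frames: list[BondFrame] = []
    flicker_active: dict[tuple[int, int], tuple[int, float]] = {}  # pair -> (end_frame, order)
    for k in range(n_frames):
        for pair, etype, desc, mol in by_frame.get(k, []):
            current = nominal.get(pair, 0.0)
            if etype == "dissociation" and current <= 0:
                raise ValueError(f"dissociation of absent bond {pair} at frame {k}")
            if etype in ("single_to_double", "double_to_single") and current <= 0:
                raise ValueError(f"transition on absent bond {pair} at frame {k}")
            nominal[pair] = _NOMINAL_AFTER[etype]
            log.events.append(
                LoggedEvent(
                    descriptor=desc, molecule_index=mol, event_type=etype,
                    frame=k, atom_pair=pair,
                )
            )
        if by_frame.get(k):
            reconcile(k)
        # flicker insertion (above the operating cutoff: briefly fuses species)
        if script.flicker_rate > 0 and rng.random() < script.flicker_rate:
            ids = sorted(initial.atoms)
            a, b = rng.choice(len(ids), size=2, replace=False)
            pair = (ids[min(a, b)], ids[max(a, b)])
            if nominal.get(pair, 0.0) == 0 and pair not in flicker_active:
                length = int(rng.integers(FLICKER_LIFETIME_FRAMES[0],
                                          FLICKER_LIFETIME_FRAMES[1] + 1))
                length = min(length, n_frames - k)
                order = float(rng.uniform(*FLICKER_ORDER_RANGE))
                flicker_active[pair] = (k + length - 1, order)
                log.flickers.append((pair, k, length))
        # weak contacts (below the operating cutoff: only visible to low cutoffs)
        if script.weak_contact_rate > 0 and rng.random() < script.weak_contact_rate:
            ids = sorted(initial.atoms)
            a, b = rng.choice(len(ids), size=2, replace=False)
            pair = (ids[min(a, b)], ids[max(a, b)])
            if nominal.get(pair, 0.0) == 0 and pair not in flicker_active:
                length = int(rng.integers(FLICKER_LIFETIME_FRAMES[0],
                                          FLICKER_LIFETIME_FRAMES[1] + 1))
                length = min(length, n_frames - k)
                order = float(rng.uniform(*WEAK_CONTACT_ORDER_RANGE))
                flicker_active[pair] = (k + length - 1, order)
        # emit frame
        bonds_out: dict[tuple[int, int], float] = {}
        alive = [(p, o) for p, o in nominal.items() if o > 0]
        if alive:
            noise = rng.normal(0.0, script.noise_sd, size=len(alive)) if script.noise_sd > 0 \
                else np.zeros(len(alive))
            for (p, o), eps in zip(alive, noise):
                bonds_out[p] = max(0.0, o + float(eps))
        for pair, (end, order) in list(flicker_active.items()):
            if k > end:
                del flicker_active[pair]
            else:
                bonds_out[pair] = order
        frames.append(
            BondFrame(
                timestep=k * meta.frames_per_output,
                time_fs=k * meta.frame_interval_fs,
                atoms=initial.atoms,
                bonds=bonds_out,
            )
        )
    for comp, first in open_intervals.items():
        log.species_intervals.append(
            SpeciesInterval(
                atom_ids=comp,
                formula=hill_formula(initial.atoms[a] for a in comp),
                first_frame=first,
                last_frame=n_frames - 1,
            )
        )
    log.species_intervals.sort(key=lambda iv: (iv.first_frame, min(iv.atom_ids)))
    return frames, log


# ---------------------------------------------------------------------------
# temperature-ramp generator
# ---------------------------------------------------------------------------

def generate_ramp(
    template: MoleculeTemplate,
    n_molecules: int,
    T0_K: float,
    scale_K: float,
    seed: int,
    n_O2: int = 0,
    frame_interval_ps: float = 1.0,
    t_start_K: float = RAMP_T_START_K,
    t_end_K: float = RAMP_T_END_K,
    rate_K_per_ps: float = RAMP_RATE_K_PER_PS,
    noise_sd: float = DEFAULT_NOISE_SD,
    replicate_id: str = "r0",
) -> tuple[list[BondFrame], RampSeries]:
    """Linear-ramp run in which molecules dissociate stochastically.

    Each intact molecule independently survives with the shifted-exponential
    law S(T) = exp(-(T - T0)/scale) above T0 (per-frame hazard
    1 - S(T_k)/S(T_{k-1})); on dissociation one uniformly random template
    bond of that copy drops to order 0 for the rest of the run.  The returned
    :class:`RampSeries` is the generator's own intact-count bookkeeping.
    """
    if not (t_start_K <= T0_K):
        raise ValueError("T0 must lie at or above the ramp start")
    rng = np.random.default_rng(seed)
    initial, layout = generate_box(template, n_molecules, n_O2)
    n_frames = int(round((t_end_K - t_start_K) / (rate_K_per_ps * frame_interval_ps))) + 1
    temperatures = t_start_K + rate_K_per_ps * frame_interval_ps * np.arange(n_frames)
    # timesteps consistent with a 0.25 fs MD step so parsed dumps recover
    # the frame interval
    steps_per_frame = int(round(frame_interval_ps * 1000.0 / 0.25))

    # per-molecule bond pairs (all template bonds, not just labeled ones)
    mol_pairs: list[list[tuple[int, int]]] = []
    for mol in layout.molecules:
        pairs = []
        for i, j, _, _ in template.bonds:
            a, b = mol.local_to_atom[i], mol.local_to_atom[j]
            pairs.append((min(a, b), max(a, b)))
        mol_pairs.append(pairs)

    nominal = dict(initial.bonds)
    intact = np.ones(n_molecules, dtype=bool)
    counts = np.zeros(n_frames)
    counts[0] = n_molecules
    frames: list[BondFrame] = []

    def emit(k: int) -> BondFrame:
        alive = [(p, o) for p, o in nominal.items() if o > 0]
        bonds_out: dict[tuple[int, int], float] = {}
        if alive:
            noise = rng.normal(0.0, noise_sd, size=len(alive)) if noise_sd > 0 \
                else np.zeros(len(alive))
            for (p, o), eps in zip(alive, noise):
                bonds_out[p] = max(0.0, o + float(eps))
        return BondFrame(
            timestep=k * steps_per_frame, time_fs=k * frame_interval_ps * 1000.0,
            atoms=initial.atoms, bonds=bonds_out,
        )

    def survival(T: float) -> float:
        return 1.0 if T <= T0_K else float(np.exp(-(T - T0_K) / scale_K))

    frames.append(emit(0))
    for k in range(1, n_frames):
        s_prev, s_now = survival(temperatures[k - 1]), survival(temperatures[k])
        hazard = 0.0 if s_prev <= 0 else 1.0 - s_now / s_prev
        if hazard > 0:
            dissociate = intact & (rng.random(n_molecules) < hazard)
            for m in np.nonzero(dissociate)[0]:
                pair_idx = int(rng.integers(len(mol_pairs[m])))
                nominal[mol_pairs[m][pair_idx]] = 0.0
                intact[m] = False
        counts[k] = int(intact.sum())
        frames.append(emit(k))
    truth = RampSeries(temperatures, counts, replicate_id)
    return frames, truth


# ---------------------------------------------------------------------------
# mechanism presets
# ---------------------------------------------------------------------------

def _element_atom(frame: BondFrame, pair: tuple[int, int], element: str) -> int:
    """The atom of a pair with the given element."""
    for a in pair:
        if frame.atoms[a] == element:
            return a
    raise ValueError(f"no {element} atom in pair {pair}")


def preset_molecule_a(
    n_co2: int = 3,
    n_c2h6o2: int = 3,
    n_unreacted: int = 2,
    n_O2: int = 20,
    n_frames: int = 400,
    noise_sd: float = DEFAULT_NOISE_SD,
    flicker_rate: float = 0.0,
    seed: int = 0,
) -> tuple[BondFrame, BoxLayout, ReactionScript, TrajectoryMeta]:
    """Monomer scenario: CO2 and ethyl-hydroperoxide pathways.

    CO2 copies run ethyl elimination (4A), ester C-O single-to-double (3A),
    then C-C scission (2A) releasing O=C-O that is carbon dioxide.
    Hydroperoxide copies run phenolic H loss (1A) and ethyl elimination
    (4A); the ethyl then captures an O2 (new C-O bond) and the freed H
    (new H-O bond), giving C2H6O2.
    """
    template = packaged_template("A")
    n_mol = n_co2 + n_c2h6o2 + n_unreacted
    initial, layout = generate_box(template, n_mol, n_O2)
    events: list[ScriptedEvent] = []
    for i in range(n_co2):
        m = i
        events += [
            ScriptedEvent("dissociation", frame=100 + 2 * i, label="4A", molecule_index=m),
            ScriptedEvent("single_to_double", frame=112 + 2 * i, label="3A", molecule_index=m),
            ScriptedEvent("dissociation", frame=180 + 2 * i, label="2A", molecule_index=m),
        ]
    for i in range(n_c2h6o2):
        m = n_co2 + i
        pair_1a = layout.labeled_pair(m, "1A")
        pair_4a = layout.labeled_pair(m, "4A")
        h_atom = _element_atom(initial, pair_1a, "H")
        ethyl_c = _element_atom(initial, pair_4a, "C")
        o2 = layout.o2_pairs[i]
        events += [
            ScriptedEvent("dissociation", frame=80 + 2 * i, label="1A", molecule_index=m),
            ScriptedEvent("dissociation", frame=140 + 2 * i, label="4A", molecule_index=m),
            ScriptedEvent("formation", frame=200 + 2 * i, atom_pair=(ethyl_c, o2[0]),
                          molecule_index=m),
            ScriptedEvent("formation", frame=260 + 2 * i, atom_pair=(o2[1], h_atom),
                          molecule_index=m),
        ]
    script = ReactionScript(events=events, noise_sd=noise_sd,
                            flicker_rate=flicker_rate, seed=seed)
    meta = TrajectoryMeta(timestep_fs=0.25, frames_per_output=1000, n_frames=n_frames)
    return initial, layout, script, meta


def preset_molecule_b(
    n_h2o: int = 3,
    n_unreacted: int = 2,
    n_O2: int = 10,
    n_frames: int = 400,
    noise_sd: float = DEFAULT_NOISE_SD,
    flicker_rate: float = 0.0,
    seed: int = 0,
) -> tuple[BondFrame, BoxLayout, ReactionScript, TrajectoryMeta]:
    """Dimer scenario: water from phenolic H plus side-chain OH.

    On each reacting copy, both rings run the same purely thermal sequence:
    phenolic O-H scission (1B, 1B') releases an H atom, side-chain C-O
    scission (4B, 4B') releases a hydroxyl, and a new H-O bond joins them
    into H2O.
    """
    template = packaged_template("B")
    n_mol = n_h2o + n_unreacted
    initial, layout = generate_box(template, n_mol, n_O2)
    events: list[ScriptedEvent] = []
    for i in range(n_h2o):
        m = i
        for suffix, offset in (("", 0), ("'", 10)):
            pair_1b = layout.labeled_pair(m, "1B" + suffix)
            pair_4b = layout.labeled_pair(m, "4B" + suffix)
            h_atom = _element_atom(initial, pair_1b, "H")
            o_atom = _element_atom(initial, pair_4b, "O")
            events += [
                ScriptedEvent("dissociation", frame=80 + 2 * i + offset,
                              label="1B" + suffix, molecule_index=m),
                ScriptedEvent("dissociation", frame=140 + 2 * i + offset,
                              label="4B" + suffix, molecule_index=m),
                ScriptedEvent("formation", frame=200 + 2 * i + offset,
                              atom_pair=(h_atom, o_atom), molecule_index=m),
            ]
    script = ReactionScript(events=events, noise_sd=noise_sd,
                            flicker_rate=flicker_rate, seed=seed)
    meta = TrajectoryMeta(timestep_fs=0.25, frames_per_output=1000, n_frames=n_frames)
    return initial, layout, script, meta
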