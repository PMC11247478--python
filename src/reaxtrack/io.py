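"""Reading and writing ReaxFF bond-order dumps, molecule templates and result tables.

The on-disk dialect is the LAMMPS ``fix reaxff/bonds`` text format: a comment
block per frame (``# Timestep`` ...) followed by one whitespace-separated row
per atom listing its neighbours and the fractional bond order to each.  Every
bond appears twice (once in each atom's row); parsing reconciles the pair to a
single entry keyed ``(lo, hi)``.

Atom ids are 1-based everywhere in this package.  Times are stored in fs and
printed in ps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: mirror rows of one bond may differ by at most this before a warning is issued
DUPLICATE_TOLERANCE = 0.05


class BondsParseError(ValueError):
    """Raised when a bonds-dump file violates the dialect."""


@dataclass(frozen=True)
class TrajectoryMeta:
    """Dump cadence of a trajectory.

    Parameters
    ----------
    timestep_fs
        Integration timestep of the MD run, in femtoseconds.
    frames_per_output
        Number of MD steps between successive dump frames.
    n_frames
        Number of frames in the trajectory.
    replicate_id
        Free-form label identifying the replicate.
    """

    timestep_fs: float
    frames_per_output: int
    n_frames: int
    replicate_id: str = "r0"

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep_fs must be positive")
        if self.frames_per_output < 1:
            raise ValueError("frames_per_output must be >= 1")

    @property
    def frame_interval_fs(self) -> float:
        """Elapsed simulated time between dump frames (fs)."""
        return self.timestep_fs * self.frames_per_output

    @property
    def frame_interval_ps(self) -> float:
        return self.frame_interval_fs / 1000.0

    @property
    def duration_fs(self) -> float:
        """Time span covered by the dump (first frame at t=0)."""
        return self.frame_interval_fs * self.n_frames


#: cadence of the production runs this package is built around:
#: 0.25 fs timestep, output every 1000 steps (250 fs), 4000 frames = 1 ns.
PRODUCTION_META = TrajectoryMeta(timestep_fs=0.25, frames_per_output=1000, n_frames=4000)

#: temperature-ramp protocol: 300 K to 3500 K over 800 ps (4 K/ps).
RAMP_T_START_K = 300.0
RAMP_T_END_K = 3500.0
RAMP_RATE_K_PER_PS = 4.0


@dataclass
class BondFrame:
    """One timestep's symmetric bond table.

    ``bonds`` maps ``(atom_id_lo, atom_id_hi)`` (1-based, lo < hi) to the
    fractional bond order.  ``atoms`` maps atom id to element symbol.
    """

    timestep: int
    time_fs: float
    atoms: dict[int, str]
    bonds: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (i, j), bo in self.bonds.items():
            if i >= j:
                raise ValueError(f"bond key ({i},{j}) not stored lo < hi")
            if i not in self.atoms or j not in self.atoms:
                raise ValueError(f"bond ({i},{j}) references unknown atom")
            if bo < 0:
                raise ValueError(f"negative bond order on ({i},{j})")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def time_ps(self) -> float:
        return self.time_fs / 1000.0


@dataclass(frozen=True)
class MoleculeTemplate:
    """A reactant molecule as an element-labeled bond graph.

    ``atoms`` is a list of ``(local_index, element)`` with 1-based local
    indices; ``bonds`` is a list of ``(i, j, nominal_order, label)`` where the
    label (e.g. ``"1A"``) marks bonds that are tracked individually.
    """

    name: str
    atoms: tuple[tuple[int, str], ...]
    bonds: tuple[tuple[int, int, int, str | None], ...]
    formula: str

    def __post_init__(self) -> None:
        from .graph import hill_formula  # local import to avoid cycle

        indices = [i for i, _ in self.atoms]
        if len(set(indices)) != len(indices):
            raise ValueError("duplicate local atom indices")
        labels = [lab for *_, lab in self.bonds if lab is not None]
        if len(set(labels)) != len(labels):
            raise ValueError(f"label collision in template {self.name}")
        if not _connected(indices, [(i, j) for i, j, *_ in self.bonds]):
            raise ValueError(f"template {self.name} graph is disconnected")
        derived = hill_formula([el for _, el in self.atoms])
        if derived != self.formula:
            raise ValueError(
                f"template formula {self.formula!r} does not match atoms ({derived!r})"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def labeled_bonds(self) -> dict[str, tuple[int, int]]:
        """Map label -> (local i, local j)."""
        return {lab: (i, j) for i, j, _, lab in self.bonds if lab is not None}

    def element_of(self, local_index: int) -> str:
        return dict(self.atoms)[local_index]


def _connected(nodes: Sequence[int], edges: Iterable[tuple[int, int]]) -> bool:
    if len(nodes) <= 1:
        return True
    adj: dict[int, list[int]] = {n: [] for n in nodes}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(nodes)


# ---------------------------------------------------------------------------
# element maps and packaged templates
# ---------------------------------------------------------------------------

def parse_element_map(path: str | Path) -> dict[int, str]:
    """Read a two-column ``type element`` text file (``#`` starts a comment)."""
    out: dict[int, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise BondsParseError(f"{path}:{lineno}: expected 'type element'")
        out[int(parts[0])] = parts[1]
    return out


#: default atom-type -> element convention used by the synthetic generator
DEFAULT_ELEMENT_MAP = {1: "C", 2: "H", 3: "O"}


def packaged_template(name: str) -> MoleculeTemplate:
    """Load one of the packaged templates: ``"A"``, ``"B"`` or ``"O2"``."""
    fname = f"molecule_{name.lower()}.json"
    path = Path(__file__).parent / "data" / "templates" / fname
    if not path.exists():
        raise FileNotFoundError(f"no packaged template {name!r}")
    return parse_template(path)


def parse_template(path: str | Path) -> MoleculeTemplate:
    """Parse a molecule template JSON file.

    Expected keys: ``name``, ``formula``, ``atoms`` (``[[index, element], ...]``)
    and ``bonds`` (``[[i, j, order, label-or-null], ...]``).
    """
    doc = json.loads(Path(path).read_text())
    atoms = tuple((int(i), str(el)) for i, el in doc["atoms"])
    bonds = tuple(
        (int(i), int(j), int(order), None if lab is None else str(lab))
        for i, j, order, lab in doc["bonds"]
    )
    return MoleculeTemplate(
        name=str(doc["name"]), atoms=atoms, bonds=bonds, formula=str(doc["formula"])
    )


# ---------------------------------------------------------------------------
# bonds-dump parsing
# ---------------------------------------------------------------------------

def parse_bonds_dump(
    path: str | Path,
    element_map: Mapping[int, str],
    timestep_fs: float = 0.25,
    replicate_id: str = "r0",
) -> tuple[TrajectoryMeta, list[BondFrame]]:
    """Parse a ReaxFF bonds-dump file into frames.

    Each frame's bond table is symmetric by construction: the two mirror rows
    of a bond are reconciled to one ``(lo, hi)`` entry.  When the mirror
    orders differ by more than :data:`DUPLICATE_TOLERANCE` a warning is
    logged and the value from the lower atom id's row is kept.
    """
    frames: list[BondFrame] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line.startswith("# Timestep"):
            i += 1
            continue
        try:
            timestep = int(line.split()[2])
        except (IndexError, ValueError) as exc:
            raise BondsParseError(f"{path}:{i + 1}: malformed '# Timestep' header") from exc
        i += 1
        n_particles = None
        while i < n and lines[i].lstrip().startswith("#"):
            stripped = lines[i].strip()
            if stripped.startswith("# Number of particles"):
                try:
                    n_particles = int(stripped.split()[-1])
                except ValueError as exc:
                    raise BondsParseError(
                        f"{path}:{i + 1}: malformed particle-count header"
                    ) from exc
            i += 1
        if n_particles is None:
            raise BondsParseError(
                f"{path}:{i + 1}: frame at timestep {timestep} lacks "
                "'# Number of particles' header"
            )
        atoms: dict[int, str] = {}
        raw_bonds: dict[int, list[tuple[int, float]]] = {}
        for row in range(n_particles):
            if i >= n:
                raise BondsParseError(f"{path}: unexpected EOF in frame {timestep}")
            parts = lines[i].split()
            lineno = i + 1
            i += 1
            try:
                atom_id = int(parts[0])
                atom_type = int(parts[1])
                nb = int(parts[2])
                neighbor_ids = [int(p) for p in parts[3 : 3 + nb]]
                orders = [float(p) for p in parts[4 + nb : 4 + 2 * nb]]
            except (IndexError, ValueError) as exc:
                raise BondsParseError(f"{path}:{lineno}: malformed atom row") from exc
            if len(orders) != nb:
                raise BondsParseError(f"{path}:{lineno}: {nb} neighbors but "
                                      f"{len(orders)} bond orders")
            if atom_type not in element_map:
                raise BondsParseError(
                    f"{path}:{lineno}: unknown atom type {atom_type}"
                )
            if atom_id in atoms:
                raise BondsParseError(f"{path}:{lineno}: duplicate atom id {atom_id}")
            atoms[atom_id] = element_map[atom_type]
            raw_bonds[atom_id] = list(zip(neighbor_ids, orders))
        bonds: dict[tuple[int, int], float] = {}
        for atom_id, entries in sorted(raw_bonds.items()):
            for nb_id, bo in entries:
                if nb_id not in raw_bonds:
                    raise BondsParseError(
                        f"{path}: frame {timestep}: atom {atom_id} lists neighbor "
                        f"{nb_id} absent from the frame"
                    )
                key = (min(atom_id, nb_id), max(atom_id, nb_id))
                if key not in bonds:
                    if atom_id == key[0]:
                        bonds[key] = bo
                    else:
                        # mirror row seen first (lower id listed no entry); keep it
                        bonds[key] = bo
                elif atom_id == key[1]:
                    if abs(bonds[key] - bo) > DUPLICATE_TOLERANCE:
                        logger.warning(
                            "frame %d bond %s: mirror orders differ (%.4f vs %.4f); "
                            "keeping lower-id value",
                            timestep, key, bonds[key], bo,
                        )
        frames.append(
            BondFrame(
                timestep=timestep,
                time_fs=timestep * timestep_fs,
                atoms=atoms,
                bonds=bonds,
            )
        )
    if not frames:
        raise BondsParseError(f"{path}: no '# Timestep' blocks found")
    if len(frames) >= 2:
        frames_per_output = frames[1].timestep - frames[0].timestep
        if frames_per_output <= 0:
            raise BondsParseError(f"{path}: timesteps not increasing")
    else:
        frames_per_output = 1
    meta = TrajectoryMeta(
        timestep_fs=timestep_fs,
        frames_per_output=frames_per_output,
        n_frames=len(frames),
        replicate_id=replicate_id,
    )
    return meta, frames


def write_bonds_dump(
    path: str | Path,
    frames: Iterable[BondFrame],
    type_map: Mapping[str, int] | None = None,
) -> None:
    """Write frames in the bonds-dump dialect (inverse of :func:`parse_bonds_dump`).

    Bond orders are printed with 4 decimals; each bond appears in both atoms'
    rows, as the dialect requires.
    """
    if type_map is None:
        type_map = {el: t for t, el in DEFAULT_ELEMENT_MAP.items()}
    with open(path, "w") as fh:
        for frame in frames:
            neighbors: dict[int, list[tuple[int, float]]] = {a: [] for a in frame.atoms}
            for (i, j), bo in frame.bonds.items():
                neighbors[i].append((j, bo))
                neighbors[j].append((i, bo))
            max_nb = max((len(v) for v in neighbors.values()), default=0)
            fh.write(f"# Timestep {frame.timestep}\n")
            fh.write("#\n")
            fh.write(f"# Number of particles {frame.n_atoms}\n")
            fh.write(f"# Max number of bonds per atom {max_nb} with coarse bond order cutoff 0.300\n")
            fh.write("# Particle connection table and bond orders\n")
            fh.write("# id type nb id_1...id_nb mol bo_1...bo_nb abo nlp q\n")
            for atom_id in sorted(frame.atoms):
                nbs = sorted(neighbors[atom_id])
                nb = len(nbs)
                abo = sum(bo for _, bo in nbs)
                row = [str(atom_id), str(type_map[frame.atoms[atom_id]]), str(nb)]
                row += [str(nid) for nid, _ in nbs]
                row.append("0")  # molecule id: not tracked by this writer
                row += [f"{bo:.4f}" for _, bo in nbs]
                row += [f"{abo:.4f}", "0.0000", "0.0000"]
                fh.write(" ".join(row) + "\n")
            fh.write("# \n")


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

#: column schemas of the standard result tables
TABLE_SCHEMAS = {
    "census": ["replicate", "frame", "time_ps", "formula", "count"],
    "events": ["replicate", "molecule_index", "bond_label_or_pair", "event_type", "time_ps"],
    "ranking": ["formula", "mean_count"],
    "cutoff": ["cutoff", "mean_distinct", "sd_distinct"],
    "onset": ["replicate", "N0", "T0_K", "scale_K", "onset_K"],
}

_SORT_KEYS = {
    "census": ["frame", "formula"],
    "events": ["time_ps", "bond_label_or_pair"],
    "cutoff": ["cutoff"],
    "onset": ["replicate"],
}


def write_table(records: Sequence[Mapping], path: str | Path, schema: str | None = None) -> None:
    """Write records as CSV with a header, 6-significant-digit floats and a
    deterministic row order (time, then formula/label, lexicographic)."""
    if schema is not None and schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    columns = TABLE_SCHEMAS.get(schema) if schema else None
    df = pd.DataFrame(list(records), columns=columns)
    if columns is None and not df.empty:
        columns = list(df.columns)
    sort_cols = [c for c in _SORT_KEYS.get(schema or "", []) if c in df.columns]
    if not sort_cols and df.columns.size and schema is None:
        sort_cols = [c for c in ("time_ps", "frame", "formula", "label") if c in df.columns]
    if sort_cols and not df.empty:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_table`."""
    return pd.read_csv(path)
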