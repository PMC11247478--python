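"""Degradation-onset temperature from temperature-ramp runs.

During a linear ramp the number of intact reactant molecules stays at its
initial value N0 until thermal dissociation begins, then decays roughly
exponentially with temperature (the tail shape carries no physical meaning —
it only reflects the finite molecule count).  The count-vs-temperature data
are fitted with a plateau + shifted-exponential decay

    N(T) = N0                          for T <= T0
    N(T) = N0 * exp(-(T - T0)/scale)   for T >  T0

and the reported onset is the temperature at which the fitted curve first
drops below N0 by one molecule, i.e. where at least one molecule has lost
its intact structure:

    onset = T0 + scale * ln(N0 / (N0 - 1))
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import least_squares

from .events import _element_match, template_graph
from .graph import DEFAULT_CUTOFF, frame_species
from .io import BondFrame, MoleculeTemplate, RAMP_RATE_K_PER_PS, RAMP_T_START_K


@dataclass
class RampSeries:
    """Intact-molecule count versus temperature for one ramp replicate."""

    temperatures_K: np.ndarray
    intact_counts: np.ndarray
    replicate_id: str = "r0"

    def __post_init__(self) -> None:
        self.temperatures_K = np.asarray(self.temperatures_K, dtype=float)
        self.intact_counts = np.asarray(self.intact_counts, dtype=float)
        if self.temperatures_K.shape != self.intact_counts.shape:
            raise ValueError("temperature and count arrays differ in length")
        if np.any(np.diff(self.temperatures_K) < 0):
            raise ValueError("temperatures must be non-decreasing")


@dataclass(frozen=True)
class OnsetFit:
    """Fitted plateau+decay parameters and the derived onset temperature."""

    N0: float
    T0_K: float
    scale_K: float
    onset_K: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_K <= 0:
            raise ValueError("scale must be positive")


def ramp_temperatures(
    n_frames: int,
    frame_interval_ps: float,
    t_start_K: float = RAMP_T_START_K,
    rate_K_per_ps: float = RAMP_RATE_K_PER_PS,
) -> np.ndarray:
    """Per-frame temperatures of a linear ramp protocol."""
    times_ps = np.arange(n_frames) * frame_interval_ps
    return t_start_K + rate_K_per_ps * times_ps


def intact_count_series(
    frames: Sequence[BondFrame],
    template: MoleculeTemplate,
    temperatures_K: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    replicate_id: str = "r0",
) -> RampSeries:
    """Count intact template copies per frame of a ramp run.

    A molecule is intact iff some species instance's element-labeled bonded
    graph is isomorphic to the template — a formula match alone is not
    enough, since a formula-preserving rearrangement (ring-bond break, say)
    is no longer the reactant.  Verdicts are cached per distinct edge set, so
    unreacted copies cost one isomorphism test for the whole run.
    """
    temperatures_K = np.asarray(temperatures_K, dtype=float)
    if len(temperatures_K) != len(frames):
        raise ValueError("need one temperature per frame")
    tg = template_graph(template)
    cache: dict[frozenset, bool] = {}
    counts = np.zeros(len(frames))
    for k, frame in enumerate(frames):
        n_intact = 0
        for inst in frame_species(frame, cutoff):
            if inst.formula != template.formula:
                continue
            edges = frozenset(
                pair for pair, bo in frame.bonds.items()
                if bo >= cutoff and pair[0] in inst.atom_ids and pair[1] in inst.atom_ids
            )
            key = edges
            if key not in cache:
                comp = nx.Graph()
                for a in inst.atom_ids:
                    comp.add_node(a, element=frame.atoms[a])
                comp.add_edges_from(edges)
                cache[key] = nx.is_isomorphic(tg, comp, node_match=_element_match)
            if cache[key]:
                n_intact += 1
        counts[k] = n_intact
    return RampSeries(temperatures_K, counts, replicate_id)


def _model(T: np.ndarray, N0: float, T0: float, scale: float) -> np.ndarray:
    out = np.full_like(T, N0, dtype=float)
    late = T > T0
    out[late] = N0 * np.exp(-(T[late] - T0) / scale)
    return out


def fit_decay(series: RampSeries, N0: float | None = None) -> OnsetFit:
    """Least-squares fit of the plateau + shifted-exponential decay model.

    ``N0`` defaults to the first frame's count and is held fixed; T0 and the
    decay scale are fitted.  Raises if the series never decreases (there is
    nothing to fit an onset to), with residual diagnostics in the message.
    """
    T = series.temperatures_K
    N = series.intact_counts
    if N0 is None:
        N0 = float(N[0])
    if N.min() >= N0:
        const_resid = float(np.sum((N - N0) ** 2))
        raise ValueError(
            "series contains no decrease below N0="
            f"{N0:g} (constant-model residual {const_resid:g}); cannot fit an onset"
        )
    # initial guesses: T0 at the first drop, scale from the decay span
    drop_idx = int(np.argmax(N < N0))
    t0_guess = float(T[max(drop_idx - 1, 0)])
    span = float(T[-1] - T[0])
    scale_guess = max(span / 10.0, 1e-3)

    def residuals(p):
        return _model(T, N0, p[0], p[1]) - N

    result = least_squares(
        residuals,
        x0=[t0_guess, scale_guess],
        bounds=([float(T[0]) - span, 1e-6], [float(T[-1]) + span, 10 * span]),
    )
    T0, scale = float(result.x[0]), float(result.x[1])
    if N0 <= 1:
        raise ValueError("N0 must exceed 1 for an onset at N0 - 1 to exist")
    onset = T0 + scale * np.log(N0 / (N0 - 1.0))
    return OnsetFit(
        N0=N0, T0_K=T0, scale_K=scale, onset_K=float(onset),
        residual=float(np.sum(result.fun ** 2)),
    )


def aggregate_onsets(fits: Sequence[OnsetFit]) -> tuple[float, float | None]:
    """Mean and sample standard deviation of onset temperatures.

    With fewer than two fits the standard deviation is undefined and
    reported as None.
    """
    if not fits:
        raise ValueError("need at least one fit")
    onsets = np.array([f.onset_K for f in fits])
    mean = float(onsets.mean())
    sd = float(onsets.std(ddof=1)) if len(fits) >= 2 else None
    return mean, sd


def onset_records(fits: Sequence[OnsetFit], replicate_ids: Sequence[str] | None = None) -> list[dict]:
    """Rows for the onset CSV table."""
    if replicate_ids is None:
        replicate_ids = [f"r{k}" for k in range(len(fits))]
    return [
        {
            "replicate": rid,
            "N0": f.N0,
            "T0_K": f.T0_K,
            "scale_K": f.scale_K,
            "onset_K": f.onset_K,
        }
        for rid, f in zip(replicate_ids, fits)
    ]
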