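"""Off-lattice 3D cell mechanics and movement.

Cells are soft spheres with a rigid core inside a bounded cube with
reflexive boundaries.  Two movement modes exist:

* "mobile" -- cells move only because forces are applied to them (growth
  and division push neighbors apart); implemented as an iterated
  overdamped relaxation of pairwise overlaps with a soft spring on the
  external radii and a much stiffer spring on the rigid cores.
* "motile" -- cells additionally self-propel along a persistent random
  heading; the speed depends on the types of the cells currently in
  contact (S-S / S-D / D-D speeds), which acts as a surrogate for
  differential adhesion.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .cell_agents import DIFFERENTIATED, STEM

__all__ = [
    "Domain",
    "VelocityRules",
    "MechanicsParams",
    "find_contact_pairs",
    "find_contacts",
    "contacts_to_frame",
    "relax_overlaps",
    "motile_speed",
    "update_positions",
]


@dataclass
class Domain:
    """Cubic simulation domain [0, L]^3; 1 spatial unit = 6.4 um."""

    L: float = 80.0
    unit_to_um: float = 6.4

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("edge length must be positive")

    def reflect(self, positions: np.ndarray) -> np.ndarray:
        """Fold any center outside [0, L]^3 back inside (mirror reflection).

        Returns a boolean mask of rows that were reflected.
        """
        if ((positions >= 0) & (positions <= self.L)).all():
            return np.zeros(positions.shape[0], dtype=bool)
        reflected = np.zeros(positions.shape[0], dtype=bool)
        for _ in range(4):  # repeated folding handles large excursions
            low = positions < 0
            high = positions > self.L
            if not (low.any() or high.any()):
                break
            positions[low] = -positions[low]
            positions[high] = 2 * self.L - positions[high]
            reflected |= low.any(axis=1) | high.any(axis=1)
        np.clip(positions, 0.0, self.L, out=positions)
        return reflected


@dataclass
class VelocityRules:
    """Free speed plus contact-class speeds, all in spatial units / h."""

    default_speed: float = 0.3
    v_ss: float = 0.3
    v_sd: float = 0.3
    v_dd: float = 0.3

    def __post_init__(self) -> None:
        if min(self.default_speed, self.v_ss, self.v_sd, self.v_dd) < 0:
            raise ValueError("speeds must be non-negative")


@dataclass
class MechanicsParams:
    """Overlap-relaxation knobs: linear springs, overdamped sweeps."""

    k_shell: float = 0.1
    k_core: float = 1.0  # core:shell stiffness ratio 10:1
    core_tolerance: float = 1e-3
    max_sweeps: int = 20
    pair_skin: float = 0.2  # extra margin on the pair-search cutoff


def find_contact_pairs(
    positions: np.ndarray, r_ext: np.ndarray, skin: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j), i < j, with ||x_i - x_j|| < r_i + r_j + skin.

    Grid-based spatial index; near-linear in cell count.  With skin > 0 the
    pairs are a superset usable across relaxation sweeps within one step.
    """
    pi, pj, _ = find_pairs_with_dist(positions, r_ext, skin)
    return pi, pj


def find_pairs_with_dist(
    positions: np.ndarray, r_ext: np.ndarray, skin: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Like find_contact_pairs but also returns the center distances."""
    positions = np.ascontiguousarray(positions, dtype=float)
    r_ext = np.ascontiguousarray(r_ext, dtype=float)
    n = positions.shape[0]
    if n < 2:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0)
    cutoff = 2.0 * float(r_ext.max()) + skin
    cap = max(64, 40 * n)
    while True:
        pi, pj, d, m = _kernels.find_pairs_radii(positions, r_ext, skin, cutoff, cap)
        if m >= 0:
            break
        cap *= 4
    return pi[:m], pj[:m], d[:m]


def find_contacts(population) -> set[tuple[int, int]]:
    """Contacts as a set of unordered cell-id pairs (spec-level view).

    Two cells are in contact when their center distance is smaller than the
    sum of their external radii.
    """
    pi, pj = find_contact_pairs(population.positions, population.r_external)
    ids = population.ids
    return {
        (int(min(ids[a], ids[b])), int(max(ids[a], ids[b])))
        for a, b in zip(pi, pj)
    }


def contacts_to_frame(population):
    """Contact pairs of a population as a tidy table (debugging export)."""
    import pandas as pd

    pi, pj, d = find_pairs_with_dist(population.positions, population.r_external)
    ids = population.ids
    return pd.DataFrame(
        {
            "id_a": ids[pi],
            "id_b": ids[pj],
            "distance_units": d,
        }
    )


def relax_overlaps(
    positions: np.ndarray,
    r_int: np.ndarray,
    r_ext: np.ndarray,
    params: MechanicsParams | None = None,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[int, float]:
    """Push overlapping cells apart along their center lines, in place.

    Iterates overdamped displacement sweeps until the worst rigid-core
    overlap is below tolerance or max_sweeps is reached (a warning-level
    situation in crowded configurations, reported via the return value).
    Deterministic given positions.  Returns (sweeps_used, residual_core_overlap).
    """
    if params is None:
        params = MechanicsParams()
    if pairs is None:
        pairs = find_contact_pairs(positions, r_ext, skin=params.pair_skin)
    pi, pj = pairs
    return _kernels.relax_overlaps_kernel(
        positions,
        np.asarray(r_int, dtype=float),
        np.asarray(r_ext, dtype=float),
        pi,
        pj,
        len(pi),
        params.k_shell,
        params.k_core,
        params.core_tolerance,
        params.max_sweeps,
    )


def motile_speed(cell_is_stem: bool, contact_types, rules: VelocityRules) -> float:
    """Contact-class speed of one motile cell.

    No contacts -> free speed.  A stem cell with at least one stem neighbor
    moves at the S-S speed; a stem-differentiated contact (seen from either
    side) gives the S-D speed; differentiated cells among only
    differentiated neighbors move at the D-D speed.
    """
    counts = Counter(contact_types)
    n_stem = counts.get(STEM, 0) + counts.get(True, 0)
    n_diff = counts.get(DIFFERENTIATED, 0) + counts.get(False, 0)
    if n_stem + n_diff == 0:
        return rules.default_speed
    if cell_is_stem:
        return rules.v_ss if n_stem >= 1 else rules.v_sd
    return rules.v_sd if n_stem >= 1 else rules.v_dd


def _contact_speeds(
    is_stem: np.ndarray, pairs: tuple[np.ndarray, np.ndarray], rules: VelocityRules
) -> np.ndarray:
    """Vectorized motile_speed for the whole population."""
    n = is_stem.shape[0]
    pi, pj = pairs
    stem_nb = np.zeros(n, dtype=bool)
    diff_nb = np.zeros(n, dtype=bool)
    np.logical_or.at(stem_nb, pi, is_stem[pj])
    np.logical_or.at(stem_nb, pj, is_stem[pi])
    np.logical_or.at(diff_nb, pi, ~is_stem[pj])
    np.logical_or.at(diff_nb, pj, ~is_stem[pi])
    speeds = np.full(n, rules.default_speed)
    has_nb = stem_nb | diff_nb
    speeds[has_nb & is_stem & stem_nb] = rules.v_ss
    speeds[has_nb & is_stem & ~stem_nb] = rules.v_sd
    speeds[has_nb & ~is_stem & stem_nb] = rules.v_sd
    speeds[has_nb & ~is_stem & ~stem_nb] = rules.v_dd
    return speeds


def update_positions(
    population,
    dt: float,
    domain: Domain,
    mode: str = "mobile",
    rng: np.random.Generator | None = None,
    rules: VelocityRules | None = None,
    params: MechanicsParams | None = None,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
    r_ext: np.ndarray | None = None,
) -> None:
    """One movement tick: self-propulsion (motile mode) then overlap
    relaxation, then boundary reflection.  Mutates the population.

    Motile cells advance speed*dt along a persistent random heading that is
    re-drawn only on contact events or reflections; mobile cells move only
    through the overlap-relaxation displacements.
    """
    if mode not in ("mobile", "motile"):
        raise ValueError(f"unknown movement mode {mode!r}")
    if params is None:
        params = MechanicsParams()
    pos = population.positions
    if r_ext is None:
        r_ext = population.r_external
    if pairs is None:
        pairs = find_contact_pairs(pos, r_ext, skin=params.pair_skin)
    if mode == "motile":
        if rng is None:
            rng = np.random.default_rng()
        if rules is None:
            rules = VelocityRules()
        # initialize missing headings
        norms = np.linalg.norm(population.heading, axis=1)
        fresh = norms < 1e-12
        if fresh.any():
            h = rng.normal(size=(int(fresh.sum()), 3))
            population.heading[fresh] = h / np.linalg.norm(h, axis=1, keepdims=True)
        d = np.linalg.norm(pos[pairs[0]] - pos[pairs[1]], axis=1)
        touching = d < r_ext[pairs[0]] + r_ext[pairs[1]]
        tpairs = (pairs[0][touching], pairs[1][touching])
        population.speed = _contact_speeds(population.is_stem, tpairs, rules)
        pos += population.speed[:, None] * dt * population.heading
        in_contact = np.zeros(len(population), dtype=bool)
        in_contact[tpairs[0]] = True
        in_contact[tpairs[1]] = True
        redraw = in_contact
    else:
        redraw = np.zeros(len(population), dtype=bool)
    relax_overlaps(pos, population.core_ratio * r_ext, r_ext, params, pairs=pairs)
    reflected = domain.reflect(pos)
    redraw = redraw | reflected
    if mode == "motile" and redraw.any():
        h = rng.normal(size=(int(redraw.sum()), 3))
        population.heading[redraw] = h / np.linalg.norm(h, axis=1, keepdims=True)
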