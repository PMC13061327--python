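"""Single-cell life cycle: growth, division gating, fate assignment.

Cells are visco-elastic spheres with a rigid core.  Volume grows linearly
between a birth volume of 1 and a hard cap of 2.2 (dimensionless sphere
volume units; 1 spatial unit = 6.4 um).  A cell divides once its volume has
at least doubled AND its Cyclin E protein has reached the proliferation
threshold.  Each daughter inherits half the mother's volume and half of her
molecular amounts; the stem/differentiated fate of each daughter is decided
at division by comparing its CD133 protein to the differentiation
threshold.  A division where a differentiated mother yields two stem
daughters is a de-differentiation event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grn_dynamics import CD133, CYCLIN_E, GrnState

__all__ = [
    "STEM",
    "DIFFERENTIATED",
    "V_BIRTH",
    "V_DIVISION",
    "V_MAX",
    "UNIT_UM",
    "CellState",
    "FateConfig",
    "radius_from_volume",
    "grow",
    "can_divide",
    "divide",
    "assign_fate",
    "is_dedifferentiation",
]

STEM = "stem"
DIFFERENTIATED = "differentiated"

V_BIRTH = 1.0
V_DIVISION = 2.0
V_MAX = 2.2
UNIT_UM = 6.4  # one spatial unit in micrometres


def radius_from_volume(V):
    """External radius of a sphere of volume V: (3V / 4 pi)^(1/3).

    V = 1 gives r ~= 0.62 spatial units (~4 um); V = 2 gives r ~= 0.78
    units (~5 um at 6.4 um/unit).
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("volume must be positive")
    r = (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)
    return float(r) if np.ndim(r) == 0 else r


@dataclass
class FateConfig:
    """Fate and cycle thresholds.

    differentiation_threshold : CD133 protein amount above which a daughter
        is (or remains) a stem cell, evaluated at division only.
    proliferation_threshold : Cyclin E protein amount gating division (0.01).
    growth_rate : linear volume growth rate g (volume units / h).
    """

    differentiation_threshold: float = 0.004
    proliferation_threshold: float = 0.01
    growth_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.differentiation_threshold <= 0:
            raise ValueError("differentiation threshold must be positive")
        if self.proliferation_threshold <= 0 or self.growth_rate <= 0:
            raise ValueError("thresholds and growth rate must be positive")


@dataclass
class CellState:
    """One agent: geometry, kinematics, molecular state and lineage ids."""

    id: int = 0
    mother_id: int | None = None
    type: str = STEM
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    volume: float = V_BIRTH
    core_ratio: float = 0.5  # r_internal / r_external
    speed: float = 0.0
    grn: GrnState = field(default_factory=GrnState)
    birth_time: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.type not in (STEM, DIFFERENTIATED):
            raise ValueError(f"unknown cell type {self.type!r}")
        if not (0 < self.core_ratio < 1):
            raise ValueError("core_ratio must lie in (0, 1)")

    @property
    def r_external(self) -> float:
        return radius_from_volume(self.volume)

    @property
    def r_internal(self) -> float:
        return self.core_ratio * self.r_external


def grow(cell: CellState, dt: float, g: float) -> CellState:
    """Linear volume growth capped at V_MAX; radii follow the volume."""
    if dt < 0:
        raise ValueError("dt must be non-negative")
    cell.volume = min(cell.volume + g * dt, V_MAX)
    return cell


def can_divide(cell: CellState, cfg: FateConfig) -> bool:
    """True iff volume has at least doubled and Cyclin E protein has
    reached the proliferation threshold."""
    return bool(
        cell.volume >= V_DIVISION
        and cell.grn.P[CYCLIN_E] >= cfg.proliferation_threshold
    )


def assign_fate(P_CD133: float, Th: float) -> str:
    """Stem iff CD133 protein >= the differentiation threshold.

    Boundary-inclusive: initial cells carry exactly 2*Th so their first
    daughters (at exactly Th after halving) remain stem.
    """
    if Th <= 0:
        raise ValueError("threshold must be positive")
    return STEM if P_CD133 >= Th else DIFFERENTIATED


def divide(
    cell: CellState,
    rng: np.random.Generator,
    cfg: FateConfig | None = None,
    time: float = 0.0,
    next_id: int | None = None,
) -> tuple[CellState, CellState]:
    """Split a division-ready mother into two daughters.

    Each daughter receives half the volume and half of every molecular
    amount (amounts, not concentrations, so the split conserves totals
    exactly).  Daughters are placed at the mother's center +/- eps*u for a
    uniformly random unit vector u, with eps half the daughter radius; the
    mechanics layer resolves any residual overlap.  Fates are assigned from
    each daughter's CD133 protein.
    """
    if cfg is None:
        cfg = FateConfig()
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v_half = cell.volume / 2.0
    eps = 0.5 * radius_from_volume(v_half)
    base = next_id if next_id is not None else cell.id + 1
    daughters = []
    for k, sign in enumerate((1.0, -1.0)):
        grn = GrnState(cell.grn.M / 2.0, cell.grn.P / 2.0)
        d = CellState(
            id=base + k,
            mother_id=cell.id,
            type=assign_fate(grn.P[CD133], cfg.differentiation_threshold),
            position=cell.position + sign * eps * u,
            volume=v_half,
            core_ratio=cell.core_ratio,
            speed=cell.speed,
            grn=grn,
            birth_time=time,
        )
        daughters.append(d)
    return daughters[0], daughters[1]


def is_dedifferentiation(mother_type: str, daughter1_type: str, daughter2_type: str) -> bool:
    """True iff a differentiated mother produced two stem daughters."""
    return (
        mother_type == DIFFERENTIATED
        and daughter1_type == STEM
        and daughter2_type == STEM
    )
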