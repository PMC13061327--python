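"""Population-level orchestration: initialization, time loop, logging, scans.

One simulation starts from 15 stem cells packed at the center of a cubic
domain and advances in ticks of dt = 0.1 h.  Each tick: (1) contact
detection; (2) signaling terms from start-of-step state; (3) per-cell PDMP
advance of the gene network; (4) linear volume growth; (5) divisions with
fate assignment and event logging; (6) movement, overlap relaxation and
boundary reflection.  The run stops when the population exceeds the
configured stop count (no cell death, so the population is non-decreasing).

Scenarios: "none" (no signaling), "contact" (stem-stem contact signal of
strength gamma) and "diffusive" (nonlocal Gaussian stem-cell signal).
"""

from __future__ import annotations

import dataclasses
import hashlib
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from . import cell_agents as ca
from .grn_dynamics import CD133, CYCLIN_E, GENE_NAMES, GeneParams, InteractionMatrix
from .mechanics_motion import (
    Domain,
    MechanicsParams,
    VelocityRules,
    find_pairs_with_dist,
    update_positions,
)
from .population import Population
from .signaling import DiffusionConfig, contact_signal_field, perceived_diffusive_signal

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "initialize_population",
    "step",
    "run",
    "dedifferentiation_fraction",
    "scan",
]

DIVISION_COLUMNS = [
    "time",
    "mother_id",
    "mother_type",
    "daughter1_id",
    "daughter1_type",
    "daughter2_id",
    "daughter2_type",
    "dedifferentiation",
]


@dataclass
class SimulationConfig:
    """Full parameter set of one simulation run."""

    dt: float = 0.1
    n_init: int = 15
    stop_count: int = 10_000
    seed: int = 0
    scenario: str = "none"  # none | contact | diffusive
    gamma: float = 0.3  # contact-signal strength
    movement: str = "mobile"  # mobile | motile
    snapshot_stride: int = 0  # in steps; 0 disables intermediate snapshots
    max_hours: float = 20_000.0  # simulated-time safety stop
    wall_budget_s: float = float("inf")  # wall-clock budget; partial result past it
    core_ratio: float = 0.5
    fate: ca.FateConfig = field(default_factory=ca.FateConfig)
    grn: GeneParams = field(default_factory=GeneParams)
    theta: InteractionMatrix = field(default_factory=InteractionMatrix)
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    domain: Domain = field(default_factory=Domain)
    velocity: VelocityRules = field(default_factory=VelocityRules)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_init < 1 or self.stop_count <= self.n_init:
            raise ValueError("require dt > 0, n_init >= 1, stop_count > n_init")
        if self.scenario not in ("none", "contact", "diffusive"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.movement not in ("mobile", "motile"):
            raise ValueError(f"unknown movement mode {self.movement!r}")

    # -- plain key-value serialization ------------------------------------
    def to_dict(self) -> dict:
        d = {
            "dt": self.dt,
            "n_init": self.n_init,
            "stop_count": self.stop_count,
            "seed": self.seed,
            "scenario": self.scenario,
            "gamma": self.gamma,
            "movement": self.movement,
            "snapshot_stride": self.snapshot_stride,
            "max_hours": self.max_hours,
            "core_ratio": self.core_ratio,
            "differentiation_threshold": self.fate.differentiation_threshold,
            "proliferation_threshold": self.fate.proliferation_threshold,
            "growth_rate": self.fate.growth_rate,
            "delta": self.diffusion.delta,
            "q": self.diffusion.q,
            "epsilon": self.diffusion.epsilon,
            "diffusion_method": self.diffusion.method,
            "include_self": self.diffusion.include_self,
            "stem_only_perception": self.diffusion.stem_only_perception,
            "L": self.domain.L,
            "unit_to_um": self.domain.unit_to_um,
            "default_speed": self.velocity.default_speed,
            "v_ss": self.velocity.v_ss,
            "v_sd": self.velocity.v_sd,
            "v_dd": self.velocity.v_dd,
            "k_shell": self.mechanics.k_shell,
            "k_core": self.mechanics.k_core,
            "core_tolerance": self.mechanics.core_tolerance,
            "max_sweeps": self.mechanics.max_sweeps,
            "burst_mean": self.grn.burst_mean,
        }
        for g, name in enumerate(GENE_NAMES):
            for p in ("d0", "d1", "s1", "k0", "k1", "beta"):
                d[f"{p}_{name}"] = float(getattr(self.grn, p)[g])
        for si, sn in enumerate(GENE_NAMES):
            for ti, tn in enumerate(GENE_NAMES):
                d[f"theta_{sn}_{tn}"] = float(self.theta.theta[si, ti])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        grn_kwargs = {}
        for p in ("d0", "d1", "s1", "k0", "k1", "beta"):
            vals = [d.pop(f"{p}_{name}", None) for name in GENE_NAMES]
            if any(v is not None for v in vals):
                defaults = getattr(GeneParams(), p)
                grn_kwargs[p] = np.array(
                    [defaults[g] if v is None else v for g, v in enumerate(vals)]
                )
        if "burst_mean" in d:
            grn_kwargs["burst_mean"] = d.pop("burst_mean")
        theta = InteractionMatrix().theta.copy()
        for si, sn in enumerate(GENE_NAMES):
            for ti, tn in enumerate(GENE_NAMES):
                key = f"theta_{sn}_{tn}"
                if key in d:
                    theta[si, ti] = d.pop(key)
        fate = ca.FateConfig(
            differentiation_threshold=d.pop("differentiation_threshold", 0.004),
            proliferation_threshold=d.pop("proliferation_threshold", 0.01),
            growth_rate=d.pop("growth_rate", 0.05),
        )
        diffusion = DiffusionConfig(
            q=d.pop("q", 0.3),
            delta=d.pop("delta", 2.0),
            epsilon=d.pop("epsilon", 0.01),
            method=d.pop("diffusion_method", "fast"),
            include_self=d.pop("include_self", True),
            stem_only_perception=d.pop("stem_only_perception", True),
        )
        domain = Domain(L=d.pop("L", 80.0), unit_to_um=d.pop("unit_to_um", 6.4))
        velocity = VelocityRules(
            default_speed=d.pop("default_speed", 0.3),
            v_ss=d.pop("v_ss", 0.3),
            v_sd=d.pop("v_sd", 0.3),
            v_dd=d.pop("v_dd", 0.3),
        )
        mechanics = MechanicsParams(
            k_shell=d.pop("k_shell", 0.1),
            k_core=d.pop("k_core", 1.0),
            core_tolerance=d.pop("core_tolerance", 1e-3),
            max_sweeps=d.pop("max_sweeps", 20),
        )
        return cls(
            fate=fate,
            grn=GeneParams(**grn_kwargs),
            theta=InteractionMatrix(theta),
            diffusion=diffusion,
            domain=domain,
            velocity=velocity,
            mechanics=mechanics,
            **d,
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# tumoroid simulation configuration (key = value)\n")
            for key, val in self.to_dict().items():
                fh.write(f"{key} = {val}\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        d = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, val = line.partition("=")
                d[key.strip()] = yaml.safe_load(val.strip())
        return cls.from_dict(d)

    def replace(self, **overrides) -> "SimulationConfig":
        d = self.to_dict()
        d.update(overrides)
        return SimulationConfig.from_dict(d)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SimulationResult:
    """Trajectory snapshots, division log and bookkeeping of one run."""

    population: Population
    divisions: pd.DataFrame
    snapshots: list  # (time, DataFrame) pairs
    config: SimulationConfig
    final_time: float
    wall_time: float
    partial: bool = False

    @property
    def n_dedifferentiation(self) -> int:
        return int(self.divisions["dedifferentiation"].sum())

    @property
    def n_divisions(self) -> int:
        return len(self.divisions)


def _cluster_offsets(n: int) -> np.ndarray:
    """First n integer-lattice points by distance to the origin (a compact,
    contiguous cluster when scaled to one cell diameter)."""
    r = 3
    pts = np.array(
        [(i, j, k) for i in range(-r, r + 1) for j in range(-r, r + 1) for k in range(-r, r + 1)],
        dtype=float,
    )
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], (pts**2).sum(axis=1)))
    return pts[order[:n]]


def initialize_population(cfg: SimulationConfig, rng: np.random.Generator) -> Population:
    """The founding cluster: n_init stem cells side by side at the center.

    Every founder has volume 1, CD133 protein at exactly twice the
    differentiation threshold (so first-generation daughters can remain
    stem), all other proteins at 0, and an initial CD133 mRNA drawn from
    the exponential burst distribution (mean 50 molecules); other mRNAs 0.
    """
    n = cfg.n_init
    spacing = 2.0 * ca.radius_from_volume(1.0)
    offsets = _cluster_offsets(n) * spacing
    center = np.full(3, cfg.domain.L / 2.0)
    positions = center + offsets
    if np.any(positions < 0) or np.any(positions > cfg.domain.L):
        raise ValueError("initial cluster does not fit inside the domain")
    M = np.zeros((n, 3))
    M[:, CD133] = rng.exponential(cfg.grn.burst_mean, size=n)
    P = np.zeros((n, 3))
    P[:, CD133] = 2.0 * cfg.fate.differentiation_threshold
    return Population(
        positions=positions,
        volume=np.ones(n),
        is_stem=np.ones(n, dtype=bool),
        M=M,
        P=P,
        core_ratio=cfg.core_ratio,
    )


class _RunState:
    """Mutable loop state shared between `step` calls."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator, pop: Population):
        self.cfg = cfg
        self.rng = rng
        self.pop = pop
        self.time = 0.0
        self.next_id = int(pop.ids.max()) + 1
        self.division_rows: list[tuple] = []


def _signal_field(state: _RunState, pairs, touching) -> np.ndarray:
    cfg = state.cfg
    pop = state.pop
    if cfg.scenario == "contact":
        tp = (pairs[0][touching], pairs[1][touching])
        return cfg.gamma * contact_signal_field(pop.is_stem, tp)
    if cfg.scenario == "diffusive":
        return perceived_diffusive_signal(pop, cfg.diffusion)
    return np.zeros(len(pop))


def step(state: _RunState) -> int:
    """Advance the population by one tick of dt hours.

    Returns the number of divisions performed this tick.
    """
    cfg = state.cfg
    pop = state.pop
    # (1) contacts (with a skin so the pair list survives the tick)
    r_ext = ca.radius_from_volume(pop.volume)
    pi, pj, dist = find_pairs_with_dist(pop.positions, r_ext, skin=cfg.mechanics.pair_skin)
    touching = dist < r_ext[pi] + r_ext[pj]
    # (2) signaling from start-of-step state
    signal = _signal_field(state, (pi, pj), touching)
    pop.signal = signal
    # (3) gene-network advance
    _kernels.pdmp_population(
        pop.M,
        pop.P,
        signal,
        cfg.grn.d0,
        cfg.grn.d1,
        cfg.grn.s1,
        cfg.grn.k0,
        cfg.grn.k1,
        cfg.grn.beta,
        cfg.theta.theta,
        cfg.grn.burst_mean,
        cfg.dt,
    )
    # (4) growth
    np.minimum(pop.volume + cfg.fate.growth_rate * cfg.dt, ca.V_MAX, out=pop.volume)
    # (5) divisions
    ready = np.flatnonzero(
        (pop.volume >= ca.V_DIVISION) & (pop.P[:, CYCLIN_E] >= cfg.fate.proliferation_threshold)
    )
    n_div = ready.size
    if n_div:
        n_old = len(pop)
        second_daughters = []
        for i in ready:
            mother = pop.cell(int(i))
            d1, d2 = ca.divide(
                mother, state.rng, cfg.fate, time=state.time + cfg.dt, next_id=state.next_id
            )
            state.next_id += 2
            pop.set_cell(int(i), d1)  # first daughter reuses the mother slot
            second_daughters.append(d2)
            state.division_rows.append(
                (
                    state.time + cfg.dt,
                    mother.id,
                    mother.type,
                    d1.id,
                    d1.type,
                    d2.id,
                    d2.type,
                    ca.is_dedifferentiation(mother.type, d1.type, d2.type),
                )
            )
        pop.append(second_daughters)
        # extend the pair list incrementally: a second daughter inherits its
        # mother's neighborhood (it is born inside the mother sphere, within
        # the pair-search skin) plus the sibling pair
        new_index = np.full(n_old, -1, dtype=np.int64)
        new_index[ready] = n_old + np.arange(n_div)
        mi = new_index[pi] >= 0
        mj = new_index[pj] >= 0
        both = mi & mj
        pi = np.concatenate(
            [pi, new_index[pi[mi]], pi[mj], new_index[pi[both]], ready]
        )
        pj = np.concatenate(
            [pj, pj[mi], new_index[pj[mj]], new_index[pj[both]], new_index[ready]]
        )
        r_ext = ca.radius_from_volume(pop.volume)
    # (6) movement + overlap relaxation + reflection
    update_positions(
        pop,
        cfg.dt,
        cfg.domain,
        mode=cfg.movement,
        rng=state.rng,
        rules=cfg.velocity,
        params=cfg.mechanics,
        pairs=(pi, pj),
        r_ext=r_ext,
    )
    state.time += cfg.dt
    return n_div


def run(cfg: SimulationConfig, progress: bool = False) -> SimulationResult:
    """Run one simulation until the population exceeds cfg.stop_count."""
    t0 = _time.perf_counter()
    rng = np.random.default_rng(cfg.seed)
    _kernels.seed_kernel_rng(int(np.random.SeedSequence(cfg.seed).generate_state(1)[0]) % 2**31)
    pop = initialize_population(cfg, rng)
    state = _RunState(cfg, rng, pop)
    snapshots = []
    partial = False
    n_steps = 0
    while len(state.pop) <= cfg.stop_count:
        step(state)
        n_steps += 1
        if cfg.snapshot_stride and n_steps % cfg.snapshot_stride == 0:
            snapshots.append((state.time, state.pop.to_frame()))
        if state.time >= cfg.max_hours or _time.perf_counter() - t0 > cfg.wall_budget_s:
            partial = True
            break
        if progress and n_steps % 500 == 0:
            print(f"  t={state.time:8.1f} h  n={len(state.pop):6d}")
    snapshots.append((state.time, state.pop.to_frame()))
    divisions = pd.DataFrame(state.division_rows, columns=DIVISION_COLUMNS)
    return SimulationResult(
        population=state.pop,
        divisions=divisions,
        snapshots=snapshots,
        config=cfg,
        final_time=state.time,
        wall_time=_time.perf_counter() - t0,
        partial=partial,
    )


def dedifferentiation_fraction(result: SimulationResult) -> float:
    """Percent of division events where a differentiated mother produced
    two stem daughters.  Undefined (raises) when no divisions occurred."""
    if result.n_divisions == 0:
        raise ValueError("de-differentiation fraction undefined: no divisions logged")
    return 100.0 * result.n_dedifferentiation / result.n_divisions


def scan(
    base_cfg: SimulationConfig,
    grid: list[dict],
    seeds: list[int],
    ranges=None,
    z_fraction: float = 0.5,
) -> pd.DataFrame:
    """Parameter-scan driver: run replicates per grid point, compute the
    four indices on the central cross-section, classify against the
    experimental ranges, and flag points where all four are within range.

    grid is a list of config-override dicts; returns one row per grid point
    with per-index mean, sd and classification.
    """
    from .spatial_stats import (
        ExperimentalRanges,
        centrality_index,
        classify,
        cross_section,
        entropy_index,
        morans_I,
        stem_percentage,
    )

    if ranges is None:
        ranges = ExperimentalRanges()
    rows = []
    for overrides in grid:
        vals = {"percentage": [], "morans_i": [], "entropy": [], "centrality": []}
        for seed in seeds:
            cfg = base_cfg.replace(seed=seed, **overrides)
            res = run(cfg)
            table = cross_section(res.population, z_fraction, unit_to_um=cfg.domain.unit_to_um)
            vals["percentage"].append(stem_percentage(table))
            vals["morans_i"].append(morans_I(table))
            vals["entropy"].append(entropy_index(table))
            vals["centrality"].append(centrality_index(table))
        row = dict(overrides)
        all_within = True
        for name, series in vals.items():
            mean = float(np.mean(series))
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = float(np.std(series, ddof=1)) if len(series) > 1 else 0.0
            cls = classify(mean, getattr(ranges, name))
            row[f"{name}_class"] = cls
            all_within &= cls == "within"
        row["acceptable"] = all_within
        rows.append(row)
    return pd.DataFrame(rows)
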