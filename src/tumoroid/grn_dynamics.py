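"""Per-cell stochastic gene-expression engine.

Each cell carries a three-gene regulatory network (CD133, SYP, Cyclin E)
modeled as a bursty piecewise-deterministic Markov process (PDMP): mRNA and
protein decay/accumulate deterministically between transcriptional bursts,
and bursts arrive at a protein-dependent rate shaped by a sigmoid of the
gene's regulatory input.  CD133 and SYP form a toggle switch (mutual
repression, self-activation); SYP strongly activates Cyclin E, which gates
proliferation.  Cell-cell signaling (contact or diffusive) enters only the
CD133 burst rate.

Units: time in hours, molecular state in per-cell amounts (molecules for
mRNA; protein on the same amount scale), so that halving at cell division
is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CD133",
    "SYP",
    "CYCLIN_E",
    "GENE_NAMES",
    "GeneParams",
    "InteractionMatrix",
    "GrnState",
    "SignalTerm",
    "compute_sigma",
    "burst_rate",
    "relax",
    "apply_burst",
    "pdmp_step",
    "single_cell_trajectory",
]

CD133, SYP, CYCLIN_E = 0, 1, 2
GENE_NAMES = ("CD133", "SYP", "CyclinE")
N_GENES = 3

_NAME_TO_INDEX = {name: i for i, name in enumerate(GENE_NAMES)}


def _gene_index(gene) -> int:
    """Resolve a gene given as index or name; raise on anything unknown."""
    if isinstance(gene, str):
        try:
            return _NAME_TO_INDEX[gene]
        except KeyError:
            raise ValueError(f"unknown gene {gene!r}; expected one of {GENE_NAMES}")
    idx = int(gene)
    if idx not in (0, 1, 2):
        raise ValueError(f"unknown gene index {gene!r}; expected 0, 1 or 2")
    return idx


@dataclass
class GeneParams:
    """Kinetic parameters, one entry per gene in order (CD133, SYP, CyclinE).

    d0 : mRNA degradation rate (h^-1); d1 : protein degradation rate (h^-1);
    s1 : protein synthesis rate (h^-1); k0/k1 : min/max burst frequency
    (h^-1); beta : basal activity (dimensionless); burst_mean : mean of the
    exponential burst size (molecules).
    """

    d0: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, 1.0]))
    d1: np.ndarray = field(default_factory=lambda: np.array([0.001, 0.01, 0.01]))
    s1: np.ndarray = field(default_factory=lambda: np.array([1e-5, 1e-4, 1e-4]))
    k0: np.ndarray = field(default_factory=lambda: np.zeros(3))
    k1: np.ndarray = field(default_factory=lambda: np.ones(3))
    beta: np.ndarray = field(default_factory=lambda: np.array([-3.0, -5.0, -5.0]))
    burst_mean: float = 50.0

    def __post_init__(self) -> None:
        for name in ("d0", "d1", "s1", "k0", "k1", "beta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        # equality is admitted so the d0 == d1 analytic limit of the
        # relaxation flow stays constructible
        if np.any(self.d1 < 0) or np.any(self.d0 < self.d1):
            raise ValueError("require d0 >= d1 >= 0 per gene")
        if np.any(self.k0 < 0) or np.any(self.k1 < self.k0):
            raise ValueError("require k1 >= k0 >= 0 per gene")
        if self.burst_mean <= 0:
            raise ValueError("burst_mean must be positive")


@dataclass
class InteractionMatrix:
    """Gene-gene interaction strengths theta[source, target] (dimensionless).

    theta[i, j] is the influence of gene i's protein on the burst rate of
    gene j.  The default encodes the CD133/SYP toggle switch
    (self-activation 15, mutual repression -40) and the proliferation arm
    (SYP -> CyclinE = 250, CD133 -> CyclinE = -2).
    """

    theta: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                #  CD133   SYP  CyclinE   (targets)
                [15.0, -40.0, -2.0],  # source CD133
                [-40.0, 15.0, 250.0],  # source SYP
                [0.0, 0.0, 0.0],  # source CyclinE
            ]
        )
    )

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (N_GENES, N_GENES):
            raise ValueError("theta must be 3x3")


@dataclass
class GrnState:
    """Per-cell molecular state: mRNA amounts M and protein amounts P."""

    M: np.ndarray = field(default_factory=lambda: np.zeros(3))
    P: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if np.any(self.M < 0) or np.any(self.P < 0):
            raise ValueError("molecular amounts must be non-negative")

    def copy(self) -> "GrnState":
        return GrnState(self.M.copy(), self.P.copy())


@dataclass
class SignalTerm:
    """Signaling contribution to the CD133 sigmoid argument.

    kind is one of {"none", "contact", "diffusive"}; value holds gamma*S for
    contact signaling or S_diff for diffusive signaling (both >= 0).
    """

    kind: str = "none"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "contact", "diffusive"):
            raise ValueError(f"unknown signal kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("signal value must be non-negative")


def compute_sigma(
    P: np.ndarray,
    target,
    theta: InteractionMatrix | np.ndarray | None = None,
    beta: float | None = None,
    signal: SignalTerm | None = None,
) -> float:
    """Regulatory input sigma of one gene given the protein vector.

    sigma_target = beta_target + sum_source theta[source, target] * P_source,
    plus the signaling term when the target is CD133 (signaling affects only
    CD133 dynamics).
    """
    j = _gene_index(target)
    P = np.asarray(P, dtype=float)
    if P.shape != (N_GENES,):
        raise ValueError("P must have one entry per gene")
    th = theta.theta if isinstance(theta, InteractionMatrix) else theta
    if th is None:
        th = InteractionMatrix().theta
    if beta is None:
        beta = GeneParams().beta[j]
    sigma = float(beta) + float(np.asarray(th)[:, j] @ P)
    if signal is not None and signal.kind != "none" and j == CD133:
        sigma += signal.value
    return sigma


def burst_rate(sigma: float, k0: float, k1: float):
    """Burst frequency k0 + (k1 - k0) / (1 + exp(-sigma)), in h^-1.

    Monotone increasing in sigma and bounded in [k0, k1]; evaluated in a
    numerically safe form for large |sigma|.
    """
    if np.any(np.asarray(k0) < 0) or np.any(np.asarray(k1) < np.asarray(k0)):
        raise ValueError("require k1 >= k0 >= 0")
    # scipy.special.expit semantics without the import cost in hot paths
    sig = np.where(
        np.asarray(sigma, dtype=float) >= 0,
        1.0 / (1.0 + np.exp(-np.clip(sigma, -700, 700))),
        np.exp(np.clip(sigma, -700, 700)) / (1.0 + np.exp(np.clip(sigma, -700, 700))),
    )
    out = k0 + (k1 - k0) * sig
    return float(out) if np.ndim(out) == 0 else out


def relax(state: GrnState, dt: float, params: GeneParams) -> GrnState:
    """Deterministic flow between bursts, solved in closed form.

    M' = -d0 M and P' = s1 M - d1 P give
    M(dt) = M0 exp(-d0 dt),
    P(dt) = P0 exp(-d1 dt) + s1 M0 (exp(-d1 dt) - exp(-d0 dt)) / (d0 - d1),
    with the analytic limit s1 M0 dt exp(-d0 dt) when d0 == d1.  Exact,
    not an Euler step.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    M0, P0 = state.M, state.P
    e0 = np.exp(-params.d0 * dt)
    e1 = np.exp(-params.d1 * dt)
    diff = params.d0 - params.d1
    with np.errstate(divide="ignore", invalid="ignore"):
        conv = np.where(diff != 0, params.s1 * M0 * (e1 - e0) / np.where(diff != 0, diff, 1.0),
                        params.s1 * M0 * dt * e0)
    return GrnState(M0 * e0, P0 * e1 + conv)


def apply_burst(state: GrnState, gene, burst_mean: float, rng: np.random.Generator) -> GrnState:
    """Increase the gene's mRNA by one exponential draw with the given mean."""
    if burst_mean <= 0:
        raise ValueError("burst_mean must be positive")
    g = _gene_index(gene)
    out = state.copy()
    out.M[g] += rng.exponential(burst_mean)
    return out


def pdmp_step(
    state: GrnState,
    dt: float,
    params: GeneParams,
    theta: InteractionMatrix | np.ndarray | None = None,
    signal: SignalTerm | None = None,
    rng: np.random.Generator | None = None,
) -> GrnState:
    """Advance the PDMP over one interval [t, t + dt].

    Per gene, a candidate burst time is drawn from an exponential clock at
    the current burst rate; if the earliest candidate falls inside the
    remaining interval the state is relaxed to that time, the burst applied,
    rates recomputed from the updated proteins, and the procedure repeats.
    Otherwise the state relaxes deterministically to the interval end.
    Multiple bursts per step are possible.  Clocks are drawn in fixed gene
    order (CD133, SYP, CyclinE) for reproducibility.
    """
    if rng is None:
        rng = np.random.default_rng()
    th = theta.theta if isinstance(theta, InteractionMatrix) else theta
    if th is None:
        th = InteractionMatrix().theta
    cur = state.copy()
    remaining = float(dt)
    while True:
        rates = np.empty(N_GENES)
        for g in range(N_GENES):
            sigma = compute_sigma(cur.P, g, th, params.beta[g], signal)
            rates[g] = burst_rate(sigma, params.k0[g], params.k1[g])
        waits = np.empty(N_GENES)
        for g in range(N_GENES):
            waits[g] = rng.exponential(1.0 / rates[g]) if rates[g] > 0 else np.inf
        g_min = int(np.argmin(waits))
        if waits[g_min] >= remaining:
            return relax(cur, remaining, params)
        cur = relax(cur, float(waits[g_min]), params)
        cur = apply_burst(cur, g_min, params.burst_mean, rng)
        remaining -= float(waits[g_min])


def single_cell_trajectory(
    t_end: float,
    dt: float = 0.1,
    params: GeneParams | None = None,
    theta: InteractionMatrix | None = None,
    signal: SignalTerm | None = None,
    state: GrnState | None = None,
    rng: np.random.Generator | None = None,
    path=None,
):
    """Record one cell's GRN trajectory on a dt grid (debugging aid).

    Returns a DataFrame with columns time, M_<gene>, P_<gene>; writes it as
    CSV when a path is given.
    """
    import pandas as pd

    if params is None:
        params = GeneParams()
    if rng is None:
        rng = np.random.default_rng()
    cur = state.copy() if state is not None else GrnState()
    rows = []
    t = 0.0
    while t <= t_end + 1e-9:
        row = {"time": t}
        for g, name in enumerate(GENE_NAMES):
            row[f"M_{name}"] = cur.M[g]
            row[f"P_{name}"] = cur.P[g]
        rows.append(row)
        cur = pdmp_step(cur, dt, params, theta, signal, rng)
        t += dt
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
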