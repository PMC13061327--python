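"""Stem-cell signaling terms entering the CD133 burst rate.

Two mechanisms are modeled:

* contact signaling -- a binary signal S in {0, 1}: a stem cell perceives
  S = 1 iff at least one of the cells it touches is also a stem cell; the
  term gamma*S is added to the CD133 sigmoid argument.
* diffusive signaling -- every stem cell emits a Gaussian plume of squared
  length scale delta ("reachable area"); the signal perceived at position l
  is the Gauss transform S_diff = sum_j q_j exp(-||l - h_j||^2 / delta)
  over stem-cell sources j.  Emission and perception are both stem-cell
  characteristics, and a stem cell perceives its own emission (autocrine
  term) by default.

The fast Gauss transform here is a cutoff-truncated evaluation with a
certified per-target relative error: the neglected tail is bounded by
(total excluded strength) * exp(-rc^2/delta), and the cutoff rc is enlarged
per target until that bound is below epsilon times the retained sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .mechanics_motion import find_contact_pairs

__all__ = [
    "DiffusionConfig",
    "contact_signal",
    "contact_signal_field",
    "gauss_transform_direct",
    "gauss_transform_fast",
    "perceived_diffusive_signal",
]


@dataclass
class DiffusionConfig:
    """Diffusive-signal parameters.

    q : per-source strength (0.3); delta : reachable area, the squared
    length scale of the Gaussian kernel (spatial units^2); epsilon :
    relative-error tolerance of the fast evaluation (0.01); method :
    "direct" or "fast"; include_self : autocrine self-term flag;
    stem_only_perception : restrict perception to stem cells.
    """

    q: float = 0.3
    delta: float = 2.0
    epsilon: float = 0.01
    method: str = "fast"
    include_self: bool = True
    stem_only_perception: bool = True

    def __post_init__(self) -> None:
        if self.q < 0 or self.delta <= 0 or self.epsilon <= 0:
            raise ValueError("require q >= 0, delta > 0, epsilon > 0")
        if self.method not in ("direct", "fast"):
            raise ValueError(f"unknown method {self.method!r}")


def contact_signal(cell, contacts) -> int:
    """Binary contact signal for one cell given its contact neighbors.

    S = 1 iff the cell is stem AND at least one contact neighbor is stem;
    emission and perception are both stem-only.  `contacts` is an iterable
    of neighboring CellState objects (or anything with a .type attribute).
    """
    if cell.type != "stem":
        return 0
    return int(any(nb.type == "stem" for nb in contacts))


def contact_signal_field(
    is_stem: np.ndarray, pairs: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Vectorized contact signal over a population given contact pairs."""
    n = is_stem.shape[0]
    pi, pj = pairs
    stem_nb = np.zeros(n, dtype=bool)
    ss = is_stem[pi] & is_stem[pj]
    stem_nb[pi[ss]] = True
    stem_nb[pj[ss]] = True
    return (is_stem & stem_nb).astype(float)


def gauss_transform_direct(
    source_positions: np.ndarray,
    q,
    delta: float,
    target_positions: np.ndarray,
) -> np.ndarray:
    """Exact Gauss transform by direct summation (quadratic cost).

    A target coincident with a source (including a target that *is* a
    source) receives that source's full strength q (exp(0) = 1).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    src = np.atleast_2d(np.asarray(source_positions, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_positions, dtype=float))
    if src.size == 0:
        return np.zeros(tgt.shape[0])
    qv = np.broadcast_to(np.asarray(q, dtype=float), (src.shape[0],))
    d2 = ((tgt[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    return (np.exp(-d2 / delta) * qv[None, :]).sum(axis=1)


def gauss_transform_fast(
    source_positions: np.ndarray,
    q,
    delta: float,
    target_positions: np.ndarray,
    epsilon: float = 0.01,
    return_stats: bool = False,
):
    """Approximate Gauss transform with certified relative error <= epsilon.

    Sub-quadratic for bounded local density: each target only sums sources
    within a cutoff radius rc chosen so that the neglected Gaussian tail is
    provably below epsilon times the retained sum; targets for which the
    bound is not yet met get their cutoff enlarged (worst case degrading to
    the exact direct sum).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if delta <= 0:
        raise ValueError("delta must be positive")
    src = np.atleast_2d(np.asarray(source_positions, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_positions, dtype=float))
    n_src, n_tgt = src.shape[0], tgt.shape[0]
    out = np.zeros(n_tgt)
    stats = {"kernel_evals": 0}
    if n_src == 0:
        return (out, stats) if return_stats else out
    qv = np.broadcast_to(np.asarray(q, dtype=float), (n_src,)).astype(float)
    q_tot = float(qv.sum())
    tree = cKDTree(src)
    rc = float(np.sqrt(delta * np.log(max(n_src, 2) / epsilon)))
    # rc beyond this covers every source exactly
    span = float(np.linalg.norm(src.max(axis=0) - src.min(axis=0))) if n_src > 1 else 0.0
    pending = np.arange(n_tgt)
    while pending.size:
        lists = tree.query_ball_point(tgt[pending], rc)
        lens = np.array([len(l) for l in lists])
        flat = np.fromiter(
            (j for l in lists for j in l), dtype=np.int64, count=int(lens.sum())
        )
        rep = np.repeat(pending, lens)
        d2 = ((tgt[rep] - src[flat]) ** 2).sum(axis=1)
        contrib = qv[flat] * np.exp(-d2 / delta)
        stats["kernel_evals"] += int(flat.size)
        s_near = np.zeros(pending.size)
        np.add.at(s_near, np.repeat(np.arange(pending.size), lens), contrib)
        q_near = np.zeros(pending.size)
        np.add.at(q_near, np.repeat(np.arange(pending.size), lens), qv[flat])
        tail = (q_tot - q_near) * np.exp(-rc * rc / delta)
        ok = (tail <= epsilon * s_near) | (q_near >= q_tot)
        out[pending[ok]] = s_near[ok]
        pending = pending[~ok]
        if pending.size:
            if rc > max(span, 1.0) * 2:
                # cutoff already exceeds the configuration span: exact
                out[pending] = gauss_transform_direct(src, qv, delta, tgt[pending])
                stats["kernel_evals"] += int(pending.size) * n_src
                break
            rc *= 1.6
    return (out, stats) if return_stats else out


def perceived_diffusive_signal(population, cfg: DiffusionConfig) -> np.ndarray:
    """Per-cell diffusive signal S_diff for a population.

    Sources are the current stem cells (strength q each, at the cell
    centers); perception is restricted to stem cells unless configured
    otherwise (differentiated cells then read S_diff = 0).
    """
    is_stem = population.is_stem
    pos = population.positions
    n = pos.shape[0]
    out = np.zeros(n)
    stem_idx = np.flatnonzero(is_stem)
    if stem_idx.size == 0:
        return out
    src = np.ascontiguousarray(pos[stem_idx])
    if cfg.stem_only_perception:
        tgt_idx = stem_idx
    else:
        tgt_idx = np.arange(n)
    if cfg.method == "direct" or stem_idx.size < 64:
        vals = gauss_transform_direct(src, cfg.q, cfg.delta, pos[tgt_idx])
        if not cfg.include_self:
            vals[np.isin(tgt_idx, stem_idx)] -= cfg.q
        out[tgt_idx] = vals
        return out
    if cfg.stem_only_perception:
        # sources == targets: symmetric pair accumulation with a cutoff
        # certified by the always-present autocrine term (>= q per target).
        rc = float(np.sqrt(cfg.delta * np.log(stem_idx.size / cfg.epsilon)))
        vals = np.full(stem_idx.size, cfg.q)  # self term
        cap = max(64, 60 * stem_idx.size)
        while True:
            pi, pj, m = _kernels.find_pairs_grid(src, rc, cap)
            if m >= 0:
                break
            cap *= 4
        pi, pj = pi[:m], pj[:m]
        d2 = ((src[pi] - src[pj]) ** 2).sum(axis=1)
        _kernels.gauss_sum_pairs(vals, cfg.q, pi, pj, d2, cfg.delta)
        if not cfg.include_self:
            vals -= cfg.q
        out[stem_idx] = vals
        return out
    vals = gauss_transform_fast(src, cfg.q, cfg.delta, pos[tgt_idx], cfg.epsilon)
    if not cfg.include_self:
        vals[np.isin(tgt_idx, stem_idx)] -= cfg.q
    out[tgt_idx] = vals
    return out
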