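"""Spatial statistics on 2D labeled cell tables.

The comparison layer between simulated tumoroid cross-sections and
immunohistochemistry-derived cell tables (QuPath-style exports): four
summary indices -- stem-cell percentage, Moran's I (binary labels,
row-normalized neighbor weights, 15 um neighbor radius), the Shannon
entropy of the stem-stem pairwise-distance histogram, and the centrality
ratio -- plus the aSS intra-coefficient (a normalized same-type
neighborhood fraction) with a permutation-based confidence band.  Each index is classified below /
within / above the experimentally observed range.

All coordinates are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .cell_agents import DIFFERENTIATED, STEM

__all__ = [
    "UndefinedStatistic",
    "CellTable",
    "ExperimentalRanges",
    "StatsReport",
    "AssBand",
    "cross_section",
    "stem_percentage",
    "morans_I",
    "entropy_index",
    "centrality_index",
    "a_ss",
    "a_ss_band",
    "a_ss_scan",
    "classify",
    "compute_report",
]


class UndefinedStatistic(ValueError):
    """A statistic is mathematically undefined for the given table
    (e.g. single-label table, too few stem cells, no neighbor pairs)."""


@dataclass
class CellTable:
    """2D labeled point pattern: x/y in um and a binary stem label."""

    x: np.ndarray
    y: np.ndarray
    stem: np.ndarray  # boolean: True = stem, False = differentiated
    radius: np.ndarray | None = None  # optional cell radii in um

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.stem = np.asarray(self.stem, dtype=bool)
        if self.x.size == 0:
            raise ValueError("cell table must contain at least one cell")
        if not (self.x.shape == self.y.shape == self.stem.shape):
            raise ValueError("x, y and labels must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if self.radius is not None:
            self.radius = np.asarray(self.radius, dtype=float)

    def __len__(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def n_stem(self) -> int:
        return int(self.stem.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x_um": self.x,
                "y_um": self.y,
                "label": np.where(self.stem, STEM, DIFFERENTIATED),
            }
        )
        if self.radius is not None:
            df["radius_um"] = self.radius
        return df


@dataclass
class ExperimentalRanges:
    """Observed (min, max) bands of the four indices across IHC sections."""

    percentage: tuple = (2.8, 11.2)
    morans_i: tuple = (0.09, 0.48)
    entropy: tuple = (0.05, 0.21)
    centrality: tuple = (0.53, 1.1)

    def __post_init__(self) -> None:
        for name in ("percentage", "morans_i", "entropy", "centrality"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min must not exceed max")


def cross_section(population, z_fraction: float, L: float = 80.0, unit_to_um: float = 6.4) -> CellTable:
    """2D cell table from the plane z = z_fraction * L through a 3D population.

    A cell belongs to the section when its sphere intersects the plane
    (|z_center - z0| <= external radius).  Coordinates are converted to um.
    """
    if not (0 < z_fraction < 1):
        raise ValueError("z_fraction must lie in (0, 1)")
    if len(population) == 0:
        raise ValueError("population is empty")
    z0 = z_fraction * L
    r = population.r_external
    mask = np.abs(population.positions[:, 2] - z0) <= r
    if not mask.any():
        # legal but degenerate: empty plane cut
        raise UndefinedStatistic(f"no cell sphere intersects the plane z = {z0}")
    return CellTable(
        x=population.positions[mask, 0] * unit_to_um,
        y=population.positions[mask, 1] * unit_to_um,
        stem=population.is_stem[mask],
        radius=r[mask] * unit_to_um,
    )


def stem_percentage(table: CellTable) -> float:
    """100 * (number of stem cells) / (total number of cells)."""
    return 100.0 * table.n_stem / len(table)


def _neighbor_adjacency(xy: np.ndarray, radius: float) -> csr_matrix:
    """Symmetric boolean adjacency for pairs within `radius` (inclusive)."""
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = xy.shape[0]
    if pairs.size == 0:
        return csr_matrix((n, n))
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))


def morans_I(table: CellTable, neighbor_radius: float = 15.0) -> float:
    """Moran's spatial autocorrelation of the binary stem labels.

    I = N * sum_ij w_ij (x_i - m)(x_j - m) / (sum_ij w_ij * sum_i (x_i - m)^2)
    with w_ii = 0 and each non-isolated row normalized to sum 1 (isolated
    cells keep an all-zero row and drop out of the numerator).  Cells are
    neighbors at center distance <= neighbor_radius (um).
    """
    n = len(table)
    labels = table.stem.astype(float)
    z = labels - labels.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise UndefinedStatistic("Moran's I undefined: single-label table")
    adj = _neighbor_adjacency(table.xy, neighbor_radius)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if deg.sum() == 0:
        raise UndefinedStatistic("Moran's I undefined: no neighbor pairs")
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    num = float(z @ (inv_deg * (adj @ z)))  # sum_i (1/deg_i) sum_{j in N(i)} z_i z_j
    W = float((deg > 0).sum())  # row-normalized weights: each live row sums to 1
    return n * num / (W * denom)


def _pattern_diameter(xy: np.ndarray) -> float:
    """Largest pairwise distance, via convex-hull vertices for big tables."""
    if xy.shape[0] > 30:
        from scipy.spatial import ConvexHull

        try:
            xy = xy[ConvexHull(xy).vertices]
        except Exception:  # degenerate (collinear) patterns
            pass
    return float(pdist(xy).max()) if xy.shape[0] > 1 else 0.0


def entropy_index(table: CellTable, bins: int = 64, max_distance: float | None = None) -> float:
    """Shannon entropy of the stem-stem pairwise-distance histogram.

    Distances are binned into `bins` equal-width bins over [0, D] where D
    is the diameter of the full point pattern (the image-diagonal analogue,
    but invariant under rigid motions); H = -sum p_i log p_i with natural
    log and empty bins contributing 0.  Classification on this index is
    calibration-sensitive (the binning is a convention).
    """
    stem_xy = table.xy[table.stem]
    if stem_xy.shape[0] < 2:
        raise UndefinedStatistic("entropy undefined: fewer than two stem cells")
    if max_distance is None:
        max_distance = _pattern_diameter(table.xy)
        if max_distance == 0.0:
            max_distance = 1.0
    dists = pdist(stem_xy)
    counts, _ = np.histogram(dists, bins=bins, range=(0.0, max_distance))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def centrality_index(table: CellTable, center: str = "centroid") -> float:
    """Mean stem-to-center distance over mean differentiated-to-center
    distance; < 1 means stem cells sit closer to the image center.

    center = "centroid" (of all cells; default) or "bbox" (bounding-box
    center).
    """
    if table.n_stem == 0 or table.n_stem == len(table):
        raise UndefinedStatistic("centrality undefined: single-label table")
    xy = table.xy
    if center == "centroid":
        c = xy.mean(axis=0)
    elif center == "bbox":
        c = (xy.max(axis=0) + xy.min(axis=0)) / 2.0
    else:
        raise ValueError(f"unknown center convention {center!r}")
    d = np.linalg.norm(xy - c, axis=1)
    return float(d[table.stem].mean() / d[~table.stem].mean())


def _ass_from_counts(stem_counts, all_counts, n_stem, n_total) -> float:
    """aSS from per-stem-cell neighborhood counts (focal cell excluded).

    aSS = (Nt - 1) / (NS (NS - 1)) * sum_i NS(C_i, r) / Nt(C_i, r), with
    the 0/0 ratio of an isolated focal cell counting as 1.
    """
    ratios = np.where(all_counts > 0, stem_counts / np.maximum(all_counts, 1), 1.0)
    return float((n_total - 1) / (n_stem * (n_stem - 1)) * ratios.sum())


def a_ss(table: CellTable, r: float) -> float:
    """Intra-coefficient of same-type aggregation around stem cells.

    Averages, over stem cells, the stem fraction of the (<= r)-neighborhood
    (excluding the focal cell), normalized so that the mean over random
    labelings is 1; > 1 indicates stem-cell clustering.  Requires >= 2 stem
    cells.
    """
    n_stem, n_total = table.n_stem, len(table)
    if n_stem < 2:
        raise UndefinedStatistic("aSS undefined: fewer than two stem cells")
    xy = table.xy
    tree_all = cKDTree(xy)
    stem_xy = xy[table.stem]
    tree_stem = cKDTree(stem_xy)
    all_counts = np.array([len(l) - 1 for l in tree_all.query_ball_point(stem_xy, r)])
    stem_counts = np.array([len(l) - 1 for l in tree_stem.query_ball_point(stem_xy, r)])
    return _ass_from_counts(stem_counts, all_counts, n_stem, n_total)


@dataclass
class AssBand:
    """Permutation confidence band for aSS under random labeling."""

    q: float
    sigma2: float
    alpha: float
    n_perm: int
    degenerate: bool = False  # no neighborhoods at this radius

    @property
    def interval(self) -> tuple:
        return (1.0 - self.q, 1.0 + self.q)

    def rejects(self, ass_value: float) -> bool:
        return abs(ass_value - 1.0) > self.q


def a_ss_band(
    table: CellTable,
    r: float,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> AssBand:
    """Confidence band [1 - q, 1 + q] for aSS under random labeling.

    The variance of aSS under the null (labels uniformly permuted, stem
    count fixed) is estimated empirically over n_perm permutations, and
    q = sqrt(var / alpha) (a Chebyshev-style band guaranteeing >= 1 - alpha
    coverage).  Randomness is rejected when |aSS - 1| > q.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if rng is None:
        rng = np.random.default_rng()
    n_stem, n_total = table.n_stem, len(table)
    if n_stem < 2:
        raise UndefinedStatistic("aSS band undefined: fewer than two stem cells")
    adj = _neighbor_adjacency(table.xy, r)
    all_counts = np.asarray(adj.sum(axis=1)).ravel()
    if all_counts.sum() == 0:
        return AssBand(q=0.0, sigma2=0.0, alpha=alpha, n_perm=n_perm, degenerate=True)
    vals = np.empty(n_perm)
    labels = np.zeros(n_total, dtype=float)
    for p in range(n_perm):
        labels[:] = 0.0
        idx = rng.choice(n_total, size=n_stem, replace=False)
        labels[idx] = 1.0
        stem_counts = (adj @ labels)[idx]
        vals[p] = _ass_from_counts(stem_counts, all_counts[idx], n_stem, n_total)
    sigma2 = float(vals.var())
    return AssBand(q=float(np.sqrt(sigma2 / alpha)), sigma2=sigma2, alpha=alpha, n_perm=n_perm)


def a_ss_scan(
    table: CellTable,
    r_grid,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, float]:
    """aSS and its band over a radius grid.

    Returns (curve, r_accept) where r_accept is the first grid radius at
    which randomness is no longer rejected (|aSS - 1| <= q), or NaN if it
    is rejected everywhere on the grid.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0 or np.any(np.diff(r_grid) <= 0) or np.any(r_grid <= 0):
        raise ValueError("r_grid must be positive and strictly increasing")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    r_accept = np.nan
    for r in r_grid:
        val = a_ss(table, r)
        band = a_ss_band(table, r, alpha=alpha, n_perm=n_perm, rng=rng)
        rejected = band.rejects(val) and not band.degenerate
        rows.append(
            {
                "r_um": r,
                "a_ss": val,
                "q": band.q,
                "lower": band.interval[0],
                "upper": band.interval[1],
                "rejected": rejected,
                "degenerate": band.degenerate,
            }
        )
        if not rejected and np.isnan(r_accept):
            r_accept = float(r)
    return pd.DataFrame(rows), r_accept


def classify(value: float, rng: tuple) -> str:
    """Below / within / above an experimental (min, max) band;
    boundary-inclusive within."""
    lo, hi = rng
    if lo > hi:
        raise ValueError("min must not exceed max")
    if value < lo:
        return "below"
    if value > hi:
        return "above"
    return "within"


@dataclass
class StatsReport:
    """The four indices with their classification, plus the aSS curve."""

    percentage: float
    morans_i: float
    entropy: float
    centrality: float
    classification: dict = field(default_factory=dict)
    ass_curve: pd.DataFrame | None = None
    ass_accept_radius: float = float("nan")

    @property
    def all_within(self) -> bool:
        return all(v == "within" for v in self.classification.values())

    def to_dict(self) -> dict:
        return {
            "percentage": self.percentage,
            "morans_i": self.morans_i,
            "entropy": self.entropy,
            "centrality": self.centrality,
            "classification": dict(self.classification),
            "ass_accept_radius": self.ass_accept_radius,
        }


def compute_report(
    table: CellTable,
    ranges: ExperimentalRanges | None = None,
    neighbor_radius: float = 15.0,
    bins: int = 64,
    ass_r_grid=None,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> StatsReport:
    """All indices of one table, classified against the experimental bands."""
    if ranges is None:
        ranges = ExperimentalRanges()
    values = {
        "percentage": stem_percentage(table),
        "morans_i": morans_I(table, neighbor_radius),
        "entropy": entropy_index(table, bins),
        "centrality": centrality_index(table),
    }
    classification = {k: classify(v, getattr(ranges, k)) for k, v in values.items()}
    curve, r_accept = (None, float("nan"))
    if ass_r_grid is not None:
        curve, r_accept = a_ss_scan(table, ass_r_grid, n_perm=n_perm, rng=rng)
    return StatsReport(
        **values,
        classification=classification,
        ass_curve=curve,
        ass_accept_radius=r_accept,
    )
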