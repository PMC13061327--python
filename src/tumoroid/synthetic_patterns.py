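"""Synthetic labeled 2D point patterns emulating IHC cell tables.

Generates cell tables in the geometry of the histology sections (~2,500
cells on a ~450 um field, stem fractions of a few percent, cell radius
~4.5 um) with controlled label structure: random (the null model),
clustered (stem labels concentrated near Gaussian cluster centers) and
dispersed (pairwise stem-stem separation enforced).  The clustered and
dispersed generators assign labels on a *fixed* point set, so they perturb
only the label autocorrelation, not the point density -- which is exactly
what the spatial indices measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_agents import DIFFERENTIATED, STEM
from .spatial_stats import CellTable

__all__ = [
    "PatternSpec",
    "gen_random",
    "gen_clustered",
    "gen_dispersed",
    "generate",
    "write_table",
    "read_table",
]


@dataclass
class PatternSpec:
    """Geometry and label structure of a synthetic section."""

    n: int = 2500
    stem_fraction: float = 0.06
    extent: float = 450.0  # square side, um
    structure: str = "random"  # random | clustered | dispersed
    n_clusters: int = 4
    cluster_sd: float = 20.0  # um
    min_separation: float = 30.0  # um, dispersed patterns
    hard_core: float = 0.0  # optional minimum point separation, um
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.stem_fraction < 1):
            raise ValueError("stem_fraction must lie in (0, 1)")
        if self.n < 10:
            raise ValueError("need at least 10 cells")
        if self.extent <= 0 or self.cluster_sd <= 0 or self.min_separation <= 0:
            raise ValueError("geometry parameters must be positive")
        if self.structure not in ("random", "clustered", "dispersed"):
            raise ValueError(f"unknown structure {self.structure!r}")


def _positions(spec: PatternSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform points on the square, optionally with a hard-core radius."""
    if spec.hard_core <= 0:
        return rng.uniform(0, spec.extent, size=(spec.n, 2))
    # dart throwing; fails loudly on infeasible packings
    pts = np.empty((spec.n, 2))
    placed = 0
    hc2 = spec.hard_core**2
    for _ in range(200 * spec.n):
        cand = rng.uniform(0, spec.extent, size=2)
        if placed == 0 or (((pts[:placed] - cand) ** 2).sum(axis=1) >= hc2).all():
            pts[placed] = cand
            placed += 1
            if placed == spec.n:
                return pts
    raise ValueError(
        f"could not place {spec.n} points with hard-core {spec.hard_core} um "
        f"on a {spec.extent} um field"
    )


def gen_random(spec: PatternSpec, rng: np.random.Generator | None = None) -> CellTable:
    """Null model: uniform positions, i.i.d. Bernoulli(stem_fraction) labels."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    xy = _positions(spec, rng)
    stem = rng.random(spec.n) < spec.stem_fraction
    return CellTable(xy[:, 0], xy[:, 1], stem)


def gen_clustered(spec: PatternSpec, rng: np.random.Generator | None = None) -> CellTable:
    """Stem labels concentrated around Gaussian cluster centers.

    The point set is the same uniform geometry as gen_random; the
    round(n * stem_fraction) stem labels go to the points with the highest
    mixture density over n_clusters isotropic Gaussians (sd = cluster_sd),
    jittered by the sampling of centers.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    xy = _positions(spec, rng)
    n_stem = round(spec.n * spec.stem_fraction)
    centers = rng.uniform(0.2 * spec.extent, 0.8 * spec.extent, size=(spec.n_clusters, 2))
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    density = np.exp(-d2 / (2 * spec.cluster_sd**2)).sum(axis=1)
    # preferential assignment: sample stem cells weighted by local density
    weights = density + 1e-12
    idx = rng.choice(spec.n, size=n_stem, replace=False, p=weights / weights.sum())
    stem = np.zeros(spec.n, dtype=bool)
    stem[idx] = True
    return CellTable(xy[:, 0], xy[:, 1], stem)


def gen_dispersed(
    spec: PatternSpec, rng: np.random.Generator | None = None
) -> CellTable:
    """Stem labels placed with pairwise separation >= min_separation.

    Greedy best-effort: candidate points are visited in random order and
    labeled stem only if far enough from all previously chosen stem cells;
    if the separation is infeasible the remaining labels are assigned to
    the farthest available points (with a warning).
    """
    import warnings

    if rng is None:
        rng = np.random.default_rng(spec.seed)
    xy = _positions(spec, rng)
    n_stem = round(spec.n * spec.stem_fraction)
    order = rng.permutation(spec.n)
    chosen: list[int] = []
    min2 = spec.min_separation**2
    for i in order:
        if len(chosen) == n_stem:
            break
        if not chosen or (((xy[chosen] - xy[i]) ** 2).sum(axis=1) >= min2).all():
            chosen.append(int(i))
    if len(chosen) < n_stem:
        warnings.warn(
            f"dispersed pattern infeasible at separation {spec.min_separation} um; "
            f"placing {n_stem - len(chosen)} stem labels best-effort"
        )
        remaining = [i for i in order if i not in set(chosen)]
        for i in remaining[: n_stem - len(chosen)]:
            chosen.append(int(i))
    stem = np.zeros(spec.n, dtype=bool)
    stem[chosen] = True
    return CellTable(xy[:, 0], xy[:, 1], stem)


_GENERATORS = {"random": gen_random, "clustered": gen_clustered, "dispersed": gen_dispersed}


def generate(spec: PatternSpec, rng: np.random.Generator | None = None) -> CellTable:
    """Dispatch on spec.structure."""
    return _GENERATORS[spec.structure](spec, rng)


# -- CSV round-trip ---------------------------------------------------------

_COLUMN_ALIASES = {
    # QuPath detection exports can be mapped by renaming these columns
    "x_um": "x_um",
    "y_um": "y_um",
    "label": "label",
    "centroid x um": "x_um",
    "centroid y um": "y_um",
}


def write_table(table: CellTable, path) -> None:
    """Write a cell table as CSV (columns x_um, y_um, label[, radius_um])."""
    table.to_frame().to_csv(path, index=False)


def read_table(path, column_map: dict | None = None) -> CellTable:
    """Read a cell table CSV; raises descriptive errors on malformed input.

    column_map renames e.g. QuPath headers onto the expected schema
    (x_um, y_um, label).  Labels must be exactly 'stem' or 'differentiated'.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={k.strip().lower(): v for k, v in column_map.items()})
    missing = {"x_um", "y_um", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    labels = df["label"].astype(str)
    bad = ~labels.isin([STEM, DIFFERENTIATED])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: row {row}: unknown label {labels.iloc[row]!r} "
            f"(expected '{STEM}' or '{DIFFERENTIATED}')"
        )
    if df[["x_um", "y_um"]].isna().any().any():
        raise ValueError(f"{path}: malformed rows with missing coordinates")
    radius = df["radius_um"].to_numpy() if "radius_um" in df.columns else None
    return CellTable(
        x=df["x_um"].to_numpy(dtype=float),
        y=df["y_um"].to_numpy(dtype=float),
        stem=(labels == STEM).to_numpy(),
        radius=radius,
    )
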