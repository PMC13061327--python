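"""Struct-of-arrays container for the whole cell population.

The simulator operates on flat NumPy arrays for speed; `CellState` objects
(see `cell_agents`) are views materialized on demand for single-cell work
and for snapshot round-trips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cell_agents as ca
from .grn_dynamics import GENE_NAMES, GrnState

__all__ = ["Population"]


class Population:
    """All per-cell state as parallel arrays of length n_cells."""

    def __init__(
        self,
        positions: np.ndarray,
        volume: np.ndarray,
        is_stem: np.ndarray,
        M: np.ndarray,
        P: np.ndarray,
        ids: np.ndarray | None = None,
        mother_ids: np.ndarray | None = None,
        birth_time: np.ndarray | None = None,
        heading: np.ndarray | None = None,
        speed: np.ndarray | None = None,
        core_ratio: float = 0.5,
    ) -> None:
        n = positions.shape[0]
        self.positions = np.asarray(positions, dtype=float)
        self.volume = np.asarray(volume, dtype=float)
        self.is_stem = np.asarray(is_stem, dtype=bool)
        self.M = np.asarray(M, dtype=float)
        self.P = np.asarray(P, dtype=float)
        self.ids = np.arange(n) if ids is None else np.asarray(ids, dtype=np.int64)
        self.mother_ids = (
            np.full(n, -1, dtype=np.int64)
            if mother_ids is None
            else np.asarray(mother_ids, dtype=np.int64)
        )
        self.birth_time = (
            np.zeros(n) if birth_time is None else np.asarray(birth_time, dtype=float)
        )
        self.heading = np.zeros((n, 3)) if heading is None else np.asarray(heading, dtype=float)
        self.speed = np.zeros(n) if speed is None else np.asarray(speed, dtype=float)
        self.core_ratio = float(core_ratio)
        self.signal = np.zeros(n)  # last perceived signaling term, for snapshots

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def r_external(self) -> np.ndarray:
        return ca.radius_from_volume(self.volume)

    @property
    def r_internal(self) -> np.ndarray:
        return self.core_ratio * self.r_external

    def cell(self, i: int) -> ca.CellState:
        """Materialize cell i as a CellState (copies the molecular state)."""
        mid = int(self.mother_ids[i])
        return ca.CellState(
            id=int(self.ids[i]),
            mother_id=None if mid < 0 else mid,
            type=ca.STEM if self.is_stem[i] else ca.DIFFERENTIATED,
            position=self.positions[i].copy(),
            volume=float(self.volume[i]),
            core_ratio=self.core_ratio,
            speed=float(self.speed[i]),
            grn=GrnState(self.M[i].copy(), self.P[i].copy()),
            birth_time=float(self.birth_time[i]),
        )

    def append(self, cells: list[ca.CellState]) -> None:
        """Append freshly created cells (daughters) to the arrays."""
        if not cells:
            return
        self.positions = np.vstack([self.positions, [c.position for c in cells]])
        self.volume = np.concatenate([self.volume, [c.volume for c in cells]])
        self.is_stem = np.concatenate([self.is_stem, [c.type == ca.STEM for c in cells]])
        self.M = np.vstack([self.M, [c.grn.M for c in cells]])
        self.P = np.vstack([self.P, [c.grn.P for c in cells]])
        self.ids = np.concatenate([self.ids, [c.id for c in cells]])
        self.mother_ids = np.concatenate(
            [self.mother_ids, [-1 if c.mother_id is None else c.mother_id for c in cells]]
        )
        self.birth_time = np.concatenate([self.birth_time, [c.birth_time for c in cells]])
        self.heading = np.vstack([self.heading, np.zeros((len(cells), 3))])
        self.speed = np.concatenate([self.speed, [c.speed for c in cells]])
        self.signal = np.concatenate([self.signal, np.zeros(len(cells))])

    def set_cell(self, i: int, c: ca.CellState) -> None:
        """Overwrite slot i with a freshly created cell (slot reuse at
        division keeps sibling arrays compact without a full copy)."""
        self.positions[i] = c.position
        self.volume[i] = c.volume
        self.is_stem[i] = c.type == ca.STEM
        self.M[i] = c.grn.M
        self.P[i] = c.grn.P
        self.ids[i] = c.id
        self.mother_ids[i] = -1 if c.mother_id is None else c.mother_id
        self.birth_time[i] = c.birth_time
        self.heading[i] = 0.0
        self.speed[i] = c.speed
        self.signal[i] = 0.0

    def delete(self, indices) -> None:
        """Remove cells by positional index (used when mothers divide)."""
        keep = np.ones(len(self), dtype=bool)
        keep[np.asarray(indices, dtype=int)] = False
        for name in (
            "positions",
            "volume",
            "is_stem",
            "M",
            "P",
            "ids",
            "mother_ids",
            "birth_time",
            "heading",
            "speed",
            "signal",
        ):
            setattr(self, name, getattr(self, name)[keep])

    def to_frame(self) -> pd.DataFrame:
        """Snapshot as a tidy table (one row per cell)."""
        df = pd.DataFrame(
            {
                "id": self.ids,
                "mother_id": self.mother_ids,
                "type": np.where(self.is_stem, ca.STEM, ca.DIFFERENTIATED),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "volume": self.volume,
                "signal": self.signal,
                "birth_time": self.birth_time,
            }
        )
        for g, name in enumerate(GENE_NAMES):
            df[f"M_{name}"] = self.M[:, g]
            df[f"P_{name}"] = self.P[:, g]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, core_ratio: float = 0.5) -> "Population":
        M = df[[f"M_{n}" for n in GENE_NAMES]].to_numpy()
        P = df[[f"P_{n}" for n in GENE_NAMES]].to_numpy()
        pop = cls(
            positions=df[["x", "y", "z"]].to_numpy(),
            volume=df["volume"].to_numpy(),
            is_stem=(df["type"] == ca.STEM).to_numpy(),
            M=M,
            P=P,
            ids=df["id"].to_numpy(),
            mother_ids=df["mother_id"].to_numpy(),
            birth_time=df["birth_time"].to_numpy(),
            core_ratio=core_ratio,
        )
        pop.signal = df["signal"].to_numpy(dtype=float)
        return pop
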