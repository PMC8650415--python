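"""The in-memory container for proteochemometric (PCM) training data.

A ``PCMDataset`` is an n × d feature matrix (d = 600 by default: a
compound embedding concatenated with a protein embedding) plus a
1-dimensional p-affinity label per row, tagged with the compound and
kinase identifier the row came from and a flag marking rows that were
synthesized by a generative model rather than measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .standardize import DEFAULT_CUTOFF


@dataclass
class PCMDataset:
    X: np.ndarray  # (n, d) float features
    y: np.ndarray  # (n,) p-affinity labels
    compound_ids: np.ndarray  # (n,) str
    kinase_ids: np.ndarray  # (n,) str
    synthetic: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.X.shape[0]
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.y.shape != (n,):
            raise ValueError("y length must match X rows")
        if self.synthetic is None:
            self.synthetic = np.zeros(n, dtype=bool)
        self.compound_ids = np.asarray(self.compound_ids, dtype=object)
        self.kinase_ids = np.asarray(self.kinase_ids, dtype=object)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        for name, arr in (("compound_ids", self.compound_ids),
                          ("kinase_ids", self.kinase_ids),
                          ("synthetic", self.synthetic)):
            if arr.shape != (n,):
                raise ValueError(f"{name} length must match X rows")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("features and labels must be finite")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        """Feature dimension (label excluded)."""
        return self.X.shape[1]

    def active_mask(self, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
        return self.y >= cutoff

    def n_pos(self, cutoff: float = DEFAULT_CUTOFF) -> int:
        return int(self.active_mask(cutoff).sum())

    def n_neg(self, cutoff: float = DEFAULT_CUTOFF) -> int:
        return len(self) - self.n_pos(cutoff)

    def rows(self) -> np.ndarray:
        """The (n, d+1) matrix with the label as the last column."""
        return np.column_stack([self.X, self.y])

    def subset(self, idx) -> "PCMDataset":
        idx = np.asarray(idx)
        return PCMDataset(self.X[idx], self.y[idx], self.compound_ids[idx],
                          self.kinase_ids[idx], self.synthetic[idx])

    def concat(self, other: "PCMDataset") -> "PCMDataset":
        if other.dim != self.dim:
            raise ValueError("feature dimensions differ")
        return PCMDataset(
            np.vstack([self.X, other.X]),
            np.concatenate([self.y, other.y]),
            np.concatenate([self.compound_ids, other.compound_ids]),
            np.concatenate([self.kinase_ids, other.kinase_ids]),
            np.concatenate([self.synthetic, other.synthetic]),
        )

    # -- persistence ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.dim)])
        df.insert(0, "compound_id", self.compound_ids)
        df.insert(1, "kinase_id", self.kinase_ids)
        df["label"] = self.y
        df["synthetic"] = self.synthetic
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PCMDataset":
        feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        feat_cols.sort(key=lambda c: int(c[1:]))
        synthetic = df["synthetic"].to_numpy(dtype=bool) if "synthetic" in df else None
        return cls(
            df[feat_cols].to_numpy(dtype=float),
            df["label"].to_numpy(dtype=float),
            df["compound_id"].to_numpy(dtype=object),
            df["kinase_id"].to_numpy(dtype=object),
            synthetic,
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "PCMDataset":
        return cls.from_frame(pd.read_csv(path))


def rows_to_dataset(rows: np.ndarray, prefix: str = "gen") -> PCMDataset:
    """Wrap raw (n, d+1) generated rows (label last) as a synthetic dataset."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[1] < 2:
        raise ValueError("rows must be 2-D with at least one feature and a label")
    n = rows.shape[0]
    ids = np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
    return PCMDataset(rows[:, :-1], rows[:, -1], ids, ids,
                      np.ones(n, dtype=bool))
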