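"""Class-balancing strategies for imbalanced PCM training sets.

"Balanced" here means equal numbers of active (p-affinity ≥ 6) and
inactive rows. Three routes are provided: appending generator-sampled
positive rows (the augmentation route), SmoteR interpolation between
rare (active) neighbours, and random undersampling of the majority
negatives. Oversampling never alters an original row; added rows are
flagged synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dataset import PCMDataset
from .genmodels import GeneratorHandle, DEFAULT_VALID_RANGE
from .standardize import DEFAULT_CUTOFF


@dataclass(frozen=True)
class BalanceReport:
    n_pos_before: int
    n_neg_before: int
    n_added: int
    n_removed: int
    method: str  # aae | gan | smoter | rus | none

    def __post_init__(self):
        if min(self.n_pos_before, self.n_neg_before, self.n_added, self.n_removed) < 0:
            raise ValueError("counts must be non-negative")


def augment_to_balance(
    train: PCMDataset,
    gen: GeneratorHandle,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE,
    max_draw_factor: int = 100,
    method: str = "aae",
) -> tuple[PCMDataset, BalanceReport]:
    """Append generated positive rows until the classes reach parity.

    Generated rows must pass the valid-label filter (label within
    ``valid_range``); rejected draws are re-sampled. If acceptance stays
    below 1% after ``max_draw_factor`` times the needed rows have been
    drawn, the generator is deemed starved and an error is raised. When
    positives already match or exceed negatives the set is returned
    unchanged.
    """
    n_pos, n_neg = train.n_pos(cutoff), train.n_neg(cutoff)
    need = n_neg - n_pos
    if need <= 0:
        return train, BalanceReport(n_pos, n_neg, 0, 0, "none")

    lo, hi = valid_range
    accepted: list[np.ndarray] = []
    n_acc = 0
    drawn = 0
    chunk = max(need, 64)
    attempt = 0
    while n_acc < need:
        rows = gen.sample(chunk, seed=seed + attempt)
        attempt += 1
        drawn += chunk
        labels = rows[:, -1]
        ok = rows[(labels >= lo) & (labels <= hi)]
        if len(ok):
            accepted.append(ok)
            n_acc += len(ok)
        if drawn >= max_draw_factor * need and n_acc < 0.01 * drawn:
            raise RuntimeError(
                f"generator starved: {n_acc} valid rows in {drawn} draws "
                f"(labels must lie in [{lo}, {hi}])"
            )

    new_rows = np.vstack(accepted)[:need]
    n = len(new_rows)
    synth = PCMDataset(
        new_rows[:, :-1], new_rows[:, -1],
        np.array([f"synth-c{i}" for i in range(n)], dtype=object),
        np.array([f"synth-k{i}" for i in range(n)], dtype=object),
        np.ones(n, dtype=bool),
    )
    balanced = train.concat(synth)
    return balanced, BalanceReport(n_pos, n_neg, need, 0, method)


def smoter(
    train: PCMDataset,
    k: int = 5,
    relevance_cutoff: float = DEFAULT_CUTOFF,
    oversample_pct: float | None = None,
    seed: int = 0,
) -> PCMDataset:
    """SmoteR oversampling of the rare (active) rows.

    Each synthetic row interpolates a rare row ``a`` with one of its
    ``k`` nearest rare neighbours ``b`` (Euclidean over features):
    ``x = a + u·(b − a)`` with ``u ~ U(0, 1)``; the label is the
    distance-weighted average of the two parent labels, so it always
    lies between them. ``oversample_pct`` is the number of synthetic
    rows as a percentage of the rare count; ``None`` oversamples to
    exact class parity.
    """
    rare_idx = np.flatnonzero(train.y >= relevance_cutoff)
    if len(rare_idx) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} rare rows, have {len(rare_idx)}")
    n_rare = len(rare_idx)
    if oversample_pct is None:
        n_new = max(0, len(train) - 2 * n_rare)  # reach parity
    else:
        if oversample_pct < 0:
            raise ValueError("oversample_pct must be non-negative")
        n_new = int(round(oversample_pct / 100.0 * n_rare))
    if n_new == 0:
        return train

    rng = np.random.default_rng(seed)
    Xr, yr = train.X[rare_idx], train.y[rare_idx]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n_rare)).fit(Xr)
    _, neigh = nn.kneighbors(Xr)  # column 0 is the row itself

    feats = np.empty((n_new, train.dim))
    labels = np.empty(n_new)
    for s in range(n_new):
        a = int(rng.integers(n_rare))
        b = int(neigh[a][1 + rng.integers(neigh.shape[1] - 1)])
        u = rng.random()
        x = Xr[a] + u * (Xr[b] - Xr[a])
        d_a = np.linalg.norm(x - Xr[a])
        d_b = np.linalg.norm(x - Xr[b])
        if d_a + d_b == 0:
            labels[s] = 0.5 * (yr[a] + yr[b])
        else:
            labels[s] = (d_b * yr[a] + d_a * yr[b]) / (d_a + d_b)
        feats[s] = x

    synth = PCMDataset(
        feats, labels,
        np.array([f"smoter-c{i}" for i in range(n_new)], dtype=object),
        np.array([f"smoter-k{i}" for i in range(n_new)], dtype=object),
        np.ones(n_new, dtype=bool),
    )
    return train.concat(synth)


def random_undersample(
    train: PCMDataset,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
) -> PCMDataset:
    """Uniformly drop majority negatives until the classes reach parity."""
    pos_idx = np.flatnonzero(train.y >= cutoff)
    neg_idx = np.flatnonzero(train.y < cutoff)
    if len(neg_idx) <= len(pos_idx):
        return train
    rng = np.random.default_rng(seed)
    keep_neg = rng.choice(neg_idx, size=len(pos_idx), replace=False)
    keep = np.sort(np.concatenate([pos_idx, keep_neg]))
    return train.subset(keep)
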