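"""Synthetic data generation for desk-scale testing of every stage.

Real kinase bioactivity corpora are large downloads; this module builds
small, fully seeded stand-ins with known ground truth: raw activity
tables that exercise the standardization rules, toy SMILES/FASTA corpora
for embedding training and similarity filtering, and structured
600-feature PCM datasets with Gaussian-cluster class structure and a
controlled positive/negative imbalance (1:4 by default, echoing the
imbalance the augmentation machinery is designed to repair).

Positive labels are drawn inside the valid activity range [6, 11] and
negative labels in [3, 6), so the activity cutoff at 6 separates the
classes exactly and generated-label validity has a meaningful target.
What these fixtures deliberately do not emulate: real structure-activity
relationships, activity cliffs, or kinome phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import PCMDataset


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic PCM dataset.

    Class structure lives in a ``latent_dim``-dimensional space (real
    compound⊕protein embeddings are strongly correlated, with intrinsic
    dimension far below 600) and is mapped to ``dim`` observed features
    by a fixed random linear map. ``cluster_sd`` controls class overlap
    in the latent space: at the default 1.0 the classes overlap enough
    that the minority class is genuinely harder to fit, while small
    values (≲0.2) give near-perfect nearest-centroid separability.
    """

    n_pos: int = 100
    n_neg: int = 400
    dim: int = 600
    latent_dim: int = 12
    n_clusters_pos: int = 3
    n_clusters_neg: int = 3
    cluster_sd: float = 1.0
    label_range_pos: tuple[float, float] = (6.0, 11.0)
    label_range_neg: tuple[float, float] = (3.0, 6.0)
    n_compounds: int = 40
    n_kinases: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg == 0:
            raise ValueError("need a positive number of rows")
        if self.dim <= 0 or self.latent_dim <= 0 or self.cluster_sd <= 0:
            raise ValueError("dim, latent_dim and cluster_sd must be positive")
        if self.n_clusters_pos < 1 or self.n_clusters_neg < 1:
            raise ValueError("need at least one cluster per class")
        if self.n_compounds * self.n_kinases < self.n_pos + self.n_neg:
            raise ValueError("compound × kinase grid too small for the row count")
        for lo, hi in (self.label_range_pos, self.label_range_neg):
            if lo >= hi:
                raise ValueError("label ranges must be increasing")


def make_pcm_dataset(spec: SyntheticSpec) -> tuple[PCMDataset, dict]:
    """Draw a clustered, imbalanced synthetic PCM dataset.

    Latent features come from per-class Gaussian clusters (standard
    normal centers, spread ``cluster_sd``) and are embedded into the
    observed feature space by a random linear map; labels are uniform
    within the class's range, and each row is assigned a distinct
    synthetic (compound, kinase) pair so the pair-input cross-validation
    splitters have entity structure to work with. Returns the dataset
    plus a ground-truth manifest with class and cluster memberships.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg

    centers_pos = rng.normal(size=(spec.n_clusters_pos, spec.latent_dim))
    centers_neg = rng.normal(size=(spec.n_clusters_neg, spec.latent_dim))
    lift = rng.normal(0, 1.0 / np.sqrt(spec.latent_dim), (spec.latent_dim, spec.dim))

    cluster_pos = rng.integers(spec.n_clusters_pos, size=spec.n_pos)
    cluster_neg = rng.integers(spec.n_clusters_neg, size=spec.n_neg)
    Z = np.vstack([
        centers_pos[cluster_pos] + rng.normal(0, spec.cluster_sd, (spec.n_pos, spec.latent_dim)),
        centers_neg[cluster_neg] + rng.normal(0, spec.cluster_sd, (spec.n_neg, spec.latent_dim)),
    ])
    X = Z @ lift + rng.normal(0, 0.05, (n, spec.dim))
    y = np.concatenate([
        rng.uniform(*spec.label_range_pos, spec.n_pos),
        rng.uniform(*spec.label_range_neg, spec.n_neg),
    ])

    pair_idx = rng.choice(spec.n_compounds * spec.n_kinases, size=n, replace=False)
    compound_ids = np.array([f"CPD{i // spec.n_kinases:04d}" for i in pair_idx], dtype=object)
    kinase_ids = np.array([f"KIN{i % spec.n_kinases:04d}" for i in pair_idx], dtype=object)

    perm = rng.permutation(n)
    ds = PCMDataset(X[perm], y[perm], compound_ids[perm], kinase_ids[perm])
    manifest = {
        "is_positive": (perm < spec.n_pos),
        "cluster": np.concatenate([cluster_pos, cluster_neg + spec.n_clusters_pos])[perm],
        "centers_pos": centers_pos,
        "centers_neg": centers_neg,
        "lift": lift,
    }
    return ds, manifest


# small pool of valid, structurally varied SMILES used to seed toy tables
_TOY_SMILES_POOL = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)C", "CC(C)(C)C", "CCO", "CCN",
    "CCOC", "CC(=O)O", "CC(=O)N", "c1ccccc1", "Cc1ccccc1", "c1ccncc1",
    "c1ccc2ccccc2c1", "Oc1ccccc1", "Nc1ccccc1", "CC(=O)Nc1ccccc1",
    "c1ccc(-c2ccccc2)cc1", "C1CCCCC1", "C1CCNCC1", "O=C1CCCCC1",
    "CCc1ccccc1O", "COc1ccccc1", "CN1CCCC1", "CC(N)C(=O)O", "OCC1CCCCO1",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_toy_activity_table(
    n_rows: int = 60,
    duplicate_rate: float = 0.2,
    unit_mix: tuple[str, ...] = ("nM", "uM", "pKi"),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Build a raw activity table with engineered duplicate groups.

    ``n_rows`` base measurements get distinct (compound, kinase) pairs;
    a ``duplicate_rate`` fraction of them receive a second measurement —
    alternately with coefficient of variation below the 0.05 threshold
    (group survives deduplication with one member) and above it (group is
    removed). The manifest records the expected survivor count.
    """
    if not 0.0 <= duplicate_rate <= 1.0:
        raise ValueError("duplicate_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    base = []
    for i in range(n_rows):
        smiles = _TOY_SMILES_POOL[i % len(_TOY_SMILES_POOL)]
        kinase = f"KIN{i // len(_TOY_SMILES_POOL):03d}"
        p = rng.uniform(3.5, 10.5)
        base.append((smiles, kinase, p))
        rows.append(_raw_row(smiles, kinase, p, rng, unit_mix))

    n_dup = int(round(duplicate_rate * n_rows))
    dup_idx = rng.choice(n_rows, size=n_dup, replace=False)
    n_removed = 0
    for j, i in enumerate(dup_idx):
        smiles, kinase, p = base[i]
        if j % 2 == 0:
            # CV of {p, 1.02p} ≈ 0.014 < 0.05: group keeps one member
            rows.append(_raw_row(smiles, kinase, 1.02 * p, rng, unit_mix))
        else:
            # CV of {p, 1.3p} ≈ 0.18 > 0.05: group removed entirely
            rows.append(_raw_row(smiles, kinase, 1.3 * p, rng, unit_mix))
            n_removed += 1

    table = pd.DataFrame(rows, columns=["smiles", "kinase_id", "measure_type", "value", "unit"])
    table = table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    manifest = {
        "n_groups": n_rows,
        "n_groups_removed": n_removed,
        "expected_survivors": n_rows - n_removed,
    }
    return table, manifest


def _raw_row(smiles: str, kinase: str, p: float, rng: np.random.Generator,
             unit_mix: tuple[str, ...]) -> tuple:
    form = unit_mix[int(rng.integers(len(unit_mix)))]
    if form == "pKi":
        return (smiles, kinase, "pKi", p, "dimensionless")
    nM = 10.0 ** (9.0 - p)
    if form == "uM":
        return (smiles, kinase, "Ki", nM / 1e3, "uM")
    return (smiles, kinase, "Ki", nM, "nM")


def make_toy_corpora(n_molecules: int = 20, n_proteins: int = 10, seed: int = 0,
                     min_len: int = 50, max_len: int = 300) -> tuple[list[str], list[tuple[str, str]]]:
    """Toy SMILES list and FASTA-style (id, sequence) records.

    Molecules cycle through a pool of small valid structures; protein
    sequences are uniform random draws over the 20 canonical amino
    acids with lengths in [min_len, max_len].
    """
    if n_molecules < 1 or n_proteins < 1:
        raise ValueError("counts must be at least 1")
    rng = np.random.default_rng(seed)
    smiles = [_TOY_SMILES_POOL[i % len(_TOY_SMILES_POOL)] for i in range(n_molecules)]
    proteins = []
    for i in range(n_proteins):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list(_AA), size=length))
        proteins.append((f"PROT{i:03d}", seq))
    return smiles, proteins


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
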