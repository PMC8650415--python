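"""PCM2vec featurization: compound and protein sequence embeddings.

Compounds are turned into "molecule sentences" — the ordered list of
Morgan-algorithm substructure identifiers at radii 0 and 1, one per atom
per radius — and embedded by summing per-identifier skip-gram vectors
(the Mol2Vec construction). Proteins are split into three frames of
non-overlapping 3-grams (offsets 0, 1, 2) and embedded by summing
per-3-gram vectors within each frame, then combining the three frame
vectors (the ProtVec construction). Three combination schemes assemble
the joint compound⊕protein feature vector:

* ``c1`` — 100-dim compound ⊕ sum of three 100-dim frame vectors (200)
* ``c2`` — 300-dim compound ⊕ sum of three 300-dim frame vectors (600)
* ``c3`` — 300-dim compound ⊕ concat of three 100-dim frame vectors (600)

``c2`` is the default; with the 1-dim affinity label appended the
training row is 601-dimensional.

Embeddings are pluggable: train a skip-gram model on any corpus with
:func:`train_skipgram` (a NumPy skip-gram with negative sampling), or
load pre-trained vectors from a word2vec-format text table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .dataset import PCMDataset

logger = logging.getLogger(__name__)

SCHEME_DIMS = {"c1": 200, "c2": 600, "c3": 600}


# ---------------------------------------------------------------------------
# molecule sentences and protein n-gram frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeSentence:
    """Ordered Morgan substructure identifiers, atom-major then by radius."""

    identifiers: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.identifiers)


@dataclass(frozen=True)
class NgramFrames:
    """Three reading frames of non-overlapping amino-acid n-grams."""

    frames: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]


def mol_sentence(smiles: str, radii: Sequence[int] = (0, 1)) -> MoleculeSentence:
    """Build the molecule sentence of a SMILES string.

    For each heavy atom the Morgan environment identifier is emitted at
    every requested radius (default 0 and 1), in atom order, radius-minor;
    a molecule in which every atom has a bond therefore yields
    ``len(radii) ×`` heavy-atom-count identifiers. An isolated atom (e.g.
    methane) has no radius-1 environment and contributes only its
    radius-0 identifier.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    radii = sorted(set(int(r) for r in radii))
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=max(radii), includeRedundantEnvironments=True)
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=out)
    by_atom_radius: dict[tuple[int, int], int] = {}
    for identifier, hits in out.GetBitInfoMap().items():
        for atom_idx, radius in hits:
            by_atom_radius[(atom_idx, radius)] = identifier
    ids = []
    for atom_idx in range(mol.GetNumAtoms()):
        for radius in radii:
            # an atom may lack an environment at a radius (small molecule)
            if (atom_idx, radius) in by_atom_radius:
                ids.append(by_atom_radius[(atom_idx, radius)])
    return MoleculeSentence(tuple(ids))


def prot_ngrams(sequence: str, n: int = 3) -> NgramFrames:
    """Split a protein sequence into three frames of non-overlapping n-grams.

    Frame k (k = 0, 1, 2) tiles ``sequence[k:]`` with words of length
    ``n``; a trailing partial word is dropped. An empty sequence yields
    three empty frames.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    sequence = sequence.strip().upper()
    frames = []
    for k in range(3):
        sub = sequence[k:]
        frames.append(tuple(sub[i:i + n] for i in range(0, len(sub) - n + 1, n)))
    return NgramFrames(tuple(frames))


# ---------------------------------------------------------------------------
# skip-gram embedding model
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingModel:
    """A token → dense-vector table with a fixed dimension.

    Tokens are stored as strings; integer substructure identifiers are
    converted transparently. Tokens absent from the vocabulary embed as
    the zero vector, preserving the sum semantics of sentence embedding.
    """

    vocabulary: dict[str, np.ndarray]
    dim: int

    def __post_init__(self):
        for tok, vec in self.vocabulary.items():
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has wrong dimension")

    def vector(self, token) -> np.ndarray:
        return self.vocabulary.get(str(token), np.zeros(self.dim))

    def __contains__(self, token) -> bool:
        return str(token) in self.vocabulary

    # word2vec text dialect: "n_tokens dim" header then "token v1 ... vd"
    def save_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dim}\n")
            for tok, vec in self.vocabulary.items():
                fh.write(tok + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")

    @classmethod
    def load_text(cls, path) -> "EmbeddingModel":
        with open(path) as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            vocab = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab[parts[0]] = np.array([float(v) for v in parts[1:]])
        if len(vocab) != n:
            raise ValueError("token count does not match header")
        return cls(vocab, dim)


def train_skipgram(
    corpus: Iterable[Sequence],
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    min_count: int = 1,
    negative: int = 5,
    lr: float = 0.025,
) -> EmbeddingModel:
    """Train skip-gram embeddings with negative sampling on a corpus.

    Single-threaded and fully seeded, so two runs with the same corpus
    and seed produce identical models. Tokens occurring fewer than
    ``min_count`` times are excluded from the vocabulary.
    """
    if dim <= 0:
        raise ValueError("dim must be positive")
    sentences = [[str(t) for t in s] for s in corpus]
    if not sentences:
        raise ValueError("corpus is empty")

    counts: dict[str, int] = {}
    for s in sentences:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("no token reaches min_count")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    neg_p = freq / freq.sum()

    encoded = [[index[t] for t in s if t in index] for s in sentences]
    pairs: list[tuple[int, int]] = []
    for s in encoded:
        for i, center in enumerate(s):
            lo, hi = max(0, i - window), min(len(s), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, s[j]))
    if not pairs:
        # degenerate corpus of singleton sentences: keep the init vectors
        return EmbeddingModel({t: W_in[index[t]].copy() for t in vocab}, dim)

    pairs_arr = np.array(pairs)
    n_pairs = len(pairs_arr)
    total = epochs * n_pairs
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        negs = rng.choice(V, size=(n_pairs, negative), p=neg_p)
        for k, pidx in enumerate(order):
            center, context = pairs_arr[pidx]
            alpha = lr * max(1e-4, 1.0 - step / total)
            step += 1
            v = W_in[center]
            targets = np.concatenate(([context], negs[k]))
            labels = np.zeros(len(targets))
            labels[0] = 1.0
            u = W_out[targets]
            scores = 1.0 / (1.0 + np.exp(-np.clip(u @ v, -30, 30)))
            g = (scores - labels) * alpha
            W_in[center] = v - g @ u
            W_out[targets] -= np.outer(g, v)
    return EmbeddingModel({t: W_in[index[t]].copy() for t in vocab}, dim)


# ---------------------------------------------------------------------------
# embedding and combination
# ---------------------------------------------------------------------------

def embed_molecule(sentence: MoleculeSentence, model: EmbeddingModel) -> np.ndarray:
    """Sum of the identifier vectors of a molecule sentence."""
    vec = np.zeros(model.dim)
    for identifier in sentence.identifiers:
        vec += model.vector(identifier)
    return vec


def embed_protein(frames: NgramFrames, model: EmbeddingModel, mode: str = "sum") -> np.ndarray:
    """Embed three n-gram frames.

    Each frame embeds as the sum of its 3-gram vectors; ``mode='sum'``
    returns the elementwise sum of the three frame vectors (length
    ``dim``), ``mode='concat'`` their concatenation (length ``3·dim``).
    """
    frame_vecs = []
    for frame in frames.frames:
        v = np.zeros(model.dim)
        for gram in frame:
            v += model.vector(gram)
        frame_vecs.append(v)
    if mode == "sum":
        return frame_vecs[0] + frame_vecs[1] + frame_vecs[2]
    if mode == "concat":
        return np.concatenate(frame_vecs)
    raise ValueError(f"unknown mode {mode!r}")


def combine(compound_vec: np.ndarray, protein_vec: np.ndarray, scheme: str = "c2") -> np.ndarray:
    """Concatenate compound and protein embeddings under a scheme.

    c1: 100 ⊕ 100 → 200; c2: 300 ⊕ 300 → 600; c3: 300 ⊕ 300 (three
    concatenated 100-dim frames) → 600. Compound vector comes first.
    """
    expected = {"c1": (100, 100), "c2": (300, 300), "c3": (300, 300)}
    if scheme not in expected:
        raise ValueError(f"unknown combination scheme {scheme!r}")
    dc, dp = expected[scheme]
    if compound_vec.shape != (dc,) or protein_vec.shape != (dp,):
        raise ValueError(
            f"scheme {scheme} expects compound dim {dc} and protein dim {dp}, "
            f"got {compound_vec.shape} and {protein_vec.shape}"
        )
    return np.concatenate([compound_vec, protein_vec])


def assemble_pcm2vec(feature: np.ndarray, p_affinity: float) -> np.ndarray:
    """Append the affinity label to a feature vector (601-dim for c2)."""
    feature = np.asarray(feature, dtype=float)
    if not np.all(np.isfinite(feature)) or not math.isfinite(p_affinity):
        raise ValueError("feature vector and label must be finite")
    return np.concatenate([feature, [p_affinity]])


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by FASTA record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def protein_frame_mode(scheme: str) -> str:
    return "concat" if scheme == "c3" else "sum"


def featurize_table(
    std_table: pd.DataFrame,
    sequences: dict[str, str],
    mol_model: EmbeddingModel,
    prot_model: EmbeddingModel,
    scheme: str = "c2",
) -> PCMDataset:
    """Build a PCMDataset from a standardized activity table.

    ``std_table`` needs columns ``smiles, kinase_id, p_affinity``;
    ``sequences`` maps kinase ids to amino-acid sequences. Rows whose
    kinase has no sequence are dropped with a warning.
    """
    mode = protein_frame_mode(scheme)
    mol_cache: dict[str, np.ndarray] = {}
    prot_cache: dict[str, np.ndarray] = {}
    feats, labels, cids, kids = [], [], [], []
    for row in std_table.itertuples(index=False):
        kid = str(row.kinase_id)
        smi = str(row.smiles)
        if kid not in sequences:
            logger.warning("no sequence for kinase %s; row dropped", kid)
            continue
        if smi not in mol_cache:
            mol_cache[smi] = embed_molecule(mol_sentence(smi), mol_model)
        if kid not in prot_cache:
            prot_cache[kid] = embed_protein(prot_ngrams(sequences[kid]), prot_model, mode)
        feats.append(combine(mol_cache[smi], prot_cache[kid], scheme))
        labels.append(float(row.p_affinity))
        cids.append(smi)
        kids.append(kid)
    return PCMDataset(np.array(feats), np.array(labels), np.array(cids, dtype=object),
                      np.array(kids, dtype=object))
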