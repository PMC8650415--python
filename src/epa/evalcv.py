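"""Pair-input evaluation: four-level CV, strict-unseen filters, metrics.

Pair-input models look deceptively good when test pairs share a
compound or kinase with the training set, so validation is stratified
into four levels:

* CV1 — unknown pairs: a random 80/20 row split;
* CV2 — unknown kinases: train and test kinase sets are disjoint;
* CV3 — unknown compounds: train and test compound sets are disjoint;
* CV4 — both unknown: kinases *and* compounds disjoint.

Entity partitions are resampled until the train:test row ratio is close
to 4:1 and (optionally) the classes are near parity on both sides. The
"strict unseen" filters additionally remove test rows whose kinase
exceeds 25% global-alignment sequence identity, or whose compound
exceeds 0.8 Morgan-fingerprint Tanimoto similarity, to anything in
training.

Also here: the regression/classification metric suite, compound
selectivity profiling (selectivity score, subfamily odds ratio), the
Truchon–Bailey BEDROC early-recognition metric, the PCA→t-SNE space
projection, and the paired t-test used for method comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import (
    f1_score,
    mean_absolute_error,
    mean_squared_error,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .dataset import PCMDataset
from .standardize import DEFAULT_CUTOFF

CV_LEVELS = ("CV1", "CV2", "CV3", "CV4")
DEFAULT_RATIO_TOL = 0.02
DEFAULT_PARITY_TOL = 0.05
DEFAULT_BEDROC_ALPHA = 80.5


# ---------------------------------------------------------------------------
# four-level cross-validation splitting
# ---------------------------------------------------------------------------

@dataclass
class CVSplit:
    level: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    constraints_met: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.level not in CV_LEVELS:
            raise ValueError(f"unknown CV level {self.level!r}")
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")


def _parity_gap(labels: np.ndarray, cutoff: float) -> float:
    pos = int((labels >= cutoff).sum())
    neg = len(labels) - pos
    return abs(pos - neg) / max(1, pos + neg)


def _check(ds: PCMDataset, train_idx, test_idx, ratio_tol, parity_tol, cutoff):
    n_train, n_test = len(train_idx), len(test_idx)
    if n_train == 0 or n_test == 0:
        return None, np.inf
    ratio_gap = abs(n_train / (n_train + n_test) - 0.8)
    met = {"ratio": ratio_gap <= ratio_tol}
    score = ratio_gap
    if parity_tol is not None:
        gt = _parity_gap(ds.y[train_idx], cutoff)
        ge = _parity_gap(ds.y[test_idx], cutoff)
        met["parity_train"] = gt <= parity_tol
        met["parity_test"] = ge <= parity_tol
        score += max(0.0, gt - parity_tol) + max(0.0, ge - parity_tol)
    return met, score


def split_cv(
    dataset: PCMDataset,
    level: str,
    seed: int = 0,
    max_iter: int = 500,
    ratio_tol: float = DEFAULT_RATIO_TOL,
    parity_tol: float | None = DEFAULT_PARITY_TOL,
    cutoff: float = DEFAULT_CUTOFF,
) -> CVSplit:
    """Draw one CV split at the requested level.

    Candidate entity partitions are resampled up to ``max_iter`` times
    until the 4:1 row-ratio tolerance (and the class-parity tolerance,
    unless ``parity_tol`` is ``None``) is met; otherwise the failure is
    reported with the best ratios achieved. Entity-exclusion constraints
    (disjoint kinases for CV2, compounds for CV3, both for CV4) hold for
    every candidate by construction.
    """
    if level not in CV_LEVELS:
        raise ValueError(f"unknown CV level {level!r}")
    if dataset.n_pos(cutoff) == 0 or dataset.n_neg(cutoff) == 0:
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    kinases = np.unique(dataset.kinase_ids.astype(str))
    compounds = np.unique(dataset.compound_ids.astype(str))

    best = None
    best_score = np.inf
    for _ in range(max_iter):
        if level == "CV1":
            # stratified 80/20 row split
            train_parts, test_parts = [], []
            for mask in (dataset.y >= cutoff, dataset.y < cutoff):
                idx = rng.permutation(np.flatnonzero(mask))
                cut = int(round(0.8 * len(idx)))
                train_parts.append(idx[:cut])
                test_parts.append(idx[cut:])
            train_idx = np.sort(np.concatenate(train_parts))
            test_idx = np.sort(np.concatenate(test_parts))
        elif level in ("CV2", "CV3"):
            ids = dataset.kinase_ids if level == "CV2" else dataset.compound_ids
            pool = kinases if level == "CV2" else compounds
            side = rng.random(len(pool)) < 0.8
            train_ents = set(pool[side])
            in_train = np.array([e in train_ents for e in ids.astype(str)])
            train_idx = np.flatnonzero(in_train)
            test_idx = np.flatnonzero(~in_train)
        else:  # CV4: 2/3 of each entity axis on the training side
            kin_side = rng.random(len(kinases)) < 2 / 3
            cpd_side = rng.random(len(compounds)) < 2 / 3
            kin_train = set(kinases[kin_side])
            cpd_train = set(compounds[cpd_side])
            k_in = np.array([k in kin_train for k in dataset.kinase_ids.astype(str)])
            c_in = np.array([c in cpd_train for c in dataset.compound_ids.astype(str)])
            train_idx = np.flatnonzero(k_in & c_in)
            test_idx = np.flatnonzero(~k_in & ~c_in)

        met, score = _check(dataset, train_idx, test_idx, ratio_tol, parity_tol, cutoff)
        if met is None:
            continue
        if score < best_score:
            best_score = score
            best = (train_idx, test_idx, met)
        if all(met.values()):
            return CVSplit(level, train_idx, test_idx, met)

    detail = "" if best is None else f"; best constraint state {best[2]}"
    raise RuntimeError(
        f"{level} split constraints not satisfied in {max_iter} iterations{detail}"
    )


# ---------------------------------------------------------------------------
# strict-unseen filtering
# ---------------------------------------------------------------------------

_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1.0, mismatch_score=0.0,
    open_gap_score=-1.0, extend_gap_score=-0.5,
)


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches over alignment length."""
    if not a or not b:
        return 0.0
    aln = _ALIGNER.align(a, b)[0]
    return aln.counts().identities / aln.length


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def tanimoto_similarity(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto on radius-2 hashed Morgan fingerprints (2048 bits)."""
    fps = []
    for smi in (smiles_a, smiles_b):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smi!r}")
        fps.append(_FP_GEN.GetFingerprint(mol))
    return DataStructs.TanimotoSimilarity(fps[0], fps[1])


def strict_filter(
    split: CVSplit,
    dataset: PCMDataset,
    sequences: dict[str, str] | None = None,
    smiles: dict[str, str] | None = None,
    identity_max: float = 0.25,
    tanimoto_max: float = 0.8,
) -> CVSplit:
    """Drop test rows too similar to the training entities.

    CV2 removes test rows whose kinase has *more than* ``identity_max``
    sequence identity to any training kinase; CV3 likewise with
    *more than* ``tanimoto_max`` compound Tanimoto; CV4 applies both
    (thresholds are strict, so boundary values are retained). The
    training side is never touched.
    """
    if split.level not in ("CV2", "CV3", "CV4"):
        raise ValueError("strict filtering applies to CV2, CV3 and CV4 splits")
    keep = np.ones(len(split.test_idx), dtype=bool)

    if split.level in ("CV2", "CV4"):
        if sequences is None:
            raise ValueError("kinase sequences required for CV2/CV4 filtering")
        train_kin = np.unique(dataset.kinase_ids[split.train_idx].astype(str))
        test_kin = np.unique(dataset.kinase_ids[split.test_idx].astype(str))
        bad_kin = set()
        for tk in test_kin:
            for rk in train_kin:
                if sequence_identity(sequences[tk], sequences[rk]) > identity_max:
                    bad_kin.add(tk)
                    break
        keep &= np.array([k not in bad_kin
                          for k in dataset.kinase_ids[split.test_idx].astype(str)])

    if split.level in ("CV3", "CV4"):
        if smiles is None:
            raise ValueError("compound SMILES required for CV3/CV4 filtering")
        fps = {cid: _FP_GEN.GetFingerprint(Chem.MolFromSmiles(smi))
               for cid, smi in smiles.items()}
        train_cpd = np.unique(dataset.compound_ids[split.train_idx].astype(str))
        test_cpd = np.unique(dataset.compound_ids[split.test_idx].astype(str))
        bad_cpd = set()
        for tc in test_cpd:
            for rc in train_cpd:
                if DataStructs.TanimotoSimilarity(fps[tc], fps[rc]) > tanimoto_max:
                    bad_cpd.add(tc)
                    break
        keep &= np.array([c not in bad_cpd
                          for c in dataset.compound_ids[split.test_idx].astype(str)])

    test_idx = split.test_idx[keep]
    if len(test_idx) == 0:
        raise RuntimeError("strict filtering removed the entire test set")
    met = dict(split.constraints_met)
    met["strict_filtered"] = True
    return CVSplit(split.level, split.train_idx, test_idx, met)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    pcc: float | None = None
    mae: float | None = None
    mse: float | None = None
    rmse: float | None = None
    auc: float | None = None
    f1: float | None = None
    precision: float | None = None
    recall: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def regression_metrics(y_true, y_pred) -> MetricsReport:
    """PCC, MAE, MSE and RMSE between measured and predicted affinities."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) < 2:
        raise ValueError("need at least two points")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("PCC undefined for zero-variance input")
    pcc = float(stats.pearsonr(y_true, y_pred).statistic)
    mse = float(mean_squared_error(y_true, y_pred))
    return MetricsReport(
        pcc=pcc,
        mae=float(mean_absolute_error(y_true, y_pred)),
        mse=mse,
        rmse=float(np.sqrt(mse)),
    )


def classification_metrics(y_true, y_pred, cutoff: float = DEFAULT_CUTOFF) -> MetricsReport:
    """AUC/F1/precision/recall after thresholding affinities at the cutoff.

    True classes come from thresholding ``y_true``; AUC ranks by the
    continuous predictions (midrank ties), while F1/precision/recall
    threshold the predictions at the same cutoff.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cls_true = (y_true >= cutoff).astype(int)
    if cls_true.min() == cls_true.max():
        raise ValueError("both classes must be present in y_true")
    cls_pred = (y_pred >= cutoff).astype(int)
    return MetricsReport(
        auc=float(roc_auc_score(cls_true, y_pred)),
        f1=float(f1_score(cls_true, cls_pred, zero_division=0)),
        precision=float(precision_score(cls_true, cls_pred, zero_division=0)),
        recall=float(recall_score(cls_true, cls_pred, zero_division=0)),
    )


def all_metrics(y_true, y_pred, cutoff: float = DEFAULT_CUTOFF) -> MetricsReport:
    reg = regression_metrics(y_true, y_pred)
    cls = classification_metrics(y_true, y_pred, cutoff)
    return MetricsReport(**{**reg.as_dict(), **cls.as_dict()})


# ---------------------------------------------------------------------------
# kinase-profiling scores
# ---------------------------------------------------------------------------

@dataclass
class KinaseProfile:
    """Per-kinase affinities of one compound, optionally with subfamilies."""

    kinase_ids: np.ndarray
    p_affinities: np.ndarray
    subfamilies: np.ndarray | None = None

    def __post_init__(self):
        self.kinase_ids = np.asarray(self.kinase_ids, dtype=object)
        self.p_affinities = np.asarray(self.p_affinities, dtype=float)
        if len(np.unique(self.kinase_ids.astype(str))) != len(self.kinase_ids):
            raise ValueError("kinase ids must be unique within a profile")
        if self.p_affinities.shape != self.kinase_ids.shape:
            raise ValueError("affinity count must match kinase count")
        if self.subfamilies is not None:
            self.subfamilies = np.asarray(self.subfamilies, dtype=object)
            if self.subfamilies.shape != self.kinase_ids.shape:
                raise ValueError("subfamily count must match kinase count")


def selectivity_score(profile: KinaseProfile, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Hits (p-affinity ≥ cutoff) over kinases tested; lower = more selective."""
    if len(profile.kinase_ids) == 0:
        raise ValueError("empty profile")
    return float(np.mean(profile.p_affinities >= cutoff))


def odds_ratio(profile: KinaseProfile, subfamily, cutoff: float = DEFAULT_CUTOFF,
               correction: float = 0.5) -> float:
    """Odds ratio of hitting kinases inside vs outside one subfamily.

    Built from the 2×2 table {hit, non-hit} × {in subfamily, outside};
    any zero cell triggers the Haldane–Anscombe correction (adding
    ``correction`` to every cell).
    """
    if profile.subfamilies is None:
        raise ValueError("profile carries no subfamily labels")
    in_fam = profile.subfamilies.astype(str) == str(subfamily)
    if not in_fam.any():
        raise ValueError(f"subfamily {subfamily!r} absent from profile")
    hit = profile.p_affinities >= cutoff
    a = float((hit & in_fam).sum())      # hit, in subfamily
    b = float((hit & ~in_fam).sum())     # hit, outside
    c = float((~hit & in_fam).sum())     # non-hit, in subfamily
    d = float((~hit & ~in_fam).sum())    # non-hit, outside
    if min(a, b, c, d) == 0:
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# BEDROC
# ---------------------------------------------------------------------------

def bedroc(y_score, y_active, alpha: float = DEFAULT_BEDROC_ALPHA) -> float:
    """Truchon–Bailey BEDROC: exponentially weighted early recognition.

    Actives ranked uniformly at the top give values near 1, at the bottom
    near 0. ``alpha`` sets how sharply early ranks are weighted (80.5
    concentrates ~80% of the weight in the first ~2% of the list). Ties
    in ``y_score`` are broken by midrank averaging of the weights.
    """
    score = np.asarray(y_score, dtype=float)
    active = np.asarray(y_active, dtype=bool)
    if score.shape != active.shape:
        raise ValueError("score and activity vectors must have equal length")
    n = len(score)
    n_act = int(active.sum())
    if n_act == 0 or n_act == n:
        raise ValueError("need at least one active and one inactive")

    order = np.argsort(-score, kind="stable")
    ranked = active[order]
    weights = np.exp(-alpha * (np.arange(1, n + 1)) / n)
    # average weights across tied scores so ordering within a tie is moot
    sorted_scores = score[order]
    tie_start = 0
    w = weights.copy()
    for i in range(1, n + 1):
        if i == n or sorted_scores[i] != sorted_scores[tie_start]:
            if i - tie_start > 1:
                w[tie_start:i] = weights[tie_start:i].mean()
            tie_start = i
    s = float(w[ranked].sum())

    ra = n_act / n
    rie = (s / n_act) / ((1.0 / n) * (1.0 - np.exp(-alpha)) / (np.exp(alpha / n) - 1.0))
    return float(
        rie * ra * np.sinh(alpha / 2.0)
        / (np.cosh(alpha / 2.0) - np.cosh(alpha / 2.0 - alpha * ra))
        + 1.0 / (1.0 - np.exp(alpha * (1.0 - ra)))
    )


# ---------------------------------------------------------------------------
# projection and paired comparison
# ---------------------------------------------------------------------------

def project_space(features: np.ndarray, n_pcs: int = 50, tsne_params: dict | None = None,
                  seed: int = 0) -> np.ndarray:
    """PCA to ``n_pcs`` components, then Barnes–Hut t-SNE to 2-D."""
    import warnings

    X = np.asarray(features, dtype=float)
    n, d = X.shape
    cap = min(n, d)
    if n_pcs > cap:
        warnings.warn(f"n_pcs={n_pcs} exceeds min(n, d)={cap}; clipping", stacklevel=2)
        n_pcs = cap
    reduced = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    params = dict(tsne_params or {})
    params.setdefault("perplexity", min(30.0, max(2.0, (n - 1) / 3.0)))
    params.setdefault("init", "pca")
    tsne = TSNE(n_components=2, method="barnes_hut", random_state=seed, **params)
    return tsne.fit_transform(reduced)


@dataclass(frozen=True)
class PairedComparison:
    p_value: float
    mean_diff: float  # mean(b − a); positive favors b
    favors: str  # 'a', 'b' or 'neither'
    degenerate: bool  # True when the differences have zero variance


def paired_comparison(metric_runs_a, metric_runs_b) -> PairedComparison:
    """Two-sided paired t-test between matched metric runs.

    ``mean_diff > 0`` means method *b* scored higher on average. A
    zero-variance difference vector (e.g. a constant shift) makes the
    t statistic degenerate; the result is flagged and the p-value set to
    0 for a nonzero shift and 1 for identical runs.
    """
    a = np.asarray(metric_runs_a, dtype=float)
    b = np.asarray(metric_runs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("runs must be equal-length 1-D vectors")
    if len(a) < 2:
        raise ValueError("need at least two paired runs")
    diff = b - a
    mean_diff = float(diff.mean())
    favors = "b" if mean_diff > 0 else ("a" if mean_diff < 0 else "neither")
    if np.std(diff) <= 1e-12 * (1.0 + abs(mean_diff)):
        return PairedComparison(0.0 if mean_diff != 0 else 1.0, mean_diff, favors, True)
    res = stats.ttest_rel(b, a)
    return PairedComparison(float(res.pvalue), mean_diff, favors, False)
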