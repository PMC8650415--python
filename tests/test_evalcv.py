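import numpy as np
import pytest
from scipy import stats

from epa import (
    KinaseProfile,
    bedroc,
    classification_metrics,
    make_toy_corpora,
    odds_ratio,
    paired_comparison,
    project_space,
    regression_metrics,
    selectivity_score,
    sequence_identity,
    split_cv,
    strict_filter,
    tanimoto_similarity,
)
from epa.evalcv import CVSplit


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

class TestSplitCV:
    def test_cv1_test_fraction(self, pcm_balanced):
        ds, _ = pcm_balanced
        split = split_cv(ds, "CV1", seed=1)
        frac = len(split.test_idx) / len(ds)
        assert abs(frac - 0.2) <= 0.02
        assert np.intersect1d(split.train_idx, split.test_idx).size == 0

    def test_cv2_kinases_disjoint(self, pcm_balanced):
        ds, _ = pcm_balanced
        split = split_cv(ds, "CV2", seed=3)
        train_k = set(ds.kinase_ids[split.train_idx])
        test_k = set(ds.kinase_ids[split.test_idx])
        assert not train_k & test_k

    def test_cv3_compounds_disjoint(self, pcm_balanced):
        ds, _ = pcm_balanced
        split = split_cv(ds, "CV3", seed=3)
        assert not (set(ds.compound_ids[split.train_idx])
                    & set(ds.compound_ids[split.test_idx]))

    def test_cv4_both_disjoint(self, pcm_balanced):
        ds, _ = pcm_balanced
        split = split_cv(ds, "CV4", seed=4)
        assert not (set(ds.kinase_ids[split.train_idx])
                    & set(ds.kinase_ids[split.test_idx]))
        assert not (set(ds.compound_ids[split.train_idx])
                    & set(ds.compound_ids[split.test_idx]))

    def test_ratio_constraint_met(self, pcm_balanced):
        ds, _ = pcm_balanced
        for level in ("CV2", "CV3", "CV4"):
            split = split_cv(ds, level, seed=2)
            n_tr, n_te = len(split.train_idx), len(split.test_idx)
            assert abs(n_tr / (n_tr + n_te) - 0.8) <= 0.02

    def test_unsatisfiable_parity_reports_failure(self, pcm_imbalanced_small):
        ds, _ = pcm_imbalanced_small  # 1:4 — parity can never be met
        with pytest.raises(RuntimeError, match="constraints"):
            split_cv(ds, "CV1", seed=0, max_iter=20)

    def test_unknown_level_rejected(self, pcm_balanced):
        ds, _ = pcm_balanced
        with pytest.raises(ValueError):
            split_cv(ds, "CV5")


class TestStrictFilter:
    @pytest.fixture(scope="class")
    def entity_data(self):
        from epa import PCMDataset

        # 6 kinases: K0..K2 train-side, K3..K5 test-side; K3 shares K0's
        # sequence (identity 1.0) and must be filtered out at CV2.
        rng = np.random.default_rng(0)
        _, prots = make_toy_corpora(n_molecules=1, n_proteins=6, seed=1,
                                    min_len=60, max_len=90)
        seqs = {f"K{i}": prots[i][1] for i in range(6)}
        seqs["K3"] = seqs["K0"]
        smiles = {"C0": "CCO", "C1": "c1ccccc1O", "C2": "CCCC",
                  "C3": "CCO", "C4": "c1ccncc1", "C5": "CC(=O)O"}
        n = 40
        kin = np.array([f"K{i % 6}" for i in range(n)], dtype=object)
        cpd = np.array([f"C{i % 6}" for i in range(n)], dtype=object)
        ds = PCMDataset(rng.normal(size=(n, 5)), rng.uniform(4, 9, n), cpd, kin)
        train_rows = np.flatnonzero(np.isin(kin, ["K0", "K1", "K2"])
                                    & np.isin(cpd, ["C0", "C1", "C2"]))
        test_rows = np.flatnonzero(np.isin(kin, ["K3", "K4", "K5"])
                                   & np.isin(cpd, ["C3", "C4", "C5"]))
        return ds, seqs, smiles, train_rows, test_rows

    def test_identical_sequence_removed_at_cv2(self, entity_data):
        ds, seqs, _, train_rows, test_rows = entity_data
        split = CVSplit("CV2", train_rows, test_rows)
        out = strict_filter(split, ds, sequences=seqs)
        kept_kin = set(ds.kinase_ids[out.test_idx])
        assert "K3" not in kept_kin

    def test_filter_matches_bruteforce_pairwise_oracle(self, entity_data):
        ds, seqs, smiles, train_rows, test_rows = entity_data
        split = CVSplit("CV4", train_rows, test_rows)
        out = strict_filter(split, ds, sequences=seqs, smiles=smiles)

        train_kin = set(ds.kinase_ids[train_rows])
        train_cpd = set(ds.compound_ids[train_rows])
        expected = []
        for idx in test_rows:
            k, c = ds.kinase_ids[idx], ds.compound_ids[idx]
            k_bad = any(sequence_identity(seqs[k], seqs[tk]) > 0.25
                        for tk in train_kin)
            c_bad = any(tanimoto_similarity(smiles[c], smiles[tc]) > 0.8
                        for tc in train_cpd)
            if not k_bad and not c_bad:
                expected.append(idx)
        np.testing.assert_array_equal(np.sort(out.test_idx), np.sort(expected))

    def test_boundary_similarity_retained(self, entity_data):
        # thresholds are strict: a compound exactly at the threshold stays
        ds, seqs, smiles, train_rows, test_rows = entity_data
        split = CVSplit("CV3", train_rows, test_rows)
        sims = [tanimoto_similarity(smiles[c], smiles[tc])
                for c in ("C4", "C5") for tc in ("C0", "C1", "C2")]
        threshold = max(sims)  # choose the max observed similarity as cutoff
        out = strict_filter(split, ds, smiles=smiles, tanimoto_max=threshold)
        kept_cpd = set(ds.compound_ids[out.test_idx])
        assert {"C4", "C5"} <= kept_cpd  # at-threshold values survive
        assert "C3" not in kept_cpd      # identical compound (1.0) does not

    def test_train_side_untouched_and_subset(self, entity_data):
        ds, seqs, smiles, train_rows, test_rows = entity_data
        split = CVSplit("CV4", train_rows, test_rows)
        out = strict_filter(split, ds, sequences=seqs, smiles=smiles)
        np.testing.assert_array_equal(out.train_idx, train_rows)
        assert set(out.test_idx) <= set(test_rows)

    def test_cv1_rejected(self, entity_data):
        ds, seqs, _, train_rows, test_rows = entity_data
        with pytest.raises(ValueError):
            strict_filter(CVSplit("CV1", train_rows, test_rows), ds, sequences=seqs)


# ---------------------------------------------------------------------------
# metric oracles
# ---------------------------------------------------------------------------

def _brute_pcc(a, b):
    a, b = np.asarray(a), np.asarray(b)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


def _brute_auc(y_cls, score):
    pos = score[y_cls == 1]
    neg = score[y_cls == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


class TestRegressionMetrics:
    def test_identity_prediction(self):
        y = np.array([5.0, 6.0, 7.0, 9.0])
        rep = regression_metrics(y, y)
        assert rep.pcc == pytest.approx(1.0)
        assert rep.mae == 0.0 and rep.mse == 0.0

    def test_constant_shift(self):
        y = np.array([5.0, 6.0, 7.0, 9.0])
        rep = regression_metrics(y, y + 0.5)
        assert rep.mae == pytest.approx(0.5)
        assert rep.pcc == pytest.approx(1.0)

    def test_matches_bruteforce_formulas(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y, p = rng.normal(7, 2, 20), rng.normal(7, 2, 20)
            rep = regression_metrics(y, p)
            assert rep.pcc == pytest.approx(_brute_pcc(y, p), abs=1e-12)
            assert rep.mae == pytest.approx(np.abs(y - p).mean(), abs=1e-12)
            assert rep.mse == pytest.approx(((y - p) ** 2).mean(), abs=1e-12)
            assert rep.rmse == pytest.approx(np.sqrt(rep.mse), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            regression_metrics([7.0, 7.0, 7.0], [6.0, 7.0, 8.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([1.0, 2.0], [1.0])


class TestClassificationMetrics:
    def test_perfect_separation(self):
        y = np.array([4.0, 5.0, 8.0, 9.0])
        p = np.array([4.1, 4.9, 8.3, 9.1])
        rep = classification_metrics(y, p)
        assert rep.auc == 1.0 and rep.f1 == 1.0

    def test_constant_prediction_auc_half(self):
        y = np.array([4.0, 5.0, 8.0, 9.0])
        rep = classification_metrics(y, np.full(4, 5.0))
        assert rep.auc == pytest.approx(0.5)

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = rng.uniform(3, 10, 20)
            p = rng.uniform(3, 10, 20)
            if (y >= 6).all() or (y < 6).all():
                continue
            rep = classification_metrics(y, p)
            cls_t, cls_p = (y >= 6).astype(int), (p >= 6).astype(int)
            tp = int(((cls_t == 1) & (cls_p == 1)).sum())
            fp = int(((cls_t == 0) & (cls_p == 1)).sum())
            fn = int(((cls_t == 1) & (cls_p == 0)).sum())
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert rep.precision == pytest.approx(prec, abs=1e-12)
            assert rep.recall == pytest.approx(rec, abs=1e-12)
            assert rep.f1 == pytest.approx(f1, abs=1e-12)
            assert rep.auc == pytest.approx(_brute_auc(cls_t, p), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([7.0, 8.0], [7.0, 8.0])


class TestProfiling:
    def test_selectivity_ratio(self):
        prof = KinaseProfile([f"K{i}" for i in range(10)],
                             [7.0] * 3 + [4.0] * 7)
        assert selectivity_score(prof) == pytest.approx(0.3)

    def test_selectivity_extremes(self):
        none = KinaseProfile(["K1", "K2"], [4.0, 5.0])
        full = KinaseProfile(["K1", "K2"], [8.0, 9.0])
        assert selectivity_score(none) == 0.0
        assert selectivity_score(full) == 1.0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            selectivity_score(KinaseProfile([], []))

    def test_odds_ratio_direct_formula(self):
        # table (hit∩fam, hit∩out, miss∩fam, miss∩out) = (4,1,2,8) → 16
        fams = ["A"] * 6 + ["B"] * 9
        affs = [7.0] * 4 + [4.0] * 2 + [7.0] * 1 + [4.0] * 8
        prof = KinaseProfile([f"K{i}" for i in range(15)], affs, fams)
        assert odds_ratio(prof, "A") == pytest.approx(16.0)

    def test_odds_ratio_independence_gives_one(self):
        # hits proportional inside/outside the family: 2/4 vs 3/6
        fams = ["A"] * 4 + ["B"] * 6
        affs = [8.0, 8.0, 4.0, 4.0] + [8.0] * 3 + [4.0] * 3
        prof = KinaseProfile([f"K{i}" for i in range(10)], affs, fams)
        assert odds_ratio(prof, "A") == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        # all family members hit: a=2, b=1, c=0, d=3 → corrected table
        fams = ["A", "A", "B", "B", "B", "B"]
        affs = [8.0, 8.0, 8.0, 4.0, 4.0, 4.0]
        prof = KinaseProfile([f"K{i}" for i in range(6)], affs, fams)
        expected = (2.5 * 3.5) / (1.5 * 0.5)
        assert odds_ratio(prof, "A") == pytest.approx(expected)

    def test_absent_subfamily_rejected(self):
        prof = KinaseProfile(["K1"], [7.0], ["A"])
        with pytest.raises(ValueError):
            odds_ratio(prof, "Z")


class TestBedroc:
    def test_perfect_early_recognition(self):
        score = -np.arange(1000, dtype=float)
        active = np.zeros(1000, bool)
        active[:10] = True
        assert bedroc(score, active) == pytest.approx(1.0, abs=1e-3)

    def test_worst_case(self):
        score = -np.arange(1000, dtype=float)
        active = np.zeros(1000, bool)
        active[-10:] = True
        assert bedroc(score, active) == pytest.approx(0.0, abs=1e-3)

    def test_matches_independent_implementation(self):
        from rdkit.ML.Scoring import Scoring

        rng = np.random.default_rng(9)
        for _ in range(10):
            score = rng.normal(size=200)
            active = rng.random(200) < 0.1
            if active.sum() in (0, 200):
                continue
            order = np.argsort(-score)
            ranked = [[score[i], int(active[i])] for i in order]
            expected = Scoring.CalcBEDROC(ranked, 1, 80.5)
            assert bedroc(score, active) == pytest.approx(expected, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bedroc([1.0, 2.0], [True, True])

    def test_value_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            score = rng.normal(size=50)
            active = rng.random(50) < 0.2
            if active.sum() in (0, 50):
                continue
            assert 0.0 <= bedroc(score, active) <= 1.0


class TestProjection:
    def test_output_shape(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 60))
        coords = project_space(X, n_pcs=20, seed=1)
        assert coords.shape == (120, 2)

    def test_npcs_clipped_with_warning(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 10))
        with pytest.warns(UserWarning, match="clipping"):
            coords = project_space(X, n_pcs=50, seed=1)
        assert coords.shape == (30, 2)

    def test_separated_clusters_stay_separable(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.3, size=(60, 40))
        b = rng.normal(0, 0.3, size=(60, 40)) + 6.0
        coords = project_space(np.vstack([a, b]), n_pcs=10, seed=3)
        labels = np.array([0] * 60 + [1] * 60)
        cents = np.array([coords[labels == i].mean(0) for i in (0, 1)])
        assign = np.argmin(
            np.linalg.norm(coords[:, None, :] - cents[None], axis=2), axis=1)
        assert (assign == labels).mean() > 0.9

    def test_duplicated_row_lands_nearby(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 20))
        X[-1] = X[0]
        coords = project_space(X, n_pcs=10, seed=5)
        d_dup = np.linalg.norm(coords[0] - coords[-1])
        spread = np.linalg.norm(coords - coords.mean(0), axis=1).mean()
        assert d_dup < 0.25 * spread


class TestPairedComparison:
    def test_identical_runs(self):
        res = paired_comparison([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.mean_diff == 0.0 and res.degenerate

    def test_constant_shift_flags_degenerate(self):
        a = np.linspace(0.1, 0.9, 20)
        res = paired_comparison(a, a + 1.0)
        assert res.favors == "b" and res.degenerate
        assert res.p_value == 0.0

    def test_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.6, 0.1, 15)
        b = a + rng.normal(0.05, 0.05, 15)
        res = paired_comparison(a, b)
        d = b - a
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.favors == ("b" if d.mean() > 0 else "a")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0], [2.0])
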