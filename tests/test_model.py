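"""Feature ranking, subject-wise folds and the SVM evaluation protocol."""

import numpy as np
import pandas as pd
import pytest

import pcgfusion as pf
from pcgfusion.model import confusion_metrics


def make_table(n_subjects=30, segments=4, n_features=10, informative=2,
               effect=2.0, seed=0, p_cad=0.5):
    """Random feature table with known informative columns (subject-level
    effect plus segment-level noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        label = "CAD" if (s < int(n_subjects * p_cad)) else "non-CAD"
        shift = effect if label == "CAD" else 0.0
        base = rng.standard_normal(n_features)
        for k in range(segments):
            feats = base + rng.standard_normal(n_features)
            feats[:informative] += shift
            row = {"subject_id": f"s{s:02d}", "label": label,
                   "segment_index": k}
            row.update({f"f{i}": feats[i] for i in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestInformationGain:
    def test_perfect_predictor_one_bit(self):
        y = np.array([0, 1] * 50)
        assert pf.information_gain(y.astype(float), y) == pytest.approx(1.0)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(10_000)
        y = rng.integers(0, 2, 10_000)
        assert pf.information_gain(x, y) < 0.01

    def test_four_row_toy_table_closed_form(self):
        # x = [1, 2, 3, 4], y = [0, 0, 1, 1], 2 equal-frequency bins:
        # both bins pure -> IG = H(y) = 1 bit
        ig = pf.information_gain([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1], n_bins=2)
        assert ig == pytest.approx(1.0)
        # interleaved labels: each bin stays 50/50 -> IG = 0
        ig0 = pf.information_gain([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1], n_bins=2)
        assert ig0 == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_label_entropy(self, rng):
        for _ in range(20):
            x = rng.standard_normal(200)
            y = rng.integers(0, 2, 200)
            ig = pf.information_gain(x, y)
            p = y.mean()
            h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
            assert -1e-12 <= ig <= h + 1e-12

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pf.information_gain(np.arange(10.0), np.zeros(10, dtype=int))


class TestSvmRfe:
    def test_informative_features_ranked_top(self):
        rng = np.random.default_rng(2)
        n = 200
        y = np.array([0] * 100 + [1] * 100)
        x = rng.standard_normal((n, 20))
        x[:, 3] += 1.5 * y
        x[:, 11] -= 1.5 * y
        x = (x - x.mean(0)) / x.std(0)
        ranking = pf.svm_rfe(pd.DataFrame(x, columns=[f"f{i}" for i in range(20)]),
                             y, elimination_step=2)
        assert {"f3", "f11"} <= set(ranking.top(4))

    def test_step_equal_to_total_is_single_fit_order(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 40 + [1] * 40)
        x = rng.standard_normal((80, 6))
        x[:, 0] += 2.0 * y
        ranking = pf.svm_rfe(x, y, elimination_step=6)
        assert ranking.features[0] == "f0"
        assert sorted(ranking.features) == [f"f{i}" for i in range(6)]

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60)
        x = rng.standard_normal((60, 8))
        a = pf.svm_rfe(x, y, 2)
        b = pf.svm_rfe(x, y, 2)
        assert a.features == b.features

    def test_ranking_is_permutation(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 50)
        x = rng.standard_normal((50, 7))
        ranking = pf.svm_rfe(x, y, 3)
        assert sorted(ranking.features) == [f"f{i}" for i in range(7)]


class TestSubjectKfold:
    def test_cohort_21_15_balanced_folds(self):
        subjects = np.repeat([f"s{i}" for i in range(36)], 4)
        labels = np.repeat(["CAD"] * 21 + ["non-CAD"] * 15, 4)
        folds = pf.subject_kfold(subjects, labels, k=5, seed=1)
        seen = []
        for train, test in folds:
            assert train.isdisjoint(test)
            cad = sum(s.startswith("s") and int(s[1:]) < 21 for s in test)
            non = len(test) - cad
            assert cad in (4, 5) and non == 3
            seen.extend(test)
        assert sorted(seen) == sorted(set(seen))  # no subject in two folds
        assert len(seen) == 36

    def test_k1_rejected(self):
        with pytest.raises(ValueError, match="k must be >= 2"):
            pf.subject_kfold(["a", "b"], ["CAD", "non-CAD"], k=1)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="subjects per class"):
            pf.subject_kfold(["a", "b", "c", "d"],
                             ["CAD", "CAD", "CAD", "non-CAD"], k=2)


class TestConfusionMetrics:
    def test_printed_example(self):
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [1] * 2 + [0] * 8
        m = confusion_metrics(y_true, y_pred)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (9, 1, 8, 2)
        assert m["se"] == pytest.approx(90.0)
        assert m["sp"] == pytest.approx(80.0)
        assert m["acc"] == pytest.approx(85.0)

    def test_accuracy_between_se_and_sp_weighted(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            p = rng.integers(0, 2, 50)
            if len(np.unique(y)) < 2:
                continue
            m = confusion_metrics(y, p)
            n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
            blended = (m["se"] * n_pos + m["sp"] * n_neg) / 50
            assert m["acc"] == pytest.approx(blended, abs=1e-9)


def _generic_model(table, **kw):
    from pcgfusion.model import POWER_GRID
    kw.setdefault("feature_set", None)
    kw.setdefault("c_grid", POWER_GRID[::2])
    kw.setdefault("gamma_grid", POWER_GRID[::2])
    kw.setdefault("inner_k", 3)
    return pf.SubjectwiseSVM(table, **kw)


class TestSubjectwiseSVM:
    def test_separable_cohort_perfect_accuracy(self):
        table = make_table(effect=10.0, informative=5, seed=1)
        res = _generic_model(table).fit(n_features=5, k=5, seed=0)
        assert res.accuracy == pytest.approx(100.0)

    def test_no_leakage_under_test_label_shuffle(self):
        # permuting the labels of held-out subjects must not change the
        # ranking computed on the training fold
        table = make_table(effect=2.0, seed=2)
        model = _generic_model(table)
        folds = pf.subject_kfold(model.subjects, model.y, k=5, seed=0)
        res = model.fit(n_features=4, k=5, seed=0, folds=folds)
        shuffled = table.copy()
        test0 = sorted(folds[0][1])
        mask = shuffled.subject_id.isin(test0)
        flipped = shuffled.loc[mask, "label"].map(
            {"CAD": "non-CAD", "non-CAD": "CAD"})
        shuffled.loc[mask, "label"] = flipped
        res2 = _generic_model(shuffled).fit(n_features=4, k=5, seed=0,
                                            folds=folds)
        assert (res.fold_details[0]["ranking"].features
                == res2.fold_details[0]["ranking"].features)
        assert (res.fold_details[0]["selected"]
                == res2.fold_details[0]["selected"])

    def test_summary_mentions_protocol(self):
        table = make_table(effect=4.0, seed=3)
        res = _generic_model(table).fit(n_features=4, k=5, seed=0)
        text = res.summary()
        assert "subject-wise" in text
        assert "Acc" in text and "Se" in text and "Sp" in text

    def test_sweep_truncates_to_full_set(self):
        table = make_table(effect=4.0, seed=4, n_features=5)
        df = _generic_model(table).sweep(step=3, k=3, seed=0)
        assert df["n_features"].tolist() == [3, 5]
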