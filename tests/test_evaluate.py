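import numpy as np
import pandas as pd
import pytest

from aimpanel.classify import UNASSIGNED, AssignmentConfig, assign
from aimpanel.errors import ParameterError, ValidationError
from aimpanel.evaluate import (accuracy_report, call_rate, collapse_to_lineage,
                               confusion, embed_2d, flag_label_outliers,
                               threshold_sweep)
from aimpanel.io_formats import MISSING, GenotypeMatrix, SampleLabel, SnpKey


class TestConfusion:
    def test_perfect_predictions_identity_percentages(self):
        cm = confusion(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        pct = cm.row_percentages()
        assert pct.loc["a", "a"] == 100.0 and pct.loc["b", "b"] == 100.0
        assert pct.loc["a", "b"] == 0.0

    def test_simple_misclassification_row(self):
        truth = ["a"] * 10
        pred = ["a"] * 9 + ["b"]
        cm = confusion(truth, pred, ["a", "b"])
        pct = cm.row_percentages()
        assert pct.loc["a", "a"] == 90.0 and pct.loc["a", "b"] == 10.0

    def test_unassigned_excluded_from_percentages(self):
        truth = ["a"] * 10
        pred = ["a"] * 8 + ["b", UNASSIGNED]
        cm = confusion(truth, pred, ["a", "b"])
        pct = cm.row_percentages()
        assert pct.loc["a", "a"] == pytest.approx(88.9)
        assert pct.loc["a", "b"] == pytest.approx(11.1)
        assert cm.unassigned["a"] == 1

    def test_count_conservation_per_class_and_overall(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        truth = rng.choice(classes, size=200).tolist()
        pred = [t if rng.random() < 0.7 else
                (UNASSIGNED if rng.random() < 0.5 else rng.choice(classes))
                for t in truth]
        cm = confusion(truth, pred, classes)
        for cls in classes:
            n_true = truth.count(cls)
            assert cm.counts.loc[cls].sum() + cm.unassigned[cls] == n_true
        assert cm.total == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion(["a"], ["a", "b"], ["a", "b"])


class TestAccuracyReport:
    def test_identity_matrix_is_perfect(self):
        cm = confusion(["a", "b"], ["a", "b"], ["a", "b"])
        rep = accuracy_report(cm)
        assert rep["overall_accuracy_pct"] == 100.0
        assert rep["misclassified_pct"] == 0.0

    def test_misclassified_fraction_of_total(self):
        # 95 of 2505 misclassified -> 3.8%
        truth = ["a"] * 2505
        pred = ["a"] * 2410 + ["b"] * 95
        rep = accuracy_report(confusion(truth, pred, ["a", "b"]))
        assert rep["misclassified_pct"] == pytest.approx(3.8, abs=0.01)

    def test_assigned_denominator_with_threshold(self):
        # counts ((8,1),(0,9)) with 1 unassigned in class a -> 17/18 correct
        truth = ["a"] * 10 + ["b"] * 9
        pred = ["a"] * 8 + ["b", UNASSIGNED] + ["b"] * 9
        rep = accuracy_report(confusion(truth, pred, ["a", "b"]))
        assert rep["denominator"] == "assigned"
        assert rep["overall_accuracy_pct"] == pytest.approx(100 * 17 / 18, abs=1e-9)
        assert rep["n_unassigned"] == 1

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            accuracy_report(confusion([], [], ["a"]))


class TestCollapseToLineage:
    MAP = {"carnica": "C", "cecropia": "C", "macedonica": "C", "mellifera": "M"}

    def test_simple_mapping(self):
        assert collapse_to_lineage(["carnica"], self.MAP) == ["C"]

    def test_within_lineage_confusion_becomes_correct(self):
        truth = ["cecropia"]
        pred = ["macedonica"]
        assert collapse_to_lineage(pred, self.MAP) == collapse_to_lineage(truth, self.MAP)

    def test_unassigned_preserved_and_unknown_rejected(self):
        assert collapse_to_lineage([UNASSIGNED], self.MAP) == [UNASSIGNED]
        with pytest.raises(ValidationError):
            collapse_to_lineage(["iberiensis"], self.MAP)

    def test_lineage_accuracy_dominates_subspecies_accuracy(self, classified_sim):
        sim = classified_sim
        calls = assign(sim["probs"], AssignmentConfig(0.0))
        y = sim["y_test"]
        s2l = sim["config"].subspecies_to_lineage
        sub_acc = float(np.mean(calls.values == y.values))
        lin_acc = float(np.mean(
            np.array(collapse_to_lineage(calls.tolist(), s2l))
            == np.array([s2l[v] for v in y])
        ))
        assert lin_acc >= sub_acc


class TestThresholdSweep:
    def probs(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.ones(3) * 0.5, size=n)
        p = pd.DataFrame(raw, columns=["a", "b", "c"])
        truth = [p.columns[i] if rng.random() < 0.8 else "a"
                 for i in p.to_numpy().argmax(axis=1)]
        return p, truth

    def test_zero_threshold_assigns_everything(self):
        p, truth = self.probs()
        row = threshold_sweep(p, truth, [0.0]).iloc[0]
        assert row["assigned_fraction"] == 1.0

    def test_above_one_threshold_keeps_only_certainty(self):
        p, truth = self.probs()
        row = threshold_sweep(p, truth, [1.0 + 1e-9]).iloc[0]
        assert row["n_assigned"] == int((p.max(axis=1) >= 1.0 + 1e-9).sum())

    def test_conservation_and_monotonicity(self):
        p, truth = self.probs(3)
        taus = np.linspace(0, 1, 21)
        sweep = threshold_sweep(p, truth, taus)
        assert (sweep["n_assigned"] + sweep["n_unassigned"] == len(truth)).all()
        assert (np.diff(sweep["n_unassigned"]) >= 0).all()
        miscls_count = (sweep["n_assigned"]
                        * sweep["misclassified_assigned_pct"].fillna(0) / 100)
        assert (np.diff(np.round(miscls_count, 9)) <= 1e-9).all()


class TestCallRate:
    def gm(self, g, labels=None):
        g = np.asarray(g, dtype=np.int8)
        snps = [SnpKey("chr1", j + 1, "A", "C") for j in range(g.shape[1])]
        return GenotypeMatrix([f"s{i}" for i in range(g.shape[0])], snps, g, labels)

    def test_no_missing_is_one(self):
        per_sample, _ = call_rate(self.gm([[0, 1, 2, 1]]))
        assert per_sample.iloc[0] == 1.0

    def test_one_missing_of_four(self):
        per_sample, _ = call_rate(self.gm([[0, 1, MISSING, 2]]))
        assert per_sample.iloc[0] == 0.75

    def test_class_mean_tracks_null_rate(self, small_sim):
        _, data = small_sim
        _, per_class = call_rate(data.genotypes)
        # simulated with a 5% subspecies-wide null-allele rate
        assert per_class.between(0.90, 1.0).all()
        assert per_class.mean() == pytest.approx(0.95, abs=0.02)


class TestEmbed2d:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 8))
        np.testing.assert_array_equal(embed_2d(X, seed=1, perplexity=5),
                                      embed_2d(X, seed=1, perplexity=5))

    def test_separated_classes_stay_separated(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.2, (20, 10)),
                       rng.normal(8, 0.2, (20, 10))])
        Y = embed_2d(X, seed=0, perplexity=5)
        c1, c2 = Y[:20].mean(axis=0), Y[20:].mean(axis=0)
        spread = np.linalg.norm(Y[:20] - c1, axis=1).mean()
        assert np.linalg.norm(c1 - c2) > spread

    def test_perplexity_constraint(self):
        with pytest.raises(ParameterError):
            embed_2d(np.zeros((5, 3)), seed=0, perplexity=10)
        with pytest.raises(ParameterError):
            embed_2d(np.zeros((2, 3)), seed=0, perplexity=1)


class TestFlagLabelOutliers:
    def labelled_gm(self, seed=0, mislabel=None):
        rng = np.random.default_rng(seed)
        a = rng.choice([0, 1], p=[0.9, 0.1], size=(15, 60)).astype(np.int8)
        b = rng.choice([2, 1], p=[0.9, 0.1], size=(15, 60)).astype(np.int8)
        g = np.vstack([a, b])
        samples = [f"s{i}" for i in range(30)]
        labels = {}
        for i, s in enumerate(samples):
            cls = "alpha" if i < 15 else "beta"
            if mislabel is not None and i == mislabel:
                cls = "beta" if cls == "alpha" else "alpha"
            labels[s] = cls
        snps = [SnpKey("chr1", j + 1, "A", "C") for j in range(60)]
        return GenotypeMatrix(samples, snps, g), labels

    def test_clean_labels_not_flagged(self):
        gm, labels = self.labelled_gm()
        assert flag_label_outliers(gm, labels, k=5) == []

    def test_planted_mislabel_flagged_exactly(self):
        gm, labels = self.labelled_gm(mislabel=3)
        assert flag_label_outliers(gm, labels, k=5) == ["s3"]

    def test_k1_uses_nearest_other_sample(self):
        gm, labels = self.labelled_gm(mislabel=7)
        assert "s7" in flag_label_outliers(gm, labels, k=1)

    def test_k_must_be_smaller_than_n(self):
        gm, labels = self.labelled_gm()
        with pytest.raises(ParameterError):
            flag_label_outliers(gm, labels, k=30)
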