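import itertools

import numpy as np
import pandas as pd
import pytest

from odepkit.learning import (
    CohortDataset,
    auc_binary,
    auc_multiclass,
    balanced_accuracy,
    filter_features,
    fit_lda,
    ks_compare,
    lopo_evaluate,
    majority_vote_curve,
    sfs_select,
)


def auc_pair_count(pos, neg):
    """Brute-force AUC over all (positive, negative) pairs; ties count 0.5."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aucm_enumeration(values, labels):
    """Exhaustive multiclass AUC over all class pairs and one-vs-rest splits."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    best = 0.5
    for ci, cj in itertools.combinations(classes, 2):
        a = auc_pair_count(values[labels == ci], values[labels == cj])
        best = max(best, a, 1 - a)
    for ci in classes:
        a = auc_pair_count(values[labels == ci], values[labels != ci])
        best = max(best, a, 1 - a)
    return best


def make_dataset(seed=0, n_patients=3, cells=6, n_noise=8, separation=3.0):
    """Three-class feature table: one informative feature plus pure noise."""
    rng = np.random.default_rng(seed)
    classes = ["CTRL", "RIF", "uRPL"]
    rows, labels, patients, videos = [], [], [], []
    for k, cls in enumerate(classes):
        for p in range(n_patients):
            offset = rng.normal(0, 0.3)
            for c in range(cells):
                good = k * separation + offset + rng.normal()
                noise = rng.standard_normal(n_noise)
                rows.append(np.concatenate([[good], noise]))
                labels.append(cls)
                patients.append(f"{cls}_P{p}")
                videos.append(f"{cls}_P{p}_V{c // 3}")
    names = ["good"] + [f"noise{i}" for i in range(n_noise)]
    idx = [f"cell{i}" for i in range(len(rows))]
    return CohortDataset(
        features=pd.DataFrame(rows, columns=names, index=idx),
        labels=pd.Series(labels, index=idx),
        patients=pd.Series(patients, index=idx),
        videos=pd.Series(videos, index=idx),
        feature_families={n: ("local" if n == "good" else "centroid") for n in names},
    )


class TestAuc:
    def test_perfect_separation(self):
        v = [1, 2, 3, 10, 11, 12]
        y = ["n", "n", "n", "p", "p", "p"]
        assert auc_binary(v, y, positive="p") == 1.0

    def test_all_ties_give_half(self):
        assert auc_binary([5, 5, 5, 5], ["p", "p", "n", "n"], positive="p") == 0.5

    def test_toy_four_point_case(self):
        v = [3, 5, 1, 4]
        y = ["p", "p", "n", "n"]
        assert auc_binary(v, y, positive="p") == 0.75

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            auc_binary([1, 2], ["p", "p"], positive="p")

    def test_matches_pairwise_oracle_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pos = rng.integers(0, 6, 7).astype(float)
            neg = rng.integers(0, 6, 5).astype(float)
            v = np.concatenate([pos, neg])
            y = ["p"] * 7 + ["n"] * 5
            assert auc_binary(v, y, positive="p") == pytest.approx(
                auc_pair_count(pos, neg)
            )


class TestAucMulticlass:
    def test_fully_separated_class_scores_one(self):
        v = [0, 1, 2, 10, 11, 12, 10.5, 11.5, 12.5]
        y = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        assert auc_multiclass(v, y) == 1.0

    def test_lower_bounded_by_half(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.standard_normal(12)
            y = rng.choice(["A", "B", "C"], 12)
            if len(set(y)) < 2:
                continue
            assert 0.5 <= auc_multiclass(v, y) <= 1.0

    def test_nine_point_toy_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            v = rng.integers(0, 5, 9).astype(float)
            y = np.array(["A", "A", "A", "B", "B", "B", "C", "C", "C"])
            assert auc_multiclass(v, y) == pytest.approx(aucm_enumeration(v, y))


class TestFilter:
    def test_engineered_separator_survives(self):
        ds = make_dataset(separation=5.0)
        survivors = filter_features(ds)
        assert "good" in survivors

    def test_family_thresholds_applied_in_order(self):
        # one feature duplicated into both families: with a multiclass AUC
        # between 0.6 and 0.75 it must pass as centroid and fail as local
        rng = np.random.default_rng(21)
        y = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
        v = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.75, 1, 20),
                            rng.normal(0.4, 1, 20)])
        a = auc_multiclass(v, y)
        assert 0.6 < a < 0.75  # construction check
        idx = [f"c{i}" for i in range(60)]
        ds = CohortDataset(
            features=pd.DataFrame({"f_cent": v, "f_loc": v}, index=idx),
            labels=pd.Series(y, index=idx),
            patients=pd.Series([f"{c}_P{i % 2}" for i, c in enumerate(y)], index=idx),
            videos=pd.Series(idx, index=idx),
            feature_families={"f_cent": "centroid", "f_loc": "local"},
        )
        survivors = filter_features(ds)
        assert "f_cent" in survivors and "f_loc" not in survivors

    def test_empty_survivor_set_warns(self):
        ds = make_dataset(separation=0.0, n_noise=2)
        with pytest.warns(UserWarning):
            filter_features(ds, th_centroid=0.999, th_local=0.999)


class TestSfs:
    def test_perfect_feature_chosen_first(self):
        ds = make_dataset(separation=5.0, n_noise=10)
        selected, trace = sfs_select(
            ds.features, ds.labels, ds.patients, list(ds.features.columns)
        )
        assert selected[0] == "good"
        assert len(trace) == len(selected)

    def test_all_noise_selection_halts_quickly(self):
        ds = make_dataset(separation=0.0, n_noise=12)
        candidates = [c for c in ds.features.columns if c != "good"]
        selected, _ = sfs_select(ds.features, ds.labels, ds.patients, candidates)
        assert len(selected) <= 6  # stops within window + 1 steps

    def test_selection_is_deterministic(self):
        ds = make_dataset(separation=2.0)
        args = (ds.features, ds.labels, ds.patients, list(ds.features.columns))
        assert sfs_select(*args) == sfs_select(*args)


class TestLda:
    def test_three_classes_give_two_canonical_axes(self):
        ds = make_dataset()
        model = fit_lda(ds.features, ds.labels, ["good", "noise0", "noise1"])
        assert model.canonical_scores(ds.features).shape[1] == 2
        assert model.loadings.shape == (3, 2)

    def test_separated_classes_fit_accurately(self):
        ds = make_dataset(separation=8.0)
        model = fit_lda(ds.features, ds.labels, ["good", "noise0"])
        acc = balanced_accuracy(ds.labels, model.predict(ds.features))
        assert acc >= 0.95

    def test_permuted_labels_remove_separation(self):
        ds = make_dataset(separation=5.0, n_patients=4, cells=10)
        rng = np.random.default_rng(0)
        y = pd.Series(rng.permutation(ds.labels.to_numpy()), index=ds.labels.index)
        model = fit_lda(ds.features, y, ["good", "noise0"])
        assert balanced_accuracy(y, model.predict(ds.features)) < 0.6

    def test_small_classes_trigger_shrinkage(self):
        ds = make_dataset(n_patients=1, cells=2, n_noise=8)
        model = fit_lda(ds.features, ds.labels, list(ds.features.columns))
        assert model.shrinkage_used


class TestLopo:
    def test_every_cell_predicted_exactly_once(self):
        ds = make_dataset(separation=4.0)
        report = lopo_evaluate(ds)
        assert len(report.predictions) == len(ds.features)
        assert report.confusion_cell.sum() == len(ds.features)
        # row sums equal class counts
        counts = ds.labels.value_counts()
        for i, c in enumerate(report.classes):
            assert report.confusion_cell[i].sum() == counts[c]

    def test_separable_cohort_classified_accurately(self):
        ds = make_dataset(separation=4.0)
        report = lopo_evaluate(ds)
        assert report.balanced_accuracy_cell >= 0.9

    def test_training_checksums_exclude_the_test_patient(self):
        import hashlib

        ds = make_dataset(separation=4.0)
        report = lopo_evaluate(ds)
        assert len(report.train_checksums) == ds.patients.nunique()
        first_patient = ds.patients.unique()[0]
        train = ds.features.loc[ds.patients != first_patient]
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(train.to_numpy(dtype=float)).tobytes())
        h.update(",".join(map(str, train.index)).encode())
        assert report.train_checksums[0] == h.hexdigest()

    def test_patient_level_label_permutation_is_chance(self):
        ds = make_dataset(separation=4.0, n_patients=4, cells=8)
        rng = np.random.default_rng(2)
        patients = ds.patients.unique()
        new_class = dict(
            zip(patients, rng.permutation(np.repeat(["CTRL", "RIF", "uRPL"], 4)))
        )
        y = ds.patients.map(new_class)
        ds_perm = CohortDataset(
            features=ds.features,
            labels=y,
            patients=ds.patients,
            videos=ds.videos,
            feature_families=ds.feature_families,
        )
        report = lopo_evaluate(ds_perm)
        assert 0.1 <= report.balanced_accuracy_cell <= 0.6


class TestVoting:
    def _report(self, p_correct=0.7, cells=67, n_patients=2, seed=0):
        rng = np.random.default_rng(seed)
        classes = ["CTRL", "RIF", "uRPL"]
        rows = []
        for cls in classes:
            others = [c for c in classes if c != cls]
            for p in range(n_patients):
                for c in range(cells):
                    correct = rng.random() < p_correct
                    pred = cls if correct else others[rng.integers(2)]
                    rows.append(
                        {
                            "patient": f"{cls}_P{p}",
                            "video": f"{cls}_P{p}_V0",
                            "true": cls,
                            "pred": pred,
                            "p_CTRL": 1 / 3,
                            "p_RIF": 1 / 3,
                            "p_uRPL": 1 / 3,
                        }
                    )
        from odepkit.learning import EvaluationReport

        preds = pd.DataFrame(rows, index=[f"c{i}" for i in range(len(rows))])
        return EvaluationReport(
            predictions=preds,
            classes=classes,
            confusion_cell=np.zeros((3, 3), dtype=int),
            confusion_experiment=np.zeros((3, 3), dtype=int),
            balanced_accuracy_cell=p_correct,
            balanced_accuracy_experiment=p_correct,
            selections=[],
            train_checksums=[],
        )

    def test_single_cell_groups_match_per_cell_accuracy(self):
        report = self._report(p_correct=0.7)
        curve = majority_vote_curve(report, max_cells=1, n_rep=2000, seed=3)
        expected = (
            report.predictions.assign(ok=lambda d: d.true == d.pred)
            .groupby("patient")["ok"]
            .mean()
            .mean()
        )
        assert curve["mean"].iloc[0] == pytest.approx(expected, abs=0.03)

    def test_groups_of_33_cells_nearly_always_correct(self):
        report = self._report(p_correct=0.7)
        curve = majority_vote_curve(report, max_cells=33, n_rep=200, seed=4)
        assert curve["mean"].iloc[-1] >= 0.95

    def test_accuracy_nondecreasing_with_group_size(self):
        report = self._report(p_correct=0.7, cells=30)
        curve = majority_vote_curve(report, max_cells=10, n_rep=400, seed=5)
        means = curve["mean"].to_numpy()
        assert np.all(np.diff(means) >= -0.05)  # Monte-Carlo slack

    def test_oversized_group_names_offending_patient(self):
        report = self._report(cells=5)
        with pytest.raises(ValueError, match="patient"):
            majority_vote_curve(report, max_cells=6)


class TestKs:
    def test_identical_samples_score_zero(self):
        x = np.arange(10.0)
        stat, _ = ks_compare(x, x)
        assert stat == 0.0

    def test_disjoint_supports_score_one(self):
        stat, p = ks_compare([1.0, 2, 3], [10.0, 11, 12])
        assert stat == 1.0
        assert p < 0.05

    def test_twenty_point_toy_matches_ecdf_scan(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1.2, 20)
        stat, _ = ks_compare(a, b)
        grid = np.sort(np.concatenate([a, b]))
        ecdf_diff = max(
            abs((a <= t).mean() - (b <= t).mean()) for t in grid
        )
        assert stat == pytest.approx(ecdf_diff)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])
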