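"""Fold audits, metric formulas against brute force, bootstrap behaviour,
and the cross-validation / hold-out drivers on separable bag cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import slidemil as sm
from slidemil.evaluation import POSITIVE, case_table, folds_to_frame
from slidemil.synthetic import bag_manifest

# confusion counts of the worked omentum hold-out example: 50 benign all
# correct, 2 of 50 metastatic called benign (rows true, cols predicted)
OMENTUM_COUNTS = np.array([[50, 0], [2, 48]])


def _manifest(n_cases_per_class=12, slides_per_case=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for label in sm.LABELS:
        for c in range(n_cases_per_class):
            case = f"{label[:3]}-case-{c}"
            for s in range(int(rng.integers(1, slides_per_case + 1))):
                rows.append(
                    {
                        "slide_id": f"{case}-s{s}",
                        "case_id": case,
                        "cohort": "omentum",
                        "label": label,
                        "mpp": 1.0,
                        "path": "",
                    }
                )
    return pd.DataFrame(rows)


class TestFolds:
    def test_partition_and_proportions(self):
        manifest = _manifest()
        splits = sm.make_stratified_case_folds(manifest, k=5, seed=1)
        cases = set(manifest["case_id"])
        tested = [c for s in splits for c in s.test_cases]
        # every case tested exactly once across folds
        assert sorted(tested) == sorted(cases)
        labels = case_table(manifest).set_index("case_id")["label"]
        n = len(cases)
        for s in splits:
            # disjoint and exhaustive within the fold
            assert s.train_cases | s.val_cases | s.test_cases == cases
            # 60-20-20 in case counts, within rounding
            assert abs(len(s.train_cases) - 0.6 * n) <= 2
            assert abs(len(s.val_cases) - 0.2 * n) <= 1
            assert abs(len(s.test_cases) - 0.2 * n) <= 1
            # stratification within one case of global proportions
            for part in (s.val_cases, s.test_cases):
                pos = sum(labels[c] == POSITIVE for c in part)
                assert abs(pos - 0.5 * len(part)) <= 1

    def test_slides_follow_their_case(self):
        manifest = _manifest(slides_per_case=3, seed=2)
        splits = sm.make_stratified_case_folds(manifest, k=5, seed=0)
        for s in splits:
            for _, row in manifest.iterrows():
                roles = {
                    role
                    for role, cs in (
                        ("train", s.train_cases),
                        ("val", s.val_cases),
                        ("test", s.test_cases),
                    )
                    if row["case_id"] in cs
                }
                assert len(roles) == 1  # exhaustive straddle audit

    def test_determinism_and_frame(self):
        manifest = _manifest()
        a = sm.make_stratified_case_folds(manifest, k=5, seed=9)
        b = sm.make_stratified_case_folds(manifest, k=5, seed=9)
        assert a == b
        frame = folds_to_frame(a)
        assert set(frame["role"]) == {"train", "val", "test"}

    def test_too_few_cases_rejected(self):
        manifest = _manifest(n_cases_per_class=3)
        with pytest.raises(ValueError, match="at least 5"):
            sm.make_stratified_case_folds(manifest, k=5)


class TestConfusionAndMetrics:
    def test_all_correct_diagonal(self):
        c = sm.confusion(["benign", "metastatic"], ["benign", "metastatic"])
        np.testing.assert_array_equal(c, [[1, 0], [0, 1]])

    def test_omentum_worked_example_counts(self):
        y_true = ["benign"] * 50 + ["metastatic"] * 50
        y_pred = ["benign"] * 50 + ["benign"] * 2 + ["metastatic"] * 48
        np.testing.assert_array_equal(sm.confusion(y_true, y_pred), OMENTUM_COUNTS)

    @given(st.lists(st.tuples(st.sampled_from(sm.LABELS), st.sampled_from(sm.LABELS)),
                    min_size=1, max_size=30))
    def test_matches_exhaustive_tally(self, pairs):
        y_true = [a for a, _ in pairs]
        y_pred = [b for _, b in pairs]
        c = sm.confusion(y_true, y_pred)
        for i, ti in enumerate(sm.LABELS):
            for j, pj in enumerate(sm.LABELS):
                assert c[i, j] == sum(
                    1 for a, b in pairs if a == ti and b == pj
                )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            sm.confusion(["benign"], ["weird"])

    def test_omentum_class_metrics(self):
        b = sm.class_metrics(OMENTUM_COUNTS, "benign")
        assert round(b["precision"], 3) == 0.962
        assert b["sensitivity"] == 1.0
        assert b["specificity"] == 0.96
        assert round(b["f1"], 3) == 0.980
        m = sm.class_metrics(OMENTUM_COUNTS, "metastatic")
        assert m["precision"] == 1.0
        assert m["sensitivity"] == 0.96
        assert m["specificity"] == 1.0
        assert round(m["f1"], 3) == 0.980

    def test_perfect_counts_all_ones(self):
        perfect = np.array([[20, 0], [0, 20]])
        for label in sm.LABELS:
            assert all(v == 1.0 for v in sm.class_metrics(perfect, label).values())

    def test_undefined_ratio_is_nan_not_zero(self):
        no_pos_pred = np.array([[5, 0], [3, 0]])
        m = sm.class_metrics(no_pos_pred, "metastatic")
        assert np.isnan(m["precision"]) and np.isnan(m["f1"])

    def test_accuracy_metrics(self):
        acc = sm.accuracy_metrics(OMENTUM_COUNTS)
        assert acc["accuracy"] == 0.98
        assert acc["balanced_accuracy"] == (1.0 + 0.96) / 2
        with pytest.raises(ValueError):
            sm.accuracy_metrics(np.zeros((2, 2), dtype=int))

    @given(st.integers(0, 2**31 - 1))
    def test_accuracy_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.choice(sm.LABELS, size=20)
        p = rng.choice(sm.LABELS, size=20)
        c = sm.confusion(y, p)
        acc = sm.accuracy_metrics(c)
        assert acc["accuracy"] == pytest.approx(np.mean(y == p))


class TestAuroc:
    def test_separated_and_tied(self):
        y = ["benign", "benign", "metastatic", "metastatic"]
        assert sm.auroc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert sm.auroc(y, [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_undefined(self):
        assert np.isnan(sm.auroc(["benign", "benign"], [0.1, 0.9]))

    @given(st.integers(0, 2**31 - 1))
    def test_equals_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        y = np.array(["benign"] * n, dtype=object)
        y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = "metastatic"
        scores = rng.choice(np.linspace(0, 1, 5), size=n)  # force ties
        pos = scores[y == "metastatic"]
        neg = scores[y == "benign"]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = wins / (len(pos) * len(neg))
        assert sm.auroc(y, scores) == pytest.approx(oracle)


class TestBootstrap:
    def test_degenerate_metric_gives_zero_width(self):
        y = np.array(["benign"] * 5 + ["metastatic"] * 5)
        ci = sm.bootstrap_ci(
            lambda a, b: float(np.mean(a == b)), y, y, n_bootstrap=200, seed=0
        )
        assert ci.mean == 1.0 and ci.low == 1.0 and ci.high == 1.0

    def test_same_seed_identical(self):
        rng = np.random.default_rng(0)
        y = rng.choice(sm.LABELS, size=30)
        p = rng.choice(sm.LABELS, size=30)
        f = lambda a, b: float(np.mean(a == b))
        a = sm.bootstrap_ci(f, y, p, n_bootstrap=300, seed=7)
        b = sm.bootstrap_ci(f, y, p, n_bootstrap=300, seed=7)
        assert (a.mean, a.low, a.high) == (b.mean, b.low, b.high)

    def test_mean_within_monte_carlo_error(self):
        # accuracy is linear in the resampled slides, so the bootstrap
        # replicate mean is an unbiased estimate of the point estimate
        rng = np.random.default_rng(1)
        y = rng.choice(sm.LABELS, size=80)
        p = np.where(rng.random(80) < 0.8, y, rng.choice(sm.LABELS, size=80))
        f = lambda a, b: float(np.mean(a == b))
        point = f(y, p)
        ci = sm.bootstrap_ci(f, y, p, n_bootstrap=10_000, seed=3)
        mc_se = ci.sd / np.sqrt(10_000)
        assert abs(ci.mean - point) < 3 * mc_se
        assert ci.low <= point <= ci.high

    def test_mostly_undefined_metric_rejected(self):
        y = np.array(["benign"] * 4)
        with pytest.raises(ValueError, match="undefined"):
            sm.bootstrap_ci(sm.auroc, y, np.ones(4), n_bootstrap=20, seed=0)


@pytest.fixture(scope="module")
def bag_cv():
    """Cross-validation on a separable synthetic bag cohort."""
    spec = sm.BagSimSpec(
        n_bags_per_class=25, bag_size_range=(10, 30), feature_dim=16, seed=21
    )
    bags, labels = sm.generate_feature_bags(spec)
    manifest = bag_manifest(bags, labels)
    cfg = sm.TrainConfig(
        learning_rate=1e-3, max_epochs=60, min_epochs=15, patience=8, seed=3
    )
    result = sm.run_cross_validation(
        manifest, {b.slide_id: b for b in bags}, train_config=cfg,
        k=5, seed=4, n_bootstrap=300,
    )
    return spec, bags, labels, manifest, result


class TestCrossValidationDriver:
    def test_every_slide_predicted_once(self, bag_cv):
        _, bags, _, manifest, result = bag_cv
        assert sorted(result.predictions["slide_id"]) == sorted(manifest["slide_id"])

    def test_separable_cohort_auroc(self, bag_cv):
        *_, result = bag_cv
        assert result.report.auroc.point >= 0.95

    def test_report_invariants(self, bag_cv):
        *_, result = bag_cv
        rep = result.report
        for metric in (rep.accuracy, rep.balanced_accuracy, rep.auroc, rep.f1):
            assert 0.0 <= metric.point <= 1.0
            assert metric.ci_low <= metric.boot_mean <= metric.ci_high
        assert np.asarray(rep.counts).sum() == rep.n_slides

    def test_missing_bag_rejected(self, bag_cv):
        _, bags, _, manifest, _ = bag_cv
        with pytest.raises(ValueError, match="no feature bag"):
            sm.run_cross_validation(manifest, {}, k=5, seed=0)


class TestHoldoutDriver:
    def test_leakage_guard_is_hard_error(self, bag_cv):
        _, bags, _, manifest, result = bag_cv
        with pytest.raises(ValueError, match="training"):
            sm.run_holdout(
                result.models, manifest, {b.slide_id: b for b in bags},
                result.train_case_ids,
            )

    def test_separable_holdout_auroc(self, bag_cv):
        spec, _, _, _, result = bag_cv
        hb, hl = sm.generate_feature_bags(
            sm.BagSimSpec(
                n_bags_per_class=15, bag_size_range=(10, 30), feature_dim=16, seed=99
            )
        )
        hm = bag_manifest(hb, hl, cohort="simbags-holdout", bags_per_case=1)
        preds, report = sm.run_holdout(
            result.models, hm, {b.slide_id: b for b in hb},
            result.train_case_ids, n_bootstrap=300, seed=1,
        )
        assert len(preds) == len(hm)
        assert report.auroc.point >= 0.95
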