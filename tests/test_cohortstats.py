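"""ROC/AUC, cutoff selection, diagnostic tables, rank statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbsquant import simdata
from hbsquant.cohortstats import (
    ConfusionCounts,
    build_table5,
    classify_by_cutoff,
    confusion_counts,
    diagnostics,
    mann_whitney,
    median_iqr,
    pearson_r,
    roc,
    select_cutoff,
)


def brute_force_auc(pos, neg):
    """Exhaustive pair-counting oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClassify:
    def test_low_is_positive_inclusive(self):
        pred = classify_by_cutoff(np.asarray([1.5, 2.0, 3.0]), 1.85)
        np.testing.assert_array_equal(pred, [True, False, False])
        assert classify_by_cutoff(np.asarray([1.5, 2.0]), 2.0).all()
        assert not classify_by_cutoff(np.asarray([1.5, 2.0]), 1.0).any()

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            classify_by_cutoff(np.asarray([1.0, np.nan]), 1.5)


class TestDiagnostics:
    def test_published_grade_ab_row(self):
        # 18 positives all test-positive, 6 of 20 negatives test-positive.
        d = diagnostics(ConfusionCounts(tp=18, fp=6, tn=14, fn=0))
        assert d["se"] == 100.0
        assert d["sp"] == pytest.approx(70.0)
        assert d["ppv"] == pytest.approx(75.0)
        assert d["npv"] == 100.0
        assert d["lr_pos"] == pytest.approx(10.0 / 3.0)
        assert d["lr_neg"] == 0.0

    def test_published_grade_b_row(self):
        d = diagnostics(ConfusionCounts(tp=6, fp=8, tn=24, fn=0))
        assert d["se"] == 100.0
        assert d["sp"] == pytest.approx(75.0)
        assert d["ppv"] == pytest.approx(42.857, abs=1e-3)
        assert d["npv"] == 100.0
        assert d["lr_pos"] == pytest.approx(4.0)

    def test_perfect_specificity_gives_infinite_lr(self):
        d = diagnostics(ConfusionCounts(tp=5, fp=0, tn=10, fn=1))
        assert d["lr_pos"] == float("inf")

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            diagnostics(ConfusionCounts(tp=0, fp=3, tn=5, fn=0))
        with pytest.raises(ValueError, match="negative"):
            diagnostics(ConfusionCounts(tp=3, fp=0, tn=0, fn=1))

    def test_counts_conserved(self):
        pred = np.asarray([True, True, False, False, True])
        labels = np.asarray([True, False, False, True, True])
        c = confusion_counts(pred, labels)
        assert c.n == 5


class TestRoc:
    def test_perfect_separation(self):
        scores = np.asarray([1.0, 1.2, 3.0, 4.0])
        labels = np.asarray([True, True, False, False])
        assert roc(scores, labels)["auc"] == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.uniform(size=4000) < 0.5
        assert roc(scores, labels)["auc"] == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc(np.asarray([1.0, 2.0]), np.asarray([True, True]))

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_pair_counting_oracle(self, data):
        n_pos = data.draw(st.integers(1, 25))
        n_neg = data.draw(st.integers(1, 25))
        values = st.integers(0, 10)  # coarse grid to force ties
        pos = data.draw(st.lists(values, min_size=n_pos, max_size=n_pos))
        neg = data.draw(st.lists(values, min_size=n_neg, max_size=n_neg))
        scores = np.asarray(pos + neg, dtype=float)
        labels = np.asarray([True] * n_pos + [False] * n_neg)
        # low_is_positive=False: higher score = more positive.
        auc = roc(scores, labels, low_is_positive=False)["auc"]
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_ci_contains_auc_and_is_clipped(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)])
        labels = np.asarray([False] * 20 + [True] * 20)
        r = roc(scores, labels, low_is_positive=False)
        lo, hi = r["auc_ci95"]
        assert 0.0 <= lo <= r["auc"] <= hi <= 1.0


class TestSelectCutoff:
    def test_separable_midpoint(self):
        scores = np.asarray([1.0, 1.5, 3.0, 4.0])
        labels = np.asarray([True, True, False, False])
        assert select_cutoff(scores, labels) == pytest.approx(2.25)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            select_cutoff(np.full(6, 2.0), np.asarray([True] * 3 + [False] * 3))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff(np.asarray([1.0, 2.0]), np.asarray([True, True]))

    def test_monotone_transform_preserves_classification(self, rng):
        scores = rng.uniform(0.5, 5.0, 40)
        labels = scores + rng.normal(0, 0.8, 40) < 2.5
        c1 = select_cutoff(scores, labels)
        c2 = select_cutoff(scores**3, labels)
        np.testing.assert_array_equal(
            classify_by_cutoff(scores, c1), classify_by_cutoff(scores**3, c2)
        )

    def test_recovers_generative_threshold_under_strong_effect(self):
        # Near-deterministic grade assignment at FLR-F = 2.5: the selected
        # cutoff must land next to the generative threshold, classifying
        # every patient away from it correctly (patients within the narrow
        # stochastic transition zone may legitimately flip).
        for seed in range(25):
            df = simdata.generate_cohort(
                60, effect_slope=500.0, intercept_a=500.0 * 2.5,
                intercept_b=500.0 * 1.5, seed=seed,
            )
            labels = df["true_grade"].isin(["A", "B"]).to_numpy()
            if labels.all() or not labels.any():
                continue
            scores = df["flr_f"].to_numpy()
            c = select_cutoff(scores, labels)
            clear = np.abs(scores - 2.5) > 0.05
            assert np.array_equal(
                classify_by_cutoff(scores[clear], c), labels[clear]
            )
            assert abs(c - 2.5) < 0.15


class TestRankStats:
    def test_mann_whitney_identity_with_auc(self, rng):
        a = rng.normal(1.0, 1.0, 17)
        b = rng.normal(0.0, 1.0, 23)
        u, _ = mann_whitney(a, b)
        scores = np.concatenate([a, b])
        labels = np.asarray([True] * 17 + [False] * 23)
        auc = roc(scores, labels, low_is_positive=False)["auc"]
        assert u == pytest.approx(auc * 17 * 23, abs=1e-9)

    def test_identical_groups_p_near_one(self):
        a = np.asarray([1.0, 2.0, 3.0, 4.0, 5.0])
        _, p = mann_whitney(a, a.copy())
        assert p > 0.9

    def test_disjoint_ranges_minimal_u(self):
        u, p = mann_whitney(np.asarray([1.0, 2.0, 3.0, 4.0]), np.asarray([10.0, 11.0, 12.0, 13.0]))
        assert u == 0.0
        assert p < 0.05

    def test_pearson(self):
        x = np.asarray([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_median_iqr_linear_interpolation(self):
        med, q1, q3 = median_iqr(np.asarray([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (med, q1, q3) == (3.0, 2.0, 4.0)


@pytest.fixture(scope="module")
def graded_reference():
    from hbsquant import outcomes

    df = simdata.reference_cohort()
    grades, fifties = [], []
    for _, r in df.iterrows():
        course = outcomes.PostopCourse.single_day(
            pod=5, bilirubin_umol_l=r["bilirubin_umol_l_pod5"],
            inr=r["inr_pod5"], pt_pct=r["pt_pct_pod5"],
            any_deviation_noninvasive=bool(r["deviation_noninvasive"]),
            invasive_procedure=bool(r["invasive_procedure"]),
        )
        grades.append(outcomes.isgls_grade(course))
        fifties.append(outcomes.fifty_fifty(course))
    return df.assign(isgls_grade=grades, fifty_fifty=fifties)


class TestBuildTable5:
    def test_grading_recovers_intended_strata(self, graded_reference):
        df = graded_reference
        assert (df["isgls_grade"] == df["intended_grade"]).all()
        assert df["fifty_fifty"].sum() == 4

    def test_flr_f_rows_match_published_metrics(self, graded_reference):
        table = build_table5(graded_reference, indices=("flr_f",))
        rows = {r["endpoint"]: r for _, r in table.iterrows()}
        r5050 = rows["50-50"]
        assert r5050["se"] == 100.0
        assert r5050["sp"] == pytest.approx(100.0 * 30 / 34, abs=1e-9)
        assert r5050["ppv"] == pytest.approx(50.0)
        assert r5050["lr_pos"] == pytest.approx(8.5)
        rb = rows["ISGLS-B"]
        assert (rb["se"], rb["sp"]) == (100.0, 75.0)
        assert rb["ppv"] == pytest.approx(100.0 * 6 / 14, abs=1e-9)
        rab = rows["ISGLS-A/B"]
        assert (rab["se"], rab["sp"]) == (100.0, 70.0)
        assert rab["ppv"] == pytest.approx(75.0)
        assert rab["npv"] == 100.0
        assert rab["lr_pos"] == pytest.approx(10.0 / 3.0)

    def test_patient_order_invariance(self, graded_reference):
        t1 = build_table5(graded_reference)
        shuffled = graded_reference.sample(frac=1.0, random_state=3).reset_index(drop=True)
        t2 = build_table5(shuffled)
        for col in ("cutoff", "auc", "se", "sp", "ppv", "npv"):
            np.testing.assert_allclose(t1[col].to_numpy(), t2[col].to_numpy())

    def test_missing_columns_named(self, graded_reference):
        with pytest.raises(ValueError, match="flr_f"):
            build_table5(graded_reference.drop(columns=["flr_f"]))

    def test_endpoint_without_positives_rejected(self, graded_reference):
        df = graded_reference.copy()
        df["fifty_fifty"] = False
        with pytest.raises(ValueError):
            build_table5(df, endpoints=("50-50",))

    def test_effect_beats_noise_covariate(self):
        # FLR-F driven by the generative effect must out-rank a pure-noise
        # score in nearly all seeded cohorts.
        wins = 0
        n_seeds = 60
        for seed in range(n_seeds):
            df = simdata.generate_cohort(38, seed=seed)
            labels = df["true_grade"].isin(["A", "B"]).to_numpy()
            if labels.all() or not labels.any():
                wins += 1
                continue
            auc_f = roc(df["flr_f"].to_numpy(), labels)["auc"]
            noise = np.random.default_rng(seed + 10_000).normal(size=len(df))
            auc_n = roc(noise, labels)["auc"]
            wins += auc_f > auc_n
        assert wins >= 0.95 * n_seeds
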