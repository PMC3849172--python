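"""Outcome-correlation ranking, CI classifier, forward selection, threshold."""

import logging

import numpy as np
import pandas as pd
import pytest

from prognosig import (
    GOOD,
    POOR,
    DataError,
    SimulationConfig,
    choose_threshold,
    ci_score,
    classify,
    derive_outcome_labels,
    forward_select,
    generate_dataset,
    loocv_accuracy,
    outcome_correlations,
)
from prognosig.cluster import ClusterAssignment

from conftest import SMALL


def make_expr(values, samples=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=samples or [f"s{i}" for i in range(values.shape[1])],
    )


OUTCOME6 = pd.Series([GOOD] * 3 + [POOR] * 3, index=[f"s{i}" for i in range(6)])


def naive_loocv(expr, outcome, probes):
    """Independent double-loop LOOCV oracle using np.corrcoef only."""
    sub = expr.loc[list(probes)]
    hits = 0
    for sample in sub.columns:
        rest = [s for s in sub.columns if s != sample]
        good = [s for s in rest if outcome[s] == GOOD]
        poor = [s for s in rest if outcome[s] == POOR]
        cg = np.corrcoef(sub[sample], sub[good].mean(axis=1))[0, 1]
        cp = np.corrcoef(sub[sample], sub[poor].mean(axis=1))[0, 1]
        pred = GOOD if cg > cp else POOR
        hits += pred == outcome[sample]
    return hits / sub.shape[1]


class TestOutcomeCorrelations:
    def test_probe_equal_to_outcome_ranks_first(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 0.1, (4, 6))
        values[0] = [1, 1, 1, 0, 0, 0]  # identical to the coded outcome
        corr = outcome_correlations(make_expr(values), OUTCOME6)
        assert corr.table.loc["g0", "r"] == pytest.approx(1.0)
        assert corr.ranked_probes[0] == "g0"

    def test_orthogonal_probe_filtered_out(self):
        values = np.zeros((2, 6))
        values[0] = [1, -1, 0, 1, -1, 0]  # orthogonal to outcome
        values[1] = [1, 1, 1, 0, 0, 0]
        corr = outcome_correlations(make_expr(values), OUTCOME6)
        assert corr.table.loc["g0", "r"] == pytest.approx(0.0, abs=1e-12)
        assert "g0" not in corr.ranked_probes

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.normal(0, 1, (8, 6)))
        corr = outcome_correlations(expr, OUTCOME6, r_min=0.0)
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        for probe in expr.index:
            expected = np.corrcoef(expr.loc[probe], y)[0, 1]
            assert corr.table.loc[probe, "r"] == pytest.approx(expected, abs=1e-12)

    def test_constant_probe_excluded_with_warning(self, caplog):
        values = np.vstack([[5.0] * 6, [1, 1, 1, 0, 0, 0]])
        with caplog.at_level(logging.WARNING):
            corr = outcome_correlations(make_expr(values), OUTCOME6)
        assert "g0" not in corr.table.index
        assert any("constant" in rec.message for rec in caplog.records)

    def test_constant_outcome_raises(self):
        expr = make_expr(np.random.default_rng(2).normal(size=(3, 6)))
        outcome = pd.Series([GOOD] * 6, index=expr.columns)
        with pytest.raises(DataError, match="constant"):
            outcome_correlations(expr, outcome)

    def test_antisymmetric_under_outcome_flip(self):
        rng = np.random.default_rng(3)
        expr = make_expr(rng.normal(0, 1, (10, 6)))
        flipped = OUTCOME6.map({GOOD: POOR, POOR: GOOD})
        a = outcome_correlations(expr, OUTCOME6)
        b = outcome_correlations(expr, flipped)
        assert np.allclose(a.table["r"].values, -b.table["r"].values, atol=1e-12)
        assert list(a.ranked_probes) == list(b.ranked_probes)

    def test_rank_ties_broken_by_probe_id(self):
        values = np.vstack([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1]])  # r = +1 and -1
        corr = outcome_correlations(make_expr(values), OUTCOME6)
        assert list(corr.ranked_probes) == ["g0", "g1"]


class TestCiScore:
    def test_profile_equal_to_centroid(self):
        centroid = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert ci_score(centroid, centroid) == pytest.approx(1.0)

    def test_negated_centered_profile(self):
        centroid = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        neg = -(centroid - centroid.mean()) + centroid.mean()
        assert ci_score(neg, centroid) == pytest.approx(-1.0)

    def test_matches_pearson_formula(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.normal(size=5), index=list("abcde"))
        b = pd.Series(rng.normal(size=5), index=list("abcde"))
        assert ci_score(a, b) == pytest.approx(np.corrcoef(a, b)[0, 1], abs=1e-12)

    def test_missing_probes_excluded_pairwise(self):
        a = pd.Series([1.0, np.nan, 3.0, 4.0, 2.0], index=list("abcde"))
        b = pd.Series([1.0, 2.0, 3.0, 4.0, 1.0], index=list("abcde"))
        expected = np.corrcoef([1, 3, 4, 2], [1, 3, 4, 1])[0, 1]
        assert ci_score(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_profile_raises(self):
        a = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(DataError, match="constant"):
            ci_score(a, b)

    def test_too_few_pairs_raises(self):
        a = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(DataError, match=">= 3"):
            ci_score(a, a)


class TestLoocvAccuracy:
    def test_noiseless_planted_probes_are_perfect(self):
        cfg = SimulationConfig(seed=6, noise_sd=0.0, **SMALL)
        matrix, annotation, truth = generate_dataset(cfg)
        tumors = annotation.loc[annotation["lesion"] == "malignant", "sample_id"].tolist()
        expr = matrix.values[tumors]
        outcome = truth.patient_groups.rename(index=lambda p: f"{p}T")
        assert loocv_accuracy(expr, outcome, truth.prognosis_probe_ids) == 1.0

    def test_equals_naive_double_loop(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = rng.integers(8, 13)
            expr = make_expr(rng.normal(0, 1, (6, n)), samples=[f"s{i}" for i in range(n)])
            labels = [GOOD] * (n // 2) + [POOR] * (n - n // 2)
            outcome = pd.Series(labels, index=expr.columns).sample(frac=1, random_state=seed)
            assert loocv_accuracy(expr, outcome, expr.index) == pytest.approx(
                naive_loocv(expr, outcome, expr.index)
            )

    def test_null_labels_near_chance(self):
        # frozen Monte-Carlo band for the permutation-null mean accuracy
        accs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            expr = make_expr(rng.normal(0, 1, (10, 12)), samples=[f"s{i}" for i in range(12)])
            outcome = pd.Series([GOOD] * 6 + [POOR] * 6, index=expr.columns).sample(
                frac=1, random_state=seed
            )
            accs.append(loocv_accuracy(expr, outcome, expr.index))
        assert 0.42 <= np.mean(accs) <= 0.58

    def test_invariant_under_probe_reordering_and_sample_rescaling(self):
        rng = np.random.default_rng(9)
        expr = make_expr(rng.normal(0, 1, (8, 10)), samples=[f"s{i}" for i in range(10)])
        outcome = pd.Series([GOOD] * 5 + [POOR] * 5, index=expr.columns)
        base = loocv_accuracy(expr, outcome, expr.index)
        assert loocv_accuracy(expr, outcome, expr.index[::-1]) == base
        rescaled = expr.copy()
        rescaled["s3"] = rescaled["s3"] * 4.0 + 2.0  # held-out profile: affine-invariant
        assert loocv_accuracy(rescaled, outcome, expr.index) == base


class TestChooseThreshold:
    def test_separated_scores_zero_fnr_midpoint(self):
        scores = pd.Series([0.9, 0.8, 0.7, 0.2, 0.1, 0.0], index=OUTCOME6.index)
        t, fnr = choose_threshold(scores, OUTCOME6, target_fnr=0.0)
        assert t == pytest.approx((0.7 + 0.2) / 2)
        assert fnr == 0.0

    def test_matches_exhaustive_scan(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_good, n_poor = rng.integers(4, 9), rng.integers(4, 9)
            scores = pd.Series(
                np.round(rng.normal(0, 1, n_good + n_poor), 2),
                index=[f"s{i}" for i in range(n_good + n_poor)],
            )
            outcome = pd.Series([GOOD] * n_good + [POOR] * n_poor, index=scores.index)
            target = float(rng.uniform(0, 0.5))
            t, fnr = choose_threshold(scores, outcome, target)
            good = np.sort(scores[outcome == GOOD].values)
            # oracle: scan every candidate cutpoint, keep the largest with FNR <= target
            candidates = np.concatenate([[scores.min() - 1], np.unique(scores.values)])
            feasible = [c for c in candidates if (good <= c).mean() <= target]
            best = max(feasible)
            assert (good <= t).mean() == pytest.approx((good <= best).mean())
            assert fnr == pytest.approx((good <= t).mean())
            assert fnr <= target

    def test_invalid_target_raises(self):
        scores = pd.Series([0.5, 0.4], index=["a", "b"])
        outcome = pd.Series([GOOD, POOR], index=["a", "b"])
        with pytest.raises(DataError, match="target_fnr"):
            choose_threshold(scores, outcome, target_fnr=1.0)


class TestForwardSelect:
    @staticmethod
    def perfect_pool(n_probes=5, n_good=5, n_poor=5, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([1.0] * n_good + [0.0] * n_poor)
        slopes = np.arange(1, n_probes + 1, dtype=float)
        offsets = rng.normal(0, 0.2, n_probes)
        values = slopes[:, None] * y[None, :] + offsets[:, None]
        values += rng.normal(0, 0.01, values.shape)
        expr = make_expr(values, samples=[f"s{i}" for i in range(n_good + n_poor)])
        outcome = pd.Series([GOOD] * n_good + [POOR] * n_poor, index=expr.columns)
        return expr, outcome

    def test_five_perfect_probes_select_all_at_full_accuracy(self):
        expr, outcome = self.perfect_pool()
        corr = outcome_correlations(expr, outcome)
        sig = forward_select(expr, outcome, corr, batch=5)
        assert sig.size == 5
        assert sig.loocv_accuracy == 1.0
        assert sig.accuracy_curve == [(5, 1.0)]

    def test_pool_smaller_than_batch_gets_single_evaluation(self):
        expr, outcome = self.perfect_pool(n_probes=3)
        corr = outcome_correlations(expr, outcome)
        sig = forward_select(expr, outcome, corr, batch=5)
        assert sig.size == 3
        assert len(sig.accuracy_curve) == 1

    def test_curve_bounded_and_selected_size_attains_maximum(self, small_dataset):
        matrix, annotation, truth = small_dataset
        tumors = annotation.loc[annotation["lesion"] == "malignant", "sample_id"].tolist()
        expr = matrix.values[tumors]
        outcome = truth.patient_groups.loc[[s[:-1] for s in tumors]].rename(
            index=lambda p: f"{p}T"
        )
        corr = outcome_correlations(expr.loc[truth.de_probe_ids], outcome)
        sig = forward_select(expr, outcome, corr, batch=3)
        accs = [a for _, a in sig.accuracy_curve]
        assert all(0.0 <= a <= 1.0 for a in accs)
        best = max(accs)
        assert dict(sig.accuracy_curve)[sig.size] == best
        assert sig.size == min(s for s, a in sig.accuracy_curve if a == best)
        assert sig.achieved_fnr <= sig.target_fnr

    def test_empty_pool_raises(self):
        expr, outcome = self.perfect_pool()
        corr = outcome_correlations(expr, outcome, r_min=0.999999)
        corr.ranked.drop(corr.ranked.index, inplace=True)
        with pytest.raises(DataError, match="empty"):
            forward_select(expr, outcome, corr)


class TestClassify:
    def test_threshold_rule_calls_good_above_threshold(self):
        expr, outcome = TestForwardSelect.perfect_pool(seed=2)
        corr = outcome_correlations(expr, outcome)
        sig = forward_select(expr, outcome, corr)
        scores, calls = classify(expr, sig)
        assert ((scores > sig.threshold) == (calls == GOOD)).all()


class TestDeriveOutcomeLabels:
    @staticmethod
    def annotation_for(samples, survivals):
        return pd.DataFrame(
            {
                "sample_id": samples,
                "patient_id": [s[:-1] for s in samples],
                "lesion": "malignant",
                "stage": "I",
                "pathology": "x",
                "metastasis_5yr": ["no", "no", "yes", "yes"],
                "survival_months": survivals,
                "event": [0, 0, 1, 1],
                "cohort": "training",
            }
        )

    def test_cluster_coding_names_longer_survival_good(self):
        samples = ["p1T", "p2T", "p3T", "p4T"]
        ann = self.annotation_for(samples, [60.0, 55.0, 10.0, 5.0])
        assignment = ClusterAssignment(labels=pd.Series([2, 2, 1, 1], index=samples))
        labels = derive_outcome_labels(assignment, ann, coding="cluster")
        assert (labels[["p1T", "p2T"]] == GOOD).all()
        assert (labels[["p3T", "p4T"]] == POOR).all()

    def test_metastasis_coding_uses_flag(self):
        samples = ["p1T", "p2T", "p3T", "p4T"]
        ann = self.annotation_for(samples, [60.0, 55.0, 10.0, 5.0])
        labels = derive_outcome_labels(None, ann, coding="metastasis")
        assert (labels[["p1T", "p2T"]] == GOOD).all()
        assert (labels[["p3T", "p4T"]] == POOR).all()

    def test_unknown_coding_raises(self):
        with pytest.raises(DataError, match="coding"):
            derive_outcome_labels(None, self.annotation_for(
                ["p1T", "p2T", "p3T", "p4T"], [1.0, 2.0, 3.0, 4.0]), coding="nope")
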