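"""AUC machinery, age-controlled bootstrap, and leave-one-out scoring."""

import numpy as np
import pandas as pd
import pytest

from rnflpca.detection import (age_controlled_bootstrap_auc, auc, compare_auc,
                               loo_scores, roc_curve_points)


def pair_count_auc(scores, labels):
    """Independent oracle: exhaustive case-control pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.ones(10), [0] * 5 + [1] * 5) == 0.5

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pair_counting_oracle(self, trial):
        rng = np.random.default_rng(trial)
        scores = rng.integers(0, 10, size=30).astype(float)  # ties likely
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[:2] = [True, False]
        base = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(base)
        assert auc(3 * scores - 7, labels) == pytest.approx(base)

    def test_negated_scores_flip_auc(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        assert auc(-scores, labels) == pytest.approx(1 - auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])

    def test_roc_curve_area_matches_auc(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        pts = roc_curve_points(scores, labels)
        area = np.trapezoid(pts["tpr"], pts["fpr"])
        assert area == pytest.approx(auc(scores, labels), abs=1e-12)


class TestAgeControlledBootstrap:
    def test_no_confound_limit_matches_plain_auc(self):
        rng = np.random.default_rng(3)
        n = 200
        labels = np.r_[np.ones(100), np.zeros(100)].astype(bool)
        ages = rng.normal(60, 8, size=n)  # identical age distributions
        scores = labels + rng.normal(0, 1.0, size=n)
        res = age_controlled_bootstrap_auc(scores, labels, ages,
                                           n_boot=400, seed=0)
        assert res.auc == pytest.approx(auc(scores, labels), abs=0.02)
        assert res.ci[0] < res.auc < res.ci[1]

    def test_pure_age_confound_is_removed(self):
        """Score = age + noise with age confounded with the label: the naive
        AUC is inflated, the age-matched bootstrap AUC is near chance."""
        rng = np.random.default_rng(4)
        n = 300
        labels = np.r_[np.ones(150), np.zeros(150)].astype(bool)
        # overlapping supports: every case age has comparable controls
        ages = np.where(labels, rng.normal(62, 10, n), rng.normal(48, 10, n))
        scores = ages + rng.normal(0, 5.0, size=n)
        naive = auc(scores, labels)
        res = age_controlled_bootstrap_auc(scores, labels, ages,
                                           n_boot=500, seed=1)
        assert naive > 0.7
        assert abs(res.auc - 0.5) < 0.1

    def test_fixed_seed_is_deterministic(self, rng):
        labels = rng.random(80) < 0.5
        labels[:2] = [True, False]
        scores = rng.normal(size=80)
        ages = rng.normal(60, 10, size=80)
        a = age_controlled_bootstrap_auc(scores, labels, ages, n_boot=300,
                                         seed=7)
        b = age_controlled_bootstrap_auc(scores, labels, ages, n_boot=300,
                                         seed=7)
        assert a.auc == b.auc and a.ci == b.ci

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            age_controlled_bootstrap_auc([1.0, 2.0], [0, 1], [50.0, 60.0],
                                         n_boot=10)


class TestCompareAUC:
    def _fixture(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        labels = rng.random(n) < 0.5
        labels[:2] = [True, False]
        ages = rng.normal(60, 8, size=n)
        return rng, labels, ages

    def test_identical_models_give_zero_delta_p_one(self):
        rng, labels, ages = self._fixture(1)
        s = rng.normal(size=len(labels))
        res = compare_auc(s, s, labels, ages, n_boot=300, seed=0)
        assert res.delta == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_separating_beats_random_score(self):
        rng, labels, ages = self._fixture(2)
        good = labels.astype(float)                      # perfect separation
        noise = rng.normal(size=len(labels))             # uninformative
        res = compare_auc(good, noise, labels, ages, n_boot=500, seed=0)
        assert res.delta > 0.3
        assert res.p_value < 0.01

    def test_swap_negates_delta_keeps_p(self):
        rng, labels, ages = self._fixture(3)
        a = labels + rng.normal(0, 1, size=len(labels))
        b = rng.normal(size=len(labels))
        r1 = compare_auc(a, b, labels, ages, n_boot=300, seed=5)
        r2 = compare_auc(b, a, labels, ages, n_boot=300, seed=5)
        assert r1.delta == pytest.approx(-r2.delta, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1.0], [1.0, 2.0], [0, 1], [50.0, 60.0])


def _toy_table(n_participants=24, seed=0, signal=True):
    """Scan table with a scalar measurement; no maps needed."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        group = "glaucoma" if i < n_participants // 2 else "healthy"
        shift = -20.0 if (group == "glaucoma" and signal) else 0.0
        for v in range(3):
            rows.append(dict(scan_id=f"P{i}_m{v}", participant_id=f"P{i}",
                             eye_id=f"P{i}_OD", visit_month=float(3 * v),
                             age=rng.normal(60, 8), group=group,
                             mean_cprnflt=95.0 + shift + rng.normal(0, 3),
                             sap_md=rng.normal(0, 1),
                             fdt_md=rng.normal(0, 1)))
    return pd.DataFrame(rows)


class TestLooScores:
    def test_separable_cohort_scored_correctly(self):
        table = _toy_table(signal=True)
        preds = loo_scores(table, model_id="cprnflt")
        assert preds["score"].between(0, 1).all()
        assert auc(preds["score"], preds["label"]) > 0.95

    def test_no_participant_trains_its_own_fold(self):
        """Structural guard: scoring is complete and participant-keyed."""
        table = _toy_table()
        preds = loo_scores(table, model_id="cprnflt")
        assert len(preds) == len(table)
        assert set(preds["scan_id"]) == set(table["scan_id"])
        assert preds["score"].notna().all()

    def test_calibration_near_prevalence_on_null_data(self):
        table = _toy_table(n_participants=40, seed=3, signal=False)
        preds = loo_scores(table, model_id="cprnflt")
        prevalence = preds["label"].mean()
        assert abs(preds["score"].mean() - prevalence) < 0.1

    def test_pca_model_requires_stack(self):
        with pytest.raises(ValueError):
            loo_scores(_toy_table(), None, model_id="pca10")

    def test_pca_loo_on_synthetic_cohort(self, small_cohort, registered_small):
        cohort, _ = small_cohort
        stack, _ = registered_small
        preds = loo_scores(cohort.table, stack, model_id="pca10", k=6)
        a = auc(preds["score"], preds["label"])
        assert a > 0.9  # strong structural damage is easily detected
        # comparator under the identical protocol
        preds_c = loo_scores(cohort.table, model_id="cprnflt")
        assert auc(preds_c["score"], preds_c["label"]) > 0.7
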