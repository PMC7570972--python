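"""Cohort statistics: paired t-tests, ANOVA, calibration, classification."""

import numpy as np
import pytest

import residentirl as ri
from residentirl.cohort_stats import (
    ALPHA,
    PreferenceSample,
    between_group_anova,
    between_home_anova,
    classify_diagnosis,
    learn_window_vectors,
    within_home_change,
)
from residentirl.features import FEATURE_NAMES

TOILET_O = FEATURE_NAMES.index("o_toilet")
BED = FEATURE_NAMES.index("d_bedroom")


def _samples(thetas, home="h1", label="healthy", start=0):
    return [
        PreferenceSample(home_id=home, window_id=start + i, theta=t, label=label)
        for i, t in enumerate(thetas)
    ]


class TestWithinHomeChange:
    def test_identical_windows_give_t_zero_p_one(self, rng):
        thetas = rng.normal(size=(30, 14))
        samples = _samples(np.vstack([thetas, thetas]))
        rep = within_home_change(samples, 30, 30)
        assert np.all(rep.statistic == 0.0) and np.all(rep.p_values == 1.0)
        assert rep.overall_mean_p == 1.0

    def test_three_sd_shift_is_detected(self, rng):
        first = rng.normal(size=(30, 14))
        last = rng.normal(size=(30, 14))
        last[:, BED] += 3.0  # 3 pooled SDs on one feature
        rep = within_home_change(_samples(np.vstack([first, last])), 30, 30)
        assert rep.p_values[BED] < 0.01
        assert rep.significant[BED]

    def test_summary_means_are_arithmetic_means(self, rng):
        thetas = rng.normal(size=(40, 14))
        rep = within_home_change(_samples(thetas), 10, 10)
        assert rep.overall_mean_p == pytest.approx(rep.p_values.mean())
        assert rep.duration_mean_p == pytest.approx(rep.p_values[:10].mean())

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            within_home_change(_samples(rng.normal(size=(2, 14))), 1, 1)

    def test_type_one_error_calibrated_under_null(self, rng):
        """Per-feature rejection rate at α=0.05 within [0.02, 0.08] over 500
        null replications."""
        rejections = 0
        trials = 0
        for _ in range(500):
            thetas = rng.normal(size=(40, 14))
            rep = within_home_change(_samples(thetas), 20, 20)
            rejections += int(rep.significant.sum())
            trials += 14
        rate = rejections / trials
        assert 0.02 <= rate <= 0.08


class TestAnova:
    def test_f_statistic_matches_hand_computed_fixture(self):
        """Two groups of three: groups (1,2,3) and (3,4,5).
        Grand mean 3; SSB = 3·(2−3)² + 3·(4−3)² = 6, MSB = 6.
        SSW = 2+2 = 4, MSW = 4/4 = 1 → F = 6."""
        thetas = np.zeros((6, 14))
        thetas[:, 0] = [1, 2, 3, 3, 4, 5]
        samples = _samples(thetas[:3], home="a") + _samples(thetas[3:], home="b")
        rep = between_home_anova(samples)
        assert rep.statistic[0] == pytest.approx(6.0)

    def test_one_home_shifted_on_o_toilet_is_flagged(self, rng):
        a = rng.normal(size=(12, 14))
        b = rng.normal(size=(12, 14))
        b[:, TOILET_O] += 3.0
        rep = between_home_anova(_samples(a, home="a") + _samples(b, home="b"))
        assert rep.p_values[TOILET_O] < 0.01

    def test_null_mean_p_is_near_half(self, rng):
        """Under exchangeable homes, p-values are uniform: the overall mean
        p over 200 replications sits near 0.5."""
        means = []
        for _ in range(200):
            a = rng.normal(size=(8, 14))
            b = rng.normal(size=(8, 14))
            rep = between_home_anova(_samples(a, home="a") + _samples(b, home="b"))
            means.append(rep.overall_mean_p)
        assert abs(np.mean(means) - 0.5) < 0.1

    def test_single_sample_homes_are_excluded(self, rng):
        good = _samples(rng.normal(size=(5, 14)), home="a") + _samples(
            rng.normal(size=(5, 14)), home="b"
        )
        lone = _samples(rng.normal(size=(1, 14)), home="c")
        with pytest.warns(UserWarning, match="fewer than 2"):
            rep = between_home_anova(good + lone)
        assert np.all(rep.p_values <= 1.0)

    def test_identical_groups_give_p_one(self):
        theta = np.tile(np.arange(14.0), (4, 1))
        samples = _samples(theta, home="a", label="healthy") + _samples(
            theta, home="b", label="decline"
        )
        rep = between_group_anova(samples)
        assert np.all(rep.p_values == 1.0)

    def test_shuffled_labels_rarely_significant(self, rng):
        """Between-group ANOVA under label permutation: every feature is
        non-significant in at least 90% of the null replications (1000 reps,
        where the binomial noise of the 10% cutoff is negligible), and the
        pooled rejection rate stays calibrated around α."""
        flags = np.zeros(14)
        reps = 1000
        for _ in range(reps):
            thetas = rng.normal(size=(16, 14))
            labels = np.array(["healthy"] * 8 + ["decline"] * 8)
            rng.shuffle(labels)
            samples = [
                PreferenceSample("h%d" % (i // 2), i, thetas[i], labels[i])
                for i in range(16)
            ]
            rep = between_group_anova(samples)
            flags += rep.significant
        assert 0.02 <= flags.sum() / (14 * reps) <= 0.08
        assert np.all(flags / reps <= 0.10)


class TestClassifier:
    def _separable(self, rng, n=12):
        # d_bedroom occupies disjoint ranges per class; the other features
        # carry no variation, so every split must use the separator
        healthy = np.zeros((n, 14))
        decline = np.zeros((n, 14))
        healthy[:, BED] = rng.uniform(0.0, 0.25, size=n)
        decline[:, BED] = rng.uniform(0.75, 1.0, size=n)
        out = []
        for mat, label, homes in (
            (healthy, "healthy", ("h1", "h2")),
            (decline, "decline", ("d1", "d2")),
        ):
            for i, t in enumerate(mat):
                out.append(
                    PreferenceSample(homes[i % 2], i, t, label)
                )
        return out

    def test_separable_cohort_is_classified_perfectly(self, rng):
        result = classify_diagnosis(self._separable(rng), seed=0)
        assert result.accuracy == 1.0
        assert result.precision == result.recall == result.f1 == 1.0

    def test_importances_sum_to_one_and_rank_the_separator(self, rng):
        result = classify_diagnosis(self._separable(rng), seed=0)
        assert result.importances.sum() == pytest.approx(1.0)
        assert int(np.argmax(result.importances)) == BED

    def test_f1_identity_holds(self, rng):
        thetas = rng.normal(size=(20, 14))
        labels = ["healthy"] * 10 + ["decline"] * 10
        samples = [
            PreferenceSample("h%d" % i, i, thetas[i], labels[i]) for i in range(20)
        ]
        res = classify_diagnosis(samples, seed=1)
        if res.precision + res.recall > 0:
            expected = 2 * res.precision * res.recall / (res.precision + res.recall)
            assert res.f1 == pytest.approx(expected)

    def test_shuffled_labels_accuracy_near_class_prior(self, rng):
        """Null check: with labels shuffled the LOO accuracy stays within
        ±0.15 of the majority-class prior over 20 replications."""
        accs = []
        for _ in range(20):
            thetas = rng.normal(size=(20, 14))
            labels = np.array(["healthy"] * 10 + ["decline"] * 10)
            rng.shuffle(labels)
            samples = [
                PreferenceSample("h%d" % i, i, thetas[i], labels[i])
                for i in range(20)
            ]
            accs.append(classify_diagnosis(samples, seed=2).accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            classify_diagnosis(_samples(rng.normal(size=(6, 14))), seed=0)

    def test_leave_one_home_out_mode(self, rng):
        res = classify_diagnosis(self._separable(rng), seed=0, by_home=True)
        assert res.accuracy == 1.0


class TestLearnWindowVectors:
    def test_month_and_day_window_counts(self, sim_floorplan):
        home = ri.simulate_home("h", sim_floorplan, ri.recovery_profile(), 61, seed=9)
        data = ri.prepare_home(home.events, sim_floorplan)
        cfg = ri.IrlConfig(max_iter=100)
        months = learn_window_vectors({"h": data}, window="month", irl_config=cfg)
        assert len(months) == 2  # 61 days -> two complete 30-day windows
        days = learn_window_vectors({"h": data}, window="day", irl_config=cfg)
        assert len(days) == len(data.days)
        assert [s.window_id for s in months] == [0, 1]

    def test_stationary_resident_monthly_vectors_cluster_by_home(self, sim_floorplan):
        """Month-θ of one stationary resident are mutually closer (cosine)
        than θ across two residents with different preferences."""
        cfg = ri.IrlConfig(max_iter=500)
        homes = {}
        for name, prof in (("a", ri.healthy_profile(False)), ("b", ri.decline_profile(False))):
            sim = ri.simulate_home(name, sim_floorplan, prof, 60, seed=33)
            homes[name] = ri.prepare_home(sim.events, sim_floorplan)
        samples = learn_window_vectors(homes, window="month", irl_config=cfg)
        by_home = {}
        for s in samples:
            by_home.setdefault(s.home_id, []).append(s.theta)

        def cos(u, v):
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        within = cos(*by_home["a"])
        across = np.mean(
            [cos(u, v) for u in by_home["a"] for v in by_home["b"]]
        )
        assert within > across
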