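"""Matching/categorization decoding and silencing ablations on planted codes."""

import numpy as np
import pandas as pd
import pytest

from numsense import behavior
from numsense.behavior import (
    MatchingTrialSet,
    build_matching_trials,
    categorize_numerosity,
    choose_silencing,
    matching_study,
    performance_fits,
    silencing_study,
    train_test_matching,
)

NUMS = (0, 1, 2, 3, 4)


def graded_code(n, rng, sd=0.25, n_units=20):
    """Population code: unit u prefers numerosity u%5 with Gaussian tuning."""
    prefs = np.arange(n_units) % 5
    resp = np.exp(-0.5 * ((n - prefs) / 1.0) ** 2)
    return resp + sd * rng.standard_normal(n_units)


def make_trials(n_trials, rng, code=graded_code, numerosities=NUMS):
    rows, sa, ta = [], [], []
    for t in range(n_trials):
        same = t % 2 == 0
        s = int(numerosities[rng.integers(len(numerosities))])
        q = s if same else int(
            [n for n in numerosities if n != s][rng.integers(len(numerosities) - 1)]
        )
        rows.append({"trial": t, "sample_numerosity": s, "test_numerosity": q,
                     "same": s == q})
        sa.append(code(s, rng))
        ta.append(code(q, rng))
    return MatchingTrialSet(pd.DataFrame(rows), np.array(sa), np.array(ta))


class TestMatching:
    def test_balance_and_determinism_with_pixel_recorder(self):
        recorder = lambda imgs: imgs.reshape(len(imgs), -1).sum(1, keepdims=True)
        rng = np.random.default_rng(0)
        ts = build_matching_trials(recorder, 60, (0, 1, 2), rng, image_size=112)
        assert ts.n_trials == 60
        assert ts.labels.sum() == 30
        ts2 = build_matching_trials(
            recorder, 60, (0, 1, 2), np.random.default_rng(0), image_size=112
        )
        pd.testing.assert_frame_equal(ts.trials, ts2.trials)
        np.testing.assert_array_equal(ts.sample_acts, ts2.sample_acts)

    def test_set_restriction(self):
        seen = []

        def recorder(imgs):
            seen.append(imgs)
            return imgs.reshape(len(imgs), -1)[:, :3]

        rng = np.random.default_rng(1)
        ts = build_matching_trials(
            recorder, 10, (0, 1), rng, sets=("control1",), image_size=112
        )
        # control1 zero stimuli carry the raised luminance-equating background
        zero_rows = ts.trials["sample_numerosity"] == 0
        assert zero_rows.any()

    def test_argument_validation(self):
        rec = lambda imgs: imgs.reshape(len(imgs), -1)
        with pytest.raises(ValueError, match="n_trials"):
            build_matching_trials(rec, 0, NUMS, np.random.default_rng(0))
        with pytest.raises(ValueError, match="empty"):
            build_matching_trials(rec, 4, (), np.random.default_rng(0))

    def test_perfect_code_reaches_ceiling(self):
        rng = np.random.default_rng(2)
        one_hot = lambda n, r: np.eye(5)[n] + 0.01 * r.standard_normal(5)
        code = lambda n, r=rng: one_hot(n, r)
        res = train_test_matching(make_trials(300, rng, code),
                                  make_trials(300, rng, code))
        assert res.accuracy > 0.97

    def test_shuffled_labels_fall_to_chance(self):
        rng = np.random.default_rng(3)
        train = make_trials(400, rng)
        # shuffle the labels: responses carry no information about same/diff
        train.trials["same"] = rng.permutation(train.trials["same"].to_numpy())
        test = make_trials(400, rng)
        res = train_test_matching(train, test)
        # binomial noise around 0.5 at n=400: 3 sigma ~ 0.075
        assert abs(res.accuracy - 0.5) < 0.08

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(4)
        train = make_trials(40, rng)
        train.trials["same"] = True
        with pytest.raises(ValueError, match="single class"):
            train_test_matching(train, make_trials(40, rng))

    def test_performance_function_peaks_at_sample(self):
        rng = np.random.default_rng(5)
        res = train_test_matching(make_trials(600, rng), make_trials(600, rng))
        for pf in res.performance:
            i = list(pf.test_numerosities).index(pf.sample_numerosity)
            with np.errstate(invalid="ignore"):
                assert np.nanargmax(pf.p_same) == i

    def test_zero_distance_effect(self):
        rng = np.random.default_rng(6)
        res = train_test_matching(make_trials(800, rng), make_trials(800, rng))
        pf0 = next(p for p in res.performance if p.sample_numerosity == 0)
        assert pf0.p_same[1] > pf0.p_same[2]

    def test_matching_study_aggregates(self):
        def recorder_factory(seed):
            r = np.random.default_rng(seed)
            return lambda imgs: np.stack(
                [graded_code(int(img.sum() // 400), r) for img in imgs]
            )

        # recorder decodes numerosity from summed area of standard displays
        study = matching_study(
            recorder_factory, n_reps=2, n_train=40, n_test=40,
            numerosities=(0, 1, 2), sets=("standard",), base_seed=0,
            image_size=112,
        )
        assert len(study.per_rep) == 2
        assert 0 <= study.accuracy <= 1
        assert len(study.performance) == 3


class TestPerformanceFits:
    def _functions(self, widths):
        nums = np.arange(5)
        return [
            behavior.PerformanceFunction(
                s, nums, np.exp(-0.5 * ((nums - s) / w) ** 2), np.zeros(5)
            )
            for s, w in enumerate(widths)
        ]

    def test_planted_widths_recovered(self):
        fits = performance_fits(self._functions([0.5, 0.7, 0.9, 1.1, 1.3]))
        assert fits.size_effect_r > 0.9

    def test_flat_function_excluded(self):
        funcs = self._functions([0.5, 0.7, 0.9, 1.1])
        nums = np.arange(5)
        funcs.append(
            behavior.PerformanceFunction(4, nums, np.full(5, 0.5), np.zeros(5))
        )
        fits = performance_fits(funcs)
        assert 4 in fits.excluded

    def test_too_few_functions_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            performance_fits(self._functions([1.0, 1.0]))

    def test_log_symmetric_functions_prefer_log_axis(self):
        from numsense import tuning

        nums = np.arange(9)
        xl = tuning.log_axis(nums)
        funcs = [
            behavior.PerformanceFunction(
                s, nums,
                np.exp(-0.5 * ((xl - np.log2(s + 1)) / 0.45) ** 2),
                np.zeros(9),
            )
            for s in (1, 2, 3, 4, 5)
        ]
        fits = performance_fits(funcs)
        assert fits.scale is not None
        assert fits.scale.mean_r2_log > fits.scale.mean_r2_linear


def zero_gated_code(labels, rng, n_units=60, noise=0.05):
    """Numerosity 0 is carried ONLY by the first 12 designated zero units;
    countable numerosities are carried by disjoint unit groups."""
    prefs = np.repeat(np.arange(5), n_units // 5)
    X = noise * rng.standard_normal((len(labels), n_units))
    for i, y in enumerate(labels):
        X[i, prefs == y] += 1.0
    return X, prefs


class TestCategorization:
    def test_chance_level_for_uninformative_features(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(NUMS, 60)
        X = rng.standard_normal((len(labels), 30))
        res = categorize_numerosity(X, labels, rng=np.random.default_rng(1))
        assert abs(res.accuracy - 0.2) < 0.1  # five balanced classes

    def test_confusion_matrix_bookkeeping(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(NUMS, 40)
        X, _ = zero_gated_code(labels, rng)
        res = categorize_numerosity(X, labels, rng=np.random.default_rng(2))
        cm = res.confusion
        assert cm.counts.sum() == len(labels) - len(labels) // 2
        np.testing.assert_allclose(cm.rates.sum(axis=1), 1.0)
        assert cm.accuracy == pytest.approx(
            np.trace(cm.counts) / cm.counts.sum()
        )
        assert res.accuracy > 0.9

    def test_empty_silencing_equals_none(self):
        rng = np.random.default_rng(2)
        labels = np.repeat(NUMS, 20)
        X, prefs = zero_gated_code(labels, rng)
        a = categorize_numerosity(X, labels, rng=np.random.default_rng(3))
        sil = behavior.SilencingCondition("none", np.array([], int))
        b = categorize_numerosity(
            X, labels, rng=np.random.default_rng(3), silencing=sil
        )
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)

    def test_out_of_range_silencing_rejected(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(NUMS, 10)
        X, _ = zero_gated_code(labels, rng)
        sil = behavior.SilencingCondition("zero_tuned", np.array([999]))
        with pytest.raises(ValueError, match="subset"):
            categorize_numerosity(X, labels, silencing=sil)

    def test_silencing_zero_units_collapses_zero_only(self):
        rng = np.random.default_rng(4)
        labels = np.repeat(NUMS, 60)
        X, prefs = zero_gated_code(labels, rng)
        split = np.random.default_rng(5)
        intact = categorize_numerosity(X, labels, rng=np.random.default_rng(5))
        zs = choose_silencing(prefs, "zero_tuned")
        silenced = categorize_numerosity(
            X, labels, rng=np.random.default_rng(5), silencing=zs
        )
        assert intact.tpr[0] > 0.9
        assert silenced.tpr[0] < 0.4  # zero class collapses toward chance
        np.testing.assert_allclose(silenced.tpr[1:], intact.tpr[1:], atol=0.1)

    def test_matched_random_silencing_spares_zero(self):
        rng = np.random.default_rng(6)
        labels = np.repeat(NUMS, 60)
        X, prefs = zero_gated_code(labels, rng)
        rs = choose_silencing(prefs, "random_nonzero_matched",
                              rng=np.random.default_rng(7))
        assert len(rs.unit_ids) == np.sum(prefs == 0)
        assert not np.any(prefs[rs.unit_ids] == 0)
        res = categorize_numerosity(
            X, labels, rng=np.random.default_rng(8), silencing=rs
        )
        assert res.tpr[0] > 0.9

    def test_error_trial_evaluation(self):
        rng = np.random.default_rng(7)
        labels = np.repeat(NUMS, 20)
        X, _ = zero_gated_code(labels, rng)
        err_labels = np.array([0, 1, 2, 3, 4])
        err_X = rng.standard_normal((5, X.shape[1]))  # uninformative errors
        res = categorize_numerosity(
            X, labels, rng=np.random.default_rng(8),
            error_acts=err_X, error_labels=err_labels,
        )
        assert res.error_accuracy is not None
        assert res.error_accuracy <= res.accuracy


@pytest.fixture(scope="module")
def code():
    rng = np.random.default_rng(0)
    labels = np.repeat(NUMS, 60)
    X, prefs = zero_gated_code(labels, rng)
    return X, labels, prefs


class TestSilencingStudy:

    def test_zero_silencing_significant_random_not(self, code):
        X, labels, prefs = code
        study = silencing_study(X, labels, prefs, n_reps=10, base_seed=1)
        assert study.zero_tpr_mean["none"] > 0.9
        assert study.zero_tpr_mean["zero_tuned"] < 0.4
        _, p_zero = study.tests[("none", "zero_tuned")]
        _, p_rand = study.tests[("none", "random_nonzero_matched")]
        assert p_zero < 0.01
        assert p_rand > 0.05

    def test_per_class_silencing_hits_only_that_class(self, code):
        X, labels, prefs = code
        study = silencing_study(
            X, labels, prefs, modes=("none",), ks=(3,), n_reps=6, base_seed=2
        )
        tpr_none = study.tpr["none"].mean(axis=0)
        tpr_k = study.tpr["class:3"].mean(axis=0)
        assert tpr_none[3] - tpr_k[3] > 0.5
        others = [i for i in range(5) if i != 3]
        np.testing.assert_allclose(tpr_k[others], tpr_none[others], atol=0.1)

    def test_identical_conditions_give_p_one(self, code):
        X, labels, prefs = code
        # with no zero-tuned units the "zero_tuned" condition silences nothing
        study = silencing_study(
            X, labels, np.where(prefs == 0, 1, prefs),
            modes=("none", "zero_tuned"), n_reps=5, base_seed=3,
        )
        _, p = study.tests[("none", "zero_tuned")]
        assert p == 1.0

    def test_too_few_reps_rejected(self, code):
        X, labels, prefs = code
        with pytest.raises(ValueError, match="repetitions"):
            silencing_study(X, labels, prefs, n_reps=2)
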