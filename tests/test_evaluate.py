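"""Accuracy metrics, cross-validation protocol, shuffled controls."""

import numpy as np
import pandas as pd
import pytest

from myodecode.evaluate import (
    correlation,
    crossvalidate,
    make_folds,
    pruning_stats,
    scaled_cv_sizes,
    shuffle_control,
    sliding_window_eval,
    sliding_window_medians,
    vaf,
)
from myodecode.session import RunConfig


class TestVaf:
    def test_perfect_reconstruction_scores_one(self, rng):
        y = rng.standard_normal(100)
        assert vaf(y, y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self, rng):
        y = rng.standard_normal(100)
        assert vaf(y, np.full(100, y.mean())) == pytest.approx(0.0)

    def test_worked_example(self):
        assert vaf([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_can_be_negative(self, rng):
        y = rng.standard_normal(100)
        assert vaf(y, -5.0 * y) < 0.0

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            vaf(np.ones(10), np.zeros(10))

    def test_correlation_bounds(self, rng):
        y = rng.standard_normal(50)
        assert correlation(y, y) == pytest.approx(1.0)
        assert correlation(y, -y) == pytest.approx(-1.0)


class TestFolds:
    def test_protocol_sizes_at_129_trials(self, rng):
        folds = make_folds(129, 6, 108, 21, rng)
        assert len(folds) == 6
        tests = [set(te) for _, te in folds]
        for tr, te in folds:
            assert len(tr) == 108 and len(te) == 21
            assert not set(tr) & set(te)
        # disjoint test sets across folds
        all_test = set().union(*tests)
        assert len(all_test) == 6 * 21

    def test_seeded_folds_reproducible(self):
        f1 = make_folds(60, 6, 40, 10, np.random.default_rng(3))
        f2 = make_folds(60, 6, 40, 10, np.random.default_rng(3))
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_too_few_trials_rejected_with_hint(self, rng):
        with pytest.raises(ValueError, match="scale"):
            make_folds(50, 6, 108, 21, rng)

    def test_scaled_sizes(self):
        assert scaled_cv_sizes(129) == (108, 21)
        n_train, n_test = scaled_cv_sizes(60)
        assert n_train + n_test <= 60


class TestShuffleControl:
    def test_multiset_preserved_per_channel(self, rng):
        x = rng.standard_normal((3, 1000))
        shuf = shuffle_control(x, 100, rng)
        for c in range(3):
            np.testing.assert_array_equal(np.sort(shuf[c]), np.sort(x[c]))
        assert not np.allclose(shuf, x)

    def test_channels_shuffled_independently(self, rng):
        x = np.tile(np.arange(1000.0), (2, 1))
        shuf = shuffle_control(x, 100, np.random.default_rng(0))
        assert not np.array_equal(shuf[0], shuf[1])

    def test_single_block_is_identity_with_warning(self, rng):
        x = rng.standard_normal((2, 100))
        with pytest.warns(UserWarning, match="identity"):
            shuf = shuffle_control(x, 100, rng)
        np.testing.assert_array_equal(shuf, x)

    def test_trailing_partial_block_stays(self, rng):
        x = rng.standard_normal((1, 250))
        shuf = shuffle_control(x, 100, rng)
        np.testing.assert_array_equal(shuf[0, 200:], x[0, 200:])


class TestCrossValidate:
    def test_noiseless_session_reaches_vaf_099(self, noiseless_bundle):
        b = noiseless_bundle
        cv = crossvalidate(b.emg, b.inputs, b.classes, b.run_cfg, seed=2,
                           variants=("both",))
        means = cv.session_means()
        assert (means["vaf"] >= 0.99).all()

    def test_fixed_seed_reproduces_metrics(self, noiseless_bundle):
        b = noiseless_bundle
        cv1 = crossvalidate(b.emg, b.inputs, b.classes, b.run_cfg, seed=4,
                            variants=("both",), collect_traces=False)
        cv2 = crossvalidate(b.emg, b.inputs, b.classes, b.run_cfg, seed=4,
                            variants=("both",), collect_traces=False)
        pd.testing.assert_frame_equal(cv1.metrics, cv2.metrics)

    def test_full_model_beats_single_input_models(self, noisy_bundle):
        b = noisy_bundle
        cv = crossvalidate(b.emg, b.inputs, b.classes, b.run_cfg, seed=2,
                           collect_traces=False)
        by_var = cv.session_means().groupby("variant")["vaf"].mean()
        assert by_var["both"] > by_var["descending"]
        assert by_var["both"] > by_var["afferent"]

    def test_shuffled_training_destroys_prediction(self, noisy_bundle):
        from myodecode.preprocess import epoch_and_baseline

        b = noisy_bundle
        cont = np.concatenate([b.truth.descending, b.truth.afferent], axis=0)
        shuf = shuffle_control(cont, 400, np.random.default_rng(13))
        shuf_tensor = epoch_and_baseline(
            shuf, b.truth.events, list(b.inputs.labels), "inputs"
        )
        cv = crossvalidate(
            b.emg, b.inputs, b.classes, b.run_cfg, seed=2,
            variants=("both", "shuffled"), shuffled_inputs=shuf_tensor,
            collect_traces=False,
        )
        by_var = cv.session_means().groupby("variant")["vaf"].mean()
        assert by_var["both"] >= 0.8
        assert by_var["shuffled"] <= 0.1

    def test_shuffled_inputs_pruned_more_than_true_inputs(self, full_support_bundle):
        """In a model mixing true descending with block-shuffled afferent
        inputs, the shuffled class is pruned far more often than the true
        afferent inputs are in the veridical model."""
        import dataclasses

        from myodecode.lagmodel import SparseLagRegression
        from myodecode.preprocess import epoch_and_baseline

        b = full_support_bundle
        shuf = shuffle_control(b.truth.afferent, 400, np.random.default_rng(13))
        shuf_aff = epoch_and_baseline(
            shuf, b.truth.events, list(b.afferent.labels), "afferent"
        )
        n_desc = b.descending.n_entities
        mixed_values = np.concatenate(
            [b.inputs.values[:n_desc], shuf_aff.values], axis=0
        )
        mixed = dataclasses.replace(b.inputs, values=mixed_values)
        res_true = SparseLagRegression(b.emg, b.inputs, b.classes).fit()
        res_mixed = SparseLagRegression(b.emg, mixed, b.classes).fit()
        true_kept = res_true.retained_proportion("afferent").mean()
        shuf_kept = res_mixed.retained_proportion("afferent").mean()
        assert true_kept >= 0.9
        assert shuf_kept <= 0.6
        assert shuf_kept < true_kept


def test_sliding_window_contrast(sliding_table):
    """Post-onset windows gain accuracy from afferent inputs; the earliest
    (pre-onset) window does not."""
    med = sliding_window_medians(sliding_table)
    pv = med.pivot_table(index="window_center_ms", columns="variant",
                         values="vaf", aggfunc="mean")
    delta = pv["both"] - pv["descending"]
    pre = delta[delta.index <= -200.0]
    post = delta[(delta.index >= 200.0) & (delta.index <= 900.0)]
    assert (pre < 0.05).all()
    assert post.mean() > 0.1

def test_sliding_window_nonoverlapping_partition_count(noiseless_bundle):
    import dataclasses

    b = noiseless_bundle
    cfg = dataclasses.replace(b.run_cfg, sliding_window_ms=500.0, sliding_step_ms=500.0)
    table = sliding_window_eval(b.emg, b.inputs, b.classes, cfg, seed=3,
                                variants=("both",))
    # target span is 1950 ms -> floor(1950 / 500) = 3 non-overlapping windows
    assert table["window_center_ms"].nunique() == 3


def test_pruning_stats_bounds(noisy_results):
    table = pruning_stats(noisy_results)
    assert set(table["input_class"]) == {"descending", "afferent"}
    assert table["retained"].between(0.0, 1.0).all()
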