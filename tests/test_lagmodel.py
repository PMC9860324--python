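"""Lag embedding and the grouped-ARD sparse decoder."""

import numpy as np
import pytest

from myodecode.lagmodel import (
    LagSpec,
    SparseLagRegression,
    ard_group_fit,
    build_design,
    build_targets,
)
from myodecode.tensors import TrialTensor

TIMES = np.arange(-500, 1505, 5.0)


def make_tensor(values, kind="inputs"):
    values = np.asarray(values, dtype=float)
    labels = [f"ch{i}" for i in range(values.shape[0])]
    return TrialTensor(values, TIMES[: values.shape[2]], labels, kind=kind)


class TestLagSpec:
    def test_defaults_cover_5_to_50_ms(self):
        spec = LagSpec()
        assert spec.n_lags == 10
        assert spec.lags[0] == -10 and spec.lags[-1] == -1

    def test_nonnegative_lags_rejected(self):
        with pytest.raises(ValueError):
            LagSpec(l_min=-5, l_max=0)


class TestBuildDesign:
    def test_ramp_column_for_lag_minus_one_holds_previous_bin(self):
        ramp = np.arange(401.0)[None, None, :]
        X, targets = build_design(make_tensor(ramp))
        assert targets[0] == 10  # first valid target bin = -450 ms
        # column for l = -1 is the last lag column of the channel
        np.testing.assert_array_equal(X[:, 9], targets - 1.0)
        np.testing.assert_array_equal(X[:, 0], targets - 10.0)

    def test_three_channels_give_thirty_columns(self, rng):
        X, _ = build_design(make_tensor(rng.standard_normal((3, 2, 401))))
        assert X.shape == (2 * 391, 30)

    def test_rows_never_mix_trials(self, rng):
        vals = rng.standard_normal((1, 2, 401))
        X, targets = build_design(make_tensor(vals))
        # first row of trial 2 must draw history from trial 2 only
        row = X[391]
        np.testing.assert_array_equal(row, vals[0, 1, 0:10])

    def test_trial_shorter_than_history_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            build_design(make_tensor(rng.standard_normal((1, 1, 8))))


class TestArdGroupFit:
    def test_zero_targets_prune_everything(self, rng):
        X = rng.standard_normal((200, 20))
        fit = ard_group_fit(X, np.zeros(200), np.repeat(np.arange(2), 10))
        assert np.all(fit.weights == 0.0)
        assert fit.pruned.all()

    def test_recovers_single_relevant_channel_weight(self, rng):
        # noiseless target = 2 x channel 1 at lag -1; 20 channels, 5000 rows
        n_ch, n_lags, n_rows = 20, 10, 5000
        X = rng.standard_normal((n_rows, n_ch * n_lags))
        w_true = np.zeros(n_ch * n_lags)
        w_true[9] = 2.0  # channel 0, lag -1
        y = X @ w_true
        fit = ard_group_fit(X, y, np.repeat(np.arange(n_ch), n_lags))
        assert fit.weights[9] == pytest.approx(2.0, rel=0.01)
        assert fit.pruned[1:].sum() >= 18
        w_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        kept = ~fit.pruned[np.repeat(np.arange(n_ch), n_lags)]
        big = np.abs(w_ols) > 1e-6
        match = kept & big
        assert np.allclose(fit.weights[match], w_ols[match], rtol=0.01)

    def test_deterministic_given_data(self, rng):
        X = rng.standard_normal((400, 30))
        y = X[:, 3] - 0.5 * X[:, 17] + 0.1 * rng.standard_normal(400)
        groups = np.repeat(np.arange(3), 10)
        f1 = ard_group_fit(X, y, groups)
        f2 = ard_group_fit(X, y, groups)
        np.testing.assert_array_equal(f1.weights, f2.weights)
        np.testing.assert_array_equal(f1.alpha, f2.alpha)
        assert f1.n_iter == f2.n_iter

    def test_nonfinite_inputs_rejected(self, rng):
        X = rng.standard_normal((100, 10))
        y = X[:, 0].copy()
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ard_group_fit(X, y, np.zeros(10, dtype=int))

    def test_pruned_channels_have_exactly_zero_weights(self, noisy_results):
        w_norms = np.linalg.norm(noisy_results.weights, axis=2)
        assert np.all(w_norms[noisy_results.pruned] == 0.0)


class TestModelResults:
    def test_noiseless_fit_matches_least_squares_oracle(self, noiseless_bundle, noiseless_results):
        b = noiseless_bundle
        X, targets = build_design(b.inputs)
        Y = build_targets(b.emg, targets)
        w_ols = np.linalg.lstsq(X, Y, rcond=None)[0].T.reshape(
            b.emg.n_entities, b.inputs.n_entities, 10
        )
        w = noiseless_results.weights
        big = np.abs(w_ols) > 1e-6 * np.abs(w_ols).max()
        assert np.allclose(w[big], w_ols[big], rtol=0.01)

    def test_noiseless_prediction_is_near_perfect(self, noiseless_bundle, noiseless_results):
        from myodecode.evaluate import vaf

        pred = noiseless_results.predict()
        for j in range(noiseless_bundle.emg.n_entities):
            assert vaf(noiseless_bundle.emg.values[j, :, 10:], pred.values[j]) >= 0.99

    def test_prediction_linear_in_inputs(self, noiseless_bundle, noiseless_results):
        import dataclasses

        b = noiseless_bundle
        doubled = dataclasses.replace(b.inputs, values=2.0 * b.inputs.values)
        p1 = noiseless_results.predict(b.inputs)
        p2 = noiseless_results.predict(doubled)
        np.testing.assert_allclose(p2.values, 2.0 * p1.values, rtol=1e-12)

    def test_zero_weight_model_predicts_zero(self, noiseless_bundle, noiseless_results):
        import copy

        res = copy.deepcopy(noiseless_results)
        res.weights = np.zeros_like(res.weights)
        assert np.all(res.predict().values == 0.0)

    def test_reconstruction_causality(self, noiseless_bundle, noiseless_results):
        """Changing inputs at bins >= t leaves the reconstruction at t unchanged."""
        import dataclasses

        b = noiseless_bundle
        cut = 200  # tensor bin index; target index cut-10
        vals = b.inputs.values.copy()
        vals[:, :, cut:] += 5.0
        pert = dataclasses.replace(b.inputs, values=vals)
        p1 = noiseless_results.predict(b.inputs)
        p2 = noiseless_results.predict(pert)
        np.testing.assert_array_equal(
            p1.values[:, :, : cut - 10], p2.values[:, :, : cut - 10]
        )

    def test_channel_mismatch_rejected(self, noiseless_bundle, noiseless_results):
        with pytest.raises(ValueError, match="channels"):
            noiseless_results.predict(noiseless_bundle.inputs.select_entities([0, 1]))

    def test_restricted_variant_drops_other_class(self, noiseless_bundle):
        b = noiseless_bundle
        model = SparseLagRegression(b.emg, b.inputs, b.classes)
        desc_only = model.restricted("descending")
        assert all(c == "descending" for c in desc_only.channel_classes)
        assert desc_only.inputs.n_entities == (b.classes == "descending").sum()
        both = model.restricted("both")
        assert both.inputs.n_entities == b.inputs.n_entities

    def test_descending_only_cannot_explain_afferent_driven_muscle(self, noisy_bundle):
        """A muscle driven purely by afferent input is unexplained by the
        descending-only model on held-out trials."""
        from myodecode.evaluate import vaf
        from myodecode.synthetic import forward_emg

        b = noisy_bundle
        rng = np.random.default_rng(99)
        aff_vals = b.afferent.values
        w = np.zeros((1, aff_vals.shape[0], 10))
        w[0, 2, :] = np.linspace(0.5, 1.5, 10)
        flat = forward_emg(
            aff_vals.reshape(aff_vals.shape[0], -1), w
        ).reshape(1, b.afferent.n_trials, -1)
        flat += 0.05 * flat.std() * rng.standard_normal(flat.shape)
        emg = TrialTensor(flat, b.emg.times, ["aff_muscle"], kind="emg")
        train = np.arange(0, 60)
        test = np.arange(60, 80)
        desc = b.descending
        model = SparseLagRegression(
            emg.select_trials(train), desc.select_trials(train),
            np.array(["descending"] * desc.n_entities),
        )
        res = model.fit()
        pred = res.predict(desc.select_trials(test))
        score = vaf(emg.values[0, test, 10:], pred.values[0])
        assert score < 0.1

    def test_support_recovery_at_default_noise(self, noisy_bundle, noisy_results):
        truth = noisy_bundle.truth
        sup = truth.support_mask
        retained_true = (~noisy_results.pruned[:, sup]).mean()
        pruned_null = noisy_results.pruned[:, ~sup].mean()
        assert retained_true >= 0.8
        assert pruned_null >= 0.8

    def test_summary_mentions_every_muscle(self, noisy_results):
        text = noisy_results.summary()
        for name in noisy_results.muscle_names:
            assert name in text
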