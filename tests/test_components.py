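"""Linear attribution: component additivity, sizes, area splits, signs."""

import numpy as np
import pytest

from myodecode.components import (
    ComponentTrace,
    component,
    component_size,
    initial_movement_afferent_size,
    per_area_components,
    size_table,
)


class TestComponent:
    def test_all_channels_equals_full_reconstruction(self, noiseless_bundle, noiseless_results):
        full = noiseless_results.predict()
        comp = component(noiseless_results, noiseless_bundle.inputs, "all")
        np.testing.assert_array_equal(comp.values, full.values)

    def test_empty_subset_gives_zero_trace(self, noiseless_bundle, noiseless_results):
        comp = component(noiseless_results, noiseless_bundle.inputs, [])
        assert np.all(comp.values == 0.0)

    def test_descending_plus_afferent_equals_full(self, noisy_bundle, noisy_results):
        full = noisy_results.predict()
        desc = component(noisy_results, noisy_bundle.inputs, "descending")
        aff = component(noisy_results, noisy_bundle.inputs, "afferent")
        scale = np.abs(full.values).max()
        assert np.abs(desc.values + aff.values - full.values).max() < 1e-12 * scale

    def test_per_electrode_partition_sums_to_full(self, noiseless_bundle, noiseless_results):
        full = noiseless_results.predict()
        total = np.zeros_like(full.values)
        for k in range(noiseless_bundle.inputs.n_entities):
            total += component(noiseless_results, noiseless_bundle.inputs, [k]).values
        scale = np.abs(full.values).max()
        assert np.abs(total - full.values).max() < 1e-12 * scale

    def test_component_invariant_to_inputs_outside_subset(self, noiseless_bundle, noiseless_results):
        import dataclasses

        b = noiseless_bundle
        desc_idx = np.nonzero(b.classes == "descending")[0]
        comp1 = component(noiseless_results, b.inputs, desc_idx)
        vals = b.inputs.values.copy()
        vals[b.classes == "afferent"] += 3.0
        comp2 = component(
            noiseless_results, dataclasses.replace(b.inputs, values=vals), desc_idx
        )
        np.testing.assert_array_equal(comp1.values, comp2.values)

    def test_unknown_channel_rejected(self, noiseless_bundle, noiseless_results):
        with pytest.raises(ValueError, match="unknown channel"):
            component(noiseless_results, noiseless_bundle.inputs, ["nonsense"])


def make_trace(values, times):
    values = np.asarray(values, dtype=float)
    return ComponentTrace(
        values=values, times=np.asarray(times, dtype=float),
        muscle_names=[f"m{i}" for i in range(values.shape[0])],
        subset_label="test", channel_indices=np.arange(1),
    )


class TestComponentSize:
    times = np.arange(0, 1000, 5.0)

    def test_constant_positive_trace(self):
        tr = make_trace(np.ones((1, 1, 200)), self.times)
        assert component_size(tr, (0, 1000), "positive")[0] == pytest.approx(1.0)
        assert component_size(tr, (0, 1000), "negative")[0] == pytest.approx(0.0)

    def test_half_positive_half_negative(self):
        vals = np.concatenate([np.ones(100), -np.ones(100)])[None, None, :]
        tr = make_trace(vals, self.times)
        assert component_size(tr, (0, 1000), "positive")[0] == pytest.approx(0.5)
        assert component_size(tr, (0, 1000), "negative")[0] == pytest.approx(-0.5)
        # alternative denominator: mean over surviving bins only
        assert component_size(tr, (0, 1000), "positive", denominator="active")[0] == pytest.approx(1.0)

    def test_zero_trace_both_sizes_zero(self):
        tr = make_trace(np.zeros((2, 3, 200)), self.times)
        np.testing.assert_array_equal(component_size(tr, (0, 1000), "positive"), 0.0)
        np.testing.assert_array_equal(component_size(tr, (0, 1000), "negative"), 0.0)

    def test_window_outside_span_rejected(self):
        tr = make_trace(np.zeros((1, 1, 200)), self.times)
        with pytest.raises(ValueError, match="window"):
            component_size(tr, (2000, 3000), "positive")


class TestPerArea:
    def test_area_components_partition_descending(self, noisy_bundle, noisy_results):
        b = noisy_bundle
        areas = b.session.ecog_areas
        traces, table = per_area_components(noisy_results, b.inputs, areas)
        desc = component(noisy_results, b.inputs, "descending")
        total = sum(tr.values for tr in traces.values())
        scale = np.abs(desc.values).max()
        assert np.abs(total - desc.values).max() < 1e-12 * scale
        assert set(table["area"]) == set(areas)

    def test_single_area_equals_descending_component(self, noisy_bundle, noisy_results):
        b = noisy_bundle
        areas = ["M1"] * (b.classes == "descending").sum()
        traces, _ = per_area_components(noisy_results, b.inputs, areas)
        desc = component(noisy_results, b.inputs, "descending")
        np.testing.assert_allclose(traces["M1"].values, desc.values, atol=1e-12)

    def test_full_reconstruction_normalized_size_is_one(self, noisy_bundle, noisy_results):
        full = component(noisy_results, noisy_bundle.inputs, "all")
        size = component_size(full, (-100, 1150), "positive")
        norm = size / size
        np.testing.assert_allclose(norm, 1.0)

def test_area_concentration():
    """Weights placed only on M1-labelled channels make the M1 subcomponent
    dominate the per-area normalized sizes."""
    from myodecode.lagmodel import SparseLagRegression
    from myodecode.synthetic import SynthConfig, generate_session
    from myodecode.preprocess import epoch_and_baseline
    from myodecode.tensors import stack_inputs

    cfg = SynthConfig(
        n_ecog_channels=8, n_afferent_units=4, n_muscles=2, n_trials=40,
        trial_spacing_s=3.2, seed=31,
        descending_support_channels=[0, 1, 2],  # all M1 under the 45/30/25 split
        negative_afferent_fraction=0.0,
    )
    sess, truth = generate_session(cfg)
    assert all(sess.ecog_areas[k] == "M1" for k in [0, 1, 2])
    emg = epoch_and_baseline(truth.emg_mod, truth.events, sess.muscle_names, "emg")
    desc = epoch_and_baseline(truth.descending, truth.events, sess.ecog_labels, "descending")
    aff = epoch_and_baseline(truth.afferent, truth.events, sess.unit_labels, "afferent")
    inputs, classes = stack_inputs(desc, aff)
    res = SparseLagRegression(emg, inputs, classes).fit()
    _, table = per_area_components(res, inputs, sess.ecog_areas)
    wide = table.pivot(index="muscle", columns="area", values="normalized_size")
    assert (wide["M1"] > wide["PMd"]).all()
    assert (wide["M1"] > wide["PMv"]).all()


class TestInitialMovementSize:
    def test_agonist_positive_antagonist_negative(self, noisy_bundle, noisy_results):
        b = noisy_bundle
        aff = component(noisy_results, b.inputs, "afferent")
        sizes = initial_movement_afferent_size(aff, (55.0, 100.0))
        aff_w = b.truth.weights[:, (b.classes == "afferent"), :]
        net = aff_w.sum(axis=(1, 2))
        agonists = net > 0
        assert np.all(sizes[agonists] > 0)
        assert np.all(sizes[~agonists] < 0)

    def test_zero_afferent_weights_give_zero_size(self, noisy_bundle, noisy_results):
        import copy

        res = copy.deepcopy(noisy_results)
        res.weights[:, res.channel_classes == "afferent", :] = 0.0
        aff = component(res, noisy_bundle.inputs, "afferent")
        np.testing.assert_array_equal(
            initial_movement_afferent_size(aff, (55.0, 100.0)), 0.0
        )

    def test_window_outside_trace_rejected(self, noisy_bundle, noisy_results):
        aff = component(noisy_results, noisy_bundle.inputs, "afferent")
        with pytest.raises(ValueError, match="window"):
            initial_movement_afferent_size(aff, (1600.0, 1700.0))


def test_size_table_layout(noisy_bundle, noisy_results):
    table = size_table(noisy_results, noisy_bundle.inputs, (-100.0, 1150.0))
    assert set(table["subset"]) == {"all", "descending", "afferent"}
    assert set(table["sign"]) == {"positive", "negative"}
    assert len(table) == 6 * noisy_bundle.emg.n_entities
    assert (table.loc[table.sign == "positive", "size"] >= 0).all()
    assert (table.loc[table.sign == "negative", "size"] <= 0).all()
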