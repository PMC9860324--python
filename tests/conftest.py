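"""Shared fixtures: synthetic sessions at desk scale, epoched tensors,
and fitted decoders, generated once per test session."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from myodecode.lagmodel import SparseLagRegression
from myodecode.preprocess import epoch_and_baseline
from myodecode.session import RunConfig
from myodecode.synthetic import SynthConfig, generate_session
from myodecode.tensors import stack_inputs


def bundle_session(cfg: SynthConfig) -> SimpleNamespace:
    """Generate a session and epoch its exact modulation-domain traces."""
    session, truth = generate_session(cfg)
    emg = epoch_and_baseline(truth.emg_mod, truth.events, session.muscle_names, "emg")
    desc = epoch_and_baseline(
        truth.descending, truth.events, session.ecog_labels, "descending"
    )
    aff = epoch_and_baseline(truth.afferent, truth.events, session.unit_labels, "afferent")
    inputs, classes = stack_inputs(desc, aff)
    return SimpleNamespace(
        cfg=cfg,
        session=session,
        truth=truth,
        emg=emg,
        descending=desc,
        afferent=aff,
        inputs=inputs,
        classes=classes,
        run_cfg=RunConfig().scaled_for(cfg.n_trials),
    )


@pytest.fixture(scope="session")
def noiseless_bundle() -> SimpleNamespace:
    """Small noiseless session: the linear model is exactly recoverable."""
    return bundle_session(
        SynthConfig(
            n_ecog_channels=10,
            n_afferent_units=8,
            n_muscles=3,
            n_trials=40,
            trial_spacing_s=3.2,
            noise_sd=0.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def noisy_bundle() -> SimpleNamespace:
    """Default-noise session used for recovery and evaluation tests."""
    return bundle_session(
        SynthConfig(
            n_ecog_channels=12,
            n_afferent_units=10,
            n_muscles=6,
            n_trials=80,
            trial_spacing_s=3.5,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def noiseless_results(noiseless_bundle):
    model = SparseLagRegression(
        noiseless_bundle.emg, noiseless_bundle.inputs, noiseless_bundle.classes
    )
    return model.fit()


@pytest.fixture(scope="session")
def noisy_results(noisy_bundle):
    model = SparseLagRegression(
        noisy_bundle.emg, noisy_bundle.inputs, noisy_bundle.classes
    )
    return model.fit()


@pytest.fixture(scope="session")
def sliding_bundle() -> SimpleNamespace:
    """Session whose afferent drive is purely facilitative, for the
    sliding-window and temporal-ordering analyses."""
    return bundle_session(
        SynthConfig(
            n_ecog_channels=10,
            n_afferent_units=8,
            n_muscles=3,
            n_trials=60,
            trial_spacing_s=3.5,
            negative_afferent_fraction=0.0,
            seed=9,
        )
    )


@pytest.fixture(scope="session")
def sliding_table(sliding_bundle):
    from myodecode.evaluate import sliding_window_eval

    b = sliding_bundle
    return sliding_window_eval(b.emg, b.inputs, b.classes, b.run_cfg, seed=3)


@pytest.fixture(scope="session")
def full_support_bundle() -> SimpleNamespace:
    """Session where every input channel genuinely drives the EMG, for
    the shuffled-control pruning comparison."""
    return bundle_session(
        SynthConfig(
            n_ecog_channels=8,
            n_afferent_units=6,
            n_muscles=3,
            n_trials=60,
            trial_spacing_s=3.5,
            support_fraction=1.0,
            seed=17,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
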