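"""Cross-validated decoding accuracy, shuffled controls, sliding windows.

Accuracy is the Pearson correlation and the variance accounted for,

    VAF = 1 - sum_t (y(t) - f(t))^2 / sum_t (y(t) - mean(y))^2,

computed per muscle on concatenated test-trial modulation traces.
Cross-validation follows the session protocol: folds with disjoint
randomly drawn test trials (defaults 6 folds, 108 training and 21 test
trials per fold), per-session values are fold means (medians for
sliding windows).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import component
from .lagmodel import LagSpec, SparseLagRegression, SparseLagResults
from .session import RunConfig
from .tensors import TrialTensor

logger = logging.getLogger(__name__)


def vaf(y: np.ndarray, f: np.ndarray) -> float:
    """Variance accounted for; 1 is perfect, 0 matches the mean, may be < 0."""
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if y.size != f.size or y.size < 2:
        raise ValueError("traces must share a length of at least 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("target trace has zero variance")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


def correlation(y: np.ndarray, f: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    f = np.asarray(f, dtype=float).ravel()
    if y.std() == 0 or f.std() == 0:
        return np.nan
    return float(np.corrcoef(y, f)[0, 1])


def make_folds(
    n_trials: int,
    n_folds: int,
    n_train: int,
    n_test: int,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random trial folds with disjoint test sets (when counts permit)."""
    if n_test + n_train > n_trials:
        raise ValueError(
            f"{n_train} train + {n_test} test trials exceed the {n_trials} "
            "available; scale n_train/n_test down (e.g. RunConfig.scaled_for)"
        )
    folds = []
    if n_folds * n_test <= n_trials:
        perm = rng.permutation(n_trials)
        test_sets = [perm[i * n_test : (i + 1) * n_test] for i in range(n_folds)]
    else:
        logger.warning("test sets cannot be disjoint: %d folds x %d test > %d trials",
                       n_folds, n_test, n_trials)
        test_sets = [rng.choice(n_trials, size=n_test, replace=False) for _ in range(n_folds)]
    for test in test_sets:
        rest = np.setdiff1d(np.arange(n_trials), test)
        train = rest if rest.size == n_train else rng.choice(rest, size=n_train, replace=False)
        folds.append((np.sort(train), np.sort(test)))
    return folds


def scaled_cv_sizes(n_trials: int, n_folds: int = 6) -> tuple[int, int]:
    """Train/test sizes proportional to the 108/21-of-129 protocol."""
    n_test = max(1, int(round(n_trials * 21 / 129)))
    n_train = min(n_trials - n_test, max(1, int(round(n_trials * 108 / 129))))
    return n_train, n_test


@dataclass
class CrossValResult:
    """Per-fold metrics plus the fold-averaged traces the events module needs."""

    metrics: pd.DataFrame            # (fold, muscle, variant) -> r, vaf, retained_*
    fold_traces: list[dict] = field(default_factory=list)
    times_by_kind: dict = field(default_factory=dict)
    folds: list = field(default_factory=list)
    fold_results: list[SparseLagResults] = field(default_factory=list)  # "both" models

    def session_means(self) -> pd.DataFrame:
        """Fold-mean r and VAF per (muscle, variant)."""
        return (
            self.metrics.groupby(["muscle", "variant"])[["r", "vaf"]]
            .mean()
            .reset_index()
        )


def crossvalidate(
    emg: TrialTensor,
    inputs: TrialTensor,
    channel_classes: np.ndarray,
    config: RunConfig | None = None,
    seed: int | None = None,
    variants: tuple[str, ...] = ("both", "descending", "afferent"),
    shuffled_inputs: TrialTensor | None = None,
    collect_traces: bool = True,
    max_iter: int = 500,
) -> CrossValResult:
    """Sixfold cross-validated decoding of a session's trial tensors.

    ``variants`` may include ``"both"``, ``"descending"``, ``"afferent"``
    and ``"shuffled"`` (train on block-shuffled inputs, test on the real
    ones; requires ``shuffled_inputs``).  Metrics are computed on
    concatenated test-trial traces.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    folds = make_folds(emg.n_trials, cfg.n_folds, cfg.n_train, cfg.n_test, rng)
    spec = LagSpec(cfg.delta_ms, cfg.l_min, cfg.l_max)
    first = -cfg.l_min

    rows = []
    fold_traces: list[dict] = []
    fold_results: list[SparseLagResults] = []
    for fold, (train, test) in enumerate(folds):
        emg_train = emg.select_trials(train)
        emg_test = emg.select_trials(test)
        inputs_test = inputs.select_trials(test)
        y_test = emg_test.values[:, :, first:]           # (muscles, test, targets)

        results_by_variant: dict[str, SparseLagResults] = {}
        for variant in variants:
            if variant == "shuffled":
                if shuffled_inputs is None:
                    raise ValueError("variant 'shuffled' requires shuffled_inputs")
                model = SparseLagRegression(
                    emg_train, shuffled_inputs.select_trials(train),
                    channel_classes, spec,
                )
                res = model.fit(max_iter=max_iter)
                # test with the unshuffled inputs
                pred = res.predict(inputs_test)
            else:
                base = SparseLagRegression(emg_train, inputs.select_trials(train),
                                           channel_classes, spec)
                res = base.restricted(variant).fit(max_iter=max_iter)
                ch = _variant_channels(channel_classes, variant)
                pred = res.predict(
                    inputs_test if variant == "both" else inputs_test.select_entities(ch)
                )
            results_by_variant[variant] = res
            for j, muscle in enumerate(emg.labels):
                y = y_test[j].ravel()
                f = pred.values[j].ravel()
                row = {
                    "fold": fold, "muscle": muscle, "variant": variant,
                    "r": correlation(y, f), "vaf": vaf(y, f),
                }
                for cls in ("descending", "afferent"):
                    if (res.channel_classes == cls).any():
                        row[f"retained_{cls}"] = res.retained_proportion(cls)[j]
                    else:
                        row[f"retained_{cls}"] = np.nan
                rows.append(row)

        if collect_traces and "both" in results_by_variant:
            res = results_by_variant["both"]
            recon = res.predict(inputs_test)
            desc = component(res, inputs_test, "descending")
            aff = component(res, inputs_test, "afferent")
            fold_traces.append({
                "observed": emg_test.trial_average(),
                "reconstruction": recon.trial_average(),
                "descending": desc.trial_average(),
                "afferent": aff.trial_average(),
            })
            fold_results.append(res)

    times_by_kind = {
        "observed": emg.times,
        "reconstruction": emg.times[first:],
        "descending": emg.times[first:],
        "afferent": emg.times[first:],
    }
    return CrossValResult(
        metrics=pd.DataFrame(rows),
        fold_traces=fold_traces,
        times_by_kind=times_by_kind,
        folds=folds,
        fold_results=fold_results,
    )


def _variant_channels(channel_classes: np.ndarray, variant: str) -> np.ndarray:
    if variant == "both":
        return np.arange(channel_classes.size)
    return np.nonzero(channel_classes == variant)[0]


def shuffle_control(
    values: np.ndarray,
    block_bins: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Block-shuffle each channel's continuous time series independently.

    The time axis is cut into consecutive blocks of ``block_bins``; the
    block order is permuted independently per channel (a trailing
    partial block stays in place), destroying event time-locking while
    preserving each channel's value multiset and short-range dynamics.
    """
    x = np.atleast_2d(np.asarray(values, dtype=float)).copy()
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = x.shape[-1]
    n_blocks = n // block_bins
    if n_blocks < 2:
        warnings.warn("fewer than 2 blocks: shuffle is the identity", stacklevel=2)
        return x if np.asarray(values).ndim > 1 else x[0]
    head = n_blocks * block_bins
    for c in range(x.shape[0]):
        blocks = x[c, :head].reshape(n_blocks, block_bins)
        x[c, :head] = blocks[gen.permutation(n_blocks)].ravel()
    return x if np.asarray(values).ndim > 1 else x[0]


def sliding_window_eval(
    emg: TrialTensor,
    inputs: TrialTensor,
    channel_classes: np.ndarray,
    config: RunConfig | None = None,
    seed: int | None = None,
    variants: tuple[str, ...] = ("both", "descending"),
    max_iter: int = 300,
) -> pd.DataFrame:
    """VAF of models refit within a sliding window over the epoch.

    One model per (window, fold, variant, muscle), fit on training rows
    whose target bin falls inside the window and scored on the
    *test-trial-averaged* trace within the window.  Returns a tidy
    DataFrame; the per-session value is the fold median
    (``groupby(...).median()``).
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    folds = make_folds(emg.n_trials, cfg.n_folds, cfg.n_train, cfg.n_test, rng)
    spec = LagSpec(cfg.delta_ms, cfg.l_min, cfg.l_max)
    first = -cfg.l_min
    target_times = emg.times[first:]

    win = cfg.sliding_window_ms
    step = cfg.sliding_step_ms
    if win > target_times[-1] - target_times[0]:
        raise ValueError("sliding window exceeds the epoch")
    centers = np.arange(target_times[0] + win / 2, target_times[-1] - win / 2 + 1e-9, step)

    rows = []
    for fold, (train, test) in enumerate(folds):
        emg_train = emg.select_trials(train)
        emg_test_avg = emg.select_trials(test).trial_average()[:, first:]
        inputs_test = inputs.select_trials(test)
        for variant in variants:
            base = SparseLagRegression(
                emg_train, inputs.select_trials(train), channel_classes, spec
            ).restricted(variant)
            ch = _variant_channels(channel_classes, variant)
            test_in = inputs_test.select_entities(ch)
            for center in centers:
                sel = (target_times >= center - win / 2 - 1e-9) & (
                    target_times < center + win / 2 - 1e-9
                )
                wmodel = _window_model(base, sel)
                res = wmodel.fit(max_iter=max_iter)
                pred_avg = res.predict(test_in).trial_average()[:, sel]
                for j, muscle in enumerate(emg.labels):
                    y = emg_test_avg[j, sel]
                    if np.var(y) <= 0:
                        continue
                    rows.append({
                        "fold": fold, "muscle": muscle, "variant": variant,
                        "window_center_ms": float(center),
                        "vaf": vaf(y, pred_avg[j]),
                    })
    return pd.DataFrame(rows)


def _window_model(model: SparseLagRegression, target_mask: np.ndarray) -> SparseLagRegression:
    """Restrict a model's trials' target bins to a window (rows subset)."""
    first = -model.lag_spec.l_min
    # keep lag context: bins [i - first, i] for each selected target bin i
    idx = np.nonzero(target_mask)[0] + first
    lo = idx.min() - first
    hi = idx.max() + 1
    emg_w = TrialTensor(
        model.emg.values[:, :, lo:hi], model.emg.times[lo:hi], model.emg.labels,
        kind=model.emg.kind, stage="epoched",
    )
    in_w = TrialTensor(
        model.inputs.values[:, :, lo:hi], model.inputs.times[lo:hi],
        model.inputs.labels, kind=model.inputs.kind, stage="epoched",
    )
    return SparseLagRegression(emg_w, in_w, model.channel_classes, model.lag_spec)


def sliding_window_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Fold-median VAF per (muscle, variant, window centre)."""
    return (
        table.groupby(["muscle", "variant", "window_center_ms"])["vaf"]
        .median()
        .reset_index()
    )


def pruning_stats(results: SparseLagResults) -> pd.DataFrame:
    """Retained (unpruned) channel proportion per muscle and input class."""
    rows = []
    for cls in ("descending", "afferent"):
        if not (results.channel_classes == cls).any():
            continue
        retained = results.retained_proportion(cls)
        for j, muscle in enumerate(results.muscle_names):
            rows.append({"muscle": muscle, "input_class": cls, "retained": retained[j]})
    return pd.DataFrame(rows)
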