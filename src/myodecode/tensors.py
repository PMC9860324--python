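"""Epoched trial tensors: the in-memory currency of the pipeline.

All movement-related modulation traces live on a common 200-Hz grid of
5-ms bins aligned to movement onset.  A :class:`TrialTensor` holds one
signal class (EMG envelopes, descending high-gamma, afferent rates, or a
reconstruction) for all entities and trials of a session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: modulation-domain sampling rate, Hz
FS_MOD = 200.0
#: modulation-domain bin width, ms
BIN_MS = 1000.0 / FS_MOD
#: analysis epoch around movement onset, ms
EPOCH_MS = (-500.0, 1500.0)
#: baseline window for modulation computation, ms
BASELINE_MS = (-1250.0, -750.0)


class StageError(TypeError):
    """Raised when a processing stage is applied to data of the wrong stage."""


@dataclass
class TrialTensor:
    """Entity x trial x time array of movement-related modulation.

    Parameters
    ----------
    values
        Array of shape ``(n_entities, n_trials, n_bins)``.
    times
        Bin times in ms relative to movement onset, length ``n_bins``,
        uniformly spaced at 5 ms.
    labels
        One label per entity (muscle name, channel id, unit id).
    kind
        Signal class tag: ``"emg"``, ``"descending"``, ``"afferent"``,
        ``"inputs"`` (stacked descending+afferent) or ``"reconstruction"``.
    stage
        Processing-stage tag; epoched tensors carry ``"epoched"`` and
        refuse to be epoched again.
    """

    values: np.ndarray
    times: np.ndarray
    labels: list[str]
    kind: str = "signal"
    stage: str = "epoched"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("TrialTensor values must be 3-D (entity, trial, time)")
        if self.times.shape != (self.values.shape[2],):
            raise ValueError("times length must match the time axis")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per entity required")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, BIN_MS, atol=1e-6):
                raise ValueError("time axis must be uniform 5-ms bins")

    # -- basic geometry -------------------------------------------------
    @property
    def n_entities(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    def bin_of(self, t_ms: float) -> int:
        """Index of the bin whose time equals ``t_ms`` (nearest bin)."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def window_slice(self, start_ms: float, stop_ms: float) -> slice:
        """Half-open bin slice covering ``start_ms <= t < stop_ms``."""
        idx = np.nonzero((self.times >= start_ms - 1e-9) & (self.times < stop_ms - 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"window [{start_ms}, {stop_ms}) ms outside trace span")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    # -- selection ------------------------------------------------------
    def select_entities(self, index: Sequence[int] | np.ndarray) -> "TrialTensor":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            values=self.values[index],
            labels=[self.labels[i] for i in index],
        )

    def select_trials(self, index: Sequence[int] | np.ndarray) -> "TrialTensor":
        index = np.asarray(index, dtype=int)
        return replace(self, values=self.values[:, index])

    def trial_average(self) -> np.ndarray:
        """Trial-averaged waveforms, shape ``(n_entities, n_bins)``."""
        return self.values.mean(axis=1)

    def restrict_times(self, start_ms: float, stop_ms: float) -> "TrialTensor":
        sl = self.window_slice(start_ms, stop_ms)
        return replace(self, values=self.values[:, :, sl], times=self.times[sl])


def stack_inputs(descending: TrialTensor, afferent: TrialTensor) -> tuple[TrialTensor, np.ndarray]:
    """Stack descending and afferent tensors into one input tensor.

    Returns the stacked tensor (kind ``"inputs"``) and an array of class
    labels (``"descending"`` / ``"afferent"``) per input channel, in the
    stacking order (descending first).
    """
    if descending.n_trials != afferent.n_trials:
        raise ValueError("trial counts differ between input classes")
    if not np.allclose(descending.times, afferent.times):
        raise ValueError("time axes differ between input classes")
    values = np.concatenate([descending.values, afferent.values], axis=0)
    labels = list(descending.labels) + list(afferent.labels)
    classes = np.array(
        ["descending"] * descending.n_entities + ["afferent"] * afferent.n_entities
    )
    return (
        TrialTensor(values, descending.times, labels, kind="inputs", stage="epoched"),
        classes,
    )
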