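"""Linear attribution of reconstructions to input subsets.

Because the decoder is linear, the reconstruction splits exactly into
the contribution of any channel subset: zero the weights outside the
subset and predict.  Components over any partition of the channels
(descending/afferent, per cortical area, per electrode) sum to the full
reconstruction.

Component *sizes* summarise a component over the movement-related
modulation period as the temporal mean of the positive- (or negative-)
clipped trial-averaged trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lagmodel import SparseLagResults
from .tensors import TrialTensor


@dataclass
class ComponentTrace:
    """Reconstruction restricted to a channel subset."""

    values: np.ndarray       # (n_muscles, n_trials, n_bins)
    times: np.ndarray        # ms
    muscle_names: list[str]
    subset_label: str
    channel_indices: np.ndarray

    def trial_average(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def as_tensor(self) -> TrialTensor:
        return TrialTensor(
            self.values, self.times, self.muscle_names,
            kind=f"component:{self.subset_label}", stage="epoched",
        )


def _resolve_subset(results: SparseLagResults, subset) -> tuple[np.ndarray, str]:
    labels = results.channel_labels
    n = len(labels)
    if isinstance(subset, str):
        if subset == "all":
            return np.arange(n), "all"
        mask = results.channel_classes == subset
        if not mask.any():
            raise ValueError(f"no input channel of class {subset!r}")
        return np.nonzero(mask)[0], subset
    idx = []
    for item in subset:
        if isinstance(item, str):
            if item not in labels:
                raise ValueError(f"unknown channel {item!r}")
            idx.append(labels.index(item))
        else:
            i = int(item)
            if not 0 <= i < n:
                raise ValueError(f"channel index {i} out of range")
            idx.append(i)
    return np.asarray(sorted(set(idx)), dtype=int), f"subset[{len(idx)}]"


def component(
    results: SparseLagResults,
    inputs: TrialTensor,
    subset,
) -> ComponentTrace:
    """The part of the reconstruction attributable to ``subset``.

    ``subset`` may be a class name (``"descending"``, ``"afferent"``,
    ``"all"``), or a sequence of channel labels or indices.  The empty
    subset yields a zero trace.
    """
    idx, label = _resolve_subset(results, subset)
    recon = results.predict(inputs, channels=idx)
    return ComponentTrace(
        values=recon.values,
        times=recon.times,
        muscle_names=recon.labels,
        subset_label=label,
        channel_indices=idx,
    )


def component_size(
    trace: ComponentTrace,
    window_ms: tuple[float, float],
    sign: str = "positive",
    denominator: str = "window",
) -> np.ndarray:
    """Temporal mean of the clipped trial-averaged component, per muscle.

    ``sign="positive"`` clips negative values to zero (returns >= 0);
    ``sign="negative"`` clips positive values (returns <= 0).  With the
    default ``denominator="window"`` the mean is over every bin of the
    window (half-wave-rectified mean); ``denominator="active"`` divides
    by the number of bins surviving the clip instead.
    """
    avg = trace.trial_average()
    lo, hi = window_ms
    sel = (trace.times >= lo - 1e-9) & (trace.times < hi - 1e-9)
    if not sel.any():
        raise ValueError(f"window [{lo}, {hi}) ms outside component span")
    seg = avg[:, sel]
    if sign == "positive":
        clipped = np.clip(seg, 0.0, None)
    elif sign == "negative":
        clipped = np.clip(seg, None, 0.0)
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    if denominator == "window":
        return clipped.mean(axis=1)
    if denominator == "active":
        n_active = (clipped != 0).sum(axis=1)
        total = clipped.sum(axis=1)
        return np.where(n_active > 0, total / np.maximum(n_active, 1), 0.0)
    raise ValueError("denominator must be 'window' or 'active'")


def per_area_components(
    results: SparseLagResults,
    inputs: TrialTensor,
    areas: list[str],
    window_ms: tuple[float, float] = (-100.0, 1150.0),
) -> tuple[dict[str, ComponentTrace], pd.DataFrame]:
    """Cortical-area subcomponents of the descending component.

    ``areas`` gives one area label per *descending* channel, in channel
    order.  Area components partition the descending component; sizes
    are normalized by the size of the full reconstruction.

    Returns the per-area traces and a tidy table of normalized sizes,
    one row per (muscle, area).
    """
    desc_idx = np.nonzero(results.channel_classes == "descending")[0]
    if len(areas) != desc_idx.size:
        raise ValueError("one area label per descending channel required")
    areas = list(areas)
    full = component(results, inputs, "all")
    full_size = component_size(full, window_ms, "positive")

    traces: dict[str, ComponentTrace] = {}
    rows = []
    for area in sorted(set(areas)):
        idx = desc_idx[[i for i, a in enumerate(areas) if a == area]]
        tr = component(results, inputs, idx)
        tr.subset_label = area
        traces[area] = tr
        size = component_size(tr, window_ms, "positive")
        norm = np.where(full_size > 0, size / np.where(full_size > 0, full_size, 1.0), np.nan)
        for j, muscle in enumerate(tr.muscle_names):
            rows.append(
                {"muscle": muscle, "area": area, "size": size[j], "normalized_size": norm[j]}
            )
    return traces, pd.DataFrame(rows)


def initial_movement_afferent_size(
    trace: ComponentTrace,
    window_ms: tuple[float, float] = (55.0, 100.0),
) -> np.ndarray:
    """Signed temporal mean of a component early in the movement.

    Applied to the afferent component over 55-100 ms after movement
    onset, the sign classifies the afferent effect on each muscle as
    facilitative (> 0, stretch-reflex analog) or suppressive (< 0,
    reciprocal-inhibition analog).
    """
    lo, hi = window_ms
    if lo < trace.times[0] or hi > trace.times[-1] + 1e-9:
        raise ValueError("window outside component span")
    sel = (trace.times >= lo - 1e-9) & (trace.times < hi - 1e-9)
    return trace.trial_average()[:, sel].mean(axis=1)


def size_table(
    results: SparseLagResults,
    inputs: TrialTensor,
    window_ms: tuple[float, float],
) -> pd.DataFrame:
    """Component sizes per (muscle, subset, sign) for CSV export."""
    rows = []
    for subset in ("all", "descending", "afferent"):
        tr = component(results, inputs, subset)
        for sign in ("positive", "negative"):
            sizes = component_size(tr, window_ms, sign)
            for j, muscle in enumerate(tr.muscle_names):
                rows.append(
                    {"muscle": muscle, "subset": subset, "sign": sign, "size": sizes[j]}
                )
    return pd.DataFrame(rows)
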