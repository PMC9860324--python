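"""Threshold-based onset and offset detection on trial-averaged traces.

The threshold is one-fifth of the maximum of the *observed* EMG
waveform within -250..+250 ms around movement onset; the same threshold
is shared by the reconstruction and its components.  A trace turns "on"
at the first bin of the earliest run of at least five consecutive bins
strictly above threshold (searching from the epoch start), and "off" at
the first bin at or after +500 ms starting a run of at least five
consecutive bins strictly below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: run length (bins) required to call an onset or offset
RUN_BINS = 5
#: window for the reference-trace maximum, ms around movement onset
THRESHOLD_WINDOW_MS = (-250.0, 250.0)
#: fraction of the reference maximum used as the threshold
THRESHOLD_FRACTION = 0.2
#: earliest offset search time, ms
OFFSET_SEARCH_MS = 500.0


@dataclass
class EventTimes:
    """Detected modulation onset/offset of one averaged trace."""

    onset_ms: float | None
    offset_ms: float | None
    threshold: float
    reference_id: str = ""

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.onset_ms is not None and self.offset_ms is not None:
            if not self.onset_ms < self.offset_ms:
                raise ValueError("onset must precede offset")


def _first_run_start(mask: np.ndarray, run: int = RUN_BINS) -> int | None:
    """Index of the first bin starting ``run`` consecutive True bins."""
    if mask.size < run:
        return None
    window = np.lib.stride_tricks.sliding_window_view(mask.astype(int), run)
    hits = np.nonzero(window.sum(axis=1) == run)[0]
    return int(hits[0]) if hits.size else None


def threshold_from_reference(reference: np.ndarray, times: np.ndarray) -> float:
    """One-fifth of the reference maximum in -250..+250 ms."""
    sel = (times >= THRESHOLD_WINDOW_MS[0] - 1e-9) & (times <= THRESHOLD_WINDOW_MS[1] + 1e-9)
    if not sel.any():
        raise ValueError("reference trace does not cover -250..250 ms")
    peak = float(np.max(reference[sel]))
    if peak <= 0:
        raise ValueError("reference maximum in -250..250 ms must be positive")
    return THRESHOLD_FRACTION * peak


def detect_onset(
    target: np.ndarray,
    times: np.ndarray,
    reference: np.ndarray | None = None,
    reference_times: np.ndarray | None = None,
    threshold: float | None = None,
    reference_id: str = "",
) -> EventTimes:
    """Onset (and offset) of an averaged trace against a shared threshold.

    Either a precomputed ``threshold`` or a ``reference`` trace (the
    observed EMG average) must be given.  Comparison is strict (>), so
    a trace exactly at threshold does not trigger.
    """
    target = np.asarray(target, dtype=float)
    times = np.asarray(times, dtype=float)
    if threshold is None:
        if reference is None:
            raise ValueError("either threshold or reference required")
        ref_t = times if reference_times is None else np.asarray(reference_times)
        threshold = threshold_from_reference(np.asarray(reference, dtype=float), ref_t)

    i = _first_run_start(target > threshold)
    onset = float(times[i]) if i is not None else None
    offset = detect_offset(target, times, threshold)
    if onset is not None and offset is not None and not onset < offset:
        offset = None
    return EventTimes(onset_ms=onset, offset_ms=offset, threshold=threshold,
                      reference_id=reference_id)


def detect_offset(target: np.ndarray, times: np.ndarray, threshold: float) -> float | None:
    """First bin at/after +500 ms starting >= 5 consecutive sub-threshold bins."""
    target = np.asarray(target, dtype=float)
    times = np.asarray(times, dtype=float)
    start = np.searchsorted(times, OFFSET_SEARCH_MS - 1e-9)
    if start >= times.size:
        return None
    i = _first_run_start(target[start:] < threshold)
    return float(times[start + i]) if i is not None else None


def onset_table(fold_traces: list[dict], times_by_kind: dict) -> pd.DataFrame:
    """Per-fold onset times of observed/reconstructed traces and components.

    Parameters
    ----------
    fold_traces
        One dict per cross-validation fold mapping trace kind (e.g.
        ``"observed"``, ``"reconstruction"``, ``"descending"``,
        ``"afferent"``) to an ``(n_muscles, n_bins)`` test-trial-averaged
        array.  The ``"observed"`` entry supplies the shared threshold.
    times_by_kind
        Time axis (ms) per trace kind (the reconstruction axis starts
        at -450 ms, the observed axis at -500 ms).

    Returns
    -------
    DataFrame with one row per (fold, muscle, kind); onset/offset are
    NaN when not detected.  Session-level summaries are means over
    folds, excluding absent onsets (``groupby().mean()`` skips NaN and
    ``count()`` reports how many folds detected one).
    """
    rows = []
    for fold, traces in enumerate(fold_traces):
        observed = traces["observed"]
        obs_times = np.asarray(times_by_kind["observed"], dtype=float)
        n_muscles = observed.shape[0]
        for j in range(n_muscles):
            try:
                thr = threshold_from_reference(observed[j], obs_times)
            except ValueError:
                thr = None
            for kind, arr in traces.items():
                t = np.asarray(times_by_kind[kind], dtype=float)
                if thr is None:
                    rows.append({"fold": fold, "muscle": j, "kind": kind,
                                 "onset_ms": np.nan, "offset_ms": np.nan})
                    continue
                ev = detect_onset(arr[j], t, threshold=thr, reference_id=f"observed/{j}")
                rows.append({
                    "fold": fold,
                    "muscle": j,
                    "kind": kind,
                    "onset_ms": np.nan if ev.onset_ms is None else ev.onset_ms,
                    "offset_ms": np.nan if ev.offset_ms is None else ev.offset_ms,
                })
    return pd.DataFrame(rows)


def session_onset_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Fold-averaged onsets per (muscle, kind) with detection counts."""
    g = table.groupby(["muscle", "kind"])
    out = g.agg(
        onset_ms=("onset_ms", "mean"),
        offset_ms=("offset_ms", "mean"),
        n_folds_detected=("onset_ms", "count"),
    ).reset_index()
    return out
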