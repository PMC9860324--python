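"""Raw signal conditioning to 200-Hz movement-related modulation traces.

Three signal classes are reduced to a common modulation domain:

* EMG: causal 1.5-60 Hz bandpass, rectification, anti-aliased resampling
  to 200 Hz, 11-bin (55 ms) centred moving average.
* ECoG: causal 1.5-240 Hz bandpass, short-time Fourier transform on
  100-ms Hann windows at a 5-ms step, per-frequency-bin normalisation of
  power to the session mean, band averages in high-gamma 1 (60-120 Hz)
  and high-gamma 2 (120-180 Hz).
* Afferent spikes: piecewise-constant inverse interspike interval
  convolved with a unit-area causal exponential kernel (tau = 50 ms),
  sampled at 200 Hz.

Epoching aligns the traces to movement onset, subtracts the baseline
mean from -1250 to -750 ms, and crops to -500..+1500 ms (401 bins).

Filters are applied forward-only (causal): the analysis reasons about
millisecond-level lead and lag between cortex, afferents and muscle, and
zero-phase filtering would leak signal backwards in time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .tensors import BASELINE_MS, BIN_MS, EPOCH_MS, FS_MOD, StageError, TrialTensor

logger = logging.getLogger(__name__)

#: high-gamma band edges, Hz (band 1, band 2)
HG_BANDS = ((60.0, 120.0), (120.0, 180.0))
#: exponential rate-kernel time constant, s
RATE_TAU_S = 0.050
#: EMG envelope smoothing window, bins at 200 Hz
EMG_SMOOTH_BINS = 11


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    if x.ndim == 2:
        return x, False
    raise ValueError("expected a 1-D trace or 2-D (channels, samples) array")


def _resample_to_mod(x: np.ndarray, fs: float) -> np.ndarray:
    """Polyphase anti-aliased resampling from ``fs`` to 200 Hz (last axis)."""
    frac = Fraction(int(round(FS_MOD)), int(round(fs))).limit_denominator(10000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def n_mod_samples(n_raw: int, fs: float) -> int:
    """Length of the 200-Hz grid covering ``n_raw`` samples at ``fs``."""
    return int(np.ceil(n_raw * FS_MOD / fs))


def emg_envelope(raw: np.ndarray, fs: float) -> np.ndarray:
    """Rectified, smoothed EMG envelope at 200 Hz.

    Parameters
    ----------
    raw
        EMG in uV, shape ``(n_samples,)`` or ``(n_muscles, n_samples)``.
    fs
        Sampling rate in Hz; must be at least 500 Hz so the 60-Hz band
        edge is well below Nyquist.
    """
    x, squeeze = _as_2d(raw)
    if fs < 500.0:
        raise ValueError(f"EMG sampling rate {fs} Hz too low for the 1.5-60 Hz band")
    sos = sps.butter(2, [1.5, 60.0], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfilt(sos, x, axis=-1)
    rectified = np.abs(filtered)
    resampled = _resample_to_mod(rectified, fs)
    # polyphase decimation can ring slightly negative; the envelope is
    # nonnegative by definition
    resampled = np.maximum(resampled, 0.0)
    kernel = np.full(EMG_SMOOTH_BINS, 1.0 / EMG_SMOOTH_BINS)
    smoothed = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), -1, resampled
    )
    return smoothed[0] if squeeze else smoothed


@dataclass
class HighGammaResult:
    """Normalized high-gamma band power at 200 Hz (per channel)."""

    hg1: np.ndarray   # (n_channels, n_frames), 60-120 Hz
    hg2: np.ndarray   # (n_channels, n_frames), 120-180 Hz
    mean: np.ndarray  # (n_channels, n_frames), mean of the two bands
    times: np.ndarray  # frame centres, s from recording start

    def band(self, mode: str) -> np.ndarray:
        if mode == "mean":
            return self.mean
        if mode == "hg1":
            return self.hg1
        if mode == "hg2":
            return self.hg2
        raise ValueError(f"unknown high-gamma mode {mode!r}")


def high_gamma(
    raw: np.ndarray,
    fs: float,
    bands: tuple[tuple[float, float], tuple[float, float]] = HG_BANDS,
) -> HighGammaResult:
    """Normalized high-gamma band power of ECoG at a 5-ms step.

    Power in each STFT frequency bin is divided by its session mean, so
    per channel and frequency bin the time-mean of normalized power is
    one; the band trace is the mean over that band's bins.
    """
    x, _ = _as_2d(raw)
    if fs < 500.0:
        raise ValueError(f"ECoG sampling rate {fs} Hz too low for high-gamma analysis")
    hop = fs / FS_MOD
    if abs(hop - round(hop)) > 1e-9:
        raise ValueError("ECoG sampling rate must be an integer multiple of 200 Hz")
    hop = int(round(hop))
    nperseg = int(round(0.1 * fs))
    if x.shape[-1] < nperseg:
        raise ValueError("signal shorter than one 100-ms STFT window")

    if fs >= 480.0:
        sos = sps.butter(2, [1.5, min(240.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfilt(sos, x, axis=-1)
    else:  # pragma: no cover - guarded by the fs check above
        logger.warning("skipping 1.5-240 Hz prefilter at fs=%s Hz", fs)

    freqs, times, zxx = sps.stft(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg - hop,
        boundary="zeros",
        padded=True,
        axis=-1,
    )
    power = np.abs(zxx) ** 2  # (n_channels, n_freqs, n_frames)
    # keep exactly the frames covering the recording on the 200-Hz grid,
    # then normalise each frequency bin to its session-mean power
    n_out = n_mod_samples(np.shape(raw)[-1], fs)
    power = power[..., :n_out]
    times = times[:n_out]
    mean_power = power.mean(axis=-1, keepdims=True)
    norm = power / np.where(mean_power > 0, mean_power, 1.0)

    def band_mean(lo: float, hi: float) -> np.ndarray:
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"no STFT bins inside {lo}-{hi} Hz")
        return norm[:, sel, :].mean(axis=1)

    hg1 = band_mean(*bands[0])
    hg2 = band_mean(*bands[1])
    return HighGammaResult(hg1=hg1, hg2=hg2, mean=0.5 * (hg1 + hg2), times=times)


def afferent_rate(
    spike_times: np.ndarray,
    duration_s: float,
    tau_s: float = RATE_TAU_S,
) -> np.ndarray:
    """Instantaneous firing rate at 200 Hz from spike times.

    The inverse interspike interval is held piecewise constant between
    consecutive spikes (zero outside the first..last spike span) and
    convolved with a causal exponential kernel of time constant
    ``tau_s`` normalized to unit area, so a sustained regular train at
    rate r converges to r.
    """
    spikes = np.asarray(spike_times, dtype=float)
    n = int(round(duration_s * FS_MOD))
    grid = np.arange(n) / FS_MOD
    if spikes.size < 2:
        logger.warning("fewer than 2 spikes; returning a zero rate trace")
        return np.zeros(n)
    if np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")

    inst = np.zeros(n)
    isi = np.diff(spikes)
    # value 1/ISI on [s_i, s_{i+1})
    idx = np.searchsorted(spikes, grid, side="right") - 1
    inside = (idx >= 0) & (idx < isi.size)
    safe = np.where(inside, idx, 0)
    inst[inside] = 1.0 / isi[safe][inside]

    # unit-area causal exponential kernel as a single-pole IIR filter
    a = np.exp(-1.0 / (FS_MOD * tau_s))
    rate = sps.lfilter([1.0 - a], [1.0, -a], inst)
    return rate


def epoch_and_baseline(
    values: np.ndarray,
    events_s: np.ndarray,
    labels: list[str],
    kind: str,
    epoch_ms: tuple[float, float] = EPOCH_MS,
    baseline_ms: tuple[float, float] = BASELINE_MS,
) -> TrialTensor:
    """Epoch continuous 200-Hz traces around movement onsets.

    The baseline (mean over ``baseline_ms``, default -1250..-750 ms) is
    subtracted per entity and trial before cropping to ``epoch_ms``
    (default -500..+1500 ms, 401 bins).  Events whose full context does
    not fit in the recording are dropped with a warning.
    """
    if isinstance(values, TrialTensor):
        raise StageError("input is already epoched; epoching twice is not defined")
    x, _ = _as_2d(values)
    if x.shape[0] != len(labels):
        raise ValueError("one label per entity required")
    n = x.shape[-1]

    b0 = int(round(baseline_ms[0] / BIN_MS))
    b1 = int(round(baseline_ms[1] / BIN_MS))
    e0 = int(round(epoch_ms[0] / BIN_MS))
    e1 = int(round(epoch_ms[1] / BIN_MS))
    lo = min(b0, e0)

    trials = []
    for t_ev in np.asarray(events_s, dtype=float):
        c = int(round(t_ev * FS_MOD))
        if c + lo < 0 or c + e1 >= n:
            logger.warning("dropping event at %.3f s: epoch context out of range", t_ev)
            continue
        baseline = x[:, c + b0 : c + b1].mean(axis=1, keepdims=True)
        trials.append(x[:, c + e0 : c + e1 + 1] - baseline)
    if not trials:
        raise ValueError("no event admits the full epoch context")
    tensor = np.stack(trials, axis=1)
    times = np.arange(e0, e1 + 1) * BIN_MS
    return TrialTensor(tensor, times, list(labels), kind=kind, stage="epoched")


def preprocess_session(session, config=None, emg_source: str = "raw"):
    """Full session preprocessing to epoched trial tensors.

    Parameters
    ----------
    session : SessionDataset
    config : RunConfig, optional
        Epoch/baseline windows and the high-gamma mode; defaults used
        when omitted.
    emg_source
        ``"raw"`` runs the envelope pipeline on the recorded EMG;
        ``"derived"`` uses the 200-Hz modulation traces stored with the
        session (exact for generator output), if present.

    Returns
    -------
    dict with keys ``"emg"``, ``"descending"``, ``"afferent"``
        (each a :class:`TrialTensor`).
    """
    from .session import RunConfig

    cfg = config or RunConfig()
    epoch = tuple(cfg.epoch_ms)
    base = tuple(cfg.baseline_ms)

    hg = high_gamma(session.ecog, session.ecog_fs, bands=cfg.hg_bands)
    if cfg.hg_mode == "separate":
        desc_values = np.concatenate([hg.hg1, hg.hg2], axis=0)
        desc_labels = [f"{c}/hg1" for c in session.ecog_labels] + [
            f"{c}/hg2" for c in session.ecog_labels
        ]
    else:
        desc_values = hg.band(cfg.hg_mode)
        desc_labels = list(session.ecog_labels)

    duration = session.duration_s
    rates = np.stack(
        [afferent_rate(st, duration) for st in session.afferent_units], axis=0
    )
    n = min(desc_values.shape[-1], rates.shape[-1])

    if emg_source == "derived":
        if session.derived is None or "emg_mod" not in session.derived:
            raise ValueError("session has no derived EMG modulation traces")
        emg_values = session.derived["emg_mod"]
    elif emg_source == "raw":
        emg_values = emg_envelope(session.emg, session.emg_fs)
    else:
        raise ValueError(f"unknown emg_source {emg_source!r}")
    n = min(n, emg_values.shape[-1])

    return {
        "emg": epoch_and_baseline(
            emg_values[:, :n], session.events, list(session.muscle_names), "emg", epoch, base
        ),
        "descending": epoch_and_baseline(
            desc_values[:, :n], session.events, desc_labels, "descending", epoch, base
        ),
        "afferent": epoch_and_baseline(
            rates[:, :n], session.events, list(session.unit_labels), "afferent", epoch, base
        ),
    }
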