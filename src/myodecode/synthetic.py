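"""Synthetic multiregional sessions with a known linear forward model.

The generator emulates the statistical structure the decoder assumes:

* cortical channels carry smooth trial-locked high-gamma bumps that
  begin a configurable lead time (default 150 ms) before each movement
  onset, emitted as amplitude-modulated 60-180 Hz noise so the STFT
  pipeline genuinely recovers the latent envelope;
* afferent units fire inhomogeneous-Poisson spike trains whose rate
  modulates from movement onset (plus an optional delay);
* EMG is a lagged linear mixture (5-50 ms of input history) of the
  *preprocessed-domain* inputs under a channel-sparse ground-truth
  weight tensor, plus white observation noise, embedded as a raw
  rectifiable carrier signal.

Because the mixture is applied to the very traces the preprocessing
stage recomputes (high-gamma power, exponential-kernel firing rates),
the ground truth is exact in the modulation domain and the whole
pipeline is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import preprocess
from .session import AREAS, SessionDataset
from .tensors import FS_MOD

#: lag indices of the forward model (bins of 5 ms, strictly negative)
LAG_INDICES = np.arange(-10, 0)


@dataclass
class SynthConfig:
    """Generator parameters; defaults mirror the study conditions."""

    n_ecog_channels: int = 32
    n_afferent_units: int = 20
    n_muscles: int = 10
    n_trials: int = 150
    trial_spacing_s: float = 4.0
    cortical_lead_ms: float = 150.0
    afferent_delay_ms: float = 0.0
    support_fraction: float = 0.5
    noise_sd: float = 0.3              # fraction of modulation SD
    negative_afferent_fraction: float = 0.25  # fraction of muscles with net-negative afferent drive
    afferent_balance: float = 0.8      # afferent/descending contribution SD ratio
    afferent_baseline_hz: tuple = (10.0, 30.0)
    ecog_fs: float = 1000.0
    emg_fs: float = 2000.0
    descending_support_channels: list | None = None
    afferent_support_channels: list | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_ecog_channels", "n_afferent_units", "n_muscles", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.support_fraction <= 1.0:
            raise ValueError("support_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.trial_spacing_s < 3.0:
            raise ValueError(
                "trial_spacing_s too short: the -1250..+1500 ms epoch context "
                "must fit between consecutive events"
            )


@dataclass
class GroundTruth:
    """Everything needed to score recovery against the generator."""

    weights: np.ndarray        # (n_muscles, n_inputs, n_lags)
    support_mask: np.ndarray   # (n_inputs,) bool: channel has any nonzero weight
    latent_emg: np.ndarray     # (n_muscles, n_time) noiseless modulation EMG
    emg_mod: np.ndarray        # (n_muscles, n_time) noisy modulation EMG
    descending: np.ndarray     # (n_desc, n_time) latent-recovered high-gamma traces
    afferent: np.ndarray       # (n_aff, n_time) firing-rate traces
    latent_envelope: np.ndarray  # (n_desc, n_time) latent cortical envelopes
    latent_rate: np.ndarray    # (n_aff, n_time) latent afferent rates
    events: np.ndarray
    input_classes: np.ndarray = field(default=None)  # "descending"/"afferent" per input

    @property
    def n_descending(self) -> int:
        return self.descending.shape[0]


def forward_emg(
    inputs: np.ndarray,
    weights: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Lagged linear mixture of input traces.

    ``output[j, t] = sum_k sum_l weights[j, k, l] * inputs[k, t + l]``
    with lag indices ``l = -10..-1`` (columns of ``weights`` ordered by
    ascending lag, i.e. index 0 is l = -10).  Output at time t therefore
    depends only on inputs 5-50 ms in the past; the first 10 bins use a
    zero-padded history.
    """
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    w = np.asarray(weights, dtype=float)
    if w.ndim == 2:
        w = w[None, ...]
    n_muscles, n_inputs, n_lags = w.shape
    if n_inputs != x.shape[0]:
        raise ValueError(f"weights expect {n_inputs} inputs, got {x.shape[0]}")
    if n_lags != LAG_INDICES.size:
        raise ValueError(f"weights must carry {LAG_INDICES.size} lags per input")

    # FIR taps: y[t] = sum_m b[m] x[t-m], b[m] = w at lag l=-m
    out = np.zeros((n_muscles, x.shape[1]))
    for j in range(n_muscles):
        taps = np.zeros(n_lags + 1)
        for k in range(n_inputs):
            taps[1:] = w[j, k, ::-1]  # taps[m] = w[j, k, l=-m]
            out[j] += sps.lfilter(taps, [1.0], x[k])
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        out = out + gen.normal(0.0, noise_sd, size=out.shape)
    return out


def _bump_profile(rise_ms: float = 100.0, plateau_ms: float = 500.0, fall_ms: float = 300.0) -> np.ndarray:
    """Smooth unit-height bump: half-cosine rise, plateau, half-cosine fall."""
    dt = 1000.0 / FS_MOD
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(int(rise_ms / dt)) / (rise_ms / dt)))
    plateau = np.ones(int(plateau_ms / dt))
    n_fall = int(fall_ms / dt)
    fall = 0.5 * (1 + np.cos(np.pi * np.arange(n_fall) / n_fall))
    return np.concatenate([rise, plateau, fall])


def _add_bumps(
    trace: np.ndarray,
    events_s: np.ndarray,
    start_offset_ms: float,
    amplitudes: np.ndarray,
    profile: np.ndarray,
) -> None:
    """Add one amplitude-scaled bump per event, in place."""
    n = trace.shape[-1]
    for ev, amp in zip(events_s, amplitudes):
        i0 = int(round((ev + start_offset_ms / 1000.0) * FS_MOD))
        i1 = min(i0 + profile.size, n)
        if i0 < 0 or i0 >= n:
            continue
        trace[i0:i1] += amp * profile[: i1 - i0]


def _slow_noise(rng: np.random.Generator, n: int, sd: float, cutoff_hz: float = 2.0) -> np.ndarray:
    sos = sps.butter(2, cutoff_hz, btype="low", fs=FS_MOD, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _poisson_spikes(
    rate_200: np.ndarray,
    rng: np.random.Generator,
    refractory_s: float = 0.002,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times from a 200-Hz rate trace (1-ms grid).

    A short absolute refractory period keeps interspike intervals
    bounded away from zero, as for real units, so inverse-ISI rate
    estimates stay finite and well behaved.
    """
    fine_fs = 1000.0
    t200 = np.arange(rate_200.size) / FS_MOD
    n_fine = int(rate_200.size * fine_fs / FS_MOD)
    t_fine = np.arange(n_fine) / fine_fs
    rate_fine = np.interp(t_fine, t200, np.maximum(rate_200, 0.0))
    hits = rng.random(n_fine) < rate_fine / fine_fs
    times = np.sort(t_fine[hits] + rng.random(int(hits.sum())) / fine_fs)
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            keep.append(t)
            last = t
    return np.asarray(keep)


def _sample_weights(
    rng: np.random.Generator,
    n_muscles: int,
    n_channels: int,
    support: np.ndarray,
) -> np.ndarray:
    """Nonnegative weights with a smooth unimodal lag profile on supported channels."""
    n_lags = LAG_INDICES.size
    base = np.sin(np.pi * (np.arange(n_lags) + 0.5) / n_lags) ** 2  # peak mid-history
    w = np.zeros((n_muscles, n_channels, n_lags))
    for k in support:
        profile = base * (1.0 + 0.3 * rng.uniform(-1, 1, n_lags))
        profile = np.maximum(profile, 0.0)
        amps = rng.uniform(0.5, 1.5, n_muscles)
        w[:, k, :] = amps[:, None] * profile[None, :]
    return w


def _enforce_epoched_mixture(
    emg: np.ndarray,
    weights: np.ndarray,
    inputs: np.ndarray,
    events_s: np.ndarray,
    baseline_bins: tuple[int, int] = (-250, -150),
    epoch_bins: tuple[int, int] = (-100, 300),
) -> None:
    """Per-trial epoch-consistency correction, in place.

    Subtracts, over each trial's epoch span, the constant
    ``sum_{k,l} w[j,k,l] (mean_B x_k(t+l) - mean_B x_k(t))`` so that the
    epoched, baseline-subtracted EMG equals the lagged mixture of the
    epoched, baseline-subtracted inputs exactly.
    """
    b0, b1 = baseline_bins
    e0, e1 = epoch_bins
    n = emg.shape[-1]
    for ev in events_s:
        c = int(round(ev * FS_MOD))
        if c + b0 + LAG_INDICES[0] < 0 or c + e1 >= n:
            continue
        base_means = inputs[:, c + b0 : c + b1].mean(axis=1)          # (k,)
        lag_means = np.stack(
            [inputs[:, c + b0 + l : c + b1 + l].mean(axis=1) for l in LAG_INDICES],
            axis=1,
        )                                                              # (k, l)
        mismatch = np.einsum("jkl,kl->j", weights, lag_means - base_means[:, None])
        emg[:, c + e0 : c + e1 + 1] += mismatch[:, None]


def _areas_for(n_channels: int) -> list[str]:
    """Deterministic M1/PMd/PMv assignment (roughly 45/30/25%)."""
    n_m1 = max(1, int(round(0.45 * n_channels)))
    n_pmd = max(1, int(round(0.30 * n_channels)))
    areas = ["M1"] * n_m1 + ["PMd"] * n_pmd
    areas += ["PMv"] * (n_channels - len(areas))
    return areas[:n_channels]


def generate_session(cfg: SynthConfig) -> tuple[SessionDataset, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    Identical configs (including seed) give identical sessions.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- event times ---------------------------------------------------
    jitter = rng.uniform(-0.2, 0.2, cfg.n_trials)
    events = 2.0 + np.arange(cfg.n_trials) * cfg.trial_spacing_s + jitter
    duration = float(events[-1] + 2.0)
    n200 = int(round(duration * FS_MOD))
    profile = _bump_profile()

    # --- cortical latent envelopes and raw ECoG ------------------------
    latent_env = np.empty((cfg.n_ecog_channels, n200))
    n_raw_ecog = int(round(duration * cfg.ecog_fs))
    t_raw = np.arange(n_raw_ecog) / cfg.ecog_fs
    t200 = np.arange(n200) / FS_MOD
    ecog = np.empty((cfg.n_ecog_channels, n_raw_ecog))
    sos_carrier = sps.butter(4, [60.0, 180.0], btype="bandpass", fs=cfg.ecog_fs, output="sos")
    sos_lf = sps.butter(2, 10.0, btype="low", fs=cfg.ecog_fs, output="sos")
    for k in range(cfg.n_ecog_channels):
        env = np.ones(n200)
        # multi-fold band-power increases, as typical for movement-locked
        # high-gamma; the depth must clear the chi-square estimator noise
        # of 100-ms band-power frames
        amps = rng.uniform(2.0, 4.0) * (1.0 + 0.3 * rng.uniform(-1, 1, cfg.n_trials))
        _add_bumps(env, events, -cfg.cortical_lead_ms, amps, profile)
        env += _slow_noise(rng, n200, sd=0.05)
        latent_env[k] = np.maximum(env, 0.05)
        carrier = sps.sosfilt(sos_carrier, rng.standard_normal(n_raw_ecog))
        lf = sps.sosfilt(sos_lf, rng.standard_normal(n_raw_ecog))
        env_up = np.interp(t_raw, t200, latent_env[k])
        ecog[k] = 20.0 * np.sqrt(env_up) * carrier + 30.0 * lf

    # --- afferent spike trains -----------------------------------------
    latent_rate = np.empty((cfg.n_afferent_units, n200))
    spike_trains: list[np.ndarray] = []
    lo, hi = cfg.afferent_baseline_hz
    for k in range(cfg.n_afferent_units):
        rate = np.full(n200, rng.uniform(lo, hi))
        amps = rng.uniform(20.0, 60.0) * (1.0 + 0.3 * rng.uniform(-1, 1, cfg.n_trials))
        _add_bumps(rate, events, cfg.afferent_delay_ms, amps, profile)
        latent_rate[k] = rate
        spikes = _poisson_spikes(rate, rng)
        # keep spikes inside the shortest raw-signal span (sample rounding)
        spike_trains.append(spikes[spikes < duration - 2e-3])

    # --- preprocessed-domain input traces ------------------------------
    hg = preprocess.high_gamma(ecog, cfg.ecog_fs)
    descending = hg.mean
    afferent = np.stack(
        [preprocess.afferent_rate(st, duration) for st in spike_trains], axis=0
    )
    n_common = min(descending.shape[-1], afferent.shape[-1], n200)
    descending = descending[:, :n_common]
    afferent = afferent[:, :n_common]
    latent_env = latent_env[:, :n_common]
    latent_rate = latent_rate[:, :n_common]

    # --- ground-truth weights ------------------------------------------
    if cfg.descending_support_channels is not None:
        d_support = np.asarray(cfg.descending_support_channels, dtype=int)
    else:
        n_sup = int(round(cfg.support_fraction * cfg.n_ecog_channels))
        d_support = np.sort(rng.choice(cfg.n_ecog_channels, size=n_sup, replace=False))
    if cfg.afferent_support_channels is not None:
        a_support = np.asarray(cfg.afferent_support_channels, dtype=int)
    else:
        n_sup = int(round(cfg.support_fraction * cfg.n_afferent_units))
        a_support = np.sort(rng.choice(cfg.n_afferent_units, size=n_sup, replace=False))

    w_desc = _sample_weights(rng, cfg.n_muscles, cfg.n_ecog_channels, d_support)
    w_aff = _sample_weights(rng, cfg.n_muscles, cfg.n_afferent_units, a_support)

    # The mixture acts on input modulations: session means are removed
    # first so tonic power/rate levels do not pile into a huge EMG
    # offset.  Constants cancel identically under epoching, so the
    # epoched mixture is unaffected.
    desc_mod = descending - descending.mean(axis=1, keepdims=True)
    aff_mod = afferent - afferent.mean(axis=1, keepdims=True)

    # scale so both classes contribute comparably, then flip the afferent
    # sign on "antagonist" muscles (reciprocal-inhibition analog)
    y_desc = forward_emg(desc_mod, w_desc)
    y_aff = forward_emg(aff_mod, w_aff)
    for j in range(cfg.n_muscles):
        sd_d, sd_a = y_desc[j].std(), y_aff[j].std()
        scale = cfg.afferent_balance * sd_d / sd_a if sd_a > 0 else 0.0
        w_aff[j] *= scale
        y_aff[j] *= scale
    n_neg = int(round(cfg.negative_afferent_fraction * cfg.n_muscles))
    antagonists = np.arange(cfg.n_muscles - n_neg, cfg.n_muscles)
    w_aff[antagonists] *= -1.0
    y_aff[antagonists] *= -1.0

    latent = y_desc + y_aff
    # The mixture model is defined on trial-epoched, baseline-subtracted
    # modulation traces.  Baseline-window means of the lagged inputs differ
    # slightly from the unlagged means, which would leave a small per-trial
    # constant inconsistency after epoching; remove it here so the epoched
    # EMG is an exact lagged mixture of the epoched inputs.
    _enforce_epoched_mixture(latent, np.concatenate([w_desc, w_aff], axis=1),
                             np.concatenate([desc_mod, aff_mod], axis=0), events)
    sd_mod = latent.std(axis=1, keepdims=True)
    noise = rng.normal(0.0, 1.0, latent.shape) * (cfg.noise_sd * sd_mod)
    offset = np.maximum(0.0, -(latent + noise).min(axis=1, keepdims=True)) + 0.5 * sd_mod
    latent_emg = latent + offset
    emg_mod = latent + noise + offset

    # --- raw EMG: modulation times a rectifiable in-band carrier --------
    # The carrier is a deterministic tone inside the 1.5-60 Hz envelope
    # band (per-muscle frequency, random phase): its rectified mean is
    # constant, so the envelope pipeline recovers the modulation rather
    # than carrier statistics.  Interference-pattern realism is not the
    # generator's aim; recoverability of the modulation is.
    n_raw_emg = int(round(duration * cfg.emg_fs))
    t_raw_emg = np.arange(n_raw_emg) / cfg.emg_fs
    emg_raw = np.empty((cfg.n_muscles, n_raw_emg))
    t_mod = np.arange(emg_mod.shape[-1]) / FS_MOD
    for j in range(cfg.n_muscles):
        freq = 35.0 + 1.7 * (j % 8)
        carrier = np.sin(2.0 * np.pi * freq * t_raw_emg + rng.uniform(0, 2 * np.pi))
        carrier /= np.abs(carrier).mean()
        emg_raw[j] = np.interp(t_raw_emg, t_mod, emg_mod[j]) * carrier

    # --- kinematics: one moving joint, smoothed ramp from onset ---------
    joints = ["wrist_FE", "elbow_FE", "shoulder_FE"]
    kin = np.zeros((len(joints), n200))
    ramp = _bump_profile(rise_ms=150.0, plateau_ms=800.0, fall_ms=400.0)
    _add_bumps(kin[0], events, 0.0, np.full(cfg.n_trials, 20.0), ramp)
    kin += 0.5 * rng.standard_normal(kin.shape)

    weights = np.concatenate([w_desc, w_aff], axis=1)
    support = np.zeros(cfg.n_ecog_channels + cfg.n_afferent_units, dtype=bool)
    support[d_support] = True
    support[cfg.n_ecog_channels + a_support] = True
    classes = np.array(
        ["descending"] * cfg.n_ecog_channels + ["afferent"] * cfg.n_afferent_units
    )

    session = SessionDataset(
        ecog=ecog,
        ecog_fs=cfg.ecog_fs,
        afferent_units=spike_trains,
        emg=emg_raw,
        emg_fs=cfg.emg_fs,
        events=events,
        ecog_areas=_areas_for(cfg.n_ecog_channels),
        ecog_grid=np.stack(
            [np.arange(cfg.n_ecog_channels) % 8, np.arange(cfg.n_ecog_channels) // 8],
            axis=1,
        ).astype(float),
        muscle_names=[f"muscle{j:02d}" for j in range(cfg.n_muscles)],
        unit_labels=[f"C{6 + k % 3}" for k in range(cfg.n_afferent_units)],
        kinematics=kin,
        kinematics_fs=FS_MOD,
        joint_names=joints,
        derived={"emg_mod": emg_mod, "descending": descending, "afferent": afferent},
    )
    session.validate()
    truth = GroundTruth(
        weights=weights,
        support_mask=support,
        latent_emg=latent_emg,
        emg_mod=emg_mod,
        descending=descending,
        afferent=afferent,
        latent_envelope=latent_env,
        latent_rate=latent_rate,
        events=events,
        input_classes=classes,
    )
    return session, truth
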