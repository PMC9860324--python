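"""Session container, HDF5 persistence, and run configuration.

A session is one continuous recording: multichannel ECoG with cortical
area labels, afferent unit spike times, multichannel EMG, optional joint
kinematics, and movement-onset event times.  All times are seconds from
recording start; epoching converts to ms relative to movement onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

logger = logging.getLogger(__name__)

KNOWN_GROUPS = {"ecog", "afferents", "emg", "kinematics", "events", "derived",
                "ground_truth", "models"}
AREAS = ("M1", "PMd", "PMv")


class SessionValidationError(ValueError):
    """A session field violates a container invariant."""


class SessionFormatError(ValueError):
    """An on-disk session file does not conform to the expected layout."""


@dataclass
class SessionDataset:
    """One recording session with all simultaneously acquired signals."""

    ecog: np.ndarray            # (n_channels, n_samples), uV
    ecog_fs: float
    afferent_units: list[np.ndarray]   # spike times, s
    emg: np.ndarray             # (n_muscles, n_samples), uV
    emg_fs: float
    events: np.ndarray          # movement onsets, s
    ecog_areas: list[str]       # per-channel area label in AREAS
    ecog_grid: np.ndarray       # (n_channels, 2) electrode grid position
    muscle_names: list[str]
    unit_labels: list[str]      # DRG segment label per unit
    kinematics: np.ndarray | None = None   # (n_joints, n_samples), deg
    kinematics_fs: float = 200.0
    joint_names: list[str] = field(default_factory=list)
    derived: dict | None = None  # continuous 200-Hz modulation traces

    # -- labels / geometry ---------------------------------------------
    @property
    def ecog_labels(self) -> list[str]:
        return [f"ecog{c:02d}" for c in range(self.ecog.shape[0])]

    @property
    def duration_s(self) -> float:
        spans = [self.ecog.shape[-1] / self.ecog_fs, self.emg.shape[-1] / self.emg_fs]
        if self.kinematics is not None and self.kinematics.size:
            spans.append(self.kinematics.shape[-1] / self.kinematics_fs)
        return min(spans)

    def validate(self) -> None:
        if self.ecog_fs <= 0 or self.emg_fs <= 0:
            raise SessionValidationError("sampling rates must be positive")
        n_ch = self.ecog.shape[0]
        if len(self.ecog_areas) != n_ch:
            raise SessionValidationError("ecog_areas: one area label per ECoG channel required")
        bad = sorted(set(self.ecog_areas) - set(AREAS))
        if bad:
            raise SessionValidationError(f"ecog_areas: unknown area label(s) {bad}")
        if self.ecog_grid.shape != (n_ch, 2):
            raise SessionValidationError("ecog_grid: expected (n_channels, 2) positions")
        if self.emg.shape[0] != len(self.muscle_names):
            raise SessionValidationError("muscle_names: one name per EMG channel required")
        if len(self.afferent_units) != len(self.unit_labels):
            raise SessionValidationError("unit_labels: one label per afferent unit required")
        dur = self.duration_s
        ev = np.asarray(self.events, dtype=float)
        if ev.size and (ev.min() < 1.25 or ev.max() > dur - 1.5):
            raise SessionValidationError(
                "events: every event must lie >= 1.25 s after recording start "
                "and >= 1.5 s before its end"
            )
        for i, st in enumerate(self.afferent_units):
            st = np.asarray(st)
            if st.size and (np.any(np.diff(st) < 0) or st.min() < 0 or st.max() > dur + 1e-9):
                raise SessionValidationError(f"afferent_units[{i}]: spike times unsorted or out of span")


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def write_session(session: SessionDataset, path: str | Path) -> None:
    """Write a validated session to an HDF5 container."""
    session.validate()
    with h5py.File(path, "w") as f:
        g = f.create_group("ecog")
        g.create_dataset("data", data=session.ecog)
        g.attrs["fs"] = float(session.ecog_fs)
        g.create_dataset("areas", data=np.array(session.ecog_areas, dtype="S"))
        g.create_dataset("grid", data=np.asarray(session.ecog_grid))

        g = f.create_group("afferents")
        g.create_dataset("labels", data=np.array(session.unit_labels, dtype="S"))
        for i, st in enumerate(session.afferent_units):
            g.create_dataset(f"unit_{i:03d}", data=np.asarray(st, dtype=float))

        g = f.create_group("emg")
        g.create_dataset("data", data=session.emg)
        g.attrs["fs"] = float(session.emg_fs)
        g.create_dataset("muscles", data=np.array(session.muscle_names, dtype="S"))

        if session.kinematics is not None:
            g = f.create_group("kinematics")
            g.create_dataset("data", data=session.kinematics)
            g.attrs["fs"] = float(session.kinematics_fs)
            g.create_dataset("joints", data=np.array(session.joint_names, dtype="S"))

        f.create_dataset("events", data=np.asarray(session.events, dtype=float))

        if session.derived:
            g = f.create_group("derived")
            for key, val in session.derived.items():
                g.create_dataset(key, data=np.asarray(val))


def _decode(arr) -> list[str]:
    return [s.decode() if isinstance(s, bytes) else str(s) for s in arr]


def read_session(path: str | Path) -> SessionDataset:
    """Read a session container; tolerant of extra groups, strict on missing ones."""
    with h5py.File(path, "r") as f:
        for name in ("ecog", "afferents", "emg", "events"):
            if name not in f:
                raise SessionFormatError(f"missing required group /{name}")
        for name in f:
            if name not in KNOWN_GROUPS and name != "events":
                logger.warning("ignoring unknown group /%s", name)

        g = f["ecog"]
        ecog = g["data"][...]
        ecog_fs = float(g.attrs["fs"])
        areas = _decode(g["areas"][...])
        grid = g["grid"][...]

        g = f["afferents"]
        unit_labels = _decode(g["labels"][...])
        units = [g[k][...] for k in sorted(g) if k.startswith("unit_")]

        g = f["emg"]
        emg = g["data"][...]
        emg_fs = float(g.attrs["fs"])
        muscles = _decode(g["muscles"][...])

        kin = None
        kin_fs = 200.0
        joints: list[str] = []
        if "kinematics" in f:
            g = f["kinematics"]
            kin = g["data"][...]
            kin_fs = float(g.attrs["fs"])
            joints = _decode(g["joints"][...])

        events = f["events"][...]

        derived = None
        if "derived" in f:
            derived = {k: f["derived"][k][...] for k in f["derived"]}

    return SessionDataset(
        ecog=ecog,
        ecog_fs=ecog_fs,
        afferent_units=units,
        emg=emg,
        emg_fs=emg_fs,
        events=events,
        ecog_areas=areas,
        ecog_grid=grid,
        muscle_names=muscles,
        unit_labels=unit_labels,
        kinematics=kin,
        kinematics_fs=kin_fs,
        joint_names=joints,
        derived=derived,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis parameters shared across pipeline stages.

    Defaults follow the study conditions: 5-ms lag bins over 5-50 ms of
    input history, high-gamma bands 60-120 and 120-180 Hz, epochs of
    -500..+1500 ms with a -1250..-750 ms baseline, and sixfold
    cross-validation with 108 training and 21 test trials.
    """

    delta_ms: float = 5.0
    l_min: int = -10
    l_max: int = -1
    hg_bands: tuple = ((60.0, 120.0), (120.0, 180.0))
    hg_mode: str = "mean"         # "mean", "hg1", "hg2" or "separate"
    epoch_ms: tuple = (-500.0, 1500.0)
    baseline_ms: tuple = (-1250.0, -750.0)
    n_folds: int = 6
    n_train: int = 108
    n_test: int = 21
    modulation_window_ms: tuple = (-100.0, 1150.0)
    initial_movement_window_ms: tuple = (55.0, 100.0)
    sliding_window_ms: float = 500.0
    sliding_step_ms: float = 100.0
    shuffle_block_ms: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        if self.delta_ms <= 0:
            raise ValueError("delta_ms must be positive")
        if not (self.l_min <= self.l_max < 0):
            raise ValueError("lag indices must be strictly negative with l_min <= l_max")
        for name in ("epoch_ms", "baseline_ms", "modulation_window_ms",
                     "initial_movement_window_ms"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy start < end")
        if self.n_folds < 1 or self.n_train < 1 or self.n_test < 1:
            raise ValueError("CV sizes must be positive")
        if self.hg_mode not in ("mean", "hg1", "hg2", "separate"):
            raise ValueError(f"unknown hg_mode {self.hg_mode!r}")

    def scaled_for(self, n_trials: int) -> "RunConfig":
        """Copy with train/test sizes scaled to ``n_trials`` (108/21-of-129 ratio)."""
        from dataclasses import replace

        n_test = max(1, int(round(n_trials * 21 / 129)))
        n_train = min(n_trials - n_test, max(1, int(round(n_trials * 108 / 129))))
        return replace(self, n_train=n_train, n_test=n_test)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload = payload.get("run", payload)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        for key in ("hg_bands",):
            if key in payload:
                payload[key] = tuple(tuple(b) for b in payload[key])
        for key in ("epoch_ms", "baseline_ms", "modulation_window_ms",
                    "initial_movement_window_ms"):
            if key in payload:
                payload[key] = tuple(payload[key])
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k, v in payload.items():
            if isinstance(v, tuple):
                payload[k] = [list(b) if isinstance(b, tuple) else b for b in v]
        with open(path, "w") as fh:
            yaml.safe_dump({"run": payload}, fh)
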