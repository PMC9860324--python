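"""End-to-end orchestration: simulate -> preprocess -> fit -> decompose
-> events -> evaluate, with per-stage artifacts and a run manifest.

Every stage is deterministic given the config and the global seed; the
seed is expanded into independent per-stage substreams so stages are
individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import events as events_mod
from .components import component, initial_movement_afferent_size, size_table
from .evaluate import (
    crossvalidate,
    pruning_stats,
    shuffle_control,
    sliding_window_eval,
    sliding_window_medians,
)
from .lagmodel import LagSpec, SparseLagRegression, SparseLagResults
from .preprocess import epoch_and_baseline, preprocess_session
from .session import RunConfig, SessionDataset, read_session, write_session
from .synthetic import SynthConfig, generate_session
from .tensors import stack_inputs

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "fit", "decompose", "events", "evaluate")


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's artifact is absent."""

    def __init__(self, stage: str, path: Path):
        super().__init__(f"stage '{stage}' requires missing artifact {path}")
        self.stage = stage


def load_configs(path: str | Path | None) -> tuple[SynthConfig, RunConfig]:
    """Read ``synth:`` and ``run:`` sections from one YAML file."""
    if path is None:
        return SynthConfig(), RunConfig()
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    synth = payload.get("synth", {})
    known = set(SynthConfig.__dataclass_fields__)
    unknown = set(synth) - known
    if unknown:
        raise ValueError(f"unknown synth-config keys: {sorted(unknown)}")
    if "afferent_baseline_hz" in synth:
        synth["afferent_baseline_hz"] = tuple(synth["afferent_baseline_hz"])
    synth_cfg = SynthConfig(**synth)
    run_payload = payload.get("run", {})
    run_cfg = RunConfig(**{}) if not run_payload else RunConfig.from_yaml(path)
    return synth_cfg, run_cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Independent sub-seeds (< 2**31) per randomised stage."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    names = ("simulate", "crossval", "shuffle")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def config_hash(synth_cfg: SynthConfig, run_cfg: RunConfig) -> str:
    payload = json.dumps(
        {"synth": asdict(synth_cfg), "run": asdict(run_cfg)},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def simulate_stage(synth_cfg: SynthConfig, out: Path, seed: int) -> Path:
    cfg = SynthConfig(**{**asdict(synth_cfg), "seed": seed})
    session, truth = generate_session(cfg)
    path = out / "session.h5"
    write_session(session, path)
    with h5py.File(path, "a") as f:
        g = f.create_group("ground_truth")
        g.create_dataset("weights", data=truth.weights)
        g.create_dataset("support_mask", data=truth.support_mask)
        g.create_dataset("latent_emg", data=truth.latent_emg)
        g.create_dataset("input_classes", data=truth.input_classes.astype("S"))
    return path


def preprocess_stage(session_path: Path, run_cfg: RunConfig, emg_source: str = "raw") -> dict:
    if not session_path.exists():
        raise MissingArtifactError("preprocess", session_path)
    session = read_session(session_path)
    tensors = preprocess_session(session, run_cfg, emg_source=emg_source)
    with h5py.File(session_path, "a") as f:
        g = f.require_group("derived")
        for key, tensor in tensors.items():
            name = f"epoch_{key}"
            if name in g:
                del g[name]
            d = g.create_dataset(name, data=tensor.values)
            d.attrs["kind"] = tensor.kind
        if "epoch_times" in g:
            del g["epoch_times"]
        g.create_dataset("epoch_times", data=tensors["emg"].times)
    return tensors


def fit_stage(session_path: Path, tensors: dict, run_cfg: RunConfig, variant: str = "both") -> SparseLagResults:
    inputs, classes = stack_inputs(tensors["descending"], tensors["afferent"])
    spec = LagSpec(run_cfg.delta_ms, run_cfg.l_min, run_cfg.l_max)
    model = SparseLagRegression(tensors["emg"], inputs, classes, spec).restricted(variant)
    results = model.fit()
    with h5py.File(session_path, "a") as f:
        if "models" in f:
            del f["models"]
        g = f.create_group("models")
        g.attrs["variant"] = variant
        g.create_dataset("weights", data=results.weights)
        g.create_dataset("alpha", data=results.alpha)
        g.create_dataset("pruned", data=results.pruned)
        g.create_dataset("channel_classes", data=results.channel_classes.astype("S"))
    return results


def run_pipeline(
    config_path: str | Path | None,
    outdir: str | Path,
    seed: int = 0,
    stages: tuple[str, ...] = STAGES,
    emg_source: str = "raw",
    with_shuffle: bool = True,
    with_sliding: bool = False,
) -> dict:
    """Run the pipeline and return the manifest (also written as JSON)."""
    synth_cfg, run_cfg = load_configs(config_path)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest: dict = {
        "seed": seed,
        "stage_seeds": seeds,
        "config_hash": config_hash(synth_cfg, run_cfg),
        "stages": {},
        "artifacts": {},
    }
    session_path = out / "session.h5"

    if "simulate" in stages:
        session_path = simulate_stage(synth_cfg, out, seeds["simulate"])
        manifest["stages"]["simulate"] = "done"
        manifest["artifacts"]["simulate"] = [str(session_path)]

    tensors = None
    if "preprocess" in stages:
        tensors = preprocess_stage(session_path, run_cfg, emg_source=emg_source)
        manifest["stages"]["preprocess"] = "done"
        manifest["artifacts"]["preprocess"] = [str(session_path) + "#/derived"]
    elif any(s in stages for s in ("fit", "decompose", "events", "evaluate")):
        if not session_path.exists():
            raise MissingArtifactError("fit", session_path)
        tensors = preprocess_stage(session_path, run_cfg, emg_source=emg_source)

    results = None
    if "fit" in stages:
        results = fit_stage(session_path, tensors, run_cfg)
        (out / "model_summary.txt").write_text(results.summary() + "\n")
        manifest["stages"]["fit"] = "done"
        manifest["artifacts"]["fit"] = [str(session_path) + "#/models",
                                        str(out / "model_summary.txt")]

    if tensors is not None:
        inputs, classes = stack_inputs(tensors["descending"], tensors["afferent"])

    if "decompose" in stages:
        if results is None:
            raise MissingArtifactError("decompose", session_path)
        sizes = size_table(results, inputs, tuple(run_cfg.modulation_window_ms))
        aff = component(results, inputs, "afferent")
        initial = initial_movement_afferent_size(
            aff, tuple(run_cfg.initial_movement_window_ms)
        )
        sizes_path = out / "component_sizes.csv"
        sizes.to_csv(sizes_path, index=False)
        initial_df = pd.DataFrame({
            "muscle": results.muscle_names,
            "initial_afferent_size": initial,
        })
        initial_path = out / "initial_afferent_sizes.csv"
        initial_df.to_csv(initial_path, index=False)
        manifest["stages"]["decompose"] = "done"
        manifest["artifacts"]["decompose"] = [str(sizes_path), str(initial_path)]

    cv = None
    if "events" in stages or "evaluate" in stages:
        shuffled_tensor = None
        variants = ["both", "descending", "afferent"]
        if with_shuffle:
            session = read_session(session_path)
            cont = np.concatenate(
                [session.derived["descending"], session.derived["afferent"]], axis=0
            ) if session.derived else None
            if cont is not None:
                block = int(round(run_cfg.shuffle_block_ms / 5.0))
                shuf = shuffle_control(cont, block, np.random.default_rng(seeds["shuffle"]))
                shuffled_tensor = epoch_and_baseline(
                    shuf, session.events, list(inputs.labels), "inputs",
                    tuple(run_cfg.epoch_ms), tuple(run_cfg.baseline_ms),
                )
                variants.append("shuffled")
        cv = crossvalidate(
            tensors["emg"], inputs, classes, run_cfg, seed=seeds["crossval"],
            variants=tuple(variants), shuffled_inputs=shuffled_tensor,
        )

    if "events" in stages:
        table = events_mod.onset_table(cv.fold_traces, cv.times_by_kind)
        summary = events_mod.session_onset_summary(table)
        onsets_path = out / "onsets.csv"
        table.to_csv(onsets_path, index=False)
        summary_path = out / "onsets_summary.csv"
        summary.to_csv(summary_path, index=False)
        manifest["stages"]["events"] = "done"
        manifest["artifacts"]["events"] = [str(onsets_path), str(summary_path)]

    if "evaluate" in stages:
        metrics_path = out / "metrics.csv"
        cv.metrics.to_csv(metrics_path, index=False)
        prune_path = out / "pruning.csv"
        pd.concat(
            [pruning_stats(r).assign(fold=i) for i, r in enumerate(cv.fold_results)]
        ).to_csv(prune_path, index=False)
        artifacts = [str(metrics_path), str(prune_path)]
        if with_sliding:
            sw = sliding_window_eval(tensors["emg"], inputs, classes, run_cfg,
                                     seed=seeds["crossval"])
            sw_path = out / "sliding_window.csv"
            sliding_window_medians(sw).to_csv(sw_path, index=False)
            artifacts.append(str(sw_path))
        summary = {
            "config_hash": manifest["config_hash"],
            "seed": seed,
            "mean_vaf": cv.session_means().groupby("variant")["vaf"].mean().to_dict(),
        }
        summary_path = out / "run_summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
        artifacts.append(str(summary_path))
        manifest["stages"]["evaluate"] = "done"
        manifest["artifacts"]["evaluate"] = artifacts

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
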