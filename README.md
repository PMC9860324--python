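# myodecode

Reconstruction of forelimb muscle activity from simultaneously recorded
motor-cortical and peripheral-afferent signals, for researchers asking
how descending motor commands and somatosensory feedback converge on
spinal motor neurons during voluntary movement.

During reaching, motor-cortical (M1/PMd/PMv) high-gamma activity rises
*before* movement onset while peripheral afferents start firing *at*
movement onset.  `myodecode` models the EMG envelope of each muscle
*j* as a lagged linear mixture of both input classes,

    y_j(t) = Σ_k Σ_l  w_{j,k,l} · x_k(t + lδ),     δ = 5 ms,  l = −10 … −1,

where x_k are 200-Hz movement-related modulation traces: normalized
ECoG high-gamma band power ("descending input") and exponential-kernel
firing rates of afferent units ("afferent input"), each taken 5–50 ms
before the predicted EMG sample.  Weights are estimated by grouped
automatic relevance determination — one relevance hyperparameter per
input channel, shared by its ten lag weights — so uninformative
channels are pruned exactly to zero.  Because the model is linear, the
reconstruction decomposes exactly into descending and afferent
components (or per-area and per-electrode subcomponents), whose onset
times and sizes quantify *when* and *how much* each pathway contributes.

A synthetic-session generator with a known forward model stands in for
animal recordings, so every stage — signal conditioning, decoding,
attribution, onset detection, cross-validation, controls — is testable
at desk scale against exact ground truth.

## Worked example

```python
import numpy as np
from myodecode import (
    SynthConfig, generate_session, preprocess_session, RunConfig,
    SparseLagRegression, crossvalidate, stack_inputs,
)
from myodecode.components import component, initial_movement_afferent_size
from myodecode.events import onset_table, session_onset_summary

cfg = SynthConfig(n_ecog_channels=12, n_afferent_units=10, n_muscles=4,
                  n_trials=60, trial_spacing_s=3.5, seed=0)
session, truth = generate_session(cfg)

run_cfg = RunConfig().scaled_for(60)          # 108/21-of-129 CV ratio at 60 trials
tensors = preprocess_session(session, run_cfg, emg_source="derived")
inputs, classes = stack_inputs(tensors["descending"], tensors["afferent"])

results = SparseLagRegression(tensors["emg"], inputs, classes).fit()
print(results.summary())
```

```
Sparse lagged EMG decoder (grouped ARD)
  inputs: 22 channels x 10 lags (5-50 ms history)
  muscles: 4

  muscle       retained   desc    aff  iters  conv  noise SD
  muscle00         0.50   0.50   0.50     15  True      11.4
  muscle01         0.50   0.50   0.50     14  True      10.5
  muscle02         0.50   0.50   0.50     13  True      9.26
  muscle03         0.50   0.50   0.50     16  True      5.33
```

Half of the channels are retained per muscle — exactly the generator's
ground-truth support fraction: the decoder prunes the channels that do
not drive this session's EMG.  Cross-validated accuracy and the onset
times of the input components:

```python
cv = crossvalidate(tensors["emg"], inputs, classes, run_cfg, seed=1)
print(cv.session_means().groupby("variant")[["r", "vaf"]].mean().round(3))

summary = session_onset_summary(onset_table(cv.fold_traces, cv.times_by_kind))
print(summary.pivot(index="muscle", columns="kind", values="onset_ms").round(1))

aff = component(results, inputs, "afferent")
print(np.round(initial_movement_afferent_size(aff), 3))
```

```
                r    vaf
variant
afferent    0.755  0.575
both        0.969  0.939
descending  0.854  0.716

kind    afferent  descending  observed  reconstruction
muscle
0          116.7       -77.5     -80.0           -78.3
1          115.8       -79.2     -77.5           -78.3
2          117.5       -78.3     -75.0           -77.5
3            NaN       -90.8     -90.0           -90.8

[ 8.351  7.522  6.344 -8.232]
```

Read this as the study's core result in miniature: the model using both
inputs reconstructs held-out EMG best (VAF 0.94 vs 0.72/0.58 for either
input alone); the descending component rises with the observed EMG
≈80 ms *before* movement onset while the afferent component rises
≈120 ms *after* it (muscle 3's afferent effect is suppressive, so it
never crosses the positive threshold); and the early-movement
(55–100 ms) afferent size is positive for the three facilitated muscles
and negative for the reciprocally inhibited one.

## Command line

The same pipeline runs from the shell, each stage seeded and
reproducible:

```sh
myodecode run --config config.yaml --seed 1 --out runs/demo
myodecode simulate --seed 1 --out runs/demo        # individual stages
myodecode evaluate --sliding --out runs/demo
```

Artifacts are an HDF5 session container (`/ecog`, `/afferents`, `/emg`,
`/kinematics`, `/events`, plus `/derived` tensors and `/models`), CSV
metric/onset/component-size tables, and a JSON run manifest; re-running
with the same config and seed reproduces them bit for bit.

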