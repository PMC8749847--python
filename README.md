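# gaitmood

Emotion recognition from skeletal gait sequences: handcrafted joint-relative
geometric features fused with raw motion-capture coordinates, classified by a
tapered LSTM + MLP network, plus a synthetic gait generator so the entire
pipeline runs and is tested without any external data.

A gait sequence is a `T x V x C` tensor (frames x joints x axes; the default
skeleton has 16 joints, 3 coordinates, 60 Hz). Per frame the network input
concatenates:

* the flattened raw coordinates (width `V*C` = 48),
* joint relative angles (JRA) at the mid-spine joint, `C(V-1,2)` = 105 columns,
* joint relative distances (JRD) for all joint pairs, `C(V,2)` = 120 columns,

for a total width of 273. The classifier is a three-layer LSTM stack
(128/64/64 units, tanh) followed by a tapered MLP (64/32/32, tanh, optional
batch normalization after the first layer, dropout 0.2 after the second) and
a 4-class softmax. Training uses RMSprop (momentum 0.5, rho 0.3, epsilon
1e-7, learning rate 1e-4), categorical cross-entropy, batch 64, stratified
80:10:10 splitting. The whole network — batched LSTM with backpropagation
through time, batch-norm, dropout, RMSprop — is implemented in NumPy
(`gaitmood/_backend.py`); no deep-learning framework is required. A separate
per-timestep reference cell (`gaitmood.model_core.lstm_cell_step`) acts as an
independent oracle for the backend.

## CLI

Single entry point `gaitmood` with subcommands:

```bash
# synthetic dataset (CSV per sequence + JSON sidecars + manifest.json)
gaitmood simulate --out data/ --scale 0.1 --seed 1

# assembled feature matrices as CSV
gaitmood features --in data/manifest.json --out feats/ --jra --jrd

# train (YAML config optional; flags override)
gaitmood train --manifest data/manifest.json --seed 1 --out run/

# evaluate a run on its held-out test split
gaitmood evaluate --run run/ --manifest data/manifest.json --split test --out report.json

# parameter counts of the three published variants (180,484 / 295,684 / 295,940)
gaitmood params --json

# end-to-end desk-scale reproduction on synthetic data
gaitmood repro --seed 1 --scale 0.1 --out repro/
```

Exit codes: 0 success, 2 config error, 3 data/format error, 4 invariant
failure.

## Layout

| module | role |
| --- | --- |
| `gaitmood.skeleton_data` | topology/sequence/dataset types, CSV+JSON I/O, stratified splitting |
| `gaitmood.geometric_features` | JRA/JRD features and input assembly |
| `gaitmood.model_core` | reference LSTM cell, network builder, parameter counter, inference |
| `gaitmood._backend` | NumPy training backend (LSTM BPTT, dense, batch-norm, dropout, RMSprop) |
| `gaitmood.training` | training recipe, history, model persistence |
| `gaitmood.evaluation` | confusion matrix, per-class AP, micro/macro mAP |
| `gaitmood.synthetic_gait` | class-conditioned kinematic gait generator |
| `gaitmood.cli` | `gaitmood` command line |
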