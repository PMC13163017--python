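# bleatkit

Lightweight 1D acoustic-feature pipeline for classifying livestock
vocalizations on resource-constrained hardware. The pipeline turns raw WAV
clips into a 156-descriptor feature vector (MFCC/Δ/ΔΔ statistics, spectral
shape and contrast, temporal energy, ecoacoustic indices, and pYIN
fundamental-frequency statistics), balances and standardizes the training
partition (stratified split → SMOTE → z-score), trains classical classifiers
or a compact MLP, and reports support-weighted metrics plus an
edge-efficiency benchmark (inference latency and serialized footprint).

A deterministic synthetic bleat generator (`bleatkit.synth`) produces
class-conditioned harmonic/noisy/hybrid calls so the entire pipeline is
testable without any field recordings.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a full
end-to-end run (synthesize 480 clips → extract → split → SMOTE → scale →
MLP) that takes ~1 minute.

## CLI

```bash
# 1. generate a synthetic labeled corpus (<out>/<class_name>/NNNN.wav)
bleatkit simulate --out corpus/ --n-per-class 60 --seed 7

# 2. extract the feature table (clip_id, label, 156 feature columns)
bleatkit extract --in corpus/ --out features.csv --schema table1 --rate 22050

# 3. split / SMOTE / standardize / train / report held-out metrics
bleatkit train --features features.csv --model mlp --smote --seed 7 --out model.bundle

# 4. evaluate a saved bundle on a feature table
bleatkit evaluate --model model.bundle --features features.csv

# 5. latency + footprint benchmark
bleatkit bench --model model.bundle --repeats 30
```

`--schema extended` adds the per-coefficient standard deviations of the
three cepstral blocks (276 features total). Model families for `train
--model`: `mlp`, `gradient_boosted_trees`, `hist_gradient_boosting`,
`random_forest`, `extra_trees`, `k_nearest_neighbors`, `logistic`, `lda`,
`qda`, `ridge`, `linear_svm`, `naive_bayes`, `decision_tree`, `adaboost`,
`dummy_majority`.

## Package layout

| module | responsibility |
| --- | --- |
| `audio_io` | WAV read/write, polyphase resampling, 2-s duration standardization, corpus walker |
| `spectral` | STFT, RMS/ZCR/autocorrelation, flux/temporal centroid, centroid/bandwidth/roll-off/contrast/flatness/entropy |
| `cepstral` | 128-band mel bank, MFCCs, Δ/ΔΔ regression deltas, per-coefficient statistics |
| `pitch_eco` | probabilistic YIN pitch tracking, F0 statistics, Acoustic Complexity Index, bioacoustic index |
| `schema` | ordered 156/276-feature schema and full-vector extraction |
| `synth` | class-conditioned synthetic call generator and corpus writer |
| `prep` | stratified split, SMOTE, z-score scaler, importance-threshold selection |
| `models` | classifier families, MLP grid search, generic stochastic tuning |
| `evaluation` | confusion matrices, weighted metrics, Cohen's kappa, permutation importance |
| `benchmark` | per-sample latency and serialized-bundle footprint |
| `cli` | `bleatkit` subcommands tying the stages together |
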