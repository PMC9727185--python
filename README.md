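# ghknn

Binary classification of protein sequences with a graph-regularized kernel
local-hyperplane nearest-neighbour classifier (GHKNN), built around a
188-dimensional physicochemical sequence descriptor and SMOTE class
balancing.

## What it does

* **`ghknn.sequence_io`** — FASTA reading with residue cleaning (uppercase,
  nonstandard residues deleted, minimum cleaned length 2) and lossless
  TSV/CSV feature-table round-tripping.
* **`ghknn.features_188d`** — the 188-D descriptor: 20 amino-acid
  composition values plus, for each of 8 physicochemical properties
  (polarity, hydrophobicity, normalized van der Waals volume,
  polarizability, charge, secondary structure, solvent accessibility,
  surface tension), 3 composition + 15 distribution + 3 transition values.
  The 3-way residue partitions are shipped as an editable data file
  (`src/ghknn/data/ctd_groups.tsv`); the property order there fixes the
  feature layout.
* **`ghknn.resampling`** — SMOTE oversampling: synthetic minority rows
  `x + u * (x_n - x)` with `u ~ U(0,1)` and `x_n` among the k nearest
  minority neighbours; fully seed-reproducible.
* **`ghknn.ghknn`** — the classifier. Per class, a kernel local hyperplane
  is fitted through the test point's k class-neighbours by solving the
  positive-definite system `(K + lam*I + mu*L) alpha = K(V, x)` with ridge
  weight `lam`, RBF bandwidth `gamma`, and an unnormalized graph Laplacian
  `L` of the RBF similarity graph among the neighbours weighted by `mu`;
  the predicted class minimizes the kernel-space residual. The input-space
  baseline `hknn_distance` (linear kernel, `mu = 0`) is included and the
  two agree exactly in that configuration. Defaults: `lam=0.01`,
  `gamma=2**-15`, `mu=0.1`, `k=10`.
* **`ghknn.evaluation`** — SN/SP/ACC/MCC from pooled confusion counts,
  stratified k-fold cross-validation (fold-internal SMOTE by default, with
  an explicit leaky `resample_all` variant), one-parameter-at-a-time
  sweeps, and the end-to-end pipeline driver.
* **`ghknn.synthetic_data`** — seeded fixtures: two sequence populations
  with a controllable residue-composition bias, and Gaussian feature
  clusters for classifier-only tests.
* **`ghknn.cli`** — one executable with subcommands.

## CLI

```bash
# generate a synthetic labeled FASTA
ghknn simulate --n-pos 100 --n-neg 100 --bias 2 --seed 7 \
    --out synth.fasta --labels labels.tsv

# extract features (188d or aac)
ghknn extract --in synth.fasta --labels labels.tsv --out feats.tsv

# SMOTE-balance a feature table
ghknn balance --in feats.tsv --out feats_bal.tsv --k 5 --seed 7 --target match

# cross-validated metrics
ghknn eval --in feats.tsv --out metrics.json --folds 5 --seed 7

# one-parameter sweep
ghknn sweep --in feats.tsv --out sweep.csv --which lam --grid 0.01,0.1,1,10

# predict a test table against a training table
ghknn predict --train feats.tsv --test feats.tsv --out preds.tsv \
    --lam 0.01 --gamma 3.0517578125e-05 --mu 0.1 --k 10

# full pipeline from a YAML config (flags override the file)
ghknn run --config config.yaml --seed 7
```

A minimal `config.yaml`:

```yaml
fasta: synth.fasta
labels: labels.tsv
descriptor: 188d
params: {lam: 0.01, gamma: 3.0517578125e-05, mu: 0.1, k: 10}
resample: {enabled: true, k_neighbors: 5, target: match, apply: train-folds}
cv_folds: 5
seed: 7
out_dir: results
```

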