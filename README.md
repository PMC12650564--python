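# gpcomp

Genomic prediction on autoencoder-compressed genotype matrices.

The pipeline takes diploid biallelic SNP dosages (0/1/2) from a VCF or a
delimited matrix, applies marker quality control (call rate, minor allele
frequency, Hardy–Weinberg), one-hot encodes the dosages, splits the encoded
matrix into approximately equal SNP chunks, trains one small symmetric
autoencoder per chunk (ReLU encoder, sigmoid bottleneck and decoder,
element-wise reconstruction MSE), and concatenates the bottleneck
activations into a compressed feature matrix. Breeding values are then
predicted with:

- **GBLUP** — genomic relationship matrix from raw dosages
  (allele-frequency-centered `W Wᵀ / Σ2pq`) or from standardized compressed
  features (`X Xᵀ / n_cols`), REML variance components via
  eigendecomposition, and BLUP of breeding values with validation
  phenotypes masked;
- **Bayesian whole-genome regression** — from-scratch Gibbs samplers for
  four marker-effect priors: per-marker variances, spike-and-slab with
  fixed null proportion π (default 0.99), common-slab with π estimated,
  and the Bayesian lasso (defaults: 18,000 cycles, 3,000 burn-in);
- **ML regressors** — SVR, random forest, kernel ridge, and
  gradient-boosted trees, tuned by grid search with an inner 5-fold CV on
  the training fold only (the gradient-boosting method is backed by
  scikit-learn's `HistGradientBoostingRegressor`).

Everything is evaluated by repeated k-fold cross-validation (default
20 × 5) with accuracy (Pearson r), dispersion bias (|1 − b_y,GEBV|), MSE,
and MAE, reported per fold and pooled.

A `synthetic_data` module generates test populations with tunable allele
frequencies, geometric adjacent-marker LD, optional full-sib families, and
additive phenotypes whose realized heritability hits the target exactly.

## CLI

Each stage runs standalone and hands off through files in a run directory
(per-chunk CSVs plus JSON manifests with checksums), or the whole flow runs
from one YAML config:

```sh
gpcomp simulate --out sim --n-individuals 200 --m-snps 500 --h2 0.5 --seed 1
gpcomp qc --genotypes sim/genotypes.tsv --out qc
gpcomp encode --genotypes qc/genotypes_qc.tsv --out enc --n-chunks 10
gpcomp compress --chunks enc/chunks_manifest.json --out comp --neurons 20,16,12,5
gpcomp evaluate --features comp/compressed.tsv --phenotypes sim/phenotypes.tsv \
    --method gblup,bayes_b,krr --out metrics
gpcomp run --config config.yaml --out rundir   # full pipeline
```

Example `config.yaml`:

```yaml
seed: 1
inputs:
  genotypes: sim/genotypes.tsv
  phenotypes: sim/phenotypes.tsv
qc: {min_call_rate: 0.90, min_maf: 0.05, hwe_p: 1.0e-7}
encoding: {n_chunks: 10}
autoencoder: {neurons: [20, 16, 12, 5], batch_size: 32, epochs: 200}
bayes: {iterations: 18000, burn_in: 3000}
cv: {k_folds: 5, repeats: 20}
predictors: [gblup, bayes_a, bayes_b, krr]
```

Reruns with the same config and seed reproduce all outputs byte-for-byte;
one global seed fans out to stage seeds by fixed offsets recorded in the
manifest. Exit codes: 0 ok, 2 config error, 3 data error, 4 numerical
failure.

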