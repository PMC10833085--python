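# scmtl

Multi-task deep learning for single-cell transcriptomics: train jointly on
one or more CITE-seq (or scRNA-seq) reference datasets and, for an scRNA-seq
query, produce **cell-type annotations**, **imputed surface-protein
expression**, and a shared **low-dimensional embedding**.

Highlights:

- **Hybrid feature extraction** — per-cell normalization + log transform,
  then two branches concatenated: (A) highly-variable-gene selection with
  per-gene scaling, and (B) empirical-Bayes batch correction (ComBat)
  followed by truncated SVD and maximum-likelihood factor analysis.
- **Heterogeneous panels** — references with different antibody panels are
  merged on the gene intersection / protein union; a censored MSE scores
  only proteins actually measured in each cell's source panel.
- **Balanced multi-task training** — a residual-block network with two
  linear heads; per-task loss weights are adapted every mini-batch so each
  task's gradient norm on the shared embedding weights tracks its relative
  training rate. Class imbalance is handled by logarithmic class weights
  (`log(total/count + alpha)`) and label-smoothed cross-entropy.
- **Synthetic data + noise injection** — a seeded CITE-seq simulator
  (negative-binomial RNA, linear protein readout, batch effects, rare types)
  plus exact-count dropout and label-noise corruption operators, so the full
  pipeline is testable offline.
- **Pure numpy network** — forward/backward passes are implemented by hand
  (no GPU or autodiff dependency); everything runs on CPU and is
  deterministic given a seed.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (loss/merge/decomposition
oracles, GradNorm finite-difference checks, end-to-end recovery, dropout
robustness, determinism).

## CLI

One entry point, `scmtl`, with subcommands `simulate`, `train`, `annotate`,
`predict-proteins`, `embed`, `evaluate`, `inject-noise`. Configuration is a
flat YAML file with prefixed keys (`sim_*`, `feat_*`, `net_*`, `train_*`)
and a global `seed`; unknown keys exit with code 2, missing files with 3.

```bash
# generate a synthetic multi-batch CITE-seq dataset
scmtl simulate --config sim.yaml --out data/

# train on one or more references (optionally transductive with a query)
scmtl train --config train.yaml --ref data/batch0 --ref data/batch1 --out model/

# annotate / impute / embed a query
scmtl annotate --model model/ --query data/batch0 --out pred.csv
scmtl predict-proteins --model model/ --query data/batch0 --out prot.csv
scmtl embed --model model/ --data data/batch0 --kind reference --out emb.csv

# score predictions
scmtl evaluate --truth data/batch0/labels.csv --pred pred.csv --out report.json

# corruption experiments
scmtl inject-noise --mode dropout --proportion 0.8 --seed 1 --input data/batch0 --out noisy/
```

Example config:

```yaml
seed: 0
feat_n_hvg: 550
feat_k_tsvd: 300
feat_k_fa: 180
net_hidden_dim: 512
net_n_resnet_blocks: 4
net_embedding_dim: 128
train_epochs: 100
train_batch_size: 512
```

Supported dataset formats (`--format`): directory-based `csv` (dense matrix,
header = gene ids) and `mtx` (Matrix Market + gene/barcode sidecars), and
single-file `h5ad`.

## Package layout

```
src/scmtl/
  data_model.py   # dataset containers, panel merging, filtering, I/O
  features.py     # normalize/log, HVG, ComBat, TSVD, FA, block assembly
  network.py      # residual multi-task network (numpy forward/backward)
  objectives.py   # class weights, smoothed CE, censored MSE, GradNorm
  training.py     # training loop, inference endpoints, pipeline helper
  synthetic.py    # CITE-seq simulator + dropout / label-noise injection
  evaluation.py   # accuracy/F1, protein PCC/RMSE, ARI, Kruskal-Wallis
  cli.py          # subcommand wiring, config validation, exit codes
```
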