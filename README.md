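# gaelink

Link prediction for labelled bipartite association matrices (miRNA–disease
style) by collaboratively training two graph autoencoders — one propagating
the association matrix over a row-entity similarity graph, the other
propagating its transpose over a column-entity similarity graph — under a
joint objective that couples an attention-gated matrix-completion term with
the two reconstruction errors.

The package covers the full pipeline:

- **Similarity construction** (`gaelink.similarity`): Gaussian
  interaction-profile kernels from the association matrix, curated
  functional-similarity fusion for row entities, and hierarchy-based
  semantic similarity (decay-based and information-content-based
  contribution models, averaged) for column entities, with the Gaussian
  kernel as fallback for uncovered pairs.
- **Graph normalization** (`gaelink.graph`): symmetric degree
  normalization `D^{-1/2} S D^{-1/2}`.
- **Model** (`gaelink.model`): two four-layer graph autoencoders
  (tanh/ReLU encoder, sigmoid/ReLU decoder), convex score blending,
  rowwise-softmax attention scoring, and an Adam training loop. Forward and
  backward passes are hand-written dense NumPy, so the objective is literal
  and the gradients are finite-difference checkable.
- **Evaluation** (`gaelink.evaluation`): confusion metrics (including
  Matthews correlation), AUROC/AUPR, sensitivity at fixed specificity
  (default 0.99), a leak-free five-fold cross-validation harness that
  recomputes all Y-derived similarities per training fold, and a
  hyperparameter sweep driver.
- **Synthetic data** (`gaelink.synthetic`): seeded planted-community
  generators emitting association edge lists, curated similarity tables,
  and random disease hierarchies in the same TSV dialects the CLI reads.
- **CLI and I/O** (`gaelink.cli`, `gaelink.io`, `gaelink.ranking`):
  end-to-end commands and per-disease top-k candidate ranking.

## CLI

```bash
# generate a planted synthetic dataset
gaelink simulate --out data/ --m 200 --n 150 --rank 3 --density 0.03 \
    --noise 0.05 --curated-coverage 0.5 --dag-coverage 0.5 --seed 1

# build the fused similarity matrices
gaelink similarity --associations data/associations.tsv \
    --mirna-sim data/mirna_similarity.tsv \
    --dag-edges data/dag_edges.tsv --dag-membership data/dag_membership.tsv \
    --out-mirna data/Sm.tsv --out-disease data/Sd.tsv

# five-fold cross-validation report
gaelink cv --associations data/associations.tsv --seed 1 --out cv.tsv

# train on the full matrix, then rank unknown candidates per disease
gaelink train --associations data/associations.tsv --seed 1 \
    --out-checkpoint model.json --out-scores F.tsv
gaelink predict --associations data/associations.tsv --scores F.tsv \
    -k 50 --out rankings.tsv

# hyperparameter grids
gaelink sweep --associations data/associations.tsv --seed 1 \
    --param alpha=0.1,0.3,0.5,0.7,0.9 --out sweep.tsv
```

Hyperparameters can be supplied as a flat `key = value` config file
(`--config run.cfg`) whose keys mirror `gaelink.model.Hyperparams`
(`alpha`, `beta`, `lam`, `hidden_dim`, `inter_dim`, `dropout`,
`learning_rate`, `max_epochs`, `tol`, `seed`, `attention_scale`,
`loss_mode`); unknown keys are rejected. Exit codes: 0 success, 2
usage/config error, 3 data error, 4 numerical divergence.

## File formats

All artifacts are TSV with string identifiers. Associations are two-column
headered edge lists (`mirna_id`, `disease_id`); similarity matrices are
square labelled tables; hierarchies are a `(child, parent)` edge list plus
a `(disease_id, dag_node)` membership table; rankings are
`(disease_id, rank, mirna_id, score)`. Note that an edge list can only
name entities with at least one association.
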