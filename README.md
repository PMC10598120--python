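# tripletgene

Deep metric learning for small-sample, high-dimensional expression data:
a joint triplet loss with a **strict semi-hard constraint** (JTSC), a 1D
convolutional embedding network with per-window clinical-covariate
interleaving, and a cross-validated downstream classifier.

## Who this is for

Computational biologists classifying a few hundred samples against tens of
thousands of genes — disease vs control from blood expression, early- vs
late-stage tumors — where direct classifiers overfit. Instead of training a
classifier on raw genes, an embedding function `f : R^p → R^d` is trained on
triplets (anchor `a`, positive `p` same class, negative `n` other class) so
that classes separate in `R^d`; a one-layer classifier then scores the
embedding.

## The method

With squared Euclidean distances and margin `m`, triplets are categorized
**hard** (`d_n² < d_p²`), **easy** (`d_n² − d_p² ≥ m`, zero loss) or
**semi-hard** (in between). Because anchor and positive share a class, their
roles are arbitrary — but the category is not symmetric in them. The strict
miner keeps only triplets that remain semi-hard after switching anchor and
positive, recomputed online every epoch. Training minimizes

```
l_joint = [‖x_a−x_p‖² − ‖x_a−x_n‖² + m]₊            (triplet)
        + [‖x_p−x_a‖² − ‖x_p−x_n‖² + m]₊            (switching)
        + [‖x_a−x_p‖² − 4 tan²α ‖x_n−x_c‖²]₊        (angular, x_c = (x_a+x_p)/2)
```

with dual early stopping: validation-loss patience, or too few strict
semi-hard triplets left to mine. The embedder is a 1D conv net whose stride
equals its kernel, with normalized clinical covariates replicated into every
kernel window. All numerics (network, Adam, loss gradients) are plain NumPy
with hand-derived gradients, verified against finite differences.

## Worked example

```python
import tripletgene as tg

ds = tg.normalize_features(
    tg.generate(tg.SyntheticConfig(n_samples=200, n_genes=1000,
                                   n_informative=50, effect_size=1.5, seed=0)))
train, val, test = tg.train_val_test_split(ds, (0.6, 0.2, 0.2), seed=0)

spec = tg.EmbeddingModelSpec(n_genes=1000, embedding_dim=30, init_seed=0)
cfg = tg.TrainingConfig(n_triplets=2000, learning_rate=0.01, batch_size=300,
                        min_semi_hard=50, patience=30, max_epochs=150, seed=0)
f, history = tg.train_embedding(train, val, spec, cfg)
print(history.to_frame().to_string(index=False))
```

prints (this is `examples/04_train_embedding.py`):

```
 epoch  easy  semi_hard  hard  strict_semi_hard  train_loss  val_loss
     0    30       1069   901               678    0.564311  0.537212
     1  1074        620   306               275    0.482591  0.494652
     2  1526        317   157               101    0.445669  0.512813
     3  1668        228   104                73    0.431345  0.511323
     4  1833        123    44                30    0.485727  0.511323
stopped: min_semi_hard (best epoch 1)
held-out test AUC of the classifier on embeddings: 0.942
```

Reading it: of 2,000 training triplets, 30 start easy and 901 hard under the
untrained embedding; as the embedding learns, easy triplets accumulate
(30 → 1833) while the ambiguous semi-hard/hard pool drains, until fewer than
50 strict semi-hard triplets remain and mining stops. The classifier on the
learned embedding reaches AUC 0.942 on the held-out test split.

More narrative scripts live in `examples/` (losses, mining, clinical
interleaving, cross-validation). The CLI mirrors the library:

```
tripletgene simulate --config config.yaml --seed 1 --outdir out/
tripletgene train    --config config.yaml --seed 1 --outdir out/
tripletgene evaluate --config config.yaml --seed 1 --outdir out/
tripletgene ablate   --config config.yaml --seed 1 --outdir out/
```

Every run writes its resolved configuration (seeds, versions) next to the
outputs; identical configs produce byte-identical TSVs.

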