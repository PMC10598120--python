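"""Train the 1D-CNN embedding with online strict semi-hard mining.

Watch the category trajectory: as the embedding separates the classes, easy
triplets accumulate while semi-hard and hard ones drain away, until fewer
strict semi-hard triplets remain than the training floor and mining stops.
"""

import tripletgene as tg

ds = tg.normalize_features(
    tg.generate(tg.SyntheticConfig(n_samples=200, n_genes=1000,
                                   n_informative=50, effect_size=1.5, seed=0))
)
train, val, test = tg.train_val_test_split(ds, (0.6, 0.2, 0.2), seed=0)

spec = tg.EmbeddingModelSpec(n_genes=1000, embedding_dim=30, init_seed=0)
cfg = tg.TrainingConfig(n_triplets=2000, learning_rate=0.01, batch_size=300,
                        min_semi_hard=50, patience=30, max_epochs=150, seed=0)
f, history = tg.train_embedding(train, val, spec, cfg)

print(history.to_frame().to_string(index=False))
print(f"stopped: {history.stop_reason} (best epoch {history.best_epoch})")

g = tg.train_classifier(f.embed(train), train.labels, seed=0)
scores = g.predict_proba(f.embed(test))
print(f"held-out test AUC of the classifier on embeddings: "
      f"{tg.auc(scores, test.labels):.3f}")
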