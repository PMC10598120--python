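"""Cross-validated evaluation of the full embed-then-classify pipeline.

Per fold the feature standardization is fit on the training portion only,
20% of it becomes the early-stopping validation set, and metrics are taken
on the untouched test fold.
"""

import tripletgene as tg

ds = tg.generate(tg.SyntheticConfig(n_samples=200, n_genes=1000,
                                    n_informative=50, effect_size=1.5, seed=0))
spec = tg.EmbeddingModelSpec(n_genes=1000, embedding_dim=30, init_seed=0)
cfg = tg.TrainingConfig(n_triplets=2000, learning_rate=0.01, max_epochs=150, seed=0)

report = tg.cross_validate(ds, k_folds=5, spec=spec, train_cfg=cfg, seed=0)
print(report.to_frame().to_string(index=False))
for metric, stats in report.summary().items():
    print(f"{metric}: {stats['mean']:.3f} +/- {stats['sd']:.3f}")
# AUC near 1 here reflects the configured 1.5-SD signal on 50 genes;
# with effect_size = 0 the same pipeline hovers around 0.5.
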