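"""Evaluation machinery: per-class metrics, bootstrap CIs, cluster indices.

Evaluates a quick primary model on the preset's test split with 1000
bootstrap resamples and embedding cluster quality.
"""

import numpy as np

from macnet import (TrainConfig, apply_scaler, ctg_like_preset, evaluate,
                    fit_scaler, stratified_split, train_primary)

seed = 3
table = ctg_like_preset(seed)
split = stratified_split(table, 0.77, seed)
scaler = fit_scaler(split.train)
train_t, test_t = (apply_scaler(s, scaler) for s in (split.train, split.test))

cfg = TrainConfig(primary_epochs=60, patience=30, maal_delay=10, seed=seed)
net, *_ = train_primary(train_t, cfg)

report = evaluate(
    test_t.labels,
    net.predict(test_t.features),
    n_classes=3,
    scores=net.predict_proba(test_t.features),
    embeddings=net.embed(test_t.features),
    bootstrap=1000,
    seed=seed,
)

print(f"accuracy     : {report.accuracy:.4f}")
print(f"weighted F1  : {report.weighted_f1:.4f}")
print(f"per-class recall : {np.round(report.recall, 3).tolist()}")
print(f"weighted AUC : {report.auc_weighted:.4f}")
lo, hi = report.ci["accuracy"]
print(f"accuracy 95% bootstrap CI (B=1000): [{lo:.4f}, {hi:.4f}]")
print(f"embedding silhouette {report.silhouette:.4f}, "
      f"Davies-Bouldin {report.davies_bouldin:.4f}")
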