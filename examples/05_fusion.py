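"""Full dual-path pipeline: GRU + incremental tree + learned fusion.

Both branches are trained and frozen, then a small 1-D CNN learns, per
beat, how much weight (W1 vs W2) to give each branch before the final
softmax. All three models are scored on the same held-out beats.
"""

import numpy as np

from ecgfusion import (FusionConfig, IncrementalPlan, SyntheticConfig,
                       TrainConfig, beat_features, compute_metrics,
                       gru_predict, incremental_train, make_record_at_snr,
                       overall_accuracy, segment_beats, split_dataset,
                       train_fusion, train_gru)

record, r_pos, _l = make_record_at_snr(
    SyntheticConfig(n_beats=1500, class_mix=(0.55, 0.15, 0.2, 0.1), seed=5),
    snr_db=10.0)
X, y = segment_beats(record, r_pos).to_matrix()
sp = split_dataset(len(y), seed=5)

featurize = lambda beats: beat_features(beats, segmented=True).features
tree_res = incremental_train(featurize(X), y,
                             IncrementalPlan(seed=5, max_depth=12))
gru_params, _trace = train_gru(X[sp.train], y[sp.train],
                               X[sp.valid], y[sp.valid], TrainConfig(seed=0))
model, _ft = train_fusion(X[sp.valid], y[sp.valid], gru_params,
                          tree_res.tree, featurize, FusionConfig(seed=0))

test = sp.test
tree_pred = tree_res.tree.predict_label(featurize(X[test]))
gru_probs, _h = gru_predict(gru_params, X[test])
gru_pred = np.asarray(gru_params.classes, dtype=object)[gru_probs.argmax(1)]
fused_pred = model.predict_label(X[test])

for name, pred in [("tree", tree_pred), ("GRU", gru_pred),
                   ("fused", fused_pred)]:
    print(f"{name:>5}: accuracy {overall_accuracy(y[test], pred):6.2f}%")

w2 = model.fusion_weights(X[test])[:, 1]
print(f"\nlearned tree weight W2 over test beats: "
      f"mean {w2.mean():.3f}, range [{w2.min():.3f}, {w2.max():.3f}]")
print(compute_metrics(y[test], fused_pred).round(2).to_string())
print("The fused model should match or beat the better single branch;"
      " W2 shows how much the frequency-domain tree contributed per beat.")
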