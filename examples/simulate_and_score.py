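"""Generate a small labeled corpus, extract features, train the decision
tree and score held-out recordings.

Run:  python examples/simulate_and_score.py
"""

import numpy as np

import pronosup as p
from pronosup.updrs import LabeledFeatures, train_tree

# 5 severity classes x 8 recordings, reproducible from one seed
recordings, labels = p.generate_dataset(range(5), per_class=8, seed=7)
table = p.corpus_feature_table(recordings, labels)
print(table.groupby("label")[["mean_angRate", "std_rsquare_1n"]].mean().round(3))
print("(speed falls and rhythm variation rises with severity)\n")

data = LabeledFeatures.from_frame(table)
rng = np.random.default_rng(0)
idx = rng.permutation(len(table))
train_idx, test_idx = idx[:32], idx[32:]
model = train_tree(LabeledFeatures(data.X[train_idx], data.y[train_idx],
                                   data.feature_names,
                                   [data.ids[i] for i in train_idx]))
preds = [model.predict_one(dict(zip(data.feature_names, data.X[i])))
         for i in test_idx]
acc = np.mean(np.array(preds) == data.y[test_idx])
print(f"pruned tree: {model.n_leaves()} leaves, "
      f"features used: {sorted(model.used_features())}")
print(f"held-out accuracy on {len(test_idx)} recordings: {acc:.2f}")
print("(each prediction is a UPDRS item-3.6 score, 0 = normal ... 4 = severe)")
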