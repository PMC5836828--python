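"""Train damage-state classifiers on synthetic comets.

Builds a labeled set of normal / necrosis / apoptosis comets, extracts the
HOG + box-ratio features, and cross-validates the four supported
classifiers. Accuracy near 1.0 reflects the clean separability of the
synthetic archetypes, not performance on real images.
"""

import cometkit as ck
from cometkit.datasets import synthetic_training_set

X, y = synthetic_training_set(per_class=60, feature_set="hog_full_box", seed=0)
print(f"training set: {X.shape[0]} comets x {X.shape[1]} features "
      "(900 HOG + 1 box-ratio)")

for name in ("svm_linear", "nn_softmax", "cart"):
    train_acc, test_acc = ck.train_and_evaluate(X, y, name, folds=10, seed=0)
    print(f"{name:>11}: train {train_acc:.3f}  test {test_acc:.3f} "
          "(10-fold CV)")
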