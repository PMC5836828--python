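"""Damage-state classification: HOG + box-ratio features and four
pluggable classifiers for {normal, necrosis, apoptosis}.

Comet crops are resized to 50x50; since an apoptotic comet always keeps
its (dim) nucleus in the left half, a second descriptor is taken from the
25x50 left half.  HOG uses 9 unsigned orientation bins, 8x8-pixel cells
and overlapping 2x2-cell blocks with 1-cell stride and L2 block
normalization, giving exactly 900 features on 50x50 (6x6 cells) and 360
on 25x50 (3x6 cells); appending the box-ratio (bounding-box width over
height, which flags the horizontally long necrosis type) yields 901/361.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import hog
from skimage.transform import resize
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSES = ("normal", "necrosis", "apoptosis")

FEATURE_SETS = {
    "hog_left": 360,
    "hog_left_box": 361,
    "hog_full": 900,
    "hog_full_box": 901,
}


def prepare_patches(crop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(full, left_half): the crop resized to 50x50 (bilinear) and its
    first 25 columns."""
    crop = np.asarray(crop, dtype=np.float64)
    if crop.size == 0:
        raise ValueError("empty crop")
    full = resize(crop, (50, 50), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)
    return full, full[:, :25].copy()


def hog_features(patch: np.ndarray) -> np.ndarray:
    """Block-normalized histogram-of-oriented-gradients descriptor.

    Length is (cells_rows - 1)(cells_cols - 1) x 4 x 9 for 8x8-pixel
    cells: 900 for a 50x50 patch, 360 for 25x50.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape[0] < 16 or patch.shape[1] < 16:
        raise ValueError(f"patch {patch.shape} too small for 2x2 blocks of 8x8 cells")
    return hog(patch, orientations=9, pixels_per_cell=(8, 8),
               cells_per_block=(2, 2), block_norm="L2",
               feature_vector=True)


def box_ratio(bbox: tuple[int, int, int, int]) -> float:
    """Bounding-box width / height (half-open box convention)."""
    r0, c0, r1, c1 = bbox
    height = r1 - r0
    if height <= 0:
        raise ValueError("bbox height must be positive")
    return (c1 - c0) / height


def build_feature_vector(crop: np.ndarray, bbox: tuple[int, int, int, int],
                         feature_set: str = "hog_full_box") -> np.ndarray:
    """Assemble one of the four feature sets from a comet crop."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; "
                         f"choose from {sorted(FEATURE_SETS)}")
    full, left = prepare_patches(crop)
    if feature_set.startswith("hog_left"):
        vec = hog_features(left)
    else:
        vec = hog_features(full)
    if feature_set.endswith("_box"):
        vec = np.concatenate([vec, [box_ratio(bbox)]])
    assert vec.size == FEATURE_SETS[feature_set]
    return vec


class PairwiseCascadeSVM:
    """Three binary linear SVMs aggregated into a decision tree.

    Stage 1 runs normal-vs-necrosis; its winner then meets apoptosis in the
    corresponding pairwise classifier, whose verdict is final.
    """

    _PAIRS = (("normal", "necrosis"), ("normal", "apoptosis"),
              ("necrosis", "apoptosis"))

    def __init__(self, random_state: int = 0):
        self.random_state = random_state
        self._models: dict[tuple[str, str], SVC] = {}

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PairwiseCascadeSVM":
        y = np.asarray(y)
        for pair in self._PAIRS:
            sel = np.isin(y, pair)
            clf = SVC(kernel="linear", random_state=self.random_state)
            clf.fit(X[sel], y[sel])
            self._models[pair] = clf
        return self

    def _pair_predict(self, pair: tuple[str, str], x: np.ndarray) -> str:
        return str(self._models[pair].predict(x[None, :])[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = []
        for x in np.asarray(X):
            w1 = self._pair_predict(("normal", "necrosis"), x)
            final_pair = ("normal", "apoptosis") if w1 == "normal" \
                else ("necrosis", "apoptosis")
            out.append(self._pair_predict(final_pair, x))
        return np.asarray(out)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def make_classifier(name: str, seed: int = 0):
    """Factory for the four supported damage-state classifiers."""
    if name == "svm_linear":
        return PairwiseCascadeSVM(random_state=seed)
    if name == "nn_softmax":
        # a single softmax output layer over the raw features
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
            n_estimators=200, random_state=seed)
    if name == "cart":
        return DecisionTreeClassifier(max_depth=10, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def train_and_evaluate(features: np.ndarray, labels: np.ndarray,
                       classifier: str = "svm_linear", folds: int = 10,
                       seed: int = 0) -> tuple[float, float]:
    """Stratified k-fold cross-validation; returns fold-averaged
    (train accuracy, test accuracy)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"every class needs >= {folds} samples for "
                         f"{folds}-fold CV; got {dict(zip(classes, counts))}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    train_acc, test_acc = [], []
    for tr, te in skf.split(X, y):
        clf = make_classifier(classifier, seed)
        clf.fit(X[tr], y[tr])
        train_acc.append(clf.score(X[tr], y[tr]))
        test_acc.append(clf.score(X[te], y[te]))
    return float(np.mean(train_acc)), float(np.mean(test_acc))
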