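"""Synthetic training sets for the damage-state classifiers.

The generator's three morphology archetypes stand in for expert-labeled
comet crops: each training sample is a rendered single comet, segmented by
the mask floor, cropped, and featurized.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .classify import CLASSES, build_feature_vector
from .io import bbox_of, crop_comet


def synthetic_training_set(per_class: int = 60,
                           feature_set: str = "hog_full_box",
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render ``per_class`` comets of each class and return (X, y)."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for class_label in CLASSES:
        for _ in range(per_class):
            spec = synth.sample_spec(rng, class_label)
            margin = 4 * max(spec.head_sigma, spec.tail_sigma or 0.0)
            spec.head_center = (margin, margin)
            patch, _ = synth.render_comet(spec, seed=int(rng.integers(2 ** 31)))
            mask = patch > (synth.BACKGROUND_MEAN + 3 * synth.BACKGROUND_NOISE_SD)
            if not mask.any():
                continue
            labels = mask.astype(np.int32)
            crop = crop_comet(patch, labels, 1)
            X.append(build_feature_vector(crop, bbox_of(mask), feature_set))
            y.append(class_label)
    return np.asarray(X), np.asarray(y)
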