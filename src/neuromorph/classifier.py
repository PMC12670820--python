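"""Random-forest pixel classification of histology images.

Training pixels come from ROI-derived masks (value 255 = unlabeled,
excluded).  Class imbalance is handled by per-class pixel caps with a
deterministic, input-order-invariant subsampling scheme: labeled pixels
are keyed by (image content hash, row, col) and sorted before the seeded
subsample is drawn, so shuffling the training set leaves the model
unchanged.  Prediction emits the six-channel per-pixel probability map
("6-dimensional matrix") and is tiled for large inputs: each tile carries
enough real-image context (the filter support radius) that tiled and
untiled predictions agree bit-for-bit away from image borders.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureConfig, extract_pixel_features
from .tissue import CLASS_MAP, N_CLASSES, UNLABELED

__all__ = [
    "TrainedModel",
    "train_classifier",
    "predict_probability",
    "predict_labels",
    "save_model",
    "load_model",
]

_SERIAL_VERSION = 1


@dataclass
class TrainedModel:
    """A fitted forest plus everything needed to reapply it."""

    forest: RandomForestClassifier
    feature_config: FeatureConfig
    class_map: dict[int, str]
    n_trees: int
    seed: int
    training_summary: dict

    def __post_init__(self) -> None:
        if self.class_map != CLASS_MAP:
            raise ValueError("model class_map differs from the package-wide map")


def _image_key(image: np.ndarray) -> str:
    arr = np.ascontiguousarray(image)
    return hashlib.sha1(
        arr.tobytes() + str(arr.shape).encode()
    ).hexdigest()


def train_classifier(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    feature_config: FeatureConfig = FeatureConfig(),
    n_trees: int = 100,
    seed: int = 0,
    max_pixels_per_class: int = 50_000,
) -> TrainedModel:
    """Fit the pixel classifier on ROI-labeled images.

    Every class 0..5 must have at least one labeled (non-sentinel) pixel
    across the training set; a missing class raises, naming it.  At most
    ``max_pixels_per_class`` pixels per class are used (seeded subsample).
    The training summary records per-class pixel counts and pixel accuracy
    on a 10 % stratified held-out split (classes with a single labeled
    pixel stay in the training split).
    """
    if len(images) != len(masks):
        raise ValueError("images and masks differ in length")
    if not images:
        raise ValueError("empty training set")

    # canonical order: sort image/mask pairs by image content hash
    order = sorted(range(len(images)), key=lambda i: _image_key(images[i]))
    feats_per_class: dict[int, list[np.ndarray]] = {c: [] for c in CLASS_MAP}
    for idx in order:
        image, mask = images[idx], np.asarray(masks[idx])
        if image.shape[:2] != mask.shape:
            raise ValueError(
                f"image {idx}: mask shape {mask.shape} does not match "
                f"image {image.shape[:2]}"
            )
        labeled = mask != UNLABELED
        if not labeled.any():
            continue
        stack = extract_pixel_features(image, feature_config)
        for cls in CLASS_MAP:
            rows, cols = np.nonzero(mask == cls)
            if rows.size == 0:
                continue
            # sort by (row, col) for input-order invariance
            key = np.lexsort((cols, rows))
            feats_per_class[cls].append(stack[rows[key], cols[key]])

    missing = [
        CLASS_MAP[c] for c, chunks in feats_per_class.items() if not chunks
    ]
    if missing:
        raise ValueError(
            f"no labeled pixels for class(es): {', '.join(missing)}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF0]))
    X_parts, y_parts, counts = [], [], {}
    for cls in sorted(feats_per_class):
        feats = np.concatenate(feats_per_class[cls], axis=0)
        counts[CLASS_MAP[cls]] = int(feats.shape[0])
        if feats.shape[0] > max_pixels_per_class:
            pick = rng.choice(
                feats.shape[0], size=max_pixels_per_class, replace=False
            )
            feats = feats[np.sort(pick)]
        X_parts.append(feats)
        y_parts.append(np.full(feats.shape[0], cls, dtype=np.int64))

    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts, axis=0)

    # manual stratified 10 % hold-out (singleton classes stay in training)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        n_test = int(round(0.1 * idx.size)) if idx.size >= 2 else 0
        n_test = min(n_test, idx.size - 1)
        if n_test > 0:
            picked = rng.choice(idx.size, size=n_test, replace=False)
            test_mask = np.zeros(idx.size, dtype=bool)
            test_mask[picked] = True
            test_idx.append(idx[test_mask])
            train_idx.append(idx[~test_mask])
        else:
            train_idx.append(idx)
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx) if test_idx else np.empty(0, dtype=int)

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X[train_idx], y[train_idx])
    heldout_acc = (
        float((forest.predict(X[test_idx]) == y[test_idx]).mean())
        if test_idx.size
        else float("nan")
    )
    summary = dict(
        pixels_per_class=counts,
        pixels_used=int(train_idx.size),
        heldout_pixels=int(test_idx.size),
        heldout_accuracy=heldout_acc,
    )
    return TrainedModel(
        forest=forest,
        feature_config=feature_config,
        class_map=dict(CLASS_MAP),
        n_trees=n_trees,
        seed=int(seed),
        training_summary=summary,
    )


def predict_probability(
    model: TrainedModel,
    image: np.ndarray,
    tile_size: int = 1024,
) -> np.ndarray:
    """Per-pixel class probabilities, shape (H, W, 6), channels sum to 1.

    Large images are processed in tiles with an overlap equal to the filter
    support radius, so memory stays bounded and tile seams are exact.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got {image.shape}")
    expected = model.feature_config.n_features
    if model.forest.n_features_in_ != expected:  # pragma: no cover - paranoia
        raise ValueError(
            f"model expects {model.forest.n_features_in_} features but "
            f"config yields {expected}"
        )
    h, w = image.shape[:2]
    overlap = model.feature_config.max_radius
    core = max(tile_size - 2 * overlap, 1)
    out = np.empty((h, w, N_CLASSES), dtype=np.float32)
    for r0 in range(0, h, core):
        for c0 in range(0, w, core):
            r1, c1 = min(r0 + core, h), min(c0 + core, w)
            rp0, cp0 = max(r0 - overlap, 0), max(c0 - overlap, 0)
            rp1, cp1 = min(r1 + overlap, h), min(c1 + overlap, w)
            window = image[rp0:rp1, cp0:cp1]
            stack = extract_pixel_features(window, model.feature_config)
            ch, cw = r1 - r0, c1 - c0
            sub = stack[r0 - rp0 : r0 - rp0 + ch, c0 - cp0 : c0 - cp0 + cw]
            flat = sub.reshape(-1, expected)
            prob = model.forest.predict_proba(flat)
            full = np.zeros((flat.shape[0], N_CLASSES), dtype=np.float32)
            full[:, model.forest.classes_.astype(int)] = prob
            out[r0:r1, c0:c1] = full.reshape(ch, cw, N_CLASSES)
    return out


def predict_labels(prob: np.ndarray) -> np.ndarray:
    """Harden a probability map to labels; ties go to the lower class index."""
    prob = np.asarray(prob)
    if prob.ndim != 3 or prob.shape[2] != N_CLASSES:
        raise ValueError(f"expected (H, W, {N_CLASSES}) map, got {prob.shape}")
    return np.argmax(prob, axis=2).astype(np.uint8)


def save_model(model: TrainedModel, path: str | Path) -> Path:
    """Serialize a trained model (joblib); round-trips to identical output."""
    path = Path(path)
    joblib.dump(
        dict(
            version=_SERIAL_VERSION,
            forest=model.forest,
            feature_config=vars(model.feature_config),
            class_map=model.class_map,
            n_trees=model.n_trees,
            seed=model.seed,
            training_summary=model.training_summary,
        ),
        path,
    )
    return path


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("version") != _SERIAL_VERSION:
        raise ValueError(f"{path}: unsupported model file version")
    return TrainedModel(
        forest=blob["forest"],
        feature_config=FeatureConfig(**blob["feature_config"]),
        class_map={int(k): v for k, v in blob["class_map"].items()},
        n_trees=blob["n_trees"],
        seed=blob["seed"],
        training_summary=blob["training_summary"],
    )
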