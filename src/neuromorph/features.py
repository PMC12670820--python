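"""Per-pixel features for random-forest tissue classification.

An ilastik-style bank: raw color plus, per Gaussian scale, smoothed color,
gradient magnitude and local variance, each computed per RGB channel with
reflective boundary handling.  With the default four scales and three
scale-dependent kinds this yields 3 + 3*4*3 = 39 channels.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_gradient_magnitude

__all__ = ["FeatureConfig", "extract_pixel_features", "feature_count"]

_KINDS = ("raw_color", "gaussian_smooth", "gradient_magnitude", "local_variance")


@dataclass(frozen=True)
class FeatureConfig:
    """Which features to compute and at which Gaussian scales (pixels)."""

    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    feature_kinds: tuple[str, ...] = _KINDS
    color_space: str = "RGB"

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(float(s) for s in self.scales))
        object.__setattr__(self, "feature_kinds", tuple(self.feature_kinds))
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be strictly positive")
        if list(self.scales) != sorted(set(self.scales)):
            raise ValueError("scales must be strictly increasing")
        if not self.feature_kinds:
            raise ValueError("at least one feature kind required")
        unknown = set(self.feature_kinds) - set(_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds {sorted(unknown)}")
        if self.color_space != "RGB":
            raise ValueError("only RGB color space is supported")

    @property
    def n_features(self) -> int:
        scale_kinds = [k for k in self.feature_kinds if k != "raw_color"]
        n = 3 * len(self.scales) * len(scale_kinds)
        if "raw_color" in self.feature_kinds:
            n += 3
        return n

    @property
    def max_radius(self) -> int:
        """Spatial support radius of the widest filter (truncate = 4 sigma)."""
        return int(4.0 * max(self.scales) + 0.5)


def feature_count(config: FeatureConfig) -> int:
    return config.n_features


def extract_pixel_features(
    image: np.ndarray, config: FeatureConfig = FeatureConfig()
) -> np.ndarray:
    """Compute the (H, W, F) float32 feature stack for an RGB image.

    Deterministic; boundaries handled by reflection.  Channel order is
    raw color first (if requested), then for each remaining kind in config
    order, for each scale, the three color channels.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got {image.shape}")
    h, w = image.shape[:2]
    if min(h, w) < 4 * max(config.scales):
        warnings.warn(
            f"image {h}x{w} smaller than 4x the largest scale "
            f"({max(config.scales)}); boundary reflection dominates"
        )
    img = image.astype(np.float32)
    planes: list[np.ndarray] = []
    if "raw_color" in config.feature_kinds:
        planes.extend(img[..., ch] for ch in range(3))
    for kind in config.feature_kinds:
        if kind == "raw_color":
            continue
        for sigma in config.scales:
            for ch in range(3):
                planes.append(_scale_feature(img[..., ch], kind, sigma))
    return np.stack(planes, axis=-1)


def _scale_feature(plane: np.ndarray, kind: str, sigma: float) -> np.ndarray:
    if kind == "gaussian_smooth":
        return gaussian_filter(plane, sigma, mode="reflect")
    if kind == "gradient_magnitude":
        return gaussian_gradient_magnitude(plane, sigma, mode="reflect")
    if kind == "local_variance":
        mean = gaussian_filter(plane, sigma, mode="reflect")
        mean_sq = gaussian_filter(plane * plane, sigma, mode="reflect")
        return np.maximum(mean_sq - mean * mean, 0.0)
    raise ValueError(f"unknown feature kind {kind!r}")
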