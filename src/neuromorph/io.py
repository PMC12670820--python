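"""Reading and writing of on-disk artifacts.

Conventions (fixed package-wide):

* Pixel coordinates are ``(row, col)``, 0-based, origin at the top-left.
* RGB images are 8-bit, shape ``(H, W, 3)``; PNG and uncompressed TIFF
  round-trip losslessly.
* Label masks are stored as indexed PNG with the fixed six-entry palette of
  :mod:`neuromorph.tissue`; value 255 is the "unlabeled" sentinel.
* Polygon ROIs are filled with a half-open convention: a pixel belongs to a
  polygon iff its center lies inside (centers infinitesimally shifted toward
  +row/+col so that an edge lying exactly on an integer coordinate includes
  the pixel to its right/below once, never twice).
* The cohort metadata table is a CSV with header
  ``sample_id,group,nrs,age,sex,mpp``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from matplotlib.path import Path as MplPath
from PIL import Image

from .tissue import (
    CLASS_MAP,
    GROUPS,
    PALETTE,
    SENTINEL_COLOR,
    TissueClass,
    UNLABELED,
)

COHORT_COLUMNS = ("sample_id", "group", "nrs", "age", "sex", "mpp")


@dataclass(frozen=True)
class CohortRecord:
    """Clinical metadata for one sample.

    ``nrs`` is the Numeric Rating Scale pain score (integer 0-10);
    ``mpp`` is the image scale in microns per pixel.
    """

    sample_id: str
    group: str
    nrs: int
    age: float
    sex: str
    mpp: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        if not (0 <= self.nrs <= 10):
            raise ValueError(
                f"sample {self.sample_id!r}: NRS {self.nrs} outside 0-10"
            )
        if self.group in ("control", "nonpainful_neuroma") and self.nrs != 0:
            raise ValueError(
                f"sample {self.sample_id!r}: group {self.group!r} requires NRS 0"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(
                f"sample {self.sample_id!r}: sex must be 'male' or 'female'"
            )
        if not self.mpp > 0:
            raise ValueError(f"sample {self.sample_id!r}: mpp must be > 0")


@dataclass(frozen=True)
class RoiAnnotation:
    """A polygonal region of interest carrying one tissue label.

    ``polygon`` is an ordered list of ``(row, col)`` vertices (floats allowed);
    at least three vertices are required.
    """

    polygon: tuple[tuple[float, float], ...]
    label: TissueClass
    sample_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "polygon", tuple(map(tuple, self.polygon)))
        if len(self.polygon) < 3:
            raise ValueError(
                f"ROI {self.sample_id!r}/{self.label!r}: need >= 3 vertices"
            )
        object.__setattr__(self, "label", TissueClass(self.label))


# ---------------------------------------------------------------------------
# RGB images
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as an 8-bit RGB array of shape (H, W, 3).

    Grayscale inputs are promoted to RGB by channel replication (with a
    warning).  Higher bit depths and exotic color modes raise ``ValueError``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.dtype != np.uint8:
            raise ValueError(
                f"{path}: expected 8-bit image, found dtype {arr.dtype}"
            )
        if arr.ndim == 2:
            warnings.warn(f"{path}: grayscale input promoted to RGB")
            arr = np.stack([arr] * 3, axis=-1)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"{path}: expected RGB, found shape {arr.shape}")
        return np.ascontiguousarray(arr)
    with Image.open(path) as im:
        if im.mode == "L":
            warnings.warn(f"{path}: grayscale input promoted to RGB")
            im = im.convert("RGB")
        elif im.mode == "P":
            raise ValueError(
                f"{path}: indexed image; use read_mask for label masks"
            )
        elif im.mode != "RGB":
            raise ValueError(
                f"{path}: expected 8-bit RGB, found mode {im.mode!r}"
            )
        return np.asarray(im, dtype=np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write an 8-bit RGB array to PNG or (uncompressed) TIFF."""
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError(
            f"expected uint8 (H, W, 3) array, got {image.dtype} {image.shape}"
        )
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, image)
        else:
            Image.fromarray(image, mode="RGB").save(path)
    except OSError as exc:  # pragma: no cover - environment-dependent
        raise OSError(f"failed to write image {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Label masks (indexed PNG)
# ---------------------------------------------------------------------------

def _mask_palette() -> list[int]:
    flat = [0] * (256 * 3)
    for code, rgb in PALETTE.items():
        flat[code * 3 : code * 3 + 3] = rgb
    flat[UNLABELED * 3 : UNLABELED * 3 + 3] = SENTINEL_COLOR
    return flat


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a label mask as an indexed PNG with the fixed class palette."""
    path = Path(path)
    mask = np.asarray(mask)
    _validate_mask_values(mask)
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(_mask_palette())
    im.save(path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read an indexed-PNG label mask back to a 2-D uint8 array."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode != "P":
            raise ValueError(f"{path}: expected indexed PNG label mask")
        mask = np.asarray(im, dtype=np.uint8)
    _validate_mask_values(mask, origin=str(path))
    return mask


def _validate_mask_values(mask: np.ndarray, origin: str = "mask") -> None:
    if mask.ndim != 2:
        raise ValueError(f"{origin}: mask must be 2-D, got shape {mask.shape}")
    values = np.unique(mask)
    bad = [int(v) for v in values if v not in CLASS_MAP and v != UNLABELED]
    if bad:
        raise ValueError(f"{origin}: invalid label values {bad}")


# ---------------------------------------------------------------------------
# ROI rasterization
# ---------------------------------------------------------------------------

_HALF_OPEN_EPS = 1e-7


def rois_to_mask(
    rois: list[RoiAnnotation], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize polygon ROIs into a training mask.

    Pixels covered by no ROI get the sentinel 255 (excluded from training);
    overlaps are resolved last-listed-wins.  Out-of-bounds vertices raise,
    naming the offending ROI.
    """
    h, w = shape
    mask = np.full((h, w), UNLABELED, dtype=np.uint8)
    for i, roi in enumerate(rois):
        poly = np.asarray(roi.polygon, dtype=float)
        if (
            poly[:, 0].min() < 0
            or poly[:, 1].min() < 0
            or poly[:, 0].max() > h
            or poly[:, 1].max() > w
        ):
            raise ValueError(
                f"ROI #{i} (sample {roi.sample_id!r}, label "
                f"{roi.label.name.lower()}) has vertices outside the "
                f"{h}x{w} canvas"
            )
        r0 = max(int(np.floor(poly[:, 0].min())), 0)
        r1 = min(int(np.ceil(poly[:, 0].max())) + 1, h)
        c0 = max(int(np.floor(poly[:, 1].min())), 0)
        c1 = min(int(np.ceil(poly[:, 1].max())) + 1, w)
        if r1 <= r0 or c1 <= c0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        centers = np.column_stack(
            [rr.ravel() + _HALF_OPEN_EPS, cc.ravel() + _HALF_OPEN_EPS]
        )
        inside = MplPath(poly).contains_points(centers)
        sub = mask[r0:r1, c0:c1].ravel()
        sub[inside] = int(roi.label)
        mask[r0:r1, c0:c1] = sub.reshape(r1 - r0, c1 - c0)
    return mask


# ---------------------------------------------------------------------------
# Cohort metadata and result tables
# ---------------------------------------------------------------------------

def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read and validate the cohort metadata CSV.

    Group and sex values are normalized case-insensitively; any invalid row
    raises with its row number and sample id.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                CohortRecord(
                    sample_id=str(row["sample_id"]),
                    group=str(row["group"]).strip().lower(),
                    nrs=int(row["nrs"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]).strip().lower(),
                    mpp=float(row["mpp"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, row {idx}: {exc}") from exc
    return records


def write_cohort_table(records: list[CohortRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([vars(r) for r in records], columns=COHORT_COLUMNS)
    df.to_csv(path, index=False)
    return path


def write_results(
    compositions: pd.DataFrame,
    report: dict,
    composition_path: str | Path,
    report_path: str | Path,
) -> None:
    """Write per-sample compositions as TSV and the stats report as JSON."""
    compositions.to_csv(composition_path, sep="\t", index=False)
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)


def write_probability_map(prob: np.ndarray, path: str | Path) -> Path:
    """Write an (H, W, 6) probability map as a float32 multi-channel TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(prob, dtype=np.float32))
    return path


def read_probability_map(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[-1] != 6:
        raise ValueError(f"{path}: expected (H, W, 6) map, got {arr.shape}")
    return arr
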