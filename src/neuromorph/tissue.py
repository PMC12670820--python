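"""Tissue-class vocabulary shared by every stage of the pipeline.

The segmentation problem distinguishes five tissue qualities seen in an
Elastica-van-Gieson (EvG) stained peripheral-nerve cross-section, plus the
slide background: organized nervous tissue (intact, round fascicles),
unorganized nervous tissue (neuroma mini-fascicles), connective tissue,
adipose tissue, and erythrocytes.  Label masks use one fixed integer code
per class; 255 is reserved as the "unlabeled" sentinel for ROI-derived
training masks and never appears in predicted masks.
"""

from __future__ import annotations

from enum import IntEnum


class TissueClass(IntEnum):
    """Integer label codes used in every mask across the package."""

    BACKGROUND = 0
    ORGANIZED_NERVOUS = 1
    UNORGANIZED_NERVOUS = 2
    CONNECTIVE = 3
    ADIPOSE = 4
    ERYTHROCYTE = 5


#: Canonical code -> name mapping (bijective, identical package-wide).
CLASS_MAP: dict[int, str] = {
    0: "background",
    1: "organized_nervous",
    2: "unorganized_nervous",
    3: "connective",
    4: "adipose",
    5: "erythrocyte",
}

NAME_TO_CLASS: dict[str, int] = {v: k for k, v in CLASS_MAP.items()}

N_CLASSES: int = 6

#: Sentinel for "no annotation here" in training masks (excluded from training).
UNLABELED: int = 255

#: Tissue classes (everything except background), in code order.
TISSUE_CLASSES: tuple[TissueClass, ...] = (
    TissueClass.ORGANIZED_NERVOUS,
    TissueClass.UNORGANIZED_NERVOUS,
    TissueClass.CONNECTIVE,
    TissueClass.ADIPOSE,
    TissueClass.ERYTHROCYTE,
)

NERVOUS_CLASSES: tuple[TissueClass, ...] = (
    TissueClass.ORGANIZED_NERVOUS,
    TissueClass.UNORGANIZED_NERVOUS,
)

#: Invented EvG-like base palette (RGB, 0-255).  The real stain gives collagen
#: a pink/red tone, nervous tissue yellow-brown, adipose near-white vacuoles
#: and erythrocytes a saturated red; only class separability matters here.
PALETTE: dict[int, tuple[int, int, int]] = {
    0: (236, 233, 226),   # background: off-white slide
    1: (186, 156, 104),   # organized nervous: tan / yellow-brown
    2: (138, 108, 88),    # unorganized nervous: darker brown
    3: (204, 118, 124),   # connective: van-Gieson pink-red
    4: (252, 251, 248),   # adipose: white vacuole
    5: (186, 38, 44),     # erythrocyte: saturated red
}

#: Display color for the unlabeled sentinel in indexed PNGs.
SENTINEL_COLOR: tuple[int, int, int] = (0, 0, 0)

GROUPS: tuple[str, ...] = ("control", "nonpainful_neuroma", "painful_neuroma")
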