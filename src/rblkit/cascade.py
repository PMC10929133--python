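"""Cascade plumbing: dental-region extraction and position/region merging.

The upstream segmentation stage produces (a) a stack of overlapping
per-tooth position masks over the full panoramic frame and (b) a 4-class
region map over the extracted dental area.  This module crops the dental
region out of the position stack and intersects each tooth's position mask
with the region labels to yield per-tooth crown/suprabony/intrabony masks.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Tuple

import numpy as np

from .masks import (
    CROWN,
    INTRABONY,
    SUPRABONY,
    MaskError,
    RegionMap,
    ToothPositionStack,
    ToothRegionMask,
)

logger = logging.getLogger(__name__)

BoundingBox = Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open

DEFAULT_CROP_PADDING = 10


class NoTeethError(MaskError):
    """All position masks are empty: there is no dental region to extract."""


def crop_dental_region(
    positions: ToothPositionStack, padding: int = DEFAULT_CROP_PADDING
) -> Tuple[BoundingBox, ToothPositionStack]:
    """Tight bounding box of all teeth, expanded by ``padding`` and clipped.

    Returns the half-open box in parent-image coordinates and the position
    stack cropped to it; per-tooth membership is preserved.
    """
    if padding < 0:
        raise MaskError(f"padding must be >= 0, got {padding}")
    union = positions.union()
    if not union.any():
        raise NoTeethError("no teeth detected: every position mask is empty")
    rows = np.any(union, axis=1).nonzero()[0]
    cols = np.any(union, axis=0).nonzero()[0]
    r0 = max(0, int(rows[0]) - padding)
    c0 = max(0, int(cols[0]) - padding)
    r1 = min(positions.height, int(rows[-1]) + 1 + padding)
    c1 = min(positions.width, int(cols[-1]) + 1 + padding)
    cropped = ToothPositionStack(
        height=r1 - r0,
        width=c1 - c0,
        masks={t: m[r0:r1, c0:c1] for t, m in positions.masks.items()},
    )
    return (r0, c0, r1, c1), cropped


def merge_positions_with_regions(
    positions: ToothPositionStack,
    regions: RegionMap,
    min_pixels: int = 1,
    frame_offset: Tuple[int, int] = (0, 0),
) -> List[ToothRegionMask]:
    """Intersect each tooth's position mask with the 4-class region map.

    For tooth t: crown = positions[t] ∧ (regions == 3), suprabony with
    label 2, intrabony with label 1.  Pixels claimed by several teeth appear
    in every claiming tooth's output (multi-label semantics).  Teeth whose
    merged masks total fewer than ``min_pixels`` are omitted and logged.
    """
    if positions.shape != regions.shape:
        raise MaskError(
            f"position stack shape {positions.shape} != region map shape {regions.shape}"
        )
    crown_m = regions.region(CROWN)
    supra_m = regions.region(SUPRABONY)
    intra_m = regions.region(INTRABONY)
    out: List[ToothRegionMask] = []
    for tooth in positions.teeth():
        pos = positions.masks[tooth]
        crown = pos & crown_m
        supra = pos & supra_m
        intra = pos & intra_m
        total = int(crown.sum()) + int(supra.sum()) + int(intra.sum())
        if total < max(min_pixels, 1):
            logger.info("tooth %d omitted: %d labelled pixels under its position mask",
                        tooth, total)
            continue
        out.append(
            ToothRegionMask(
                tooth_number=tooth,
                crown=crown,
                suprabony=supra,
                intrabony=intra,
                frame_offset=frame_offset,
            )
        )
    return out


def crop_and_merge(
    positions: ToothPositionStack,
    regions: RegionMap,
    padding: int = DEFAULT_CROP_PADDING,
    min_pixels: int = 1,
) -> Tuple[BoundingBox, List[ToothRegionMask]]:
    """Crop the dental region, then merge against the region map.

    ``regions`` may cover either the full parent frame (it is cropped with
    the same box) or already just the cropped frame — the usual cascade, in
    which the region segmenter runs on the extracted dental area only.
    """
    box, cropped = crop_dental_region(positions, padding)
    r0, c0, r1, c1 = box
    if regions.shape == positions.shape:
        regions = RegionMap(labels=regions.labels[r0:r1, c0:c1])
    teeth = merge_positions_with_regions(
        cropped, regions, min_pixels=min_pixels, frame_offset=(r0, c0)
    )
    return box, teeth
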