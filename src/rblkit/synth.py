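"""Seeded tooth/dentition phantoms with exact ground truth.

Real panoramic radiographs and their annotations are private clinical data,
so every downstream operation is exercised on geometric phantoms instead: a
tooth is a rounded-rectangle crown atop one to three tapered roots, the
alveolar bone crest is a straight line perpendicular to the tooth axis, and
the coronal ``bone_loss_fraction`` of the root is labelled suprabony (the
part exposed by bone loss).  Landmarks (CEJ, ABC, AP) are placed
analytically and transformed together with the shape, so the generator
knows its own RBL% exactly: ``true_rbl = 100 * bone_loss_fraction``.

Everything is deterministic for a fixed (spec, seed); randomness is only
used for optional boundary jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .masks import (
    CROWN,
    INTRABONY,
    SUPRABONY,
    LandmarkSet,
    RegionMap,
    ToothLandmarks,
    ToothPositionStack,
    ToothRegionMask,
    rasterize_shape,
    write_landmarks_csv,
    write_position_masks,
    write_region_map,
)
from .measurement import Stage, assign_stage


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class ToothSpec:
    """Parameters of one phantom tooth.

    Dimensions are in pixels and default to a plausible single-root tooth at
    panoramic-radiograph scale.  ``bone_loss_fraction`` is the fraction of
    the root length coronal to the bone crest; ``tilt`` rotates the whole
    tooth (and its landmarks) about its center.
    """

    tooth_number: int = 3
    root_count: int = 1
    crown_height: float = 40.0
    crown_width: float = 60.0
    root_length: float = 120.0
    root_width: float = 44.0
    bone_loss_fraction: float = 0.3
    tilt: float = 0.0  # radians
    center: Optional[Tuple[float, float]] = None  # (row, col) on the canvas

    def __post_init__(self) -> None:
        if self.root_count not in (1, 2, 3):
            raise SynthError(f"root_count must be 1..3, got {self.root_count}")
        if min(self.crown_height, self.crown_width, self.root_length, self.root_width) <= 0:
            raise SynthError("tooth dimensions must be positive")
        if not (0.0 <= self.bone_loss_fraction <= 1.0):
            raise SynthError(f"bone_loss_fraction {self.bone_loss_fraction} outside [0, 1]")


@dataclass(frozen=True)
class PhantomTruth:
    """A generated dentition with its exact per-tooth ground truth."""

    region_map: RegionMap
    positions: ToothPositionStack
    landmarks: LandmarkSet
    true_rbl: Dict[int, float]
    stages: Dict[int, Stage]
    specs: Tuple[ToothSpec, ...] = field(default_factory=tuple)


# fraction of the root top width remaining at the tip (linear taper)
_TIP_TAPER = 0.3
# inter-root gap as a fraction of the total root span, for multi-root teeth
_ROOT_GAP_FRAC = 0.18


def _local_geometry(spec: ToothSpec):
    """Crown/root polygons, supra strip and landmarks in the upright frame.

    Local coordinates are (row, col) with the crown top at row 0 and the
    tooth midline at col 0; shapely treats (row, col) as its (x, y).
    """
    y_cej = spec.crown_height
    y_tip = y_cej + spec.root_length
    hw_c = spec.crown_width / 2.0
    hw_r = spec.root_width / 2.0

    crown = box(0.0, -hw_c, y_cej, hw_c)
    rad = min(spec.crown_height, spec.crown_width) / 5.0
    crown = crown.buffer(-rad).buffer(rad)  # rounded corners

    k = spec.root_count
    gap = _ROOT_GAP_FRAC * spec.root_width if k > 1 else 0.0
    w_each = (spec.root_width - gap * (k - 1)) / k
    roots = []
    for j in range(k):
        cx = -hw_r + w_each / 2.0 + j * (w_each + gap)
        top_hw = w_each / 2.0
        tip_hw = top_hw * _TIP_TAPER
        roots.append(
            Polygon(
                [
                    (y_cej, cx - top_hw),
                    (y_cej, cx + top_hw),
                    (y_tip, cx + tip_hw),
                    (y_tip, cx - tip_hw),
                ]
            )
        )
    root = unary_union(roots)

    f = spec.bone_loss_fraction
    y_bone = y_cej + f * spec.root_length
    if f <= 0:
        supra = Polygon()  # empty
    elif f >= 1:
        supra = root
    else:
        strip = box(y_cej - 1.0, -hw_c - 1.0, y_bone, hw_c + 1.0)
        supra = root.intersection(strip)

    cej_prox = np.array([y_cej, -hw_r])
    cej_dist = np.array([y_cej, hw_r])
    ap = np.array([y_tip, 0.0])
    # ABC sits on the bone-level line, fraction f along the CEJ->AP line,
    # so both manual formulas recover exactly 100*f at zero tilt
    abc_prox = cej_prox + f * (ap - cej_prox)
    abc_dist = cej_dist + f * (ap - cej_dist)
    landmarks_local = {
        "cej_proximal": cej_prox,
        "cej_distal": cej_dist,
        "abc_proximal": abc_prox,
        "abc_distal": abc_dist,
        "ap": ap,
    }
    center_local = np.array([y_tip / 2.0, 0.0])
    return crown, root, supra, landmarks_local, center_local, y_tip


def _rigid_transform(tilt: float, center_local: np.ndarray, center_target: np.ndarray):
    """Rotation by ``tilt`` about the tooth center, then move onto the canvas.

    Returns (shapely transform params, point transform function).  Positive
    tilt rotates from the row axis toward the column axis.
    """
    c, s = math.cos(tilt), math.sin(tilt)
    R = np.array([[c, -s], [s, c]])
    offset = center_target - R @ center_local

    def tpoint(p: np.ndarray) -> np.ndarray:
        return R @ np.asarray(p, dtype=float) + offset

    # shapely affine_transform: x' = a*x + b*y + xoff, y' = d*x + e*y + yoff
    shapely_params = [c, -s, s, c, float(offset[0]), float(offset[1])]
    return shapely_params, tpoint


def _canvas_for(spec: ToothSpec) -> Tuple[int, int]:
    total_h = spec.crown_height + spec.root_length
    half_diag = 0.5 * math.hypot(total_h, max(spec.crown_width, spec.root_width))
    side = int(2 * math.ceil(half_diag)) + 8
    return side, side


def generate_tooth(
    spec: ToothSpec,
    seed: int = 0,
    canvas: Optional[Tuple[int, int]] = None,
) -> Tuple[ToothRegionMask, ToothLandmarks, float]:
    """Rasterize one phantom tooth; returns (regions, landmarks, true RBL%).

    Region precedence where polygons touch: crown, then suprabony, then
    intrabony, keeping the three masks pixelwise disjoint.  ``seed`` is part
    of the interface for symmetry with the dentition generator; a single
    tooth is fully deterministic.
    """
    crown, root, supra, lms, center_local, _ = _local_geometry(spec)
    if canvas is None:
        canvas = _canvas_for(spec)
    h, w = canvas
    center_target = (
        np.asarray(spec.center, dtype=float)
        if spec.center is not None
        else np.array([h / 2.0, w / 2.0])
    )
    params, tpoint = _rigid_transform(spec.tilt, center_local, center_target)
    crown_t = affinity.affine_transform(crown, params)
    root_t = affinity.affine_transform(root, params)
    supra_t = affinity.affine_transform(supra, params) if not supra.is_empty else supra

    whole = unary_union([crown_t, root_t])
    r0, c0, r1, c1 = whole.bounds
    if r0 < -0.5 or c0 < -0.5 or r1 > h - 0.5 or c1 > w - 0.5:
        raise SynthError(
            f"tooth {spec.tooth_number} exceeds the {h}x{w} canvas "
            f"(bounds {whole.bounds})"
        )

    crown_m = rasterize_shape(crown_t, canvas)
    root_m = rasterize_shape(root_t, canvas)
    supra_ras = rasterize_shape(supra_t, canvas) if not supra_t.is_empty else np.zeros(canvas, bool)
    supra_m = supra_ras & root_m & ~crown_m
    intra_m = root_m & ~crown_m & ~supra_ras

    regions = ToothRegionMask(
        tooth_number=spec.tooth_number,
        crown=crown_m,
        suprabony=supra_m,
        intrabony=intra_m,
    )
    landmarks = ToothLandmarks(
        cej_proximal=tuple(tpoint(lms["cej_proximal"])),
        cej_distal=tuple(tpoint(lms["cej_distal"])),
        abc_proximal=tuple(tpoint(lms["abc_proximal"])),
        abc_distal=tuple(tpoint(lms["abc_distal"])),
        ap=tuple(tpoint(lms["ap"])),
    )
    return regions, landmarks, 100.0 * spec.bone_loss_fraction


def _jitter_mask(mask: np.ndarray, flip_prob: float, rng: np.random.Generator) -> np.ndarray:
    """Flip boundary pixels (both sides of the edge) with given probability."""
    inner = mask & ~ndimage.binary_erosion(mask)
    outer = ndimage.binary_dilation(mask) & ~mask
    boundary = inner | outer
    flips = boundary & (rng.random(mask.shape) < flip_prob)
    return mask ^ flips


def _flip_probability(jitter_sd: float) -> float:
    # chance a N(0, sd) boundary displacement exceeds half a pixel
    if jitter_sd <= 0:
        return 0.0
    return math.erfc(0.5 / (jitter_sd * math.sqrt(2.0)))


def generate_panorama(
    specs: Sequence[ToothSpec],
    canvas: Tuple[int, int] = (256, 1024),
    overlap_shift: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> PhantomTruth:
    """Place phantom teeth left-to-right on one canvas with known truth.

    ``overlap_shift`` (pixels) pulls neighbouring teeth together so their
    crowns overlap and the position stack becomes genuinely multi-label.
    The region map resolves contested pixels deterministically (the later
    tooth wins) while the position stack keeps every membership.
    ``jitter_sd`` adds seeded boundary-pixel flips to the masks for
    robustness tests; landmarks and the stored truth are never jittered.
    """
    if not specs:
        raise SynthError("no tooth specs given")
    h, w = canvas
    placed: List[ToothSpec] = []
    next_col = 0.0
    prev_half = None
    for spec in specs:
        if spec.center is not None:
            placed.append(spec)
            continue
        half = spec.crown_width / 2.0
        if prev_half is None:
            next_col = half + 8.0
        else:
            next_col += prev_half + half - overlap_shift
        placed.append(replace(spec, center=(h / 2.0, next_col)))
        prev_half = half
    seen = set()
    for spec in placed:
        if spec.tooth_number in seen:
            raise SynthError(f"duplicate tooth number {spec.tooth_number}")
        seen.add(spec.tooth_number)

    rng = np.random.default_rng(seed)
    flip_p = _flip_probability(jitter_sd)

    labels = np.zeros(canvas, dtype=np.uint8)
    masks: Dict[int, np.ndarray] = {}
    landmarks: LandmarkSet = {}
    true_rbl: Dict[int, float] = {}
    stages: Dict[int, Stage] = {}
    for spec in placed:
        regions, lms, rbl = generate_tooth(spec, seed=seed, canvas=canvas)
        crown_m, supra_m, intra_m = regions.crown, regions.suprabony, regions.intrabony
        if flip_p > 0:
            crown_m = _jitter_mask(crown_m, flip_p, rng)
            supra_m = _jitter_mask(supra_m, flip_p, rng)
            intra_m = _jitter_mask(intra_m, flip_p, rng)
            # re-impose the crown > supra > intra precedence after jitter
            supra_m &= ~crown_m
            intra_m &= ~crown_m & ~supra_m
        pos = crown_m | supra_m | intra_m
        masks[spec.tooth_number] = pos
        labels[crown_m] = CROWN  # later tooth wins contested pixels
        labels[supra_m] = SUPRABONY
        labels[intra_m] = INTRABONY
        landmarks[spec.tooth_number] = lms
        true_rbl[spec.tooth_number] = rbl
        stages[spec.tooth_number] = assign_stage(rbl)

    return PhantomTruth(
        region_map=RegionMap(labels=labels),
        positions=ToothPositionStack(height=h, width=w, masks=masks),
        landmarks=landmarks,
        true_rbl=true_rbl,
        stages=stages,
        specs=tuple(placed),
    )


def write_phantom_bundle(truth: PhantomTruth, out_dir) -> None:
    """Write a phantom as plain files: region PNG, mask PNGs, two CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_region_map(truth.region_map, out / "region_map.png")
    write_position_masks(truth.positions, out / "positions")
    write_landmarks_csv(truth.landmarks, out / "landmarks.csv")
    rows = [
        {
            "tooth_number": t,
            "true_rbl_percent": truth.true_rbl[t],
            "stage": truth.stages[t].name,
        }
        for t in sorted(truth.true_rbl)
    ]
    pd.DataFrame(rows).to_csv(out / "truth.csv", index=False)
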