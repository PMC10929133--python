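"""Mask and label containers plus file I/O for the measurement pipeline.

The pipeline consumes two kinds of segmentation output:

* a *region map* — a single-channel label image over {0 background,
  1 intrabony root, 2 suprabony root, 3 crown};
* a *tooth position stack* — 32 binary masks, one per universal-numbering
  tooth position, in which a pixel may belong to several teeth at once
  (overlapping teeth are the norm on a panoramic projection).

All geometry in the package uses (row, col) coordinates with the origin at
the top-left and pixel centers at integer coordinates.  LabelMe polygons
store points as (x, y) and are converted to (row=y, col=x) on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

#: Region labels of the 4-class semantic segmentation scheme.
BACKGROUND, INTRABONY, SUPRABONY, CROWN = 0, 1, 2, 3
REGION_LABELS = (BACKGROUND, INTRABONY, SUPRABONY, CROWN)

#: Universal numbering: permanent dentition positions 1..32.
TOOTH_NUMBERS = tuple(range(1, 33))

#: Third molars (excluded from whole-dentition staging by default).
THIRD_MOLARS = frozenset({1, 16, 17, 32})


class MaskError(ValueError):
    """Raised for invalid mask content (labels, shapes, polygons)."""


def _as_bool_grid(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 2:
        raise MaskError(f"{name} must be a 2-D grid, got shape {a.shape}")
    return a.astype(bool)


@dataclass(frozen=True)
class RegionMap:
    """Per-pixel 4-class label grid for one image or crop."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.labels)
        if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
            raise MaskError(f"region map must be a non-empty 2-D grid, got shape {a.shape}")
        bad = np.setdiff1d(np.unique(a), REGION_LABELS)
        if bad.size:
            raise MaskError(f"region map contains out-of-range label {bad[0]} (allowed: 0,1,2,3)")
        object.__setattr__(self, "labels", a.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    def region(self, label: int) -> np.ndarray:
        """Binary mask of one region label."""
        if label not in REGION_LABELS:
            raise MaskError(f"unknown region label {label}")
        return self.labels == label


@dataclass(frozen=True)
class ToothPositionStack:
    """Overlapping per-tooth binary masks keyed by universal tooth number.

    A pixel may be set in several masks; that multi-label property is
    preserved through every pipeline step.
    """

    height: int
    width: int
    masks: Dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise MaskError("stack dimensions must be positive")
        clean: Dict[int, np.ndarray] = {}
        for tooth, mask in self.masks.items():
            if tooth not in TOOTH_NUMBERS:
                raise MaskError(f"tooth number {tooth} outside universal numbering 1..32")
            m = _as_bool_grid(mask, f"mask for tooth {tooth}")
            if m.shape != (self.height, self.width):
                raise MaskError(
                    f"mask for tooth {tooth} has shape {m.shape}, "
                    f"expected {(self.height, self.width)}"
                )
            clean[tooth] = m
        object.__setattr__(self, "masks", clean)

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.height, self.width)

    def teeth(self) -> List[int]:
        return sorted(self.masks)

    def union(self) -> np.ndarray:
        """Union of all position masks (the 'dental region')."""
        out = np.zeros(self.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out


@dataclass(frozen=True)
class ToothRegionMask:
    """One tooth's crown/suprabony/intrabony masks in a shared frame.

    Within a single tooth the three regions are pairwise disjoint; the
    ``frame_offset`` records the crop origin in the parent image so
    measurements can be mapped back.
    """

    tooth_number: int
    crown: np.ndarray
    suprabony: np.ndarray
    intrabony: np.ndarray
    frame_offset: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.tooth_number not in TOOTH_NUMBERS:
            raise MaskError(f"tooth number {self.tooth_number} outside 1..32")
        c = _as_bool_grid(self.crown, "crown")
        s = _as_bool_grid(self.suprabony, "suprabony")
        i = _as_bool_grid(self.intrabony, "intrabony")
        if not (c.shape == s.shape == i.shape):
            raise MaskError("region grids must share one shape")
        if (c.astype(np.uint8) + s + i > 1).any():
            raise MaskError(f"regions of tooth {self.tooth_number} overlap; they must be disjoint")
        object.__setattr__(self, "crown", c)
        object.__setattr__(self, "suprabony", s)
        object.__setattr__(self, "intrabony", i)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.crown.shape

    def root(self) -> np.ndarray:
        """Suprabony ∪ intrabony — the measurable part of the tooth."""
        return self.suprabony | self.intrabony

    def whole(self) -> np.ndarray:
        return self.crown | self.suprabony | self.intrabony


@dataclass(frozen=True)
class ToothLandmarks:
    """Manual reference landmarks for one tooth, in (row, col) sub-pixel coords.

    CEJ: cemento-enamel junction; ABC: alveolar bone crest; AP: apical point.
    ``proximal``/``distal`` distinguish the two sides of the tooth.
    """

    cej_proximal: Tuple[float, float]
    cej_distal: Tuple[float, float]
    abc_proximal: Tuple[float, float]
    abc_distal: Tuple[float, float]
    ap: Tuple[float, float]

    def points(self) -> Dict[str, np.ndarray]:
        return {
            "cej_proximal": np.asarray(self.cej_proximal, dtype=float),
            "cej_distal": np.asarray(self.cej_distal, dtype=float),
            "abc_proximal": np.asarray(self.abc_proximal, dtype=float),
            "abc_distal": np.asarray(self.abc_distal, dtype=float),
            "ap": np.asarray(self.ap, dtype=float),
        }


#: Landmark tables are keyed by tooth number.
LandmarkSet = Dict[int, ToothLandmarks]


# ---------------------------------------------------------------------------
# rasterization

def rasterize_polygon(vertices_rc: Sequence[Tuple[float, float]], shape: Tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon given as (row, col) vertices onto a binary grid.

    A pixel is set when its center (integer coordinates) lies inside the
    polygon or exactly on its boundary (center-inclusive rule).
    """
    if len(vertices_rc) < 3:
        raise MaskError(f"polygon needs at least 3 vertices, got {len(vertices_rc)}")
    poly = Polygon([(float(r), float(c)) for r, c in vertices_rc])
    if not poly.is_valid:
        poly = poly.buffer(0)
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    r0, c0, r1, c1 = poly.bounds
    rr0, rr1 = max(0, int(np.floor(r0))), min(h - 1, int(np.ceil(r1)))
    cc0, cc1 = max(0, int(np.floor(c0))), min(w - 1, int(np.ceil(c1)))
    if rr0 > rr1 or cc0 > cc1:
        return out
    rows, cols = np.meshgrid(np.arange(rr0, rr1 + 1), np.arange(cc0, cc1 + 1), indexing="ij")
    pts = shapely.points(rows.ravel().astype(float), cols.ravel().astype(float))
    inside = shapely.covers(poly, pts).reshape(rows.shape)
    out[rr0 : rr1 + 1, cc0 : cc1 + 1] = inside
    return out


def rasterize_shape(geom, shape: Tuple[int, int]) -> np.ndarray:
    """Center-inclusive rasterization of an arbitrary shapely geometry."""
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    if geom.is_empty:
        return out
    r0, c0, r1, c1 = geom.bounds
    rr0, rr1 = max(0, int(np.floor(r0))), min(h - 1, int(np.ceil(r1)))
    cc0, cc1 = max(0, int(np.floor(c0))), min(w - 1, int(np.ceil(c1)))
    if rr0 > rr1 or cc0 > cc1:
        return out
    rows, cols = np.meshgrid(np.arange(rr0, rr1 + 1), np.arange(cc0, cc1 + 1), indexing="ij")
    pts = shapely.points(rows.ravel().astype(float), cols.ravel().astype(float))
    inside = shapely.covers(geom, pts).reshape(rows.shape)
    out[rr0 : rr1 + 1, cc0 : cc1 + 1] = inside
    return out


# ---------------------------------------------------------------------------
# file I/O

def read_region_map(path) -> RegionMap:
    """Read a single-channel indexed PNG as a 4-class region map."""
    try:
        img = Image.open(path)
    except (FileNotFoundError, OSError) as exc:
        raise MaskError(f"cannot read region map {path!r}: {exc}") from exc
    arr = np.asarray(img.convert("I") if img.mode not in ("L", "P", "I") else img)
    if arr.ndim != 2:
        raise MaskError(f"region map {path!r} is not single-channel")
    return RegionMap(labels=arr)


def write_region_map(region_map: RegionMap, path) -> None:
    Image.fromarray(region_map.labels, mode="L").save(path, format="PNG")


def read_labelme_positions(path, height: int, width: int) -> ToothPositionStack:
    """Rasterize a LabelMe-style JSON annotation into a tooth position stack.

    Shapes are labelled ``tooth_<n>`` with n in 1..32 and carry polygon
    points in LabelMe's (x, y) order.  Overlapping polygons produce
    overlapping masks; several polygons with the same label are unioned.
    """
    with open(path) as fh:
        doc = json.load(fh)
    masks: Dict[int, np.ndarray] = {}
    for shape in doc.get("shapes", []):
        label = shape.get("label", "")
        if not label.startswith("tooth_"):
            raise MaskError(f"unknown shape label {label!r} (expected 'tooth_<n>')")
        try:
            tooth = int(label[len("tooth_") :])
        except ValueError:
            raise MaskError(f"unknown shape label {label!r} (expected 'tooth_<n>')") from None
        if tooth not in TOOTH_NUMBERS:
            raise MaskError(f"label {label!r}: tooth number outside 1..32")
        points = shape.get("points", [])
        if len(points) < 3:
            raise MaskError(f"label {label!r}: polygon has {len(points)} vertices, need >= 3")
        # LabelMe stores (x, y); convert to (row, col)
        verts_rc = [(float(y), float(x)) for x, y in points]
        mask = rasterize_polygon(verts_rc, (height, width))
        if tooth in masks:
            masks[tooth] = masks[tooth] | mask
        else:
            masks[tooth] = mask
    return ToothPositionStack(height=height, width=width, masks=masks)


def write_position_masks(stack: ToothPositionStack, out_dir) -> None:
    """Write one binary PNG per tooth (``tooth_NN.png``, 0/255)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tooth, mask in stack.masks.items():
        Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(
            out / f"tooth_{tooth:02d}.png", format="PNG"
        )


def read_position_masks(in_dir) -> ToothPositionStack:
    """Read a directory of ``tooth_NN.png`` binary masks into a stack."""
    files = sorted(Path(in_dir).glob("tooth_*.png"))
    if not files:
        raise MaskError(f"no tooth_*.png masks found in {in_dir!r}")
    masks: Dict[int, np.ndarray] = {}
    shape: Optional[Tuple[int, int]] = None
    for f in files:
        tooth = int(f.stem.split("_")[1])
        arr = np.asarray(Image.open(f))
        if shape is None:
            shape = arr.shape
        masks[tooth] = arr > 0
    assert shape is not None
    return ToothPositionStack(height=shape[0], width=shape[1], masks=masks)


REPORT_COLUMNS = ["tooth_number", "A", "B", "rbl_percent", "stage", "flags"]


def write_rbl_report(results: Iterable, path) -> None:
    """Write per-tooth measurement results as a CSV, ordered by tooth number.

    Accepts the RBLResult objects produced by :mod:`rblkit.measurement`.
    """
    rows = []
    for r in sorted(results, key=lambda r: r.tooth_number):
        rows.append(
            {
                "tooth_number": r.tooth_number,
                "A": r.A,
                "B": r.B,
                "rbl_percent": r.rbl_percent,
                "stage": r.stage.name,
                "flags": "|".join(sorted(f.name for f in r.flags)),
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.to_csv(path, index=False)


def read_rbl_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise MaskError(f"RBL report {path!r} is missing columns {missing}")
    return df


def write_landmarks_csv(landmarks: Mapping[int, ToothLandmarks], path) -> None:
    rows = []
    for tooth in sorted(landmarks):
        lm = landmarks[tooth]
        row = {"tooth_number": tooth}
        for name, pt in lm.points().items():
            row[f"{name}_row"], row[f"{name}_col"] = float(pt[0]), float(pt[1])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path) -> LandmarkSet:
    df = pd.read_csv(path)
    out: LandmarkSet = {}
    for _, row in df.iterrows():
        out[int(row["tooth_number"])] = ToothLandmarks(
            cej_proximal=(row["cej_proximal_row"], row["cej_proximal_col"]),
            cej_distal=(row["cej_distal_row"], row["cej_distal_col"]),
            abc_proximal=(row["abc_proximal_row"], row["abc_proximal_col"]),
            abc_distal=(row["abc_distal_row"], row["abc_distal_col"]),
            ap=(row["ap_row"], row["ap_col"]),
        )
    return out
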