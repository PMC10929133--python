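"""Radiographic bone loss (RBL) per tooth, staging, and manual references.

RBL% = 100 * A / B, where A is the length of the tooth's principal axis
inside the convex hull of the suprabony root portion (root exposed by bone
loss) and B the length inside the hull of the whole root (suprabony plus
intrabony).  Severity staging follows the 2018 periodontitis classification
cutoffs: stage I below 15%, stage II from 15% up to (but excluding) 33%,
stage III at 33% and above.

Two manual landmark-based references are implemented for comparison:

* length method — max(L1/L2, R1/R2) * 100 from straight-line CEJ->ABC and
  CEJ->AP distances on each side of the tooth;
* distance method — max(L3/L4, R3/R4) * 100 from the same point pairs
  projected onto the tooth's long axis (axial level differences).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import FrozenSet, List, Sequence, Tuple

import numpy as np

from .geometry import (
    GeometryError,
    PrincipalAxis,
    axis_length_in_hull,
    convex_hull,
    principal_axis,
)
from .masks import THIRD_MOLARS, ToothLandmarks, ToothRegionMask

DEFAULT_STAGE_THRESHOLDS: Tuple[float, float] = (15.0, 33.0)


class Stage(enum.Enum):
    """Periodontitis bone-loss severity stage."""

    I = 1
    II = 2
    III = 3

    def __lt__(self, other: "Stage") -> bool:
        return self.value < other.value


class Flag(enum.Enum):
    """Quality flags attached to a per-tooth measurement."""

    DEGENERATE_AXIS = enum.auto()  # near-isotropic shape, axis ill-determined
    NO_INTRABONY = enum.auto()  # no bone-covered root pixels -> RBL 100
    NO_SUPRABONY = enum.auto()  # no exposed root pixels -> RBL 0
    EMPTY_ROOT = enum.auto()


class MeasurementError(ValueError):
    """Raised when a tooth or landmark set cannot be measured."""


class EmptyRootError(MeasurementError):
    """Both root regions empty: a crown-only tooth is unmeasurable."""


@dataclass(frozen=True)
class RBLResult:
    tooth_number: int
    A: float
    B: float
    rbl_percent: float
    stage: Stage
    flags: FrozenSet[Flag] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.B > 0 and not (0.0 <= self.A <= self.B + 1e-9):
            raise MeasurementError(f"invalid lengths A={self.A}, B={self.B}")
        if not (0.0 <= self.rbl_percent <= 100.0):
            raise MeasurementError(f"rbl_percent {self.rbl_percent} outside [0, 100]")


@dataclass(frozen=True)
class ManualMeasurement:
    """Side-wise lengths/distances and the two manual RBL percentages."""

    L1: float
    L2: float
    R1: float
    R2: float
    L3: float
    L4: float
    R3: float
    R4: float
    rbl_length_percent: float
    rbl_distance_percent: float


def assign_stage(
    rbl_percent: float, thresholds: Tuple[float, float] = DEFAULT_STAGE_THRESHOLDS
) -> Stage:
    """Map an RBL percentage to a severity stage.

    Boundaries: the lower cutoff belongs to stage II ("< 15%" is stage I),
    the upper cutoff belongs to stage III (">= 33%").
    """
    if not math.isfinite(rbl_percent):
        raise MeasurementError(f"rbl_percent must be finite, got {rbl_percent}")
    if not (0.0 <= rbl_percent <= 100.0):
        raise MeasurementError(f"rbl_percent {rbl_percent} outside [0, 100]")
    t1, t2 = thresholds
    if not (0.0 < t1 < t2):
        raise MeasurementError(f"invalid stage thresholds {thresholds}")
    if rbl_percent < t1:
        return Stage.I
    if rbl_percent < t2:
        return Stage.II
    return Stage.III


def measure_rbl(
    tooth: ToothRegionMask,
    axis_source: str = "tooth",
    stage_thresholds: Tuple[float, float] = DEFAULT_STAGE_THRESHOLDS,
) -> RBLResult:
    """Measure one tooth's RBL% from its region masks.

    The principal axis is fitted to the whole tooth (crown plus root) by
    default — the enclosing ellipse is a whole-body fit — or to the root
    regions only with ``axis_source='root'``.  The axis line is treated as
    infinite and clipped against each region hull, so A and B share one
    anchor even when the tooth centroid falls outside a region's hull.
    """
    if axis_source not in ("tooth", "root"):
        raise MeasurementError(f"axis_source must be 'tooth' or 'root', got {axis_source!r}")
    root = tooth.root()
    if not root.any():
        raise EmptyRootError(
            f"tooth {tooth.tooth_number}: both root regions empty (crown-only tooth)"
        )
    axis_mask = tooth.whole() if axis_source == "tooth" else root
    try:
        axis = principal_axis(axis_mask)
    except GeometryError as exc:
        raise MeasurementError(f"tooth {tooth.tooth_number}: {exc}") from exc

    flags = set()
    if axis.degenerate_flag:
        flags.add(Flag.DEGENERATE_AXIS)

    supra_any = bool(tooth.suprabony.any())
    intra_any = bool(tooth.intrabony.any())
    if not supra_any:
        flags.add(Flag.NO_SUPRABONY)
    if not intra_any:
        flags.add(Flag.NO_INTRABONY)

    B = axis_length_in_hull(axis, convex_hull(root))
    A = axis_length_in_hull(axis, convex_hull(tooth.suprabony)) if supra_any else 0.0
    A = min(A, B)  # inclusion guarantees A <= B; guard float noise only

    if B > 0:
        rbl = 100.0 * A / B
    else:
        # zero-length clip (e.g. single-pixel root): fall back to region presence
        rbl = 100.0 if (supra_any and not intra_any) else 0.0
    rbl = min(100.0, max(0.0, rbl))
    return RBLResult(
        tooth_number=tooth.tooth_number,
        A=A,
        B=B,
        rbl_percent=rbl,
        stage=assign_stage(rbl, stage_thresholds),
        flags=frozenset(flags),
    )


def _side_lengths(lm: ToothLandmarks) -> Tuple[float, float, float, float]:
    p = lm.points()
    l1 = float(np.linalg.norm(p["cej_proximal"] - p["abc_proximal"]))
    l2 = float(np.linalg.norm(p["cej_proximal"] - p["ap"]))
    r1 = float(np.linalg.norm(p["cej_distal"] - p["abc_distal"]))
    r2 = float(np.linalg.norm(p["cej_distal"] - p["ap"]))
    return l1, l2, r1, r2


def manual_rbl_length(lm: ToothLandmarks) -> float:
    """Manual RBL by straight-line lengths: max(L1/L2, R1/R2) * 100."""
    l1, l2, r1, r2 = _side_lengths(lm)
    if l2 <= 0:
        raise MeasurementError("proximal CEJ->AP length is zero; ratio undefined")
    if r2 <= 0:
        raise MeasurementError("distal CEJ->AP length is zero; ratio undefined")
    return 100.0 * max(l1 / l2, r1 / r2)


def manual_rbl_distance(lm: ToothLandmarks, axis_direction: Sequence[float]) -> float:
    """Manual RBL by axial distances: max(L3/L4, R3/R4) * 100.

    L3/L4 (and R3/R4) are the absolute projections of the CEJ->ABC and
    CEJ->AP displacement vectors onto the tooth's long-axis direction, i.e.
    level differences along the tooth axis rather than straight-line lengths.
    """
    d = np.asarray(axis_direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise MeasurementError("axis_direction must be a unit vector")
    p = lm.points()
    l3 = abs(float((p["abc_proximal"] - p["cej_proximal"]) @ d))
    l4 = abs(float((p["ap"] - p["cej_proximal"]) @ d))
    r3 = abs(float((p["abc_distal"] - p["cej_distal"]) @ d))
    r4 = abs(float((p["ap"] - p["cej_distal"]) @ d))
    if l4 <= 0:
        raise MeasurementError("proximal CEJ->AP axial distance is zero; ratio undefined")
    if r4 <= 0:
        raise MeasurementError("distal CEJ->AP axial distance is zero; ratio undefined")
    return 100.0 * max(l3 / l4, r3 / r4)


def manual_measurement(lm: ToothLandmarks, axis_direction: Sequence[float]) -> ManualMeasurement:
    """Both manual references with their intermediate side quantities."""
    l1, l2, r1, r2 = _side_lengths(lm)
    d = np.asarray(axis_direction, dtype=float)
    p = lm.points()
    l3 = abs(float((p["abc_proximal"] - p["cej_proximal"]) @ d))
    l4 = abs(float((p["ap"] - p["cej_proximal"]) @ d))
    r3 = abs(float((p["abc_distal"] - p["cej_distal"]) @ d))
    r4 = abs(float((p["ap"] - p["cej_distal"]) @ d))
    return ManualMeasurement(
        L1=l1, L2=l2, R1=r1, R2=r2, L3=l3, L4=l4, R3=r3, R4=r4,
        rbl_length_percent=manual_rbl_length(lm),
        rbl_distance_percent=manual_rbl_distance(lm, axis_direction),
    )


def max_rbl_dentition(
    results: List[RBLResult], exclude_third_molars: bool = True
) -> Tuple[float, Stage]:
    """Whole-dentition summary: the maximum per-tooth RBL% and its stage.

    Third molars (universal numbers 1, 16, 17, 32) are excluded by default,
    matching standard staging practice.
    """
    if not results:
        raise MeasurementError("no measurement results given")
    pool = [
        r for r in results
        if not (exclude_third_molars and r.tooth_number in THIRD_MOLARS)
    ]
    if not pool:
        raise MeasurementError("no teeth remain after third-molar exclusion")
    best = max(pool, key=lambda r: r.rbl_percent)
    return best.rbl_percent, best.stage
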