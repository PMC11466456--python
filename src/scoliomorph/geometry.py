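"""Planar body-axis geometry: curvature index, Cobb angles, embryo deflection angles.

The central statistic is the *curvature index* of a traced body midline: the
midline is resampled at equidistant arc-length points, a discrete local
curvature is estimated at every interior point from the circumscribed circle
through it and its two neighbours (Menger curvature), and the absolute values
are summed.  Two companion quantities are reported:

``raw_sum``
    Sum of absolute per-point curvatures, in radians per length unit.  It
    depends on the number of resampled points and on the coordinate unit, so
    it is only comparable between fish measured with one configuration.
``arc_integral``
    ``raw_sum * spacing`` — the total absolute turning of the curve in
    radians, a discretisation of the scale-invariant integral of |kappa| ds.
    For a simple closed convex curve it converges to 2*pi.

Angles are exposed in degrees at all interfaces; curvature is in radians per
calibrated length unit.  The sign convention for curvature is
counterclockwise-positive in a y-up frame (image input is flipped on load).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "View",
    "Point2D",
    "Polyline",
    "ResampledMidline",
    "CurvatureProfile",
    "CurvatureIndexResult",
    "LandmarkLine",
    "CobbMeasurement",
    "EmbryoLandmarks",
    "RoseHistogram",
    "resample_equidistant",
    "menger_curvature",
    "curvature_profile",
    "curvature_index",
    "combined_curvature_index",
    "cobb_angle",
    "total_cobb",
    "embryo_deflection_angle",
    "rose_bin",
]


class View(str, Enum):
    """Imaging view of a traced midline."""

    LATERAL = "lateral"
    DORSAL = "dorsal"


@dataclass(frozen=True)
class Point2D:
    """A point in calibrated 2D coordinates (y up)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def _as_xy(points: Sequence[Point2D] | np.ndarray) -> np.ndarray:
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
    else:
        arr = np.array([[p.x, p.y] for p in points], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) coordinate array")
    return arr


@dataclass
class Polyline:
    """An ordered trace of a body midline in one view.

    ``scale`` multiplies raw coordinates into calibrated units (1.0 if the
    trace is already calibrated).  Consecutive points closer than 1e-9 of the
    total length are merged on construction with a warning.
    """

    points: list[Point2D]
    view: View = View.LATERAL
    unit: str = "px"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if len(self.points) < 2:
            raise ValueError("a polyline needs at least 2 points")
        self.view = View(self.view)
        xy = _as_xy(self.points)
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        total = float(seg.sum())
        if total <= 0:
            raise ValueError("polyline has zero total arc length")
        tol = 1e-9 * total
        keep = np.concatenate([[True], seg > tol])
        if not keep.all():
            logger.warning(
                "merged %d near-duplicate consecutive points", int((~keep).sum())
            )
            self.points = [p for p, k in zip(self.points, keep) if k]
            if len(self.points) < 2:
                raise ValueError("polyline degenerate after duplicate merging")

    @property
    def xy(self) -> np.ndarray:
        """Calibrated (n, 2) coordinate array."""
        return _as_xy(self.points) * self.scale

    @property
    def total_length(self) -> float:
        xy = self.xy
        return float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())

    @classmethod
    def from_xy(
        cls,
        xy: np.ndarray,
        view: View | str = View.LATERAL,
        unit: str = "px",
        scale: float = 1.0,
    ) -> "Polyline":
        return cls([Point2D(float(x), float(y)) for x, y in np.asarray(xy)], View(view), unit, scale)


@dataclass
class ResampledMidline:
    """A midline resampled at constant arc-length steps."""

    points: list[Point2D]
    spacing: float
    n_points: int
    total_length: float
    view: View = View.LATERAL
    unit: str = "px"

    @property
    def xy(self) -> np.ndarray:
        return _as_xy(self.points)


@dataclass
class CurvatureProfile:
    """Signed Menger curvature at each interior resampled point."""

    curvatures: np.ndarray
    spacing: float
    unit: str = "px"
    view: View = View.LATERAL
    n_points: int = 0

    def __post_init__(self) -> None:
        self.curvatures = np.asarray(self.curvatures, dtype=float)
        if not np.all(np.isfinite(self.curvatures)):
            raise ValueError("non-finite curvature values")


@dataclass
class CurvatureIndexResult:
    """Curvature index of one view.

    ``raw_sum`` is the sum of |kappa_i| (sampling-dependent); ``arc_integral``
    is ``raw_sum * spacing``, the total absolute turning in radians.
    """

    raw_sum: float
    arc_integral: float
    view: View
    n_points: int
    unit: str = "px"


@dataclass(frozen=True)
class LandmarkLine:
    """A line drawn parallel to a displaced vertebra, given by two endpoints."""

    p1: Point2D
    p2: Point2D
    label: str = ""

    def __post_init__(self) -> None:
        if self.p1.x == self.p2.x and self.p1.y == self.p2.y:
            raise ValueError("degenerate landmark line: identical endpoints")

    @property
    def direction(self) -> np.ndarray:
        d = self.p2.as_array() - self.p1.as_array()
        return d / np.linalg.norm(d)


@dataclass
class CobbMeasurement:
    """One Cobb angle: the acute angle between two vertebral landmark lines."""

    line_top: LandmarkLine
    line_bottom: LandmarkLine
    angle: float
    view: View = View.LATERAL

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle <= 90.0 + 1e-9:
            raise ValueError(f"Cobb angle {self.angle} outside [0, 90]")


@dataclass(frozen=True)
class EmbryoLandmarks:
    """Eye centre, yolk centre and tail tip of one laterally imaged embryo."""

    eye_center: Point2D
    yolk_center: Point2D
    tail_tip: Point2D
    embryo_id: str = ""

    def __post_init__(self) -> None:
        for other, name in ((self.eye_center, "eye"), (self.tail_tip, "tail")):
            if (
                other.x == self.yolk_center.x
                and other.y == self.yolk_center.y
            ):
                raise ValueError(f"yolk centre coincides with {name} landmark")


@dataclass
class RoseHistogram:
    """Counts of deflection angles per angular sector of ``bin_width`` degrees."""

    counts: np.ndarray
    bin_width: float = 30.0
    total: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if 360.0 % self.bin_width != 0:
            raise ValueError("bin width must divide 360")
        if int(self.counts.sum()) != self.total:
            raise ValueError("counts do not sum to total")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(0.0, 360.0 + self.bin_width, self.bin_width)


# ---------------------------------------------------------------------------
# operations


def resample_equidistant(polyline: Polyline, n_points: int = 50) -> ResampledMidline:
    """Resample a polyline at ``n_points`` equal arc-length steps.

    Points are placed at arc lengths i*L/(n_points-1), i = 0..n_points-1, by
    linear interpolation between source vertices, so the endpoints of the
    source trace are preserved exactly.
    """
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    xy = polyline.xy
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    targets = np.linspace(0.0, total, n_points)
    rx = np.interp(targets, s, xy[:, 0])
    ry = np.interp(targets, s, xy[:, 1])
    # pin endpoints to the source ends to avoid fp drift at s = L
    rx[0], ry[0] = xy[0]
    rx[-1], ry[-1] = xy[-1]
    pts = [Point2D(float(x), float(y)) for x, y in zip(rx, ry)]
    return ResampledMidline(
        points=pts,
        spacing=total / (n_points - 1),
        n_points=n_points,
        total_length=total,
        view=polyline.view,
        unit=polyline.unit,
    )


def menger_curvature(
    p_prev: Point2D | Sequence[float],
    p: Point2D | Sequence[float],
    p_next: Point2D | Sequence[float],
) -> float:
    """Signed Menger curvature of three points: 1/R of their circumcircle.

    |kappa| = 4 * Area(triangle) / (|a| |b| |c|); the sign is the sign of the
    z-component of (p - p_prev) x (p_next - p), i.e. counterclockwise turns
    are positive.  Collinear points give 0.
    """
    a = np.asarray(p_prev.as_array() if isinstance(p_prev, Point2D) else p_prev, float)
    b = np.asarray(p.as_array() if isinstance(p, Point2D) else p, float)
    c = np.asarray(p_next.as_array() if isinstance(p_next, Point2D) else p_next, float)
    ab, bc, ca = b - a, c - b, a - c
    la, lb, lc = np.linalg.norm(ab), np.linalg.norm(bc), np.linalg.norm(ca)
    if la == 0 or lb == 0 or lc == 0:
        raise ValueError("coincident points have no defined curvature")
    cross = ab[0] * bc[1] - ab[1] * bc[0]  # twice the signed triangle area
    return float(2.0 * cross / (la * lb * lc))


def _menger_vectorized(xy: np.ndarray) -> np.ndarray:
    """Signed Menger curvature at every interior vertex of an (n, 2) path."""
    a, b, c = xy[:-2], xy[1:-1], xy[2:]
    ab, bc, ca = b - a, c - b, a - c
    la = np.linalg.norm(ab, axis=1)
    lb = np.linalg.norm(bc, axis=1)
    lc = np.linalg.norm(ca, axis=1)
    if np.any(la == 0) or np.any(lb == 0) or np.any(lc == 0):
        raise ValueError("coincident points in resampled midline")
    cross = ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0]
    return 2.0 * cross / (la * lb * lc)


def smooth_midline(midline: ResampledMidline, window: int = 1) -> ResampledMidline:
    """Moving-average pre-filter over the resampled points (window 1 = off).

    Intended for noisy manual traces; endpoints are kept fixed.  The result
    keeps the nominal spacing of the input (smoothing perturbs true arc
    length only to second order for small noise).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if window == 1:
        return midline
    xy = midline.xy.copy()
    kernel = np.ones(window) / window
    half = window // 2
    padded = np.pad(xy, ((half, half), (0, 0)), mode="edge")
    sm = np.column_stack(
        [np.convolve(padded[:, j], kernel, mode="valid") for j in range(2)]
    )
    sm[0], sm[-1] = xy[0], xy[-1]
    return ResampledMidline(
        points=[Point2D(float(x), float(y)) for x, y in sm],
        spacing=midline.spacing,
        n_points=midline.n_points,
        total_length=midline.total_length,
        view=midline.view,
        unit=midline.unit,
    )


def curvature_profile(
    midline: ResampledMidline, smooth_window: int = 1, closed: bool | None = None
) -> CurvatureProfile:
    """Menger curvature at every interior point of a resampled midline.

    For an open trace the profile has ``n_points - 2`` values: curvature is
    undefined at the two endpoints and they are excluded without padding.
    A closed trace (first and last points coincident; auto-detected when
    ``closed`` is None) wraps around the seam instead, giving one value per
    distinct point (``n_points - 1``) so that the total turning of a closed
    convex curve converges to 2*pi.
    """
    if midline.n_points < 3:
        raise ValueError("need at least 3 resampled points")
    if smooth_window > 1:
        midline = smooth_midline(midline, smooth_window)
    xy = midline.xy
    if closed is None:
        closed = bool(
            np.linalg.norm(xy[0] - xy[-1]) < 1e-9 * max(midline.total_length, 1.0)
        )
    if closed:
        # drop the duplicated endpoint and wrap one point on each side
        ring = xy[:-1]
        wrapped = np.vstack([ring[-1], ring, ring[0]])
        curv = _menger_vectorized(wrapped)
    else:
        curv = _menger_vectorized(xy)
    return CurvatureProfile(
        curvatures=curv,
        spacing=midline.spacing,
        unit=midline.unit,
        view=midline.view,
        n_points=midline.n_points,
    )


def curvature_index(profile: CurvatureProfile) -> CurvatureIndexResult:
    """Sum of absolute local curvatures, plus its arc-length integral."""
    if profile.curvatures.size == 0:
        raise ValueError("empty curvature profile")
    raw = float(np.abs(profile.curvatures).sum())
    return CurvatureIndexResult(
        raw_sum=raw,
        arc_integral=raw * profile.spacing,
        view=profile.view,
        n_points=profile.n_points,
        unit=profile.unit,
    )


def combined_curvature_index(
    lateral: CurvatureIndexResult, dorsal: CurvatureIndexResult
) -> CurvatureIndexResult:
    """Per-fish total index: component-wise sum of the two single-view results.

    Refuses to mix results computed with different units or point counts,
    because ``raw_sum`` is only meaningful within one configuration.
    """
    if lateral.unit != dorsal.unit:
        raise ValueError(
            f"unit mismatch between views: {lateral.unit!r} vs {dorsal.unit!r}"
        )
    if lateral.n_points != dorsal.n_points:
        raise ValueError(
            f"n_points mismatch between views: {lateral.n_points} vs {dorsal.n_points}"
        )
    return CurvatureIndexResult(
        raw_sum=lateral.raw_sum + dorsal.raw_sum,
        arc_integral=lateral.arc_integral + dorsal.arc_integral,
        view=lateral.view,
        n_points=lateral.n_points,
        unit=lateral.unit,
    )


def cobb_angle(line_top: LandmarkLine, line_bottom: LandmarkLine) -> float:
    """Acute angle in degrees between two undirected landmark lines.

    Equal, exactly, to the angle between the perpendiculars to the two lines
    (the clinical construction).
    """
    d1, d2 = line_top.direction, line_bottom.direction
    cosang = abs(float(d1[0]) * float(d2[0]) + float(d1[1]) * float(d2[1]))
    return math.degrees(math.acos(min(1.0, cosang)))


def cobb_angle_perpendicular(line_top: LandmarkLine, line_bottom: LandmarkLine) -> float:
    """Cobb angle via the perpendicular-lines construction (for cross-checks)."""
    p1 = (-float(line_top.direction[1]), float(line_top.direction[0]))
    p2 = (-float(line_bottom.direction[1]), float(line_bottom.direction[0]))
    cosang = abs(p1[0] * p2[0] + p1[1] * p2[1])
    return math.degrees(math.acos(min(1.0, cosang)))


def total_cobb(measurements: Sequence[CobbMeasurement]) -> float:
    """Total Cobb angle of a fish: sum over all curves and both views."""
    return float(sum(m.angle for m in measurements))


def embryo_deflection_angle(landmarks: EmbryoLandmarks) -> float:
    """Deflection of the yolk-to-tail vector relative to the eye-to-yolk axis.

    With u = yolk - eye and v = tail - yolk, returns the direction of v in a
    frame where u points along 0 degrees and counterclockwise is positive,
    mapped to [0, 360).  A straight body gives 0; a tail bent dorsally (up,
    with the head to the left) gives angles near 90.
    """
    u = landmarks.yolk_center.as_array() - landmarks.eye_center.as_array()
    v = landmarks.tail_tip.as_array() - landmarks.yolk_center.as_array()
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise ValueError("degenerate embryo landmarks: zero-length axis vector")
    ang = math.atan2(v[1], v[0]) - math.atan2(u[1], u[0])
    deg = math.degrees(ang) % 360.0
    return 0.0 if deg == 360.0 else deg


def rose_bin(angles: Sequence[float], bin_width: float = 30.0) -> RoseHistogram:
    """Bin deflection angles into left-closed sectors [k*w, (k+1)*w).

    Angles outside [0, 360) are normalised modulo 360 with a warning.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() >= 360.0):
        logger.warning("angles outside [0, 360) normalised modulo 360")
        arr = arr % 360.0
    n_bins = int(round(360.0 / bin_width))
    if n_bins * bin_width != 360.0:
        raise ValueError("bin width must divide 360")
    idx = np.floor(arr / bin_width).astype(int) if arr.size else np.array([], int)
    counts = np.bincount(idx, minlength=n_bins) if arr.size else np.zeros(n_bins, int)
    return RoseHistogram(counts=counts, bin_width=bin_width, total=int(arr.size))
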