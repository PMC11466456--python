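"""Midline acquisition: traced-coordinate CSV loading and skeleton-based
extraction from binary fish masks.

A manual trace arrives as a CSV of ordered points per (fish_id, view); a mask
arrives as a binary image.  Both are turned into calibrated
:class:`~scoliomorph.geometry.Polyline` objects in a y-up frame (image rows
are flipped on load so that the counterclockwise-positive curvature
convention of the geometry module holds).

Mask extraction keeps the largest 8-connected foreground component,
skeletonises it, and prunes the skeleton to the single longest geodesic path
between skeleton endpoints — side branches produced by fins disappear, and
what remains matches the single mouth-to-tail-base line a human tracer would
draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label
from skimage.morphology import skeletonize

from .geometry import Point2D, Polyline, View

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "HeadHint",
    "load_midline_csv",
    "extract_midline_from_mask",
    "MidlineFormatError",
    "ExtractionError",
]

MIDLINE_COLUMNS = ["fish_id", "view", "point_index", "x", "y"]


class MidlineFormatError(ValueError):
    """Raised for malformed midline CSV input."""


class ExtractionError(RuntimeError):
    """Raised when no elongated midline can be extracted from a mask."""


@dataclass
class BinaryMask:
    """A binary fish silhouette; row 0 is the image top (y-down pixel frame)."""

    pixels: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels) != 0
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2D array")
        if not self.pixels.any():
            raise ValueError("mask has no foreground pixels")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def from_image(cls, path: str | Path, scale: float = 1.0) -> "BinaryMask":
        import imageio.v3 as iio

        img = iio.imread(path)
        if img.ndim == 3:
            img = img[..., :3].max(axis=-1)
        return cls(pixels=img > 0, scale=scale)


@dataclass
class HeadHint:
    """Approximate head location, used to orient the extracted path."""

    point: Point2D | None = None


def load_midline_csv(path: str | Path, scale: float = 1.0) -> list[Polyline]:
    """Load traced midlines from CSV: one polyline per (fish_id, view) group.

    Expected columns: fish_id, view in {lateral, dorsal}, point_index, x, y.
    Points are ordered by point_index; the y axis is flipped to y-up and
    coordinates multiplied by ``scale``.  The returned polylines carry the
    fish identifier in the attribute ``fish_id``.
    """
    df = pd.read_csv(path)
    missing = [c for c in MIDLINE_COLUMNS if c not in df.columns]
    if missing:
        raise MidlineFormatError(f"{path}: missing columns {missing}")
    out: list[Polyline] = []
    for (fish_id, view), grp in df.groupby(["fish_id", "view"], sort=True):
        grp = grp.sort_values("point_index")
        idx = grp["point_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise MidlineFormatError(
                f"{path}: duplicated point_index in group ({fish_id}, {view})"
            )
        if len(grp) < 2:
            raise MidlineFormatError(
                f"{path}: group ({fish_id}, {view}) has fewer than 2 points"
            )
        pts = [
            Point2D(float(x), float(-y)) for x, y in zip(grp["x"], grp["y"])
        ]
        try:
            pl = Polyline(points=pts, view=View(str(view)), unit="calibrated", scale=scale)
        except ValueError as exc:
            raise MidlineFormatError(
                f"{path}: invalid polyline in group ({fish_id}, {view}): {exc}"
            ) from exc
        pl.fish_id = str(fish_id)  # type: ignore[attr-defined]
        out.append(pl)
    if not out:
        raise MidlineFormatError(f"{path}: no midline groups found")
    return out


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray):
    """Sparse 8-connectivity graph over skeleton pixels (weights 1 / sqrt2)."""
    coords = np.argwhere(skel)
    index = -np.ones(skel.shape, dtype=int)
    index[tuple(coords.T)] = np.arange(len(coords))
    rows, cols, w = [], [], []
    for dr, dc in _NEIGHBOURS:
        nbr = coords + [dr, dc]
        ok = (
            (nbr[:, 0] >= 0)
            & (nbr[:, 0] < skel.shape[0])
            & (nbr[:, 1] >= 0)
            & (nbr[:, 1] < skel.shape[1])
        )
        ok[ok] &= skel[tuple(nbr[ok].T)]
        src = np.flatnonzero(ok)
        dst = index[tuple(nbr[src].T)]
        rows.append(src)
        cols.append(dst)
        w.append(np.full(len(src), np.hypot(dr, dc)))
    g = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(coords), len(coords)),
    ).tocsr()
    return coords, g


def _longest_geodesic_path(coords: np.ndarray, graph) -> np.ndarray:
    """Longest shortest path between skeleton endpoints (tree-diameter sweep)."""
    degree = np.diff(graph.indptr)
    endpoints = np.flatnonzero(degree == 1)
    if len(endpoints) == 0:
        raise ExtractionError("skeleton has no endpoints (ring-shaped mask?)")
    # double-Dijkstra: farthest node from an arbitrary endpoint, then farthest
    # from that — the diameter of a tree; a good approximation off-tree.
    d0 = dijkstra(graph, indices=endpoints[0])
    d0[~np.isfinite(d0)] = -1
    a = int(np.argmax(d0))
    d1, pred = dijkstra(graph, indices=a, return_predecessors=True)
    d1[~np.isfinite(d1)] = -1
    b = int(np.argmax(d1))
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            raise ExtractionError("disconnected skeleton")
        path.append(int(p))
    return coords[path[::-1]]


def extract_midline_from_mask(
    mask: BinaryMask,
    head: HeadHint | None = None,
    tail_fraction: float = 1.0,
) -> Polyline:
    """Extract the body midline of a fish silhouette as a calibrated Polyline.

    Pipeline: largest 8-connected component -> morphological skeleton ->
    longest geodesic path between skeleton endpoints -> orientation so the
    start is nearest the head hint (leftmost endpoint if absent) -> optional
    truncation at ``tail_fraction`` of the path length (to stop at the tail
    base, excluding the fin; default 1.0 keeps everything).

    Degenerate masks without an elongated axis (e.g. a disk) yield either an
    extraction error or a warning when the path is shorter than the
    equivalent disk diameter.
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in (0, 1]")
    lbl = label(mask.pixels, connectivity=2)
    largest = np.argmax(np.bincount(lbl.ravel())[1:]) + 1
    fg = lbl == largest
    skel = skeletonize(fg)
    if not skel.any():
        raise ExtractionError("empty skeleton")
    coords, graph = _skeleton_graph(skel)
    path = _longest_geodesic_path(coords, graph)  # (row, col) pixel coords

    # degenerate-shape diagnostic: path much shorter than the blob's extent
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    path_len = float(steps.sum())
    eq_diameter = 2.0 * np.sqrt(fg.sum() / np.pi)
    if path_len < eq_diameter:
        logger.warning(
            "extracted path (%.1f px) shorter than equivalent disk diameter "
            "(%.1f px); mask has no clear elongated axis",
            path_len,
            eq_diameter,
        )

    # pixel (row, col) -> y-up (x, y)
    n_rows = mask.pixels.shape[0]
    xy = np.column_stack([path[:, 1].astype(float), (n_rows - 1 - path[:, 0]).astype(float)])

    if head is not None and head.point is not None:
        h = head.point.as_array()
        if np.linalg.norm(xy[-1] - h) < np.linalg.norm(xy[0] - h):
            xy = xy[::-1]
    elif xy[-1, 0] < xy[0, 0]:  # leftmost endpoint first
        xy = xy[::-1]

    if tail_fraction < 1.0:
        cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
        keep = cum <= tail_fraction * cum[-1]
        keep[0] = True
        xy = xy[keep]
        if len(xy) < 2:
            raise ExtractionError("truncated path too short")

    return Polyline.from_xy(xy, view=View.LATERAL, unit="calibrated", scale=mask.scale)
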