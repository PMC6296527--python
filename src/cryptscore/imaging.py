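"""Quantitative scoring of immunostained colorectal hemicrypts.

The unit of analysis is a *hemicrypt*: one half of a longitudinally bisected
colonic crypt, traced as a polygon that extends from the muscularis mucosae
(base) to the colon lumen (apex).  Scoring partitions the traced outline into
``n_segments`` (default 50) equal-width segments along the crypt axis —
roughly the width of one normal colonocyte each — and integrates the
background-corrected optical density of the immunostain within each segment
and over the whole hemicrypt.

Optical density follows Beer–Lambert densitometry:
``OD = -log10(I / I_bg)`` where ``I`` is the transmitted pixel intensity and
``I_bg`` the blank-field (background) intensity.  Darker labeling gives larger
OD.  Segment values are *integrated* OD (sums of per-pixel OD), so zone
totals are additive: whole = upper + lower.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from skimage.draw import polygon2mask

__all__ = [
    "HemicryptOutline",
    "SegmentSet",
    "SegmentProfile",
    "GeometryError",
    "partition_hemicrypt",
    "pixel_optical_density",
    "score_hemicrypt",
    "estimate_background",
]

#: minimum admissible pixel intensity when converting to OD (one count);
#: prevents -log10 of zero on saturated-dark pixels.
INTENSITY_FLOOR = 1.0

#: number of arc-length samples per lateral border when building the axis.
_AXIS_SAMPLES = 256


class GeometryError(ValueError):
    """Raised for degenerate or invalid hemicrypt outlines."""


def segment_index(t: np.ndarray, n_segments: int) -> np.ndarray:
    """Half-open segment binning of axial coordinates: t in [k/n, (k+1)/n).

    A coordinate exactly on a boundary belongs to the higher-index segment;
    a small forward tolerance keeps that rule stable against the ~1 ulp
    rounding of arc-length computation.
    """
    k = np.floor(np.asarray(t) * n_segments + 1e-8).astype(np.int64)
    return np.clip(k, 0, n_segments - 1)


@dataclass(frozen=True)
class HemicryptOutline:
    """A traced hemicrypt polygon with base/apex edge designation.

    Parameters
    ----------
    vertices
        Ordered ``(x, y)`` pixel coordinates of the outline, 0-based,
        ``x`` = column, ``y`` = row, origin at the top-left of the image.
    base_range
        Inclusive index interval ``(i, j)`` into ``vertices`` marking the
        basal edge (muscularis mucosae side).
    apex_range
        Inclusive index interval marking the luminal (apex) edge.
    """

    vertices: tuple[tuple[float, float], ...]
    base_range: tuple[int, int]
    apex_range: tuple[int, int]
    hemicrypt_id: str = ""
    image_id: str = ""
    marker_id: str = "other"

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        n = len(verts)
        if n < 3:
            raise GeometryError("outline needs at least 3 vertices")
        for name, (i, j) in (("base_range", self.base_range), ("apex_range", self.apex_range)):
            if not (0 <= i <= j < n):
                raise GeometryError(f"{name}={self.base_range if name == 'base_range' else self.apex_range} out of bounds for {n} vertices")
        bi, bj = self.base_range
        ai, aj = self.apex_range
        if set(range(bi, bj + 1)) & set(range(ai, aj + 1)):
            raise GeometryError("base and apex vertex ranges overlap")
        poly = self.polygon
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("outline polygon is self-intersecting or invalid")
        if poly.area <= 0:
            raise GeometryError("outline polygon has zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def _edge_vertices(self, vrange: tuple[int, int]) -> np.ndarray:
        i, j = vrange
        return np.asarray(self.vertices[i : j + 1], dtype=float)

    @property
    def base_midpoint(self) -> np.ndarray:
        return _polyline_midpoint(self._edge_vertices(self.base_range))

    @property
    def apex_midpoint(self) -> np.ndarray:
        return _polyline_midpoint(self._edge_vertices(self.apex_range))

    def lateral_borders(self) -> tuple[np.ndarray, np.ndarray]:
        """The two border polylines joining base to apex, both oriented base→apex."""
        n = len(self.vertices)
        verts = np.asarray(self.vertices, dtype=float)
        bi, bj = self.base_range
        ai, aj = self.apex_range
        if bj < ai:
            side1 = verts[bj : ai + 1]                       # base end -> apex start
            idx2 = list(range(aj, n)) + list(range(0, bi + 1))  # apex end -> base start (wraps)
            side2 = verts[idx2][::-1]
        else:  # apex range precedes base range in vertex order
            side1 = verts[aj : bi + 1][::-1]
            idx2 = list(range(bj, n)) + list(range(0, ai + 1))
            side2 = verts[idx2]
        if len(side1) < 2 or len(side2) < 2:
            raise GeometryError("lateral borders are degenerate (base adjacent to apex)")
        return side1, side2

    def medial_axis(self, n_samples: int = _AXIS_SAMPLES) -> LineString:
        """Approximate crypt axis: midpoints of the two lateral borders.

        The polyline runs from the base-edge midpoint to the apex-edge
        midpoint; interior points are midpoints of the two borders sampled
        at equal normalized arc length.
        """
        side1, side2 = self.lateral_borders()
        s = np.linspace(0.0, 1.0, n_samples)
        p1 = _sample_polyline(side1, s)
        p2 = _sample_polyline(side2, s)
        mid = 0.5 * (p1 + p2)
        pts = np.vstack([self.base_midpoint, mid[1:-1], self.apex_midpoint])
        # drop consecutive duplicates (straight symmetric shapes collapse points)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)
        pts = pts[keep]
        if len(pts) < 2:
            raise GeometryError("degenerate axis: base and apex midpoints coincide")
        return LineString(pts)

    def raster_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the outline."""
        rc = np.asarray([(y, x) for x, y in self.vertices], dtype=float)
        return polygon2mask(shape, rc)


def _polyline_midpoint(pts: np.ndarray) -> np.ndarray:
    """Arc-length midpoint of a polyline (the point itself if a single vertex)."""
    if len(pts) == 1:
        return pts[0].astype(float)
    return _sample_polyline(pts, np.array([0.5]))[0]


def _sample_polyline(pts: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Sample a polyline at normalized arc-length positions ``s`` in [0, 1]."""
    seg = np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return np.repeat(pts[:1], len(s), axis=0)
    x = np.interp(s * total, cum, pts[:, 0])
    y = np.interp(s * total, cum, pts[:, 1])
    return np.column_stack([x, y])


@dataclass(frozen=True)
class SegmentSet:
    """Partition of a hemicrypt interior into axial segments.

    ``labels`` is an image-shaped integer array: ``-1`` outside the outline,
    otherwise the 0-based segment index (0 = base, ``n_segments - 1`` = apex).
    ``axial_t`` holds each interior pixel's normalized axial coordinate
    ``t ∈ [0, 1)`` (NaN outside).
    """

    labels: np.ndarray
    axial_t: np.ndarray
    n_segments: int

    @property
    def masks(self) -> list[np.ndarray]:
        return [self.labels == k for k in range(self.n_segments)]

    @property
    def pixel_counts(self) -> np.ndarray:
        inside = self.labels >= 0
        return np.bincount(self.labels[inside], minlength=self.n_segments)

    def interior_mask(self) -> np.ndarray:
        return self.labels >= 0


@dataclass(frozen=True)
class SegmentProfile:
    """Integrated OD per axial segment plus the whole-hemicrypt total."""

    hemicrypt_id: str
    marker_id: str
    od_segments: np.ndarray
    od_whole: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        seg = np.asarray(self.od_segments, dtype=float)
        object.__setattr__(self, "od_segments", seg)
        if np.any(seg < 0):
            raise ValueError("segment OD values must be nonnegative")
        total = float(seg.sum())
        if self.od_whole is None:
            object.__setattr__(self, "od_whole", total)
        elif not np.isclose(self.od_whole, total, rtol=1e-9, atol=1e-9):
            raise ValueError(
                f"od_whole={self.od_whole!r} does not equal the segment sum {total!r}"
            )

    @property
    def n_segments(self) -> int:
        return len(self.od_segments)


def partition_hemicrypt(
    outline: HemicryptOutline,
    image_shape: tuple[int, int],
    n_segments: int = 50,
) -> SegmentSet:
    """Assign each interior pixel of a hemicrypt to one of ``n_segments``.

    Every pixel gets a normalized axial coordinate ``t``: the arc length of
    its nearest point on the medial axis divided by the total axis length
    (0 at the base, approaching 1 at the apex).  Segment ``k`` (0-based)
    collects pixels with ``t ∈ [k/n, (k+1)/n)``; a ``t`` exactly on a
    boundary goes to the higher-index segment.

    Parameters
    ----------
    outline
        Validated hemicrypt outline.
    image_shape
        ``(rows, cols)`` of the image the outline lives in.
    n_segments
        Number of equal-width axial segments (1 or more).
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    axis = outline.medial_axis()
    mask = outline.raster_mask(image_shape)
    rows, cols = np.nonzero(mask)
    labels = np.full(image_shape, -1, dtype=np.int32)
    axial_t = np.full(image_shape, np.nan, dtype=float)
    if rows.size:
        pts = shapely.points(np.column_stack([cols, rows]).astype(float))
        t = shapely.line_locate_point(axis, pts) / axis.length
        t = np.clip(t, 0.0, np.nextafter(1.0, 0.0))
        seg = segment_index(t, n_segments)
        labels[rows, cols] = seg
        axial_t[rows, cols] = t
    return SegmentSet(labels=labels, axial_t=axial_t, n_segments=n_segments)


def pixel_optical_density(
    intensity: float | np.ndarray,
    background_intensity: float,
    intensity_floor: float = INTENSITY_FLOOR,
) -> float | np.ndarray:
    """Background-corrected optical density of transmitted intensity.

    ``OD = -log10(I / I_bg)``; intensities at or below zero are clamped to
    ``intensity_floor`` (one count by default) rather than raising, so
    saturated-dark pixels map to a large finite OD.
    """
    if background_intensity <= 0:
        raise ValueError("background_intensity must be positive")
    arr = np.asarray(intensity, dtype=float)
    od = -np.log10(np.maximum(arr, intensity_floor) / background_intensity)
    if np.isscalar(intensity) or arr.ndim == 0:
        return float(od)
    return od


def score_hemicrypt(
    image: np.ndarray,
    outline: HemicryptOutline,
    background_intensity: float,
    n_segments: int = 50,
    segments: SegmentSet | None = None,
) -> SegmentProfile:
    """Integrated background-corrected OD per segment and overall.

    Per-pixel OD is clipped at zero (pixels lighter than background carry no
    stain) and summed over each segment mask; the whole-hemicrypt value is
    the sum of the segment values.
    """
    image = np.asarray(image, dtype=float)
    if background_intensity is None or background_intensity <= 0:
        raise ValueError("a positive background_intensity is required")
    xs = [x for x, _ in outline.vertices]
    ys = [y for _, y in outline.vertices]
    if min(xs) < -0.5 or min(ys) < -0.5 or max(xs) > image.shape[1] - 0.5 or max(ys) > image.shape[0] - 0.5:
        raise ValueError("outline extends outside the image bounds")
    if segments is None:
        segments = partition_hemicrypt(outline, image.shape, n_segments)
    inside = segments.interior_mask()
    od = pixel_optical_density(image[inside], background_intensity)
    od = np.clip(od, 0.0, None)
    sums = np.bincount(segments.labels[inside], weights=od, minlength=segments.n_segments)
    return SegmentProfile(
        hemicrypt_id=outline.hemicrypt_id,
        marker_id=outline.marker_id,
        od_segments=sums,
    )


def estimate_background(image: np.ndarray, region: np.ndarray | Sequence[tuple[int, int]]) -> float:
    """Robust (median) background intensity over a blank-field pixel region.

    ``region`` is either a boolean mask of the image or a sequence of
    ``(row, col)`` pixel indices lying outside all hemicrypt outlines.
    """
    image = np.asarray(image, dtype=float)
    region_arr = np.asarray(region)
    if region_arr.dtype == bool:
        values = image[region_arr]
    else:
        if region_arr.size == 0:
            values = np.empty(0)
        else:
            rc = region_arr.reshape(-1, 2)
            values = image[rc[:, 0], rc[:, 1]]
    if values.size == 0:
        raise ValueError("background region is empty")
    med = float(np.median(values))
    if med <= 0:
        warnings.warn("background median is nonpositive; clamping to intensity floor")
        med = INTENSITY_FLOOR
    return med
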