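"""Landmark-placement geometry and femoral-head-coverage (FHC) scoring.

The annotation protocol traces the bony ilium--acetabulum contour of a
neonatal hip ultrasound with 13 ordered points. Point 4 sits where the
osseous contour first deviates from the straight ilium line, point 12 is
the deepest visible acetabular point, and point 0 lies on the ilium,
proximal to point 4, at half the point-4-to-point-12 distance. The
remaining points are spread with equal arc-length spacing: points 1-3
between 0 and 4, points 5-11 between 4 and 12.

Femoral head coverage is the percentage of the femoral-head circle lying
on the acetabular side of the straight line through points 0 and 4
("beneath" the ilium line). It is computed in closed form from
circular-segment area and categorized after Morin:
category 0 (> 58 %), category 1 (33-58 %), category 2 (< 33 %).

All coordinates are image coordinates: origin top-left, x to the right,
y downward, units pixels. Every function accepts any (x, y) array-like.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "FHCResult",
    "derive_point0",
    "resample_equal_spacing",
    "signed_line_distance",
    "fhc_percent",
    "morin_category",
]


class GeometryError(ValueError):
    """Degenerate or out-of-domain geometric input."""


@dataclass(frozen=True)
class FHCResult:
    """Femoral head coverage with its Morin category.

    percent is in [0, 100]; morin_category is 0 (> 58 %), 1 (33-58 %)
    or 2 (< 33 %).
    """

    percent: float
    morin_category: int


def _pt(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(2)
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"non-finite coordinates: {p!r}")
    return a


def derive_point0(p4, p12, ilium_dir) -> np.ndarray:
    """Place point 0 on the ilium at half the point-4-to-point-12 distance.

    Parameters
    ----------
    p4, p12
        Start of the acetabular slope and deepest acetabular point.
    ilium_dir
        Unit vector along the ilium, pointing proximally (away from the
        acetabulum).

    Returns
    -------
    ndarray of shape (2,): ``p4 + ilium_dir * |p4 - p12| / 2``.

    The distance is the Euclidean chord between points 4 and 12, which is
    reproducible from the two points alone and pins the ilium-to-acetabulum
    length ratio so that probe-positioning variation is minimized.
    """
    p4 = _pt(p4)
    p12 = _pt(p12)
    d = _pt(ilium_dir)
    chord = float(np.linalg.norm(p12 - p4))
    if chord == 0.0:
        raise GeometryError("points 4 and 12 coincide; cannot derive point 0")
    if abs(np.linalg.norm(d) - 1.0) > 1e-8:
        raise GeometryError("ilium_dir must be a unit vector")
    return p4 + d * (chord / 2.0)


def _cumulative_arclength(vertices: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise GeometryError("polyline has repeated consecutive vertices")
    return np.concatenate([[0.0], np.cumsum(seg)])


def _project_to_polyline(vertices: np.ndarray, cum: np.ndarray, p: np.ndarray) -> float:
    """Arc-length position of the point on the polyline nearest to ``p``."""
    a = vertices[:-1]
    b = vertices[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / seg_len2, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", foot - p, foot - p)
    i = int(np.argmin(d2))
    return float(cum[i] + t[i] * math.sqrt(seg_len2[i]))


def _point_at_arclength(vertices: np.ndarray, cum: np.ndarray, s) -> np.ndarray:
    x = np.interp(s, cum, vertices[:, 0])
    y = np.interp(s, cum, vertices[:, 1])
    return np.stack([x, y], axis=-1)


def resample_equal_spacing(contour, anchors, n_interior: int) -> np.ndarray:
    """Equally spaced points on a contour strictly between two anchors.

    The contour is a polyline (>= 2 vertices); both anchors are projected
    onto it, and ``n_interior`` points are returned at equal arc-length
    gaps between the two projections (gaps anchor->p1->...->anchor all
    equal). Used to place protocol points 1-3 (between points 0 and 4)
    and 5-11 (between points 4 and 12).
    """
    vertices = np.asarray(contour, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 2 or vertices.shape[1] != 2:
        raise GeometryError("contour must be an (m, 2) polyline with m >= 2")
    if n_interior < 0:
        raise GeometryError("n_interior must be >= 0")
    cum = _cumulative_arclength(vertices)
    s0 = _project_to_polyline(vertices, cum, _pt(anchors[0]))
    s1 = _project_to_polyline(vertices, cum, _pt(anchors[1]))
    if s0 == s1:
        raise GeometryError("anchors project to the same arc position")
    if n_interior == 0:
        return np.empty((0, 2), dtype=float)
    k = np.arange(1, n_interior + 1, dtype=float)
    targets = s0 + k * (s1 - s0) / (n_interior + 1)
    return _point_at_arclength(vertices, cum, targets)


def signed_line_distance(point, line_a, line_b, positive_ref) -> float:
    """Distance from ``point`` to the infinite line a-b, signed positive on
    the side containing ``positive_ref``."""
    a = _pt(line_a)
    b = _pt(line_b)
    p = _pt(point)
    ref = _pt(positive_ref)
    d = b - a
    length = float(np.linalg.norm(d))
    if length == 0.0:
        raise GeometryError("line endpoints coincide")
    n = np.array([-d[1], d[0]]) / length
    ref_side = float(np.dot(ref - a, n))
    if ref_side == 0.0:
        raise GeometryError("side-reference point lies on the line")
    sign = 1.0 if ref_side > 0 else -1.0
    return sign * float(np.dot(p - a, n))


def circular_segment_area(radius: float, h: float) -> float:
    """Area of the circular segment cut off at distance ``h`` (0 <= h <= r)
    from the center: ``r^2 acos(h/r) - h sqrt(r^2 - h^2)``."""
    if not 0.0 <= h <= radius:
        raise GeometryError("segment height outside [0, r]")
    return radius * radius * math.acos(h / radius) - h * math.sqrt(
        radius * radius - h * h
    )


def fhc_percent(p0, p4, head_center, head_rim, covered_side_ref) -> FHCResult:
    """Femoral head coverage by the acetabulum, in percent.

    A straight line is drawn from point 0 through point 4 (the ilium
    line); the femoral head is the circle centered at ``head_center``
    with radius ``|head_rim - head_center|``. The covered portion is the
    part of the circle on the acetabular side of the line, identified as
    the side containing ``covered_side_ref`` (protocol point 12, the
    deepest acetabular point). Coverage is the covered area as a
    percentage of the circle area, from the circular-segment formula.
    """
    center = _pt(head_center)
    rim = _pt(head_rim)
    r = float(np.linalg.norm(rim - center))
    if r <= 0.0:
        raise GeometryError("femoral head radius must be positive")
    s = signed_line_distance(center, p0, p4, covered_side_ref)
    h = abs(s)
    if h >= r:
        percent = 100.0 if s > 0 else 0.0
    else:
        seg = circular_segment_area(r, h)
        area = math.pi * r * r
        if s >= 0:  # center on the covered side: segment is the uncovered cap
            percent = 100.0 * (area - seg) / area
        else:
            percent = 100.0 * seg / area
    return FHCResult(percent=percent, morin_category=morin_category(percent))


def morin_category(percent: float) -> int:
    """Morin FHC category: 0 for > 58 %, 1 for 33-58 % (inclusive), 2 for < 33 %."""
    if not 0.0 <= percent <= 100.0:
        raise GeometryError(f"FHC percent out of range: {percent!r}")
    if percent > 58.0:
        return 0
    if percent >= 33.0:
        return 1
    return 2
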