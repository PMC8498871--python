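"""Polygon and label-mask geometry primitives.

Coordinates are 0-based pixel indices, origin top-left, x = column,
y = row; boundary vertices sit at pixel centers.  Polygons are simple
(non-self-intersecting) and implicitly closed.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

__all__ = [
    "shoelace_area",
    "polygon_moments",
    "equivalent_ellipse_axes",
    "min_area_rect",
    "trace_boundary",
]


def shoelace_area(vertices: np.ndarray, signed: bool = False) -> float:
    """Area of a simple closed polygon by the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    a = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(a) if signed else float(abs(a))


def polygon_moments(vertices: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and central second-moment matrix of a polygon interior.

    Green's-theorem closed forms over the (implicitly closed) vertex loop;
    exact for any simple polygon, orientation-independent.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    if a == 0:
        raise GeometryError("degenerate (zero-area) polygon")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    ixx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    iyy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    # central moments, normalized by area (covariance of the uniform lamina)
    sgn_a = a
    cov = np.array(
        [
            [ixx / sgn_a - cx * cx, ixy / sgn_a - cx * cy],
            [ixy / sgn_a - cx * cy, iyy / sgn_a - cy * cy],
        ]
    )
    return float(abs(a)), np.array([cx, cy]), cov


def equivalent_ellipse_axes(vertices: np.ndarray) -> tuple[float, float]:
    """(major, minor) full axis lengths of the moments-equivalent ellipse.

    The ellipse with the same area and second moments as the polygon
    interior; for a rectangle a×b this returns axes in the exact ratio
    a : b, and the construction is rotation-equivariant.
    """
    _, _, cov = polygon_moments(vertices)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 0:
        raise GeometryError("degenerate boundary: ellipse axes undefined")
    minor, major = 4.0 * np.sqrt(evals)  # uniform ellipse: var = (semi-axis)²/4
    return float(major), float(minor)


def min_area_rect(vertices: np.ndarray) -> tuple[float, float]:
    """(long, short) side lengths of the minimum-area enclosing rectangle.

    Rotating calipers over the convex hull: the optimal rectangle has a
    side collinear with a hull edge.
    """
    from scipy.spatial import ConvexHull, QhullError

    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    try:
        hull = v[ConvexHull(v).vertices]
    except QhullError as e:
        raise GeometryError(f"degenerate boundary for min-area rectangle: {e}") from e
    edges = np.roll(hull, -1, axis=0) - hull
    ang = np.arctan2(edges[:, 1], edges[:, 0])
    best = None
    for a in np.unique(np.mod(ang, np.pi / 2)):
        c, s = np.cos(a), np.sin(a)
        rot = hull @ np.array([[c, -s], [s, c]])
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        if best is None or w * h < best[0]:
            best = (w * h, max(w, h), min(w, h))
    return best[1], best[2]


_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
)


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered outer-boundary pixel centers of a connected binary region.

    Moore-neighbor tracing with Jacob's stopping criterion; returns an
    (n, 2) array of (x=col, y=row) pixel-center coordinates walking the
    outer contour once (first vertex not repeated).  The region must be
    8-connected and non-empty.
    """
    mask = np.asarray(mask, dtype=bool)
    pad = np.pad(mask, 1)
    rows, cols = np.nonzero(pad)
    if rows.size == 0:
        raise GeometryError("empty region")
    # start at the top-most, then left-most pixel; entered from the left
    start = (rows.min(), cols[rows == rows.min()].min())
    if rows.size == 1:
        return np.array([[start[1] - 1, start[0] - 1]], dtype=float)
    boundary = [start]
    # backtrack direction index: came from the west neighbor
    prev_dir = 6
    cur = start
    first_move = None
    while True:
        found = False
        for k in range(8):
            d = (prev_dir + 1 + k) % 8
            nb = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if pad[nb]:
                if (cur, nb) == first_move:
                    pts = np.array(boundary, dtype=float)
                    return np.column_stack([pts[:, 1] - 1, pts[:, 0] - 1])
                if first_move is None:
                    first_move = (cur, nb)
                boundary.append(nb)
                prev_dir = (d + 4) % 8
                cur = nb
                found = True
                break
        if not found:  # isolated pixel
            pts = np.array(boundary, dtype=float)
            return np.column_stack([pts[:, 1] - 1, pts[:, 0] - 1])
    # not reached
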