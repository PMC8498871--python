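"""Per-cell morphometrics from segmentation label masks.

Given an integer label image (one positive label per cell, background 0),
this module measures each cell's projected area, centroid and aspect
ratio, plus population statistics (density, area skewness) that
characterize monolayer crowding and jamming, the nucleus/cytoplasm
intensity ratio used for YAP localization, and cell-volume arithmetic.

Processing mirrors common segmentation post-processing: the one-pixel
outline of every mask is subtracted before the outer contour is traced,
so touching cells never share pixels.  The aspect ratio (length/width) is
the mean of two independent estimators — the moments-equivalent-ellipse
axis ratio and the minimum-area rotated rectangle side ratio — since
ellipse-style fits run high and enclosing rectangles run low for some
cell shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .polygon import (
    equivalent_ellipse_axes,
    min_area_rect,
    polygon_moments,
    shoelace_area,
    trace_boundary,
)

__all__ = [
    "CellRecord",
    "PopulationStats",
    "extract_cells",
    "polygon_area",
    "centroid",
    "aspect_ratio",
    "population_stats",
    "yap_ratio",
    "cell_volume",
    "isotropic_expansion",
    "area_skewness",
]


@dataclass
class CellRecord:
    """Morphometrics of one segmented cell in one frame."""

    cell_id: int
    frame: int
    centroid_xy: tuple[float, float]  # µm, x = column direction
    area_um2: float
    aspect_ratio: float
    boundary: np.ndarray  # (n, 2) pixel-center (x, y) outer contour
    touches_border: bool = False
    ellipse_ok: bool = True


@dataclass
class PopulationStats:
    n_cells: int
    density_per_mm2: float
    area_skewness: float | None


def polygon_area(boundary: np.ndarray, pixel_um: float = 1.0) -> float:
    """Shoelace area of the closed contour polygon, in µm²."""
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    return shoelace_area(boundary) * pixel_um**2


def centroid(pixels_or_boundary: np.ndarray, pixel_um: float = 1.0) -> tuple[float, float]:
    """Center of mass (x, y) in µm.

    Accepts either an (n, 2) array of (x, y) pixel coordinates belonging
    to the cell (first-order moments over the pixel set) or a boolean
    mask.
    """
    arr = np.asarray(pixels_or_boundary)
    if arr.dtype == bool:
        ys, xs = np.nonzero(arr)
        if xs.size == 0:
            raise ValueError("empty pixel set")
        return (float(xs.mean() * pixel_um), float(ys.mean() * pixel_um))
    if arr.size == 0:
        raise ValueError("empty pixel set")
    return (float(arr[:, 0].mean() * pixel_um), float(arr[:, 1].mean() * pixel_um))


def aspect_ratio(
    boundary: np.ndarray,
    method: str = "mean",
    return_branches: bool = False,
):
    """Cell aspect ratio (length/width ≥ 1) from the boundary polygon.

    ``method='mean'`` (default) averages the moments-equivalent-ellipse
    axis ratio and the minimum-area rotated-rectangle side ratio.  If the
    ellipse branch is infeasible (fewer than 5 vertices or a degenerate
    moment matrix) the rectangle branch alone is returned and flagged.
    ``method='ellipse'``/``'rect'`` select a single branch; ``'conic'``
    uses a least-squares algebraic conic fit instead of the moment
    ellipse (biased high for rectangle-like shapes).

    Returns the ratio, or ``(ratio, ellipse_ratio, rect_ratio,
    ellipse_ok)`` when ``return_branches`` is set.
    """
    b = np.asarray(boundary, dtype=float)
    rect_ratio = None
    long_, short = min_area_rect(b)
    if short <= 0:
        raise GeometryError("degenerate (collinear) boundary")
    rect_ratio = long_ / short
    ell_ratio = None
    ellipse_ok = True
    if method in ("mean", "ellipse"):
        if b.shape[0] < 5:
            ellipse_ok = False
        else:
            try:
                major, minor = equivalent_ellipse_axes(b)
                ell_ratio = major / minor
            except GeometryError:
                ellipse_ok = False
    elif method == "conic":
        from skimage.measure import EllipseModel

        m = EllipseModel()
        if b.shape[0] < 5 or not m.estimate(b):
            ellipse_ok = False
        else:
            _, _, a, bb, _ = m.params
            hi, lo = max(a, bb), min(a, bb)
            if lo <= 0:
                ellipse_ok = False
            else:
                ell_ratio = hi / lo
    if method == "rect":
        ratio = rect_ratio
    elif method in ("ellipse", "conic"):
        if not ellipse_ok:
            raise GeometryError("ellipse fit infeasible for this boundary")
        ratio = ell_ratio
    else:  # mean of both branches, rectangle-only fallback
        ratio = (
            0.5 * (ell_ratio + rect_ratio) if ellipse_ok and ell_ratio else rect_ratio
        )
    if return_branches:
        return ratio, ell_ratio, rect_ratio, ellipse_ok
    return ratio


def extract_cells(
    labels: np.ndarray,
    pixel_um: float = 1.0,
    frame: int = 0,
    min_boundary_px: int = 4,
) -> list[CellRecord]:
    """One :class:`CellRecord` per label in a segmentation mask.

    For each label the one-pixel outline ring is subtracted (erosion with
    the 4-connected structuring element) before the outer contour of the
    largest remaining component is traced, so adjacent cells never
    overlap.  Labels whose interior boundary has fewer than
    ``min_boundary_px`` pixels are skipped with a warning; labels touching
    the image border are kept but flagged (truncated geometry).  An empty
    label image yields an empty list.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be a 2-D integer array")
    if np.any(labels < 0):
        raise ValueError("labels must be non-negative")
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    records: list[CellRecord] = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        interior = ndimage.binary_erosion(mask)  # subtract the outline ring
        if interior.sum() < min_boundary_px:
            warnings.warn(
                f"label {lab}: fewer than {min_boundary_px} pixels after "
                "outline subtraction; skipped",
                stacklevel=2,
            )
            continue
        # outer contour only: trace the largest connected component
        comp, n_comp = ndimage.label(interior)
        if n_comp > 1:
            sizes = ndimage.sum_labels(interior, comp, index=range(1, n_comp + 1))
            interior = comp == (1 + int(np.argmax(sizes)))
        boundary = trace_boundary(interior)
        if boundary.shape[0] < min_boundary_px:
            warnings.warn(f"label {lab}: degenerate contour; skipped", stacklevel=2)
            continue
        boundary = boundary + np.array([sl[1].start, sl[0].start], dtype=float)
        ys, xs = np.nonzero(interior)
        pix = np.column_stack([xs + sl[1].start, ys + sl[0].start]).astype(float)
        try:
            ar, _, _, ell_ok = aspect_ratio(boundary, return_branches=True)
        except GeometryError:
            warnings.warn(f"label {lab}: degenerate geometry; skipped", stacklevel=2)
            continue
        touches = (
            sl[0].start == 0
            or sl[1].start == 0
            or sl[0].stop == labels.shape[0]
            or sl[1].stop == labels.shape[1]
        )
        records.append(
            CellRecord(
                cell_id=lab,
                frame=frame,
                centroid_xy=centroid(pix, pixel_um),
                area_um2=polygon_area(boundary, pixel_um),
                aspect_ratio=float(ar),
                boundary=boundary,
                touches_border=touches,
                ellipse_ok=ell_ok,
            )
        )
    return records


def area_skewness(areas: np.ndarray) -> float:
    """Fisher–Pearson moment coefficient g1 = m3 / m2^(3/2) (biased form).

    NaN for a constant sample (zero variance).
    """
    from scipy.stats import skew

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(skew(np.asarray(areas, dtype=float), bias=True))


def population_stats(
    records_or_areas, monolayer_area_mm2: float
) -> PopulationStats:
    """Cell density (per mm² of occupied monolayer) and area skewness."""
    if monolayer_area_mm2 <= 0:
        raise ValueError("monolayer area must be positive")
    if len(records_or_areas) and isinstance(records_or_areas[0], CellRecord):
        areas = np.array([r.area_um2 for r in records_or_areas])
    else:
        areas = np.asarray(records_or_areas, dtype=float)
    n = areas.size
    skew_val = area_skewness(areas) if n >= 3 else None
    return PopulationStats(
        n_cells=int(n),
        density_per_mm2=n / monolayer_area_mm2,
        area_skewness=skew_val,
    )


def yap_ratio(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    exclude_gt1: bool = True,
) -> tuple[dict[int, float], int]:
    """Nucleus-to-whole-cell mean-intensity ratio per cell.

    ``cell_mask``/``nucleus_mask`` may be boolean (one cell) or integer
    label images with matching ids.  The ratio is mean(I | nucleus) /
    mean(I | cell); with ``exclude_gt1`` (default, mirroring the
    convention that ratios above 1 indicate mis-segmentation) such cells
    are dropped and counted.  Returns ``(ratios by cell id, n_excluded)``.
    """
    img = np.asarray(image, dtype=float)
    nuc = np.asarray(nucleus_mask)
    cell = np.asarray(cell_mask)
    if img.shape != nuc.shape or img.shape != cell.shape:
        raise ValueError("image and masks must share a shape")
    if nuc.dtype == bool:
        nuc = nuc.astype(np.uint8)
        cell = cell.astype(np.uint8)
    ids = np.unique(cell)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("empty cell mask")
    ratios: dict[int, float] = {}
    excluded = 0
    for i in ids:
        csel = cell == i
        nsel = nuc == i
        if not nsel.any():
            raise ValueError(f"cell {int(i)}: empty nucleus mask")
        if np.any(nsel & ~csel):
            raise ValueError(f"cell {int(i)}: nucleus not contained in cell")
        r = float(img[nsel].mean() / img[csel].mean())
        if exclude_gt1 and r > 1.0:
            excluded += 1
            continue
        ratios[int(i)] = r
    return ratios, excluded


def cell_volume(base_area_um2: float, height_um: float) -> float:
    """Cell volume V = A·h in µm³ (flat-slab approximation)."""
    if base_area_um2 <= 0 or height_um <= 0:
        raise ValueError("area and height must be positive")
    return base_area_um2 * height_um


def isotropic_expansion(volume_ratio: float) -> tuple[float, float]:
    """Radius and height scale factors for isotropic cylinder growth.

    Proportionally even changes in radius and height: both scale by the
    cube root of the volume ratio.
    """
    if volume_ratio <= 0:
        raise ValueError("volume ratio must be positive")
    s = volume_ratio ** (1.0 / 3.0)
    return (s, s)
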