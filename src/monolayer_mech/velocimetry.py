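"""Collective-migration statistics from gridded velocity fields.

The statistics implemented here quantify how coherently an epithelial
monolayer moves while it expands into free space:

* the order parameter — the mean cosine of the angle between each local
  velocity vector and the migration direction (the outward normal of the
  advancing edge); 1 means fully edge-directed motion, 0 no net
  directionality;
* edge-distance profiles of speed and order;
* the 2-D spatial autocorrelation of the velocity fluctuations and its
  radial average;
* the correlation length, defined from the weighted integral of the radial
  autocorrelation up to its first zero crossing;
* a minimal window-based particle image velocimetry (PIV) stage for image
  pairs.

Velocities are in µm/h on a regular grid with pitch ``spacing_um`` (the
reference acquisition uses 32 px interrogation windows with 50% overlap,
i.e. a 12.08 µm mesh).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .errors import DegenerateFieldError, GeometryError

__all__ = [
    "VectorField",
    "CorrelationCurve",
    "EdgeProfile",
    "order_parameter",
    "edge_profile",
    "spatial_autocorrelation",
    "radial_average",
    "correlation_length",
    "piv_displacement",
    "largest_interior_rectangle",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class VectorField:
    """A 2-D velocity field on a regular grid.

    Attributes
    ----------
    u, v : ndarray, shape (ny, nx)
        Velocity components in µm/h (x = column direction, y = row direction).
    spacing_um : float
        Grid pitch in µm.
    mask : ndarray of bool
        True where the monolayer occupies the grid node.
    t_min : float
        Timestamp of the frame in minutes.
    migration_axis : tuple of float
        Unit vector of the edge normal, i.e. the mean migration direction.
    """

    u: np.ndarray
    v: np.ndarray
    spacing_um: float
    mask: np.ndarray | None = None
    t_min: float = 0.0
    migration_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2-D arrays of identical shape")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.mask is None:
            self.mask = np.ones(self.u.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.u.shape:
                raise ValueError("mask shape must match u/v")
        ax = np.asarray(self.migration_axis, dtype=float)
        n = np.hypot(ax[0], ax[1])
        if n == 0:
            raise ValueError("migration_axis must be nonzero")
        self.migration_axis = (ax[0] / n, ax[1] / n)
        if not np.all(np.isfinite(self.u[self.mask])) or not np.all(
            np.isfinite(self.v[self.mask])
        ):
            raise ValueError("u and v must be finite inside the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class CorrelationCurve:
    """Radially averaged velocity autocorrelation, normalized to AC(0) = 1."""

    r_um: np.ndarray
    ac: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.r_um = np.asarray(self.r_um, dtype=float)
        self.ac = np.asarray(self.ac, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs)
        if np.any(np.diff(self.r_um) <= 0):
            raise ValueError("r_um must be strictly increasing")


@dataclass
class EdgeProfile:
    """Speed and order versus distance from the advancing monolayer edge.

    The first ``drop_first`` bins are retained but flagged: window-based
    velocimetry is biased right at the free edge, so those points are
    conventionally not reported.
    """

    distance_um: np.ndarray
    mean_speed_um_per_h: np.ndarray
    mean_order: np.ndarray
    n_samples: np.ndarray
    drop_first: int = 2

    def trusted(self) -> "EdgeProfile":
        """Return the profile with the edge-artifact bins removed."""
        k = self.drop_first
        return EdgeProfile(
            self.distance_um[k:],
            self.mean_speed_um_per_h[k:],
            self.mean_order[k:],
            self.n_samples[k:],
            drop_first=0,
        )


# ---------------------------------------------------------------------------
# order parameter


def order_parameter(field: VectorField) -> float:
    """Mean cos α over masked vectors, α the angle to the migration axis.

    Zero-magnitude vectors carry no direction and are excluded from the
    mean.  Raises :class:`DegenerateFieldError` if every masked vector is
    zero.
    """
    ax, ay = field.migration_axis
    u = field.u[field.mask]
    v = field.v[field.mask]
    mag = np.hypot(u, v)
    nz = mag > 0
    if not np.any(nz):
        raise DegenerateFieldError("order parameter undefined: all vectors zero")
    cos_a = (u[nz] * ax + v[nz] * ay) / mag[nz]
    return float(np.mean(cos_a))


# ---------------------------------------------------------------------------
# edge-distance profiles


def _edge_distance(field: VectorField, method: str) -> np.ndarray:
    """Distance (µm) of every masked node from the free edge; NaN outside."""
    mask = field.mask
    dist = np.full(mask.shape, np.nan)
    if method == "edt":
        from scipy.ndimage import distance_transform_edt

        # distance to the nearest unmasked node, measured inside the mask
        if mask.all():
            raise GeometryError("edt edge distance needs free space in the mask")
        dist[mask] = (distance_transform_edt(mask) * field.spacing_um)[mask]
        return dist
    ax, ay = field.migration_axis
    if abs(ax) == 1.0 and ay == 0.0:
        # edge along columns: per row, furthest masked column in axis direction
        for i in range(mask.shape[0]):
            cols = np.flatnonzero(mask[i])
            if cols.size == 0:
                continue
            edge = cols.max() if ax > 0 else cols.min()
            dist[i, cols] = np.abs(edge - cols) * field.spacing_um
    elif abs(ay) == 1.0 and ax == 0.0:
        for j in range(mask.shape[1]):
            rows = np.flatnonzero(mask[:, j])
            if rows.size == 0:
                continue
            edge = rows.max() if ay > 0 else rows.min()
            dist[rows, j] = np.abs(edge - rows) * field.spacing_um
    else:
        raise GeometryError(
            "axis edge-distance requires an axis-aligned migration_axis; "
            "use method='edt' for oblique axes"
        )
    return dist


def edge_profile(
    fields: Sequence[VectorField],
    bin_um: float = 12.08,
    drop_first: int = 2,
    method: Literal["axis", "edt"] = "axis",
) -> EdgeProfile:
    """Time-averaged speed and order binned by distance from the free edge.

    ``method='axis'`` measures distance along the migration axis from the
    furthest occupied node of each grid row/column (the edge is assumed to
    be roughly aligned perpendicular to the axis); ``'edt'`` uses the
    Euclidean distance transform of the monolayer mask.
    """
    if len(fields) == 0:
        raise ValueError("need at least one frame")
    if bin_um <= 0:
        raise ValueError("bin_um must be positive")
    sums_speed: dict[int, float] = {}
    sums_order: dict[int, float] = {}
    counts: dict[int, int] = {}
    for f in fields:
        if not np.any(f.mask):
            raise DegenerateFieldError("empty monolayer mask")
        dist = _edge_distance(f, method)
        ax, ay = f.migration_axis
        speed = f.speed()
        with np.errstate(invalid="ignore", divide="ignore"):
            order = np.where(speed > 0, (f.u * ax + f.v * ay) / speed, np.nan)
        sel = f.mask & np.isfinite(dist)
        # epsilon guards against distances exactly on a bin edge landing low
        bins = np.floor(dist[sel] / bin_um + 1e-9).astype(int)
        for b, s, o in zip(bins, speed[sel], order[sel]):
            sums_speed[b] = sums_speed.get(b, 0.0) + s
            counts[b] = counts.get(b, 0) + 1
            if np.isfinite(o):
                sums_order[b] = sums_order.get(b, 0.0) + o
    ks = sorted(counts)
    centers = np.array([(k + 0.5) * bin_um for k in ks])
    n = np.array([counts[k] for k in ks])
    speed_mean = np.array([sums_speed[k] / counts[k] for k in ks])
    order_mean = np.array([sums_order.get(k, np.nan) / counts[k] for k in ks])
    return EdgeProfile(centers, speed_mean, order_mean, n, drop_first=drop_first)


# ---------------------------------------------------------------------------
# spatial autocorrelation


def largest_interior_rectangle(mask: np.ndarray) -> tuple[slice, slice]:
    """Row/column slices of the largest axis-aligned all-True rectangle.

    Used to crop leader-cell fingers from the monolayer mask so that the
    autocorrelation operates on a fully occupied rectangular region.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateFieldError("mask is empty")
    ny, nx = mask.shape
    heights = np.zeros(nx, dtype=int)
    best = (0, (slice(0, 0), slice(0, 0)))
    for i in range(ny):
        heights = np.where(mask[i], heights + 1, 0)
        # largest rectangle in histogram (stack method)
        stack: list[int] = []
        j = 0
        while j <= nx:
            h = heights[j] if j < nx else 0
            if not stack or heights[stack[-1]] <= h:
                stack.append(j)
                j += 1
            else:
                top = stack.pop()
                left = stack[-1] + 1 if stack else 0
                area = heights[top] * (j - left)
                if area > best[0]:
                    best = (
                        area,
                        (slice(i - heights[top] + 1, i + 1), slice(left, j)),
                    )
    return best[1]


def spatial_autocorrelation(
    field: VectorField,
    component: Literal["perpendicular", "both"] = "perpendicular",
    crop: bool = True,
) -> np.ndarray:
    """2-D autocorrelation of the mean-subtracted velocity fluctuations.

    By default only the component perpendicular to the migration axis is
    used (for migration along +x this is the y-component), which isolates
    the collective fluctuation signal from the mean drift.  The field is
    cropped to the largest mask-inscribed rectangle first.  The output is
    a ``(2H-1, 2W-1)`` array normalized so the zero-lag value is 1, with
    per-lag pair-count (unbiased) normalization; it is exactly symmetric
    under lag negation.
    """
    sl = largest_interior_rectangle(field.mask) if crop else np.s_[:, :]
    u = field.u[sl]
    v = field.v[sl]
    if u.size < 4:
        raise DegenerateFieldError("masked rectangular region too small")
    ax, ay = field.migration_axis
    if component == "perpendicular":
        comps = [-u * ay + v * ax]
    elif component == "both":
        comps = [u, v]
    else:
        raise ValueError("component must be 'perpendicular' or 'both'")
    ones = np.ones_like(u)
    counts = fftconvolve(ones, ones, mode="full")
    counts = np.maximum(np.rint(counts), 1.0)
    num = np.zeros_like(counts)
    var = 0.0
    for w in comps:
        w = w - w.mean()
        var += float(np.mean(w * w))
        num += fftconvolve(w, w[::-1, ::-1], mode="full")
    if var <= 0:
        raise DegenerateFieldError("zero variance after mean subtraction")
    ac = num / counts
    center = (u.shape[0] - 1, u.shape[1] - 1)
    ac = ac / ac[center]
    # enforce exact lag-negation symmetry (FFT rounding can break it at 1e-16)
    ac = 0.5 * (ac + ac[::-1, ::-1])
    return ac


def radial_average(
    ac2d: np.ndarray,
    spacing_um: float,
    r_max_um: float | None = None,
) -> CorrelationCurve:
    """Annular average of a centered 2-D correlation array.

    Bins are one grid spacing wide, centered at r = 0, s, 2s, ….  By
    default radii are reported out to half of the smaller half-extent,
    beyond which too few lags contribute.
    """
    ac2d = np.asarray(ac2d, dtype=float)
    ny, nx = ac2d.shape
    ci, cj = (ny - 1) // 2, (nx - 1) // 2
    ii, jj = np.meshgrid(
        np.arange(ny) - ci, np.arange(nx) - cj, indexing="ij"
    )
    r = np.hypot(ii, jj) * spacing_um
    if r_max_um is None:
        r_max_um = min(ci, cj) / 2 * spacing_um
    k = np.rint(r / spacing_um).astype(int)
    kmax = int(np.floor(r_max_um / spacing_um))
    sel = k <= kmax
    sums = np.bincount(k[sel], weights=ac2d[sel], minlength=kmax + 1)
    counts = np.bincount(k[sel], minlength=kmax + 1)
    good = counts > 0
    centers = np.arange(kmax + 1)[good] * spacing_um
    return CorrelationCurve(centers, sums[good] / counts[good], counts[good])


def correlation_length(
    curve: CorrelationCurve, normalize: bool = True
) -> float:
    """Correlation length from the weighted integral of AC(r).

    The integration limit R* is the first linearly interpolated zero
    crossing of AC (anti-correlated tails are excluded); without a
    crossing the full sampled range is used.  With ``normalize=True``
    (default) the first-moment normalization

        L = ∫₀^R* r·AC(r) dr / ∫₀^R* AC(r) dr

    is returned, which has units of µm and equals ξ for AC = exp(−r/ξ);
    ``normalize=False`` returns the raw weighted integral ∫ r·AC dr in µm².
    Trapezoidal quadrature throughout.
    """
    r = curve.r_um
    ac = curve.ac
    if r.size < 3:
        raise ValueError("need at least 3 points on the correlation curve")
    if not np.isclose(ac[0], 1.0, atol=1e-6):
        raise ValueError("curve must be normalized with AC(0) = 1")
    # first sign change + -> <= 0, linear interpolation for the crossing
    r_int, ac_int = r, ac
    for i in range(len(ac) - 1):
        if ac[i] > 0 and ac[i + 1] <= 0:
            rstar = r[i] + (r[i + 1] - r[i]) * ac[i] / (ac[i] - ac[i + 1])
            r_int = np.concatenate([r[: i + 1], [rstar]])
            ac_int = np.concatenate([ac[: i + 1], [0.0]])
            break
    num = float(np.trapezoid(r_int * ac_int, r_int))
    if not normalize:
        return num
    den = float(np.trapezoid(ac_int, r_int))
    return num / den


# ---------------------------------------------------------------------------
# minimal PIV


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2.0 * c0 + cp
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -1.0, 1.0))


def piv_displacement(
    img_a: np.ndarray,
    img_b: np.ndarray,
    window_px: int = 32,
    overlap: float = 0.5,
    snr_min: float = 1.1,
    peak_min: float = 0.3,
    global_std: float = 4.0,
    pixel_um: float = 1.0,
    dt_min: float | None = None,
) -> VectorField:
    """Window-based displacement field from an image pair.

    Each interrogation window yields the displacement of the normalized
    cross-correlation peak with sub-pixel parabolic refinement.  Vectors
    are invalidated by three filters mirroring standard PIV practice: peak
    height below ``peak_min`` (featureless windows), first-to-second peak
    ratio below ``snr_min``, and components deviating more than
    ``global_std`` standard deviations from the field mean.

    The returned :class:`VectorField` holds displacements in pixels when
    ``dt_min`` is None, otherwise velocities in µm/h using ``pixel_um``;
    its mask is False on filtered-out windows.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if a.shape[0] < window_px or a.shape[1] < window_px:
        raise ValueError("images smaller than one interrogation window")
    step = max(1, int(round(window_px * (1.0 - overlap))))
    rows = range(0, a.shape[0] - window_px + 1, step)
    cols = range(0, a.shape[1] - window_px + 1, step)
    U = np.zeros((len(rows), len(cols)))
    V = np.zeros_like(U)
    valid = np.zeros(U.shape, dtype=bool)
    c_full = window_px - 1  # zero-lag index in the full correlation
    half = window_px // 2  # physical search limit: ± half window
    ones = np.ones((window_px, window_px))
    counts = fftconvolve(ones, ones, mode="full")
    counts = np.maximum(np.rint(counts), 1.0)
    lo, hi = c_full - half, c_full + half + 1
    for ri, r0 in enumerate(rows):
        for cj, col0 in enumerate(cols):
            wa = a[r0 : r0 + window_px, col0 : col0 + window_px]
            wb = b[r0 : r0 + window_px, col0 : col0 + window_px]
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            sa = wa.std()
            sb = wb.std()
            if sa == 0 or sb == 0:
                continue
            # per-lag overlap normalization removes the window-margin bias
            corr = fftconvolve(wb, wa[::-1, ::-1], mode="full") / counts / (sa * sb)
            corr = corr[lo:hi, lo:hi]
            c0 = half
            pk = np.unravel_index(np.argmax(corr), corr.shape)
            peak = corr[pk]
            if peak < peak_min:
                continue
            # second peak outside a 3-px exclusion zone around the first
            excl = corr.copy()
            i0, j0 = pk
            excl[max(0, i0 - 3) : i0 + 4, max(0, j0 - 3) : j0 + 4] = -np.inf
            second = float(np.max(excl))
            if second > 0 and peak / second < snr_min:
                continue
            dy = float(i0 - c0)
            dx = float(j0 - c0)
            if 0 < i0 < corr.shape[0] - 1:
                dy += _parabolic_offset(
                    corr[i0 - 1, j0], corr[i0, j0], corr[i0 + 1, j0]
                )
            if 0 < j0 < corr.shape[1] - 1:
                dx += _parabolic_offset(
                    corr[i0, j0 - 1], corr[i0, j0], corr[i0, j0 + 1]
                )
            U[ri, cj] = dx
            V[ri, cj] = dy
            valid[ri, cj] = True
    # global filter: component-wise outlier cut
    if valid.sum() >= 3 and global_std > 0:
        for comp in (U, V):
            vals = comp[valid]
            sd = vals.std()
            if sd > 0:
                valid &= np.abs(comp - vals.mean()) <= global_std * sd
    if dt_min is not None:
        scale = pixel_um / (dt_min / 60.0)  # px/frame -> µm/h
        U = U * scale
        V = V * scale
    U[~valid] = 0.0
    V[~valid] = 0.0
    return VectorField(
        U, V, spacing_um=step * pixel_um, mask=valid, migration_axis=(1.0, 0.0)
    )
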