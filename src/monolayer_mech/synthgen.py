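"""Seeded synthetic inputs with known ground truth for every analysis stage.

Raw microscopy/AFM data for monolayer-migration studies are rarely
deposited, so every downstream operation in this package is validated
against synthetic stand-ins whose generating parameters are known exactly:

* spatially correlated velocity fields (Gaussian random fields with an
  isotropic exponential — optionally Gaussian — covariance and uniform
  drift), synthesized spectrally via circulant embedding;
* speckle image pairs advected by a velocity field, for the PIV stage;
* space-filling Voronoi tessellations with a controllable right-skewed
  cell-area distribution (log-normal density modulation);
* Brownian / ballistic / persistent (Ornstein–Uhlenbeck) cell tracks;
* forward-model AFM force-relaxation curves with multiplicative noise;
* two-intensity nucleus/cytoplasm images for YAP-ratio quantification.

Determinism contract: identical ``(seed, kind, params)`` produce
bit-identical output; every generator call owns its private
``numpy.random.Generator`` stream.  The Gaussianity of the velocity
fluctuations is an assumption of the stand-in, not a claim about real
monolayers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Any, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial import cKDTree

from .errors import UnresolvableCorrelationError
from .mechanics import MechParams, RelaxationCurve, ShellGeometry, forward_relaxation
from .velocimetry import VectorField

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "gen_velocity_field",
    "gen_speckle_pair",
    "gen_tessellation",
    "gen_tracks",
    "gen_force_curve",
    "gen_yap_image",
    "generate",
]

GENERATOR_KINDS = (
    "field",
    "speckle_pair",
    "tessellation",
    "tracks",
    "force_curve",
    "yap_image",
)


@dataclass(frozen=True)
class SynthSpec:
    """A fully specified, seeded generator invocation."""

    seed: int
    kind: str
    params: dict[str, Any] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an explicit integer")


@dataclass
class GroundTruth:
    """Truth record shipped with every synthetic dataset."""

    kind: str
    truth: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.truth[key]


# ---------------------------------------------------------------------------
# correlated velocity fields


def _grf_exponential(
    shape: tuple[int, int],
    spacing: float,
    xi: float,
    sigma: float,
    rng: np.random.Generator,
    kernel: str,
    pad: int,
) -> np.ndarray:
    """Stationary zero-mean GRF with isotropic covariance via circulant embedding.

    The target covariance (σ² exp(−r/ξ) or σ² exp(−r²/2ξ²)) is evaluated
    on a torus padded ``pad``× beyond the requested grid; its FFT gives the
    embedding eigenvalues, whose (clipped) square root filters white noise.
    """
    ny, nx = shape
    My, Mx = pad * ny, pad * nx
    dy = np.minimum(np.arange(My), My - np.arange(My)) * spacing
    dx = np.minimum(np.arange(Mx), Mx - np.arange(Mx)) * spacing
    r = np.hypot(dy[:, None], dx[None, :])
    if kernel == "exponential":
        cov = sigma * sigma * np.exp(-r / xi)
    elif kernel == "gaussian":
        cov = sigma * sigma * np.exp(-0.5 * (r / xi) ** 2)
    else:
        raise ValueError("kernel must be 'exponential' or 'gaussian'")
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    white = rng.standard_normal((My, Mx))
    field = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(white)).real
    return field[:ny, :nx]


def gen_velocity_field(
    shape: tuple[int, int] = (128, 128),
    spacing_um: float = 12.08,
    xi_um: float = 30.0,
    sigma: float = 5.0,
    drift: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    kernel: str = "exponential",
    migration_axis: tuple[float, float] = (1.0, 0.0),
    pad: int = 2,
) -> tuple[VectorField, GroundTruth]:
    """Correlated velocity field: GRF fluctuations (µm/h) plus uniform drift.

    Each component is an independent stationary Gaussian random field with
    isotropic covariance σ² exp(−r/ξ) (default kernel).  ``sigma=0`` gives
    the pure drift field exactly.
    """
    ny, nx = shape
    if ny < 32 or nx < 32:
        raise ValueError("shape must be at least 32×32")
    if xi_um < spacing_um:
        raise UnresolvableCorrelationError(
            f"correlation length {xi_um} µm below grid spacing {spacing_um} µm"
        )
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    if sigma == 0:
        u = np.full(shape, float(drift[0]))
        v = np.full(shape, float(drift[1]))
    else:
        u = _grf_exponential(shape, spacing_um, xi_um, sigma, rng, kernel, pad) + drift[0]
        v = _grf_exponential(shape, spacing_um, xi_um, sigma, rng, kernel, pad) + drift[1]
    field = VectorField(
        u, v, spacing_um=spacing_um, migration_axis=migration_axis
    )
    truth = GroundTruth(
        "field",
        {
            "correlation_length_um": xi_um,
            "sigma_um_per_h": sigma,
            "drift_um_per_h": tuple(float(d) for d in drift),
            "kernel": kernel,
            "spacing_um": spacing_um,
        },
    )
    return field, truth


# ---------------------------------------------------------------------------
# speckle pairs for PIV


def gen_speckle_pair(
    field: VectorField,
    dt_min: float = 7.5,
    texture_sigma_px: float = 1.0,
    pixel_um: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
    shape_px: tuple[int, int] | None = None,
    window_px: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """A speckle image and its advection by ``field`` over ``dt_min``.

    The first image is band-limited noise (Gaussian-smoothed white noise);
    the second samples it at positions displaced by −field·dt (bilinear,
    periodic boundary), so PIV on the pair should recover field·dt.  A
    warning is raised if any displacement exceeds half the interrogation
    window, beyond which correlation PIV cannot recover the shift.
    """
    rng = np.random.default_rng(seed)
    if shape_px is None:
        shape_px = (
            field.shape[0] * max(1, int(round(field.spacing_um / pixel_um))),
            field.shape[1] * max(1, int(round(field.spacing_um / pixel_um))),
        )
    H, W = shape_px
    img_a = gaussian_filter(rng.standard_normal((H, W)), texture_sigma_px, mode="wrap")
    img_a = (img_a - img_a.min()) / (img_a.max() - img_a.min())
    # displacement in px at every image pixel (bilinear upsample of the grid)
    scale = (dt_min / 60.0) / pixel_um  # µm/h -> px per dt
    node_px = field.spacing_um / pixel_um
    yy, xx = np.mgrid[0:H, 0:W]
    gy = yy / node_px
    gx = xx / node_px
    dx = map_coordinates(field.u * scale, [gy, gx], order=1, mode="grid-wrap")
    dy = map_coordinates(field.v * scale, [gy, gx], order=1, mode="grid-wrap")
    dmax = float(np.max(np.hypot(dx, dy)))
    if dmax > window_px / 2:
        warnings.warn(
            f"max displacement {dmax:.1f} px exceeds half the PIV window "
            f"({window_px // 2} px); PIV will not recover it",
            stacklevel=2,
        )
    img_b = map_coordinates(img_a, [yy - dy, xx - dx], order=1, mode="grid-wrap")
    if noise > 0:
        img_a = img_a + noise * rng.standard_normal(img_a.shape)
        img_b = img_b + noise * rng.standard_normal(img_b.shape)
    return img_a, img_b


# ---------------------------------------------------------------------------
# tessellations

# frozen calibration of the log-density σ against realized area skewness
# (plain Voronoi of points sampled from a log-normal density field with a
# one-cell-diameter smoothing length; 16-seed means at n = 500.  The σ=0
# baseline is the intrinsic Poisson-Voronoi area skewness ≈ 1.)
_SKEW_TABLE = np.array(
    [
        [0.99, 0.0],
        [1.24, 0.25],
        [1.75, 0.55],
        [2.10, 1.0],
        [2.55, 1.25],
    ]
)


def _sigma_log_for_skew(skew_target: float) -> float:
    if skew_target <= _SKEW_TABLE[0, 0]:
        return 0.0
    return float(np.interp(skew_target, _SKEW_TABLE[:, 0], _SKEW_TABLE[:, 1]))


def gen_tessellation(
    n_cells: int = 500,
    mean_area_um2: float = 250.0,
    skew_target: float = 2.0,
    frame_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    pixel_um: float = 1.0,
    points: np.ndarray | None = None,
    draw_boundaries: bool = True,
) -> tuple[np.ndarray, GroundTruth]:
    """Space-filling Voronoi label mask with a right-skewed area distribution.

    Generator points are sampled from a log-normal-modulated density field;
    denser regions yield smaller cells, so the log-field σ (calibrated once
    against realized skewness) controls the sample skewness of areas.
    ``points`` overrides the random seeding with explicit (row, col)
    positions (e.g. a regular lattice gives equal areas).  Labels are
    1..n; with ``draw_boundaries`` one-pixel ridges between cells are 0.
    The truth record carries the exact per-cell pixel areas of the emitted
    mask.  Targets below the intrinsic Poisson-Voronoi skewness (≈1) are
    not reachable by random seeding.
    """
    H, W = frame_shape
    if points is None:
        if n_cells < 1:
            raise ValueError("n_cells must be positive")
        if n_cells * mean_area_um2 > H * W * pixel_um**2:
            raise ValueError(
                "infeasible packing: n_cells × mean_area exceeds the frame area"
            )
        rng = np.random.default_rng(seed)
        sig = _sigma_log_for_skew(skew_target)
        smooth = np.sqrt(H * W / n_cells)  # ~ one mean cell diameter
        g = gaussian_filter(rng.standard_normal((H, W)), smooth, mode="wrap")
        sd = g.std()
        lam = np.exp(sig * g / sd) if sd > 0 else np.ones((H, W))
        p = (lam / lam.sum()).ravel()
        idx = rng.choice(H * W, size=n_cells, replace=False, p=p)
        pts = np.column_stack(np.unravel_index(idx, (H, W))).astype(float)
    else:
        pts = np.asarray(points, dtype=float)
        n_cells = pts.shape[0]
    yy, xx = np.mgrid[0:H, 0:W]
    pix = np.column_stack([yy.ravel() + 0.5, xx.ravel() + 0.5])
    _, lab = cKDTree(pts + 0.5 if points is None else pts).query(pix)
    labels = (lab.reshape(H, W) + 1).astype(np.uint16)
    if draw_boundaries:
        ridge = np.zeros((H, W), dtype=bool)
        ridge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
        ridge[:-1, :] |= labels[:-1, :] != labels[1:, :]
        labels = np.where(ridge, 0, labels).astype(np.uint16)
    areas_px = np.bincount(labels.ravel(), minlength=n_cells + 1)[1:]
    truth = GroundTruth(
        "tessellation",
        {
            "cell_areas_px": areas_px.astype(int).tolist(),
            "cell_areas_um2": (areas_px * pixel_um**2).tolist(),
            "points_rc": pts.tolist(),
            "skew_target": skew_target,
            "pixel_um": pixel_um,
        },
    )
    return labels, truth


# ---------------------------------------------------------------------------
# tracks


def gen_tracks(
    n: int = 100,
    n_frames: int = 100,
    dt_min: float = 7.5,
    model: str = "brownian",
    D_um2_per_min: float = 1.0,
    v_um_per_h: float = 10.0,
    tau_p_min: float = 30.0,
    box_um: float = 1000.0,
    seed: int = 0,
    areas_um2: np.ndarray | None = None,
    aspect_ratios: np.ndarray | None = None,
):
    """Detection table for ``n`` cells over ``n_frames`` frames.

    Models: ``brownian`` (i.i.d. Gaussian steps, MSD = 4Dτ), ``ballistic``
    (constant random heading at speed v, MSD = v²τ²), ``persistent``
    (stationary Ornstein–Uhlenbeck velocity with persistence time τ_p and
    rms speed v).  Starting positions are uniform in a ``box_um`` square.
    Optional per-cell morphology attributes are attached to every
    detection.  Returns ``(pandas.DataFrame, GroundTruth)`` with columns
    frame, cell_id, x_um, y_um [, area_um2, aspect_ratio].
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    if n_frames < 5:
        raise ValueError("need at least 5 frames")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box_um, size=(n, 2))
    xs = np.empty((n_frames, n, 2))
    xs[0] = pos
    if model == "brownian":
        step_sd = np.sqrt(2.0 * D_um2_per_min * dt_min)
        steps = rng.normal(0.0, step_sd, size=(n_frames - 1, n, 2))
        xs[1:] = pos + np.cumsum(steps, axis=0)
    elif model == "ballistic":
        ang = rng.uniform(0, 2 * np.pi, size=n)
        vel = (v_um_per_h / 60.0) * np.column_stack([np.cos(ang), np.sin(ang)])
        t = np.arange(n_frames)[:, None, None] * dt_min
        xs = pos[None] + vel[None] * t
    elif model == "persistent":
        # exact OU discretization; stationary rms speed v (per-axis v/√2)
        sd_ax = (v_um_per_h / 60.0) / np.sqrt(2.0)
        a = np.exp(-dt_min / tau_p_min)
        vel = rng.normal(0.0, sd_ax, size=(n, 2))
        for k in range(1, n_frames):
            xs[k] = xs[k - 1] + vel * dt_min
            vel = a * vel + sd_ax * np.sqrt(1 - a * a) * rng.standard_normal((n, 2))
    else:
        raise ValueError("model must be 'brownian', 'ballistic' or 'persistent'")
    frames = np.repeat(np.arange(n_frames), n)
    ids = np.tile(np.arange(n), n_frames)
    df = pd.DataFrame(
        {
            "frame": frames,
            "cell_id": ids,
            "x_um": xs[:, :, 0].ravel(),
            "y_um": xs[:, :, 1].ravel(),
        }
    )
    if areas_um2 is not None:
        df["area_um2"] = np.asarray(areas_um2)[ids]
    if aspect_ratios is not None:
        df["aspect_ratio"] = np.asarray(aspect_ratios)[ids]
    truth: dict[str, Any] = {"model": model, "dt_min": dt_min, "n": n}
    if model == "brownian":
        truth["diffusion_um2_per_min"] = D_um2_per_min
        truth["msd_exponent"] = 1.0
    elif model == "ballistic":
        truth["v_um_per_h"] = v_um_per_h
        truth["msd_exponent"] = 2.0
    else:
        truth["v_um_per_h"] = v_um_per_h
        truth["tau_p_min"] = tau_p_min
    return df, GroundTruth("tracks", truth)


# ---------------------------------------------------------------------------
# force-relaxation curves


def gen_force_curve(
    geometry: ShellGeometry,
    mech: MechParams,
    delta_um: float,
    times_s: Sequence[float] | np.ndarray,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> tuple[RelaxationCurve, GroundTruth]:
    """Forward-model dwell force curve with multiplicative Gaussian noise."""
    clean = forward_relaxation(geometry, mech, delta_um, times_s)
    rng = np.random.default_rng(seed)
    F = clean.F_N.copy()
    if noise_rel > 0:
        F = F * (1.0 + noise_rel * rng.standard_normal(F.shape))
    curve = RelaxationCurve(clean.t_s, F, delta_um=delta_um)
    truth = GroundTruth(
        "force_curve",
        {
            "mech_params": {
                "T0_mN_per_m": mech.T0_mN_per_m,
                "KA0_mN_per_m": mech.KA0_mN_per_m,
                "beta": mech.beta,
                "t0_s": mech.t0_s,
            },
            "delta_um": delta_um,
            "noise_rel": noise_rel,
        },
    )
    return curve, truth


# ---------------------------------------------------------------------------
# YAP intensity images


def gen_yap_image(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    I_nuc: float = 80.0,
    I_cyto: float = 160.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Two-level intensity image with a closed-form nucleus/cell ratio.

    Pixels take ``I_nuc`` inside the nucleus and ``I_cyto`` in the rest of
    the cell (0 outside), plus optional additive Gaussian noise.  The
    truth ratio is I_nuc / (f·I_nuc + (1−f)·I_cyto) with f the nuclear
    pixel fraction of the cell.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    if cell.shape != nuc.shape:
        raise ValueError("masks must have the same shape")
    if np.any(nuc & ~cell):
        raise ValueError("nucleus mask must be contained in the cell mask")
    if not nuc.any() or not cell.any():
        raise ValueError("masks must be non-empty")
    img = np.zeros(cell.shape, dtype=float)
    img[cell] = I_cyto
    img[nuc] = I_nuc
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + noise * rng.standard_normal(img.shape)
    f = nuc.sum() / cell.sum()
    truth = GroundTruth(
        "yap_image",
        {
            "yap_ratio": float(I_nuc / (f * I_nuc + (1 - f) * I_cyto)),
            "nuclear_fraction": float(f),
            "I_nuc": I_nuc,
            "I_cyto": I_cyto,
        },
    )
    return img, truth


# ---------------------------------------------------------------------------
# dispatch by SynthSpec


def generate(spec: SynthSpec):
    """Run the generator named by ``spec.kind`` with ``spec.params``."""
    fn = {
        "field": gen_velocity_field,
        "speckle_pair": gen_speckle_pair,
        "tessellation": gen_tessellation,
        "tracks": gen_tracks,
        "force_curve": gen_force_curve,
        "yap_image": gen_yap_image,
    }[spec.kind]
    return fn(seed=spec.seed, **spec.params)
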