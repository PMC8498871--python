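"""Trajectory linking, speeds, ensemble MSD and morphology-binned motility.

Detections (cell centroids per frame) are linked frame-to-frame by
optimal assignment: each consecutive frame pair is matched by minimizing
the total squared displacement, subject to a hard per-link search radius
``max_disp_um``; a track missing from up to ``memory_frames`` consecutive
frames may be resumed, and tracks with fewer than ``min_length`` points
are discarded as spurious.  The defaults mirror common monolayer
tracking practice (search radius ≈ 4.6–5.7 µm at 0.576 µm/px, memory 4,
minimum 5 points, 7.5 min frame interval).

The ensemble mean squared displacement

    MSD(τ) = ⟨|x(t+τ) − x(t)|²⟩

averages over all cells and all time origins, and is summarized by a
power law MSD(τ) = a·τⁿ fitted by linear regression in log-log space;
n ≈ 1 indicates diffusive and n → 2 directed motion.  Tracks can be
partitioned into discrete bins of cell area (100 µm²) or aspect ratio
(0.25) before fitting to resolve morphology-dependent motility.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "LinkConfig",
    "Track",
    "MsdCurve",
    "PowerLawFit",
    "link",
    "mean_speed",
    "ensemble_msd",
    "fit_power_law",
    "bin_and_fit",
]


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters (defaults for monolayer data at 0.576 µm/px)."""

    max_disp_um: float = 4.6
    memory_frames: int = 4
    min_length: int = 5

    def __post_init__(self) -> None:
        if self.max_disp_um <= 0 or self.memory_frames < 0 or self.min_length < 1:
            raise ValueError("invalid linking configuration")


@dataclass
class Track:
    """A linked trajectory; positions in µm, frames strictly increasing."""

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    dt_min: float = 7.5
    attrs: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.size

    def median_attr(self, name: str) -> float:
        if name not in self.attrs:
            raise KeyError(f"track carries no attribute {name!r}")
        return float(np.median(self.attrs[name]))


@dataclass
class MsdCurve:
    """Ensemble MSD; lag 0 is included with MSD 0 by definition."""

    lag_min: np.ndarray
    msd_um2: np.ndarray
    n_obs: np.ndarray
    fit: "PowerLawFit | None" = None


@dataclass
class PowerLawFit:
    """MSD(τ) = a·τⁿ with τ in minutes; a in µm²·minⁿ̄."""

    a_um2: float
    n: float
    window_min: tuple[float, float]

    def msd_at(self, lag_min: float) -> float:
        return self.a_um2 * lag_min**self.n


# ---------------------------------------------------------------------------
# linking


def _assign(
    last_xy: np.ndarray, det_xy: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    """Minimal total-squared-displacement matching with a hard radius.

    Rectangular assignment with per-row/column "no match" alternatives
    priced at the search-radius cost, so any link longer than
    ``max_disp`` is rejected in favor of ending/starting a track.
    """
    na, nd = len(last_xy), len(det_xy)
    if na == 0 or nd == 0:
        return []
    d2 = np.sum((last_xy[:, None, :] - det_xy[None, :, :]) ** 2, axis=2)
    cutoff = max_disp * max_disp
    big = 1e6 * (cutoff + 1.0)
    cost = np.full((na + nd, nd + na), big)
    cost[:na, :nd] = np.where(d2 <= cutoff, d2, big)
    cost[:na, nd:] = np.where(np.eye(na, dtype=bool), cutoff * 1.0000001, big)
    cost[na:, :nd] = np.where(np.eye(nd, dtype=bool), cutoff * 1.0000001, big)
    cost[na:, nd:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < na and c < nd and cost[r, c] < big
    ]


def _assign_greedy(
    last_xy: np.ndarray, det_xy: np.ndarray, max_disp: float
) -> list[tuple[int, int]]:
    na, nd = len(last_xy), len(det_xy)
    if na == 0 or nd == 0:
        return []
    d2 = np.sum((last_xy[:, None, :] - det_xy[None, :, :]) ** 2, axis=2)
    cutoff = max_disp * max_disp
    pairs = []
    used_r: set[int] = set()
    used_c: set[int] = set()
    for flat in np.argsort(d2, axis=None):
        r, c = divmod(int(flat), nd)
        if d2[r, c] > cutoff:
            break
        if r in used_r or c in used_c:
            continue
        pairs.append((r, c))
        used_r.add(r)
        used_c.add(c)
    return pairs


def link(
    detections: pd.DataFrame,
    cfg: LinkConfig = LinkConfig(),
    dt_min: float = 7.5,
    method: str = "optimal",
) -> list[Track]:
    """Link a detection table (frame, x_um, y_um [, extra columns]) into tracks.

    Extra numeric columns (e.g. ``area_um2``, ``aspect_ratio``) are
    carried onto the tracks as per-point attributes.  Detections within a
    frame may appear in any order; the per-frame-pair matching is an
    optimal assignment (``method='greedy'`` selects nearest-first greedy
    matching instead).
    """
    required = {"frame", "x_um", "y_um"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detections must have columns {sorted(required)}")
    assign = _assign if method == "optimal" else _assign_greedy
    extra_cols = [
        c
        for c in detections.columns
        if c not in ("frame", "x_um", "y_um", "cell_id")
        and np.issubdtype(detections[c].dtype, np.number)
    ]
    open_tracks: list[dict] = []
    closed: list[dict] = []
    for frame, grp in detections.sort_values("frame").groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks that exceeded the memory gap
        still = []
        for tr in open_tracks:
            if frame - tr["frames"][-1] > cfg.memory_frames + 1:
                closed.append(tr)
            else:
                still.append(tr)
        open_tracks = still
        det_xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        det_extra = {c: grp[c].to_numpy(dtype=float) for c in extra_cols}
        matched_dets: set[int] = set()
        if open_tracks:
            last_xy = np.array([t["xy"][-1] for t in open_tracks])
            for r, c in assign(last_xy, det_xy, cfg.max_disp_um):
                t = open_tracks[r]
                t["frames"].append(frame)
                t["xy"].append(det_xy[c])
                for k in extra_cols:
                    t["attrs"][k].append(det_extra[k][c])
                matched_dets.add(c)
        for c in range(det_xy.shape[0]):
            if c not in matched_dets:
                open_tracks.append(
                    {
                        "frames": [frame],
                        "xy": [det_xy[c]],
                        "attrs": {k: [det_extra[k][c]] for k in extra_cols},
                    }
                )
    closed.extend(open_tracks)
    tracks = []
    tid = 0
    for tr in closed:
        if len(tr["frames"]) < cfg.min_length:
            continue
        tracks.append(
            Track(
                track_id=tid,
                frames=np.array(tr["frames"]),
                xy=np.array(tr["xy"]),
                dt_min=dt_min,
                attrs={k: np.array(v) for k, v in tr["attrs"].items()},
            )
        )
        tid += 1
    return tracks


# ---------------------------------------------------------------------------
# speeds and MSD


def mean_speed(track: Track) -> float:
    """Mean step speed |Δx|/Δt over consecutive stored points, in µm/h.

    Averaging per time step normalizes tracks recorded at different frame
    rates; gap-spanning steps use their actual time separation.
    """
    if len(track) < 2:
        raise ValueError("track must have at least 2 points")
    d = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    dt_h = np.diff(track.frames) * track.dt_min / 60.0
    return float(np.mean(d / dt_h))


def ensemble_msd(tracks: Sequence[Track], max_lag: int | None = None) -> MsdCurve:
    """Ensemble MSD over all tracks and time origins.

    Lags are in frames internally and reported in minutes; pairs spanning
    memory gaps use the actually stored endpoints.  Lags with no
    observations are omitted.
    """
    if not tracks:
        raise ValueError("no tracks")
    dt = tracks[0].dt_min
    span = max(int(t.frames[-1] - t.frames[0]) for t in tracks)
    if max_lag is None:
        max_lag = span
    max_lag = min(max_lag, span)
    if max_lag < 1:
        raise ValueError("no valid displacement pairs")
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    counts[0] = sum(len(t) for t in tracks)
    for t in tracks:
        idx = {int(f): i for i, f in enumerate(t.frames)}
        frames = t.frames
        for lag in range(1, max_lag + 1):
            tgt = frames + lag
            pairs = [(idx[int(f)], idx[int(g)]) for f, g in zip(frames, tgt) if int(g) in idx]
            if not pairs:
                continue
            i0, i1 = np.array(pairs).T
            disp = t.xy[i1] - t.xy[i0]
            sums[lag] += float(np.sum(disp * disp))
            counts[lag] += len(pairs)
    good = counts > 0
    lags = np.flatnonzero(good)
    msd = np.zeros(lags.size)
    nz = lags > 0
    msd[nz] = sums[lags[nz]] / counts[lags[nz]]
    return MsdCurve(lag_min=lags * dt, msd_um2=msd, n_obs=counts[lags])


def fit_power_law(
    curve: MsdCurve, window_min: tuple[float, float] | None = None
) -> PowerLawFit:
    """Fit MSD(τ) = a·τⁿ by least squares on (log τ, log MSD).

    Nonpositive MSD values inside the window are excluded; at least three
    points must remain.  The default window spans all positive lags up to
    60 min.
    """
    if window_min is None:
        window_min = (0.0, 60.0)
    lo, hi = window_min
    sel = (curve.lag_min > max(lo, 0)) & (curve.lag_min <= hi) & (curve.msd_um2 > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 positive MSD points in the fit window")
    slope, intercept = np.polyfit(
        np.log(curve.lag_min[sel]), np.log(curve.msd_um2[sel]), 1
    )
    fit = PowerLawFit(a_um2=float(np.exp(intercept)), n=float(slope), window_min=window_min)
    curve.fit = fit
    return fit


def bin_and_fit(
    tracks: Sequence[Track],
    attribute: str = "area_um2",
    bin_width: float = 100.0,
    fit_window_min: tuple[float, float] = (0.0, 60.0),
    min_tracks: int = 3,
    msd_at_min: float = 60.0,
) -> dict[int, dict]:
    """Per-morphology-bin MSD amplitude and exponent.

    Tracks are partitioned by their median attribute value into half-open
    bins [k·w, (k+1)·w) — a value exactly on an edge joins the upper bin —
    and the ensemble MSD and its power-law fit are computed per bin; bins
    with fewer than ``min_tracks`` tracks are suppressed.  Returns
    ``{bin index: {bin_lo, bin_hi, n_tracks, msd_at, a, n}}`` where
    ``msd_at`` is the fitted power law evaluated at ``msd_at_min``.
    """
    groups: dict[int, list[Track]] = {}
    for t in tracks:
        val = t.median_attr(attribute)
        groups.setdefault(int(np.floor(val / bin_width)), []).append(t)
    out: dict[int, dict] = {}
    for k in sorted(groups):
        members = groups[k]
        if len(members) < min_tracks:
            continue
        curve = ensemble_msd(members)
        try:
            fit = fit_power_law(curve, fit_window_min)
        except ValueError:
            continue
        out[k] = {
            "bin_lo": k * bin_width,
            "bin_hi": (k + 1) * bin_width,
            "n_tracks": len(members),
            "msd_at": fit.msd_at(msd_at_min),
            "a": fit.a_um2,
            "n": fit.n,
        }
    return out
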