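"""Readers and writers for the package's plain-text and TIFF interchange formats.

Conventions: comma-separated UTF-8 CSV with a mandatory header row and
``#``-prefixed metadata lines; units are always declared in the metadata,
never implied.  Label masks are single-channel integer TIFFs.  All
writers are deterministic: re-writing identical data yields bit-identical
files (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UnitMismatchError
from .mechanics import RelaxationCurve, ShellGeometry
from .velocimetry import CorrelationCurve, EdgeProfile, VectorField

__all__ = [
    "write_vector_field_csv",
    "read_vector_field_csv",
    "write_labels_tiff",
    "read_labels_tiff",
    "write_tracks_csv",
    "read_detections_csv",
    "write_force_curve",
    "read_force_curve",
    "write_truth_json",
    "sha256_file",
    "Manifest",
]

_VFIELD_COLUMNS = ["frame", "row", "col", "x_um", "y_um", "u_um_per_h", "v_um_per_h", "valid"]


def _read_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_vector_field_csv(path, fields: Sequence[VectorField]) -> None:
    """Write a time series of vector fields to one CSV file."""
    path = Path(path)
    f0 = fields[0]
    ax = f0.migration_axis
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# spacing_um={float(f0.spacing_um)!r}\n")
        fh.write(f"# migration_axis={float(ax[0])!r},{float(ax[1])!r}\n")
        fh.write("# units=um_per_h\n")
        fh.write(f"# t_min={','.join(repr(float(f.t_min)) for f in fields)}\n")
        fh.write(",".join(_VFIELD_COLUMNS) + "\n")
        for k, f in enumerate(fields):
            ny, nx = f.shape
            sp = float(f.spacing_um)
            for i in range(ny):
                for j in range(nx):
                    fh.write(
                        f"{k},{i},{j},{j * sp!r},{i * sp!r},"
                        f"{float(f.u[i, j])!r},{float(f.v[i, j])!r},{int(f.mask[i, j])}\n"
                    )


def read_vector_field_csv(path) -> list[VectorField]:
    """Read a vector-field time series written by :func:`write_vector_field_csv`."""
    path = Path(path)
    meta = _read_metadata(path)
    if meta.get("units", "um_per_h") != "um_per_h":
        raise UnitMismatchError(
            f"{path}: expected velocities in um_per_h, header declares {meta.get('units')!r}"
        )
    if "spacing_um" not in meta:
        raise FormatError(f"{path}: missing spacing_um metadata")
    spacing = float(meta["spacing_um"])
    axis = tuple(float(x) for x in meta.get("migration_axis", "1,0").split(","))
    t_mins = [float(x) for x in meta.get("t_min", "0").split(",")]
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(_VFIELD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    frames = sorted(df["frame"].unique())
    if frames != list(range(len(frames))):
        raise FormatError(f"{path}: frame indices must be 0..n-1 without gaps")
    out = []
    for k in frames:
        sub = df[df["frame"] == k]
        ny = int(sub["row"].max()) + 1
        nx = int(sub["col"].max()) + 1
        if len(sub) != ny * nx:
            raise FormatError(f"{path}: frame {k} is not a full {ny}x{nx} grid")
        u = np.full((ny, nx), np.nan)
        v = np.full((ny, nx), np.nan)
        mask = np.zeros((ny, nx), dtype=bool)
        r = sub["row"].to_numpy(int)
        c = sub["col"].to_numpy(int)
        u[r, c] = sub["u_um_per_h"].to_numpy(float)
        v[r, c] = sub["v_um_per_h"].to_numpy(float)
        mask[r, c] = sub["valid"].to_numpy(int) > 0
        bad = mask & (~np.isfinite(u) | ~np.isfinite(v))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            line = int(np.flatnonzero((r == i) & (c == j))[0])
            raise FormatError(f"{path}: NaN velocity inside the mask (frame {k}, data row {line})")
        u[~mask] = 0.0
        v[~mask] = 0.0
        t = t_mins[k] if k < len(t_mins) else float(k)
        out.append(
            VectorField(u, v, spacing_um=spacing, mask=mask, t_min=t, migration_axis=axis)
        )
    return out


def write_labels_tiff(path, labels: np.ndarray) -> None:
    import tifffile

    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError("label image must be integer-typed")
    tifffile.imwrite(Path(path), labels.astype(np.uint16), photometric="minisblack")


def read_labels_tiff(path, pixel_um: float = 1.0) -> np.ndarray:
    """Read a single-channel integer label TIFF (8- or 16-bit)."""
    import tifffile

    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2-D TIFF, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: expected an integer TIFF, got {arr.dtype}")
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    return arr.astype(np.int32)


def write_tracks_csv(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_detections_csv(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), comment="#", float_precision="round_trip")
    missing = {"frame", "x_um", "y_um"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_force_curve(path, curve: RelaxationCurve, geom: ShellGeometry, t0_s: float = 1.0) -> None:
    """Two-column CSV (t_s, F_N) plus a JSON sidecar with geometry/indentation."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("t_s,F_N\n")
        for t, f in zip(curve.t_s, curve.F_N):
            fh.write(f"{float(t)!r},{float(f)!r}\n")
    sidecar = {
        "R1_um": geom.R1_um,
        "phi_deg": geom.phi_deg,
        "indenter_half_angle_deg": geom.indenter_half_angle_deg,
        "delta_um": curve.delta_um,
        "t0_s": t0_s,
    }
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_force_curve(path) -> tuple[RelaxationCurve, ShellGeometry, float]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["t_s", "F_N"]:
        raise FormatError(f"{path}: expected exactly columns t_s,F_N")
    with open(path.with_suffix(".json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    geom = ShellGeometry(
        meta["R1_um"], meta["phi_deg"], meta.get("indenter_half_angle_deg", 17.5)
    )
    curve = RelaxationCurve(
        df["t_s"].to_numpy(float), df["F_N"].to_numpy(float), delta_um=meta["delta_um"]
    )
    return curve, geom, float(meta.get("t0_s", 1.0))


def write_truth_json(path, truth) -> None:
    from .synthgen import GroundTruth

    obj = {"kind": truth.kind, "truth": truth.truth} if isinstance(truth, GroundTruth) else truth
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Checksummed inventory of the artifacts a pipeline run produced."""

    artifacts: list[dict]

    def add(self, path, stage: str) -> None:
        path = Path(path)
        for a in self.artifacts:
            if a["path"] == path.name:
                raise ValueError(f"artifact {path.name} already recorded")
        self.artifacts.append(
            {"path": path.name, "stage": stage, "sha256": sha256_file(path)}
        )

    def write(self, path) -> None:
        with open(Path(path), "w", encoding="utf-8") as fh:
            json.dump({"artifacts": self.artifacts}, fh, indent=2, sort_keys=True)
            fh.write("\n")
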