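"""File I/O for every pipeline artifact.

Apertures travel as NIfTI 3D volumes (x, y, t) with pixel-size metadata
plus a JSON design sidecar; BOLD as NIfTI 4D or a CSV matrix with a
voxel-label CSV; pRF tables, probe tables, coverage/TD maps and
perimetry as CSV (maps with a JSON sidecar).  Every writer/reader pair
round-trips within numeric-text precision.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import PerimetryGrid
from .reconstruction import CoverageMap
from .stimulus import StimulusAperture, StimulusDesign, pixel_grid

LABEL_COLUMNS = ("voxel_id", "hemisphere", "area", "roi_group", "sub_roi")


class FormatError(ValueError):
    """Malformed or inconsistent on-disk artifact."""


def write_aperture(aperture: StimulusAperture, path: str | Path) -> Path:
    path = Path(path)
    pitch = float(aperture.xs[1] - aperture.xs[0])
    affine = np.diag([pitch, pitch, aperture.frame_duration_s, 1.0])
    img = nib.Nifti1Image(aperture.frames.astype(np.uint8), affine)
    img.header.set_zooms((pitch, pitch, aperture.frame_duration_s))
    nib.save(img, path)
    sidecar = dataclasses.asdict(aperture.design)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_aperture(path: str | Path) -> StimulusAperture:
    path = Path(path)
    img = nib.load(path)
    frames = np.asarray(img.dataobj).astype(np.uint8)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing design sidecar {sidecar}")
    design = StimulusDesign(**json.loads(sidecar.read_text()))
    n_pix = frames.shape[0]
    xs, ys = pixel_grid(n_pix, design.field_radius_deg)
    pitch_file = float(img.header.get_zooms()[0])
    pitch_cfg = float(xs[1] - xs[0])
    if abs(pitch_file - pitch_cfg) > 1e-4:
        warnings.warn(
            f"aperture pixel size {pitch_file:.4f} deg does not match the "
            f"design-implied pitch {pitch_cfg:.4f} deg", stacklevel=2)
    return StimulusAperture(frames=frames, design=design, xs=xs, ys=ys)


def write_bold(data_per_scan: list[np.ndarray], labels: pd.DataFrame,
               out_dir: str | Path, stem: str = "bold") -> Path:
    """One CSV matrix per scan (voxels x frames) + one label CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, arr in enumerate(data_per_scan, start=1):
        pd.DataFrame(arr).to_csv(out_dir / f"{stem}_scan{i}.csv", index=False)
    labels.to_csv(out_dir / f"{stem}_labels.csv", index=False)
    return out_dir


def read_bold(out_dir: str | Path, stem: str = "bold"
              ) -> tuple[list[np.ndarray], pd.DataFrame]:
    out_dir = Path(out_dir)
    scans = sorted(out_dir.glob(f"{stem}_scan*.csv"))
    if not scans:
        raise FormatError(f"no {stem}_scan*.csv in {out_dir}")
    data = [pd.read_csv(p).to_numpy(float) for p in scans]
    labels = read_labels(out_dir / f"{stem}_labels.csv")
    return data, labels


def read_labels(path: str | Path) -> pd.DataFrame:
    labels = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing:
        raise FormatError(f"label file {path} missing columns {missing}")
    return labels


def write_prf_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_prf_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ("voxel_id", "x0", "y0", "sigma", "ve")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"pRF table {path} missing columns {missing}")
    if df[list(required)].isna().any().any():
        raise FormatError(f"pRF table {path} contains NaNs in required columns")
    return df


def write_probe_table(probe_maps, path: str | Path) -> Path:
    """Long-format probe CSV: voxel_id, x, y, ve."""
    path = Path(path)
    frames = []
    for pm in probe_maps:
        df = pd.DataFrame(pm.probes, columns=["x", "y", "ve"])
        df.insert(0, "voxel_id", pm.voxel_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("voxel_id", "x", "y", "ve") if c not in df.columns]
    if missing:
        raise FormatError(f"probe table {path} missing columns {missing}")
    return df


def write_map(grid: np.ndarray, path: str | Path, meta: dict | None = None) -> Path:
    """26x26 (or any) map as a headerless CSV matrix + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(grid, float), delimiter=",")
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    grid = np.loadtxt(path, delimiter=",")
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return grid, meta


def write_coverage_map(cm: CoverageMap, path: str | Path) -> Path:
    return write_map(cm.grid, path, meta=dict(
        technique=cm.technique, scope=cm.scope, extent=cm.extent,
        normalized=cm.normalized, empty=cm.empty))


def read_coverage_map(path: str | Path) -> CoverageMap:
    grid, meta = read_map(path)
    return CoverageMap(grid=grid, technique=meta.get("technique", "mp"),
                       scope=meta.get("scope", "full_field"),
                       extent=float(meta.get("extent", 6.5)),
                       normalized=bool(meta.get("normalized", False)),
                       empty=bool(meta.get("empty", False)))


def write_perimetry(grid: PerimetryGrid, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(dict(x=grid.locations[:, 0], y=grid.locations[:, 1],
                           value=grid.values))
    df.attrs = {}
    header = f"# grid_type={grid.grid_type} mode={grid.mode}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_perimetry(path: str | Path) -> PerimetryGrid:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in ("x", "y", "value") if c not in df.columns]
    if missing:
        raise FormatError(f"perimetry file {path} missing columns {missing}")
    return PerimetryGrid(locations=df[["x", "y"]].to_numpy(float),
                         values=df["value"].to_numpy(float),
                         grid_type=meta.get("grid_type", "unknown"),
                         mode=meta.get("mode", "db"))
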