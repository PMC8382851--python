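"""Visual-field reconstruction: coverage maps, normative referencing,
total deviation in dB and confidence-interval classification.

The fitted models are back-projected onto the visual field:

* pRF: the VE > 15%, ecc <= 6.5 deg voxels' Gaussians, weighted by VE,
  are summed per hemisphere ROI; the two hemisphere maps are averaged
  and the result normalised to [0, 1].  The map is rasterised on the
  same 26 x 26 grid as MP so the two techniques are cell-comparable.
* MP: the included voxels' binned probe maps are summed per hemispheric
  sub-ROI (3 per hemisphere); the six maps are averaged and normalised.

An individual's normalised coverage map (CM) is divided by a normative
map — the average of the controls' normalised CMs (leave-one-out for a
control itself), which corrects the central oversampling produced by
cortical magnification.  The ratio is expressed as total deviation
``10 * log10(cm / normative)`` floored at -30 dB, and classified against
the pooled control distribution's CI boundaries (90/96/98/99%): below
the lower 5% bound = "below normal limits", above the upper = "above",
else "within".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microprobe import ProbeMap, N_BINS_DEFAULT

__all__ = ["CoverageMap", "NormativeMap", "TotalDeviationMap",
           "EmptyROIError", "coverage_from_prfs", "coverage_from_probes",
           "combine_and_normalize", "build_normative_map",
           "total_deviation_db", "ci_boundaries", "classify_deviation"]

FLOOR_DB = -30.0
CI_LEVELS = (90, 96, 98, 99)


class EmptyROIError(ValueError):
    """No voxel of the ROI survived the inclusion gate."""

    def __init__(self, roi: str):
        super().__init__(f"no included voxels in ROI {roi!r}")
        self.roi = roi


def cell_centers(n_bins: int = N_BINS_DEFAULT, extent: float = 6.5) -> np.ndarray:
    width = 2.0 * extent / n_bins
    return -extent + width * (np.arange(n_bins) + 0.5)


@dataclass
class CoverageMap:
    """VF sampling-density raster ``grid[iy, ix]`` over [-extent, extent]^2."""

    grid: np.ndarray
    technique: str                       # prf | mp
    scope: str = "full_field"
    extent: float = 6.5
    normalized: bool = False
    roi_selection: str = "whole_visual_cortex"
    provenance: list = field(default_factory=list)
    empty: bool = False                  # zero map standing in for an empty ROI

    @property
    def n_bins(self) -> int:
        return self.grid.shape[0]


@dataclass
class NormativeMap:
    grid: np.ndarray
    provenance: list
    extent: float = 6.5
    leave_one_out_excluded: object = None
    technique: str = "mp"


@dataclass
class TotalDeviationMap:
    """dB deviation from the normative map, with validity mask and labels."""

    db: np.ndarray
    valid: np.ndarray                    # False where the normative map is ~0
    floor_db: float = FLOOR_DB
    extent: float = 6.5
    technique: str = "mp"
    labels: np.ndarray | None = None     # 'below' | 'within' | 'above'
    boundaries: dict | None = None

    def values(self) -> np.ndarray:
        """Valid cells' dB values, flattened."""
        return self.db[self.valid]


def coverage_from_prfs(models: pd.DataFrame, n_bins: int = N_BINS_DEFAULT,
                       extent: float = 6.5, scope: str = "hemisphere",
                       allow_empty: bool = False) -> CoverageMap:
    """Sum the included voxels' VE-weighted Gaussians on the cell grid.

    ``models`` must already carry the inclusion mask; only rows with
    ``included`` are used (all rows if the column is absent).
    """
    if "included" in models.columns:
        models = models[models["included"]]
    if len(models) == 0:
        if allow_empty:
            return CoverageMap(grid=np.zeros((n_bins, n_bins)), technique="prf",
                               scope=scope, extent=extent, empty=True)
        raise EmptyROIError(scope)
    c = cell_centers(n_bins, extent)
    X, Y = np.meshgrid(c, c)
    grid = np.zeros((n_bins, n_bins))
    for _, m in models.iterrows():
        ve = min(1.0, max(0.0, float(m["ve"])))
        grid += ve * np.exp(-((X - m["x0"]) ** 2 + (Y - m["y0"]) ** 2)
                            / (2.0 * float(m["sigma"]) ** 2))
    return CoverageMap(grid=grid, technique="prf", scope=scope, extent=extent,
                       provenance=list(models["voxel_id"]))


def coverage_from_probes(probe_maps: list[ProbeMap], scope: str = "sub_roi",
                         extent: float = 6.5,
                         allow_empty: bool = False) -> CoverageMap:
    """Elementwise sum of included voxels' binned (VE-weighted) probe maps."""
    if len(probe_maps) == 0:
        if allow_empty:
            return CoverageMap(grid=np.zeros((N_BINS_DEFAULT, N_BINS_DEFAULT)),
                               technique="mp", scope=scope, extent=extent,
                               empty=True)
        raise EmptyROIError(scope)
    grid = np.sum([pm.binned for pm in probe_maps], axis=0)
    return CoverageMap(grid=grid, technique="mp", scope=scope, extent=extent,
                       provenance=[pm.voxel_id for pm in probe_maps])


def combine_and_normalize(parts: list[CoverageMap]) -> CoverageMap:
    """Average the part maps elementwise and normalise the result to max 1.

    pRF mode takes the two hemisphere maps, MP mode the six sub-ROI maps;
    an empty (lesioned-away) part contributes zeros, flagged upstream.
    """
    if len(parts) == 0:
        raise ValueError("no coverage maps to combine")
    shapes = {p.grid.shape for p in parts}
    techniques = {p.technique for p in parts}
    if len(shapes) != 1 or len(techniques) != 1:
        raise ValueError("parts must share grid shape and technique")
    mean = np.mean([p.grid for p in parts], axis=0)
    peak = mean.max()
    if peak <= 0:
        raise EmptyROIError("full_field")
    prov = [p.provenance for p in parts]
    return CoverageMap(grid=mean / peak, technique=parts[0].technique,
                       scope="full_field", extent=parts[0].extent,
                       normalized=True, provenance=prov)


def build_normative_map(controls: dict[object, CoverageMap],
                        exclude_id: object = None) -> NormativeMap:
    """Average of the controls' normalised CMs, optionally leaving one out.

    The normative map captures (and thereby corrects, through division)
    the centrally peaked sampling density that cortical magnification
    imposes on every coverage map.
    """
    keys = [k for k in controls if k != exclude_id]
    if exclude_id is not None and len(keys) < 1:
        raise ValueError("cannot leave one out of a single-control set")
    if len(keys) == 0:
        raise ValueError("no control maps supplied")
    for k in keys:
        if not controls[k].normalized:
            raise ValueError(f"control {k!r} map is not normalised")
    grid = np.mean([controls[k].grid for k in keys], axis=0)
    first = controls[keys[0]]
    return NormativeMap(grid=grid, provenance=keys, extent=first.extent,
                        leave_one_out_excluded=exclude_id,
                        technique=first.technique)


def total_deviation_db(cm: CoverageMap, normative: NormativeMap,
                       floor_db: float = FLOOR_DB,
                       eps_frac: float = 1e-4) -> TotalDeviationMap:
    """``10 * log10(cm / normative)``, floored at ``floor_db``.

    Cells where the normative map is below ``eps_frac`` of its maximum
    are masked invalid (the ratio is meaningless there) rather than
    floored.
    """
    if cm.grid.shape != normative.grid.shape:
        raise ValueError("coverage and normative maps must share the grid")
    eps = eps_frac * normative.grid.max()
    valid = normative.grid > eps
    db = np.full(cm.grid.shape, floor_db)
    with np.errstate(divide="ignore"):
        ratio = np.where(valid, cm.grid / np.where(valid, normative.grid, 1.0), 0.0)
        db[valid] = 10.0 * np.log10(np.maximum(ratio[valid], 10.0 ** (floor_db / 10.0)))
    db = np.maximum(db, floor_db)
    return TotalDeviationMap(db=db, valid=valid, floor_db=floor_db,
                             extent=cm.extent, technique=cm.technique)


def ci_boundaries(values: np.ndarray, levels=CI_LEVELS) -> dict[int, tuple[float, float]]:
    """Two-sided CI boundaries of the pooled control sensitivities.

    For level L the bounds are the ``(100 - L)/2`` and ``100 - (100-L)/2``
    percentiles (90% -> 5th and 95th).
    """
    values = np.asarray(values, float).ravel()
    if values.size == 0:
        raise ValueError("no values to compute boundaries from")
    out = {}
    for L in levels:
        lo = (100.0 - L) / 2.0
        out[int(L)] = (float(np.percentile(values, lo)),
                       float(np.percentile(values, 100.0 - lo)))
    return out


def classify_deviation(td: TotalDeviationMap,
                       boundaries: dict[int, tuple[float, float]],
                       level: int = 90) -> TotalDeviationMap:
    """Label each valid cell against the CI boundaries (closed interval:
    a cell exactly at a bound is "within").  Invalid cells get "masked"."""
    if level not in boundaries:
        raise ValueError(f"boundaries for the {level}% CI are required")
    lo, hi = boundaries[level]
    labels = np.full(td.db.shape, "within", dtype=object)
    labels[td.db < lo] = "below"
    labels[td.db > hi] = "above"
    labels[~td.valid] = "masked"
    td.labels = labels
    td.boundaries = dict(boundaries)
    return td
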