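"""Synthetic cortex, lesions, BOLD simulation and matched perimetry.

Generates ground-truth voxel populations with contralateral retinotopic
organisation across two hemispheres, eccentricity-dependent pRF sizes,
optional bilateral / multi-RF voxels, unilateral lesions producing
hemianopic or quadrantanopic field loss (with optional spared islands),
HRF-convolved BOLD responses with additive Gaussian noise, and matched
Humphrey-style perimetry grids — so the full reconstruction pipeline can
be exercised without any acquired data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bold import GaussianRF, HRFSpec, canonical_hrf
from .forward import build_prediction_bank
from .stimulus import StimulusAperture

AREAS = ("V1", "V2", "V3", "hV4", "VO1", "VO2",
         "LO1", "LO2", "TO1", "TO2", "V3b", "V3a")
EARLY_AREAS = ("V1", "V2")

__all__ = [
    "AREAS",
    "EARLY_AREAS",
    "Voxel",
    "GroundTruthCortex",
    "LesionSpec",
    "PerimetryGrid",
    "generate_retinotopy",
    "apply_lesion",
    "simulate_bold",
    "generate_perimetry",
]


@dataclass(frozen=True)
class Voxel:
    """One simulated voxel: true RF(s) with relative gains plus labels."""

    voxel_id: int
    rfs: tuple[GaussianRF, ...]
    gains: tuple[float, ...]
    hemisphere: str
    area: str
    sub_roi: int
    lesion: str = "intact"          # intact | silenced | attenuated
    lesion_gain: float = 1.0

    @property
    def roi_group(self) -> str:
        return "early" if self.area in EARLY_AREAS else "extrastriate"

    @property
    def primary_rf(self) -> GaussianRF:
        return self.rfs[int(np.argmax(self.gains))]


@dataclass(frozen=True)
class LesionSpec:
    """Visual-field region of damage (the deficit, in VF coordinates).

    ``region`` is ``"right_hemifield"``, ``"left_hemifield"``, one of the
    ``"upper_right" / "upper_left" / "lower_right" / "lower_left"``
    quadrants, or ``"disc"`` (circle given by ``disc=(cx, cy, radius)``).
    ``mode`` silences or attenuates (by ``gain``) every voxel whose
    primary RF center falls inside the region, except inside the
    ``spared_islands`` discs ``(cx, cy, radius)``.
    """

    region: str = "right_hemifield"
    mode: str = "silence"           # silence | attenuate
    gain: float = 0.0
    spared_islands: tuple[tuple[float, float, float], ...] = ()
    disc: tuple[float, float, float] | None = None

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        region = {
            "right_hemifield": x > 0,
            "left_hemifield": x < 0,
            "upper_right": (x > 0) & (y > 0),
            "upper_left": (x < 0) & (y > 0),
            "lower_right": (x > 0) & (y < 0),
            "lower_left": (x < 0) & (y < 0),
        }
        if self.region == "disc":
            if self.disc is None:
                raise ValueError("disc region requires disc=(cx, cy, radius)")
            cx, cy, r = self.disc
            inside = np.hypot(x - cx, y - cy) <= r
        else:
            try:
                inside = region[self.region]
            except KeyError:
                raise ValueError(f"unknown lesion region {self.region!r}") from None
        for cx, cy, r in self.spared_islands:
            inside = inside & ~(np.hypot(x - cx, y - cy) <= r)
        return inside


@dataclass
class GroundTruthCortex:
    """A simulated two-hemisphere voxel population."""

    voxels: list[Voxel]
    seed: int
    lesions: list[LesionSpec] = field(default_factory=list)

    def labels(self) -> pd.DataFrame:
        rows = []
        for v in self.voxels:
            rows.append(dict(voxel_id=v.voxel_id, hemisphere=v.hemisphere,
                             area=v.area, roi_group=v.roi_group, sub_roi=v.sub_roi,
                             lesion=v.lesion))
        return pd.DataFrame(rows)

    def truth(self) -> pd.DataFrame:
        """Primary-RF ground truth table (one row per voxel)."""
        rows = []
        for v in self.voxels:
            rf = v.primary_rf
            rows.append(dict(voxel_id=v.voxel_id, x0=rf.x0, y0=rf.y0,
                             sigma=rf.sigma, n_rfs=len(v.rfs), lesion=v.lesion))
        return pd.DataFrame(rows)


def _sample_positions(rng, n, ecc_range, hemisphere, foveal_exponent=0.5):
    """Positions in the hemifield contralateral to ``hemisphere``.

    Eccentricity ~ CDF u**(1/(2*foveal_exponent)) over [e0, e1];
    0.5 gives uniform density over the disc area, smaller values
    oversample the fovea (mimicking cortical magnification).
    """
    e0, e1 = ecc_range
    u = rng.uniform(size=n)
    p = 1.0 / (2.0 * foveal_exponent)
    ecc = e0 + (e1 - e0) * u ** p
    # left hemisphere represents the right hemifield (x >= 0)
    lo, hi = (-np.pi / 2, np.pi / 2) if hemisphere == "left" else (np.pi / 2, 3 * np.pi / 2)
    ang = rng.uniform(lo, hi, size=n)
    return ecc * np.cos(ang), ecc * np.sin(ang)


def generate_retinotopy(
    n_voxels_per_hemisphere: int,
    ecc_range: tuple[float, float] = (0.25, 6.5),
    sigma_slope: float = 0.25,
    sigma_intercept: float = 0.2,
    bilateral_fraction: float = 0.0,
    multi_rf_fraction: float = 0.0,
    foveal_exponent: float = 0.5,
    seed: int = 0,
) -> GroundTruthCortex:
    """Generate an intact two-hemisphere cortex.

    Each hemisphere's voxels carry primary RFs in the contralateral
    hemifield (up to ``bilateral_fraction`` exceptions) with sizes
    following the linear law ``sigma = intercept + slope * ecc``.
    A ``multi_rf_fraction`` of voxels receives a second, equal-gain RF
    mirrored across the vertical meridian.  Voxels are assigned to the
    12 visual areas (V1/V2 = early) and to 3 sub-ROIs per hemisphere.
    """
    if n_voxels_per_hemisphere < 1:
        raise ValueError("need at least one voxel per hemisphere")
    e0, e1 = ecc_range
    if not (0 <= e0 < e1):
        raise ValueError(f"invalid ecc_range {ecc_range}")
    rng = np.random.default_rng(seed)
    voxels: list[Voxel] = []
    vid = 0
    # weight early areas more heavily: V1/V2 hold roughly half the voxels
    area_w = np.array([0.25, 0.25] + [0.05] * 10)
    for hemisphere in ("left", "right"):
        n = n_voxels_per_hemisphere
        xs, ys = _sample_positions(rng, n, ecc_range, hemisphere, foveal_exponent)
        flip = rng.uniform(size=n) < bilateral_fraction
        xs = np.where(flip, -xs, xs)
        areas = rng.choice(AREAS, size=n, p=area_w / area_w.sum())
        sub = rng.integers(1, 4, size=n)
        multi = rng.uniform(size=n) < multi_rf_fraction
        for i in range(n):
            ecc = float(np.hypot(xs[i], ys[i]))
            sigma = sigma_intercept + sigma_slope * ecc
            rf = GaussianRF(float(xs[i]), float(ys[i]), float(sigma))
            rfs, gains = [rf], [1.0]
            if multi[i] and abs(xs[i]) > 1e-6:
                rfs.append(GaussianRF(float(-xs[i]), float(ys[i]), float(sigma)))
                gains.append(1.0)
            voxels.append(Voxel(voxel_id=vid, rfs=tuple(rfs), gains=tuple(gains),
                                hemisphere=hemisphere, area=str(areas[i]),
                                sub_roi=int(sub[i])))
            vid += 1
    return GroundTruthCortex(voxels=voxels, seed=seed)


def apply_lesion(cortex: GroundTruthCortex, lesion: LesionSpec) -> GroundTruthCortex:
    """Return a copy of the cortex with the lesion applied.

    Voxels whose *primary* RF center falls inside the lesioned VF region
    are silenced or attenuated; spared islands stay intact.
    """
    if lesion.mode not in ("silence", "attenuate"):
        raise ValueError(f"unknown lesion mode {lesion.mode!r}")
    if lesion.mode == "attenuate" and lesion.gain == 1.0:
        return GroundTruthCortex(voxels=list(cortex.voxels), seed=cortex.seed,
                                 lesions=list(cortex.lesions))
    out = []
    for v in cortex.voxels:
        rf = v.primary_rf
        if bool(lesion.contains(rf.x0, rf.y0)):
            if lesion.mode == "silence":
                out.append(replace(v, lesion="silenced", lesion_gain=0.0))
            else:
                out.append(replace(v, lesion="attenuated", lesion_gain=lesion.gain))
        else:
            out.append(v)
    return GroundTruthCortex(voxels=out, seed=cortex.seed,
                             lesions=cortex.lesions + [lesion])


def simulate_bold(
    cortex: GroundTruthCortex,
    apertures: Sequence[StimulusAperture],
    hrf: HRFSpec,
    noise_sd: float | None = None,
    snr: float | None = None,
    amplitude: float = 1.0,
    baseline: float = 100.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Simulate raw BOLD for every voxel and scan.

    Per voxel: gain-weighted sum of per-RF predictions (lesion gain
    applied) + baseline + i.i.d. Gaussian noise.  If ``snr`` is given
    instead of ``noise_sd``, the noise SD is set to
    ``mean responsive-voxel signal SD / snr`` (one scalar per cohort, so
    silenced voxels receive comparable noise).

    Returns a list of ``(n_voxels, n_frames)`` arrays (one per scan, in
    aperture order) and the voxel label table.
    """
    rng = np.random.default_rng(seed)
    banks = [build_prediction_bank([ap], hrf, cycle_average=False) for ap in apertures]
    scans = []
    for bank in banks:
        clean = np.zeros((len(cortex.voxels), bank.n_frames))
        for i, v in enumerate(cortex.voxels):
            g_lesion = {"intact": 1.0, "silenced": 0.0}.get(v.lesion, v.lesion_gain)
            if g_lesion == 0.0:
                continue
            for rf, g in zip(v.rfs, v.gains):
                clean[i] += g_lesion * g * bank.gaussian_prediction(rf.x0, rf.y0, rf.sigma)
        scans.append(baseline + amplitude * clean)
    if noise_sd is None:
        if snr is None:
            noise_sd = 0.0
        else:
            sds = [s.std(axis=1) for s in scans]
            responsive = np.concatenate(sds)[np.concatenate(sds) > 1e-12]
            if responsive.size == 0:
                raise ValueError("no responsive voxels; cannot set noise from SNR")
            noise_sd = float(responsive.mean()) / snr
    noisy = [s + rng.normal(0.0, noise_sd, size=s.shape) for s in scans]
    return noisy, cortex.labels()


# ---------------------------------------------------------------------------
# Perimetry
# ---------------------------------------------------------------------------

def _grid_24_2() -> np.ndarray:
    """Standard Humphrey 24-2 lattice (54 points, right-eye convention).

    Points sit at odd multiples of 3 deg; rows at |y| = 21 span |x| <= 9,
    |y| = 15 span |x| <= 15, |y| <= 9 span |x| <= 21, plus the two nasal
    points at (27, +-3).
    """
    pts = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        if abs(y) == 21:
            max_x = 9
        elif abs(y) == 15:
            max_x = 15
        else:
            max_x = 21
        for x in range(-max_x, max_x + 1, 6):
            pts.append((x, y))
    pts += [(27, 3), (27, -3)]
    return np.array(pts, float)


def _grid_30_2() -> np.ndarray:
    """Standard Humphrey 30-2 lattice (76 points at odd multiples of 3)."""
    pts = []
    for y in range(-27, 28, 6):
        for x in range(-27, 28, 6):
            if np.hypot(x, y) <= 29.5:
                pts.append((x, y))
    return np.array(pts, float)


@dataclass
class PerimetryGrid:
    """Perimetry result on a standard lattice.

    ``values`` are dB sensitivities (HFA mode; <= 41 dB, floor 0) or
    0/1 seen flags (Esterman mode).
    """

    locations: np.ndarray
    values: np.ndarray
    grid_type: str
    mode: str = "db"            # db | total_deviation | binary
    normal_db: float = 30.0
    floor_db: float = 0.0

    def in_field(self, radius: float = 6.5) -> np.ndarray:
        return np.hypot(self.locations[:, 0], self.locations[:, 1]) <= radius

    def blind_mask(self, threshold_db: float = 5.0) -> np.ndarray:
        if self.mode == "binary":
            return self.values < 0.5
        if self.mode == "total_deviation":
            return self.values <= threshold_db - self.normal_db
        return self.values <= threshold_db


def generate_perimetry(
    cortex: GroundTruthCortex,
    grid_type: str = "24-2",
    noise_sd_db: float = 1.0,
    mode: str = "db",
    seed: int = 0,
) -> PerimetryGrid:
    """Perimetry matched to the cortex's lesions.

    Locations inside any lesioned VF region (outside spared islands) get
    floor sensitivity (0 dB, or "missed" in Esterman/binary mode);
    sighted locations get an age-normal ~30 dB plus measurement noise.
    Attenuated regions are perimetrically blind too: near-threshold light
    detection is abolished even where suprathreshold stimulation still
    evokes a (reduced) cortical response — the dissociation that makes
    such regions interesting for fMRI-based field mapping.
    """
    if grid_type == "24-2":
        locs = _grid_24_2()
    elif grid_type == "30-2":
        locs = _grid_30_2()
    elif grid_type == "esterman":
        locs = _grid_30_2()
        mode = "binary"
    else:
        raise ValueError(f"unknown grid_type {grid_type!r}")
    rng = np.random.default_rng(seed)
    normal = 30.0
    vals = np.full(len(locs), normal)
    for lesion in cortex.lesions:
        inside = lesion.contains(locs[:, 0], locs[:, 1])
        vals[inside] = 0.0
    if mode == "binary":
        return PerimetryGrid(locations=locs, values=(vals > 5.0).astype(float),
                             grid_type=grid_type, mode="binary")
    sighted = vals > 0
    vals = vals + np.where(sighted, rng.normal(0.0, noise_sd_db, size=len(locs)), 0.0)
    vals = np.clip(vals, 0.0, 41.0)
    if mode == "total_deviation":
        vals = vals - normal
    return PerimetryGrid(locations=locs, values=vals, grid_type=grid_type, mode=mode)
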