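"""End-to-end study driver: configuration, simulation, both fits,
reconstruction, classification and comparison, with a run manifest.

The stages mirror the analysis flow: simulate (or load) cohort BOLD ->
fit pRF -> fit MP -> reconstruct coverage / total-deviation maps against
a normative control map -> compare techniques and perimetry.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .bold import HRFSpec, average_cycles
from .cohort import (GroundTruthCortex, LesionSpec, apply_lesion,
                     generate_perimetry, generate_retinotopy, simulate_bold)
from .compare import (contribution_table, contribution_stats, linear_vs_polynomial,
                      perimetry_concordance, pool_sensitivities, qq_points)
from .forward import PredictionBank, build_prediction_bank
from .microprobe import MPSettings, ProbeMap, mp_inclusion, run_micro_probing_batch
from .prf import GridSpec, build_grid, fit_cohort
from .reconstruction import (CI_LEVELS, FLOOR_DB, CoverageMap, build_normative_map,
                             ci_boundaries, classify_deviation, combine_and_normalize,
                             coverage_from_prfs, coverage_from_probes,
                             total_deviation_db)
from .stimulus import StimulusAperture, StimulusDesign, build_wedge_ring


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All knobs of one study run, with the study-condition defaults."""

    design: StimulusDesign = dc_field(default_factory=StimulusDesign)
    hrf: HRFSpec = dc_field(default_factory=HRFSpec)
    grid: GridSpec = dc_field(default_factory=GridSpec)
    mp: MPSettings = dc_field(default_factory=MPSettings)
    n_pix: int = 101
    ve_min: float = 0.15
    ecc_max: float = 6.5
    floor_db: float = FLOOR_DB
    ci_levels: tuple = CI_LEVELS
    n_controls: int = 8
    n_voxels_per_hemisphere: int = 1000
    snr: float = 1.0
    refine: bool = True
    lesion: LesionSpec | None = dc_field(
        default_factory=lambda: LesionSpec(region="right_hemifield", mode="silence"))
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.ve_min <= 1.0:
            raise ConfigError(f"ve_min must be in [0, 1], got {self.ve_min}")
        if self.ecc_max <= 0:
            raise ConfigError("ecc_max must be positive")
        if self.floor_db >= 0:
            raise ConfigError("floor_db must be negative")
        if self.n_controls < 2:
            raise ConfigError("need at least two controls for a normative map")
        if self.mp.n_probes < 1:
            raise ConfigError("n_probes must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            d["design"] = StimulusDesign(**d["design"])
        if "hrf" in d and isinstance(d["hrf"], dict):
            d["hrf"] = HRFSpec(**d["hrf"])
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = GridSpec(**d["grid"])
        if "mp" in d and isinstance(d["mp"], dict):
            d["mp"] = MPSettings(**d["mp"])
        if "lesion" in d and isinstance(d["lesion"], dict):
            lj = dict(d["lesion"])
            if "spared_islands" in lj:
                lj["spared_islands"] = tuple(tuple(t) for t in lj["spared_islands"])
            d["lesion"] = LesionSpec(**lj)
        if "ci_levels" in d:
            d["ci_levels"] = tuple(d["ci_levels"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def build_scan_pair(design: StimulusDesign, n_pix: int
                    ) -> tuple[StimulusAperture, StimulusAperture]:
    """The two mapping scans: cw/expanding and ccw/contracting."""
    return (build_wedge_ring(design, n_pix),
            build_wedge_ring(design.reversed_direction(), n_pix))


def preprocess(raw_scans: list[np.ndarray], design: StimulusDesign) -> np.ndarray:
    """Cycle-average each scan and concatenate along time (the analysis
    series both estimators are fitted against)."""
    return np.concatenate([average_cycles(s, design) for s in raw_scans], axis=-1)


@dataclass
class ParticipantResult:
    participant: str
    prf: pd.DataFrame
    probe_maps: list[ProbeMap]
    mp_included: np.ndarray
    cm_prf: CoverageMap
    cm_mp: CoverageMap


def reconstruct_prf_cm(prf: pd.DataFrame, extent: float = 6.5) -> CoverageMap:
    """Per-hemisphere VE-weighted Gaussian sums, averaged and normalised.
    A hemisphere with no included voxel contributes a zero map."""
    parts = [coverage_from_prfs(prf[prf["hemisphere"] == h], extent=extent,
                                scope=f"{h}_hemisphere", allow_empty=True)
             for h in ("left", "right")]
    return combine_and_normalize(parts)


def reconstruct_mp_cm(probe_maps: list[ProbeMap], labels: pd.DataFrame,
                      ve_min: float = 0.15, extent: float = 6.5) -> CoverageMap:
    """Per hemispheric sub-ROI sums of included voxels' binned maps,
    averaged over the six sub-ROIs and normalised."""
    by_id = {pm.voxel_id: pm for pm in probe_maps}
    parts = []
    for h in ("left", "right"):
        for s in (1, 2, 3):
            sel = labels[(labels["hemisphere"] == h) & (labels["sub_roi"] == s)]
            maps = [by_id[v] for v in sel["voxel_id"] if v in by_id
                    and mp_inclusion(by_id[v], ve_min)]
            parts.append(coverage_from_probes(maps, scope=f"{h}_sub{s}",
                                              extent=extent, allow_empty=True))
    return combine_and_normalize(parts)


def analyze_participant(
    participant: str,
    raw_scans: list[np.ndarray],
    labels: pd.DataFrame,
    design: StimulusDesign,
    bank: PredictionBank,
    grid,
    config: RunConfig,
    seed: int,
    keep_probes: bool = False,
) -> ParticipantResult:
    """Fit both estimators on one participant's data and build both CMs."""
    data = preprocess(raw_scans, design)
    prf = fit_cohort(data, labels, bank, grid=grid, refine=config.refine,
                     ve_min=config.ve_min, ecc_max=config.ecc_max)
    probe_maps = run_micro_probing_batch(data, bank, config.mp, seed=seed,
                                         voxel_ids=labels["voxel_id"].to_numpy())
    included = np.array([mp_inclusion(pm, config.ve_min) for pm in probe_maps])
    cm_prf = reconstruct_prf_cm(prf, extent=config.ecc_max)
    cm_mp = reconstruct_mp_cm(probe_maps, labels, ve_min=config.ve_min,
                              extent=config.ecc_max)
    if not keep_probes:
        # the binned maps carry everything downstream stages need; raw
        # probes for a whole cohort would hold gigabytes
        for pm in probe_maps:
            pm.probes = np.empty((0, 3), dtype=np.float32)
    return ParticipantResult(participant=participant, prf=prf,
                             probe_maps=probe_maps, mp_included=included,
                             cm_prf=cm_prf, cm_mp=cm_mp)


@dataclass
class StudyResult:
    """Everything the downstream statistics need from one simulated study."""

    controls: dict[str, ParticipantResult]
    patients: dict[str, ParticipantResult]
    normative: dict[str, object]                 # technique -> NormativeMap
    control_td: dict[str, dict[str, object]]     # technique -> id -> classified TD
    patient_td: dict[str, dict[str, object]]
    boundaries: dict[str, dict]                  # technique -> CI boundary table
    cortices: dict[str, GroundTruthCortex]
    perimetry: dict[str, object]


def run_study(config: RunConfig, patients: dict[str, LesionSpec] | None = None,
              progress: bool = False) -> StudyResult:
    """Simulate and analyse a full cohort under ``config``.

    Controls differ from patients only by the absence of a lesion; the
    controls' TD maps use leave-one-out normative maps, the patients'
    the all-control normative map.  Classification boundaries come from
    the pooled control TD cells per technique.
    """
    config.validate()
    if patients is None:
        patients = {"P1": config.lesion} if config.lesion is not None else {}
    rng_root = np.random.default_rng(config.seed)
    apertures = build_scan_pair(config.design, config.n_pix)
    bank = build_prediction_bank(apertures, config.hrf)
    grid = build_grid(bank, config.grid)

    cortices: dict[str, GroundTruthCortex] = {}
    results: dict[str, ParticipantResult] = {}
    perimetry = {}
    ids = [f"C{i + 1}" for i in range(config.n_controls)] + list(patients)
    for pid in ids:
        sub_seed = int(rng_root.integers(2**31 - 1))
        cortex = generate_retinotopy(config.n_voxels_per_hemisphere,
                                     ecc_range=(0.25, config.ecc_max),
                                     seed=sub_seed)
        if pid in patients:
            lesions = patients[pid]
            if isinstance(lesions, LesionSpec):
                lesions = [lesions]
            for lesion in lesions:
                cortex = apply_lesion(cortex, lesion)
            perimetry[pid] = generate_perimetry(cortex, seed=sub_seed + 1)
        raw, labels = simulate_bold(cortex, apertures, config.hrf,
                                    snr=config.snr, seed=sub_seed + 2)
        results[pid] = analyze_participant(pid, raw, labels, config.design,
                                           bank, grid, config, seed=sub_seed + 3)
        cortices[pid] = cortex
        if progress:
            print(f"  analysed {pid}", flush=True)

    controls = {pid: results[pid] for pid in ids if pid not in patients}
    patient_res = {pid: results[pid] for pid in patients}

    normative, control_td, patient_td, boundaries = {}, {}, {}, {}
    for tech in ("prf", "mp"):
        cms = {pid: (r.cm_prf if tech == "prf" else r.cm_mp)
               for pid, r in controls.items()}
        norm_all = build_normative_map(cms)
        normative[tech] = norm_all
        tds = {}
        for pid in controls:
            norm_loo = build_normative_map(cms, exclude_id=pid)
            tds[pid] = total_deviation_db(cms[pid], norm_loo,
                                          floor_db=config.floor_db)
        pooled = np.concatenate([td.values() for td in tds.values()])
        bounds = ci_boundaries(pooled, config.ci_levels)
        boundaries[tech] = bounds
        for pid in tds:
            classify_deviation(tds[pid], bounds)
        control_td[tech] = tds
        ptd = {}
        for pid, r in patient_res.items():
            cm = r.cm_prf if tech == "prf" else r.cm_mp
            td = total_deviation_db(cm, norm_all, floor_db=config.floor_db)
            ptd[pid] = classify_deviation(td, bounds)
        patient_td[tech] = ptd

    return StudyResult(controls=controls, patients=patient_res,
                       normative=normative, control_td=control_td,
                       patient_td=patient_td, boundaries=boundaries,
                       cortices=cortices, perimetry=perimetry)


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 patients: dict[str, LesionSpec] | None = None) -> dict:
    """Execute all stages, write artifacts, and return the run manifest."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(config=config.to_dict(), config_hash=config.config_hash(),
                          seed=config.seed, stages=[])
    t0 = time.time()

    def stage(name):
        manifest["stages"].append(dict(name=name, elapsed_s=round(time.time() - t0, 2)))

    apertures = build_scan_pair(config.design, config.n_pix)
    for i, ap in enumerate(apertures, start=1):
        vio.write_aperture(ap, out_dir / f"aperture_scan{i}.nii")
    stage("stimulus")

    result = run_study(config, patients=patients)
    stage("simulate_and_fit")

    excl = {}
    for pid, r in {**result.controls, **result.patients}.items():
        vio.write_prf_table(r.prf, out_dir / f"prf_{pid}.csv")
        excl[pid] = r.prf.attrs.get("exclusion_fractions", {})
    manifest["prf_exclusion_fractions"] = excl
    stage("fit_prf")

    for pid, r in {**result.controls, **result.patients}.items():
        np.savetxt(out_dir / f"mp_cm_{pid}.csv", r.cm_mp.grid, delimiter=",")
    stage("fit_mp")

    for tech in ("prf", "mp"):
        vio.write_map(result.normative[tech].grid, out_dir / f"normative_{tech}.csv",
                      meta=dict(technique=tech,
                                provenance=result.normative[tech].provenance))
        for pid, td in result.patient_td[tech].items():
            vio.write_map(td.db, out_dir / f"td_{tech}_{pid}.csv",
                          meta=dict(boundaries=td.boundaries, floor=td.floor_db))
        manifest.setdefault("ci_boundaries", {})[tech] = {
            str(k): list(v) for k, v in result.boundaries[tech].items()}
    stage("reconstruct")

    comparison = {}
    for tech in ("prf", "mp"):
        pooled = pool_sensitivities(list(result.control_td[tech].values()),
                                    "controls", tech)
        comparison[f"{tech}_control_90ci"] = list(pooled.boundaries[90])
    manifest["comparison"] = comparison
    stage("compare")

    manifest["n_stages"] = len(manifest["stages"])
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest
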