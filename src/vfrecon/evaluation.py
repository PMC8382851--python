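"""End-to-end validation experiments on synthetic cohorts.

Each function runs one self-contained experiment — simulate ground
truth, run the estimator(s), measure the result — and returns plain
numbers.  The acceptance script and the end-to-end tests are built on
them, and they are convenient for benchmarking parameter changes; all
randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .bold import GaussianRF
from .cohort import LesionSpec, generate_retinotopy, generate_perimetry, simulate_bold
from .compare import perimetry_concordance
from .forward import PredictionBank, build_prediction_bank
from .microprobe import MPSettings, run_micro_probing_batch
from .pipeline import RunConfig, build_scan_pair, preprocess, reconstruct_mp_cm, run_study
from .prf import build_grid, exhaustive_fine_search, fit_cohort, grid_search_fit, refine_fit
from .reconstruction import ci_boundaries, total_deviation_db
from .stimulus import StimulusDesign, time_average_map

# spared-island geometry: centered on a standard perimetry lattice point
# (3, -3) so the blind-but-responsive question is actually probed by the
# 30-2 grid; wholly inside the lost right hemifield and the 6.5-deg field
DEFAULT_ISLAND = (3.0, -3.0, 1.5)


def _sub_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def scan_arithmetic(design: StimulusDesign | None = None) -> dict:
    """Timing bookkeeping of one mapping scan."""
    design = design or StimulusDesign()
    return dict(
        scan_duration_s=design.total_duration_s,
        n_frames=design.n_frames,
        acquired_volumes=design.acquired_volumes(n_dummy=4),
    )


def top_decile_centroid(probes: np.ndarray) -> tuple[float, float]:
    """VE-weighted centroid of the top-decile (by VE) probes."""
    top = probes[probes[:, 2] >= np.quantile(probes[:, 2], 0.9)]
    w = top[:, 2].sum()
    return float((top[:, 0] * top[:, 2]).sum() / w), \
        float((top[:, 1] * top[:, 2]).sum() / w)


def prf_recovery_experiment(bank: PredictionBank, grid, n_voxels: int = 200,
                            snr: float = 1.0, seed: int = 0,
                            apertures=None, hrf=None) -> dict:
    """Ground-truth recovery of (x0, y0, sigma) by the full pRF fit."""
    s_cortex, s_noise = _sub_seeds(seed, 2)
    cortex = generate_retinotopy(n_voxels // 2, seed=s_cortex)
    raw, labels = simulate_bold(cortex, apertures, hrf, snr=snr, seed=s_noise)
    data = preprocess(raw, apertures[0].design)
    fits = fit_cohort(data, labels, bank, grid=grid, refine=True)
    truth = cortex.truth().merge(fits, on="voxel_id", suffixes=("_true", "_fit"))
    return dict(
        median_abs_dx=float(np.median(np.abs(truth.x0_true - truth.x0_fit))),
        median_abs_dy=float(np.median(np.abs(truth.y0_true - truth.y0_fit))),
        median_abs_dsigma=float(np.median(np.abs(truth.sigma_true - truth.sigma_fit))),
        n=len(truth),
    )


def oracle_equivalence_experiment(bank: PredictionBank, grid, n_voxels: int = 20,
                                  seed: int = 0) -> dict:
    """Refined fit vs exhaustive 0.01-deg fine-grid search on noiseless voxels."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_voxels):
        ecc = 0.5 + 5.0 * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        x, y = ecc * np.cos(ang), ecc * np.sin(ang)
        s = 0.2 + 0.25 * ecc
        data = bank.gaussian_prediction(x, y, s)
        coarse = grid_search_fit(data, grid)
        model = refine_fit(data, coarse, bank)
        ox, oy, osig, _ = exhaustive_fine_search(
            data, bank, (model.x0, model.y0, model.sigma))
        worst = max(worst, abs(model.x0 - ox), abs(model.y0 - oy),
                    abs(model.sigma - osig))
    return dict(max_param_discrepancy=float(worst), n=n_voxels)


def mp_prf_agreement_experiment(bank: PredictionBank, grid, n_voxels: int = 50,
                                snr: float = 1.0, seed: int = 0,
                                apertures=None, hrf=None,
                                mp: MPSettings = MPSettings(),
                                ve_min: float = 0.3) -> dict:
    """Median distance between MP top-decile centroids and pRF centers."""
    s_cortex, s_noise, s_mp = _sub_seeds(seed, 3)
    cortex = generate_retinotopy(n_voxels // 2, seed=s_cortex)
    raw, labels = simulate_bold(cortex, apertures, hrf, snr=snr, seed=s_noise)
    data = preprocess(raw, apertures[0].design)
    fits = fit_cohort(data, labels, bank, grid=grid, refine=True)
    maps = run_micro_probing_batch(data, bank, mp, seed=s_mp,
                                   voxel_ids=labels["voxel_id"].to_numpy())
    dists = []
    for (_, row), pm in zip(fits.iterrows(), maps):
        if row["ve"] < ve_min:
            continue
        cx, cy = top_decile_centroid(pm.probes)
        dists.append(np.hypot(cx - row["x0"], cy - row["y0"]))
    return dict(median_distance=float(np.median(dists)), n=len(dists))


def bimodal_detection_experiment(bank: PredictionBank, grid, n_voxels: int = 40,
                                 seed: int = 0, apertures=None, hrf=None,
                                 mp: MPSettings = MPSettings(),
                                 ve_min: float = 0.15) -> dict:
    """Noiseless equal-gain mirror-pair voxels: fraction whose MP map shows
    at least two supra-threshold clusters (the single-Gaussian fit always
    commits to one center)."""
    s_cortex, s_mp = _sub_seeds(seed, 2)
    cortex = generate_retinotopy(n_voxels, multi_rf_fraction=1.0, seed=s_cortex)
    keep = [v for v in cortex.voxels if len(v.rfs) == 2][:n_voxels]
    data = np.vstack([
        sum(g * bank.gaussian_prediction(rf.x0, rf.y0, rf.sigma)
            for rf, g in zip(v.rfs, v.gains))
        for v in keep])
    maps = run_micro_probing_batch(data, bank, mp, seed=s_mp)
    detected = 0
    for pm in maps:
        _, n_clusters = ndimage.label(pm.binned_max >= ve_min)
        if n_clusters >= 2:
            detected += 1
    # the conventional fit on the same voxels: always a single center
    prf_centers = [grid_search_fit(data[i], grid) for i in range(min(5, len(keep)))]
    return dict(detection_fraction=detected / len(keep), n=len(keep),
                prf_centers_per_voxel=1 if prf_centers else 0)


def _cell_grid(n_bins: int = 26, extent: float = 6.5):
    w = 2.0 * extent / n_bins
    c = -extent + w * (np.arange(n_bins) + 0.5)
    X, Y = np.meshgrid(c, c)
    return X, Y


def scotoma_study(config: RunConfig, island=DEFAULT_ISLAND,
                  progress: bool = False) -> dict:
    """Full simulated study: 8 controls, one hemianopic patient (P1, right
    hemifield silenced) and one patient with an attenuated spared island
    (P2).  Returns classification metrics for the scotoma, the sighted
    field, control specificity, the island comparison and perimetry
    concordance."""
    patients = {
        "P1": LesionSpec("right_hemifield", "silence"),
        "P2": [LesionSpec("right_hemifield", "silence", spared_islands=(island,)),
               LesionSpec("disc", "attenuate", gain=0.5, disc=island)],
    }
    res = run_study(config, patients=patients, progress=progress)
    X, Y = _cell_grid(extent=config.ecc_max)
    disc = np.hypot(X, Y) <= config.ecc_max
    out: dict = {}
    for tech in ("prf", "mp"):
        td = res.patient_td[tech]["P1"]
        scotoma = (X > 0.5) & disc & td.valid      # cells fully inside the lost field
        sighted = (X < -0.5) & disc & td.valid
        below = td.labels == "below"
        within_or_above = (td.labels == "within") | (td.labels == "above")
        out[f"scotoma_below_pct_{tech}"] = float(100 * below[scotoma].mean())
        out[f"sighted_within_or_above_pct_{tech}"] = float(
            100 * within_or_above[sighted].mean())
        fr = [100.0 * ((t.labels == "within") & t.valid).sum() / t.valid.sum()
              for t in res.control_td[tech].values()]
        out[f"control_within_pct_{tech}"] = [float(f) for f in fr]
        out[f"control_within_max_abs_dev_pp_{tech}"] = float(
            max(abs(f - 90.0) for f in fr))
        td2 = res.patient_td[tech]["P2"]
        cx, cy, r = island
        in_island = (np.hypot(X - cx, Y - cy) <= r) & disc & td2.valid
        wa2 = (td2.labels == "within") | (td2.labels == "above")
        out[f"island_within_or_above_cells_{tech}"] = int(wa2[in_island].sum())
        out["island_cells_total"] = int(in_island.sum())
    peri = generate_perimetry(res.cortices["P2"], grid_type="30-2",
                              seed=config.seed + 1)
    rep = perimetry_concordance(res.patient_td["mp"]["P2"], peri)
    out["blind_but_responsive_points"] = int(rep["retained_sensitivity_count"])
    out["n_scotoma_cells"] = int(((X > 0.5) & disc).sum())
    return out


def stimulus_bias_experiment(config: RunConfig, n_voxels: int = 1000,
                             seed: int = 0) -> dict:
    """Spearman rank correlation between the MP coverage map of a dense
    uniform (noise-free) control and the 12-TR moving-window time average
    of the stimulus, over the reconstructable disc."""
    apertures = build_scan_pair(config.design, config.n_pix)
    bank = build_prediction_bank(apertures, config.hrf)
    s_cortex, s_mp = _sub_seeds(seed, 2)
    cortex = generate_retinotopy(n_voxels, seed=s_cortex)
    raw, labels = simulate_bold(cortex, apertures, config.hrf, noise_sd=0.0)
    data = preprocess(raw, config.design)
    maps = run_micro_probing_batch(data, bank, config.mp, seed=s_mp,
                                   voxel_ids=labels["voxel_id"].to_numpy())
    cm = reconstruct_mp_cm(maps, labels, ve_min=config.ve_min,
                           extent=config.ecc_max)
    ta = np.mean([time_average_map(ap, 12) for ap in apertures], axis=0)
    edges = np.linspace(-config.ecc_max, config.ecc_max, 27)
    ix = np.clip(np.digitize(bank.xs, edges) - 1, 0, 25)
    ta26 = np.zeros((26, 26))
    cnt = np.zeros((26, 26))
    np.add.at(ta26, (ix[:, None].repeat(len(ix), 1), ix[None, :].repeat(len(ix), 0)), ta)
    np.add.at(cnt, (ix[:, None].repeat(len(ix), 1), ix[None, :].repeat(len(ix), 0)), 1.0)
    ta26 /= np.maximum(cnt, 1.0)
    X, Y = _cell_grid(extent=config.ecc_max)
    disc = np.hypot(X, Y) <= config.ecc_max
    rho = stats.spearmanr(cm.grid[disc], ta26[disc]).statistic
    return dict(spearman=float(rho), n=int(disc.sum()))


def db_unit_checks(seed: int = 0) -> dict:
    """Analytic dB-conversion and CI-boundary checks."""
    from .reconstruction import CoverageMap, NormativeMap
    ones = np.ones((26, 26))
    norm = NormativeMap(grid=ones, provenance=["synthetic"])
    td_unit = total_deviation_db(CoverageMap(grid=ones.copy(), technique="mp",
                                             normalized=True), norm)
    td_tenth = total_deviation_db(CoverageMap(grid=0.1 * ones, technique="mp",
                                              normalized=True), norm)
    td_zero = total_deviation_db(CoverageMap(grid=0.0 * ones, technique="mp",
                                             normalized=True), norm)
    rng = np.random.default_rng(seed)
    draws = rng.uniform(-1.0, 1.0, 10000)
    b = ci_boundaries(draws)
    err = max(abs(b[90][0] + 0.9), abs(b[90][1] - 0.9))
    return dict(
        db_at_unit_ratio=float(td_unit.db[0, 0]),
        db_at_ratio_0p1=float(td_tenth.db[0, 0]),
        db_at_zero_coverage=float(td_zero.db[0, 0]),
        uniform_ci90_max_abs_err=float(err),
    )
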