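# vfrecon

Reconstructing maps of the **visual field (VF)** from retinotopic-mapping
fMRI — for vision scientists and clinical researchers studying hemianopia and
other cortical field defects, where perimetry labels parts of the field
"blind" yet visual cortex may still respond to stimulation there.

The package implements, end to end:

* a **wedge-and-ring mapping stimulus** generator (18° wedge + logarithmic
  ring inside a 6.5° field; two 120 s cycles + 48 s blank per 288 s scan,
  one aperture step per 2 s TR);
* a shared **BOLD forward model**: an isotropic 2D-Gaussian receptive field
  `g(x,y) = exp(−((x−x₀)² + (y−y₀)²)/2σ²)`, overlap with the binary aperture,
  convolution with the canonical double-gamma HRF, cycle averaging;
* **conventional pRF mapping** — per voxel, grid search + nonlinear
  refinement of (x₀, y₀, σ) maximising variance explained (VE), amplitude
  constrained non-negative, inclusion gate VE > 15% and ecc ≤ 6.5°;
* **micro-probing (MP)** — Metropolis–Hastings sampling of 10 000 tiny
  probes (σ = 0.01°) per voxel over latent (x, y), every visited probe
  recorded with its VE; can expose multiple receptive fields per voxel;
* **VF reconstruction** — VE-weighted back-projection into 26×26 coverage
  maps, hemisphere/sub-ROI averaging, 0–1 normalisation, division by a
  normative control map (leave-one-out for controls), total deviation
  `10·log₁₀(cm/normative)` floored at −30 dB, and classification against the
  pooled control 90/96/98/99% CI boundaries (below / within / above normal
  limits);
* **comparison analyses** — sensitivity distributions, quantile–quantile
  comparison of the two techniques, linear-vs-polynomial fits with a
  dependent-correlation z test, informative-voxel contribution statistics
  (paired t, Mann–Whitney U), and concordance with Humphrey-style perimetry;
* a **synthetic cohort generator** (ground-truth retinotopy, hemianopic /
  quadrantanopic lesions with spared islands, HRF-convolved noisy BOLD,
  matched 24-2/30-2/Esterman perimetry), so the entire pipeline runs and is
  tested without any acquired data.

See `docs/methods.md` for the model details, parameter choices and known
limitations (including an identifiability analysis of the probe model under
this stimulus).

## Worked example

Simulate a small study (four controls and one hemianopic patient), fit both
estimators, and classify the patient's field against the controls:

```python
from vfrecon import RunConfig, run_study, LesionSpec

cfg = RunConfig(n_pix=61, n_controls=4, n_voxels_per_hemisphere=400,
                refine=False, seed=7)
res = run_study(cfg, patients={"P1": LesionSpec("right_hemifield", "silence")})

td = res.patient_td["mp"]["P1"]           # classified total-deviation map
left = (td.labels[:, :13] == "below").mean()
right = (td.labels[:, 13:] == "below").mean()
print(f"90% CI bounds (MP): ({res.boundaries['mp'][90][0]:.1f}, {res.boundaries['mp'][90][1]:.1f}) dB")
print(f"cells below normal limits — sighted half: {left:.0%}, lesioned half: {right:.0%}")
```

Output (about 75 s on one core):

```
90% CI bounds (MP): (-20.7, 5.5) dB
cells below normal limits — sighted half: 4%, lesioned half: 50%
```

Half of the lesioned hemifield's map columns (x > 0) hold cells whose
sampling density falls below the controls' 90% confidence band, against 4%
false positives in the sighted half; the remaining lesioned-half cells are
masked (no normative coverage, mostly at the field edge), spill-over from
intact receptive fields straddling the vertical meridian, or casualties of
the wide CI that so small a control group produces. The full-size cohort
(8 controls, 1000 voxels/hemisphere — the package defaults) tightens the
band to roughly (−9, +4) dB and pushes the lesioned-half detection above
80% of classifiable scotoma cells.

The command-line interface mirrors the library
(`vfrecon stimulus | fit-prf | fit-mp | run`); `vfrecon run --seed 7 --out out/`
executes simulate → fit → reconstruct → compare and writes every artifact
plus a manifest.

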