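# Methods

`vfrecon` reconstructs maps of the visual field (VF) from retinotopic-mapping
fMRI. Two estimators share one forward model; their outputs are back-projected
into VF coverage maps, referenced to a normative control map, expressed as
total deviation in dB and classified against control confidence intervals.
Everything can be exercised on a simulated hemianopic cohort, so the whole
pipeline is testable without acquired data.

## Forward model

A voxel's receptive field is an isotropic 2D Gaussian
`g(x, y) = exp(−((x−x0)² + (y−y0)²) / 2σ²)` in degrees of visual angle
(x rightward, y upward, fixation at the origin). The neural drive at frame *t*
is the overlap `p(t) = Σ_pixels g · S(·,·,t)` with the binary stimulus aperture
`S`, and the BOLD prediction is `baseline + amplitude · (p ⊛ h)` with `h` the
canonical double-gamma HRF (response gamma: delay 6 s, dispersion 1 s;
undershoot: delay 16 s, dispersion 1 s, ratio 6; kernel 32 s), sampled at the
TR and peak-normalised. Only the binary aperture matters — the checkerboard
carrier of the display is not modelled, since both estimators operate on the
aperture overlap.

The mapping stimulus is a simultaneous wedge and ring inside a 6.5°-radius
field: an 18°-wide wedge starting at 3 o'clock and rotating once per 120 s
cycle, and a ring sweeping eccentricity once per cycle with borders equally
spaced in `log(ecc + r0)`, `r0 = 0.35°` (a standard log-eccentricity spacing
approximating cortical magnification). One scan is two cycles plus a 48 s
blank — 288 s, one aperture step per 2 s TR, 144 frames; with four discarded
dummy volumes a scan acquires 148 volumes. Scan 1 runs clockwise/expanding,
scan 2 counter-clockwise/contracting with the wedge re-anchored at 3 o'clock.
The ring's duty cycle is not uniquely determined by a log-spacing rule alone;
we use 6 of the 60 per-cycle steps (a 10% duty). Widening it was examined and
rejected: a 20% duty both strengthens the iso-eccentric ambiguity discussed
below (mirror-course correlation 0.65 → 0.90) and increases the micro-probing
peak displacement. The aperture raster defaults to 101×101 pixels (≈0.13°
pitch, ≥4 pixels per map cell).

Analysis operates on cycle-averaged data: the two stimulus cycles of each scan
are averaged frame-wise (halving white-noise variance), the blank appended,
and both scans concatenated — 168 frames. Both estimators fit this series
against per-pixel predicted responses computed once per stimulus ("prediction
bank"): because overlap, HRF convolution and cycle averaging are all linear,
any Gaussian's prediction is a separable contraction of the bank, and a tiny
probe's prediction is bilinear interpolation between four pixel responses.

## Conventional pRF estimation

Grid search over 51×51 positions covering ±6.5° and 12 log-spaced σ in
[0.1°, 5°]; amplitude (constrained non-negative — the model describes positive
responses) and baseline are solved per candidate in closed form, so candidate
VE reduces to a clipped squared correlation. Ties break deterministically
toward smaller σ, then smaller eccentricity. The coarse optimum is polished by
Nelder–Mead over (x0, y0, σ); the refined model is only accepted if VE does
not decrease. Voxels whose coarse VE falls below 0.10 keep their coarse fit —
refinement is a local polish worth a few percent VE at most, and such voxels
are far below the inclusion gate. Inclusion requires raw VE > 0.15 and fitted
eccentricity ≤ 6.5°; exclusion fractions are reported per ROI group.

An independent cross-check, `exhaustive_fine_search`, enumerates a 0.01°-pitch
grid bracketing a fit (two-stage: 0.05° pass, then 0.01°); the optimizer and
the enumeration agree to within one pitch on noiseless voxels.

## Micro-probing

Micro-probing (MP) samples the visual field with 10 000 tiny probes per voxel
(fixed σ = 0.01°, far below pixel pitch) whose center is a pair of latent
variables explored by Metropolis–Hastings. Per step, the probe's amplitude
(≥ 0) and baseline are solved by least squares; the acceptance ratio uses an
i.i.d. Gaussian residual likelihood with the noise variance estimated from the
best coarse probe fit's residual (floored at 10⁻⁴ of the data variance). The
proposal is an isotropic 0.5° Gaussian step, with a 10% chance of proposing a
reflection across the vertical meridian instead — a symmetric proposal, so
plain MH acceptance applies; it lets chains visit genuinely bilateral
receptive fields, and measurably *reduces* contralateral leakage for
single-RF voxels because wrongly-seated chains can jump back. Proposals
outside the stimulated field's bounding square are rejected. All evaluated
states are recorded with their VE. The recorded states are split across ten
chain segments; every segment starts at the coarse probe-VE argmax unless a
residual analysis (candidate must keep ≥ 0.7× the peak coarse VE *and*
explain ≥ 15% of the voxel's variance — the inclusion bar — on the residual
after regressing earlier starts out) identifies a genuinely separate second
receptive field. A chain with no accepted move over 250 steps is re-dispersed
to a start location (counted in the result).

Probes are binned on a 26×26 grid spanning [−6.5°, +6.5°] (half-open bins,
last bin closed): a VE-*sum* map (the voxel's coverage map; conserves total
probe VE) and a per-bin *max*-probe-VE map. A voxel enters the reconstruction
iff some bin's best probe reaches VE ≥ 0.15 — the criterion is a VE, not a
density, so the per-bin maximum is used rather than the n-probes-dependent
sum.

### Identifiability under this stimulus (a real limitation)

Under the cycle-averaged wedge-and-ring design, probe time courses at
iso-eccentric locations are strongly correlated: the ring (identical timing at
equal eccentricity) plus the blank and HRF smoothing dominate the variance,
and the wedge's timing signature shrinks as σ grows. Measured consequences:
mirror-pair courses correlate at 0.65–0.95; a single Gaussian can fit an
equal-gain mirror *pair* with VE up to 0.92; the probe-VE landscape of a
single-RF voxel carries contralateral lobes at 0.5–1.0× its true peak; and
the probe-VE difference between two genuinely equal mirror RFs corresponds to
likelihood ratios of e¹⁰–e⁴⁰, so an exact sampler occupies essentially only
the stronger mode. Two practical upshots, both reported by the validation
experiments rather than hidden: (1) the MP probe peak is displaced from the
true RF center by a growing amount as σ grows (agreement with the pRF center
holds to ~0.3° only for σ ≲ 1°); (2) reliable *detection* of equal mirror
pairs is limited to pairs whose likelihoods are nearly symmetric — forcing
broader cross-meridian seeding was tried and rejected because it floods the
reconstructed blind field of simulated patients with spurious density. These
are properties of the probe model under this stimulus (the same family of
effects as the stimulus-configuration bias the technique is known to show),
not sampler defects.

## Visual-field reconstruction

*pRF route*: included voxels' Gaussians, weighted by clipped VE, are summed
per hemisphere ROI on the 26×26 cell grid (the same raster as MP, so the
techniques are cell-comparable); the two hemisphere maps are averaged and the
result divided by its maximum (0–1 normalisation). *MP route*: included
voxels' binned VE-sum maps are summed per hemispheric sub-ROI (3 per
hemisphere), the six maps averaged and normalised. A hemisphere emptied by a
lesion contributes a flagged zero map so the combination still runs.

The normative map is the average of the controls' normalised coverage maps —
leave-one-out when referencing a control itself — and captures the centrally
peaked density that cortical magnification imposes on every map. An
individual's total deviation is `10·log10(cm / normative)`, floored at −30 dB;
cells where the normative map is below 10⁻⁴ of its peak are masked rather than
floored. Confidence intervals at 90/96/98/99% are two-sided percentiles of the
pooled valid control TD cells (pooling across cells and controls; per-cell
boundaries would rest on 8 values each). Classification against the 90%
bounds is closed-interval: below / within / above normal limits.

## Synthetic cohort

The generator emulates: contralateral organisation (left hemisphere carries
x ≥ 0 RFs and vice versa, with configurable bilateral and two-RF fractions —
the second RF mirrored across the vertical meridian), eccentricity sampled
area-uniformly over [0.25°, 6.5°] (foveal oversampling available via an
exponent), a linear σ–eccentricity law σ = 0.2° + 0.25·ecc, voxels assigned
to the 12 visual areas (V1/V2 ≈ half the voxels; "early" = V1+V2,
"extrastriate" = the rest) and 3 sub-ROIs per hemisphere. BOLD is the
gain-weighted sum of per-RF predictions plus baseline and i.i.d. Gaussian
frame noise; "SNR 1.0" sets the noise SD to the cohort-mean temporal SD of
the clean responses, so silenced voxels receive comparable noise. Lesions
silence or attenuate voxels whose primary RF falls in a VF region (hemifield,
quadrant or disc), with optional spared islands; matched perimetry (standard
24-2/30-2 lattices, Esterman binary mode) floors lesioned locations at 0 dB —
including attenuated ones, encoding the dissociation in which near-threshold
detection is abolished while suprathreshold stimulation still drives a
(reduced) cortical response. Deliberately not modelled: cortical geometry,
temporal autocorrelation (cycle averaging already attenuates noise; an AR
extension would sit in the generator), physiological noise, eye movements,
and between-subject HRF variability — so passing tests demonstrate pipeline
correctness and desk-scale statistical behaviour, not performance on real
scanner data.

## Problem sizes and numerical choices

The validation experiments use 200 voxels for parameter recovery, 20 for the
optimizer-vs-enumeration check, 50 for MP/pRF agreement and 40 mirror pairs
for bilateral detection, all on the default 101-pixel raster; the simulated
study (8 controls, one hemianopic and one island patient) uses 1000 voxels
per hemisphere on a 61-pixel raster with coarse-grid-only pRF fits (0.26°
grid pitch against 0.5° map cells; nonlinear refinement changes the maps
negligibly there). Cohort density is the main determinant of how stable the
control CI boundaries are: below ~500 voxels/hemisphere several percent of a
control's MP map cells are empty, the pooled total-deviation distribution
carries a point mass at the −30 dB floor, and the 90% lower bound flips
between a finite value and the floor itself across seeds — at which point no
cell can classify below normal limits. 1000/hemisphere keeps the floor mass
near 1% and the bound stable; real cortex is denser still. The MP chain's
inner loop runs all voxels in lock-step in single precision.

Known limitations: per-control "within normal limits" fractions scatter
around the construction's 90% with an SD of a few percentage points that is
dominated by map-level 0–1-normalisation jitter (division by a noisy maximum),
most visibly for the smooth, tightly-distributed pRF maps; the MP probe-peak
displacement and limited mirror-pair detection described above; and perimetry
concordance within 6.5° rests on only four standard grid locations.
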