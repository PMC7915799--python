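# Methods

## Scope and model overview

The package implements the measurement chain used for automated
differential diagnosis of odontogenic maxillary sinusitis from CT
volumes: slice preprocessing, densitometric line profiles and their
shape signatures, five quantitative indicators, a hydraulic model of
nasal airflow resistance, and a normalized-Euclidean discriminant model
over group statistics of those indicators. No clinical data ships with
the package; a phantom generator provides volumes with exact voxel-level
ground truth so every stage is testable end to end.

## Phantom generator

The synthetic sinus is a sphere of configurable radius (default 12 mm)
inside a spherical bone shell (default 2.5 mm) embedded in soft-tissue
background, on an isotropic 64³ grid at 0.5 mm spacing (32 mm field of
view). Geometry that does not fit the grid is rejected with the
offending axis named.

* **Fluid levels** are gravity-horizontal: the fill plane is chosen by
  scanning candidate row heights for the one whose below-plane voxel
  share of the cavity is closest to the requested fraction. At 64³ this
  lands within well under 1 percentage point of the target.
  Polypous (mucosa-class) content fills a band directly above the fluid
  the same way.
* **Lesions**: a cyst is a soft-tissue sphere strictly inside the air
  cavity (so profiles crossing it show an extra border); a foreign body
  is a small metal-density sphere (2000 Hu); a perforation removes bone
  voxels in a cone around the straight-down direction, exposing the
  cavity to the soft-tissue background (40 Hu) — which is exactly what
  produces the "no bone peak" profile signature.
* **Ostium**: a vertical 2 mm-radius cylinder carved through the bone
  roof. Its open fraction is realised concentrically (air inside radius
  √f·r, mucosa outside), so the air voxel share approximates f; the
  carved voxel set is returned as the anastomosis reference mask and is
  excluded from the cavity denominator of x3/x4.
* **Intensities** come from a tissue→Hu map; defaults are air −1000,
  serous fluid 19, purulent fluid 37, mucosa/polyp 45, bone 700, foreign
  body 2000, background 40. The fluid values are the published cohort
  means for serous and purulent content; mucosa, bone, background and
  foreign-body values are generic CT-plausible defaults (no published
  values exist for them) and are configurable.
* **Impulse noise** replaces each voxel independently with the volume
  minimum or maximum (equal odds) at a stated probability, driven by a
  seeded generator; phantoms are bit-reproducible given their config.

The four fill presets (`conditional_norm`, `polyposis_60`, `serous_40`,
`mixed_30_20`) reproduce the schematic 0 / 60% polyp / 40% fluid /
30%+20% configurations; lesion presets add the cyst, perforation, and
foreign-body archetypes.

What the phantoms deliberately do not emulate: anatomical cavity shape
(real sinuses are not spheres), partial-volume blur at tissue borders,
beam-hardening and scanner noise textures, and mucosal thickening that
varies around the wall. Tests passing on phantoms therefore demonstrate
the correctness of the measurement chain, not segmentation robustness on
clinical scans (segmentation is an input here, not a capability).

## Preprocessing

Median filtering is 2-D per slice (radius 1 default, reflection at
edges), matching the fact that impulse interference lives on the
tomographic images. Hu display windowing maps
[center − width/2, center + width/2] linearly to [0, 255] with clipping
and half-up rounding (deterministic across platforms). Quantitative
density (x1) is only defined on Hu-calibrated volumes; the API refuses
8-bit input rather than inverting a window.

Volumes persist as PNG slice stacks with a JSON sidecar (spacing, unit,
window). 8-bit volumes round-trip bit-identically; Hu volumes are stored
as 16-bit PNG with a fixed −1024 intercept recorded in the sidecar
(exact for integer Hu in [−1024, 64511]). DICOM series are read through
pydicom with slope/intercept rescaling to Hu.

## Densitograms

Trajectories follow the parametric line between two pixel points with
parameter step Δt = 1/d, giving ⌈d⌉+1 samples (t = 1 always included).
Sampling is nearest-voxel by default (profiles report the pixel values
the image actually holds); bilinear interpolation is available for
smoother curves. The sinus centre is the rounded centroid of
content-class voxels on the chosen slice — all content classes count, so
the centre is invariant to filling. Radial fans span the downward
semicircle (default 13 rays at 15° spacing; the ray count is an
engineering default, not a published value) and are clipped to slice
bounds.

Signature classification is rule-based with Hu-scale default thresholds
t_air = −500, t_tissue = 0, t_bone = 300, t_foreign = 1500, a 200 Hu
bone-peak prominence over the interior median, and a 3-sample minimum
tissue plateau. These thresholds are engineering choices (no published
values exist) and must be restated when classifying 8-bit profiles.
Rules fire in fixed priority — FOREIGN_BODY, PERFORATION, CYST,
TISSUE_CONTENT, NORMAL — so the most specific evidence wins; a profile
with neither tissue content nor a bone peak is reported PERFORATION,
since the missing far border is the defining evidence. Fan-level
aggregation picks the highest-priority label with at least
`min_support` rays (default 1; raise it to guard against single-ray
artefacts).

## Indicators

x2–x4 are voxel-count ratios: x2 = air share of the supplied anastomosis
mask; x3 = (mucosa + cyst)/cavity; x4 = fluid/cavity, with the cavity
the union of content classes minus the anastomosis mask. Being relative,
they are stable across voxel sizes of the same geometry (verified across
48³–96³). The anastomosis reference region must be supplied (the phantom
provides its ostium mask); whether it is one cross-section or the canal
volume is absorbed by the mask definition. x1 is the plain mean of Hu
over fluid voxels, undefined (None) without fluid.

## Airflow model

Each passage is a series of sections (S, P, Δl, ξ) with hydraulic
diameter dh = 4S/P. Pressure loss sums Darcy friction and local losses,
λ = 64/Re below Re = 2300 and 0.32/Re^0.25 above (the transition
threshold is the classical pipe-flow value; the turbulent coefficient is
kept at 0.32 as published rather than the Blasius 0.3164, and both are
configurable). Air density 1.205 kg/m³; viscosity 1.81 × 10⁻⁵ Pa·s (a
standard dry-air value; only the density is published). Local-loss ξ
values default to 0 and are user-supplied per section. Evaluating the
full friction sum with λ(Re) automatically yields Δp linear in Q in the
laminar regime and ∝ Q^1.75 in the turbulent one, so no separate
regime-specific resistance constants are needed. The parallel-passage
split solves Δp₁(Q₁) = Δp₂(QΣ − Q₁) by Brent root finding to 10⁻⁸
relative tolerance; Δp is strictly increasing in Q, so the root is
unique. x5 is reported as A = Δp/Q in kPa/(L/s); geometry-derived and
measured (rhinomanometric) routes share this definition and agree by
construction.

## Discriminant model

Feature-wise separation uses δᵢ = |mᵢ⁽⁰⁾ − mᵢ⁽¹⁾|/σᵢ with the max-σ
rule; multiparameter δ is the root sum of squares, so δ² is additive
over disjoint feature subsets and the incremental curves δ(j)/per(j) are
monotone by construction. The error probability is per = 1 − Φ(δ/2)
with Φ the probability integral Φ(x) = erf(x/√2) (equivalently
per = 2(1 − Φ_N(δ/2))): this is the reading under which the published
(δ, per) pairs 3.34→0.1, 3.78→0.06, 3.36→0.09, 1.71→0.4 and 1.98→0.32
reproduce at printed precision, whereas interpreting Φ as the standard
normal CDF reproduces almost none. The standard-normal reading remains
available via an argument.

Degenerate spread (the norm group has σ = 0 for fluid volume, x4) is
handled explicitly: in two-group comparisons the max rule usually
resolves it; if both σ are zero and the means differ the feature is
flagged as infinitely separating and excluded from the finite sum. In
classification each cluster normalizes by its own σ; a σ = 0 feature is
skipped when the patient value sits exactly on the centre and otherwise
excludes that cluster (ranked last at infinite distance) — any fluid at
all rules out the norm cluster, which is the clinically sensible
behaviour. With diagonal covariance this distance coincides with the
Mahalanobis distance (implemented and cross-checked); full-covariance
refits are out of scope because no patient-level data exists.

Distance-derived "compliance weights" over the ranked clusters are a
softmax over negative squared distances — an explicit extrapolation
labelled as such, since no formula for these probabilities is published.

### Published vs recomputed distances

The published multiparameter δ values are not exactly recoverable from
the published group means/SDs via the stated formulas: norm vs acute
serous evaluates to ≈ 3.47 against the printed 3.34, and one published
table carries apparent transcription errors (a fluid density of 399 Hu
and shifted columns for the chronic group; the fixture carries the
values consistent across the other tables). Three published (δ, per)
pairs (3.16→0.12, 4.29→0.04, 2.18→0.31) are inconsistent with
per = 1 − Φ(δ/2) under any standard reading of Φ.
`tabulated_comparisons()` therefore exposes, for every pair, the printed
δ and per, the δ and per recomputed from the group statistics, and the
per evaluated at the printed δ — nothing is silently matched.

### Monte-Carlo recovery surrogate

The clinical reliabilities cannot be reproduced without patient-level
data. As a surrogate, 200 synthetic patients per group are drawn
feature-wise (independently, matching the model's independence
assumption) from each group's (m, σ) with a fixed seed and classified by
nearest cluster centre: every pathological group recovers its own
cluster far above the 20% chance level, and the dominant confusion falls
on the closest published pairs (acute purulent vs exacerbated chronic,
printed δ = 1.71). Draws are not clipped to [0, 100] for the percentage
indicators; clipping would distort the sampling distribution the model
assumes.

## Numerical choices and problem sizes

Half-up rounding wherever values are quantised (windowing, nearest
sampling, centroid rounding); ties in cluster ranking broken by
cluster-list order and flagged; all randomness (noise, cohorts) through
seeded `numpy` generators. Default problem sizes — 64³ phantoms, 13-ray
fans, 200 patients per simulated cohort — keep the full suite within a
couple of seconds while leaving voxelization error comfortably inside
the ±2 percentage-point tolerances used for phantom recovery; the
scale-invariance check runs the same geometry at 48³ and 96³.

## Known limitations

* Spherical cavity and uniform lining are idealisations; the signature
  thresholds are untuned against clinical densitograms.
* 2-D fans on one slice only; 3-D radial fans and oblique multiplanar
  reconstructions are not implemented.
* The channel geometry route expects section series as input; deriving
  them by segmenting airway voxels from scans is out of scope.
* DICOM support is read-only and minimal (slope/intercept rescale,
  instance ordering).
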