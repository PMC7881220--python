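# Methods

This note documents the models, conventions and design decisions behind
`plaquemap`, the phantom the tests run against, and what passing tests do
and do not establish about real data.

## The phantom generator

The generator (`plaquemap.synthetic`) emulates a multi-patient carotid
plaque MSI study: per patient an elliptical tissue cross-section with an
eccentric lumen, carrying smoothed-superellipse blobs for the histological
plaque components (necrotic core NC, fibrin, foam cells FC, erythrocytes,
calcium) on a base of unlabeled intima (`other_tissue`). Blob geometry is
jittered strongly between patients and weakly between sections of one
patient, mimicking how plaque morphology drifts along a vessel.

### Spectral model

Each species panel contains seven fixed anchor species frequently reported
in plaque imaging (cholesteryl ion 369.350, 7-ketocholesterol 401.343,
CE 671.580, oxidized CE 685.567, SM(34:2) 701.571, TGs 929.768 and 955.774)
plus randomized fill species per class, drawn in class-typical m/z windows
within the acquired 300–1,200 range with ≥ 2.2 Da spacing and unique to
3 decimals. The intensity of species *s* (class *c*) at tissue pixel *x* is

```
I_s(x) = B_c · f_s · F_c(x) · fold_c(x) · ε(x) + a·B_c·|N(0,1)|
```

- `B_c` — per-class baseline (arbitrary units; all analyses are
  scale-invariant, since no per-class absolute scales are available for
  this kind of study).
- `f_s` — deterministic per-species factor in [0.6, 1.4].
- `F_c` — a smooth per-class, per-section spatial field,
  exp(heterogeneity · smoothed N(0,1)). Default amplitude **0.1**: the
  field models within-class abundance *texture*. At markedly larger
  amplitudes the fields become reproducible spatial components in their own
  right, which contradicts the phantom's declared component count (see
  "Rank selection" below); 0.1 keeps the declared ground truth
  self-consistent.
- `fold_c(x)` — the planted enrichment: the default map mirrors the
  associations the pipeline is meant to recover (SM and oxidized CE ×3 in
  NC, DG and TG ×3 in fibrin, PC ×2 in the cell-rich FC and erythrocyte
  areas). Folds are exact multipliers, so a noise-free phantom reproduces
  them to machine precision.
- `ε` — multiplicative lognormal pixel noise, σ = 0.3 by default, plus a
  small half-normal additive floor (a = 0.02) as a detector background.

Every species emits a first-isotopologue satellite at +1.00335 Da whose
per-pixel intensity is exactly `0.011 × carbon_count` times its (noisy)
parent — the first-¹³C approximation; satellites therefore survive into the
acquired peak list and must be removed by deisotoping.

Off-tissue and lumen pixels carry no signal at all.

### Ground truth and frames

Each section's segmentation mask is delivered in a displaced *histology
frame*: a hidden similarity transform (scale uniform in [0.8, 1.25],
translation drawn ±10 px around a fixed offset that keeps the histology
canvas covering the section; no rotation, matching the registration model)
maps histology to MSI coordinates, and ≥ 6 landmark pairs are written in
both frames. The `GroundTruth` record keeps the MSI-frame truth masks, the
transforms, the panel and the enrichment map.

`true_k`, the planted spatial component count, is the number of *distinct
enrichment signatures* plus one for the base tissue — FC and erythrocyte
areas share the PC signature and are deliberately one spectral component,
so the default phantom has true_k = 4, and a null phantom (no enrichment)
has true_k = 1.

### What the phantom does not model

No desorption/ionization physics, matrix effects, mass-resolution or
centroiding artifacts, pixel-to-pixel intensity drift, or misdrawn
histology. Passing recovery tests therefore shows the *pipeline logic* is
sound under realistic noise and study structure — not that any specific
clinical dataset would yield the same lipid lists.

## Preprocessing conventions

- **"Measured in a section"**: nonzero in ≥ 1% of that section's tissue
  pixels (minimum one). The presence threshold is a *strict* "more than
  30% of sections": at a 106-section scale, 32/106 is kept, 31/106 dropped.
- **Deisotoping**: peak B is a satellite iff a peak exists at
  mz(B) − 1.00335 within 0.02 Da *and* the median B/A intensity ratio over
  co-detected pixels is below 0.9 (lipids have < 90 carbons, so first
  isotopologues stay below ~1× their parent). Adduct gaps (Na−H 21.982,
  K−H 37.956, K−Na 15.974) are far outside the window and never flagged.
- **Log transform**: ln(1+x); the offset handles true zeros, and the base
  cannot affect correlation- or rank-based results. The raw-scale study is
  kept for display and for the non-log fold changes.
- **Display normalization**: per-m/z division by the 99th-percentile tissue
  intensity (robust to hot pixels), clipped to [0, 1].

## Spatial correlation

Plain per-section sample Pearson over tissue pixels, on raw intensities by
default (image-domain colocalization); pairs involving a constant image are
undefined (masked), never zero. Study averaging is the arithmetic per-cell
mean over the sections where the cell is defined — no Fisher z, matching
how such heatmaps are conventionally averaged in MSI work.

## NMF segmentation and rank selection

Multiplicative-update Frobenius NMF with random nonnegative initialization,
run to a relative-error tolerance; the objective is monotone under MU and
is checked every 10 iterations. After convergence the scale indeterminacy
is fixed canonically (H rows to unit L2 norm, magnitudes into W) — without
this, comparing weights across components (argmax assignment) is undefined.

Peaks are scaled to unit 99th percentile before pooling so high-abundance
classes do not dominate the factorization. The rank is chosen by consensus
clustering: a fixed random subsample of ≤ 2,000 pixels is factored from
`n_runs` initializations, pixels are hard-assigned to their argmax
component, and the dispersion ρ = (1/n²)·Σ 4(C − ½)² of the co-clustering
matrix is maximized over candidate ranks (ties to the smaller rank). Each
restart factors the subsample itself; factoring the full ~10⁵-pixel matrix
per restart per rank would dominate runtime without changing what the
consensus measures.

Two empirical properties of this selector are worth knowing:

- On phantoms with well-separated planted components it recovers the true
  rank reliably (≥ 80% of seeds for k ∈ {3, 4, 5} at σ = 0.3 in the
  acceptance suite).
- On *structureless* data dispersion does not decline with k — restarts on
  a fixed matrix tend to converge to similar local optima, so dispersion
  drifts mildly upward. Noise never reaches the near-binary consensus
  (ρ ≈ 0.8–1) that true structure produces, but rank selection on data
  without real cluster structure should be treated as unreliable.

Component m/z sets take peaks above 0.4 of the max-normalized component
spectrum. Max-normalization (not sum) is the chosen reading of "normalized
weight"; it makes the 0.4 cutoff a per-component relative threshold.

## Registration

Closed-form least squares for isotropic scale + translation
(s = Σ⟨p̃,q̃⟩/Σ‖p̃‖², t = q̄ − s·p̄). Rotation is excluded: the registration
model is translation+scaling only. Masks are resampled by nearest-neighbor
lookup through the inverse transform (labels are categorical and must not
be interpolated). Component mean spectra average log-scale intensities over
each label's MSI pixels, per section, with a 20-pixel minimum per component
to stabilize the mean; the "rest of the tissue" is every non-background,
non-target pixel, calcium included.

## OPLS-DA

Trygg–Wold deflation: orthogonal components (X-variation orthogonal to the
class contrast) are removed one at a time, then a single predictive
component is fit. X is centered and unit-variance scaled (the conventional
default for this analysis; Pareto and center-only scaling are available),
y is coded ±1 and centered. The orthogonal count is selected by adding
components while sevenfold cross-validated Q² improves by > 0.01, capped
at 3. Cross-validation is stratified and re-estimates all preprocessing
inside each training fold; Q² = 1 − PRESS/SS.

- **VIP**: VIP_j = √(p · Σ_a SSY_a w²_aj / Σ_a SSY_a) over the predictive
  plus orthogonal components with explained-y-variance weighting, so
  Σ VIP² equals the number of retained variables exactly. Orthogonal
  components explain (by construction) almost no y-variance, so VIP is
  effectively predictive-weight driven. VIP is unsigned; the *elevated*
  subset (positive in-minus-rest contrast) names the species characteristic
  of a component, and is what feeds the concordance analysis — the full
  VIP > 1 set also contains species depleted in the target because they
  mark a different component inside the "rest" class.
- **CV-ANOVA**: F = ((SS − PRESS)/df₁)/(PRESS/df₂) with df₁ = number of
  fitted components and df₂ = N − 1 − df₁, p from the F tail; PRESS ≥ SS
  gives p = 1. Under the null the test is mildly conservative but its
  rejection rate at 0.05 stays within [0.01, 0.10] (measured over 200 null
  datasets in the acceptance suite).
- **Permutation test**: class labels permuted (default 200×), Q²
  recomputed, p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1).
- **Acceptance rule**: models are fit per patient on that patient's
  (section, region) mean spectra; a patient is significant when R²Y > 0.5,
  Q² > 0.5 and CV-ANOVA p < 0.05, and the component's report is accepted
  when at least half of the modeled patients are significant (the 6-of-12
  pattern at the default study scale). VIPs aggregate across significant
  patients by median. A pooled-fit mode exists for comparison; per-patient
  is the default because it is robust to between-patient intensity scale
  differences.

## Univariate confirmation

Observations are per-section raw-scale mean intensities inside vs outside
the target label (sections lacking the label, or with zero outside mean,
are excluded). Fold changes are non-log ratios of those means. The Wilcoxon
signed-rank test drops zero differences, midranks ties, enumerates the
exact null by dynamic programming for n ≤ 25 and uses the tie-corrected
normal approximation with continuity correction above; results with < 5
informative pairs are flagged underpowered. ROC analysis treats the
in-label means as positives scoring above the cutoff; candidate cutoffs are
midpoints of adjacent sorted unique values, the reported cutoff maximizes
Youden's J (ties → lowest cutoff), and AUC comes from the rank statistic.
Section means (not pixels) are the ROC observations, matching the boxplot
construction of such analyses; a pixel-level variant can be built from
`paired_means` directly. No multiple-testing correction is applied by
default (raw p-values are reported); a Benjamini–Hochberg column is an
explicit extension the caller can add.

## Concordance

A VIP peak may belong to several NMF components' m/z sets (memberships
overlap); per histology component the table counts memberships and names
the plurality NMF component. Spatial agreement uses the Dice coefficient of
the component weight image binarized at its upper-quartile tissue weight
against each registered label region. Dice (not Jaccard) and the
upper-quartile threshold are declared conventions; the comparison is
qualitative by nature and no statistical test is attached to the counts.

## Problem sizes in the test and acceptance suites

The suites run on desk-scale phantoms chosen as this package's study
conditions: the end-to-end recovery phantom is 12 patients × 8 sections at
48×48 px with 3 species per class (60 acquired signals, 30 after
deisotoping); rank-recovery experiments use 20 sections at 64×64 px with
6 species per class and well-separated fold-3 components; null calibration
uses 16-observation, 8–10-variable datasets (200 CV-ANOVA / 100 permutation
replicates). Registration accuracy is measured over 100 noisy-landmark
trials at σ = 0.5 px.

## Known limitations

- No rotation or anisotropic scaling in registration; real histology/MSI
  pairs with rotational misalignment need an extended transform model.
- The dispersion-argmax rank selector is only trustworthy when genuine
  cluster structure exists (see above).
- CV-ANOVA degrees of freedom follow the published formulation; proprietary
  implementations may differ slightly in df conventions.
- The phantom's lipid-class m/z windows and baselines are stylized; tests
  built on them are deliberately scale-invariant.
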