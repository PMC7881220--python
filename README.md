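# plaquemap

Spatial lipid-pattern analysis of atherosclerotic plaque by MALDI mass
spectrometry imaging (MSI), as a tested, fully synthetic-data-driven
pipeline.

Advanced carotid plaques are heterogeneous: necrotic cores, fibrin-rich
thrombotic areas, foam cells, erythrocytes and calcifications coexist within
one cross-section. MALDI-MSI measures a centroided lipid mass spectrum at
every 45 µm pixel of a tissue section, so each m/z value becomes an image.
`plaquemap` implements the two complementary ways of mining such a study —
**unsupervised** spatial segmentation of the pooled spectra by non-negative
matrix factorization (NMF), and **histology-supervised** discriminant
modeling of plaque components — together with the preprocessing, image
registration, univariate confirmation and concordance analysis that connect
them. Because raw clinical MSI studies of this kind are rarely deposited,
the package ships a phantom generator that emulates the full study design
(12 patients, ~100 sections, ~200 peak signals in 7 lipid classes, isotope
satellites, lognormal noise, histology masks with hidden registration
transforms), with planted ground truth so that every stage of the pipeline
is testable end to end.

It is aimed at computational lipidomics/MSI researchers who want a
transparent, scriptable reference implementation of this analysis pattern.

## The methods at the core

- **Preprocessing** — peaks are kept when measured in more than 30% of all
  sections; first-isotopologue satellites (+1.00335 Da, intensity ratio
  below 0.9× the lighter partner) are removed while adducts of the same
  molecule are retained; intensities are ln(1+x)-transformed for statistics
  and normalized per m/z (99th percentile) for display.
- **Spatial correlation** — per-section Pearson correlation of lipid
  images over tissue pixels, averaged across the study and displayed in
  lipid-class blocks.
- **NMF segmentation** — multiplicative-update factorization X ≈ WH
  (pixels × peaks), with the component count chosen by maximizing the
  consensus **dispersion coefficient** ρ = (1/n²)·Σᵢⱼ 4(Cᵢⱼ − ½)² of the
  co-clustering matrix C over random restarts.
- **Registration** — least-squares translation+scaling from paired
  landmarks (q = s·p + t in closed form), nearest-neighbor mask resampling,
  and per-component mean spectra per section.
- **OPLS-DA** — two-class orthogonal projections to latent structures
  discriminant analysis (Trygg–Wold) of component-vs-rest mean spectra:
  unit-variance scaling, sevenfold cross-validated Q², CV-ANOVA and
  permutation validation, and VIP (variable influence on projection,
  Σ VIP² = number of variables). A component's model is accepted when
  R² > 0.5, Q² > 0.5 and CV-ANOVA p < 0.05 for at least half of the
  patients; its discriminative m/z set is median VIP > 1.0.
- **Univariate confirmation** — per-section in/out mean intensities on the
  raw scale, non-log fold changes, exact Wilcoxon signed-rank tests, and
  ROC cutoffs at the maximum of Youden's J.
- **Concordance** — each NMF component's m/z set (peaks above 0.4 of the
  max-normalized component spectrum) is cross-tabulated against each
  histology component's VIP set, and spatial agreement is scored by Dice
  overlap of thresholded weight images with registered masks.

## Worked example

```python
import plaquemap as pm

# a phantom study: 4 patients, 6 sections each, SM/oxCE enriched 3x in the
# necrotic core (NC), DG/TG 3x in fibrin, PC 2x in cell-rich areas
spec = pm.PhantomSpec(grid_shape=(48, 48))
study, truth = pm.generate_study(4, (6, 6), spec, seed=7)

study, peaks = pm.msi_data.preprocess_study(study)
print(len(study), "sections,", len(peaks), "peaks retained")

spectra = pm.oplsda.component_spectra_for_study(
    pm.log_transform(study), dict(truth.truth_masks))
dataset = pm.build_discriminant_dataset(spectra, "NC")
report = pm.evaluate_component_model(dataset, "NC", seed=0)
print("NC model accepted:", report.accepted,
      "| discriminative classes:",
      sorted(set(peaks.df.lipid_class.to_numpy()[report.discriminative_elevated])))
```

prints

```
24 sections, 30 peaks retained
NC model accepted: True | discriminative classes: ['SM', 'oxCE']
```

— 60 acquired signals reduce to the 30 monoisotopic species (every isotope
satellite is removed), and the necrotic-core discriminant model recovers
exactly the sphingomyelin and oxidized-cholesteryl-ester species that the
phantom planted as NC-enriched.

The same pipeline is available from the shell:

```sh
plaquemap simulate --patients 12 --sections-min 5 --sections-max 12 \
    --seed 1 --out study/
plaquemap preprocess study/ --out study.h5
plaquemap run-all --seed 1 --out report.json
```

## Layout

```
src/plaquemap/
  synthetic.py            phantom studies with planted ground truth
  msi_data.py             imzML/HDF5 I/O, peak selection, deisotoping
  spatial_correlation.py  class-sorted Pearson image correlation
  nmf.py                  NMF + consensus-dispersion rank selection
  registration.py         landmark transforms, masks, component spectra
  oplsda.py               OPLS-DA, VIP, Q2, CV-ANOVA, permutation tests
  univariate.py           fold changes, Wilcoxon, ROC/Youden
  concordance.py          VIP/NMF cross-tabulation, full pipeline
  cli.py                  `plaquemap` command group
docs/methods.md           model, parameters, design choices, limitations
```
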