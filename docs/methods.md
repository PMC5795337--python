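# Methods

This package re-implements, as tested reusable code driven by a synthetic
data generator, a LIBS-chemometrics workflow for identifying plant-product
varieties (the motivating case: four coffee cultivars coded 1–4) from
laser-induced breakdown spectra. This note documents the models, the
defaults and why, the numerical choices, and what the synthetic results do
and do not show.

## Pipeline

Stages run in a fixed order; every stage consumes and returns a
`SpectrumSet` (wavelength grid in nm, shots × wavelengths intensity matrix
in arbitrary units, per-shot metadata):

1. **Baseline correction** — negative intensities (detector noise) are
   clipped to zero. Clipping preserves peak heights; minimum subtraction,
   which shifts every value, is available behind `baseline_correct(...,
   method="min_subtract")`.
2. **Wavelet denoising** — discrete wavelet transform with an orthogonal
   basis (Daubechies-5) at decomposition level 10. Detail coefficients at
   every level are soft-thresholded at the Donoho universal threshold
   σ·√(2 ln N), with σ estimated per level as MAD/0.6745 of that level's
   coefficients; approximation coefficients pass through. Signal extension
   is symmetric and the reconstruction is trimmed to the input length.
   With `threshold_scale = 0` the transform round-trips to < 1e−8 relative
   error. The threshold rule is a standard choice; the workflow this
   follows names only the basis and level.
3. **Area normalization** — each spectrum is divided by its trapezoidal
   area over the stored grid, making the area exactly 1. The trapezoid is
   used (rather than a plain sum) so non-uniform grids normalize
   correctly. Normalization after denoising suppresses shot-energy and
   matrix-effect variation; it is scale-invariant by construction.
4. **Outlier removal** — per physical sample, the intensity of the C I
   carbon line is extracted as the window maximum over 247.86 ± 0.2 nm
   (robust to small grid misalignment), and the 75% subset of shots with
   the minimum relative standard deviation (RSD = 100·sd(n−1)/mean) is
   retained. With 16 shots per sample the C(16,12) = 1820 candidate
   subsets are enumerated exhaustively in `mode="auto"` — exact, and
   cheaper than the 100,000-draw random search, which is retained
   (`mode="random"`, seeded) for fidelity to the original resampling
   procedure and is checked against the enumeration oracle in the tests.
   Grouping is per sample by default: the RSD is a per-sample quantity,
   and keeping 12 of 16 shots per sample also yields exactly 288 retained
   spectra per variety (1152 total), consistent with a per-variety
   phrasing of the 75% rule. `group_by="variety"` is available for
   sensitivity analysis.
5. **2:1 split** — stratified per variety, seeded; 1152 retained spectra
   give 768 calibration / 384 prediction. The split unit defaults to
   individual spectra, which reproduces the 768-spectrum calibration set;
   `unit="sample"` keeps all 16 shots of a pellet together and is the
   leakage-safe alternative when pellets, not shots, are the experimental
   unit.
6. **Variable selection** — PCA (mean-centered, unscaled; spectra share
   units and are already area-normalized) on the *calibration* spectra
   only. Candidates are local maxima of |loading| of the first 3
   components exceeding `peak_prominence` (default 4) times that loading
   vector's standard deviation; a candidate within `dedupe_window_nm`
   (default 0.3 nm) of a stronger one is dropped, suppressing the side
   lobes that flank strong peaks in higher-PC loadings. Survivors are
   assigned the species of the nearest line in the built-in 20-line table
   within 0.5 nm, else `unassigned`. The 4σ prominence is a documented
   free parameter — the original workflow states no explicit cutoff — and
   is calibrated so the paper-like preset yields ≈ 20 variables.
7. **Classification** — three models, trained on either the selected
   variables or the full spectra:
   - **PLS-DA**: PLS regression (`scale=False`) of the integer class code
     on the spectra. The latent-variable count (≤ 20) maximizes
     leave-one-out CV accuracy; ties prefer fewer LVs. Each LOO fold is
     fitted once at the maximal LV count and the predictions for every
     truncation are recovered from the rotation/loading factors, so LOO
     costs n fits instead of n·max_lv. Continuous predictions map to the
     class c minimizing |ŷ − c|, clamped to the valid range, midpoints to
     the lower class — the only reading of a 0.5 threshold consistent with
     four classes and a single response. Integer coding imposes an
     artificial class ordering; `class_coding="one_hot"` (argmax decoding)
     is available.
   - **RBFNN**: exact-design radial basis function network — Gaussian
     units φ(r) = exp(−(r/spread)²) centered on *every* calibration row,
     output weights by ridge least squares (λ = 1e−8) onto one-hot
     targets, argmax decoding. Spread grid: 0.1–1 step 0.1 plus 1–100 step
     1 (109 distinct values). As spread → 0 the design matrix approaches
     the identity and the network reproduces its training labels.
   - **SVM**: one-vs-one soft-margin SVM with RBF kernel
     exp(−γ‖x−z‖²) (libsvm via scikit-learn, precomputed kernels so the C
     sweep reuses each γ's Gram matrix). Grid: C, γ ∈ [2⁻⁸, 2⁸]; the
     `SVMConfig` default step is 0.2 in log₂ (matching tuned values like
     C ≈ 9.19 that lie off integer powers), while the paper-like preset
     uses step 1.0 — on the cleanly separable synthetic classes a finer
     grid changes nothing but runtime.

   Hyperparameter selection uses stratified 5-fold CV on the calibration
   set by default. The original protocol says only "highest classification
   accuracy" without naming a set; selecting on the prediction set would
   leak, so CV is the defensible default, with `selection="calibration"`
   available to mimic training-set selection. All tuning ties prefer the
   simpler model (fewer LVs, smaller spread, smaller C then smaller γ).

`run_pipeline` derives all per-stage seeds from one master seed via
`numpy.random.SeedSequence`, asserts calibration/prediction disjointness
before each fit, and emits a JSON-serializable run report; two runs from
the same config and seed are byte-identical.

## Synthetic data generator

No spectra are deposited with the motivating study, so the generator is a
first-class, tested component that emulates the campaign's *structure*:

- **Geometry** — 4 varieties × 24 samples × 16 site spectra on a uniform
  246.53–880.26 nm grid of 20,937 points. The real Echelle grid is
  non-uniform; only its range and count are known, and every operation
  takes the grid as data, so a measured grid loads transparently.
- **Lines** — unit-height Lorentzian profiles (typical of Stark-broadened
  LIBS lines; Gaussian by config) of FWHM 0.15 nm (≈ 5 grid steps) at the
  20 built-in line wavelengths. Line amplitude = per-variety species
  concentration × per-line relative strength. Preset strengths span
  ~1–12, mimicking the order-of-magnitude spread between strong ionic
  resonance lines (Ca II 393, K I 766, Mg II 279) and weak neutral lines
  (Fe I) in real coffee spectra.
- **Between-variety signal** — the preset concentration matrix is
  `1 + amplitude × pattern`, with three orthogonal contrast patterns over
  the four varieties (species contrast ±½, two finer origin contrasts)
  assigned per species. The between-class signal is therefore exactly
  three-dimensional and is captured by the first three PCs. Trace species
  (Fe 0.8, N 0.5, Al 0.5, Na 0.45 relative amplitude) vary more than
  matrix species (Ca, K, Mg, C ≈ 0.2–0.28): trace composition genuinely
  varies more between cultivars, and this keeps the weak lines' loading
  peaks above the 4σ selection threshold.
- **Nuisance** — unit-mean lognormal shot gain with CV 0.10 (lognormal
  keeps intensities positive); additive Gaussian noise, sd 0.05 a.u.;
  baseline 0.02 a.u. with slope −1.5e−5 /nm. Noise exceeds the continuum
  in places, so raw background samples go negative exactly as in real raw
  spectra.
- **Outliers** — 10% of shots per sample (exactly round(0.1·16) = 2, so
  count assertions are exact) have their *line emission* multiplied by 3.
  A whole-spectrum gain factor would be removed exactly by unit-area
  normalization — which precedes the RSD filter — leaving nothing for the
  filter to find; an aberrant line-to-continuum ratio is both the
  physically plausible failure mode (hotter plasma, surface
  inhomogeneity) and one the carbon-line RSD statistic can see.

What the generator does **not** model: plasma physics (Saha–Boltzmann
equilibria, self-absorption, line broadening changes), wavelength-
dependent instrument response, correlated (pink) detector noise,
sample-to-sample heterogeneity within a variety, and peak-intensity
nonlinearity. Consequently the synthetic classes are more cleanly
separable than real cultivars: classifiers reaching ~100% here shows the
pipeline plumbing, tuning protocols and selection logic are correct — it
does **not** reproduce, and cannot validate, the 80–84% real-data
accuracies. The structural counts (1152/288 retained, 768 calibration,
99.90% variable reduction) are forced by the procedure and are exact.

## Problem sizes and determinism

Full-scale runs (1536 × 20,937) are used for the structural counts, line
recovery, and classifier checks; recovery and accuracy claims aggregate
ten fixed seeds (≥ 8/10 criterion). Unit tests use reduced grids (1,024–
4,096 points) and the `mini` preset (4 × 3 × 8 shots), which keeps the
whole non-acceptance suite under a minute. All randomness flows through
explicit integer seeds; hypothesis-based property tests are derandomized.

## Known limitations

- The 4σ prominence and ±0.3 nm dedupe window were chosen for the preset's
  line density; much denser line lists (e.g. Fe-rich matrices) would need
  a smaller window and possibly per-region thresholds.
- PLS-DA's LOO protocol is O(n) PLS fits; at full spectral width (20,937
  variables) it is slow and the analysis driver reports PLS-DA on selected
  variables only.
- Level-10 decomposition assumes study-like dimensions (≈ 20k points,
  narrow lines). On short grids with broad peaks the coarse detail
  levels hold few, signal-contaminated coefficients, the MAD noise
  estimate inflates, and thresholding can *erode* signal; lower the level
  (or raise it only to `pywt.dwt_max_level`) for such data.
- The RSD filter assumes the carbon line is present and well-exposed in
  every shot; saturated or missing C I lines would need a different
  reference line (configurable via `reference_line_nm`).
- `exhaustive_min_rsd_subset` guards at 10⁶ subsets; larger groups fall
  back to the seeded random search.
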