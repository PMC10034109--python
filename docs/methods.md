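# Methods

This note documents the models, parameter choices and numerical decisions
behind `rtmspredict`, and what its synthetic-data tests do and do not show.

## Problem and pipeline

The package predicts whether a patient with major depressive disorder will
respond to rTMS of the left dorsolateral prefrontal cortex (DLPFC), using
only a pretreatment resting-state EEG (32 channels, 10-20 montage, eyes
closed).  Rather than reading features off frontal scalp channels, it works
in the component domain:

1. **Preprocessing** – resample to 250 Hz; 1–60 Hz zero-phase 4th-order
   Butterworth; exclude channels whose SD deviates from the cross-channel
   mean SD by more than 3.1 times the SD of the channel SDs; adaptive 50 Hz
   removal by windowed sinusoidal regression (4-s Hann windows, 50%
   overlap — no notch hole); average reference; keep the first 300 s.
2. **Component extraction** – ICA; each component's scalp map is inverted to
   a single equivalent dipole in a homogeneous sphere; the three components
   with the largest variance weight λ whose dipoles fall in the DLPFC region
   of interest are retained.
3. **Features** – per component: Welch band powers (delta 1–4, theta 4–8,
   alpha 8–12, beta 12–24 Hz; non-overlapping 1-s Hann windows), permutation
   entropy, Higuchi fractal dimension, Lempel-Ziv complexity, correlation
   dimension (all averaged over 3000-sample epochs), and three bispectral
   summaries per band (diagonal sum, mean magnitude, normalized bispectral
   entropy).  Theta cordance is computed across the three components treated
   as sites.  21 named values per component → 63 per subject.
4. **Selection** – one-way ANOVA screen, then a GA wrapper (binary masks,
   tournament selection, uniform crossover, bit-flip mutation) whose fitness
   is inner-CV accuracy, targeted at 12 features.
5. **Classification** – SVM (RBF/polynomial), KNN and a three-layer MLP on
   z-scored features under stratified 10-fold cross-validation, reported as
   pooled confusion counts and accuracy/sensitivity/specificity/precision.

## DLPFC region of interest

The DLPFC target is localized in electrode space as the midpoint of F3 and
AF3.  The scalp midpoint is pulled inward to a cortical shell at 0.85 of
the head radius, and the ROI is a cylinder there: radius 25 mm, thickness
2.5 mm (the average cortical sheet thickness), axis radial.  Because the
2.5-mm slab is far tighter than single-dipole localization scatter, the
axial tolerance starts at 10 mm (a typical localization error at 32
channels) and relaxes in logged 1-mm steps if fewer than three components
qualify; qualifying components are ranked by λ.  A right-hemisphere mirror
(F4/AF4) is available via `roi_from_montage(side="right")`.

λ is defined as the fraction of total channel variance explained by a
component's back-projection; component series carry the scalp-map scale
(maps are unit-norm) so absolute band power survives the decomposition.

## Forward model and dipole fitting

Head: homogeneous conducting sphere, radius 85 mm, electrodes from the
standard 10-20 template projected to the sphere.  Surface potential of a
dipole at eccentricity b: Legendre series with the (2n+1)/n insulating-
boundary factor, 60 terms (exact for a central dipole; truncation error
< 1e-4 at b/R = 0.88).  Fitting inverts this model with the moment solved
linearly at each candidate location: a cached 361-point coarse grid scan,
then a shrinking 3×3×3 local grid (12 → 0.35 mm spacing).  Noiseless
forward-modeled maps are recovered to ~1 mm; goodness of fit below ~0.9
flags maps a single dipole cannot explain (e.g. bilateral patterns).

## ICA

`decompose` PCA-whitens to `n_components` (rank-reduced with a warning when
average referencing or channel exclusion lowers the rank) and supports two
algorithms.  FastICA (deflation variant) is the default: on this package's
synthetic sources it matches extended infomax's separation quality at a
tenth of the runtime and with deterministic convergence behaviour; extended
infomax remains available (`algorithm="extended-infomax"`).  Components are
always ordered by λ, descending.

## Synthetic cohort

The generator is the test surface for the whole pipeline; its defaults are
the study conditions: 46 responders + 42 non-responders, 300-s recordings,
32 channels at 1 kHz.  Each subject has three DLPFC sources inside the ROI
cylinder — an alpha-band source, a beta-band source, and a quadratically
phase-coupled triplet (1.8, 3.2 and 5 Hz, chosen so the coupling peak lands
in the delta-band bispectral features and no tone leaks into the alpha or
beta bands whose power ratios are separate effects) — plus five background
sources elsewhere, all projected through the sphere model, with white
sensor noise (2 µV), 50 Hz line noise (5 µV, per-channel amplitude), and
one high-variance bad channel whose artifact noise is band-limited to
1–60 Hz so its 20× amplitude ratio survives resampling and filtering.

Group contrasts are injected at the source level so every pipeline stage is
on the causal path: alpha power ×2 in responders, beta power ×2 in
non-responders, phase-coupling strength 0.85 (R) vs 0.15 (NR), and a
broadband-noise admixture of the coupled source of 0.15 (R) vs 0.55 (NR)
(the "complexity" contrast; responders have more regular dynamics in their
coupled rhythm).  The directions follow the published markers (higher
pretreatment beta and lower alpha in non-responders; complexity
differences).  The magnitudes are this package's choice of a strong but
overlapping contrast: each source amplitude also carries an independent
log-normal subject factor (σ = 0.25), so single features overlap between
groups and classification is non-trivial.

Band-limited sources are amplitude-modulated by a slow (≤ 0.5 Hz) positive
envelope, making them super-Gaussian (bursty, like real EEG rhythms) and
hence separable by ICA; the exponential envelope is re-smoothed so its
peaks stay slower than the cutoff, keeping ≥ 80% of each source's power
inside its nominal band.  The coupled triplet is by default the canonical
constant-amplitude phase-coupling test signal, for which the squared
normalized bispectrum reaches its textbook limits (≈1 coupled, ≈0 with a
randomized sum-frequency phase); an optional common envelope
(`params["env_sigma"]`) is available, with the caveat that the
power-spectrum normalization of the bispectrum is only bounded by 1 for
constant-amplitude signals — envelope fluctuations can push it above 1 (a
property of the estimator, not a bug).

What the synthetic cohort does **not** emulate: ocular/muscle/cardiac
artifact components (the artifact-IC stage is exercised only by its
rule-based contract), realistic head geometry, non-stationary drift,
between-subject montage variation, and any treatment effect — it generates
pretreatment EEG only.  A pipeline that passes these tests demonstrably
recovers source-level contrasts through ICA and ROI selection; it does not
demonstrate clinical validity on real EEG.

## Feature-measure numerics

* **Permutation entropy**: m = 4, τ = 1 by default (m exposed over 3–7);
  ordinal ties broken by order of occurrence (stable argsort); normalized by
  ln m!.  The length guard requires at least m! patterns.
* **Higuchi FD**: k_max = 16; slope of ln L(k) vs ln(1/k) by least squares;
  a constant series returns the sentinel 1.0 with a warning.
* **LZC**: binarization at the median (values equal to the median map to 1);
  LZ76 exhaustive-history parsing (C-speed substring search, verified
  against an independent Kaspar–Schuster implementation); normalized by
  n/log2 n.
* **Correlation dimension**: τ defaults to the first autocorrelation zero
  crossing; embedding dimensions 2–10 with distances grown incrementally;
  ≤400 evenly-spaced vectors per epoch; Theiler window = τ; C(r) over 12
  log-spaced radii between the 5th and 70th distance percentiles; slope from
  the best-R² sliding 6-point window (non-convergent error below R² = 0.5);
  reported value = first plateau over m (|ΔD| < 0.3), else the last slope.
* **Bispectrum**: direct method; 256-sample Hann segments, 50% overlap,
  nfft 256; Bis(f1,f2) = mean over segments of X(f1+f2)X*(f1)X*(f2);
  normalization by √(P(f1)P(f2)P(f1+f2)).  Band features restrict both f1
  and f2 to the band over the non-redundant triangle f2 ≤ f1,
  f1+f2 ≤ Nyquist; the bispectral entropies are divided by log of the
  region size so they lie in [0, 1].
* **Welch window**: 1 s at the working rate (250 samples at 250 Hz); the
  1-s duration governs, not a fixed 1000-sample count.

## Selection and classification choices

* GA library defaults: population 50, generations 100, crossover 0.8,
  mutation 0.02, tournament 3, inner 3-fold fitness, cardinality penalty
  0.002·|k − 12|; elitism of one.  A final trim/extend by ANOVA-F rank
  enforces exactly the target cardinality.  With the wrapper disabled the
  fallback cardinality is ⌊√(number of features)⌋.
* Execution modes: `nested` (GA inside each outer fold; leakage-free;
  default) and `paper` (GA once before CV; retained for reproducing the
  simpler published protocol).  Fold logs record the per-fold selections so
  the leakage guard is auditable.
* SVM: C = 1; RBF width defaults to a dimension-aware value (a fixed σ is
  only meaningful relative to the dimensionality it was tuned at — at 12+
  z-scored dimensions a σ of 0.7 makes the Gram matrix near-identity);
  explicit σ ∈ {0.7, 0.8, 1.0, 1.2, 1.3} and polynomial d ∈ {1, 2, 3}
  (kernel (x·x′+1)^d) populate the parameter-grid report, KNN K ∈ 1–13
  with K = 7 the default.
* MLP: one sigmoid hidden layer (size chosen from {2, 4, 8, 16} on an
  internal stratified split of the training data only), linear output,
  SGD backpropagation with adaptive learning rate, at most 1000 iterations.
* z-scoring uses the population-SD convention and is always fit on the
  training portion of a fold.
* Percent metrics are exact floats internally; the 2-decimal report
  truncates rather than rounds, which is the convention of the published
  tables the metric equations reproduce (83/88 → 94.31).

## Problem sizes in tests and the acceptance script

The generator's cohort defaults (46+42 subjects, 300 s at 1 kHz) are the
study conditions.  The test suite and acceptance script keep the group
sizes and every effect size, and shorten the recordings to 40 s at 250 Hz
native (feature estimates from 40 one-second Welch windows and 3 nonlinear
epochs per component are noisier than at 300 s, which makes the benchmark
conservative); the GA runs at population 24, generations 15 inside each
fold.  The acceptance benchmark reports the median nested 10-fold accuracy
over five seeds; the per-subject front end costs ~1 s and a full nested
run ~2 min, keeping the five-seed benchmark well inside 15 minutes on one
CPU.  Smaller cohorts (20 per group, ~32-s recordings) back the unit-level
invariant tests.

## Known limitations

* The sphere forward model and template electrode positions ignore
  individual anatomy; dipole coordinates are meaningful relative to the
  model only.
* Sources co-located in the ROI with similar spectra are not always
  separated by ICA at 40-s test lengths; selection then returns mixtures,
  which dilutes (but does not invert) injected contrasts.
* Cordance here is computed across the three selected components as sites,
  which departs from channel-space cordance conventions by construction.
* The `paper` execution mode selects features on the full table before CV
  and therefore leaks selection information, exactly as the simpler
  protocol it reproduces; use `nested` for honest error estimates.
* EDF files can be read (via mne) but not written; the native cohort format
  is a numeric matrix plus JSON sidecar.
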