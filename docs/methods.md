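# Methods

`rnflpca` implements an unsupervised structural-feature analysis of
wide-angle (12.0 × 9.0 mm) retinal nerve fiber layer (RNFL) thickness maps
for glaucoma detection and progression prediction, together with a
synthetic cohort generator that provides a fully specified test bed for
every stage.

## Analysis model

### Spatial normalisation

All maps are pooled in a right-eye-oriented canonical frame:

1. **Laterality flip.** Left-eye (OS) maps are mirrored about the vertical
   axis; landmarks are remapped as `x → (W−1)−x`.
2. **Landmark alignment.** Each eye's baseline scan carries manually
   marked fovea and optic-nerve-head (ONH) coordinates. Two point pairs
   determine a unique planar similarity transform (solve `z' = a·z + b`
   over ℂ), which maps them onto fixed canonical positions — fovea at
   (0.62·W, 0.50·H), ONH at (0.30·W, 0.47·H). A fixed canonical frame
   (rather than an arbitrarily chosen reference scan) makes the frame
   dataset-independent and runs reproducible.
3. **ECC refinement.** Follow-up scans inherit the baseline transform and
   are refined against the registered baseline by maximising the enhanced
   correlation coefficient (ECC) — the zero-mean normalised correlation of
   intensities, invariant to affine contrast changes. The optimiser is the
   forward-additive Gauss-Newton scheme of the original ECC algorithm with
   a two-level coarse-to-fine pyramid. Motion model: full similarity by
   default (parametrised as `[[1+a, −b],[b, 1+a]]x + t`, an exact scaled
   rotation), because per-scan acquisition jitter includes small scale
   changes the baseline landmarks cannot resolve; a Euclidean
   (rotation+translation) model is available. Out-of-frame pixels are
   carried as NaN, filled with the image mean for gradient computation,
   and excluded from the correlation via warped, 2-px-eroded validity
   masks — without this masking the filled border biases the solution by
   several tenths of a degree/pixel. A refinement is rejected (falling
   back to the landmark transform, flagged in the run report) if it does
   not converge or is implausibly large (scale outside [0.8, 1.25],
   |rotation| > 20°, |translation| > 25% of the frame): follow-up scans
   share the baseline pose up to jitter, so a large "correction" is a
   failed optimisation, the automated analogue of manual quality-control
   exclusion.
4. **Per-pixel standardisation.** Each pixel is scaled to zero mean and
   unit variance across the (training) scan stack. The SD is floored at
   ε = 10⁻⁶ µm so constant pixels standardise to exactly 0. NaN pixels are
   excluded from the statistics and imputed with 0 (the standardised mean)
   before PCA — zero-filling raw thickness instead would corrupt the
   per-pixel variance.

### Eigen-features

Principal component analysis of the standardised maps (one vector per
scan, all eyes and visits pooled) yields K orthonormal spatial modes
("RNFL features"); a scan is `mean + Σ_k w_k·component_k` and the weight
vector `w` is its structural representation. K defaults to 10. The solver
is a deterministic full SVD (algebraically the Gram-duality
eigendecomposition appropriate when pixels ≫ scans); components are
sign-canonicalised so each component's largest-|loading| pixel is
positive. "Change maps" render the pixels whose |loading| exceeds a
quantile of the component's loading distribution.

### Associations

Per-feature univariate OLS of each clinical measurement on (intercept,
weight, age), with the slope t-test as the association test; one-way ANOVA
on age-adjusted weights for categorical variables; Bonferroni correction
with the declared family size m = K × (number of measurements tested).
Age is always included because the diagnostic groups differ in age by
design. A 10-feature multivariate OLS (plus age) supplies the R² of
predicted-versus-true clinical measures. Associations use baseline rows
only; using both eyes of a participant violates independence — this
mirrors the emulated analysis and is noted rather than corrected.

### Detection

Participant-based leave-one-out: all scans of one participant are removed;
standardisation, PCA and an (unpenalised, ridge-stabilised on
non-convergence) logistic model are refit on the remainder; the held-out
scans are scored. Clinical comparators (mean circumpapillary RNFL
thickness, SAP MD, FDT MD) run as single-predictor logistic fits under the
identical protocol; since the logistic map is monotone, their AUCs equal
those of the raw measurements. AUC is the Mann-Whitney statistic
(ties count ½), identical to the trapezoidal ROC area.

Because age confounds the group contrast, AUCs are estimated by a
bootstrap that resamples whole participants: case participants uniformly,
control participants with weights equal to the case/control age-bin
frequency ratio (5-year bins; a bin with cases but no controls is merged
into the nearest control-occupied bin). This equalises the control age
distribution to the cases within the region of common support — purely
age-driven score differences bootstrap to AUC ≈ 0.5. Paired model
comparisons evaluate both score vectors on the same resamples; the
two-sided p-value uses the (r+1)/(B+1) convention.

Known estimator properties worth keeping in mind: pooled leave-one-out
AUC is slightly pessimistic under the null (fold-specific model offsets
act as participant-level noise and removing a participant's cluster tilts
its own scores), and the age reweighting cannot adjust cases older than
every control.

### Progression

For each measurement (mean cpRNFLt, SAP MD, FDT MD; worsening = more
negative slope for all three):

- A linear mixed model — `value ~ 1 + years` with random intercept and
  slope per participant and variance components for eye nested in
  participant (two-level within-participant eye coding), fitted by REML
  with an optimizer-retry ladder — estimates the healthy population ageing
  rate and its SE.
- The **normative rate distribution** defaults to the per-eye OLS slopes
  of the healthy eyes. The mixed model's shrunken (BLUP) per-eye slopes
  are available (`dist_method="blup"`) but deliberately not the default:
  the progression criterion compares *OLS-estimated* glaucoma rates to the
  distribution's 95th percentile, and shrinkage narrows the normative
  distribution, inflating the false-positive rate well past the nominal
  ~5% (measured 8.2% vs 4.0% over 100 simulated cohorts). Same-estimator
  comparison keeps the percentile arm calibrated.
- A glaucoma eye is **progressing** iff its OLS slope is strictly worse
  than the healthy 95th-percentile rate *and* significantly different from
  zero (two-sided P < 0.05); a perfectly constant series gets slope 0 with
  p = 1. Eyes with fewer than 3 visits are unclassifiable and counted.
- Baseline-only prediction restricts to labelled glaucoma eyes and reruns
  the participant-held-out logistic protocol on baseline feature weights
  (or a baseline clinical scalar), with the same age-controlled bootstrap.

## Synthetic cohort generator

The generator states a world with the structure the analysis assumes, at
the emulated study's design points: 93 glaucoma participants (179 eyes) and
28 healthy participants (56 eyes) by default — two-eye counts are assigned
deterministically so the totals reproduce exactly — imaged every 3 months
for 2 years (9 visits).

- **Template.** A healthy right-eye RNFL prior: peripapillary annulus
  (peak ~1.7 mm from the ONH) with a superior/inferior "double hump",
  arcuate bundles modelled as quadratic Bézier arcs sweeping from the disc
  around the macula, and a foveal pit. The global amplitude is tuned by
  Brent root finding so the mean thickness on the standard 3.45 mm
  circumpapillary circle equals a configurable target (default 95 µm).
- **Damage.** Each glaucoma eye draws one pattern — inferior arcuate,
  superior arcuate (arcs entering the disc 0.8 mm off-centre, 0.8 mm
  Gaussian cross-section, near-orthogonal masks), or diffuse macular
  (2 mm Gaussian centred on the fovea) — and a baseline severity
  (truncated N(30, 12²) µm at the pattern peak). Maps are
  `template − (severity − slope·t)·pattern`, clipped at 0.
- **Longitudinal change.** By default 15% of glaucoma eyes progress with
  pattern-peak slopes ~N(−4, 1.5²) µm/yr (≈ −0.5 to −1.5 µm/yr on the
  circle after pattern dilution, clinically plausible for progressors);
  the rest, and healthy eyes (global uniform change), follow the healthy
  ageing distribution N(−0.3, 0.25²) µm/yr. Optionally the slope can be
  coupled linearly to baseline severity (`slope_severity_coupling`), used
  to state worlds where baseline structure carries progression signal.
- **Noise.** Per-pixel Gaussian noise (default SD 2 µm) smoothed with a
  1-px Gaussian and rescaled, mimicking spatially correlated segmentation
  noise. The circle-scan measurement adds only 0.5 µm of instrument noise
  on top, because the pixel channel already propagates ~0.5–0.9 µm into
  the circle mean; the combined ~1 µm test-retest SD matches reported
  global-RNFL reproducibility.
- **Function.** Visual-field indices are linear in the *pattern-sector*
  mean deficit (dB/µm link coefficients in config, ~0.3–0.35 for MD),
  plus Gaussian noise — a sector-local link, since field loss tracks local
  rather than map-average thinning. The link coefficients are placeholders
  exposed in config; the emulated study reports no visit-level
  structure–function correlation to match.
- **Acquisition.** Every scan receives a random similarity misalignment
  (defaults ±5 px, ±3°, ±3% scale, about the grid centre) with
  edge-extended warping, and ~50% of eyes are left eyes stored mirrored;
  recorded landmarks follow the applied transform, as a grader would mark
  them on the acquired image.
- **Ages.** Healthy ~N(48, 10²), glaucoma ~N(65, 10²) years, truncated to
  [18, 95]: the age confound is present by design.

What the generator does **not** emulate: OCT device physics, layer
segmentation and its artifacts, floor effects in advanced damage,
pointwise visual fields (only MD/PSD scalars), visit attrition, and
test-retest correlation of functional measures. A green test therefore
establishes algorithmic correctness and statistical calibration on a
structurally faithful world — not clinical performance; the emulated
study's cohort-specific AUC/R² values are not reproduction targets.

## Numerical conventions

- Coordinates: pixel (x=column, y=row), origin at the top-left pixel
  centre; physical pitch 75 µm/px at the default 160×120 grid.
- Transforms map source→destination; `resample` pulls back through the
  inverse; bilinear interpolation throughout; out-of-frame = NaN.
- Circle extraction: mean of ≥256 (default 720) equally spaced bilinear
  samples; agrees with 10× oversampled quadrature within 0.1 µm.
- Determinism: every stochastic step descends from the config seed; PCA
  uses a deterministic solver; bootstrap seeds are explicit; a rerun with
  the same seed produces a byte-identical report.
- Mann-Whitney AUC via midranks; bootstrap CIs are 2.5/97.5 percentiles.

## Known limitations

- Pooled-LOO AUC pessimism (above) makes small-cohort null AUCs land
  slightly below 0.5; inference on AUC differences uses the paired
  bootstrap, not the point estimates.
- The age-matched bootstrap requires common age support; unmatchable old
  cases leave residual confounding.
- Two eyes per participant are treated as independent in the association
  models (mirroring the emulated analysis); detection/progression
  bootstraps do resample by participant.
- The ECC optimizer assumes a mostly overlapping field of view; it is a
  local method and relies on the landmark alignment for initialisation.
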