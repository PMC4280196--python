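# Methods

## Scope and model

`hypernitro` implements a quantitative hyperspectral-chemometrics chain
for total nitrogen content (TNC, % of dry matter) in plant organs:
white/dark reflectance calibration, ROI mean-spectrum extraction, SPXY
calibration/prediction partitioning, random-frog wavelength selection
with an embedded PLS submodel, PLS1 regression with LOOCV
latent-variable selection, and pixel-wise application of the fitted
linear form to render nitrogen maps.  The statistical assumption
throughout is the standard NIR one: absorbance-like features in the
reflectance spectrum vary (locally) linearly with constituent
concentration, so a linear latent-variable model suffices.

## Synthetic scenes

No public dataset pairs hyperspectral organ images with reference
nitrogen chemistry, so the package ships a generator whose output has
the structure the analysis relies on.  What it emulates:

- **Grid.** 512 uniform bands over 380–1030 nm.  A uniform grid keeps
  456 bands inside the 420–1000 nm working range; the band count after
  trimming is therefore data-dependent, never hard-coded.
- **Chemistry.** Sample-level TNC is drawn per organ/position from
  normal distributions (leaf upper/middle/lower 4.053/3.129/2.703 %,
  stem 1.390/0.849/0.736 %, root 1.186 %, with matching SDs), truncated
  to the organ envelopes leaf 2.264–4.871 %, stem 0.556–2.135 %, root
  0.847–1.470 %.  This reproduces the leaf > root > stem organ-mean
  ordering and the upper > middle > lower positional gradient.
- **Spectra.** Organ-specific smooth continua (green peak, chlorophyll
  trough, red edge, NIR plateau with a fixed water dip; a flat
  soil-like ramp for roots), minus Gaussian absorption features at
  550/650/760/970 nm whose depths are *linear* in pixel TNC
  (0.016/0.012/0.014/0.018 reflectance units per % TNC).  Linearity
  makes the design exactly recoverable by a 1-LV PLS on noise-free
  data, which the tests exploit as an oracle.
- **Noise.** Additive pixel noise (sd 0.005 reflectance), multiplicative
  scatter (sd 0.02) applied both per sample and per pixel, emulating
  sample-presentation and surface effects.  Chosen once as typical of
  calibrated laboratory Vis/NIR imaging; they are study conditions, not
  tuning knobs.
- **Spatial structure.** Each sample carries a smooth within-sample TNC
  ramp with peak-to-peak amplitude 10 % of the sample mean, recentred
  so the sample-level truth is exactly the ROI mean.  The ramp
  magnitude is a free parameter — within-sample nitrogen variance is
  not something the generator can infer from published organ-level
  statistics.
- **Un-calibration.** Designed reflectance is folded back into a
  raw/white/dark counts triplet (white ≈ 4000 counts with a 5 % column
  pattern, dark = 100 counts), so the calibration stage has real work
  to do and inverts the construction exactly when noise is zero.
- Default image size is 20×16 pixels per sample (12×10 in the reduced
  pipeline profile): large enough for meaningful ROI statistics and
  maps, small enough that a 280-sample cohort is generated in seconds.

What the generator does **not** emulate: instrument line-scan
radiometry, wavelength-dependent detector noise, specular highlights,
leaf venation and 3-D stem geometry, soil adhesion variability on
roots, and any nonlinearity between nitrogen and absorption.  Spectra
are consequently far cleaner than field data, and model metrics on
synthetic cohorts (R_P ≈ 0.99) overstate what the same code achieves on
real images; passing tests demonstrate correctness of the chain, not
field-level predictive performance.

## Numerical and design choices

- **Calibration.** The white reference is treated as 100 % reflectance
  (no tile-reflectance correction).  Zero-denominator (white = dark)
  entries become NaN; pixels with any NaN band are excluded from ROI
  means and flagged no-data in maps.
- **Trimming** keeps the closed interval [low, high] nm and never
  reorders bands.
- **SPXY.**  Joint distance d = d_x/max d_x + d_y/max d_y; a degenerate
  term (zero spread) is dropped with a warning.  Selection seeds with
  the maximal-distance pair and grows by the max–min criterion; all
  ties break toward the lowest sample index, making the procedure fully
  deterministic.  Calibration quota is round-half-up (0.75 × 120 → 90,
  0.75 × 40 → 30).  Stratified (per-organ) mode is the default because
  the target 210/70 partition is exactly proportional within organs; a
  global mode exists.  Note that with near-duplicate extreme samples
  the calibration set can miss a response extreme by a sliver; the
  coverage property is therefore only a high-probability one.
- **Random frog.**  The chain needs four decisions the algorithm sketch
  leaves open; the package resolves them as follows.  (1) *Candidate
  construction*: equal size keeps the incumbent; shrinking keeps the
  largest-|coefficient| variables of the incumbent's PLS fit; growing
  pools ω·ΔQ uniform draws from the complement with the incumbent and
  keeps the largest-|coefficient| Q*.  (2) *Acceptance*: certain when
  the candidate's CV error is no worse, else probability
  η·(err_incumbent/err_candidate) < η, consistent with η as an upper
  bound.  (3) *Subset-size proposal*: Q* ~ round(N(Q_t, θ·Q_t)) clipped
  to [1, p], no re-draws.  (4) *Submodel error*: contiguous 5-fold CV
  RMSE with at most 10 latent variables — full LOOCV inside a 10⁴-step
  chain would multiply cost for no stated benefit.  Per-run seeds are
  spawned from the master seed, so a fixed seed reproduces SP vectors
  bit for bit.  The number of wavelengths k kept after ranking is
  always explicit (defaults 10/9/7/8 for leaf/stem/root/whole-plant
  targets); no elbow detection is attempted.
  One behaviour worth knowing: on pure-noise data the chain contracts
  onto whichever variables are chance-correlated with the response in
  that cohort — a property of any data-driven selector at finite n, and
  the reason selection stability should be judged across cohorts, not
  within one.
- **PLS1.**  Mean-centring only (no autoscaling): the working signal is
  reflectance on a common scale.  NIPALS components are nested, so one
  fit per left-out sample yields the whole RMSECV curve; the LV count
  minimising RMSECV wins, ties to fewer LVs, with a default cap of 20.
  Rank exhaustion stops component extraction with a warning.  R is the
  Pearson correlation of predicted vs measured; a zero-variance vector
  makes it undefined and is reported as 0 with a degenerate flag.  The
  latent form and the linear form (b = W(PᵀW)⁻¹q) agree to 1e-8
  relative, which is tested, and scikit-learn's PLS solver serves as an
  independent oracle in the test suite.
- **Chemical imaging.**  Model wavelengths map to the nearest cube band
  within one grid step.  Predictions are raw (no clipping or smoothing)
  unless a clip range is requested.  Colour scales are per-organ
  min/max over the rendered set by default.  Maps made from
  few-wavelength models amplify per-pixel noise (fewer bands to average
  over), so pixel-level fidelity is best with full-spectrum models;
  sample-level predictions are unaffected because ROI averaging removes
  pixel noise either way — the ROI mean of a map equals the model's
  prediction of the ROI mean spectrum exactly, by linearity.
- **Pipeline.**  The `reduced` profile (60 samples, T = 500, 5 chains)
  finishes in well under a minute and is the default; `paper` restores
  the full-scale settings (280 samples, T = 10 000, 50 chains).  The
  manifest hashes every text artifact; equal seeds give equal hashes.

## Known limitations

- ENVI I/O covers the common case written by this package (byte order
  0, header offset 0, BSQ/BIL/BIP, numeric types 1–5/12/13); exotic
  header variants are rejected rather than guessed.
- PLS is single-response (PLS1) by design; multi-constituent modelling
  would need a PLS2 extension.
- The frog submodel CV uses contiguous folds for determinism; on data
  with strong serial structure in sample order this can bias the
  submodel error, though it is immaterial for the shuffled-free
  synthetic cohorts used here.
- Synthetic realism limits are listed above; conclusions about field
  performance require real imagery and reference chemistry.
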