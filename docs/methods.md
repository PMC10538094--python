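# Methods

## Scope

`serumpk` implements the computational layer of a serum bioanalytical PK
study: calibration and validation of a targeted LC–MS/MS assay, and
noncompartmental analysis (NCA) of the resulting concentration–time
profiles. Chromatography and mass spectrometry themselves are out of
scope: the pipeline begins at instrument responses (analyte/IS peak-area
ratios) and nominal or measured concentrations. A seeded synthetic-data
generator stands in for clinical serum samples, which are not publicly
available for studies of this kind.

## Generative model

Serum concentration after a single oral dose follows a one-compartment
model with first-order absorption and a lag time:

C(t) = D·ka / (V·(ka − kel)) · (e^{−kel(t−tlag)} − e^{−ka(t−tlag)}),  t > tlag; else 0

with D the dose converted mg→ng and V the apparent volume Vd/F converted
L→mL, so C is in ng/mL. This is the simplest structural model consistent
with a single-peak oral profile; the flip-flop-degenerate case ka = kel is
rejected rather than handled by its limiting form. Closed forms used as
internal anchors: Tmax = ln(ka/kel)/(ka − kel) + tlag and
AUC₀₋∞ = D/(V·kel).

### Typical-subject defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| dose | 100 | mg | the simulated trial's single oral dose |
| kel | ln2/3.93 ≈ 0.1764 | 1/h | terminal half-life ≈ 3.9 h |
| Vd/F | 1500 | L | apparent volume of a high-first-pass volatile terpene |
| ka | 2.6 | 1/h | chosen so the noise-free analytic Tmax ≈ 1.1 h |
| tlag | 0.15 | h | short capsule-dissolution delay |

ka is a simulator-only quantity: NCA never estimates it, and no claim is
made that it is identifiable from the sparse schedule.

### Variability and noise

- **Inter-individual variability (IIV):** multiplicative log-normal on ka,
  kel and Vd/F, parameterized to unit mean (σ² = ln(1+CV²), μ = −σ²/2) so
  the population mean of each parameter equals its typical value. Default
  CVs 0.30 (ka) and 0.45 (kel, Vd/F), echoing the ~50–75% between-subject
  CVs typical of sparse oral PK summaries of this compound class. tlag
  varies uniformly on [0, 0.3] h — lag times are bounded, not log-normal.
- **Assay noise:** proportional only, C_obs = C_true·(1 + CV·z), z ~
  N(0,1), floored at 0, default CV 5%. Validation-batch RSDs below 1% show
  the measurement error is concentration-proportional and small; additive
  baseline error is therefore omitted.
- **Censoring:** observations below the LLOQ (default 7.5 ng/mL) are
  flagged BLQ and masked (NaN), never zero-filled at the data layer. The
  predose sample is simulated as exactly 0 and is therefore always BLQ.
  Censoring is idempotent, and raising the LLOQ can only add flags.
- **Calibration batches:** response = slope·x + intercept + ε with
  ε ~ N(0, (CV·slope·x)²) — noise proportional to the analyte signal, the
  heteroscedasticity that motivates 1/x weighting. The same noise model
  generates QC, LOQ and stability replicates in the validation stage.
- **Two-arm scenario:** the ester-prodrug arm is modeled as the same
  kinetics with effective parent dose = prodrug dose × conversion fraction
  (defaults 90 mg × 0.1). This is an explicitly heuristic exposure-scaling
  device producing the observed mostly-BLQ pattern, not a mechanistic
  hydrolysis model.

### What the generator does not emulate

No multi-compartment or enterohepatic kinetics, no absorption-phase
variability beyond a uniform lag, no correlated IIV across parameters, no
additive/baseline assay error, no batch/day effects or drift, no
chromatogram-level structure (peak shapes, integration error). Passing
tests therefore demonstrate correctness of the estimators under a clean,
well-specified data-generating process — not robustness to every artifact
of real serum data.

## Calibration and validation

- **Weighted least squares** by the closed-form weighted normal equations;
  weights 1, 1/x or 1/x² with x the nominal concentration. Replicate
  points enter individually (duplicate standards are never averaged).
- **r² under weighting** is not uniquely defined; the reported `r_squared`
  uses weighted residual and total sums of squares about the weighted mean
  (so it is the plain r² when unweighted), and the ordinary r² of the same
  line is reported alongside as `r_squared_unweighted`.
- **Back-calculation** (y − b)/a is left unclipped; negative (sub-blank)
  values are flagged, not truncated, so QC statistics remain unbiased.
- **Acceptance bounds are closed intervals**: accuracy 80–120% and RSD
  ≤ 20% at the LOQ; standards within ±15% of nominal on back-calculation
  (±20% at the LOQ level); stability within ±15% signed deviation. "Within"
  is read inclusively throughout.
- **LOD/LOQ from S/N** assumes signal-to-noise proportional to
  concentration through the origin: lod = 3c/sn, loq = 10c/sn, hence
  loq/lod = 10/3 identically. The package's reference limits (3.5 and
  7.5 ng/mL) are assay constants, not outputs of this formula.

## Noncompartmental analysis

- **Cmax/Tmax** are the observed maximum and its time; ties break to the
  earliest time.
- **Lag time** is the time of the last BLQ/zero sample preceding the first
  quantifiable one (0 if the first post-dose sample is quantifiable) — a
  grid-limited rule, exact only up to the sampling resolution.
- **Terminal phase (λz):** candidate windows are the suffixes of the
  quantifiable points strictly after Tmax (Cmax excluded) with ≥ 3 points
  and a negative log-linear slope; the window maximizing the adjusted r²
  of the OLS fit of ln C on t wins, with differences below 1e-4 treated as
  ties broken toward more points (the conventional best-fit rule in PK
  software). λz is the negated slope; subjects with fewer than three
  eligible points, or no declining window, get an error record.
- **AUC** uses the linear trapezoidal rule on a BLQ-adjusted series:
  predose and pre-Tmax BLQ samples count as zero, post-Tmax BLQ samples
  are dropped. AUC₀₋∞ adds the observed (not λz-predicted) Cₗₐₛₜ/λz; an
  extrapolated fraction above 20% raises a quality flag rather than an
  error.
- **Derived parameters:** t½ = ln2/λz; CL/F = Dose/AUC₀₋∞ with the single
  mg→ng (10⁶) and mL→L (10³) conversion applied in `derive_parameters`;
  Vd/F = (CL/F)/λz. The identities t½·λz = ln2 and Vd/F·λz = CL/F hold by
  construction on every successful result.
- **Population summaries** are arithmetic mean ± sample SD (n−1) of
  per-subject parameters. Parameters are always averaged per subject —
  never computed from averaged concentrations or as ratios of averages,
  which give systematically different values for CL/F. Failed subjects are
  excluded and counted explicitly.

## Numerical and I/O conventions

- Degenerate inputs are rejected with typed exceptions
  (`ProfileError`, `CalibrationError`, `NCAError`); `run_nca` converts
  subject-level failures into error records so population runs never
  crash.
- AUC endpoints must coincide with sampling times of the adjusted series;
  no interpolation is performed. Trapezoid integration is exactly additive
  across interior sampling points.
- CSV dialect: comma-separated, period decimal, UTF-8, header required,
  times in hours; profile files use
  `subject_id,dose_mg,time_h,conc_ng_ml,blq` with an empty concentration
  field for censored samples, runsheets use
  `level_ng_ml,replicate,response`. Floats are written at full precision
  and parsed round-trip, so write→read is lossless.
- Every stochastic operation takes an explicit seed; pipeline stages
  derive independent sub-seeds (SHA-256 of seed and stage name, reduced
  below 2³¹) so adding a stage never perturbs another stage's draws.
  Artifacts carry the seed and a configuration hash; identical configs
  yield byte-identical outputs.

## Problem sizes in the test suite

Statistical checks use sizes chosen to give comfortable resolution at
3-SE/99% thresholds while keeping the suite fast: 1000 seeded repeats for
calibration/QC/LOQ/stability pass-rate checks, 500 subjects for IIV
moment recovery, 200 subjects at 5% assay noise for population-mean
recovery, and quarter-hour sampling to 48 h (~12 terminal half-lives) for
dense-profile parameter recovery. Brute-force oracles (grid search,
adaptive quadrature, Nelder–Mead minimization of the weighted objective,
exhaustive window enumeration) are recomputed inside the tests rather than
frozen, keeping them independent of the implementation paths they check.

## Known limitations

- The lag-time rule and λz window selection are conventions; with sparse
  schedules both are grid-limited and the reported tlag can only take
  sampling-time values.
- No sparse-sampling (batch/Bailer) NCA, bioequivalence statistics,
  multiple-dose accumulation, or compartmental fitting.
- The LOQ acceptance check evaluates spiked-sample statistics; it does not
  model chromatographic noise, so S/N-based limits are arithmetic
  projections from a reference measurement, not chromatogram-derived.
- Matrix-effect and recovery computations are not implemented (no formulas
  or values to compute against beyond pass/fail statements).
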