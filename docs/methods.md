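# Methods

This note records the models, defaults and numerical choices behind
`gestox`, and what the synthetic-data tests do and do not demonstrate.

## Study design assumed throughout

Two groups — C (normoxic control) and H (chronic hypoxia) — of pregnant
rats sampled on gestational days D8, D11, D14, D17 and D20, eight animals
per group per day, profiled in plasma and urine by ¹H NMR at 600.13 MHz.
All group contrasts are strictly within-day C-vs-H; the all-day PCA
trajectory the pipeline writes is descriptive only and drives no
screening decision.

## Synthetic cohort model

The simulator exists so that every downstream stage is testable against a
known truth without any external data.

* **Concentrations.** Each metabolite has an arbitrary-unit base level
  (staggered deterministically over 1.0–4.5 a.u.; only fold changes are
  meaningful, since absolute concentrations are not identifiable from
  binned spectra anyway). A sample's concentration is
  `base × FC(H, day) × exp(σ_log · z)` with z standard normal —
  log-normal noise keeps concentrations positive and right-skewed, as
  metabolite data are. Default σ_log = 0.15. Planted effects are H/C
  fold changes on (metabolite, day) cells, on the 0.4–2.0 scale typical
  of this kind of study.
* **Lineshape.** Each resonance is an area-normalized Lorentzian (the
  natural NMR lineshape), default linewidth 1.5 Hz FWHM, converted to ppm
  by dividing by 600.13. Multiplets are fixed intensity patterns
  (s/d/t/q/dd/m) split by a fixed J = 7 Hz; quantum-mechanical spin
  simulation and second-order effects are out of scope.
* **Peak libraries.** 36 metabolites per fluid with literature-typical
  chemical shifts, covering the full vocabulary of the packaged reference
  screening reports; lipoprotein/lipid envelopes are broad (12–18 Hz)
  singlets. Urine adds TSP at 0.00 ppm and a broad urea resonance at
  5.78 ppm (which the exclusion windows exist to remove).
* **Nuisance processes.** Per-metabolite chemical-shift jitter
  (SD 0.002 ppm, one plasma bin) exercises binning robustness; a smooth
  two-harmonic random baseline (amplitude 2 a.u.) and white noise
  (SD 0.5 a.u.) sit under peaks whose heights are O(10²–10³); urine
  samples carry a log-normal dilution factor (CV 0.3) applied to every
  metabolite *except* TSP, which enters with the buffer at a fixed
  amount — exactly why TSP calibration and quotient normalization work on
  real urine. Acquisition windows default to −0.5…9.5 ppm so both
  calibration references lie inside the axis.
* **Determinism.** All randomness flows from one `numpy.random.SeedSequence`
  per operation; identical (design, effects, seed) triples are
  bit-identical.

What the simulator does **not** emulate: phase/baseline distortions that
MestReNova-style preprocessing removes upstream, peak overlap beyond the
fixed libraries, J-coupling fine structure, relaxation-weighting
differences between pulse sequences, and between-day drift. Passing
recovery tests therefore demonstrate the statistical chain under clean,
assignment-consistent spectra — not robustness to assignment error or
heavy spectral overlap.

## Preprocessing

* **Calibration** shifts the axis so the detected reference lands on its
  nominal position: plasma uses the lactate CH₃ doublet at 1.33 ppm
  (midpoint of the two tallest smoothed local maxima in 1.20–1.45 ppm),
  urine the TSP singlet at 0.00 ppm. A reference is accepted only if its
  smoothed prominence exceeds 5× the spectrum's median absolute
  deviation; calibration is idempotent to one grid step.
* **Binning** integrates fixed-width bins (trapezoidal rule via the
  cumulative integral, so retained bins tile the region exactly):
  0.002 ppm over 0.5–9.0 ppm for plasma, excluding urea 5.5–6.0 and
  water 4.54–5.23 ppm (4250 − 250 − 345 = 3655 bins); 0.005 ppm over
  0.5–9.5 ppm for urine, excluding 5.55–6.00 and 4.50–5.10 ppm
  (1800 − 90 − 120 = 1590 bins). Bin value is the integral (intensity ×
  ppm), not the mean intensity. Bins partially overlapping an exclusion
  are dropped whole, keeping all bins equal-width; the printed exclusion
  edges align with both bin grids, so nothing is ambiguous at the
  defaults. Bin ids are center ppm to six decimals, features ordered by
  descending ppm.
* **Normalization** defaults to none for plasma and PQN for urine (each
  sample divided by the median quotient of its features against the
  cohort-median spectrum). PQN removes per-sample dilution up to the
  cohort-median factor — a shared profile under different dilutions
  collapses onto one profile, which is the property the tests assert.
  Total-area normalization (rescale to the cohort-median total integral)
  is available but known to distort when large signals genuinely change.
* **Quantification** sums retained bin integrals over per-metabolite ppm
  windows (default ±0.02 ppm around each library peak, windows inside
  exclusion regions dropped). Windows may overlap between metabolites,
  which mildly attenuates fold changes toward 1 — visible in the
  end-to-end tests and accepted as realistic crosstalk. Lipoprotein
  envelopes are flagged so their fold changes are reported masked.

## Chemometrics

* **Scaling**: PCA uses mean-centering; PLS-DA/OPLS-DA use Pareto
  scaling (centre, divide by √SD), which damps but does not erase
  intensity differences. Constant columns pass through as zeros and are
  flagged, not fatal.
* **PCA** by SVD with a deterministic sign convention (largest-magnitude
  loading element positive).
* **PLS-DA** is NIPALS PLS1 with deflation; with a single binary response
  the weight vector is closed-form per component, so no inner iteration
  is needed. y is coded −1 (C) / +1 (H) and centred.
* **OPLS-DA** follows Trygg–Wold orthogonal projections: repeatedly
  extract the component of the X-loading orthogonal to the predictive
  weight, deflate, then fit one predictive component. Defaults to 1
  predictive + 1 orthogonal component for two-class problems (the common
  software default; the orthogonal count is configurable, and the screen
  falls back to 0 orthogonal components when no y-orthogonal variation
  remains). With 0 orthogonal components the model is exactly
  1-component PLS-DA. The predictive score is oriented so q > 0, making
  positive correlation loadings mean "higher under hypoxia".
* **VIP** uses the predictive component(s) only; for OPLS the orthogonal
  components explain no Y variance by construction, so
  VIPⱼ = √(F)·|wⱼ|/‖w‖ and mean(VIP²) = 1 exactly.
* **Correlation loadings** are Pearson correlations between each scaled
  feature and the predictive score; zero-variance features give NaN and
  are masked downstream. The critical threshold r\* = t\*/√(t\*² + df)
  gives 0.666 at (α = 0.05, df = 7) and ≈ 0.497 at the pooled df = 14 of
  an 8-vs-8 comparison — both conventions are reachable: the screen uses
  the df = n − 2 rule by default, report display uses df = 7.
* **Validation**: Q² = 1 − PRESS/SS with class-stratified 7-fold CV
  (folds clamp to the minority-class size; folds ≥ n means leave-one-out);
  negative Q² is reported as-is. The permutation test (default n = 200)
  refits on uniformly permuted labels and uses the add-one estimator
  p = (1 + #{null ≥ observed})/(n + 1), so the smallest attainable p is
  1/201. CV-ANOVA forms F = ((SS − PRESS)/A)/(PRESS/(N − 1 − A)) with A
  the number of fitted components and p from F(A, N − 1 − A).

## Screening and reporting

A metabolite is significant in a comparison iff all three hold: Welch
t-test p < α (default 0.05, no multiplicity correction — the three-way
conjunction is the guard, with an optional BH flag deliberately left out
of the default path), |r| ≥ the critical value in force, and VIP ≥ the
90th percentile (linear interpolation) of that comparison's VIPs.
Raising any threshold can only shrink the hit set. Volcano datasets carry
(log₂FC, −log₁₀p, VIP, |r|) per feature; masked cells are skipped.
Reports render r as "/" below the display threshold and always show
computable fold changes; metabolite names are normalized (case, spelling
variants such as trailing-e and Greek-letter forms) before cross-fluid
set algebra, so inclusion–exclusion holds exactly.

Under a full null (no planted effects) the three criteria are strongly
correlated — all driven by the same group-mean difference — so the
per-feature false flag rate stays below α, but with ~36 metabolites a
typical null run still flags one or two somewhere. Family-wise control
is *not* a property of this screen and is not claimed by the tests; the
recovery experiment asserts per-comparison sensitivity ≥ 0.9 and
per-feature FPR ≤ 0.05.

## Enrichment

Over-representation is the upper-tail hypergeometric probability of the
observed hit/pathway overlap, drawn from a background of all quantified
metabolites in the relevant fluid (not a full compound database — the
appropriate reference metabolome for targeted NMR panels), BH-adjusted
across tested pathways. The packaged GMT is a small curated demo
collection (six pathways, members from the package's own metabolite
vocabulary) for tests and examples; it is not a KEGG export, and
database-dependent pathway counts are intentionally not asserted
anywhere.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on compact instances (cohorts of 2–8 animals
per cell, 1024–16384-point spectra, 10–50 permutations); the
planted-effect recovery experiment uses the full study geometry at the
metabolite level (8 vs 8, fold changes 2.0 and 0.5, σ_log = 0.15) over
200 seeds, and spectrum-level recovery is demonstrated on single
cohorts. The permutation-uniformity check uses n_perm = 19 over 500
null datasets so the p-grid is coarse but the rep count high. These
sizes are the package's own trade-off between statistical resolution and
a test suite that stays fast enough to run on every change.

## Known limitations

* SIMCA-P numerics are not reproduced exactly (component counts,
  centering details and CV splits differ); only the documented
  conventions above are guaranteed.
* The screen's df convention for the |r| cut is configurable precisely
  because published tables mix df = 7 and pooled-df practices.
* Quantification windows are user config; no automated assignment
  against spectral databases is attempted.
* Multi-class discriminant analysis, O2PLS, batch correction and
  network-diffusion pathway analysis are out of scope.
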