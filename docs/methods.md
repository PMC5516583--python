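# Methods

This document records the signal model, every load-bearing default with
its units and rationale, the realism and limits of the synthetic-cohort
generator, the numerical choices, and the known limitations. Quantitative
statements here are either definitions or numbers computed by the test
suite / `scripts/acceptance.py`.

## 1. Signal model

### 1.1 Acquisition

A free induction decay (FID) is a complex time series sampled at the dwell
time `1 / spectral_width_hz`. The spectrum is its discrete Fourier
transform on a strictly decreasing chemical-shift axis referenced to water
at 4.70 p.p.m. The transform pair `to_spectrum` / `to_fid` is exactly
invertible and satisfies the Parseval identity
`Σ|S|² = N Σ|s|²` (asserted to a relative error ≤ 1e-9).

Default acquisition (edited pathway): TR 2000 ms, TE 122 ms, 2048 complex
points over 2000 Hz at 127.7 MHz (3 T). Short-echo PRESS uses TE 36 ms;
unsuppressed water is acquired at TE 68 and 122 ms.

### 1.2 Resonances

Each resonance is a damped complex exponential (Lorentzian line):
amplitude `a`, shift `δ` (p.p.m.), damping `d` (Hz), contributing
`a·exp((2πi f − d) t + iφ)` with `f = (δ − 4.70)·127.7` Hz. The
frequency-domain FWHM is `d/π` Hz (asserted in the tests). Peak areas are
proportional to amplitude, which is what makes amplitude bookkeeping a
valid editing model.

**The simulated lineshape is deliberately Lorentzian while the
quantification stage fits Gaussians.** This mismatch is a design decision:
it keeps fit-error statistics non-zero and realistic, at the cost of a
small lineshape-mismatch bias (§4.3).

### 1.3 Spectral editing

Editing is modelled by amplitude bookkeeping. An *edited* resonance
appears at full amplitude in the editing-ON acquisition and at
`(1 − efficiency)` of it in OFF, so the OFF−ON difference carries
`efficiency × amplitude`. *Suppressed* resonances are identical in ON and
OFF and cancel exactly; *unedited* resonances exist only in PRESS/water
acquisitions. The GSH editing efficiency default is **0.74**
(dimensionless), a literature-typical value for GSH MEGA-PRESS at 3 T; the
measured GSH area is divided by it to return to concentration scale.

### 1.4 Contaminants

Two contaminant families survive the subtraction alongside GSH (2.95
p.p.m.):

- **Co-edited metabolite lines** at 2.82, 3.01, 3.10 and 3.26 p.p.m.
  (amplitudes 0.8–1.4% of Cr, efficiencies 0.45–0.60) — the reason the
  difference spectrum is fit with five Gaussians rather than one.
- **A co-edited macromolecular comb** spanning 2.71–3.20 p.p.m.: narrow
  (4 Hz) teeth of alternating sign at 5% of the Cr amplitude, arranged as
  near-zero-net-area dipoles at the edges of the analyte region. It is the
  dominant contribution to the analyte-region fit residual, as unmodelled
  macromolecules and subtraction artifacts are in vivo. The teeth facing
  the GSH template are negative, so the non-negative GSH component cannot
  slide onto them; near-zero net area keeps area quantification essentially
  unbiased.

### 1.5 Noise

Per transient: additive complex Gaussian noise (SD 0.045 per point at Cr
amplitude 1), one frequency offset (SD 1.5 Hz) and one zero-order phase
offset (SD 0.087 rad ≈ 5°). The noise SD and the macromolecule scale were
chosen *jointly* (before the acceptance tests were written) so that the
per-scan GSH fit error sits in the tens of percent — the regime the
modelled study reports — while true peaks at the quantification floor stay
cleanly separated from noise at the detection threshold (§3.2). The
corrupted acquisition multiplies the noise SD by 20.

## 2. Cohort generator

### 2.1 Design

15 subjects; baseline plus 3 post-dose scans for six subjects, 4 for
eight, and 5 for one (70 acquisitions). Nominal post-dose times 7.5, 19.9,
32.0, 44.7 min (plus 57.1 min for the single fifth scan), with per-bin
timing spread derived from the design's timing SEMs. Six subjects have an
undetectable baseline (truth drawn in 0.0002–0.0010, far below the
quantification floor); exactly one randomly chosen subject's second
post-dose scan is corrupted.

### 2.2 Truth model

True GSH/Cr ratios are lognormal with a shared per-subject multiplicative
effect and a per-bin within-subject component, truncated below at the
quantification floor (0.016):

- Per-bin total ln-scale sigmas are derived at import from the design's
  per-bin group means and SEMs (`CV = SEM·√n / mean`). The baseline
  targets describe all 15 subjects *including* the six imputed
  undetectables, so the detected-scan mean and variance are first
  recovered by inverting the imputation arithmetic.
- The subject effect is `SIGMA_SUBJECT = 0.45` (ln scale). It is not
  derivable from the group summaries; it is pinned by the design's
  inferential pattern — a strongly significant omnibus time effect
  requires strong within-subject correlation, while the non-significant
  7.5-minute comparison bounds it from above. It must stay below the
  smallest per-bin sigma (≈ 0.50).
- The lognormal location per bin is solved (Brent's method) so that the
  mean of the *actual sampling scheme* — subject effect fixed, within
  component resampled above the floor, the subject effect integrated by
  Gauss–Hermite quadrature — equals the target mean. Solving the plain
  marginally-truncated mean instead understates the bin means by up to
  ~16% (this was a bug, found by a test and fixed).

### 2.3 Fidelities

`mode="transients"` synthesises all 40 stored ON/OFF blocks per scan plus
PRESS and water acquisitions (~30 s per cohort to quantify).
`mode="quantified"` emits the per-scan quantification table directly using
a measurement model calibrated once against the full spectral chain
(10 cohorts, 630 analysed scans): measured ratio =
`truth × (1 − 0.040) + N(0, 0.0021)`, per-scan fit error
`= 100 × 0.0078 / measured`. Flags are design-driven (corrupt →
insufficient quality, undetectable truth → undetectable). Quantified mode
exists for Monte-Carlo studies of the inference (milliseconds per cohort);
it is *not* used by the bookkeeping or recovery checks, which run the full
chain.

### 2.4 Realism and limits

Faithful: editing bookkeeping, Lorentzian linewidths, frequency/phase
instability, co-edited contamination, per-bin group means and spreads,
undetectable baselines, the corrupted scan, scan bookkeeping. Simplified:
no eddy-current or baseline distortions beyond the modelled contaminants;
no inter-scan hardware drift; voxel composition enters only through the
CSF fraction; the macromolecular background is deterministic rather than
subject-specific; PRESS metabolite ratios are fixed multiples of Cr.

## 3. Quantification pipeline

### 3.1 Edited pathway

Per scan: 3 Hz exponential broadening → time-domain spectral registration
of all transients against their pointwise median (frequency and zero-order
phase, Levenberg–Marquardt on the first 256 samples) → averaging → ×2
zero-fill → OFF−ON difference (sign-normalised at the GSH position) →
5-Gaussian + linear-baseline fit over 2.6–3.3 p.p.m.

Fit details: components initialised at 2.82, 2.95, 3.01, 3.10, 3.26
p.p.m.; centers bounded to ±0.03 p.p.m.; all amplitudes bounded below at
zero (the difference spectrum is sign-normalised, so every edited
component is positive — this stops neighbours trading signed tail area
with the GSH line); Gaussian SD bounded to 0.004–0.025 p.p.m. (metabolite
lines here are ~12 Hz Lorentzian + 3 Hz broadening ≈ 0.02 p.p.m. SD; the
tight upper bound keeps any one Gaussian from acting as a broad
tail-catcher under the lineshape mismatch). Trust-region least squares
(`scipy.optimize.least_squares`, trf) with an analytic Jacobian,
multi-started over width initialisations 0.010/0.016/0.022 p.p.m.; the
lowest-cost start wins, making the fit deterministic.

The creatine reference is a 3-Gaussian fit (2.82, 3.03, 3.19 p.p.m.) of
the mean editing-OFF spectrum *over the same window*, so both
quantifications capture the same fraction of their mismatched Lorentzian
lineshapes and the tail truncation largely cancels in the ratio.

**Fit error** = 100 × SD(residual over the GSH ± 0.1 p.p.m. region) /
fitted GSH amplitude.

**GSH/Cr ratio** = GSH area / (Cr area × 0.74). Invariant under global
rescaling of the raw data (asserted).

### 3.2 Limit of detection

Detection uses a *linear matched filter*, not the fitted amplitude: the
difference spectrum is detrended by a line anchored on flank regions
(2.60–2.70 and 3.28–3.40 p.p.m.) and projected onto a nominal-width
Gaussian template (SD 0.016 p.p.m.) at 2.95 ± 0.1 p.p.m. The filter-output
noise is estimated *empirically* by sliding the same template through the
signal-free band (6.5–9.5 p.p.m.), which accounts for the noise
correlation introduced by apodization (an analytic white-noise SE would
understate it roughly two-fold). A scan is detectable when the filter
amplitude exceeds `DETECTION_SNR = 4.0` times that noise level — a
standard spectroscopy detection limit, chosen a priori. A linear statistic
was essential: the non-negativity-constrained fitted amplitude rectifies
noise and has heavy upper tails, which made spurious baseline
"detections" unavoidable at any threshold.

### 3.3 Quality control

Per-scan precedence:

1. **Sensitivity**: the smallest GSH/Cr the scan's own noise floor could
   detect, `4.0 × SE × 0.016·√(2π) / (Cr area × 0.74)`. If it exceeds 2 ×
   the quantification floor (0.016), the scan cannot measure the analyte
   at any plausible concentration → *insufficient quality*, even at
   baseline (an acquisition property, not a subject property). This is
   what catches the corrupted scan.
2. Combined GSH+Cr fit error above 150% or a failed fit → *insufficient
   quality* (at baseline: *undetectable*, so the cohort stage imputes it).
3. Matched-filter detection failure → *undetectable*.

A factor-of-2 serial-consistency check across a subject's scans is
recorded but advisory.

### 3.4 Absolute pathway

PRESS spectra: Hankel-SVD residual-water removal, ×2 zero-fill, 1.1 Hz
filter, then a non-negative linear-combination fit of simulated basis
spectra (Cr, NAA, Cho, Glx) plus a degree-2 polynomial baseline. CRLBs
from the Fisher information of the linear model with noise estimated at
7–10 p.p.m.; QC requires linewidth ≤ 0.1 p.p.m., SNR ≥ 5, Cr CRLB < 20%.
Water referencing corrects the water area to zero echo time with
`exp(TE/T2)`, T2 estimated from two echo times as
`(TE_b − TE_a)/ln(S_a/S_b)`; CSF partial volume divides by `(1 − f_csf)`.
Absolute GSH = ratio × corrected Cr. The whole pathway is receiver-gain
invariant (asserted).

## 4. Longitudinal statistics

### 4.1 Rules

Undetectable *baselines* are imputed at the lowest measured ratio across
the cohort divided by two (identical value for all; detectable
measurements never altered; non-baseline missing scans simply excluded).
Scans are binned by ordinal post-dose index; bins with fewer than two
observations (the single fifth scan) are dropped from summaries and the
ANOVA.

### 4.2 RM-ANOVA and comparisons

The omnibus time effect is the general-linear-model form
`value ~ C(subject) + C(time_bin)` (statsmodels OLS + type-II ANOVA), so
subjects with missing cells still contribute; a complete-case variant is
provided. On complete balanced data this equals the textbook two-way
decomposition to 1e-8 relative (asserted against a brute-force oracle).

Post-dose-versus-baseline comparisons are the model's treatment-coded
time-bin contrasts (coefficient t and p from the same fit) — the
pooled-residual standard for repeated-measures post-hoc testing — adjusted
by Holm–Šidák over the family of four comparisons at α = 0.05. Per-bin
*paired t-tests* were rejected: shared imputed baselines give near-zero
difference variance for the affected subjects and produce a spuriously
significant 7.5-minute comparison, contradicting the modelled design.

Under a permuted null (each subject's time labels shuffled within
subject), the omnibus type-I error rate is computed by the acceptance
suite over 1,000 synthetic cohorts and asserted to lie in [0.03, 0.07].

### 4.3 Percent change

`100 × mean_final / mean_baseline` ("ratio of means", the convention
matching the design's 269% figure; the `increase` convention, ratio − 100,
is also available).

## 5. Known biases and numerical notes

- **Lineshape-mismatch bias.** At zero thermal noise the full chain
  returns 0.984–0.985 of the true ratio without contaminants (constant
  across truth levels, i.e. contrast-preserving) and 0.945–1.000 with the
  full contaminant set (the deterministic macromolecular comb adds a
  truth-dependent component). The suite asserts |bias| < 8% everywhere and
  constancy (< 2 points) in the contaminant-free case. A consequence of
  fitting Gaussians to Lorentzians by design; it largely cancels in group
  contrasts.
- **Recovery at the study noise regime.** Median |relative error| of the
  full-chain GSH/Cr at truth 0.0215 is ≈ 6% (asserted < 10% over 200
  scans); the single-scan mean fit error there is ≈ 38%.
- The cohort-mean fit error over analysed scans is ≈ 30% — somewhat below
  the single-scan figure because higher-concentration scans fit with
  proportionally smaller error.
- All fits are deterministic: multi-start initialisation, no stochastic
  optimisers; cohorts are bit-reproducible under a fixed seed (asserted).
- Derived child seeds are reduced modulo 2³¹.

## 6. Open decisions

- Whether the modelled design's ANOVA used complete cases or all
  available data is unknown; the default analyses the unbalanced table
  with subject as a blocking factor, and `complete_cases=True` is exposed.
- The "269%" figure is arithmetically a ratio of means (i.e. a 169%
  increase under the usual convention); both conventions are emitted.
- `SIGMA_SUBJECT` is identifiable only through the inferential pattern,
  not the group summaries; its value is recorded with that rationale.

## 7. Limitations

- Entirely synthetic: no vendor raw-data readers, no DICOM, no GUI; an
  import shim point is left at the container-format boundary.
- No pharmacokinetic modelling and no mixed-effects/Bayesian longitudinal
  models (non-goals).
- The macromolecular background is deterministic and shared across
  subjects; real MM contamination varies between subjects and sessions.
- The quantified fidelity reuses one frozen calibration of the spectral
  chain; changing generator constants invalidates it until recalibrated.
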