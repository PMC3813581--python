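# Methods

This note documents the models, estimators and numerical choices behind
`pepmrd`, what the synthetic-data generator does and does not emulate, and
the limitations a user should know before applying the pipeline to real
spectra.

## 1. Signal model and peak processing

A linear-mode MALDI-TOF serum profile is modeled as

    y(m) = Σⱼ aⱼ · exp(−(m − μⱼ)² / 2σⱼ²) + B·exp(−(m − m₀)/τ) + ε(m),

Gaussian peptide peaks on an exponentially decaying chemical baseline with
additive Gaussian detector noise. Peak widths grow linearly with mass
(σⱼ = σ₀·μⱼ/4625, σ₀ = 2 Da by default), the TOF-typical constant-resolving-
power regime.

**Baseline subtraction** is a rolling minimum over a 100 Da window,
smoothed by a moving average of the same width, subtracted and floored at
zero. Two refinements matter numerically: (i) the windowed minimum of a
noisy signal sits ~2–3 noise SD below the noise floor, so the residual
median is subtracted afterwards to recenter peak-free regions at zero —
without this, "baseline-subtracted" spectra keep a positive offset that
corrupts SNR thresholding; (ii) the window must exceed the widest peak
(it does, by ~5×) or peaks are eaten into.

**Peak picking** finds strict local maxima of the moving-average-smoothed
signal (1 Da window) with SNR ≥ 3. The noise scale is estimated robustly
from the positive half of the detrended signal, 1.4826 × median(resid |
resid > 0): the zero floor clips negative noise, so a plain MAD of the
residual underestimates noise by ~3× and would admit noise bumps as peaks.
For symmetric noise both estimators target the same SD. Apexes closer
than 0.15% of m/z are reduced to the tallest (non-maximum suppression);
this radius sits just above the 0.1% alignment tolerance, so no peaks
that could ever occupy distinct bins are lost, while wide high-mass peaks
stop yielding duplicate detections. Centroids are intensity-weighted means
over the apex ± its half-height half-width; intensities are baseline-
corrected apex heights (integrated areas would be the natural alternative
if quantifying across very different peak widths mattered; heights are
used because the downstream statistics are all within-bin comparisons).

## 2. Alignment and TIC normalization

Peaks from all samples are pooled, sorted by m/z, and clustered greedily
left to right. A peak joins the open bin iff

    (m − mean) ≤ tol · mean   and   (m − min) ≤ tol · mean′,

where `mean` is the bin's running intensity-weighted mean, `mean′` the
mean after admission, and tol = 0.001 (the ≤ 0.1% mass-shift rule; the
boundary case merges, and the conditions are written in subtraction form
so that an exact-boundary gap is not lost to floating point). The second
condition is what guarantees the output invariant — every pair of peaks
in a bin satisfies |mᵢ − mⱼ| ≤ tol · bin m/z — which the running-mean rule
alone does not (bins can "chain" beyond the tolerance). On well-separated
clusters, i.e. whenever run-to-run calibration jitter stays within the
tolerance, both rules coincide and the greedy result equals the unique
maximal tolerance-consistent partition (verified against exhaustive
enumeration on small instances).

Each sample contributes at most one peak per bin (most intense wins,
collisions logged); absent peaks are zeros — absence of a peptide is
informative in MALDI profiling. Rows are then divided by the sample's
total detected peak intensity ("total ion current" is interpreted as the
sum over detected peaks, not the raw profile integral, making
normalization independent of baseline handling). Every nonzero row sums
to 1 ± 1e-9; relative intensities are invariant to rescaling any single
spectrum.

## 3. Screening and classification

Per-bin differential screening uses the two-tailed **Welch** t-test
(unequal variances — MALDI intensities are heteroscedastic across groups);
bins with zero variance in both groups and equal means get p = 1.
Candidate selection thresholds raw p-values, matching the profiling
convention of stringent raw cutoffs (10⁻⁴ for disease-vs-healthy, 0.05
for remission contrasts); Benjamini–Hochberg adjustment is available via
a flag but off by default. Zero-inflated bins are not special-cased: zeros
enter the t-test as values, a documented limitation (a point-mass at zero
violates normality; at the stringent thresholds used this is conservative).

Classification is a soft-margin SVM with Gaussian kernel on the selected
bins, features standardized to zero mean / unit variance — without this
the kernel scale is dominated by the few most abundant peptides.
Hyperparameters come from the canonical coarse grid C ∈ 2⁻⁵,2⁻³,…,2¹⁵,
γ ∈ 2⁻¹⁵,…,2³, scored by mean stratified five-fold CV accuracy on the
training set; ties break toward smaller C then smaller γ (the weakest
model among equals). Standardization statistics are computed inside each
training fold; the leak-detector test demonstrates that screening on all
samples before CV inflates apparent accuracy on label-shuffled data while
the honest protocol stays at chance. Held-out evaluation reports
sensitivity and specificity at the SVM's native operating point (decision
score 0) — a fixed-threshold choice, documented because ROC-optimal
operating points are also computable — and the ROC by sweeping the
decision threshold over observed scores, with trapezoidal AUC. Tied
scores move as a block, which makes the trapezoidal area exactly the
tie-corrected Mann–Whitney statistic U/(n₊n₋); this identity is asserted
exactly in tests and in the acceptance run.

## 4. Marker analysis and survival

The MRD marker is the aligned bin matching m/z 4625 within the alignment
tolerance (an absent bin is an error naming the nearest bin, never a
silent substitution). Group summaries are boxplot statistics (median,
quartiles) plus pairwise Welch tests; groups of one subject report
collapsed quartiles and unavailable (NaN) tests.

Subjects are dichotomized at relative intensity 0.02. The exact boundary
goes to the **high** stratum by default (the stratification is described
both as ">0.02" and as "≥0.02" in the source material; the operational
figure-legend form ≥ is taken, and the rule is exposed as
`boundary_rule`). Survival comparison is Kaplan–Meier estimation and the
two-group log-rank test (lifelines; tied event times follow the standard
simultaneous-death convention). With no censoring the product-limit
estimator equals the empirical survivor function exactly, and the
log-rank χ² matches an explicit risk-set enumeration — both checked as
oracles in the test suite.

The longitudinal relapse rule — flag a subject when the marker rises over
k = 2 consecutive sampling intervals and the final value exceeds the
cutoff — is a deliberately minimal formalization of the clinical
anecdote it models (a monitored patient whose marker kept climbing and
who relapsed three months later). It is a heuristic, clearly labeled as
such: a constant series above the cutoff never flags, nor does any series
below it.

## 5. Synthetic cohort generator

The generator is the package's study-condition definition, not a tuning
knob. Defaults: 250 peptide peaks log-uniformly jitter-gridded over
1,000–10,000 Da (low-mass-dense, minimum spacing ≥ 0.37% of m/z, safely
above the 0.1% bin tolerance); base abundances log-normal over ~2 orders
of magnitude; per-run calibration jitter uniform in ±0.05% applied as a
single multiplicative mass factor (so two runs differ by ≤ 0.1%, the
alignment regime); within-run (spot) and between-run intensity noise
multiplicative log-normal per peak with CVs 9% and 18% — log-normal
because replicate tables report constant CV, not constant SD, and
per-peak (not global) run factors because a global factor would cancel
under TIC normalization. Between-run noise is composed as
cv_run² = cv_between² − cv_within².

Group structure: the marker's mean relative intensity per clinical group
is {newly diagnosed 0.040, relapse 0.040, HCR 0.022, MR 0.006, healthy
0.005, solid tumor 0.018, benign hematological 0.006} — the remission-
grade ordering with relapse at the newly-diagnosed level, solid tumors
elevated and benign disorders at the healthy level. Between-subject
marker spread is wide (log-normal, CV 0.8), chosen so that newly-diagnosed
patients straddle the 0.02 cutoff roughly as the published stratum sizes
(18 low / 15 high of 33) imply. Ten additional differential peptides
carry log₂ effects of ~±1.0–1.4 scaled by disease burden (1.0 at
diagnosis/relapse, 0.5 in HCR, 0.1 in MR); other peaks vary biologically
at CV 0.35.

Survival is exponential proportional hazards: hazard
h(x) = (ln 2 / 12) · exp(c·(x − 0.02)) per month for true marker relative
intensity x, i.e. median 12 months at the reference intensity. The
default coupling c = 15 reproduces the hazard-ratio scale of the
published strata (median 12 vs 7 months); "strong coupling" conditions in
the recovery tests use c = 60. Censoring: with probability `censor_rate`
(default 0.2) the subject is censored at a uniform fraction of the
unobserved event time. Closed-form survival functions make the generator
checkable by Monte Carlo against analytic curves.

**What the generator does not emulate:** isotope envelopes, detector
saturation, adduct/matrix cluster peaks, peak-shape asymmetry, mass-
dependent ionization suppression, batch drift beyond the per-run factor,
and the wet-lab bead-enrichment chemistry. Passing tests therefore show
that the *computational* pipeline recovers planted structure under
realistic noise magnitudes — not that the biological effect sizes of any
real cohort are reproduced. Absolute intensity units are arbitrary
throughout; only relative intensities are meaningful.

## 6. Problem sizes and numerical choices

The test suite and the acceptance run use desk-scale problem sizes chosen
to make the statistics decisive while keeping a full run in tens of
seconds: the recovery cohort is n = 40 per group across four groups (160
spectra at 0.25 Da sampling), replicate QC is the 6+6 within/between
design, screen calibration uses 1,000 null matrices of 50 bins at
n = 20+20, and the AUC identity is checked on 1,000 random score vectors.
Profile rendering evaluates each Gaussian only within ±6σ. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; pipeline reports are byte-identical across
runs with the same config and seeds.

Degenerate inputs are errors, not repairs: negative intensities,
duplicate m/z values, inverted mass ranges, single-class labels,
one-class test sets, empty survival inputs, unordered longitudinal
timestamps. Two deliberate exceptions: an empty spectrum yields an empty
peak list, and an empty candidate-peak selection is a clean "no candidate
peaks" pipeline outcome (both are legitimate analysis results).

## 7. Known limitations

- No m/z recalibration or warping (lock-mass, DTW): only tolerance
  binning, as in the modeled design. Calibration errors beyond 0.1%
  split bins rather than being corrected.
- Peak intensities are apex heights; area integration is not implemented.
- The t-test screen treats zeros (missing peaks) as intensities.
- The CV-selection metric is accuracy; AUC-based selection would be
  preferable for imbalanced designs (exposed only through custom grids
  and caller-side evaluation).
- The SVM model JSON stores standardized support vectors for exact
  decision-function reconstruction; it is not a generic sklearn
  serialization.
- mzML import is minimal (first spectrum, 32/64-bit float arrays, plain
  or zlib); vendor formats and imzML are out of scope.
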