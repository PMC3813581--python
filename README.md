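# pepmrd

Serum peptidome profiling pipeline for **minimal residual disease (MRD)
monitoring in acute leukemia (AL)**, built around linear-mode MALDI-TOF
mass spectra of the low-molecular-weight serum peptidome (1,000–10,000 Da).

Blood-based MRD assessment matters because bone-marrow-based methods
(multiparameter flow cytometry, fusion-transcript PCR) are invasive and
only apply to patients with a molecular signature. Serum peptide patterns
offer a minimally invasive alternative: the relative intensity of a single
peptide peak at **m/z 4625** — a SERPINA3 (α-1-antichymotrypsin) fragment
— tracks leukemic burden across remission grades and predicts overall
survival. `pepmrd` implements every computational stage of that study
design as a tested, reusable library plus CLI, driven by a synthetic-cohort
simulator so each stage is verifiable without patient data.

## What it computes

Given per-sample spectra *(m/z, intensity)* and clinical metadata:

1. **Peak processing** — rolling-minimum baseline subtraction; SNR-thresholded
   peak picking (SNR = apex / robust noise, noise from the MAD of the
   detrended signal); intensity-weighted centroids.
2. **Alignment + normalization** — peaks pooled across samples and merged
   greedily into bins under a relative mass tolerance of 0.1%
   (|Δm/z| / m/z ≤ 10⁻³); each sample's row divided by its total detected
   ion current, so entries are relative intensities rᵢⱼ with Σⱼ rᵢⱼ = 1.
3. **Screening** — per-bin two-tailed Welch t-tests between clinical groups;
   candidate peaks selected at a raw p-value threshold (BH correction
   available behind a flag).
4. **Classification** — Gaussian-kernel soft-margin SVM on the selected,
   standardized peaks; (C, γ) tuned by grid search over C ∈ 2⁻⁵…2¹⁵,
   γ ∈ 2⁻¹⁵…2³ with stratified five-fold cross-validation; held-out
   evaluation by sensitivity, specificity and trapezoidal ROC AUC
   (= tie-corrected Mann–Whitney U / n₊n₋).
5. **Marker + survival** — m/z 4625 relative-intensity distributions per
   remission grade; dichotomization at the 0.02 relative-intensity cutoff
   (boundary to the high stratum); Kaplan–Meier curves and the two-group
   log-rank test; a longitudinal relapse flag (k consecutive rises above
   the cutoff).
6. **Peptide mass** — average/monoisotopic masses from sequence and
   mass-consistency checks of a peak identity (the 40-residue SERPINA3
   fragment has average mass 4625.4 Da).

The synthetic cohort generator plants all of this structure — ~250
log-uniformly spaced Gaussian peaks, ≤0.1% per-run calibration jitter,
9%/18% within-/between-run intensity CV, remission-graded marker means
(newly diagnosed ≈ relapse > HCR > MR ≈ healthy), and exponential
proportional-hazards survival coupled to the marker — and records the
ground truth for testing.

## Worked example

```python
from pepmrd import (SimConfig, simulate_cohort, simulate_survival, spectra_to_matrix,
                    RemissionSVM, MarkerSurvival, split_train_test)

config = SimConfig(
    group_sizes={"healthy": 30, "newly_diagnosed": 30, "HCR": 20, "MR": 20},
    survival_coupling=30.0, seed=7,
)
spectra, records, truth = simulate_cohort(config)
records = simulate_survival(records, truth["marker_rel_intensity"],
                            coupling=30.0, censor_rate=0.2, seed=8)
matrix = spectra_to_matrix(spectra)

group_of = {r.subject_id: r.group for r in records}
ids = [s for s in matrix.sample_ids if group_of[s] in ("newly_diagnosed", "healthy")]
train, test = split_train_test(ids, [group_of[s] for s in ids], 0.6, seed=9)
y = {s: int(group_of[s] == "newly_diagnosed") for s in ids}

model = RemissionSVM(matrix.subset_samples(train), [y[s] for s in train], p_threshold=1e-4)
results = model.fit(seed=10)
print(results.summary())
report = results.evaluate(matrix.subset_samples(test), [y[s] for s in test])
print(f"test set: sensitivity {report.sensitivity:.2f}, "
      f"specificity {report.specificity:.2f}, AUC {report.auc:.3f}")

leukemia = [r for r in records if r.survival_months is not None]
print(MarkerSurvival.from_cohort(matrix, leukemia).fit().summary())
```

which prints:

```
Remission SVM (Gaussian kernel)
======================================
selected peaks             6
C                      0.125
gamma                  0.125
CV folds                   5
CV accuracy            1.000
support vectors           35
test set: sensitivity 0.92, specificity 1.00, AUC 1.000
Marker-stratified overall survival
========================================
high     n=26   deaths=23   median=   5.4 mo  2-yr S=  5.2%
low      n=44   deaths=32   median=  26.3 mo  2-yr S= 54.6%
log-rank chi2=28.577  p=0.0000
```

Read it as: six peaks separated newly-diagnosed patients from healthy
controls at p < 10⁻⁴ on the training split; the tuned SVM classified the
held-out samples essentially perfectly (the planted effects are strong at
this cohort size); and subjects whose m/z 4625 relative intensity was
≥ 0.02 at baseline died markedly faster (median 5.4 vs 26.3 months) —
the planted marker–survival coupling, recovered end to end from raw
spectra.

The same flow is available from the shell:

```bash
pepmrd run-all --seed 7 --out demo_run        # full replica + report.json
pepmrd mass --seq SALVETRTIVRFNRPFLMIIVPTDTQNIFFMSKVTNPKQA --match 4625
pepmrd simulate --out data --group healthy=10 --group newly_diagnosed=10
pepmrd peaks data/spectra/*.tsv --out data/peaks
pepmrd align data/peaks/*.csv --out data/matrix.csv
```

## Layout

```
src/pepmrd/
  core.py       Spectrum / Peak / PeakMatrix / SubjectRecord containers
  simulate.py   synthetic cohort + survival + replicate-QC generators
  io.py         TSV/CSV spectra, mzML (read), matrix + metadata IO
  peaks.py      baseline, SNR peak picking, alignment, TIC norm, run CV
  screen.py     Welch t-test screening and candidate selection
  svm.py        splits, grid-searched RBF SVM, ROC/AUC; RemissionSVM model
  survival.py   marker stats, 0.02 stratification, KM/log-rank; MarkerSurvival
  masses.py     peptide average/monoisotopic mass, peak-identity match
  pipeline.py   end-to-end orchestration with a reproducible run report
  cli.py        `pepmrd` command group
```
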