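"""Synthetic serum-peptidome cohort generator.

Emulates the statistical structure of a MALDI-TOF serum profiling study of
acute leukemia: ~250 detectable peptide peaks in the 1,000-10,000 Da
window, per-run mass-calibration jitter of at most 0.1% (relative), peak
intensity reproducibility of ~9% CV within-run and ~18% between-run,
clinical groups whose mean intensity differs at a subset of peaks — in
particular a planted MRD marker peptide (default m/z 4625) whose relative
intensity is monotone in disease burden (newly-diagnosed ~ relapse > HCR >
MR ~ healthy) — and overall survival negatively coupled to the marker's
baseline level through an exponential proportional-hazards model.

Every quantity the generator plants is recorded in a ground-truth map so
downstream operations (peak picking, alignment, screening, classification,
stratification, survival) can be tested against known answers.

The intensity model is multiplicative log-normal throughout: a peptide's
peak height for subject *i*, run *r*, spot acquisition is

    base_j * group_effect(g_i, j) * subject_ij * run_rj * spot_j

with each random factor log-normal and mean-one, so coefficients of
variation compose approximately as cv_total^2 = cv_within^2 + cv_run^2 and
the replicate CV is roughly constant across the dynamic range — the regime
that replicate QC tables report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .core import GROUPS, LEUKEMIA_GROUPS, Spectrum, SubjectRecord

#: Mean relative intensity of the planted marker peptide per clinical group.
#: Ordered as the remission-grade boxplots require: newly-diagnosed and
#: relapse highest, HCR intermediate, MR back at the healthy level; solid
#: tumors elevated, benign hematological disorders at the healthy level.
DEFAULT_MARKER_GROUP_MEANS: dict[str, float] = {
    "newly_diagnosed": 0.040,
    "relapse": 0.040,
    "HCR": 0.022,
    "MR": 0.006,
    "healthy": 0.005,
    "solid_tumor": 0.018,
    "benign_heme": 0.006,
}

#: Disease burden per group, used to scale the non-marker differential
#: peaks: full burden at diagnosis/relapse, partial in HCR, minimal in MR.
_BURDEN: dict[str, float] = {
    "newly_diagnosed": 1.0,
    "relapse": 1.0,
    "HCR": 0.5,
    "MR": 0.1,
    "healthy": 0.0,
    "solid_tumor": 0.3,
    "benign_heme": 0.05,
}


def default_effect_peaks() -> list[tuple[float, dict[str, float]]]:
    """Ten differential (non-marker) peptides with burden-scaled log2 effects."""
    positions = [1530.0, 2210.0, 2790.0, 3420.0, 3910.0, 5230.0, 6140.0, 7310.0, 8420.0, 9210.0]
    sizes = [1.4, -1.2, 1.1, -1.3, 1.2, 1.0, -1.1, 1.3, -1.0, 1.2]
    out = []
    for pos, size in zip(positions, sizes):
        out.append((pos, {g: size * _BURDEN[g] for g in GROUPS}))
    return out


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions.

    Intensity units are arbitrary — only TIC-normalized relative
    intensities are meaningful downstream.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"healthy": 10, "newly_diagnosed": 10}
    )
    n_peaks: int = 250
    mz_range: tuple[float, float] = (1000.0, 10000.0)
    marker_mz: float = 4625.0
    marker_group_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_GROUP_MEANS)
    )
    effect_peaks: list[tuple[float, dict[str, float]]] = field(
        default_factory=default_effect_peaks
    )
    calibration_jitter_max: float = 0.0005  # per-run relative mass error (uniform +/-)
    within_run_cv: float = 0.09
    between_run_cv: float = 0.18
    subject_cv: float = 0.35          # biological between-subject CV, non-marker peaks
    marker_subject_cv: float = 0.80   # biological spread of the marker (wide, per the
                                      # observed overlap of strata at diagnosis)
    baseline_params: tuple[float, float] = (40.0, 1500.0)  # amplitude, decay constant (Da)
    noise_sd: float = 1.0
    peak_width_sigma: float = 2.0     # Gaussian sigma in Da at the marker mass;
                                      # widths scale linearly with m/z (TOF-like)
    grid_step: float = 0.25           # profile sampling interval, Da
    runs_per_subject: int = 1
    survival_coupling: float = 15.0   # log-hazard slope per unit marker relative intensity
    base_hazard_median: float = 12.0  # months to median survival at the reference intensity
    reference_intensity: float = 0.02
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group sizes must be non-negative")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError(f"mz_range inverted: {self.mz_range}")
        if not 0 <= self.calibration_jitter_max <= 0.001:
            raise ValueError("calibration_jitter_max must lie in [0, 0.001]")
        if not lo < self.marker_mz < hi:
            raise ValueError("marker_mz must lie inside mz_range")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class _PeakPanel:
    """The cohort's fixed peptide panel: positions + base abundances."""

    positions: np.ndarray
    base_abundance: np.ndarray
    marker_index: int
    effect_indices: list[int]
    marker_abundance_by_group: dict[str, float]


def _build_panel(config: SimConfig, rng: np.random.Generator) -> _PeakPanel:
    lo, hi = config.mz_range
    n = config.n_peaks
    # log-uniform jittered grid: realistic low-mass-dense spacing whose
    # minimum gap (>=0.37% of m/z) stays well above the alignment tolerance
    log_lo, log_hi = math.log(lo), math.log(hi)
    gaps = (np.arange(n) + rng.uniform(0.2, 0.8, n)) / n
    positions = np.exp(log_lo + gaps * (log_hi - log_lo))
    # pin the marker and the differential peaks to exact positions by
    # replacing the nearest generated peptide
    pinned = [config.marker_mz] + [mz for mz, _ in config.effect_peaks if lo < mz < hi]
    indices = []
    for mz in pinned:
        j = int(np.argmin(np.abs(positions - mz)))
        positions[j] = mz
        indices.append(j)
    marker_index, effect_indices = indices[0], indices[1:]
    order = np.argsort(positions)
    positions = positions[order]
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    marker_index = int(rank[marker_index])
    effect_indices = [int(rank[j]) for j in effect_indices]

    base = rng.lognormal(mean=math.log(60.0), sigma=1.1, size=n)
    base[marker_index] = 0.0  # set per group below
    others_total = base.sum()
    marker_by_group = {
        g: r * others_total / (1.0 - r) for g, r in config.marker_group_means.items()
    }
    return _PeakPanel(positions, base, marker_index, effect_indices, marker_by_group)


def _subject_abundances(
    panel: _PeakPanel, config: SimConfig, group: str, rng: np.random.Generator
) -> np.ndarray:
    """True per-subject peptide abundances (before run/spot noise)."""
    amp = panel.base_abundance * _lognormal_factors(rng, config.subject_cv, panel.positions.size)
    for (mz, fc_by_group), j in zip(config.effect_peaks, panel.effect_indices):
        amp[j] *= 2.0 ** fc_by_group.get(group, 0.0)
    marker_mean = panel.marker_abundance_by_group.get(group)
    if marker_mean is None:
        raise ValueError(f"no marker_group_means entry for group {group!r}")
    amp[panel.marker_index] = marker_mean * float(
        _lognormal_factors(rng, config.marker_subject_cv, 1)[0]
    )
    return amp


def _render_profile(
    positions: np.ndarray,
    amplitudes: np.ndarray,
    config: SimConfig,
    run_jitter: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = config.mz_range
    grid = np.arange(lo, hi + config.grid_step, config.grid_step)
    amp_base, decay = config.baseline_params
    signal = amp_base * np.exp(-(grid - lo) / decay)
    shifted = positions * (1.0 + run_jitter)
    sigmas = config.peak_width_sigma * shifted / config.marker_mz
    for pos, a, s in zip(shifted, amplitudes, sigmas):
        i0 = int(np.searchsorted(grid, pos - 6 * s))
        i1 = int(np.searchsorted(grid, pos + 6 * s))
        if i1 > i0:
            window = grid[i0:i1]
            signal[i0:i1] += a * np.exp(-0.5 * ((window - pos) / s) ** 2)
    signal += rng.normal(0.0, config.noise_sd, grid.size)
    return grid, np.clip(signal, 0.0, None)


def _run_cv(config: SimConfig) -> float:
    """Run-level CV so that within + run noise composes to the between-run CV."""
    return math.sqrt(max(config.between_run_cv**2 - config.within_run_cv**2, 0.0))


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[Spectrum], list[SubjectRecord], dict]:
    """Generate one cohort: spectra, subject records, and ground truth.

    Returns one spectrum per subject-run. The ground-truth map records the
    planted peak positions, per-group effect sizes, and each subject's true
    marker relative intensity (marker abundance / total abundance), which
    drives the survival simulation. Identical config and seed give
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    panel = _build_panel(config, rng)
    cv_run = _run_cv(config)

    spectra: list[Spectrum] = []
    records: list[SubjectRecord] = []
    marker_truth: dict[str, float] = {}
    group_of: dict[str, str] = {}
    counter = 0
    for group in GROUPS:  # fixed iteration order: determinism independent of dict order
        for _ in range(config.group_sizes.get(group, 0)):
            sid = f"S{counter:04d}"
            counter += 1
            amp = _subject_abundances(panel, config, group, rng)
            marker_truth[sid] = float(amp[panel.marker_index] / amp.sum())
            group_of[sid] = group
            runs = []
            for r in range(config.runs_per_subject):
                rid = f"{sid}-r{r}"
                runs.append(rid)
                jitter = rng.uniform(-config.calibration_jitter_max, config.calibration_jitter_max)
                run_f = _lognormal_factors(rng, cv_run, amp.size)
                spot_f = _lognormal_factors(rng, config.within_run_cv, amp.size)
                grid, signal = _render_profile(
                    panel.positions, amp * run_f * spot_f, config, jitter, rng
                )
                spectra.append(Spectrum(grid, signal, sid, rid))
            records.append(SubjectRecord(sid, group, runs=runs))

    truth = {
        "peak_mz": panel.positions,
        "base_abundance": panel.base_abundance,
        "marker_mz": config.marker_mz,
        "marker_index": panel.marker_index,
        "marker_group_means": dict(config.marker_group_means),
        "effect_peaks": [
            {"mz": mz, "log2fc": dict(fc)} for mz, fc in config.effect_peaks
        ],
        "marker_rel_intensity": marker_truth,
        "group": group_of,
    }
    return spectra, records, truth


def simulate_survival(
    records: Sequence[SubjectRecord],
    marker_truth: dict[str, float],
    coupling: float,
    censor_rate: float,
    seed: int,
    base_hazard_median: float = 12.0,
    reference_intensity: float = 0.02,
) -> list[SubjectRecord]:
    """Attach survival outcomes to the leukemia subjects.

    Exponential proportional hazards: subject *i* with true marker relative
    intensity x_i has hazard ``h0 * exp(coupling * (x_i - reference))``
    where ``h0 = log(2) / base_hazard_median`` months^-1, so higher marker
    intensity means stochastically shorter survival. With probability
    ``censor_rate`` the subject is censored at a uniform fraction of the
    (unobserved) event time. Non-leukemia records pass through unchanged.
    """
    if not np.isfinite(coupling):
        raise ValueError("coupling must be finite")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h0 = math.log(2.0) / base_hazard_median
    out: list[SubjectRecord] = []
    for rec in records:
        if rec.group not in LEUKEMIA_GROUPS:
            out.append(replace(rec))
            continue
        if rec.subject_id not in marker_truth:
            raise KeyError(f"marker_truth missing subject {rec.subject_id!r}")
        x = marker_truth[rec.subject_id]
        hazard = h0 * math.exp(coupling * (x - reference_intensity))
        t_event = rng.exponential(1.0 / hazard)
        censored = rng.uniform() < censor_rate
        if censored:
            months, event = t_event * rng.uniform(), False
        else:
            months, event = t_event, True
        out.append(replace(rec, survival_months=float(months), event=bool(event)))
    return out


def simulate_replicate_runs(
    config: SimConfig, n_within: int = 6, n_between: int = 6
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Replicate-QC design: repeated acquisitions of one pooled sample.

    Within-run replicates are spots on the same run (shared calibration and
    run-level factors, fresh spot noise); between-run replicates each get a
    fresh run (fresh calibration jitter and run factors plus spot noise).
    The pooled sample's abundances use the healthy group means.
    """
    rng = np.random.default_rng(config.seed)
    panel = _build_panel(config, rng)
    amp = _subject_abundances(panel, config, "healthy", rng)
    cv_run = _run_cv(config)

    within: list[Spectrum] = []
    jitter0 = rng.uniform(-config.calibration_jitter_max, config.calibration_jitter_max)
    run0 = _lognormal_factors(rng, cv_run, amp.size)
    for k in range(n_within):
        spot = _lognormal_factors(rng, config.within_run_cv, amp.size)
        grid, signal = _render_profile(panel.positions, amp * run0 * spot, config, jitter0, rng)
        within.append(Spectrum(grid, signal, subject_id="pool", run_id=f"w{k}"))

    between: list[Spectrum] = []
    for k in range(n_between):
        jitter = rng.uniform(-config.calibration_jitter_max, config.calibration_jitter_max)
        run_f = _lognormal_factors(rng, cv_run, amp.size)
        spot = _lognormal_factors(rng, config.within_run_cv, amp.size)
        grid, signal = _render_profile(panel.positions, amp * run_f * spot, config, jitter, rng)
        between.append(Spectrum(grid, signal, subject_id="pool", run_id=f"b{k}"))
    return within, between


def null_peak_matrix(
    n_samples: int, n_bins: int, cv: float = 0.18, seed: int = 0
):
    """A TIC-normalized peak matrix with no group structure.

    Per-sample bin intensities are mean-one log-normal perturbations of a
    shared abundance profile; rows are normalized to sum to one. Useful for
    calibration (type-I error) studies without rendering full spectra.
    """
    from .core import PeakMatrix

    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=math.log(60.0), sigma=1.1, size=n_bins)
    raw = base * _lognormal_factors(rng, cv, (n_samples, n_bins))
    rel = raw / raw.sum(axis=1, keepdims=True)
    lo, hi = math.log(1000.0), math.log(10000.0)
    bin_mz = np.exp(np.linspace(lo, hi, n_bins + 2)[1:-1])
    return PeakMatrix(bin_mz, [f"S{i:04d}" for i in range(n_samples)], rel)
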