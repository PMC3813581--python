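"""Core in-memory containers for the serum peptidome pipeline.

The pipeline moves through three representations: a raw profile
:class:`Spectrum` (m/z vs intensity for one MALDI-TOF acquisition), a list
of picked :class:`Peak` objects per spectrum, and the cross-sample aligned,
TIC-normalized :class:`PeakMatrix` on which all statistics run. Clinical
annotation travels alongside as :class:`SubjectRecord` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Analysis window in Da. Points and peaks outside this range are ignored
#: downstream; raw spectra may extend beyond it.
MASS_WINDOW = (1000.0, 10000.0)


@dataclass
class Spectrum:
    """One acquisition's raw profile.

    Parameters
    ----------
    mz : array of float
        Mass-to-charge values in Da, strictly increasing after validation.
    intensity : array of float
        Non-negative intensities in arbitrary units, same length as ``mz``.
    subject_id, run_id : str
        Sample provenance labels; one subject may have several runs.
    """

    mz: np.ndarray
    intensity: np.ndarray
    subject_id: str = ""
    run_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be one-dimensional")
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"mz (n={self.mz.size}) and intensity (n={self.intensity.size}) "
                "must have equal length"
            )
        if np.any(self.intensity < 0):
            bad = float(self.mz[np.argmax(self.intensity < 0)])
            raise ValueError(f"negative intensity at m/z {bad}")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size > 1:
            dup = np.flatnonzero(np.diff(self.mz) == 0)
            if dup.size:
                raise ValueError(f"duplicate m/z value {self.mz[dup[0]]!r}")

    def __len__(self) -> int:
        return int(self.mz.size)

    def crop(self, low: float = MASS_WINDOW[0], high: float = MASS_WINDOW[1]) -> "Spectrum":
        """Restrict to the analysis window (inclusive bounds)."""
        keep = (self.mz >= low) & (self.mz <= high)
        return Spectrum(self.mz[keep], self.intensity[keep], self.subject_id, self.run_id)


@dataclass(frozen=True)
class Peak:
    """A picked peak: baseline-corrected apex with SNR."""

    centroid_mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("peak intensity must be positive")


@dataclass
class PeakMatrix:
    """Aligned peak bins x samples, TIC-normalized.

    ``rel_intensity[i, j]`` is sample *i*'s relative intensity in bin *j*
    (its peak height divided by the sum of all its detected peak heights).
    A sample with no detected peaks keeps an all-zero row; every other row
    sums to 1. ``tolerance`` is the relative mass tolerance used to merge
    peaks into a bin (0.001 = the 0.1% mass-shift rule).
    """

    bin_mz: np.ndarray
    sample_ids: list[str]
    rel_intensity: np.ndarray
    tolerance: float = 0.001

    def __post_init__(self) -> None:
        self.bin_mz = np.asarray(self.bin_mz, dtype=float)
        self.rel_intensity = np.asarray(self.rel_intensity, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.rel_intensity.shape != (len(self.sample_ids), self.bin_mz.size):
            raise ValueError(
                f"rel_intensity shape {self.rel_intensity.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.bin_mz.size} bins"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id in PeakMatrix")
        if self.bin_mz.size > 1 and np.any(np.diff(self.bin_mz) <= 0):
            raise ValueError("bin_mz must be strictly increasing")
        if np.any(self.rel_intensity < 0):
            raise ValueError("relative intensities must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bins(self) -> int:
        return int(self.bin_mz.size)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample_id {sample_id!r}") from None

    def nearest_bin(self, mz: float) -> int:
        """Index of the bin whose consensus m/z is closest to ``mz``."""
        if self.n_bins == 0:
            raise ValueError("matrix has no bins")
        return int(np.argmin(np.abs(self.bin_mz - mz)))

    def find_bin(self, mz: float, tol_rel: Optional[float] = None) -> int:
        """Index of the bin matching ``mz`` within a relative tolerance.

        Raises ``KeyError`` naming the nearest bin when no bin matches.
        """
        tol = self.tolerance if tol_rel is None else tol_rel
        j = self.nearest_bin(mz)
        if abs(self.bin_mz[j] - mz) / mz <= tol:
            return j
        raise KeyError(
            f"no bin within {tol:.4%} of m/z {mz:g}; nearest is {self.bin_mz[j]:.2f}"
        )

    def column(self, mz: float, tol_rel: Optional[float] = None) -> np.ndarray:
        return self.rel_intensity[:, self.find_bin(mz, tol_rel)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return PeakMatrix(
            self.bin_mz.copy(), list(sample_ids), self.rel_intensity[idx], self.tolerance
        )

    def subset_bins(self, bin_mz: Sequence[float], tol_rel: Optional[float] = None) -> "PeakMatrix":
        """Restrict to the bins matching the given consensus m/z values."""
        idx = sorted(self.find_bin(m, tol_rel) for m in bin_mz)
        return PeakMatrix(
            self.bin_mz[idx], list(self.sample_ids), self.rel_intensity[:, idx], self.tolerance
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rel_intensity,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"{m:.2f}" for m in self.bin_mz],
        )


#: Clinical groups understood throughout the package. Leukemia groups carry
#: survival information; the last two are the disease-specificity controls.
GROUPS = (
    "healthy",
    "newly_diagnosed",
    "HCR",
    "MR",
    "relapse",
    "solid_tumor",
    "benign_heme",
)

#: Groups that are acute-leukemia disease states (survival simulation applies).
LEUKEMIA_GROUPS = ("newly_diagnosed", "HCR", "MR", "relapse")


@dataclass
class SubjectRecord:
    """Clinical annotation for one subject.

    ``survival_months`` is an event time when ``event`` is True and a
    censoring time when False; it is ``None`` for subjects without
    follow-up (controls, or survival simulation disabled).
    """

    subject_id: str
    group: str
    subtype: Optional[str] = None
    survival_months: Optional[float] = None
    event: Optional[bool] = None
    runs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.survival_months is not None and self.survival_months < 0:
            raise ValueError("survival_months must be non-negative")


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records to the metadata table (one row per subject-run)."""
    rows = []
    for r in records:
        runs = r.runs or [""]
        for run in runs:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "subtype": r.subtype,
                    "survival_months": r.survival_months,
                    "event": r.event,
                    "run_id": run,
                }
            )
    return pd.DataFrame(rows)
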