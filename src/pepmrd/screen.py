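"""Per-peak differential screening between two clinical groups.

Each aligned bin is tested with a two-tailed Welch (unequal-variance)
t-test on relative intensities; candidate peaks for model building are
those below a raw p-value threshold (no multiplicity correction by
default, with Benjamini-Hochberg available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PeakMatrix


@dataclass
class ScreenResult:
    bin_mz: float
    t_stat: float
    p_value: float
    selected: bool
    threshold: float
    group_means: tuple[float, float]


def peak_ttests(
    matrix: PeakMatrix, labels: Sequence, threshold: float = 0.05
) -> list[ScreenResult]:
    """Welch two-tailed t-test per bin between the two label classes.

    ``labels`` is a per-sample binary labelling (bool, 0/1, or two distinct
    values; the sorted-second value is the "positive" class whose mean
    enters ``group_means`` first). Degenerate bins — zero variance in both
    groups with equal means — get t = 0, p = 1. Both classes need at least
    two samples.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_samples:
        raise ValueError("labels length must equal the number of samples")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, found {classes.size}")
    neg, pos = classes[0], classes[1]
    a = matrix.rel_intensity[labels == pos]
    b = matrix.rel_intensity[labels == neg]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both groups need >= 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: scipy yields nan (equal means) or +/-inf
    degenerate = ~np.isfinite(t)
    equal_means = degenerate & np.isclose(a.mean(axis=0), b.mean(axis=0))
    t[equal_means], p[equal_means] = 0.0, 1.0
    # equal-constant-vs-different-constant bins: infinitely strong evidence
    t[degenerate & ~equal_means] = np.sign(
        a.mean(axis=0)[degenerate & ~equal_means] - b.mean(axis=0)[degenerate & ~equal_means]
    ) * np.inf
    p[degenerate & ~equal_means] = 0.0
    return [
        ScreenResult(
            bin_mz=float(matrix.bin_mz[j]),
            t_stat=float(t[j]),
            p_value=float(p[j]),
            selected=bool(p[j] < threshold),
            threshold=threshold,
            group_means=(float(a.mean(axis=0)[j]), float(b.mean(axis=0)[j])),
        )
        for j in range(matrix.n_bins)
    ]


def select_candidates(
    results: Sequence[ScreenResult], threshold: float, bh: bool = False
) -> list[float]:
    """Bin m/z values passing the p-value threshold, most significant first.

    Raw p-values by default; ``bh=True`` applies Benjamini-Hochberg and
    thresholds the adjusted values instead. Sorted by ascending p, ties
    broken by ascending bin m/z; an empty selection is allowed.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    p = np.array([r.p_value for r in results])
    if bh and p.size:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    order = sorted(range(len(results)), key=lambda j: (p[j], results[j].bin_mz))
    return [results[j].bin_mz for j in order if p[j] < threshold]


def screen_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_mz": [r.bin_mz for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_value": [r.p_value for r in results],
            "selected": [r.selected for r in results],
            "mean_pos": [r.group_means[0] for r in results],
            "mean_neg": [r.group_means[1] for r in results],
        }
    )
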