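"""Gaussian-kernel SVM remission classification.

The study design this mirrors: samples are split (stratified by clinical
group) into a training and a testing set; candidate peaks are screened on
the training set only; a radial-basis-function SVM is tuned by grid search
over (C, gamma) with five-fold cross-validation on the training set; the
chosen model is refit on the full training set and judged on the held-out
test set by sensitivity, specificity and the area under the ROC curve.

Features (relative intensities at the selected bins) are standardized to
zero mean / unit variance using statistics from the training folds only,
so the Gaussian kernel scale is comparable across peaks whose mean
intensities differ by orders of magnitude.

The module exposes the individual operations (:func:`split_train_test`,
:func:`grid_search_svm`, :func:`evaluate`) and a Model/Results pair
(:class:`RemissionSVM` / :class:`RemissionSVMResults`) wrapping them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import PeakMatrix


def default_grid() -> list[tuple[float, float]]:
    """The canonical coarse RBF grid: C in 2^-5..2^15, gamma in 2^-15..2^3."""
    cs = [2.0**k for k in range(-5, 16, 2)]
    gammas = [2.0**k for k in range(-15, 4, 2)]
    return [(c, g) for c in cs for g in gammas]


def split_train_test(
    sample_ids: Sequence[str],
    groups: Sequence[str],
    train_size,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Random stratified split into training and testing sets.

    ``train_size`` is either a fraction in (0, 1) applied per group
    (rounded), or a mapping group -> exact training count. The split is a
    partition (disjoint and exhaustive) and deterministic given the seed.
    Groups with fewer than 2 members are an error.
    """
    sample_ids = [str(s) for s in sample_ids]
    groups = [str(g) for g in groups]
    if len(sample_ids) != len(groups):
        raise ValueError("sample_ids and groups must have equal length")
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for sid, g in zip(sample_ids, groups):
        by_group.setdefault(g, []).append(sid)
    train: list[str] = []
    test: list[str] = []
    for g in sorted(by_group):
        members = by_group[g]
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        if isinstance(train_size, dict):
            n_train = int(train_size[g])
        else:
            if not 0 < train_size < 1:
                raise ValueError("fractional train_size must lie in (0, 1)")
            n_train = int(round(train_size * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1)
        if not 0 <= n_train <= len(members):
            raise ValueError(f"train count {n_train} out of range for group {g!r}")
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return train, test


@dataclass
class SVMModelSpec:
    """A fitted RBF-SVM model: selected peaks, tuned hyperparameters and
    the training-set standardization constants."""

    selected_bins: list[float]
    C: float
    gamma: float
    cv_folds: int = 5
    fold_seed: int = 0
    cv_accuracy: float = float("nan")
    scaler_mean: Optional[np.ndarray] = None
    scaler_scale: Optional[np.ndarray] = None
    n_support: Optional[list[int]] = None
    decision_scores: Optional[np.ndarray] = None
    support_vectors: Optional[np.ndarray] = None  # standardized feature space
    dual_coef: Optional[np.ndarray] = None
    intercept: float = 0.0
    _svc: Optional[SVC] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.selected_bins:
            raise ValueError("selected_bins must be non-empty")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def decision_function(self, matrix: PeakMatrix) -> np.ndarray:
        X = matrix.subset_bins(self.selected_bins).rel_intensity
        Xs = (X - self.scaler_mean) / self.scaler_scale
        if self._svc is not None:
            return self._svc.decision_function(Xs)
        if self.support_vectors is None:
            raise ValueError("model has not been fitted")
        # RBF decision: sum_i alpha_i exp(-gamma ||sv_i - x||^2) + b
        d2 = ((Xs[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def to_json(self, path) -> None:
        payload = {
            "selected_bins": [float(b) for b in self.selected_bins],
            "C": self.C,
            "gamma": self.gamma,
            "cv_folds": self.cv_folds,
            "fold_seed": self.fold_seed,
            "cv_accuracy": self.cv_accuracy,
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_scale": None if self.scaler_scale is None else self.scaler_scale.tolist(),
            "n_support": self.n_support,
            "support_vectors": None
            if self.support_vectors is None
            else self.support_vectors.tolist(),
            "dual_coef": None if self.dual_coef is None else self.dual_coef.tolist(),
            "intercept": self.intercept,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SVMModelSpec":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {
            k: None if payload.get(k) is None else np.asarray(payload[k], dtype=float)
            for k in ("scaler_mean", "scaler_scale", "support_vectors", "dual_coef")
        }
        return cls(
            selected_bins=payload["selected_bins"],
            C=payload["C"],
            gamma=payload["gamma"],
            cv_folds=payload["cv_folds"],
            fold_seed=payload["fold_seed"],
            cv_accuracy=payload["cv_accuracy"],
            n_support=payload.get("n_support"),
            intercept=float(payload.get("intercept", 0.0)),
            **arrays,
        )


def _restrict(matrix: PeakMatrix, bins: Sequence[float]) -> np.ndarray:
    return matrix.subset_bins(bins).rel_intensity


def grid_search_svm(
    matrix_train: PeakMatrix,
    labels_train: Sequence,
    selected_bins: Sequence[float],
    grid: Optional[Sequence[tuple[float, float]]] = None,
    cv_folds: int = 5,
    fold_seed: int = 0,
) -> SVMModelSpec:
    """Tune (C, gamma) by stratified k-fold CV accuracy and refit.

    For each grid point the mean cross-validated accuracy is computed on
    the training matrix restricted to ``selected_bins``, standardizing
    with training-fold statistics only. The maximizer wins; ties break
    toward smaller C then smaller gamma. The returned spec is refit on the
    whole training set (its scaler constants come from the full set).
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("grid must be non-empty")
    y = np.asarray(labels_train)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels_train must contain exactly two classes")
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify into "
            f"{cv_folds} folds without a single-class fold"
        )
    X = _restrict(matrix_train, selected_bins)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
    folds = list(skf.split(X, y))

    best: tuple[float, float, float] = (-np.inf, np.inf, np.inf)  # (acc, C, gamma)
    best_params = grid[0]
    for C, gamma in grid:
        correct = 0
        for tr, va in folds:
            pipe = Pipeline(
                [("scale", StandardScaler()), ("svc", SVC(C=C, gamma=gamma, kernel="rbf"))]
            )
            pipe.fit(X[tr], y[tr])
            correct += int((pipe.predict(X[va]) == y[va]).sum())
        acc = correct / y.size
        key = (acc, -C, -gamma)
        if key > (best[0], -best[1], -best[2]):
            best = (acc, C, gamma)
            best_params = (C, gamma)

    C, gamma = best_params
    scaler = StandardScaler().fit(X)
    svc = SVC(C=C, gamma=gamma, kernel="rbf").fit(scaler.transform(X), y)
    return SVMModelSpec(
        selected_bins=[float(b) for b in selected_bins],
        C=C,
        gamma=gamma,
        cv_folds=cv_folds,
        fold_seed=fold_seed,
        cv_accuracy=float(best[0]),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        n_support=[int(n) for n in svc.n_support_],
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        _svc=svc,
    )


@dataclass
class EvalReport:
    """Held-out evaluation: sensitivity/specificity at an operating point
    plus the full ROC curve and its trapezoidal AUC."""

    sensitivity: float
    specificity: float
    auc: float
    roc_points: list[tuple[float, float]]
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def roc_from_scores(scores: np.ndarray, y: np.ndarray) -> tuple[list[tuple[float, float]], float]:
    """ROC points by sweeping the decision threshold over all observed
    scores, and the trapezoidal AUC.

    ``y`` is boolean (True = positive). Points run from (0, 0) to (1, 1)
    and are nondecreasing in both coordinates; tied scores move as a block
    (which is what makes the trapezoidal area equal the tie-corrected
    Mann-Whitney statistic U / (n_pos * n_neg)).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC undefined: evaluation needs both classes")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep only the last index of each tied-score block
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate(
    model: SVMModelSpec,
    matrix_test: PeakMatrix,
    labels_test: Sequence,
    operating_point: float = 0.0,
) -> EvalReport:
    """Test-set sensitivity/specificity/ROC/AUC for a fitted model.

    Sensitivity and specificity are taken at the decision-score threshold
    ``operating_point`` (default 0, the SVM's native rule). The positive
    class is the larger of the two label values.
    """
    y = np.asarray(labels_test)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("test set must contain both classes")
    pos = classes[1]
    scores = model.decision_function(matrix_test)
    model.decision_scores = scores
    is_pos = y == pos
    pred_pos = scores > operating_point
    sens = float(pred_pos[is_pos].mean())
    spec = float((~pred_pos[~is_pos]).mean())
    roc, auc = roc_from_scores(scores, is_pos)
    return EvalReport(
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        roc_points=roc,
        n_pos=int(is_pos.sum()),
        n_neg=int((~is_pos).sum()),
    )


# -- Model / Results layer ----------------------------------------------------


class RemissionSVM:
    """RBF-SVM classifier of remission state built from a peak matrix.

    Parameters
    ----------
    matrix : PeakMatrix
        Training samples (aligned relative intensities).
    labels : sequence
        Binary class labels, one per sample.
    selected_bins : sequence of float, optional
        Candidate peak bins (e.g. from :func:`pepmrd.screen.select_candidates`).
        When omitted, ``p_threshold`` screens the training matrix itself.
    p_threshold : float
        Welch-t screening threshold used when ``selected_bins`` is None.
    """

    def __init__(
        self,
        matrix: PeakMatrix,
        labels: Sequence,
        selected_bins: Optional[Sequence[float]] = None,
        p_threshold: float = 0.0001,
    ) -> None:
        self.matrix = matrix
        self.labels = np.asarray(labels)
        if selected_bins is None:
            from .screen import peak_ttests, select_candidates

            results = peak_ttests(matrix, labels, threshold=p_threshold)
            selected_bins = select_candidates(results, p_threshold)
            if not selected_bins:
                raise ValueError(f"no candidate peaks at p < {p_threshold}")
        self.selected_bins = [float(b) for b in selected_bins]

    @classmethod
    def from_dataframe(cls, frame, labels, **kwargs) -> "RemissionSVM":
        """Build from a samples x bins DataFrame (columns parseable as m/z)."""
        bin_mz = np.array([float(c) for c in frame.columns])
        matrix = PeakMatrix(bin_mz, [str(i) for i in frame.index], frame.to_numpy(dtype=float))
        return cls(matrix, labels, **kwargs)

    def fit(
        self,
        grid: Optional[Sequence[tuple[float, float]]] = None,
        cv_folds: int = 5,
        seed: int = 0,
    ) -> "RemissionSVMResults":
        spec = grid_search_svm(
            self.matrix, self.labels, self.selected_bins, grid, cv_folds, fold_seed=seed
        )
        return RemissionSVMResults(self, spec)


class RemissionSVMResults:
    """Fit results: tuned hyperparameters, CV accuracy, evaluation."""

    def __init__(self, model: RemissionSVM, spec: SVMModelSpec) -> None:
        self.model = model
        self.spec = spec

    @property
    def params(self) -> dict:
        return {"C": self.spec.C, "gamma": self.spec.gamma}

    @property
    def cv_accuracy(self) -> float:
        return self.spec.cv_accuracy

    def evaluate(
        self, matrix_test: PeakMatrix, labels_test: Sequence, operating_point: float = 0.0
    ) -> EvalReport:
        return evaluate(self.spec, matrix_test, labels_test, operating_point)

    def plot_roc(self, report: EvalReport, ax=None):
        """Plot a held-out ROC curve (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr = zip(*report.roc_points)
        ax.plot(fpr, tpr, drawstyle="steps-post", label=f"AUC = {report.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls=":", color="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        return ax

    def summary(self) -> str:
        s = self.spec
        lines = [
            "Remission SVM (Gaussian kernel)",
            "=" * 38,
            f"selected peaks      {len(s.selected_bins):>8d}",
            f"C                   {s.C:>8g}",
            f"gamma               {s.gamma:>8g}",
            f"CV folds            {s.cv_folds:>8d}",
            f"CV accuracy         {s.cv_accuracy:>8.3f}",
            f"support vectors     {sum(s.n_support or []):>8d}",
        ]
        return "\n".join(lines)
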