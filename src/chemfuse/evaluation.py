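"""Classification performance statistics and the permutation test.

Per-class performance is summarised by the *efficiency*, the geometric
mean of sensitivity and specificity computed from one-vs-rest confusion
counts; overall performance by the total accuracy rate in percent.  PLS-DA
models are additionally screened for overfitting by a label-permutation
test: if the least-squares line of Q² against the permuted-label
correlation crosses the vertical axis at or below zero, the model's
predictive power genuinely depends on the true labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import PLSDA, _cv_q2_per_lv, _one_hot


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FN/TN/FP per class."""

    counts: dict[str, dict[str, int]]
    class_order: list[str]

    def __getitem__(self, cls: str) -> dict[str, int]:
        return self.counts[cls]


def confusion(y_true, y_pred, class_order: list[str]) -> ConfusionCounts:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    known = set(class_order)
    for lab in y_true + y_pred:
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class_order")
    out = {}
    for c in class_order:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        tn = sum(1 for t, p in zip(y_true, y_pred) if t != c and p != c)
        out[c] = {"TP": tp, "FN": fn, "TN": tn, "FP": fp}
    return ConfusionCounts(counts=out, class_order=list(class_order))


def efficiency(counts: ConfusionCounts, cls: str) -> float:
    """Geometric mean of sensitivity and specificity for one class.

    Undefined (NaN) when the class has no positive or no negative samples.
    """
    c = counts[cls]
    pos = c["TP"] + c["FN"]
    neg = c["TN"] + c["FP"]
    if pos == 0 or neg == 0:
        return float("nan")
    return float(np.sqrt((c["TP"] / pos) * (c["TN"] / neg)))


def total_accuracy(y_true, y_pred) -> float:
    """Percentage of correctly identified samples, to 2 decimals."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    correct = sum(1 for t, p in zip(y_true, y_pred) if t == p)
    return round(100.0 * correct / len(y_true), 2)


@dataclass
class PermutationResult:
    """Outcome of a label-permutation test of a PLS-DA configuration."""

    n_iterations: int
    permuted_r2q2: list[tuple[float, float, float]]  # (label corr, R2, Q2)
    original_r2q2: tuple[float, float]
    q2_intercept: float
    q2_slope: float = 0.0

    @property
    def not_overfitting(self) -> bool:
        return self.q2_intercept <= 0.0

    def plot(self, ax=None):
        """Q² vs permuted-label correlation with the regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.array([c for c, _, _ in self.permuted_r2q2])
        q2 = np.array([q for _, _, q in self.permuted_r2q2])
        ax.scatter(xs, q2, s=18, label="permuted")
        ax.scatter([1.0], [self.original_r2q2[1]], color="red",
                   label="original")
        grid = np.linspace(min(xs.min(), 0), 1, 50)
        ax.plot(grid, self.q2_intercept + self.q2_slope * grid,
                ls="--", lw=0.8)
        ax.set_xlabel("correlation with original labels")
        ax.set_ylabel("Q²")
        ax.legend()
        return ax


def _label_correlation(Y_perm: np.ndarray, Y_orig: np.ndarray) -> float:
    a = (Y_perm - Y_perm.mean(axis=0)).ravel()
    b = (Y_orig - Y_orig.mean(axis=0)).ravel()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def permutation_test(X_cal: np.ndarray, y_cal, max_lv: int = 10,
                     n_iter: int = 30, seed: int = 0,
                     folds: int = 7) -> PermutationResult:
    """Permutation test of a PLS-DA model fitted to ``(X_cal, y_cal)``.

    The model is first fitted normally (latent-variable count by 7-fold
    CV).  Then the class labels are permuted ``n_iter`` times; each
    permuted model is refitted with the same latent-variable count, and
    its R², cross-validated Q², and correlation with the original one-hot
    labels are recorded.  A least-squares line of Q² against the label
    correlation — including the original model at correlation 1 — is
    reported through its vertical-axis intercept; at or below zero means
    the model is not overfitting.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = list(y_cal)
    rng = np.random.default_rng(seed)
    base = PLSDA(X_cal, y_cal).fit(max_lv=max_lv, folds=folds)
    a = base.n_latent
    Y = _one_hot(y_cal, base.class_order)
    points = []
    for _ in range(n_iter):
        perm = rng.permutation(len(y_cal))
        while list(np.asarray(y_cal)[perm]) == y_cal:  # re-draw degenerate
            perm = rng.permutation(len(y_cal))
        y_p = [y_cal[i] for i in perm]
        res = PLSDA(X_cal, y_p, class_order=base.class_order).fit(
            max_lv=a, folds=folds, n_latent=a)
        corr = _label_correlation(_one_hot(y_p, base.class_order), Y)
        points.append((corr, res.r2y, res.q2))
    xs = np.array([c for c, _, _ in points] + [1.0])
    q2s = np.array([q for _, _, q in points] + [base.q2])
    slope, intercept = np.polyfit(xs, q2s, 1)
    return PermutationResult(
        n_iterations=n_iter, permuted_r2q2=points,
        original_r2q2=(base.r2y, base.q2), q2_intercept=float(intercept),
        q2_slope=float(slope))
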