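"""Mid-level feature extraction: PCA scores and Boruta variable selection.

Both extractors are fitted on the calibration set only; validation data is
passed through the fitted transform (score projection for PCA, column
subset for Boruta), so no information leaks across the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier

from ._forest import oob_indices

STATUS_CONFIRMED = "confirmed"
STATUS_TENTATIVE = "tentative"
STATUS_REJECTED = "rejected"


@dataclass
class PcaFeatures:
    """Calibration/validation PCA scores from a calibration-only fit."""

    n_components: int
    cal_scores: np.ndarray
    val_scores: np.ndarray
    explained_fraction: float
    loadings: np.ndarray  # (n_variables, n_components), orthonormal columns


def pca_extract(X_cal: np.ndarray, X_val: np.ndarray,
                max_components: int = 15, folds: int = 7) -> PcaFeatures:
    """Extract principal-component scores, choosing the component count by
    7-fold cross-validation.

    Components are added while the cross-validated Q² (one minus the
    reconstruction PRESS of held-out rows over their total sum of squares,
    both centred on training-fold means) gains at least 0.01 per
    component; the count is capped by ``max_components`` and the
    calibration rank.  Validation rows are projected onto the calibration
    loadings after centring with calibration means.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    if X_cal.shape[1] != X_val.shape[1]:
        raise ValueError("calibration and validation widths differ")
    m = X_cal.shape[0]
    cap = min(max_components, m - 1, X_cal.shape[1])
    assign = np.arange(m) % folds
    press = np.zeros(cap)
    tss = 0.0
    for f in range(folds):
        val = assign == f
        if not val.any() or val.all():
            continue
        tr = ~val
        mean = X_cal[tr].mean(axis=0)
        Xt = X_cal[tr] - mean
        Xv = X_cal[val] - mean
        kf = min(cap, Xt.shape[0])
        pca = PCA(n_components=kf, svd_solver="full")
        pca.fit(Xt)
        scores = Xv @ pca.components_.T
        tss += (Xv ** 2).sum()
        recon = np.zeros_like(Xv)
        for a in range(kf):
            recon += np.outer(scores[:, a], pca.components_[a])
            press[a] += ((Xv - recon) ** 2).sum()
        if kf < cap:
            press[kf:] += press[kf - 1]
    q2 = 1.0 - press / tss
    k = 1
    while k < cap and q2[k] - q2[k - 1] >= 0.01:
        k += 1
    mean = X_cal.mean(axis=0)
    pca = PCA(n_components=k, svd_solver="full")
    cal_scores = pca.fit_transform(X_cal - mean)
    val_scores = (X_val - mean) @ pca.components_.T
    return PcaFeatures(
        n_components=k, cal_scores=cal_scores, val_scores=val_scores,
        explained_fraction=float(pca.explained_variance_ratio_.sum()),
        loadings=pca.components_.T)


@dataclass
class FeatureDecision:
    """Per-variable Boruta verdict plus its evidence trail."""

    status: np.ndarray            # per variable: confirmed/tentative/rejected
    hits: np.ndarray              # times the variable beat the best shadow
    n_iterations: int
    importance_history: np.ndarray  # (n_iterations, p); NaN once dropped

    def selected_columns(self) -> np.ndarray:
        """Columns extracted for fusion: confirmed and tentative variables."""
        return np.flatnonzero(self.status != STATUS_REJECTED)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _oob_mda_importance(forest: RandomForestClassifier, X: np.ndarray,
                        y_enc: np.ndarray, rng: np.random.Generator
                        ) -> np.ndarray:
    """OOB permutation importance (mean decrease in accuracy) per feature.

    One row permutation per feature; every tree is evaluated on its own
    out-of-bag samples.  All feature variants are stacked into one matrix
    so each tree performs a single bulk prediction.
    """
    m, p = X.shape
    stack = np.repeat(X[None, :, :], p + 1, axis=0)  # variant 0 = baseline
    for j in range(p):
        stack[j + 1, :, j] = X[rng.permutation(m), j]
    # trees store float32 thresholds, so a single float32 copy is lossless
    # for prediction and lets us call the low-level tree predictor directly
    stack = np.ascontiguousarray(
        stack.reshape((p + 1) * m, p), dtype=np.float32)
    acc = np.zeros(p + 1)
    n_trees = len(forest.estimators_)
    for est in forest.estimators_:
        oob = oob_indices(est, m)
        if oob.size == 0:
            continue
        leaf = est.tree_.predict(stack).reshape((p + 1) * m, -1)
        pred = leaf.argmax(axis=1).reshape(p + 1, m)
        acc += (pred[:, oob] == y_enc[oob]).mean(axis=1)
    acc /= n_trees
    return acc[0] - acc[1:]


def boruta_select(X: np.ndarray, y, alpha: float = 0.05,
                  max_iter: int = 100, rf_trees: int = 500,
                  seed: int = 0) -> FeatureDecision:
    """All-relevant variable selection by the Boruta shadow-feature scheme.

    Each iteration appends freshly shuffled "shadow" copies of every still-
    candidate column, fits a random forest, and scores both real and shadow
    features by OOB permutation importance.  A real variable beating the
    best shadow registers a hit; two-sided binomial tests on the hit counts
    (Bonferroni-corrected over the variables still undecided) promote
    variables to *confirmed* or demote them to *rejected* — rejected
    columns and their shadows leave the game.  Whatever is undecided when
    the iterations run out stays *tentative*.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y))
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    y_enc = np.searchsorted(classes, y)
    m, p = X.shape
    rng = np.random.default_rng(seed)
    decided = np.full(p, "", dtype=object)
    hits = np.zeros(p, dtype=int)
    history = np.full((max_iter, p), np.nan)
    candidates = np.arange(p)
    it = 0
    for it in range(1, max_iter + 1):
        if candidates.size < 5:
            it -= 1
            break
        nc = candidates.size
        shadows = X[:, candidates].copy()
        for j in range(nc):
            shadows[:, j] = shadows[rng.permutation(m), j]
        Z = np.hstack([X[:, candidates], shadows])
        forest = RandomForestClassifier(
            n_estimators=rf_trees, max_features="sqrt", bootstrap=True,
            random_state=int(rng.integers(2 ** 31 - 1)), n_jobs=1)
        forest.fit(Z, y_enc)
        imp = _oob_mda_importance(forest, Z, y_enc, rng)
        real_imp, shadow_imp = imp[:nc], imp[nc:]
        history[it - 1, candidates] = real_imp
        hits[candidates[real_imp > shadow_imp.max()]] += 1
        # binomial decisions on the undecided variables
        thr = alpha / nc
        undecided_mask = decided[candidates] == ""
        for j in candidates[undecided_mask]:
            h = hits[j]
            p_two = 2.0 * min(binom.sf(h - 1, it, 0.5), binom.cdf(h, it, 0.5))
            if p_two < thr:
                decided[j] = (STATUS_CONFIRMED if h > it / 2
                              else STATUS_REJECTED)
        candidates = np.flatnonzero(
            (decided == "") | (decided == STATUS_CONFIRMED))
    status = np.where(decided == "", STATUS_TENTATIVE, decided).astype(object)
    n_it = max(it, 1)
    return FeatureDecision(status=np.asarray(status), hits=hits,
                           n_iterations=n_it,
                           importance_history=history[:n_it])
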