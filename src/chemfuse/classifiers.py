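"""Supervised classifiers emitting class-membership degrees.

Two pattern-recognition methods are wrapped as Model/Results pairs:

* :class:`PLSDA` — partial least squares regression of a one-hot class
  matrix on autoscaled variables; the latent-variable count is chosen by
  7-fold cross-validated Q², and variable influence is summarised by VIP
  scores.
* :class:`RandomForest` — bootstrap-aggregated classification trees with
  the out-of-bag (OOB) screening of ``n_tree`` and ``mtry``: grow a large
  forest, take the smallest tree count reaching the minimum running OOB
  error without degrading any single class, then sweep ``mtry`` around
  floor(sqrt(p)) +/- 10 and keep the lowest-OOB-error value (ties go to
  the candidate closest to the default, then to the smaller one).

Both emit a :class:`MembershipMatrix` — per-sample, per-class membership
degrees in [0, 1] — the common currency of high-level decision fusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier

from ._forest import oob_indices

from .blocks import autoscale


@dataclass
class MembershipMatrix:
    """Per-sample, per-class membership degrees in [0, 1]."""

    values: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.class_order):
            raise ValueError("values must be (samples x classes)")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("membership degrees must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def hard_classes(self) -> np.ndarray:
        """Argmax class per sample (first class wins ties)."""
        idx = np.argmax(self.values, axis=1)
        return np.asarray([self.class_order[i] for i in idx])


def rescale_rows(pred: np.ndarray) -> np.ndarray:
    """Affine per-row map onto [0, 1]: row min -> 0, row max -> 1.

    Degenerate constant rows map to 0.5 everywhere (no class preference).
    """
    pred = np.asarray(pred, dtype=float)
    lo = pred.min(axis=1, keepdims=True)
    hi = pred.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] <= 1e-12
    span[flat] = 1.0
    memb = (pred - lo) / span
    memb[flat] = 0.5
    return memb


def _one_hot(y, class_order: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(class_order)}
    Y = np.zeros((len(y), len(class_order)))
    for i, lab in enumerate(y):
        Y[i, lut[lab]] = 1.0
    return Y


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

class PLSDA:
    """PLS-DA model specification: variables ``X`` and class labels ``y``.

    ``fit`` autoscales X with calibration statistics (zero-variance columns
    are dropped with a warning), regresses the one-hot class matrix on X by
    NIPALS PLS2, and picks the latent-variable count maximising 7-fold
    cross-validated Q² (ties favour fewer components).
    """

    def __init__(self, X: np.ndarray, y, class_order: list[str] | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = list(y)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X rows and y length differ")
        self.class_order = class_order or sorted(set(self.y))
        if len(self.class_order) < 2:
            raise ValueError("PLS-DA needs at least 2 classes")

    def fit(self, max_lv: int = 10, folds: int = 7,
            n_latent: int | None = None) -> "PLSDAResults":
        X, y = self.X, self.y
        m, p = X.shape
        std = X.std(axis=0, ddof=1)
        keep = np.flatnonzero(std > 0)
        if keep.size < p:
            warnings.warn(f"dropping {p - keep.size} zero-variance columns")
        Xk = X[:, keep]
        Xs, x_mean, x_std = autoscale(Xk)
        Y = _one_hot(y, self.class_order)
        cap = min(max_lv, m - 1, keep.size)
        notes = []
        if cap < max_lv:
            notes.append(f"max_lv reduced from {max_lv} to rank cap {cap}")
        cv_q2 = _cv_q2_per_lv(Xk, Y, cap, folds)
        if n_latent is None:
            n_latent = int(np.argmax(cv_q2)) + 1  # first max -> fewer LVs
        else:
            n_latent = min(n_latent, cap)
        pls = PLSRegression(n_components=n_latent, scale=False)
        with warnings.catch_warnings():
            # NIPALS routinely hits its iteration cap on deflated residuals
            warnings.simplefilter("ignore", ConvergenceWarning)
            pls.fit(Xs, Y - Y.mean(axis=0))
        resid = (Y - Y.mean(axis=0)) - pls.predict(Xs)
        tss = ((Y - Y.mean(axis=0)) ** 2).sum()
        r2y = 1.0 - (resid ** 2).sum() / tss
        return PLSDAResults(
            model=self, pls=pls, n_latent=n_latent, cv_q2=cv_q2,
            kept_columns=keep, x_mean=x_mean, x_std=x_std,
            y_mean=Y.mean(axis=0), class_order=list(self.class_order),
            r2y=r2y, q2=float(cv_q2[n_latent - 1]), notes=notes)


def _cv_q2_per_lv(X: np.ndarray, Y: np.ndarray, max_lv: int,
                  folds: int) -> np.ndarray:
    """Q² per latent-variable count from deterministic interleaved folds.

    Fold f holds out rows i with i % folds == f; scaling and centring are
    refit inside each training fold.  Q²(a) = 1 - PRESS(a)/TSS.
    """
    m = X.shape[0]
    assign = np.arange(m) % folds
    press = np.zeros(max_lv)
    tss = 0.0
    for f in range(folds):
        val = assign == f
        if not val.any() or val.all():
            continue
        tr = ~val
        Xt, mean, std = autoscale(X[tr])
        Xv = (X[val] - mean) / std
        Ym = Y[tr].mean(axis=0)
        Yt = Y[tr] - Ym
        tss += ((Y[val] - Ym) ** 2).sum()
        cap = min(max_lv, int(np.sum(tr)) - 1)
        for a in range(1, cap + 1):
            pls = PLSRegression(n_components=a, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                pls.fit(Xt, Yt)
            pred = pls.predict(Xv) + Ym
            press[a - 1] += ((Y[val] - pred) ** 2).sum()
        if cap < max_lv:  # deeper models unavailable in this fold
            press[cap:] += press[cap - 1]
    return 1.0 - press / tss


@dataclass
class PLSDAResults:
    """Fitted PLS-DA model with its diagnostics."""

    model: PLSDA
    pls: PLSRegression
    n_latent: int
    cv_q2: np.ndarray
    kept_columns: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    class_order: list[str]
    r2y: float
    q2: float
    notes: list[str] = field(default_factory=list)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Raw predicted one-hot responses (regression scale)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"expected {self.model.X.shape[1]} variables, got {X.shape[1]}")
        Xs = (X[:, self.kept_columns] - self.x_mean) / self.x_std
        return self.pls.predict(Xs) + self.y_mean

    def predict(self, X: np.ndarray) -> MembershipMatrix:
        """Class memberships for new samples.

        Predicted one-hot responses are rescaled affinely per sample onto
        [0, 1] (row minimum -> 0, row maximum -> 1) so that downstream
        fuzzy connectives receive genuine membership degrees; the hard
        class is the row argmax either way.
        """
        memb = rescale_rows(self.decision_values(X))
        return MembershipMatrix(memb, list(self.class_order))

    def vip(self) -> np.ndarray:
        """Variable importance in projection for the fitted variables.

        VIP_j = sqrt(p * sum_a SS_a w_ja^2 / sum_a SS_a) with unit-norm
        weight vectors w_a and SS_a the response variance explained by
        component a; consequently sum_j VIP_j^2 = p exactly.
        """
        W = self.pls.x_weights_           # (p, A), unit-norm columns
        T = self.pls.x_scores_            # (m, A)
        Q = self.pls.y_loadings_          # (k, A)
        ss = (T ** 2).sum(axis=0) * (Q ** 2).sum(axis=0)
        p = W.shape[0]
        return np.sqrt(p * (W ** 2 @ ss) / ss.sum())

    def plot_vip(self, axis: np.ndarray | None = None, ax=None):
        """VIP line plot with the conventional VIP = 1 threshold marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = axis if axis is not None else self.kept_columns
        ax.plot(x, self.vip(), lw=0.8)
        ax.axhline(1.0, color="red", ls="--", lw=0.8)
        ax.set_xlabel("variable")
        ax.set_ylabel("VIP score")
        return ax

    def plot_scores(self, ax=None):
        """Scatter of the first two latent-variable scores by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        T = self.pls.x_scores_
        y = np.asarray(self.model.y)
        for c in self.class_order:
            mask = y == c
            t2 = T[mask, 1] if T.shape[1] > 1 else np.zeros(mask.sum())
            ax.scatter(T[mask, 0], t2, label=c, s=18)
        ax.set_xlabel("t[1]")
        ax.set_ylabel("t[2]")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "PLS-DA results",
            f"  samples: {self.model.X.shape[0]}  variables: {self.kept_columns.size}",
            f"  classes: {', '.join(self.class_order)}",
            f"  latent variables: {self.n_latent}",
            f"  R2Y: {self.r2y:.4f}  Q2(7-fold): {self.q2:.4f}",
        ]
        lines += [f"  note: {n}" for n in self.notes]
        return "\n".join(lines)


def plsda_fit(X, y, max_lv: int = 10, folds: int = 7,
              class_order=None) -> PLSDAResults:
    return PLSDA(X, y, class_order=class_order).fit(max_lv=max_lv, folds=folds)


def plsda_predict(results: PLSDAResults, X) -> MembershipMatrix:
    return results.predict(X)


def vip(results: PLSDAResults) -> np.ndarray:
    return results.vip()


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

@dataclass
class RfConfig:
    """Outcome of the OOB-based n_tree / mtry screening."""

    n_tree: int
    mtry: int
    oob_error_by_ntree: np.ndarray
    oob_error_by_mtry: dict[int, float]
    seed: int

    def __post_init__(self) -> None:
        if self.n_tree < 1 or self.mtry < 1:
            raise ValueError("n_tree and mtry must be >= 1")


def _oob_error_curves(forest: RandomForestClassifier, X: np.ndarray,
                      y_enc: np.ndarray, n_classes: int):
    """Running overall and per-class OOB error after each added tree.

    Samples without an OOB vote yet are excluded; a class with no voted
    samples gets error +inf so it cannot look spuriously good early on.
    """
    m = X.shape[0]
    votes = np.zeros((m, n_classes))
    overall = np.empty(len(forest.estimators_))
    per_class = np.empty((len(forest.estimators_), n_classes))
    class_masks = [y_enc == c for c in range(n_classes)]
    for t, est in enumerate(forest.estimators_):
        oob = oob_indices(est, m)
        if oob.size:
            pred = est.predict(X[oob]).astype(int)
            votes[oob, pred] += 1.0
        voted = votes.sum(axis=1) > 0
        if not voted.all():
            # the OOB error is not comparable until every sample has a vote
            overall[t] = np.inf
            per_class[t] = np.inf
            continue
        pred_all = votes.argmax(axis=1)
        wrong = pred_all != y_enc
        overall[t] = wrong.mean()
        for c in range(n_classes):
            per_class[t, c] = wrong[class_masks[c]].mean()
    return overall, per_class


def mtry_candidates(p: int, window: int = 10) -> tuple[int, int, int]:
    """Default mtry = floor(sqrt(p)) and the [default-window, default+window]
    candidate range clipped to [1, p]."""
    default = max(1, int(np.floor(np.sqrt(p))))
    return default, max(1, default - window), min(p, default + window)


def pick_mtry(oob_error_by_mtry: dict[int, float], default: int) -> int:
    """Lowest OOB error; ties resolved toward the default, then smaller."""
    return min(oob_error_by_mtry,
               key=lambda v: (oob_error_by_mtry[v], abs(v - default), v))


def rf_screen(X: np.ndarray, y, ntree_init: int = 2000,
              seed: int = 0, mtry_window: int = 10) -> RfConfig:
    """The four-step OOB screening of the forest hyper-parameters.

    1. Fit ``ntree_init`` trees at the default ``mtry`` = floor(sqrt(p)).
    2. ``n_tree`` = smallest tree count whose running overall OOB error
       equals the minimum while no class's OOB error exceeds its value at
       that minimum (all classes considered at the same time).
    3. Sweep ``mtry`` over default +/- ``mtry_window`` (clipped to [1, p])
       at that ``n_tree``; keep the lowest OOB error, ties resolved toward
       the default, then toward the smaller value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y))
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    y_enc = np.searchsorted(classes, y)
    p = X.shape[1]
    default, lo, hi = mtry_candidates(p, mtry_window)
    forest = RandomForestClassifier(
        n_estimators=ntree_init, max_features=default, bootstrap=True,
        random_state=seed, n_jobs=1)
    forest.fit(X, y)
    overall, per_class = _oob_error_curves(forest, X, y_enc, classes.size)
    t_star = int(np.argmin(overall))
    ok = (overall == overall[t_star]) & np.all(
        per_class <= per_class[t_star] + 1e-12, axis=1)
    n_tree = int(np.flatnonzero(ok)[0]) + 1
    by_mtry: dict[int, float] = {}
    for mtry in range(lo, hi + 1):
        f = RandomForestClassifier(
            n_estimators=n_tree, max_features=mtry, bootstrap=True,
            oob_score=True, random_state=seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            f.fit(X, y)
        by_mtry[mtry] = 1.0 - f.oob_score_
    mtry = pick_mtry(by_mtry, default)
    return RfConfig(n_tree=n_tree, mtry=mtry, oob_error_by_ntree=overall,
                    oob_error_by_mtry=by_mtry, seed=seed)


class RandomForest:
    """Random-forest model specification over ``X`` and labels ``y``."""

    def __init__(self, X: np.ndarray, y, class_order: list[str] | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = list(y)
        self.class_order = class_order or sorted(set(self.y))

    def fit(self, config: RfConfig | None = None, ntree_init: int = 2000,
            seed: int = 0) -> "RandomForestResults":
        if config is None:
            config = rf_screen(self.X, self.y, ntree_init=ntree_init, seed=seed)
        forest = RandomForestClassifier(
            n_estimators=config.n_tree, max_features=min(config.mtry, self.X.shape[1]),
            bootstrap=True, oob_score=True, random_state=config.seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            forest.fit(self.X, self.y)
        return RandomForestResults(
            model=self, forest=forest, config=config,
            class_order=list(self.class_order),
            oob_error=1.0 - forest.oob_score_)


@dataclass
class RandomForestResults:
    model: RandomForest
    forest: RandomForestClassifier
    config: RfConfig
    class_order: list[str]
    oob_error: float

    def predict(self, X: np.ndarray) -> MembershipMatrix:
        """Memberships = fraction of trees voting each class (rows sum 1)."""
        X = np.asarray(X, dtype=float)
        m = X.shape[0]
        k = len(self.class_order)
        order = {c: i for i, c in enumerate(self.class_order)}
        col = np.array([order[c] for c in self.forest.classes_])
        votes = np.zeros((m, k))
        for est in self.forest.estimators_:
            pred = est.predict(X).astype(int)
            votes[np.arange(m), col[pred]] += 1.0
        return MembershipMatrix(votes / len(self.forest.estimators_),
                                list(self.class_order))

    def summary(self) -> str:
        return "\n".join([
            "Random forest results",
            f"  samples: {self.model.X.shape[0]}  variables: {self.model.X.shape[1]}",
            f"  n_tree: {self.config.n_tree}  mtry: {self.config.mtry}",
            f"  OOB error: {self.oob_error:.4f}",
        ])


def rf_fit(X, y, config: RfConfig, class_order=None) -> RandomForestResults:
    return RandomForest(X, y, class_order=class_order).fit(config=config)


def rf_predict(results: RandomForestResults, X) -> MembershipMatrix:
    return results.predict(X)
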