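"""End-to-end traceability experiment over one LC and one FTIR block.

:class:`FusionExperiment` is the model object: it holds the two raw
fingerprint blocks and a :class:`~chemfuse.config.RunConfig`.  ``fit()``
executes the full protocol — shared Kennard-Stone split, per-block
pretreatment, the two single-block classifiers, and the five fusion
strategies (low-level; mid-level with PCA or Boruta features; high-level
fuzzy-vote fusion of per-block models on PCA or Boruta features) — and
returns a :class:`FusionExperimentResults` carrying the per-class
efficiency / total-accuracy report for calibration and validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import FingerprintBlock, autoscale
from .classifiers import (MembershipMatrix, PLSDA, RandomForest, rf_screen)
from .config import RunConfig
from .evaluation import confusion, efficiency, total_accuracy
from .features import boruta_select, pca_extract
from .fusion import high_level_decide, low_level_fuse, mid_level_fuse
from .preprocess import pretreat_ftir, pretreat_lc
from .sampling import SplitIndices, shared_split

SINGLE_STRATEGIES = ("LC", "FTIR")
FUSION_STRATEGIES = ("Low-level", "Mid-level PCA", "Mid-level Boruta",
                     "High-level PCA", "High-level Boruta")
CLASSIFIERS = ("PLS-DA", "RF")


@dataclass
class FusionExperimentResults:
    """Report and fitted artifacts of one full run."""

    report: pd.DataFrame
    split: SplitIndices
    class_order: list[str]
    config: RunConfig
    lc_pretreated: FingerprintBlock
    ftir_pretreated: FingerprintBlock
    boruta_decisions: dict = field(default_factory=dict)
    pca_features: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    memberships: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def validation_accuracy(self, strategy: str, classifier: str) -> float:
        r = self.report
        row = r[(r.strategy == strategy) & (r.classifier == classifier)
                & (r.set == "val")]
        return float(row.total_accuracy.iloc[0])

    def summary(self) -> str:
        lines = ["Geographical traceability experiment",
                 f"  samples: {len(self.split.calibration)} calibration / "
                 f"{len(self.split.validation)} validation",
                 f"  LC variables after pretreatment: {self.lc_pretreated.n_variables}",
                 f"  FTIR variables after pretreatment: {self.ftir_pretreated.n_variables}",
                 ""]
        lines.append(self.report.to_string(index=False,
                                           float_format=lambda v: f"{v:.2f}"))
        if self.failures:
            lines.append(f"  failed stages: {sorted(self.failures)}")
        return "\n".join(lines)


class FusionExperiment:
    """Model object: two fingerprint blocks plus the run protocol."""

    def __init__(self, lc: FingerprintBlock, ftir: FingerprintBlock,
                 config: RunConfig | None = None):
        if lc.sample_ids != ftir.sample_ids:
            raise ValueError("LC and FTIR blocks carry different samples")
        if lc.labels is None or ftir.labels is None:
            raise ValueError("both blocks need class labels")
        if lc.labels != ftir.labels:
            raise ValueError("LC and FTIR labels disagree")
        self.lc = lc
        self.ftir = ftir
        self.config = config or RunConfig()

    # -- helpers -----------------------------------------------------------

    def _evaluate(self, rows, strategy, classifier, y_cal, y_val,
                  pred_cal, pred_val, class_order):
        for set_name, y, pred in (("cal", y_cal, pred_cal),
                                  ("val", y_val, pred_val)):
            cc = confusion(y, pred, class_order)
            row = {"strategy": strategy, "classifier": classifier,
                   "set": set_name}
            for c in class_order:
                row[f"eff_{c}"] = efficiency(cc, c)
            row["total_accuracy"] = total_accuracy(y, pred)
            rows.append(row)

    def _fit_pair(self, rows, strategy, X_cal, X_val, y_cal, y_val,
                  class_order, seed):
        """Fit PLS-DA and RF on one feature space; record both."""
        cfg = self.config
        out = {}
        pls = PLSDA(X_cal, y_cal, class_order=class_order).fit(
            max_lv=cfg.max_lv, folds=cfg.folds)
        memb = (pls.predict(X_cal), pls.predict(X_val))
        self._evaluate(rows, strategy, "PLS-DA", y_cal, y_val,
                       memb[0].hard_classes(), memb[1].hard_classes(),
                       class_order)
        out["PLS-DA"] = (pls, memb)
        rfc = rf_screen(X_cal, y_cal, ntree_init=cfg.ntree_init,
                        seed=seed, mtry_window=cfg.mtry_window)
        rf = RandomForest(X_cal, y_cal, class_order=class_order).fit(config=rfc)
        memb = (rf.predict(X_cal), rf.predict(X_val))
        self._evaluate(rows, strategy, "RF", y_cal, y_val,
                       memb[0].hard_classes(), memb[1].hard_classes(),
                       class_order)
        out["RF"] = (rf, memb)
        return out

    def _high_level(self, rows, strategy, per_block_models, y_cal, y_val,
                    class_order, results):
        """Fuse the two per-block models of each classifier kind."""
        for clf in CLASSIFIERS:
            membs_cal = [per_block_models[b][clf][1][0] for b in ("lc", "ftir")]
            membs_val = [per_block_models[b][clf][1][1] for b in ("lc", "ftir")]
            dec_cal = high_level_decide(membs_cal)
            dec_val = high_level_decide(membs_val)
            self._evaluate(rows, strategy, clf, y_cal, y_val,
                           dec_cal.final_class, dec_val.final_class,
                           class_order)
            results.memberships[(strategy, clf)] = (membs_cal, membs_val)

    # -- main protocol -----------------------------------------------------

    def fit(self) -> FusionExperimentResults:
        cfg = self.config
        labels = list(self.lc.labels)
        class_order = sorted(set(labels))

        split = shared_split([self.lc, self.ftir], cfg.split_ratio)
        cal, val = split.calibration, split.validation
        y_cal = [labels[i] for i in cal]
        y_val = [labels[i] for i in val]

        # pretreatment; the COW reference is the calibration-sample mean
        lc_ref = self.lc.values[cal].mean(axis=0)
        lc_p = pretreat_lc(self.lc, reference=lc_ref,
                           segment_length=cfg.segment_length,
                           slack=cfg.slack, k=cfg.downsample_k,
                           window=cfg.sg_window, polyorder=cfg.sg_polyorder)
        ftir_p = pretreat_ftir(self.ftir, window=cfg.sg_window,
                               polyorder=cfg.sg_polyorder,
                               bands=cfg.ftir_bands)

        blocks = {"lc": lc_p, "ftir": ftir_p}
        Xc = {b: blk.values[cal] for b, blk in blocks.items()}
        Xv = {b: blk.values[val] for b, blk in blocks.items()}

        rows: list[dict] = []
        results = FusionExperimentResults(
            report=pd.DataFrame(), split=split, class_order=class_order,
            config=cfg, lc_pretreated=lc_p, ftir_pretreated=ftir_p)

        def stage(name, fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - report marks missing cells
                results.failures[name] = repr(e)
                return None

        # single-block models (reused later by feature extraction order)
        single = {}
        for i, b in enumerate(("lc", "ftir")):
            strategy = "LC" if b == "lc" else "FTIR"
            single[b] = stage(strategy, lambda b=b, s=strategy: self._fit_pair(
                rows, s, Xc[b], Xv[b], y_cal, y_val, class_order,
                seed=cfg.seed + i))

        # low-level fusion
        def low():
            fused = low_level_fuse([lc_p, ftir_p])
            return self._fit_pair(rows, "Low-level", fused.values[cal],
                                  fused.values[val], y_cal, y_val,
                                  class_order, seed=cfg.seed + 10)
        results.models["Low-level"] = stage("Low-level", low)

        # per-block feature extraction (calibration-fitted)
        def extract_pca(b):
            Xs_cal, mean, std = autoscale(Xc[b])
            Xs_val = (Xv[b] - mean) / std
            return pca_extract(Xs_cal, Xs_val, cfg.max_components, cfg.folds)

        pca = {b: stage(f"pca_{b}", lambda b=b: extract_pca(b))
               for b in ("lc", "ftir")}
        results.pca_features = pca
        bor = {b: stage(f"boruta_{b}", lambda b=b: boruta_select(
            Xc[b], y_cal, alpha=cfg.boruta_alpha,
            max_iter=cfg.boruta_max_iter, rf_trees=cfg.boruta_trees,
            seed=cfg.seed + 20 + ("lc", "ftir").index(b)))
            for b in ("lc", "ftir")}
        results.boruta_decisions = bor

        # mid-level fusion
        def mid_pca():
            Fc = mid_level_fuse([pca[b].cal_scores for b in ("lc", "ftir")])
            Fv = mid_level_fuse([pca[b].val_scores for b in ("lc", "ftir")])
            return self._fit_pair(rows, "Mid-level PCA", Fc, Fv, y_cal,
                                  y_val, class_order, seed=cfg.seed + 11)
        results.models["Mid-level PCA"] = stage("Mid-level PCA", mid_pca)

        def mid_boruta():
            sel = {b: bor[b].selected_columns() for b in ("lc", "ftir")}
            Fc = mid_level_fuse([Xc[b][:, sel[b]] for b in ("lc", "ftir")])
            Fv = mid_level_fuse([Xv[b][:, sel[b]] for b in ("lc", "ftir")])
            return self._fit_pair(rows, "Mid-level Boruta", Fc, Fv, y_cal,
                                  y_val, class_order, seed=cfg.seed + 12)
        results.models["Mid-level Boruta"] = stage("Mid-level Boruta", mid_boruta)

        # high-level fusion: one model per block on its extracted features
        def high(strategy, feats):
            per_block = {}
            for j, b in enumerate(("lc", "ftir")):
                fc, fv = feats[b]
                per_block[b] = self._fit_pair(
                    [], f"{strategy}/{b}", fc, fv, y_cal, y_val,
                    class_order, seed=cfg.seed + 30 + j)
            self._high_level(rows, strategy, per_block, y_cal, y_val,
                             class_order, results)
            return per_block

        if all(pca[b] is not None for b in ("lc", "ftir")):
            results.models["High-level PCA"] = stage(
                "High-level PCA", lambda: high(
                    "High-level PCA",
                    {b: (pca[b].cal_scores, pca[b].val_scores)
                     for b in ("lc", "ftir")}))
        if all(bor[b] is not None for b in ("lc", "ftir")):
            sel = {b: bor[b].selected_columns() for b in ("lc", "ftir")}
            results.models["High-level Boruta"] = stage(
                "High-level Boruta", lambda: high(
                    "High-level Boruta",
                    {b: (Xc[b][:, sel[b]], Xv[b][:, sel[b]])
                     for b in ("lc", "ftir")}))

        results.models.update(single)
        results.report = pd.DataFrame(rows)
        return results
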