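"""The three multi-block fusion strategies.

* low-level: concatenate the preprocessed variables of every block (each
  block autoscaled first so the wider block cannot dominate).
* mid-level: concatenate per-block extracted features (Boruta-selected
  columns or PCA scores).
* high-level: run one classifier per block, then merge the per-class
  membership degrees with the four fuzzy aggregation connectives
  (maximum, minimum, average, product) and let the operators vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .blocks import FingerprintBlock, autoscale
from .classifiers import MembershipMatrix

FUZZY_OPERATORS = ("maximum", "minimum", "average", "product")


def low_level_fuse(blocks: list[FingerprintBlock],
                   scale: bool = True) -> FingerprintBlock:
    """Column-wise concatenation of blocks sharing the same samples.

    The fused axis is a plain 0..n-1 index (retention times and
    wavenumbers are not commensurable).  Per-block autoscaling before
    concatenation is on by default and switchable off.
    """
    if not blocks:
        raise ValueError("need at least one block")
    ids0 = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ids0:
            raise ValueError("blocks carry different samples")
    if len(blocks) == 1:
        return blocks[0]
    mats = [autoscale(b.values)[0] if scale else b.values for b in blocks]
    fused = np.hstack(mats)
    return FingerprintBlock(
        fused, np.arange(fused.shape[1], dtype=float), "retention_time",
        list(ids0), blocks[0].labels)


def mid_level_fuse(feature_blocks: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-block feature matrices; empty selections pass the
    remaining blocks through with a warning."""
    if not feature_blocks:
        raise ValueError("need at least one feature block")
    mats = [np.asarray(f, dtype=float) for f in feature_blocks]
    rows = {f.shape[0] for f in mats}
    if len(rows) != 1:
        raise ValueError(f"row counts differ between feature blocks: {rows}")
    nonempty = [f for f in mats if f.shape[1] > 0]
    if len(nonempty) < len(mats):
        warnings.warn("a block contributed no features; passing the rest through")
    if not nonempty:
        raise ValueError("every block contributed zero features")
    return np.hstack(nonempty)


def fuzzy_aggregate(memberships: list[MembershipMatrix],
                    operator: str) -> MembershipMatrix:
    """Element-wise fuzzy connective across blocks per (sample, class)."""
    if operator not in FUZZY_OPERATORS:
        raise ValueError(f"operator must be one of {FUZZY_OPERATORS}")
    if not memberships:
        raise ValueError("need at least one membership matrix")
    order = memberships[0].class_order
    for mm in memberships[1:]:
        if mm.class_order != order:
            raise ValueError(
                f"class_order mismatch: {mm.class_order} vs {order}")
    stack = np.stack([mm.values for mm in memberships])
    if operator == "maximum":
        agg = stack.max(axis=0)
    elif operator == "minimum":
        agg = stack.min(axis=0)
    elif operator == "average":
        agg = stack.mean(axis=0)
    else:
        agg = stack.prod(axis=0)
    return MembershipMatrix(agg, list(order))


@dataclass
class FusionDecision:
    """Majority vote of the four fuzzy connectives."""

    per_operator_class: dict[str, np.ndarray]
    final_class: np.ndarray
    vote_detail: dict[str, np.ndarray]


def high_level_decide(memberships: list[MembershipMatrix]) -> FusionDecision:
    """Fuse per-block memberships into one decision per sample.

    Each connective aggregates the blocks and casts an argmax vote; the
    class with most operator votes wins.  A tie between classes is broken
    by the higher average-connective membership, then by class order.
    """
    if len(memberships) < 2:
        raise ValueError("high-level fusion needs at least 2 blocks")
    order = memberships[0].class_order
    per_op_memb = {op: fuzzy_aggregate(memberships, op)
                   for op in FUZZY_OPERATORS}
    per_op_class = {op: mm.hard_classes() for op, mm in per_op_memb.items()}
    m = memberships[0].values.shape[0]
    k = len(order)
    counts = np.zeros((m, k), dtype=int)
    idx = {c: i for i, c in enumerate(order)}
    for op in FUZZY_OPERATORS:
        for s, c in enumerate(per_op_class[op]):
            counts[s, idx[c]] += 1
    avg = per_op_memb["average"].values
    final = []
    for s in range(m):
        top = counts[s].max()
        tied = np.flatnonzero(counts[s] == top)
        if tied.size > 1:
            best = tied[np.argmax(avg[s, tied])]  # argmax keeps class order on ties
        else:
            best = tied[0]
        final.append(order[best])
    return FusionDecision(
        per_operator_class=per_op_class,
        final_class=np.asarray(final),
        vote_detail={op: mm.values for op, mm in per_op_memb.items()})
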