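"""Calibration/validation partitioning by the Kennard-Stone algorithm.

The deterministic max-min-distance rule picks a calibration subset that
spans the sample space: start from the two mutually farthest samples, then
repeatedly add the sample whose nearest already-picked neighbour is
farthest away.  A 2:1 split takes n_cal = floor(2m/3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .blocks import FingerprintBlock, autoscale


@dataclass
class SplitIndices:
    calibration: list[int]
    validation: list[int]

    def __post_init__(self) -> None:
        cal, val = set(self.calibration), set(self.validation)
        if cal & val:
            raise ValueError("calibration and validation overlap")
        if not self.calibration or not self.validation:
            raise ValueError("both subsets must be non-empty")


def n_calibration(m: int, ratio: tuple[int, int] = (2, 1)) -> int:
    """Calibration size for an a:b split: floor(a*m/(a+b))."""
    a, b = ratio
    return (a * m) // (a + b)


def kennard_stone(X: np.ndarray, n_cal: int) -> SplitIndices:
    """Deterministic Kennard-Stone selection of ``n_cal`` calibration rows.

    Euclidean distances; ties broken by the lowest sample index, so the
    same matrix always yields the same split.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if not 2 <= n_cal < m:
        raise ValueError(f"n_cal must be in [2, {m - 1}], got {n_cal}")
    D = cdist(X, X)
    # first pair: maximum distance; argmax scans row-major, so the first
    # (lowest-index) maximising pair wins ties
    i, j = np.unravel_index(np.argmax(D), D.shape)
    picked = [min(i, j), max(i, j)] if i != j else [0, 1]
    remaining = [k for k in range(m) if k not in picked]
    min_d = np.minimum(D[picked[0]], D[picked[1]])
    while len(picked) < n_cal:
        cand = np.argmax(min_d[remaining])
        nxt = remaining.pop(int(cand))
        picked.append(nxt)
        min_d = np.minimum(min_d, D[nxt])
    return SplitIndices(calibration=picked, validation=remaining)


def shared_split(blocks: list[FingerprintBlock],
                 ratio: tuple[int, int] = (2, 1)) -> SplitIndices:
    """One split shared by every block and fusion strategy.

    Kennard-Stone on the column-wise concatenation of the autoscaled
    blocks; autoscaling stops the wider or higher-variance block from
    dominating the distances.  All blocks must carry the same samples in
    the same order.
    """
    if not blocks:
        raise ValueError("need at least one block")
    ids0 = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ids0:
            bad = [s for s, t in zip(ids0, b.sample_ids) if s != t]
            raise ValueError(f"sample_ids differ between blocks: {bad[:5]}")
    X = np.hstack([autoscale(b.values)[0] for b in blocks])
    return kennard_stone(X, n_calibration(len(ids0), ratio))
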