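"""Fingerprint pretreatment: alignment, reduction, derivative, band removal.

The LC chain corrects retention-time shifts by correlation-optimized
warping (COW), thins the grid 1-in-3, then applies a Savitzky-Golay
second-derivative filter; the FTIR chain applies the same derivative filter
and then deletes the noise-only spectral bands.  With the standard 15-point
window the derivative step discards 7 edge columns per side, so a
7201-point chromatogram ends up with ceil(7201/3) - 14 = 2387 variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .blocks import FingerprintBlock

#: FTIR intervals (cm**-1) abandoned after derivative filtering.
DEFAULT_FTIR_BANDS = ((1750.0, 2670.0), (3700.0, 4000.0))


# ---------------------------------------------------------------------------
# correlation-optimized warping
# ---------------------------------------------------------------------------

@dataclass
class WarpingResult:
    """Outcome of COW alignment of a block against one reference signal.

    ``node_maps[s]`` lists ``(target_boundary, source_boundary)`` pairs for
    sample ``s``; boundaries are grid indices, monotone, with the first and
    last fixed to the signal ends.  ``scores[s]`` is the summed per-segment
    Pearson correlation attained by the optimal warp.
    """

    aligned: np.ndarray
    node_maps: list[list[tuple[int, int]]]
    scores: np.ndarray


def _cow_layout(n: int, segment_length: int, slack: int):
    """Segment boundaries and feasible position ranges for a length-n signal."""
    if segment_length < 2 * slack + 3:
        raise ValueError(
            f"segment_length ({segment_length}) must be >= 2*slack + 3 "
            f"(= {2 * slack + 3}) for slack {slack}")
    if n < segment_length:
        raise ValueError(
            f"signal length {n} shorter than one segment ({segment_length})")
    n_seg = max(1, round((n - 1) / (segment_length - 1)))
    bounds = np.rint(np.arange(n_seg + 1) * (n - 1) / n_seg).astype(int)
    lengths = np.diff(bounds)
    if np.any(lengths - slack < 2):
        raise ValueError(
            f"slack {slack} infeasible for segment lengths {lengths.min()}")
    # feasible source-boundary ranges: forward and backward length bounds
    lo = np.zeros(n_seg + 1, dtype=int)
    hi = np.zeros(n_seg + 1, dtype=int)
    for i in range(1, n_seg + 1):
        lo[i] = lo[i - 1] + lengths[i - 1] - slack
        hi[i] = hi[i - 1] + lengths[i - 1] + slack
    blo = np.zeros(n_seg + 1, dtype=int)
    bhi = np.zeros(n_seg + 1, dtype=int)
    blo[n_seg] = bhi[n_seg] = n - 1
    for i in range(n_seg - 1, -1, -1):
        blo[i] = blo[i + 1] - (lengths[i] + slack)
        bhi[i] = bhi[i + 1] - (lengths[i] - slack)
    lo = np.maximum(lo, blo)
    hi = np.minimum(hi, bhi)
    if np.any(lo > hi):
        raise ValueError("segment/slack combination leaves no feasible warp")
    return bounds, lengths, lo, hi


def _segment_correlations(y: np.ndarray, starts: np.ndarray, d: int,
                          ref_seg: np.ndarray) -> np.ndarray:
    """Pearson correlation of ``y`` warped from ``start .. start+d`` onto the
    reference segment, for every start at once.  Zero variance -> 0."""
    L = ref_seg.size  # points in the target segment
    grid = np.arange(L) * (d / (L - 1))
    i0 = np.minimum(grid.astype(int), d - 1)  # last point uses frac = 1
    frac = grid - i0
    idx = starts[:, None] + i0[None, :]
    V = y[idx] * (1.0 - frac) + y[idx + 1] * frac
    rc = ref_seg - ref_seg.mean()
    nr = np.sqrt((rc * rc).sum())
    s1 = V.sum(axis=1)
    s2 = (V * V).sum(axis=1)
    num = V @ rc
    var = s2 - s1 * s1 / L
    var = np.maximum(var, 0.0)
    denom = np.sqrt(var) * nr
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 1e-12, num / np.where(denom > 0, denom, 1.0), 0.0)
    return corr


def _cow_one(y: np.ndarray, reference: np.ndarray, bounds, lengths, lo, hi,
             slack: int):
    """Exact DP over source boundary positions for one sample."""
    n_seg = lengths.size
    NEG = -np.inf
    F_prev = np.full(hi[0] - lo[0] + 1, NEG)
    F_prev[0 - lo[0]] = 0.0
    parents: list[np.ndarray] = []
    for i in range(1, n_seg + 1):
        Li = lengths[i - 1]
        ref_seg = reference[bounds[i - 1]:bounds[i] + 1]
        a_vals = np.arange(lo[i - 1], hi[i - 1] + 1)
        F_cur = np.full(hi[i] - lo[i] + 1, NEG)
        parent = np.full(hi[i] - lo[i] + 1, -1, dtype=int)
        # candidate lengths ordered by closeness to nominal: ties prefer the
        # identity-like warp, so self-alignment returns the identity map
        deltas = sorted(range(Li - slack, Li + slack + 1),
                        key=lambda d: (abs(d - Li), d))
        for d in deltas:
            b_vals = a_vals + d
            ok = (b_vals >= lo[i]) & (b_vals <= hi[i]) & np.isfinite(F_prev)
            if not ok.any():
                continue
            corr = _segment_correlations(y, a_vals[ok], d, ref_seg)
            cand = F_prev[ok] + corr
            tgt = b_vals[ok] - lo[i]
            better = cand > F_cur[tgt]
            # scatter-max; duplicate targets within one delta are impossible
            F_cur[tgt[better]] = cand[better]
            parent[tgt[better]] = a_vals[ok][better]
        F_prev = F_cur
        parents.append(parent)
    score = F_prev[-1]
    x = bounds[-1]
    xs = [x]
    for i in range(n_seg, 0, -1):
        x = parents[i - 1][x - lo[i]]
        xs.append(x)
    xs = xs[::-1]
    # piecewise-linear resampling of the source onto the target boundaries
    aligned = np.empty_like(reference, dtype=float)
    for i in range(n_seg):
        t0, t1 = bounds[i], bounds[i + 1]
        src = np.linspace(xs[i], xs[i + 1], t1 - t0 + 1)
        aligned[t0:t1 + 1] = np.interp(src, np.arange(y.size), y)
    node_map = [(int(t), int(x)) for t, x in zip(bounds, xs)]
    return aligned, node_map, float(score)


def cow_align(block: FingerprintBlock, reference: np.ndarray,
              segment_length: int = 50, slack: int = 15) -> WarpingResult:
    """Align every sample to ``reference`` by correlation-optimized warping.

    The signal is cut into near-equal target segments of about
    ``segment_length`` points; each source segment may stretch or shrink by
    up to ``slack`` points.  Dynamic programming over all feasible segment
    boundaries maximizes the summed Pearson correlation of the linearly
    interpolated source segments with the reference segments — an exact
    optimum over the discrete warp space, not a heuristic.
    """
    reference = np.asarray(reference, dtype=float)
    n = block.n_variables
    if reference.shape != (n,):
        raise ValueError(
            f"reference length {reference.size} != block width {n}")
    bounds, lengths, lo, hi = _cow_layout(n, segment_length, slack)
    aligned = np.empty_like(block.values)
    node_maps, scores = [], np.empty(block.n_samples)
    for s in range(block.n_samples):
        aligned[s], nm, sc = _cow_one(block.values[s], reference,
                                      bounds, lengths, lo, hi, slack)
        node_maps.append(nm)
        scores[s] = sc
    return WarpingResult(aligned=aligned, node_maps=node_maps, scores=scores)


def cow_brute_force(y: np.ndarray, reference: np.ndarray,
                    segment_length: int, slack: int):
    """Exhaustive search over every feasible boundary tuple (tiny inputs).

    Independent oracle for :func:`cow_align`: enumerates all segment-length
    combinations, scores each warp by the same summed segment correlation,
    and returns ``(best_score, best_boundaries)``.
    """
    import itertools

    y = np.asarray(y, dtype=float)
    reference = np.asarray(reference, dtype=float)
    bounds, lengths, lo, hi = _cow_layout(y.size, segment_length, slack)
    n_seg = lengths.size
    best = (-np.inf, None)
    options = [range(L - slack, L + slack + 1) for L in lengths]
    for combo in itertools.product(*options):
        if sum(combo) != y.size - 1:
            continue
        xs = np.concatenate([[0], np.cumsum(combo)])
        total = 0.0
        for i in range(n_seg):
            ref_seg = reference[bounds[i]:bounds[i + 1] + 1]
            corr = _segment_correlations(
                y, np.array([xs[i]]), int(combo[i]), ref_seg)
            total += corr[0]
        if total > best[0] + 1e-12:
            best = (total, list(xs))
    return best


# ---------------------------------------------------------------------------
# grid reduction, derivative filtering, band deletion
# ---------------------------------------------------------------------------

def downsample_every_k(block: FingerprintBlock, k: int) -> FingerprintBlock:
    """Keep every k-th column starting from the first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = np.arange(0, block.n_variables, k)
    return block.take_columns(idx)


def sg_second_derivative(block: FingerprintBlock, window: int = 15,
                         polyorder: int = 2) -> FingerprintBlock:
    """Savitzky-Golay second derivative along each fingerprint.

    The half-window of edge columns on each side is discarded (no padding),
    so the output has ``n - window + 1`` variables; this matches treating
    only full-window convolution outputs as valid.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    n = block.n_variables
    if n < window:
        raise ValueError(f"block width {n} smaller than window {window}")
    delta = abs(block.axis[1] - block.axis[0]) if n > 1 else 1.0
    deriv = savgol_filter(block.values, window, polyorder, deriv=2,
                          delta=delta, axis=1)
    half = (window - 1) // 2
    sl = slice(half, n - half)
    return block.with_values(deriv[:, sl], block.axis[sl])


def remove_bands(block: FingerprintBlock,
                 bands=DEFAULT_FTIR_BANDS) -> FingerprintBlock:
    """Drop every column whose axis value lies in any [low, high] interval
    (inclusive).  Bands outside the axis remove nothing."""
    for lo, hi in bands:
        if not lo < hi:
            raise ValueError(f"band [{lo}, {hi}] must have low < high")
    keep = np.ones(block.n_variables, dtype=bool)
    for lo, hi in bands:
        keep &= ~((block.axis >= lo) & (block.axis <= hi))
    return block.take_columns(np.flatnonzero(keep))


def pretreat_lc(block: FingerprintBlock, reference: np.ndarray | None = None,
                segment_length: int = 50, slack: int = 15, k: int = 3,
                window: int = 15, polyorder: int = 2) -> FingerprintBlock:
    """Full LC chain: COW alignment, 1-in-k reduction, SG second derivative.

    ``reference`` defaults to the column-wise mean of the block; pass the
    calibration-set mean to keep validation pretreatment leakage-free.
    """
    if block.axis_kind != "retention_time":
        raise ValueError("pretreat_lc expects a retention_time block")
    if reference is None:
        reference = block.values.mean(axis=0)
    warped = cow_align(block, reference, segment_length, slack)
    aligned = block.with_values(warped.aligned)
    return sg_second_derivative(
        downsample_every_k(aligned, k), window, polyorder)


def pretreat_ftir(block: FingerprintBlock, window: int = 15,
                  polyorder: int = 2,
                  bands=DEFAULT_FTIR_BANDS) -> FingerprintBlock:
    """Full FTIR chain: SG second derivative, then band deletion (in that
    order — deleting first would put spliced discontinuities under the
    derivative window)."""
    if block.axis_kind != "wavenumber":
        raise ValueError("pretreat_ftir expects a wavenumber block")
    return remove_bands(sg_second_derivative(block, window, polyorder), bands)
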