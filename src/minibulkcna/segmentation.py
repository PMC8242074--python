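"""Circular binary segmentation (CBS) of normalized copy-number profiles.

Each chromosome's masked-in bins are recursively partitioned.  At every
recursion step the algorithm scans all arcs (i, j) of the circularized bin
sequence — equivalently all contiguous windows x[i:j] of the linear
sequence, edge arcs giving single-changepoint splits — and computes the
two-sample statistic comparing the mean inside the window against the mean
outside.  The maximal statistic is referred to its permutation null
(``nperm`` within-chromosome shuffles, seeded); a change is declared when
the permutation p-value is at most ``alpha``, and the algorithm recurses
into the resulting pieces.  Windows that would create a changed segment
shorter than ``min_width`` bins are never proposed.

After convergence, adjacent segments whose means differ by less than
``undo_sd`` x the sample's noise sd are iteratively re-merged ("undo
splits").  The noise sd is estimated from the sample's MAPD as
MAPD / (sqrt(2) * 0.6745).

Because permutations preserve the set of values, the pooled-variance factor
of the t statistic is constant within a scan and cancels from the
permutation comparison; the scan therefore maximizes the equivalent
statistic |sum(x[i:j]) - k * mean(x)| / sqrt(k (n - k)).

Segmentation runs on linear copy-number values by default (the calling
thresholds 2.4 / 1.7 are linear); ``log_scale=True`` segments log2(x/2)
and back-transforms segment means as 2 * 2**mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import RatioProfile
from .qc import compute_mapd, mapd_to_sd


class SegmentationError(ValueError):
    pass


@dataclass
class SegmentationConfig:
    alpha: float = 0.1
    min_width: int = 5
    undo_sd: float = 0.1
    nperm: int = 1000
    seed: int | None = None
    log_scale: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise SegmentationError("alpha must be in (0, 1)")
        if self.min_width < 2:
            raise SegmentationError("min_width must be >= 2")
        if self.nperm < 100:
            raise SegmentationError("nperm must be >= 100")


@dataclass
class Segment:
    chrom: str
    start_bin: int  # full-genome bin index, half-open
    end_bin: int
    n_bins: int  # masked-in bins in the segment
    mean: float


@dataclass
class SegmentProfile:
    """Ordered segments per chromosome for one sample."""

    sample_id: str
    segments: list[Segment]

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def validate(self, bins=None) -> None:
        for chrom, segs in self.by_chrom().items():
            for a, b in zip(segs, segs[1:]):
                if b.start_bin < a.end_bin:
                    raise SegmentationError(
                        f"overlapping segments on chromosome {chrom}"
                    )
            for seg in segs:
                if seg.end_bin <= seg.start_bin or seg.n_bins < 1:
                    raise SegmentationError("degenerate segment")
                if bins is not None:
                    sl = bins.chrom_slices().get(chrom)
                    if sl is None or seg.start_bin < sl.start or seg.end_bin > sl.stop:
                        raise SegmentationError(
                            f"segment outside chromosome {chrom} bin range"
                        )


# ---------------------------------------------------------------------------
# scan statistic


def _scan_best(y: np.ndarray, kmin: int):
    """Max window statistic with its (i, j); ties -> smallest (i, j)."""
    n = len(y)
    total = y.sum()
    S = np.concatenate(([0.0], np.cumsum(y)))
    best = -np.inf
    best_ij = None
    for k in range(kmin, n - kmin + 1):
        d = S[k:] - S[:-k]  # window sums, start i = 0..n-k
        z = np.abs(d - k * total / n) / math.sqrt(k * (n - k))
        i = int(np.argmax(z))
        zi = z[i]
        if zi > best + 1e-15:
            best, best_ij = zi, (i, i + k)
        elif abs(zi - best) <= 1e-15 and best_ij is not None and (i, i + k) < best_ij:
            best_ij = (i, i + k)
    return best, best_ij


def _perm_max(Y: np.ndarray, kmin: int) -> np.ndarray:
    """Max window statistic for each row of Y (rows are permutations)."""
    P, n = Y.shape
    total = Y.sum(axis=1, keepdims=True)
    S = np.concatenate((np.zeros((P, 1)), np.cumsum(Y, axis=1)), axis=1)
    best = np.full(P, -np.inf)
    for k in range(kmin, n - kmin + 1):
        d = S[:, k:] - S[:, :-k]
        z = np.abs(d - k * total / n) / math.sqrt(k * (n - k))
        np.maximum(best, z.max(axis=1), out=best)
    return best


def _significant_split(y, config: SegmentationConfig, rng: np.random.Generator):
    """Return (i, j) of a significant change in y, or None."""
    n = len(y)
    kmin = config.min_width
    if n < 2 * kmin:
        return None
    obs, ij = _scan_best(y, kmin)
    if ij is None or not np.isfinite(obs):
        return None
    if obs <= 1e-12:  # perfectly flat segment; nothing to test
        return None
    fail_at = config.alpha * config.nperm  # > fail_at exceedances => p > alpha
    exceed = 0
    done = 0
    chunk = 128
    while done < config.nperm:
        m = min(chunk, config.nperm - done)
        Y = rng.permuted(np.broadcast_to(y, (m, n)).copy(), axis=1)
        stats = _perm_max(Y, kmin)
        exceed += int(np.sum(stats >= obs - 1e-12))
        done += m
        if exceed > fail_at:
            return None  # early stop: p-value already above alpha
    if exceed / config.nperm <= config.alpha:
        return ij
    return None


def _segment_indices(y, config, rng) -> list[int]:
    """Changepoint positions (local indices) for one chromosome's values."""

    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        ij = _significant_split(y[lo:hi], config, rng)
        if ij is None:
            return
        i, j = ij
        cuts = [lo + i, lo + j]
        pieces = [lo] + [c for c in cuts if lo < c < hi] + [hi]
        for c in cuts:
            if lo < c < hi:
                boundaries.append(c)
        for a, b in zip(pieces, pieces[1:]):
            recurse(a, b)

    recurse(0, len(y))
    return sorted(boundaries)


def undo_splits(
    boundaries: list[int], y: np.ndarray, undo_sd: float, sd_est: float
) -> list[int]:
    """Iteratively merge adjacent segments with near-equal means.

    The adjacent pair whose means differ least is merged while that
    difference is below ``undo_sd * sd_est``; means are recomputed after
    each merge.  Returns the surviving changepoint positions.
    """
    bounds = sorted(boundaries)
    threshold = undo_sd * sd_est
    while bounds:
        edges = [0] + bounds + [len(y)]
        means = [float(np.mean(y[a:b])) for a, b in zip(edges, edges[1:])]
        diffs = np.abs(np.diff(means))
        k = int(np.argmin(diffs))
        if diffs[k] < threshold:
            del bounds[k]
        else:
            break
    return bounds


def cbs_segment(profile: RatioProfile, config: SegmentationConfig | None = None) -> SegmentProfile:
    """Segment each chromosome of a normalized profile.

    Chromosomes with fewer than ``2 * min_width`` masked-in bins form a
    single untested segment; chromosomes with no masked-in bins contribute
    none.  Segment means are always recomputed from the linear copy-number
    values of their member bins (in log mode the mean is the back-transform
    of the mean log value).
    """
    config = config or SegmentationConfig()
    rng = np.random.default_rng(config.seed)
    bins = profile.bins
    try:
        sd_est = mapd_to_sd(
            compute_mapd(profile, log2=config.log_scale)
        )
    except Exception:
        sd_est = 0.0
    segments: list[Segment] = []
    for chrom, sl in bins.chrom_slices().items():
        mask = profile.mask[sl]
        local_idx = np.flatnonzero(mask) + sl.start  # full-genome indices, masked-in
        m = len(local_idx)
        if m == 0:
            continue
        x = profile.x[local_idx]
        y = np.log2(np.maximum(x, 1e-6) / 2.0) if config.log_scale else x
        if m < 2 * config.min_width:
            bounds: list[int] = []
        else:
            bounds = _segment_indices(y, config, rng)
            bounds = undo_splits(bounds, y, config.undo_sd, sd_est)
        edges = [0] + bounds + [m]
        for a, b in zip(edges, edges[1:]):
            if config.log_scale:
                mean = float(2.0 * 2.0 ** np.mean(y[a:b]))
            else:
                mean = float(np.mean(x[a:b]))
            segments.append(
                Segment(
                    chrom=chrom,
                    start_bin=int(local_idx[a]),
                    end_bin=int(local_idx[b - 1]) + 1,
                    n_bins=b - a,
                    mean=mean,
                )
            )
    prof = SegmentProfile(sample_id=profile.sample_id, segments=segments)
    prof.validate(bins)
    return prof


# ---------------------------------------------------------------------------
# exhaustive oracle (test-only reference)


def oracle_segment(x, k_max: int) -> list[tuple[int, int, float]]:
    """Exhaustive least-squares optimal partition into <= k_max segments.

    Dynamic programming over all changepoint placements; intended as an
    independent reference on small inputs (n <= 200, k_max <= 4).  Returns
    (start, end, mean) triples; among k with equal minimal SSE the smallest
    k wins.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n > 200:
        raise SegmentationError("oracle_segment limited to n <= 200")
    if k_max > 4 or k_max < 1:
        raise SegmentationError("oracle_segment limited to 1 <= k_max <= 4")
    S = np.concatenate(([0.0], np.cumsum(x)))
    S2 = np.concatenate(([0.0], np.cumsum(x**2)))

    def sse(a: int, b: int) -> float:
        s = S[b] - S[a]
        return float(S2[b] - S2[a] - s * s / (b - a))

    INF = float("inf")
    dp = np.full((k_max + 1, n + 1), INF)
    back = np.zeros((k_max + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, k_max + 1):
        for j in range(k, n + 1):
            best, arg = INF, k - 1
            for i in range(k - 1, j):
                if dp[k - 1, i] == INF:
                    continue
                v = dp[k - 1, i] + sse(i, j)
                if v < best - 1e-12:
                    best, arg = v, i
            dp[k, j], back[k, j] = best, arg
    best_k = 1
    for k in range(2, k_max + 1):
        if dp[k, n] < dp[best_k, n] - 1e-9:
            best_k = k
    cuts = []
    j = n
    for k in range(best_k, 0, -1):
        i = back[k, j]
        cuts.append((i, j))
        j = i
    cuts.reverse()
    return [(a, b, float(np.mean(x[a:b]))) for a, b in cuts]
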