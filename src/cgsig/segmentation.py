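"""Circular binary segmentation, level merging, and MAD-threshold CNV calling.

The change-point search treats each chromosome's marker sequence as a circle
and looks for the arc whose mean differs most from its complement, measured
by a two-sample t statistic with pooled variance.  A candidate split is
accepted when its permutation p-value (marker order permuted within the
tested stretch) is at or below ``alpha``; accepted splits are recursed on
both sides.  Because wrap-around arcs are complements of contiguous ones and
|t| is symmetric under complementation, enumerating contiguous arcs covers
the circle.

After segmentation, :func:`merge_levels` pools segment levels whose member
marker values are not distinguishable by a rank-sum test, and
:func:`call_cnv` categorizes segments against multiples of the array's
median absolute deviation (amplification/homozygous deletion beyond
``high_mult``×MAD, gain/loss beyond ``low_mult``×MAD).
"""

from __future__ import annotations

import math
import zlib
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import CnvCall, MarkerProfile, Segment, SegmentedProfile

__all__ = [
    "cbs_segment",
    "merge_levels",
    "call_cnv",
    "median_absolute_deviation",
    "max_arc_t",
]

_MIN_ARC = 2  # minimum markers on each side of a tested split
_EXACT_LIMIT = 1000  # exhaustive arc search up to this many markers


def _substream(seed, *names) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a root seed."""
    keys = [zlib.crc32(str(n).encode()) & 0x7FFFFFFF for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


def _batch_max_t(x_rows: np.ndarray, lengths: np.ndarray | None = None) -> np.ndarray:
    """Max over contiguous arcs of |t| for each row of ``x_rows`` (B × n).

    t(i,j) compares arc x[i:j] (m = j−i markers) with its complement using the
    pooled two-sample variance.  Only arc lengths in ``lengths`` are scanned
    (all valid lengths by default).
    """
    x = np.asarray(x_rows, dtype=float)
    B, n = x.shape
    if n < 2 * _MIN_ARC:
        return np.zeros(B)
    P = np.concatenate([np.zeros((B, 1)), np.cumsum(x, axis=1)], axis=1)
    total = P[:, -1]
    ss_tot = (x**2).sum(axis=1)
    best = np.zeros(B)
    if lengths is None:
        lengths = np.arange(_MIN_ARC, n - _MIN_ARC + 1)
    for m in lengths:
        arc = P[:, m:] - P[:, :-m]  # (B, n-m+1) arc sums
        k = n - m
        a_mean = arc / m
        c_mean = (total[:, None] - arc) / k
        ss_within = ss_tot[:, None] - m * a_mean**2 - k * c_mean**2
        varp = np.maximum(ss_within, 0.0) / max(n - 2, 1)
        denom = varp * (1.0 / m + 1.0 / k)
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(denom > 0, (a_mean - c_mean) ** 2 / denom, np.inf)
        t2 = np.where((a_mean - c_mean) == 0, 0.0, t2)
        np.maximum(best, t2.max(axis=1), out=best)
    return np.sqrt(best)


def max_arc_t(x: np.ndarray, lengths: np.ndarray | None = None):
    """Best contiguous arc (i, j) and its |t| for a single marker stretch.

    Ties in |t| are broken toward the lexicographically smallest (i, j).
    Returns ``(i, j, tmax)`` with the arc being ``x[i:j]``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * _MIN_ARC:
        return 0, n, 0.0
    P = np.concatenate([[0.0], np.cumsum(x)])
    total = P[-1]
    ss_tot = float((x**2).sum())
    best_t2, best_ij = -1.0, (0, n)
    if lengths is None:
        lengths = np.arange(_MIN_ARC, n - _MIN_ARC + 1)
    for m in lengths:
        arc = P[m:] - P[:-m]
        k = n - m
        a_mean = arc / m
        c_mean = (total - arc) / k
        ss_within = ss_tot - m * a_mean**2 - k * c_mean**2
        varp = np.maximum(ss_within, 0.0) / max(n - 2, 1)
        denom = varp * (1.0 / m + 1.0 / k)
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(denom > 0, (a_mean - c_mean) ** 2 / denom, np.inf)
        t2 = np.where((a_mean - c_mean) == 0, 0.0, t2)
        tmax = float(t2.max())
        # complement arcs tie in exact arithmetic; resolve ties (relative
        # tolerance) toward the lexicographically smallest (i, j)
        i = int(np.flatnonzero(t2 >= tmax * (1 - 1e-9) - 1e-300).min())
        cand = (i, i + int(m))
        if tmax > best_t2 * (1 + 1e-9) or (
            tmax >= best_t2 * (1 - 1e-9) and cand < best_ij
        ):
            best_t2 = max(tmax, best_t2)
            best_ij = cand
    return best_ij[0], best_ij[1], math.sqrt(max(best_t2, 0.0))


def _candidate_lengths(n: int, rng: np.random.Generator) -> np.ndarray | None:
    """Arc lengths to scan: exhaustive for small stretches, a uniformly sampled
    subset (the fast hybrid) for very long ones."""
    if n <= _EXACT_LIMIT:
        return None
    n_keep = _EXACT_LIMIT // 2
    lengths = rng.choice(np.arange(_MIN_ARC, n - _MIN_ARC + 1), size=n_keep, replace=False)
    return np.unique(lengths)


def _split_pvalue(
    x: np.ndarray,
    t_obs: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    lengths: np.ndarray | None,
    chunk: int = 100,
) -> float:
    """(b+1)/(B+1) permutation p-value of the best-arc statistic, with early
    stopping once significance is no longer reachable."""
    reject_at = math.ceil(alpha * (n_perm + 1))  # b >= this => p > alpha
    b, done = 0, 0
    n = len(x)
    while done < n_perm:
        size = min(chunk, n_perm - done)
        perms = np.empty((size, n))
        for r in range(size):
            perms[r] = rng.permutation(x)
        null_max = _batch_max_t(perms, lengths)
        b += int((null_max >= t_obs - 1e-12).sum())
        done += size
        if b >= reject_at:
            return (b + 1) / (done + 1)  # already > alpha; conservative estimate
    return (b + 1) / (n_perm + 1)


def _refine_boundary(x: np.ndarray, i: int, j: int, window: int) -> tuple[int, int]:
    """Local exhaustive refinement of a coarse split (fast-hybrid mode)."""
    n = len(x)
    best = (i, j)
    best_t = -1.0
    for ii in range(max(0, i - window), min(i + window, n) + 1):
        for jj in range(max(ii + _MIN_ARC, j - window), min(j + window, n) + 1):
            if jj - ii < _MIN_ARC or n - (jj - ii) < _MIN_ARC:
                continue
            m = jj - ii
            a = x[ii:jj].mean()
            c = (x.sum() - x[ii:jj].sum()) / (n - m)
            ssw = ((x[ii:jj] - a) ** 2).sum() + (
                (np.delete(x, slice(ii, jj)) - c) ** 2
            ).sum()
            varp = ssw / max(n - 2, 1)
            denom = varp * (1 / m + 1 / (n - m))
            t = abs(a - c) / math.sqrt(denom) if denom > 0 else math.inf
            if t > best_t:
                best_t, best = t, (ii, jj)
    return best


def _segment_stretch(
    x: np.ndarray, alpha: float, n_perm: int, rng: np.random.Generator
) -> list[int]:
    """Recursive CBS on one contiguous stretch; returns sorted change points
    (indices into x, exclusive ends of the left parts)."""
    n = len(x)
    if n < 2 * _MIN_ARC:
        return []
    lengths = _candidate_lengths(n, rng)
    i, j, t_obs = max_arc_t(x, lengths)
    if t_obs == 0.0:
        return []
    if lengths is not None:
        i, j = _refine_boundary(x, i, j, window=max(2, n // _EXACT_LIMIT))
    p = _split_pvalue(x, t_obs, alpha, n_perm, rng, lengths)
    if p > alpha:
        return []
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    out: list[int] = []
    lo = 0
    for hi in cuts + [n]:
        out.extend(lo + c for c in _segment_stretch(x[lo:hi], alpha, n_perm, rng))
        if hi < n:
            out.append(hi)
        lo = hi
    return sorted(set(out))


def cbs_segment(
    profile: MarkerProfile,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> SegmentedProfile:
    """Segment one array's marker log ratios chromosome by chromosome.

    Parameters mirror the usual CBS defaults: split significance ``alpha``
    (permutation test, (b+1)/(B+1) estimator) and ``n_perm`` permutations.
    The RNG is seeded per (sample, chromosome) from ``seed`` so chromosomes
    can be recomputed independently.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    segments: list[Segment] = []
    for chrom in profile.chromosome_order():
        x = profile.chromosome_values(chrom)
        pos = profile.chromosome_positions(chrom)
        rng = _substream(seed, profile.sample_id, chrom)
        cuts = _segment_stretch(x, alpha, n_perm, rng) if len(x) >= 2 * _MIN_ARC else []
        bounds = [0, *cuts, len(x)]
        for lo, hi in zip(bounds, bounds[1:]):
            segments.append(
                Segment(
                    chromosome=chrom,
                    start=int(pos[lo]),
                    end=int(pos[hi - 1]) + 1,
                    n_markers=hi - lo,
                    seg_mean=float(x[lo:hi].mean()),
                )
            )
    return SegmentedProfile(sample_id=profile.sample_id, segments=segments)


# ---------------------------------------------------------------------------
# mergeLevels


def _segment_members(seg: Segment, profile: MarkerProfile) -> np.ndarray:
    mask = (
        (profile.chromosomes == seg.chromosome)
        & (profile.positions >= seg.start)
        & (profile.positions < seg.end)
    )
    return profile.log_ratios[mask]


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(np.sort(a), np.sort(b)) or (
        len(set(a)) == 1 and set(a) == set(b)
    ):
        return 1.0
    if len(np.unique(np.concatenate([a, b]))) == 1:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def merge_levels(
    segmented: SegmentedProfile,
    profile: MarkerProfile,
    merge_p: float = 1e-4,
) -> SegmentedProfile:
    """Merge segment levels whose member marker values are statistically
    indistinguishable (two-sided rank-sum test, merge while p > ``merge_p``).

    The least-significant pair of levels is merged first; merged levels take
    the pooled mean of their member markers.  Adjacent equal-mean segments on
    a chromosome are finally collapsed into single segments.
    """
    members = [_segment_members(s, profile) for s in segmented.segments]
    # levels: groups of segment indices sharing one mean
    levels: list[list[int]] = [[i] for i in range(len(segmented.segments))]

    def pooled(level: list[int]) -> np.ndarray:
        return np.concatenate([members[i] for i in level])

    while len(levels) > 1:
        best_p, best_pair = -1.0, None
        for u in range(len(levels)):
            for v in range(u + 1, len(levels)):
                p = _ranksum_p(pooled(levels[u]), pooled(levels[v]))
                if p > best_p:
                    best_p, best_pair = p, (u, v)
        if best_p <= merge_p or best_pair is None:
            break
        u, v = best_pair
        levels[u] = levels[u] + levels[v]
        del levels[v]

    mean_of = {}
    for level in levels:
        mu = float(pooled(level).mean())
        for idx in level:
            mean_of[idx] = mu
    relabeled = [
        Segment(s.chromosome, s.start, s.end, s.n_markers, mean_of[i])
        for i, s in enumerate(segmented.segments)
    ]
    # collapse adjacent equal-mean segments per chromosome
    collapsed: list[Segment] = []
    for s in relabeled:
        prev = collapsed[-1] if collapsed else None
        if (
            prev is not None
            and prev.chromosome == s.chromosome
            and prev.end <= s.start
            and prev.seg_mean == s.seg_mean
        ):
            collapsed[-1] = Segment(
                s.chromosome, prev.start, s.end, prev.n_markers + s.n_markers, s.seg_mean
            )
        else:
            collapsed.append(s)
    return SegmentedProfile(sample_id=segmented.sample_id, segments=collapsed)


# ---------------------------------------------------------------------------
# CNV calling


def median_absolute_deviation(x: np.ndarray) -> float:
    """Plain (unscaled) MAD: median of absolute deviations from the median."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def call_cnv(
    segmented: SegmentedProfile,
    profile: MarkerProfile,
    high_mult: float = 5.0,
    low_mult: float = 1.1,
    homdel_mode: str = "symmetric",
    mad_on: str = "raw",
) -> list[CnvCall]:
    """Categorize each segment by its mean against MAD-multiple thresholds.

    amplification: seg_mean > +high_mult×MAD; homozygous deletion:
    seg_mean < −high_mult×MAD (``homdel_mode="symmetric"``) or
    seg_mean < log2(0.2) (``homdel_mode="ratio"``, a copy-ratio reading of the
    deletion threshold); otherwise gain/loss beyond ±low_mult×MAD, else
    neutral.  The MAD is computed on the array's raw marker log ratios by
    default, or on residuals from segment means with ``mad_on="residual"``.
    """
    if mad_on == "raw":
        mad = median_absolute_deviation(profile.log_ratios)
    elif mad_on == "residual":
        fitted = segmented.marker_level_values(profile)
        mad = median_absolute_deviation(profile.log_ratios - fitted)
    else:
        raise ValueError(f"unknown mad_on {mad_on!r}")
    if mad <= 0:
        raise ValueError(
            "MAD of marker log ratios is 0; supply a noise floor or use mad_on='residual'"
        )
    if homdel_mode == "symmetric":
        homdel_cut = -high_mult * mad
    elif homdel_mode == "ratio":
        homdel_cut = math.log2(0.2)
    else:
        raise ValueError(f"unknown homdel_mode {homdel_mode!r}")
    calls = []
    for seg in segmented.segments:
        m = seg.seg_mean
        if m > high_mult * mad:
            cat = "amplification"
        elif m < homdel_cut:
            cat = "homozygous_deletion"
        elif m > low_mult * mad:
            cat = "gain"
        elif m < -low_mult * mad:
            cat = "loss"
        else:
            cat = "neutral"
        calls.append(
            CnvCall(segment=seg, category=cat, mad=mad, high_mult=high_mult, low_mult=low_mult)
        )
    return calls
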