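"""Recurrent copy-number aberration scoring across samples (GISTIC-style).

Per marker, the G-score sums aberration amplitudes over samples whose CNV
call at that marker belongs to the tested kind (gains ∪ amplifications, or
losses ∪ homozygous deletions) — the frequency × amplitude form.  The null
distribution is built by independently applying a uniform random cyclic
shift to each sample's marker-level segment values (preserving within-sample
segmental autocorrelation), pooling null G values over markers and
resamples.  Benjamini–Hochberg control over markers yields q-values and
significant markers are grouped into maximal runs reported as regions.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CnvCall, MarkerProfile, SegmentedProfile, chromosome_sort_key

__all__ = ["RecurrenceTrack", "gscore", "gistic_significance", "marker_map"]

GAIN_CATEGORIES = frozenset({"gain", "amplification"})
LOSS_CATEGORIES = frozenset({"loss", "homozygous_deletion"})


@dataclass
class RecurrenceTrack:
    """Per-marker recurrence scores with (optionally) resampling significance."""

    kind: str  # "gain" or "loss"
    markers: pd.DataFrame  # chromosome, position, g [, p, q, significant, region_id]
    regions: pd.DataFrame | None = None  # region_id, chromosome, start, end, peak_position

    @property
    def g(self) -> np.ndarray:
        return self.markers["g"].to_numpy()


def marker_map(profile: MarkerProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {"chromosome": profile.chromosomes, "position": profile.positions}
    )


def _check_common_map(profiles: Sequence[MarkerProfile]) -> pd.DataFrame:
    ref = marker_map(profiles[0])
    for p in profiles[1:]:
        m = marker_map(p)
        if len(m) != len(ref) or not (
            (m["chromosome"].to_numpy() == ref["chromosome"].to_numpy()).all()
            and (m["position"].to_numpy() == ref["position"].to_numpy()).all()
        ):
            raise ValueError(f"marker map of sample {p.sample_id} differs from reference")
    return ref


def _contribution(
    profile: MarkerProfile,
    segmented: SegmentedProfile,
    calls: Sequence[CnvCall],
    categories: frozenset,
) -> np.ndarray:
    """Per-marker |seg_mean| where the covering call is in ``categories``, else 0."""
    out = np.zeros(len(profile))
    for call in calls:
        if call.category not in categories:
            continue
        seg = call.segment
        mask = (
            (profile.chromosomes == seg.chromosome)
            & (profile.positions >= seg.start)
            & (profile.positions < seg.end)
        )
        out[mask] = abs(seg.seg_mean)
    return out


def gscore(
    profiles: Sequence[MarkerProfile],
    segmented: Sequence[SegmentedProfile],
    calls: Sequence[Sequence[CnvCall]],
    kind: str,
) -> RecurrenceTrack:
    """Observed per-marker G-score track for gains or losses."""
    if kind == "gain":
        categories = GAIN_CATEGORIES
    elif kind == "loss":
        categories = LOSS_CATEGORIES
    else:
        raise ValueError(f"kind must be 'gain' or 'loss', got {kind!r}")
    mmap = _check_common_map(profiles)
    g = np.zeros(len(mmap))
    for prof, seg, cl in zip(profiles, segmented, calls):
        g += _contribution(prof, seg, cl, categories)
    markers = mmap.assign(g=g)
    return RecurrenceTrack(kind=kind, markers=markers)


def _sample_contributions(
    profiles, segmented, calls, categories
) -> np.ndarray:
    return np.stack(
        [_contribution(p, s, c, categories) for p, s, c in zip(profiles, segmented, calls)]
    )


def gistic_significance(
    track: RecurrenceTrack,
    profiles: Sequence[MarkerProfile],
    segmented: Sequence[SegmentedProfile],
    calls: Sequence[Sequence[CnvCall]],
    n_resamples: int = 10000,
    fdr: float = 0.05,
    seed: int = 0,
) -> RecurrenceTrack:
    """Attach resampling p-values, BH q-values, and significant regions.

    Each resample cyclically shifts every sample's contribution vector by an
    independent uniform offset and recomputes G; per-marker p is the fraction
    of the pooled null G values (over markers × resamples) at or above the
    observed score.  When all shift combinations number at most
    ``n_resamples`` the null is enumerated exhaustively; otherwise offsets are
    sampled and the identity (unshifted) track is pooled in so p > 0.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    categories = GAIN_CATEGORIES if track.kind == "gain" else LOSS_CATEGORIES
    contrib = _sample_contributions(profiles, segmented, calls, categories)
    n_samples, n_markers = contrib.shape
    g_obs = track.g

    n_combos = float(n_markers) ** n_samples
    null_pool: list[np.ndarray] = []
    if n_combos <= n_resamples:
        for shifts in itertools.product(range(n_markers), repeat=n_samples):
            null_pool.append(
                sum(np.roll(contrib[s], k) for s, k in enumerate(shifts))
            )
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(b"gistic")])
        )
        null_pool.append(contrib.sum(axis=0))  # identity shift keeps p > 0
        for _ in range(n_resamples):
            shifts = rng.integers(0, n_markers, size=n_samples)
            null_pool.append(
                sum(np.roll(contrib[s], k) for s, k in enumerate(shifts))
            )
    null = np.concatenate(null_pool)
    null_sorted = np.sort(null)
    # p(m) = fraction of pooled null >= observed
    idx = np.searchsorted(null_sorted, g_obs - 1e-12, side="left")
    p = (len(null_sorted) - idx) / len(null_sorted)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = stats.false_discovery_control(p, method="bh")
    significant = q < fdr

    markers = track.markers.copy()
    markers["p"] = p
    markers["q"] = q
    markers["significant"] = significant

    # maximal runs of significant markers per chromosome
    region_id = np.full(len(markers), -1)
    regions = []
    rid = 0
    chroms = markers["chromosome"].to_numpy()
    positions = markers["position"].to_numpy()
    i = 0
    while i < len(markers):
        if significant[i]:
            j = i
            while (
                j + 1 < len(markers)
                and significant[j + 1]
                and chroms[j + 1] == chroms[i]
            ):
                j += 1
            run = slice(i, j + 1)
            region_id[run] = rid
            peak = i + int(np.argmax(g_obs[run]))
            regions.append(
                {
                    "region_id": rid,
                    "chromosome": chroms[i],
                    "start": int(positions[i]),
                    "end": int(positions[j]) + 1,
                    "peak_position": int(positions[peak]),
                    "peak_g": float(g_obs[peak]),
                }
            )
            rid += 1
            i = j + 1
        else:
            i += 1
    markers["region_id"] = region_id
    regions_df = pd.DataFrame(
        regions,
        columns=["region_id", "chromosome", "start", "end", "peak_position", "peak_g"],
    )
    return RecurrenceTrack(kind=track.kind, markers=markers, regions=regions_df)
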