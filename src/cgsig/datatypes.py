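"""Core in-memory containers for paired copy-number / expression cohorts.

Conventions
-----------
* Genomic intervals are 0-based, half-open internally.  SEG files
  (1-based, inclusive) and BED files (0-based, half-open) are converted at
  the I/O boundary.
* Chromosomes are ordered 1..22, X, Y (natural sort for anything else).
* Expression values are log2 scale, genes in rows, samples in columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "chromosome_sort_key",
    "MarkerProfile",
    "Segment",
    "SegmentedProfile",
    "CnvCall",
    "ExpressionMatrix",
    "PhenotypeTable",
    "validate_gene_models",
]

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24})


def chromosome_sort_key(chrom: str):
    """Sort key placing 1..22, X, Y first, then natural order for the rest."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in _CHROM_ORDER:
        return (0, _CHROM_ORDER[c], "")
    # natural sort fallback for scaffolds etc.
    num = re.findall(r"\d+", c)
    return (1, int(num[0]) if num else 0, c)


@dataclass
class MarkerProfile:
    """Ordered marker-level log2 copy-number ratios for one array.

    Markers are sorted by (chromosome, position) with strictly increasing
    positions within a chromosome; all log ratios must be finite.
    """

    sample_id: str
    chromosomes: np.ndarray  # dtype object/str, length n
    positions: np.ndarray  # int base pairs
    log_ratios: np.ndarray  # float log2 tumor/normal

    def __post_init__(self):
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.log_ratios = np.asarray(self.log_ratios, dtype=float)
        n = len(self.chromosomes)
        if not (len(self.positions) == len(self.log_ratios) == n):
            raise ValueError("marker arrays must have equal length")
        if n == 0:
            raise ValueError("empty marker profile")
        if not np.all(np.isfinite(self.log_ratios)):
            raise ValueError(f"non-finite log ratio in sample {self.sample_id}")
        order = sorted(
            range(n),
            key=lambda i: (chromosome_sort_key(self.chromosomes[i]), self.positions[i]),
        )
        if order != list(range(n)):
            self.chromosomes = self.chromosomes[order]
            self.positions = self.positions[order]
            self.log_ratios = self.log_ratios[order]
        for chrom in self.chromosome_order():
            pos = self.positions[self.chromosomes == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom} "
                    f"(sample {self.sample_id})"
                )

    def __len__(self) -> int:
        return len(self.positions)

    def chromosome_order(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chromosomes:
            seen.setdefault(c, None)
        return sorted(seen, key=chromosome_sort_key)

    def chromosome_values(self, chrom: str) -> np.ndarray:
        return self.log_ratios[self.chromosomes == chrom]

    def chromosome_positions(self, chrom: str) -> np.ndarray:
        return self.positions[self.chromosomes == chrom]


@dataclass(frozen=True)
class Segment:
    """Piecewise-constant copy-number segment (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    n_markers: int
    seg_mean: float

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class SegmentedProfile:
    """Segmentation of one array into equal-copy-number regions."""

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        self.segments = sorted(
            self.segments,
            key=lambda s: (chromosome_sort_key(s.chromosome), s.start),
        )
        prev: dict[str, int] = {}
        for seg in self.segments:
            if seg.n_markers < 1:
                raise ValueError("segment with no markers")
            if seg.start >= seg.end:
                raise ValueError(f"empty interval {seg}")
            if seg.chromosome in prev and seg.start < prev[seg.chromosome]:
                raise ValueError(
                    f"overlapping segments on chromosome {seg.chromosome} "
                    f"(sample {self.sample_id})"
                )
            prev[seg.chromosome] = seg.end

    def chromosome_segments(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chromosome == chrom]

    def marker_level_values(self, profile: MarkerProfile) -> np.ndarray:
        """Per-marker segment mean, aligned with ``profile`` marker order."""
        out = np.full(len(profile), np.nan)
        for seg in self.segments:
            mask = (
                (profile.chromosomes == seg.chromosome)
                & (profile.positions >= seg.start)
                & (profile.positions < seg.end)
            )
            out[mask] = seg.seg_mean
        return out

    def check_mean_conservation(self, profile: MarkerProfile, tol: float = 1e-9) -> None:
        """Weighted segment means must reproduce per-chromosome marker means."""
        for chrom in profile.chromosome_order():
            segs = self.chromosome_segments(chrom)
            w = np.array([s.n_markers for s in segs], dtype=float)
            m = np.array([s.seg_mean for s in segs])
            marker_mean = profile.chromosome_values(chrom).mean()
            if abs(np.average(m, weights=w) - marker_mean) > tol:
                raise AssertionError(
                    f"segment means do not conserve marker mean on {chrom}"
                )


CNV_CATEGORIES = ("amplification", "gain", "neutral", "loss", "homozygous_deletion")


@dataclass(frozen=True)
class CnvCall:
    """MAD-threshold copy-number call for one segment of one array."""

    segment: Segment
    category: str
    mad: float
    high_mult: float = 5.0
    low_mult: float = 1.1

    def __post_init__(self):
        if self.category not in CNV_CATEGORIES:
            raise ValueError(f"unknown CNV category {self.category!r}")
        if self.mad <= 0:
            raise ValueError("mad must be positive")

    @property
    def is_aberrant(self) -> bool:
        return self.category != "neutral"


@dataclass
class ExpressionMatrix:
    """Gene × sample log2 expression with optional cohort labels.

    Duplicate gene symbols are permitted before probe collapse only.
    """

    values: pd.DataFrame  # genes in rows, samples in columns
    cohort: pd.Series | None = None  # sample -> cohort label

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite (no missing values)")
        if self.cohort is not None:
            self.cohort = pd.Series(self.cohort)
            missing = [s for s in self.values.columns if s not in self.cohort.index]
            if missing:
                raise ValueError(f"samples without cohort label: {missing}")
            self.cohort = self.cohort.loc[list(self.values.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def has_duplicate_genes(self) -> bool:
        return bool(self.values.index.duplicated().any())


@dataclass
class PhenotypeTable:
    """Per-sample receptor phenotypes, batch, and right-censored follow-up."""

    table: pd.DataFrame  # index = sample ids

    REQUIRED = ("time", "event")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"phenotype table missing column {col!r}")
        t = self.table["time"].to_numpy(dtype=float)
        e = self.table["event"].to_numpy()
        if np.any(t < 0):
            raise ValueError("negative follow-up time")
        if not set(np.unique(e)) <= {0, 1}:
            raise ValueError("event must be 0 (censored) or 1 (failure)")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def subset(self, samples: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.table.loc[list(samples)])


def validate_gene_models(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-model table (gene, chromosome, start, end; 0-based half-open)."""
    required = {"gene", "chromosome", "start", "end"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene models need columns {sorted(required)}")
    if genes["gene"].duplicated().any():
        dups = genes.loc[genes["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene symbols: {dups}")
    if (genes["start"] >= genes["end"]).any():
        bad = genes.loc[genes["start"] >= genes["end"], "gene"].tolist()
        raise ValueError(f"gene models with start >= end: {bad}")
    return genes.reset_index(drop=True)
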