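"""Gene-centric copy-number values and CNV–expression concurrency detection.

A gene-centric table assigns each gene, per sample, the segmentation mean of
the segment with the largest base-pair overlap with the gene interval.
Concurrency between dosage and transcription is then assessed per gene by the
Spearman correlation between the copy-number row and the paired expression
row; a gene is flagged concurrent when it carries at least one non-neutral
CNV call, the correlation is significant (two-sided p < alpha), and the
change goes in the same direction (rho > 0: copy gain ↔ higher expression).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CnvCall, ExpressionMatrix, SegmentedProfile, validate_gene_models

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCentricTable",
    "gene_centric_table",
    "spearman_exact",
    "concurrent_genes",
]

EXACT_PERM_MAX_N = 9  # exact permutation p-value up to this many pairs


@dataclass
class GeneCentricTable:
    """Genes × samples copy-number values with per-cell source segments."""

    values: pd.DataFrame  # genes × samples, NaN for coverage gaps
    provenance: pd.DataFrame  # genes × samples of source Segment objects (or None)


def _assign_gene(segments, start: int, end: int):
    """Segment with maximal overlap with [start, end), or None."""
    best, best_ov = None, 0
    for seg in segments:
        ov = seg.overlap(start, end)
        if ov > best_ov:
            best, best_ov = seg, ov
    return best


def gene_centric_table(
    profiles: Sequence[SegmentedProfile], genes: pd.DataFrame
) -> GeneCentricTable:
    """Build the genes × samples copy-number table from segmented profiles.

    ``genes`` is a gene-model table (gene, chromosome, start, end; 0-based
    half-open).  Cells without any overlapping segment are missing; genes on
    chromosomes absent from a profile are missing too (count logged).
    """
    genes = validate_gene_models(genes)
    sample_ids = [p.sample_id for p in profiles]
    values = pd.DataFrame(
        np.nan, index=genes["gene"], columns=sample_ids, dtype=float
    )
    provenance = pd.DataFrame(None, index=genes["gene"], columns=sample_ids, dtype=object)
    for prof in profiles:
        by_chrom: dict[str, list] = {}
        for seg in prof.segments:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
        n_missing_chrom = 0
        for row in genes.itertuples():
            segs = by_chrom.get(str(row.chromosome))
            if segs is None:
                n_missing_chrom += 1
                continue
            seg = _assign_gene(segs, int(row.start), int(row.end))
            if seg is not None:
                values.at[row.gene, prof.sample_id] = seg.seg_mean
                provenance.at[row.gene, prof.sample_id] = seg
        if n_missing_chrom:
            logger.info(
                "gene_centric_table: %d genes on chromosomes absent from sample %s",
                n_missing_chrom,
                prof.sample_id,
            )
    return GeneCentricTable(values=values, provenance=provenance)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value (midrank ties).

    Enumerates all n! assignments of one rank vector; intended for n ≤ 9.
    """
    rx = _midranks(x) - (len(x) + 1) / 2
    ry = _midranks(y) - (len(y) + 1) / 2
    nx = math.sqrt((rx**2).sum())
    ny = math.sqrt((ry**2).sum())
    if nx == 0 or ny == 0:
        raise ValueError("constant input row")
    rho = float(rx @ ry / (nx * ny))
    perms = np.array(list(itertools.permutations(rx)))
    null = perms @ ry / (nx * ny)
    p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return rho, p


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) <= EXACT_PERM_MAX_N:
        return spearman_exact(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _gene_has_cnv(
    gene_row, calls_by_sample: Mapping[str, Sequence[CnvCall]]
) -> bool:
    chrom, start, end = str(gene_row.chromosome), int(gene_row.start), int(gene_row.end)
    for calls in calls_by_sample.values():
        for call in calls:
            if (
                call.is_aberrant
                and call.segment.chromosome == chrom
                and call.segment.overlap(start, end) > 0
            ):
                return True
    return False


def concurrent_genes(
    table: GeneCentricTable,
    expr: ExpressionMatrix,
    calls_by_sample: Mapping[str, Sequence[CnvCall]],
    genes: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-gene Spearman concurrency between copy number and expression.

    Returns a frame with columns gene, rho, p, n, has_cnv, concurrent,
    excluded, reason.  Correlations use complete pairs over the shared
    samples; genes with a constant copy-number or expression row, or fewer
    than ``min_pairs`` complete pairs, are excluded with a diagnostic.
    The p-value is exact by enumeration for n ≤ 9 and uses the t
    approximation otherwise.  ``concurrent`` requires has_cnv, p < alpha and
    rho > 0 (same-direction change).
    """
    genes = validate_gene_models(genes)
    paired = [s for s in table.values.columns if s in set(expr.samples)]
    if not paired:
        raise ValueError("no shared samples between copy-number table and expression")
    records = []
    gene_rows = {row.gene: row for row in genes.itertuples()}
    for gene in table.values.index:
        if gene not in expr.genes or gene not in gene_rows:
            continue
        cn = table.values.loc[gene, paired].to_numpy(dtype=float)
        ex = expr.values.loc[gene, paired].to_numpy(dtype=float)
        ok = np.isfinite(cn) & np.isfinite(ex)
        cn, ex = cn[ok], ex[ok]
        has_cnv = _gene_has_cnv(gene_rows[gene], calls_by_sample)
        rec = {
            "gene": gene,
            "rho": np.nan,
            "p": np.nan,
            "n": int(ok.sum()),
            "has_cnv": has_cnv,
            "concurrent": False,
            "excluded": False,
            "reason": "",
        }
        if len(cn) < min_pairs:
            rec.update(excluded=True, reason=f"only {len(cn)} complete pairs")
        elif np.ptp(cn) == 0 or np.ptp(ex) == 0:
            rec.update(excluded=True, reason="constant copy-number or expression row")
        else:
            rho, p = _spearman(cn, ex)
            rec.update(rho=rho, p=p)
            rec["concurrent"] = bool(has_cnv and p < alpha and rho > 0)
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("gene")
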