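"""End-to-end convenience drivers chaining the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .concurrency import GeneCentricTable, concurrent_genes, gene_centric_table
from .datatypes import CnvCall, MarkerProfile, SegmentedProfile
from .segmentation import call_cnv, cbs_segment, merge_levels
from .simulate import SimulatedCohort

__all__ = ["ConcurrencyRun", "run_concurrency_pipeline"]


@dataclass
class ConcurrencyRun:
    """Everything produced by segment → merge → call → integrate."""

    segmented: list[SegmentedProfile]
    calls: dict[str, list[CnvCall]]
    table: GeneCentricTable
    results: pd.DataFrame  # per-gene concurrency results


def run_concurrency_pipeline(
    profiles: Sequence[MarkerProfile],
    expression,
    genes: pd.DataFrame,
    alpha_split: float = 0.01,
    n_perm: int = 1000,
    alpha_concurrent: float = 0.05,
    merge_p: float = 1e-4,
    seed: int = 0,
) -> ConcurrencyRun:
    """Segment each array, merge levels, call CNVs, build the gene-centric
    table, and test per-gene copy-number/expression concurrency."""
    segmented: list[SegmentedProfile] = []
    calls: dict[str, list[CnvCall]] = {}
    for prof in profiles:
        seg = cbs_segment(prof, alpha=alpha_split, n_perm=n_perm, seed=seed)
        seg = merge_levels(seg, prof, merge_p=merge_p)
        segmented.append(seg)
        calls[prof.sample_id] = call_cnv(seg, prof)
    table = gene_centric_table(segmented, genes)
    results = concurrent_genes(table, expression, calls, genes, alpha=alpha_concurrent)
    return ConcurrencyRun(segmented=segmented, calls=calls, table=table, results=results)
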