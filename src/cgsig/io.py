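"""Readers/writers for the pipeline's tabular formats and cross-cohort harmonization.

Formats: plain TSV and GCT expression matrices, SEG segment tables
(1-based inclusive on disk, 0-based half-open in memory), BED4 gene models,
GMT gene sets, two-class CLS label files, and phenotype/marker TSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    MarkerProfile,
    PhenotypeTable,
    Segment,
    SegmentedProfile,
    chromosome_sort_key,
    validate_gene_models,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "collapse_probesets",
    "read_seg",
    "write_seg",
    "read_bed",
    "read_gmt",
    "write_gmt",
    "read_cls",
    "write_cls",
    "read_phenotype_table",
    "read_marker_table",
    "quantile_normalize",
    "harmonize_cohorts",
]

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


# ---------------------------------------------------------------------------
# expression matrices


def _parse_matrix_lines(lines: list[str], path, first_data_line: int) -> pd.DataFrame:
    header = lines[first_data_line - 1].rstrip("\n").split("\t")
    n_cols = len(header)
    samples = header[1:]
    genes, rows = [], []
    for lineno, line in enumerate(lines[first_data_line:], start=first_data_line + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != n_cols:
            raise ValueError(
                f"{path}: line {lineno} has {len(parts)} fields, expected {n_cols}"
            )
        genes.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError:
            for j, v in enumerate(parts[1:], start=2):
                try:
                    float(v)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {v!r} at line {lineno}, column {j}"
                    ) from None
            raise
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=samples)


def read_expression_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes × samples log2 expression table.

    ``dialect="tsv"``: header row of sample ids, one gene per row.
    ``dialect="gct"``: the Broad GCT format — ``#1.2`` line, a size line, and a
    Description column that is dropped.  Duplicate gene rows are retained (they
    are collapsed later by :func:`collapse_probesets`).
    """
    path = Path(path)
    lines = path.read_text().splitlines(keepends=True)
    if dialect == "tsv":
        df = _parse_matrix_lines(lines, path, first_data_line=1)
    elif dialect == "gct":
        if not lines or not lines[0].startswith("#1.2"):
            raise ValueError(f"{path}: missing GCT '#1.2' version line")
        df = _parse_matrix_lines(_strip_gct_description(lines), path, first_data_line=1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.index.duplicated().any():
        ndup = int(df.index.duplicated().sum())
        logger.info("%s: %d duplicated gene symbol rows retained for collapse", path, ndup)
    return ExpressionMatrix(values=df)


def _strip_gct_description(lines: list[str]) -> list[str]:
    """Drop GCT preamble and the Description column, yielding plain-TSV lines."""
    out = []
    for line in lines[2:]:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        out.append("\t".join([parts[0]] + parts[2:]) + "\n")
    return out


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def collapse_probesets(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Reduce probe rows to one per gene symbol, keeping the most variable probe.

    Variability is the interquartile range (Q3 − Q1, linear-interpolation
    quantiles) across all samples.  Ties are broken toward the
    lexicographically smallest probe id; unmapped probes are dropped (count
    logged).  Column order is preserved.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    df = matrix.values
    mapped = [p for p in df.index if p in probe_to_gene]
    n_dropped = len(df) - len(mapped)
    if n_dropped:
        logger.info("collapse_probesets: dropping %d unmapped probes", n_dropped)
    sub = df.loc[mapped]
    q3 = sub.quantile(0.75, axis=1)
    q1 = sub.quantile(0.25, axis=1)
    iqr = q3 - q1
    choice: dict[str, str] = {}
    for probe in sorted(mapped):  # lexicographic order makes ties deterministic
        gene = probe_to_gene[probe]
        if gene not in choice or iqr[probe] > iqr[choice[gene]]:
            choice[gene] = probe
    genes = sorted(choice)
    out = sub.loc[[choice[g] for g in genes]]
    out.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(values=out, cohort=matrix.cohort)


# ---------------------------------------------------------------------------
# SEG


def read_seg(path) -> list[SegmentedProfile]:
    """Read a SEG file.  On-disk coordinates are 1-based inclusive and become
    0-based half-open in memory."""
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SEG file missing columns {missing}")
    profiles = []
    for sample, grp in df.groupby("Sample", sort=False):
        segments = [
            Segment(
                chromosome=str(r.Chromosome),
                start=int(r.Start) - 1,
                end=int(r.End),
                n_markers=int(r.Num_Probes),
                seg_mean=float(r.Segment_Mean),
            )
            for r in grp.itertuples()
        ]
        _check_no_overlap(sample, segments)
        profiles.append(SegmentedProfile(sample_id=str(sample), segments=segments))
    return profiles


def _check_no_overlap(sample, segments: list[Segment]) -> None:
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)
    offenders = []
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                offenders.append((sample, chrom, (a.start, a.end), (b.start, b.end)))
    if offenders:
        raise ValueError(f"overlapping segments: {offenders}")


def write_seg(profiles: Iterable[SegmentedProfile], path) -> None:
    rows = []
    for prof in profiles:
        for s in prof.segments:
            rows.append(
                (prof.sample_id, s.chromosome, s.start + 1, s.end, s.n_markers, s.seg_mean)
            )
    df = pd.DataFrame(rows, columns=SEG_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# BED / GMT / CLS / phenotype / marker tables


def read_bed(path) -> pd.DataFrame:
    """Read BED4 gene models (0-based half-open, matching internal convention)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chromosome", "start", "end", "gene"],
        dtype={"chromosome": str},
    )
    return validate_gene_models(df[["gene", "chromosome", "start", "end"]])


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line with fewer than 3 fields: {line!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, descriptions=None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_cls(path) -> np.ndarray:
    """Read a two-class categorical CLS file, returning per-sample string labels."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    n, k, _ = lines[0].split()
    names = lines[1].lstrip("#").split()
    raw = lines[2].split()
    if len(raw) != int(n):
        raise ValueError(f"{path}: CLS declares {n} samples, found {len(raw)}")
    if set(raw) <= set(names):
        return np.array(raw, dtype=object)
    return np.array([names[int(v)] for v in raw], dtype=object)


def write_cls(labels: Sequence[str], path) -> None:
    names = list(dict.fromkeys(labels))
    if len(names) != 2:
        raise ValueError("CLS writer supports exactly two classes")
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write("# " + " ".join(names) + "\n")
        fh.write(" ".join(str(names.index(l)) for l in labels) + "\n")


def read_phenotype_table(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PhenotypeTable(df)


def read_marker_table(path) -> list[MarkerProfile]:
    """Read a marker TSV (marker_id, chromosome, position, one column per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    meta = {"marker_id", "chromosome", "position"}
    if not meta <= set(df.columns):
        raise ValueError(f"{path}: marker table needs columns {sorted(meta)}")
    samples = [c for c in df.columns if c not in meta]
    return [
        MarkerProfile(
            sample_id=s,
            chromosomes=df["chromosome"].to_numpy(dtype=object),
            positions=df["position"].to_numpy(),
            log_ratios=df[s].to_numpy(dtype=float),
        )
        for s in samples
    ]


# ---------------------------------------------------------------------------
# cross-cohort harmonization


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns: each sample's sorted values are replaced by
    the across-sample mean of order statistics, so all sorted column vectors
    become identical."""
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n, m = arr.shape
    rows = np.arange(n)
    for j in range(m):
        ranks[order[:, j], j] = rows
    mean_order_stats = np.sort(arr, axis=0).mean(axis=1)
    out = mean_order_stats[ranks]
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def harmonize_cohorts(matrices: Mapping[str, ExpressionMatrix]) -> ExpressionMatrix:
    """Merge expression cohorts: median-array centering within each cohort,
    then quantile normalization of the pooled matrix over the gene intersection.

    The "median array" of a cohort holds the per-gene median across that
    cohort's samples; centering subtracts it from every array of the cohort.
    """
    if not matrices:
        raise ValueError("no cohorts given")
    common: pd.Index | None = None
    for m in matrices.values():
        if m.has_duplicate_genes():
            raise ValueError("collapse probes before harmonization")
        common = m.genes if common is None else common.intersection(m.genes)
    if common is None or len(common) == 0:
        raise ValueError("empty gene intersection across cohorts")
    common = pd.Index(sorted(common))
    centered = []
    cohort_labels = {}
    for name, m in matrices.items():
        sub = m.values.loc[common]
        median_array = sub.median(axis=1)
        centered.append(sub.sub(median_array, axis=0))
        for s in sub.columns:
            cohort_labels[s] = name
    pooled = pd.concat(centered, axis=1)
    if pooled.columns.duplicated().any():
        raise ValueError("duplicate sample ids across cohorts")
    normalized = quantile_normalize(pooled)
    return ExpressionMatrix(values=normalized, cohort=pd.Series(cohort_labels))
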