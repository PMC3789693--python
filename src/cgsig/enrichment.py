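"""Gene set enrichment analysis: phenotype-permutation and pre-ranked modes.

Genes are ranked by signal-to-noise (μ1−μ2)/(σ1+σ2) between two phenotype
classes (each σ floored at 0.2·|μ|), or — in pre-ranked mode — by the
coefficient of variation sd/mean of each gene.  The enrichment score of a
gene set is the signed maximum deviation of a Kolmogorov–Smirnov-style
running sum in which set members increment by |metric|^p (normalized by the
set total) and non-members decrement by 1/(N−k).  Significance comes from
phenotype-label permutations: the normalized enrichment score (NES) divides
the observed ES by the mean same-sign null ES, nominal p is one-sided within
sign, and the FDR q is the sign-stratified ratio of null to observed tail
proportions (the usual GSEA convention; sets with q < 0.25 are reported as
enriched).
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix

__all__ = ["rank_genes", "enrichment_score", "gsea"]


def _frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def _signal_to_noise(
    X: np.ndarray, labels: np.ndarray, positive_class=None
) -> np.ndarray:
    classes = list(np.unique(labels))
    if len(classes) != 2:
        raise ValueError("phenotype mode needs exactly two classes")
    if positive_class is not None:
        if positive_class not in classes:
            raise ValueError(f"positive_class {positive_class!r} not among {classes}")
        classes = [positive_class] + [c for c in classes if c != positive_class]
    m1, m2 = labels == classes[0], labels == classes[1]
    mu1, mu2 = X[:, m1].mean(axis=1), X[:, m2].mean(axis=1)
    sd1 = X[:, m1].std(axis=1, ddof=1)
    sd2 = X[:, m2].std(axis=1, ddof=1)
    sd1 = np.maximum(sd1, 0.2 * np.abs(mu1))
    sd2 = np.maximum(sd2, 0.2 * np.abs(mu2))
    denom = sd1 + sd2
    with np.errstate(divide="ignore", invalid="ignore"):
        metric = np.where(denom > 0, (mu1 - mu2) / np.where(denom == 0, 1, denom), 0.0)
    return metric


def _order(genes: pd.Index, metric: np.ndarray) -> pd.DataFrame:
    # descending metric; ties broken stably by gene symbol
    df = pd.DataFrame({"gene": genes, "metric": metric})
    df = df.sort_values("gene", kind="stable").sort_values(
        "metric", ascending=False, kind="stable"
    )
    return df.reset_index(drop=True)


def rank_genes(
    expr,
    labels: Sequence | None = None,
    weights: Mapping[str, float] | pd.Series | None = None,
    mode: str = "phenotype",
    positive_class=None,
) -> pd.DataFrame:
    """Build the ranked gene list for GSEA.

    ``mode="phenotype"`` ranks by signal-to-noise between the two classes in
    ``labels`` (``positive_class`` picks which class counts as up-regulated;
    first class in sorted order by default); ``mode="preranked_cv"`` ranks by
    the coefficient of variation sd/mean per gene (or by explicit ``weights``
    if given).  Returns a frame with columns gene, metric, ordered top to
    bottom.
    """
    if mode == "phenotype":
        df_expr = _frame(expr)
        metric = _signal_to_noise(
            df_expr.to_numpy(dtype=float), np.asarray(labels), positive_class
        )
        return _order(df_expr.index, metric)
    if mode == "preranked_cv":
        if weights is not None:
            w = pd.Series(weights, dtype=float)
            return _order(w.index, w.to_numpy())
        df_expr = _frame(expr)
        X = df_expr.to_numpy(dtype=float)
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mu != 0, sd / mu, 0.0)
        return _order(df_expr.index, cv)
    raise ValueError(f"unknown mode {mode!r}")


def enrichment_score(
    ranked: pd.DataFrame, gene_set: Sequence[str], p: float = 1.0
):
    """ES of a gene set along the ranked list, plus the running sum and hits.

    Hits increment the running sum by |metric|^p normalized by the set's
    total (equal weights when p = 0 or when all hit metrics vanish); misses
    decrement by 1/(N−k).  ES is the running-sum value of largest magnitude.
    """
    genes = ranked["gene"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in genes), bool, len(genes))
    k = int(hit.sum())
    N = len(genes)
    if k == 0:
        raise ValueError("gene set has no member in the ranked universe")
    if k == N:
        raise ValueError("gene set equals the entire universe")
    w = np.abs(metric) ** p if p > 0 else np.ones(N)
    hit_total = w[hit].sum()
    if hit_total == 0:
        w = np.ones(N)
        hit_total = float(k)
    steps = np.where(hit, w / hit_total, -1.0 / (N - k))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running, np.flatnonzero(hit)


def _null_es(
    df_expr: pd.DataFrame,
    labels: np.ndarray,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int,
    p: float,
    seed: int,
    positive_class=None,
) -> np.ndarray:
    """Null ES matrix (sets × permutations) by phenotype-label permutation."""
    classes, counts = np.unique(labels, return_counts=True)
    n_distinct = math.comb(len(labels), int(counts[0]))
    perms: list[np.ndarray] = []
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label permutations; enumerating exhaustively"
        )
        for combo in itertools.combinations(range(len(labels)), int(counts[0])):
            lab = np.full(len(labels), classes[1], dtype=labels.dtype)
            lab[list(combo)] = classes[0]
            perms.append(lab)
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(b"gsea")])
        )
        perms = [rng.permutation(labels) for _ in range(n_perm)]
    null = np.empty((len(gene_sets), len(perms)))
    for j, lab in enumerate(perms):
        ranked = rank_genes(df_expr, lab, mode="phenotype", positive_class=positive_class)
        for i, gs in enumerate(gene_sets.values()):
            null[i, j] = enrichment_score(ranked, gs, p=p)[0]
    return null


def _sign_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """Sign-stratified FDR q: ratio of null to observed tail proportions,
    clipped to 1 and made monotone non-increasing in |NES| within each sign."""
    q = np.ones(len(nes_obs))
    for sign in (1, -1):
        obs_idx = np.flatnonzero(np.sign(nes_obs) == sign)
        if len(obs_idx) == 0:
            continue
        null_pool = nes_null[np.sign(nes_null) == sign]
        obs_pool = nes_obs[obs_idx]
        for i in obs_idx:
            thresh = abs(nes_obs[i])
            null_tail = np.mean(np.abs(null_pool) >= thresh) if len(null_pool) else 0.0
            obs_tail = np.mean(np.abs(obs_pool) >= thresh)
            q[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
        # q-value of a set = min estimated FDR over all rejection thresholds
        # at or below its |NES|: cumulative min along ascending |NES|, which
        # makes q monotone non-increasing in |NES|
        order = obs_idx[np.argsort(np.abs(nes_obs[obs_idx]))]
        running = np.inf
        for i in order:
            running = min(running, q[i])
            q[i] = running
    return q


def gsea(
    expr,
    labels: Sequence,
    gene_sets: Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    p: float = 1.0,
    seed: int = 0,
    fdr_threshold: float = 0.25,
    positive_class=None,
) -> pd.DataFrame:
    """Phenotype-permutation GSEA over a collection of gene sets.

    Returns a frame indexed by set name with columns es, nes, p (nominal,
    one-sided within sign), q (sign-stratified FDR), n_hits, enriched
    (q < ``fdr_threshold``).
    """
    df_expr = _frame(expr)
    labels = np.asarray(labels)
    ranked = rank_genes(df_expr, labels, mode="phenotype", positive_class=positive_class)
    names = list(gene_sets)
    es_obs = np.array(
        [enrichment_score(ranked, gene_sets[name], p=p)[0] for name in names]
    )
    null = _null_es(df_expr, labels, gene_sets, n_perm, p, seed, positive_class)

    nes_obs = np.empty(len(names))
    nes_null = np.empty_like(null)
    pvals = np.empty(len(names))
    for i in range(len(names)):
        row = null[i]
        for sign in (1, -1):
            same = row[np.sign(row) == sign]
            denom = np.abs(same).mean() if len(same) else 1.0
            if np.sign(es_obs[i]) == sign:
                nes_obs[i] = es_obs[i] / denom if denom > 0 else 0.0
                n_tail = int((np.abs(same) >= abs(es_obs[i])).sum())
                pvals[i] = (
                    max(n_tail, 0) / len(same) if len(same) else 1.0
                )
            mask = np.sign(row) == sign
            nes_null[i, mask] = row[mask] / denom if denom > 0 else 0.0
        if es_obs[i] == 0:
            nes_obs[i] = 0.0
            pvals[i] = 1.0
    pvals = np.clip(pvals, 1.0 / (null.shape[1] + 1), 1.0)
    q = _sign_fdr(nes_obs, nes_null.ravel())
    return pd.DataFrame(
        {
            "es": es_obs,
            "nes": nes_obs,
            "p": pvals,
            "q": q,
            "n_hits": [
                len(enrichment_score(ranked, gene_sets[n], p=p)[2]) for n in names
            ],
            "enriched": q < fdr_threshold,
        },
        index=pd.Index(names, name="gene_set"),
    )
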