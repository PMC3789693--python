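"""Centroid-based single-sample subtype prediction and two-component mixture
inference of receptor status from expression.

Single-sample prediction (SSP) mean-centers genes within the cohort and
assigns each sample to the subtype centroid with the highest rank
(Spearman) correlation over shared genes; samples below a minimum
correlation stay unclassified.  Receptor (ER/HER2-like) status is inferred
from a designated marker gene's expression with a two-component Gaussian
mixture fitted by EM — positive call when the posterior of the high
component exceeds one half.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix

__all__ = ["MixtureFit", "ssp_classify", "mixture_receptor_call"]

UNCLASSIFIED = "unclassified"


def _frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def ssp_classify(
    expr,
    centroids: pd.DataFrame,
    min_rho: float = 0.1,
    method: str = "spearman",
    min_overlap: int = 20,
) -> pd.DataFrame:
    """Assign each sample to the best-correlated subtype centroid.

    ``centroids`` is genes × subtypes.  Genes are mean-centered across the
    cohort before correlating (removing per-gene systematic shifts), the
    correlation is Spearman by default (``method="pearson"`` to switch), and
    samples whose best correlation falls below ``min_rho`` are labelled
    ``"unclassified"``.  Requires at least ``min_overlap`` shared genes.
    """
    if centroids.shape[1] < 2:
        raise ValueError("need at least two subtype centroids")
    df_expr = _frame(expr)
    shared = [g for g in centroids.index if g in df_expr.index]
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} genes shared with centroids; need >= {min_overlap}"
        )
    X = df_expr.loc[shared]
    Xc = X.sub(X.mean(axis=1), axis=0).to_numpy()
    C = centroids.loc[shared].to_numpy()
    if method == "spearman":
        Xr = np.apply_along_axis(stats.rankdata, 0, Xc)
        Cr = np.apply_along_axis(stats.rankdata, 0, C)
    elif method == "pearson":
        Xr, Cr = Xc, C
    else:
        raise ValueError(f"unknown method {method!r}")
    Xr = Xr - Xr.mean(axis=0)
    Cr = Cr - Cr.mean(axis=0)
    sx = np.sqrt((Xr**2).sum(axis=0))
    sc = np.sqrt((Cr**2).sum(axis=0))
    sx[sx == 0] = 1.0
    sc[sc == 0] = 1.0
    corr = (Xr.T @ Cr) / np.outer(sx, sc)  # samples × subtypes
    best = corr.argmax(axis=1)
    best_rho = corr.max(axis=1)
    labels = np.where(
        best_rho >= min_rho, centroids.columns.to_numpy()[best], UNCLASSIFIED
    )
    return pd.DataFrame(
        {"subtype": labels, "rho": best_rho},
        index=df_expr.columns,
    )


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture over a marker gene's expression."""

    mu_low: float
    mu_high: float
    sd_low: float
    sd_high: float
    weight_high: float
    posteriors: np.ndarray  # per-sample posterior of the high component
    calls: np.ndarray  # "positive" / "negative"
    log_likelihood: float
    loglik_path: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def separation_index(self) -> float:
        pooled = np.sqrt(
            (1 - self.weight_high) * self.sd_low**2 + self.weight_high * self.sd_high**2
        )
        return abs(self.mu_high - self.mu_low) / pooled

    @property
    def low_confidence(self) -> bool:
        return self.separation_index < 2.0


def _em_once(x: np.ndarray, mu, sd, w_high, tol, max_iter):
    """One EM run; returns params, posteriors, and loglik trajectory."""
    n = len(x)
    mu1, mu2 = mu
    sd1, sd2 = sd
    w2 = w_high
    path = []
    prev = -np.inf
    min_sd = max(1e-6 * (np.std(x) + 1e-12), 1e-9)
    for _ in range(max_iter):
        d1 = (1 - w2) * stats.norm.pdf(x, mu1, sd1)
        d2 = w2 * stats.norm.pdf(x, mu2, sd2)
        total = d1 + d2
        total[total <= 0] = np.finfo(float).tiny
        ll = float(np.log(total).sum())
        path.append(ll)
        r2 = d2 / total
        r1 = 1 - r2
        n1, n2 = r1.sum(), r2.sum()
        if n1 < 1e-10 or n2 < 1e-10:
            break
        mu1 = float((r1 * x).sum() / n1)
        mu2 = float((r2 * x).sum() / n2)
        sd1 = max(float(np.sqrt((r1 * (x - mu1) ** 2).sum() / n1)), min_sd)
        sd2 = max(float(np.sqrt((r2 * (x - mu2) ** 2).sum() / n2)), min_sd)
        w2 = float(n2 / n)
        if ll - prev < tol and np.isfinite(prev):
            return (mu1, mu2, sd1, sd2, w2), r2, path, True
        prev = ll
    return (mu1, mu2, sd1, sd2, w2), r2, path, False


def mixture_receptor_call(
    values,
    seed: int = 0,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to marker-gene expression and call
    receptor status.

    EM with ``n_restarts`` seeded restarts (quantile-based initialization with
    jitter); the best-likelihood run wins.  Components are relabelled so
    μ_low < μ_high; a sample is called positive when the posterior of the high
    component exceeds 0.5.  A separation index |μ_high−μ_low|/pooled sd below
    2 marks the fit low-confidence (e.g. unimodal input).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 samples for the mixture fit")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(b"mixture")])
    )
    spread = np.std(x) + 1e-12
    best = None
    for r in range(n_restarts):
        q_lo, q_hi = np.percentile(x, [25, 75])
        mu0 = (
            q_lo + rng.normal(0, 0.1 * spread),
            q_hi + rng.normal(0, 0.1 * spread),
        )
        sd0 = (spread / 2, spread / 2)
        w0 = float(np.clip(0.5 + rng.normal(0, 0.1), 0.05, 0.95))
        params, r2, path, converged = _em_once(x, mu0, sd0, w0, tol, max_iter)
        ll = path[-1]
        if best is None or ll > best[0]:
            best = (ll, params, r2, path, converged)
    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("EM failed to produce a finite likelihood after restarts")
    ll, (mu1, mu2, sd1, sd2, w2), r2, path, converged = best
    if mu1 > mu2:  # relabel so the high component is second; calls unchanged
        mu1, mu2 = mu2, mu1
        sd1, sd2 = sd2, sd1
        w2 = 1 - w2
        r2 = 1 - r2
    calls = np.where(r2 > 0.5, "positive", "negative")
    return MixtureFit(
        mu_low=mu1, mu_high=mu2, sd_low=sd1, sd_high=sd2, weight_high=w2,
        posteriors=r2, calls=calls, log_likelihood=ll, loglik_path=path,
        converged=converged,
    )
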