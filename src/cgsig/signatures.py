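"""Two-class differential expression screening and signature classifiers.

The screening statistic is a two-sample t-test with a random-variance model:
gene-level precisions 1/σ² are taken as Gamma(shape a, rate a·b), so that the
pooled variance s² is marginally b·F(d, 2a) with d = n1+n2−2 residual degrees
of freedom.  (a, b) are fitted once across genes by maximum likelihood on
that F characterization; the per-gene shrunken variance is

    σ̃² = (d·s² + 2a·b) / (d + 2a),     df = d + 2a,

which converges to the plain pooled t-test as a → 0.  A global multivariate
permutation test controls the family-wise behavior of the screened list, and
five classifiers (compound covariate predictor, diagonal LDA, 3-NN, nearest
centroid, linear SVM) evaluate signatures by honest leave-one-out
cross-validation with gene selection redone inside every fold.
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.svm import SVC

from .datatypes import ExpressionMatrix

__all__ = [
    "two_class_summary",
    "fit_variance_prior",
    "random_variance_ttest",
    "multivariate_permutation_test",
    "ClassifierModel",
    "train_classifier",
    "predict",
    "loocv_accuracy",
    "consensus_signature",
    "center_by_cohort",
]

CLASSIFIER_METHODS = ("ccp", "dlda", "knn3", "centroid", "svm_linear")


def _as_frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def _two_classes(labels: Sequence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    return labels, classes, (labels == classes[1]).astype(int)


def two_class_summary(X: np.ndarray, labels: Sequence):
    """Group means, pooled variance and degrees of freedom per gene (row)."""
    labels, classes, _ = _two_classes(labels)
    m1 = labels == classes[0]
    m2 = labels == classes[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per class")
    mu1 = X[:, m1].mean(axis=1)
    mu2 = X[:, m2].mean(axis=1)
    ss1 = ((X[:, m1] - mu1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X[:, m2] - mu2[:, None]) ** 2).sum(axis=1)
    d = n1 + n2 - 2
    s2 = (ss1 + ss2) / d
    return mu1, mu2, s2, d, n1, n2, classes


def fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """ML fit of (a, b) in the model s² ~ b·F(d, 2a) across genes.

    a is the prior shape (strength) of the inverse-gamma variance model and b
    its scale (roughly the typical gene variance).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) < 3:
        raise ValueError("too few positive gene variances to fit the prior")

    def nll(theta):
        a, b = np.exp(theta)
        if not (1e-4 < a < 1e4 and 1e-8 < b < 1e8):
            return 1e12
        z = pos / b
        return -(stats.f.logpdf(z, d, 2 * a) - math.log(b)).sum()

    med = float(np.median(pos))
    best = None
    for a0 in (0.5, 2.0, 8.0):
        res = optimize.minimize(
            nll, x0=[math.log(a0), math.log(med)], method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    return float(a), float(b)


def random_variance_ttest(
    expr,
    labels: Sequence,
    mode: str = "random_variance",
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-gene two-sample t-tests, shrunken-variance by default.

    ``mode="plain"`` gives the ordinary pooled-variance Student t.  ``prior``
    overrides the fitted (a, b), mostly for limiting-case checks.  Genes with
    zero variance in both classes get t = 0, p = 1 with a diagnostic flag.
    Returns a frame indexed by gene: t, p, df, mean_<class1>, mean_<class2>,
    degenerate.
    """
    df_expr = _as_frame(expr)
    X = df_expr.to_numpy(dtype=float)
    mu1, mu2, s2, d, n1, n2, classes = two_class_summary(X, labels)
    if mode == "plain":
        a, b = 0.0, 0.0
    elif mode == "random_variance":
        a, b = prior if prior is not None else fit_variance_prior(s2, d)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    var_shrunk = (d * s2 + 2 * a * b) / (d + 2 * a)
    dof = d + 2 * a
    se = np.sqrt(var_shrunk * (1 / n1 + 1 / n2))
    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, (mu1 - mu2) / np.where(se == 0, 1.0, se))
    p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.where(degenerate, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "df": dof,
            f"mean_{classes[0]}": mu1,
            f"mean_{classes[1]}": mu2,
            "degenerate": degenerate,
        },
        index=df_expr.index,
    )


def _label_permutations(labels: np.ndarray, n_perm: int, seed: int, exhaustive_limit: int):
    """Yield permuted label vectors: all distinct balanced relabelings when
    there are at most ``exhaustive_limit``, else ``n_perm`` sampled ones."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    n_distinct = math.comb(n, int(counts[0]))
    if n_distinct <= exhaustive_limit:
        idx_all = range(n)
        for combo in itertools.combinations(idx_all, int(counts[0])):
            perm = np.full(n, classes[1], dtype=labels.dtype)
            perm[list(combo)] = classes[0]
            yield perm
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(b"mvp")])
        )
        for _ in range(n_perm):
            yield rng.permutation(labels)


def multivariate_permutation_test(
    expr,
    labels: Sequence,
    alpha: float = 1e-3,
    n_perm: int = 2000,
    seed: int = 0,
    mode: str = "random_variance",
    exhaustive_limit: int = 10_000,
):
    """Global test of whether more genes pass p < ``alpha`` than chance allows.

    The observed statistic is the count of genes with p < alpha; the null
    permutes class labels (exhaustively over balanced relabelings when at
    most ``exhaustive_limit`` exist, else sampled).  For the random-variance
    mode the (a, b) prior is fitted once on the observed labels and reused
    across permutations.  Returns (global_p, selected_genes, observed_count).
    """
    df_expr = _as_frame(expr)
    labels = np.asarray(labels)
    X = df_expr.to_numpy(dtype=float)
    prior = None
    if mode == "random_variance":
        _, _, s2, d, _, _, _ = two_class_summary(X, labels)
        prior = fit_variance_prior(s2, d)
    obs = random_variance_ttest(df_expr, labels, mode=mode, prior=prior)
    observed_count = int((obs["p"] < alpha).sum())
    selected = list(obs.index[obs["p"] < alpha])

    counts = []
    exhaustive = math.comb(len(labels), int((labels == np.unique(labels)[0]).sum())) <= exhaustive_limit
    for perm in _label_permutations(labels, n_perm, seed, exhaustive_limit):
        res = random_variance_ttest(df_expr, perm, mode=mode, prior=prior)
        counts.append(int((res["p"] < alpha).sum()))
    counts = np.asarray(counts)
    if exhaustive:
        global_p = float(np.mean(counts >= observed_count))
    else:
        global_p = (int((counts >= observed_count).sum()) + 1) / (len(counts) + 1)
    return global_p, selected, observed_count


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ClassifierModel:
    """A fitted two-class signature classifier over a selected gene panel."""

    method: str
    genes: list[str]
    classes: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in CLASSIFIER_METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def _correlation_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between columns of A and columns of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.sqrt((Ac**2).sum(axis=0))
    sb = np.sqrt((Bc**2).sum(axis=0))
    sa[sa == 0] = 1.0
    sb[sb == 0] = 1.0
    corr = (Ac.T @ Bc) / np.outer(sa, sb)
    return 1.0 - corr


def _select_genes(
    expr_df: pd.DataFrame, labels, selection_alpha: float, mode: str, min_genes: int = 2
) -> list[str]:
    res = random_variance_ttest(expr_df, labels, mode=mode)
    selected = list(res.index[res["p"] < selection_alpha])
    if len(selected) < min_genes:
        # guarantee a usable panel: fall back to the smallest p-values
        selected = list(res["p"].nsmallest(min_genes).index)
    return selected


def train_classifier(
    expr,
    labels: Sequence,
    method: str,
    selection_alpha: float = 1e-3,
    mode: str = "random_variance",
    genes: Sequence[str] | None = None,
    distance: str = "correlation",
) -> ClassifierModel:
    """Fit one of the five signature classifiers.

    Gene selection (t-test p < ``selection_alpha``) is part of training unless
    an explicit ``genes`` panel is given.  Methods: ``ccp`` (compound
    covariate predictor: per-sample score Σ t_g·x_g, threshold midway between
    class mean scores), ``dlda`` (per-gene pooled-variance diagonal
    discriminant), ``knn3`` / ``centroid`` (1 − Pearson correlation distance
    by default), ``svm_linear`` (C = 1 on per-gene standardized values).
    """
    df_expr = _as_frame(expr)
    labels = np.asarray(labels)
    if genes is None:
        genes = _select_genes(df_expr, labels, selection_alpha, mode)
    genes = list(genes)
    if len(genes) < 1:
        raise ValueError("no genes selected")
    sub = df_expr.loc[genes]
    X = sub.to_numpy(dtype=float)  # genes × samples
    _, classes, _ = _two_classes(labels)
    m1, m2 = labels == classes[0], labels == classes[1]
    model = ClassifierModel(method=method, genes=genes, classes=classes)

    if method == "ccp":
        res = random_variance_ttest(sub, labels, mode=mode)
        w = res["t"].to_numpy()
        scores = w @ X
        threshold = 0.5 * (scores[m1].mean() + scores[m2].mean())
        # class1 lies on the side of its own mean score
        model.params = {
            "weights": w,
            "threshold": threshold,
            "class1_high": scores[m1].mean() > scores[m2].mean(),
            "train_scores": scores,
        }
    elif method == "dlda":
        mu1, mu2, s2, d, n1, n2, _ = two_class_summary(X, labels)
        s2 = np.where(s2 <= 0, np.maximum(s2[s2 > 0].min() if (s2 > 0).any() else 1.0, 1e-12), s2)
        model.params = {"mu1": mu1, "mu2": mu2, "s2": s2}
    elif method == "knn3":
        model.params = {"X": X, "labels": labels.copy(), "distance": distance}
    elif method == "centroid":
        model.params = {
            "centroids": np.stack([X[:, m1].mean(axis=1), X[:, m2].mean(axis=1)], axis=1),
            "distance": distance,
        }
    elif method == "svm_linear":
        mean = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        Z = ((X - mean[:, None]) / sd[:, None]).T
        svm = SVC(kernel="linear", C=1.0)
        svm.fit(Z, labels.astype(str))
        model.params = {"mean": mean, "sd": sd, "svm": svm}
    else:  # pragma: no cover - guarded by ClassifierModel
        raise ValueError(method)
    return model


def predict(model: ClassifierModel, expr) -> np.ndarray:
    """Predict class labels for samples (columns) covering the model's genes."""
    df_expr = _as_frame(expr)
    missing = [g for g in model.genes if g not in df_expr.index]
    if missing:
        raise ValueError(f"samples do not cover model genes: {missing}")
    X = df_expr.loc[model.genes].to_numpy(dtype=float)
    c0, c1 = model.classes
    p = model.params
    if model.method == "ccp":
        scores = p["weights"] @ X
        high = scores > p["threshold"]
        return np.where(high == p["class1_high"], c0, c1)
    if model.method == "dlda":
        d1 = (((X - p["mu1"][:, None]) ** 2) / p["s2"][:, None]).sum(axis=0)
        d2 = (((X - p["mu2"][:, None]) ** 2) / p["s2"][:, None]).sum(axis=0)
        return np.where(d1 <= d2, c0, c1)
    if model.method == "knn3":
        if p["distance"] == "correlation" and X.shape[0] > 1:
            D = _correlation_distance(p["X"], X)  # train × test
        else:
            D = np.sqrt(
                ((p["X"][:, :, None] - X[:, None, :]) ** 2).sum(axis=0)
            )
        out = []
        for j in range(X.shape[1]):
            order = np.lexsort((np.arange(D.shape[0]), D[:, j]))  # distance, then id order
            votes = p["labels"][order[:3]]
            out.append(c0 if (votes == c0).sum() >= 2 else c1)
        return np.asarray(out, dtype=object)
    if model.method == "centroid":
        C = p["centroids"]
        if p["distance"] == "correlation" and X.shape[0] > 1:
            D = _correlation_distance(C, X)  # 2 × test
        else:
            D = np.sqrt(((C[:, :, None] - X[:, None, :]) ** 2).sum(axis=0))
        return np.where(D[0] <= D[1], c0, c1)
    if model.method == "svm_linear":
        Z = ((X - p["mean"][:, None]) / p["sd"][:, None]).T
        return p["svm"].predict(Z).astype(object)
    raise ValueError(model.method)  # pragma: no cover


def loocv_accuracy(
    expr,
    labels: Sequence,
    method: str,
    selection_alpha: float = 1e-3,
    mode: str = "random_variance",
) -> tuple[float, pd.Series]:
    """Honest leave-one-out cross-validation accuracy.

    Gene selection AND model fitting are redone on the n−1 training samples of
    every fold; provided labels are the gold standard.  Folds that would empty
    a class are skipped with a warning.  Returns (accuracy, per-sample
    predictions).
    """
    df_expr = _as_frame(expr)
    labels = np.asarray(labels)
    n = df_expr.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for LOOCV")
    preds = pd.Series(index=df_expr.columns, dtype=object)
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        train_labels = labels[mask]
        if len(np.unique(train_labels)) < 2:
            warnings.warn(f"fold {k}: a class is empty after hold-out; fold skipped")
            continue
        model = train_classifier(
            df_expr.iloc[:, mask], train_labels, method,
            selection_alpha=selection_alpha, mode=mode,
        )
        preds.iloc[k] = predict(model, df_expr.iloc[:, [k]])[0]
    scored = preds.notna().to_numpy()
    accuracy = float(np.mean(preds.to_numpy()[scored] == labels[scored]))
    return accuracy, preds


def consensus_signature(gene_lists: Sequence[Sequence[str]]) -> list[str]:
    """Intersection of per-cohort signatures, in the first list's order."""
    if len(gene_lists) < 2:
        raise ValueError("need at least two gene lists")
    common = set(gene_lists[0])
    for lst in gene_lists[1:]:
        common &= set(lst)
    if not common:
        warnings.warn("consensus signature is empty")
    return [g for g in gene_lists[0] if g in common]


def center_by_cohort(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract per-cohort gene means: a fixed additive surrogate for the
    cross-study random effect when classifying pooled cohorts."""
    if expr.cohort is None:
        raise ValueError("expression matrix has no cohort labels")
    values = expr.values.copy()
    for cohort in expr.cohort.unique():
        cols = expr.cohort.index[expr.cohort == cohort]
        values[cols] = values[cols].sub(values[cols].mean(axis=1), axis=0)
    return ExpressionMatrix(values=values, cohort=expr.cohort)
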