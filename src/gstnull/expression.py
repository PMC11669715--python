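"""Expression-level analyses for two-group tumor cohorts.

Covers the statistics used around the GST panel: reference-gene-relative
expression, differential-expression calling under the double threshold
(|log2FC| >= 1 and BH-adjusted p <= 0.05), presence/absence partitioning,
Pearson correlation with a Fisher-z confidence interval, copy-dosage group
means, marker mutual exclusivity, and a deterministic PCA embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "DegRecord",
    "CorrelationResult",
    "ExclusivityResult",
    "relative_expression",
    "bh_adjust",
    "call_degs",
    "presence_absence",
    "pearson_with_ci",
    "dosage_analysis",
    "mutual_exclusivity",
    "pca_embed",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative expression matrix with group labels.

    ``unit`` records the scale ("FPKM", "counts" or "rel_x1000"); analyses
    that assume a particular scale document it.
    """

    values: pd.DataFrame  # genes as rows, samples as columns
    unit: str = "FPKM"
    groups: Mapping[str, str] | None = None  # sample -> group label

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")

    def samples_in_group(self, label: str) -> list[str]:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return [s for s in self.values.columns if self.groups.get(s) == label]


@dataclass(frozen=True)
class DegRecord:
    gene: str
    log2_fold_change: float
    p_value: float
    fdr: float
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ExclusivityResult:
    low_low: int
    low_high: int
    high_low: int
    high_high: int
    exclusive: bool


def relative_expression(
    matrix: ExpressionMatrix, gene: str, reference: str = "GAPDH"
) -> pd.Series:
    """Per-sample expression of ``gene`` relative to ``reference``, x1000."""
    for g in (gene, reference):
        if g not in matrix.values.index:
            raise KeyError(f"gene {g!r} not in matrix")
    ref = matrix.values.loc[reference]
    zero = ref[ref <= 0]
    if len(zero):
        raise ValueError(
            f"reference {reference!r} is zero in sample(s): {list(zero.index)}"
        )
    return 1000.0 * matrix.values.loc[gene] / ref


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    *,
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> list[DegRecord]:
    """Differential expression of group B versus group A.

    log2 fold change is ``log2((mean_B + c) / (mean_A + c))`` with
    pseudocount ``c``; the per-gene test is Welch's t on ``log2(x + c)``;
    p-values are BH-adjusted across all genes. A gene is significant only
    when BOTH |log2FC| >= ``lfc_threshold`` AND FDR <= ``fdr_threshold``.
    """
    a = matrix.samples_in_group(group_a)
    b = matrix.samples_in_group(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if matrix.values.empty:
        raise ValueError("empty gene set")
    xa = matrix.values[a].to_numpy(dtype=float)
    xb = matrix.values[b].to_numpy(dtype=float)
    c = pseudocount
    lfc = np.log2(xb.mean(axis=1) + c) - np.log2(xa.mean(axis=1) + c)
    import warnings

    with warnings.catch_warnings():
        # constant genes trigger a precision warning; their p is set to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pvals = stats.ttest_ind(
            np.log2(xb + c), np.log2(xa + c), axis=1, equal_var=False
        )
    # constant genes give nan p; treat as non-informative
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = bh_adjust(pvals)
    sig = (np.abs(lfc) >= lfc_threshold) & (fdr <= fdr_threshold)
    return [
        DegRecord(g, float(l), float(p), float(q), bool(s))
        for g, l, p, q, s in zip(matrix.values.index, lfc, pvals, fdr, sig)
    ]


def presence_absence(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    expressed_threshold: float = 1.0,
) -> dict[str, int]:
    """Four-way expressed/not-expressed partition of all genes.

    A gene counts as expressed in a group when its mean expression there
    exceeds ``expressed_threshold``. The four counts always sum to the
    number of genes.
    """
    if expressed_threshold < 0:
        raise ValueError("threshold must be >= 0")
    a = matrix.samples_in_group(group_a)
    b = matrix.samples_in_group(group_b)
    in_a = matrix.values[a].mean(axis=1) > expressed_threshold
    in_b = matrix.values[b].mean(axis=1) > expressed_threshold
    return {
        "both": int((in_a & in_b).sum()),
        "group_a_only": int((in_a & ~in_b).sum()),
        "group_b_only": int((~in_a & in_b).sum()),
        "neither": int((~in_a & ~in_b).sum()),
    }


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], *, conf: float = 0.95
) -> CorrelationResult:
    """Pearson r with Fisher-z confidence interval and two-sided t-test p.

    CI: atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3), back-transformed; the
    p-value comes from t = r sqrt(n-2) / sqrt(1-r^2) with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(r)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    half = zcrit / np.sqrt(n - 3)
    ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, ci_low=ci_low, ci_high=ci_high, p_value=p, n=n)


def dosage_analysis(
    values: Sequence[float], copy_calls: Sequence[int]
) -> tuple[dict[int, dict], dict[tuple[int, int], float]]:
    """Mean expression per copy-number group and adjacent-group fold ratios.

    Returns ``(groups, ratios)`` where ``groups[k] = {"n": ..., "mean": ...}``
    and ``ratios[(k, k+1)] = mean(copy k+1) / mean(copy k)`` for populated
    adjacent pairs with a nonzero denominator.
    """
    values = np.asarray(values, dtype=float)
    copy_calls = np.asarray(copy_calls, dtype=int)
    if values.shape != copy_calls.shape:
        raise ValueError("values and copy_calls must align")
    if values.size == 0:
        raise ValueError("no samples")
    groups = {
        int(k): {"n": int((copy_calls == k).sum()), "mean": float(values[copy_calls == k].mean())}
        for k in np.unique(copy_calls)
    }
    ratios: dict[tuple[int, int], float] = {}
    for k in sorted(groups):
        if k + 1 in groups and groups[k]["mean"] != 0:
            ratios[(k, k + 1)] = groups[k + 1]["mean"] / groups[k]["mean"]
    return groups, ratios


def mutual_exclusivity(
    matrix: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    low_threshold_a: float,
    low_threshold_b: float,
) -> ExclusivityResult:
    """Quadrant counts at per-gene 'under-expressed' thresholds.

    Two markers are mutually exclusive when no sample is low in both
    (low/low quadrant empty).
    """
    va = matrix.values.loc[gene_a]
    vb = matrix.values.loc[gene_b]
    low_a = va <= low_threshold_a
    low_b = vb <= low_threshold_b
    ll = int((low_a & low_b).sum())
    return ExclusivityResult(
        low_low=ll,
        low_high=int((low_a & ~low_b).sum()),
        high_low=int((~low_a & low_b).sum()),
        high_high=int((~low_a & ~low_b).sum()),
        exclusive=ll == 0,
    )


def pca_embed(
    matrix: ExpressionMatrix,
    n_components: int = 2,
    *,
    log_transform: bool = False,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples with a deterministic sign convention.

    Samples are observations, genes are features. Components are signed so
    that the largest-magnitude gene loading of each component is positive,
    making embeddings reproducible across linear-algebra backends. Returns
    (sample coordinates, explained-variance fractions).
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if log_transform:
        X = np.log2(X + pseudocount)
    n_samples, n_genes = X.shape
    if n_components > min(n_samples, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples)="
            f"{min(n_samples, n_genes)}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(len(s)):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    coords = U[:, :n_components] * s[:n_components]
    total_var = (s**2).sum()
    explained = (s[:n_components] ** 2 / total_var) if total_var > 0 else np.zeros(n_components)
    frame = pd.DataFrame(
        coords,
        index=matrix.values.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return frame, explained
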