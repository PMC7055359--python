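"""Bulk RNA-seq expression processing: CPM normalization, highly-expressed-gene
filtering, differential expression, and marker fold ratios.

The containers are thin wrappers around pandas DataFrames with genes as rows
and samples as columns. Differential calling uses a transparent per-gene Welch
t-test on log2(CPM+1) with Benjamini-Hochberg adjustment and a fold-change
gate; externally produced DE tables (e.g. from a negative-binomial GLM tool)
can be slotted in wherever a DE table is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "DECriteria",
    "cpm_normalize",
    "filter_highly_expressed",
    "differential_genes",
    "bh_adjust",
    "marker_fold_ratio",
]


@dataclass
class CountMatrix:
    """Raw gene x sample integer counts with a group label per sample.

    Parameters
    ----------
    counts
        DataFrame with unique gene identifiers as the index and unique sample
        identifiers as columns; entries are non-negative integers.
    groups
        Mapping (Series or dict) from sample identifier to group label
        (e.g. strain x age x cell population).
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(dict(self.groups))
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        zero = self.counts.sum(axis=0) == 0
        if zero.any():
            raise ValueError(
                f"samples with all-zero counts: {list(self.counts.columns[zero])}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def drop_unexpressed(self) -> "CountMatrix":
        """Remove genes with zero counts in every sample."""
        keep = self.counts.sum(axis=1) > 0
        return CountMatrix(self.counts.loc[keep], self.groups)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values on the CPM scale.

    ``transformed`` flags matrices carrying log2(CPM+1) values instead of raw
    CPM.
    """

    values: pd.DataFrame
    transformed: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2p1(self) -> "ExpressionMatrix":
        if self.transformed:
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), transformed=True)


@dataclass
class DECriteria:
    """Significance gates for differential calling.

    At least one of ``max_fdr`` (BH-adjusted q) and ``max_p`` (raw p) must be
    given; a gene is called differential only if its fold change exceeds
    ``min_fold_change`` (in either direction) and every supplied p/q gate is
    passed. All inequalities are strict.
    """

    max_fdr: float | None = None
    max_p: float | None = None
    min_fold_change: float = 1.5

    def __post_init__(self) -> None:
        if self.max_fdr is None and self.max_p is None:
            raise ValueError("at least one of max_fdr / max_p must be set")
        for name, val in (("max_fdr", self.max_fdr), ("max_p", self.max_p)):
            if val is not None and not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {val}")
        if self.min_fold_change <= 1.0:
            raise ValueError("min_fold_change must exceed 1")


def cpm_normalize(matrix: CountMatrix) -> ExpressionMatrix:
    """Normalize raw counts to counts-per-million per sample.

    value(g, s) = counts(g, s) / library_size(s) * 1e6, so each sample column
    sums to one million when all genes are retained.
    """
    libsize = matrix.counts.sum(axis=0)
    zero = libsize == 0
    if zero.any():
        raise ValueError(
            f"cannot CPM-normalize all-zero samples: {list(libsize.index[zero])}"
        )
    cpm = matrix.counts.astype(float).div(libsize, axis=1) * 1e6
    return ExpressionMatrix(cpm, transformed=False)


def _group_means(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    unknown = [s for s in values.columns if s not in groups.index]
    if unknown:
        raise ValueError(f"samples without a group label: {unknown}")
    return values.T.groupby(groups.loc[values.columns]).mean().T


def filter_highly_expressed(
    expr: ExpressionMatrix, groups: pd.Series, threshold: float
) -> list[str]:
    """Return the highly-expressed gene universe.

    A gene is retained iff log2(max over groups of within-group mean CPM + 1)
    strictly exceeds ``threshold`` (5 for macrophages, 4 for microglia in the
    source study's convention).
    """
    if expr.transformed:
        raise ValueError("filter operates on CPM-scale values, not log-transformed")
    if not isinstance(groups, pd.Series):
        groups = pd.Series(dict(groups))
    means = _group_means(expr.values, groups)
    score = np.log2(means.max(axis=1) + 1.0)
    return list(score.index[score > threshold])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_genes(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    universe: list[str] | None = None,
    criteria: DECriteria | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Call differential genes between two groups (``group_a`` over ``group_b``).

    Per gene: Welch t-test on log2(CPM+1) across samples, BH adjustment within
    the universe, and a fold-change gate on group-mean CPM with a pseudocount
    on both numerator and denominator. Returns a table indexed by gene with
    columns mean_cpm_a, mean_cpm_b, log2_fold_change, p, q, direction,
    significant.
    """
    if criteria is None:
        criteria = DECriteria(max_fdr=0.10)
    samples_a = [s for s, g in matrix.groups.items() if g == group_a]
    samples_b = [s for s, g in matrix.groups.items() if g == group_b]
    for name, ss in ((group_a, samples_a), (group_b, samples_b)):
        if len(ss) < 2:
            raise ValueError(f"group {name!r} has {len(ss)} samples; need >= 2")
    expr = cpm_normalize(matrix)
    if universe is not None:
        missing = set(universe) - set(matrix.gene_ids)
        if missing:
            raise ValueError(
                f"universe contains {len(missing)} genes absent from the matrix"
            )
        cpm = expr.values.loc[list(universe)]
    else:
        cpm = expr.values

    a = cpm[samples_a].to_numpy()
    b = cpm[samples_b].to_numpy()
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    # genes constant within both groups yield nan; no evidence of change
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = bh_adjust(pvals)

    fold_ok = np.power(2.0, np.abs(log2fc)) > criteria.min_fold_change
    sig = fold_ok
    if criteria.max_fdr is not None:
        sig = sig & (qvals < criteria.max_fdr)
    if criteria.max_p is not None:
        sig = sig & (pvals < criteria.max_p)

    return pd.DataFrame(
        {
            "mean_cpm_a": mean_a,
            "mean_cpm_b": mean_b,
            "log2_fold_change": log2fc,
            "p": pvals,
            "q": qvals,
            "direction": np.where(log2fc > 0, "up", "down"),
            "significant": sig,
        },
        index=cpm.index,
    )


def marker_fold_ratio(
    expr: ExpressionMatrix,
    genes: list[str],
    samples_a: list[str],
    samples_b: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene fold ratio of mean CPM between two sample populations.

    fold(g) = (mean_a(g) + pseudocount) / (mean_b(g) + pseudocount); swapping
    the populations yields the reciprocal.
    """
    if not samples_a or not samples_b:
        raise ValueError("both sample sets must be non-empty")
    if set(samples_a) & set(samples_b):
        raise ValueError("sample sets must be disjoint")
    sub = expr.values.loc[list(genes)]
    mean_a = sub[list(samples_a)].mean(axis=1)
    mean_b = sub[list(samples_b)].mean(axis=1)
    return (mean_a + pseudocount) / (mean_b + pseudocount)
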