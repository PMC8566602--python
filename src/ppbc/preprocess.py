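"""Count normalization, expression filtering, two-group differential
expression and heatmap-style hierarchical clustering.

Differential expression is a deliberately simple two-group test: Welch's t
on log2(CPM + 1) with Benjamini-Hochberg adjustment. It is not a
reimplementation of shrinkage-based count models; the pipeline downstream
needs a ranked signature and an FDR-controlled gene list, which this
provides. Fold changes are ratios of pseudocounted group-mean CPM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 1.0


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to counts per million (columns sum to 1e6)."""
    lib = counts.sum(axis=0)
    zero = lib.index[lib <= 0].tolist()
    if zero:
        raise ValueError(f"samples with zero library size: {zero}")
    return counts / lib * 1.0e6


def _two_groups(meta_or_groups) -> pd.Series:
    groups = (
        meta_or_groups["parity"] if isinstance(meta_or_groups, pd.DataFrame) else meta_or_groups
    )
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    return groups


def filter_expressed(
    counts: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    cpm_threshold: float = 0.05,
    min_samples_per_group: int = 3,
) -> pd.DataFrame:
    """Keep genes with CPM > threshold in at least ``min_samples_per_group``
    samples of *every* group; gene order is preserved."""
    groups = _two_groups(groups)
    sizes = groups.value_counts()
    small = sizes.index[sizes < min_samples_per_group].tolist()
    if small:
        raise ValueError(
            f"groups {small} have fewer than {min_samples_per_group} samples"
        )
    cpm = compute_cpm(counts)
    keep = pd.Series(True, index=counts.index)
    for level in groups.unique():
        cols = groups.index[groups == level]
        keep &= (cpm[cols] > cpm_threshold).sum(axis=1) >= min_samples_per_group
    return counts.loc[keep]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    counts: pd.DataFrame,
    groups: pd.Series | pd.DataFrame,
    contrast: tuple[str, str] = ("PPBC", "NPBC"),
) -> pd.DataFrame:
    """Two-group differential expression.

    Returns a frame indexed by gene with ``log2fc`` (test over reference
    group means on the CPM scale, pseudocount 1), Welch ``stat`` and
    two-sided ``p`` on log2(CPM+1), and BH-adjusted ``padj``. Genes with no
    variance in either group by construction (identical columns) get
    stat 0, p 1.
    """
    groups = _two_groups(groups)
    test, ref = contrast
    cols_t = groups.index[groups == test]
    cols_r = groups.index[groups == ref]
    if len(cols_t) < 2 or len(cols_r) < 2:
        raise ValueError("each group needs at least two samples")

    cpm = compute_cpm(counts)
    logcpm = np.log2(cpm + PSEUDOCOUNT)
    log2fc = np.log2(
        (cpm[cols_t].mean(axis=1) + PSEUDOCOUNT) / (cpm[cols_r].mean(axis=1) + PSEUDOCOUNT)
    )

    res = st.ttest_ind(
        logcpm[cols_t], logcpm[cols_r], axis=1, equal_var=False, nan_policy="propagate"
    )
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance, zero-difference genes: no evidence either way
    degenerate = np.isnan(stat)
    stat[degenerate] = 0.0
    p[degenerate] = 1.0
    return pd.DataFrame(
        {"log2fc": log2fc, "stat": stat, "p": p, "padj": bh_adjust(p)},
        index=counts.index,
    )


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score across columns (sample sd, ddof=1); sd=0 rows -> 0."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    z = values.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def cluster_samples(
    expr: pd.DataFrame,
    genes=None,
    zscore: bool = True,
):
    """Average-linkage Euclidean clustering of samples.

    Rows are z-scored per gene across samples (unless ``zscore=False``),
    samples are clustered on Euclidean distance with average linkage.
    Sample columns are sorted lexicographically first so that equal-height
    merges resolve deterministically. Returns ``(linkage_matrix,
    leaf_order)`` where ``leaf_order`` is the dendrogram's left-to-right
    sample IDs.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    if genes is not None:
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise KeyError(f"requested genes absent from expression: {missing[:10]}")
        expr = expr.loc[list(genes)]
    expr = expr[sorted(expr.columns)]
    mat = zscore_rows(expr) if zscore else expr
    linkage = sch.linkage(mat.to_numpy().T, method="average", metric="euclidean")
    order = [expr.columns[i] for i in sch.leaves_list(linkage)]
    return linkage, order
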