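"""T-cell receptor repertoire diversity summaries.

Given a clonotype table (sample, clonotype key, read count), computes per
sample: richness n (unique clonotypes), Shannon entropy
H = -sum_k f_k ln f_k of the clone frequencies, normalized entropy
H / ln(n), the clonality index C = 1 - H/ln(n) (0 = maximally diverse,
1 = monoclonal), the Gini index of frequency inequality, and clonal-space
occupancy — the fraction of total repertoire mass carried by clones whose
frequency falls in each of a set of bins (rare through hyperexpanded).

A single-clone repertoire has H = 0 and, by the distributional limit of
the 0/0 formula, C = 1 (normalized entropy 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: default clonal-space bins over clone frequency, right-closed
DEFAULT_BIN_EDGES = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 1.0)
DEFAULT_BIN_LABELS = ("rare", "small", "medium", "large", "hyperexpanded")


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Sum duplicate (sample, clonotype) rows; validate counts >= 1."""
    if (table["duplicate_count"] < 1).any():
        raise ValueError("clonotype counts must be >= 1")
    return (
        table.groupby(["sample_id", "clonotype_key"], sort=False)["duplicate_count"]
        .sum()
        .reset_index()
    )


def _frequencies(table: pd.DataFrame):
    for sample_id, sub in aggregate(table).groupby("sample_id", sort=True):
        counts = sub["duplicate_count"].to_numpy(dtype=float)
        yield sample_id, counts / counts.sum()


def repertoire_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, entropy, normalized entropy, clonality and Gini."""
    rows = []
    for sample_id, f in _frequencies(table):
        n = f.size
        h = float(-(f * np.log(f)).sum())
        if n >= 2:
            norm = h / np.log(n)
        else:
            norm = 0.0  # single-clone limit convention
        rows.append((sample_id, n, h, norm, 1.0 - norm, _gini(f)))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "richness", "entropy", "entropy_norm", "clonality", "gini"],
    ).set_index("sample_id")


def _gini(f: np.ndarray) -> float:
    """Gini index of frequencies via sorted cumulative sums (O(n log n)).

    Equals the mean absolute difference form
    G = sum_ij |f_i - f_j| / (2 n^2 fbar).
    """
    x = np.sort(f)
    n = x.size
    i = np.arange(1, n + 1)
    return float(2.0 * (i * x).sum() / (n * x.sum()) - (n + 1) / n)


def gini_index(table: pd.DataFrame) -> pd.Series:
    """Per-sample Gini index of clone frequencies."""
    return pd.Series(
        {sample_id: _gini(f) for sample_id, f in _frequencies(table)}, name="gini"
    ).rename_axis("sample_id")


def clonal_occupancy(
    table: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
    labels=DEFAULT_BIN_LABELS,
) -> pd.DataFrame:
    """Fraction of repertoire mass per clone-frequency bin, per sample.

    Bins are right-closed intervals (edge_i, edge_{i+1}]; the edges must be
    strictly increasing and span (0, 1].
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] != 0.0 or edges[-1] != 1.0:
        raise ValueError("bin edges must span (0, 1]")
    if labels is not None and len(labels) != edges.size - 1:
        raise ValueError("need one label per bin")
    rows = {}
    for sample_id, f in _frequencies(table):
        which = np.searchsorted(edges, f, side="left") - 1
        mass = np.bincount(which, weights=f, minlength=edges.size - 1)
        rows[sample_id] = mass
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(labels))
    return out.rename_axis("sample_id")


def summarize_repertoire(table: pd.DataFrame, bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Diversity metrics joined with clonal-space occupancy."""
    return repertoire_metrics(table).join(clonal_occupancy(table, bin_edges=bin_edges))
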