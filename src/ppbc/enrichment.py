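"""Rank-based gene set enrichment and single-sample signature scores.

The enrichment statistic is the weighted Kolmogorov-Smirnov running-sum
score: walking down a signature ranked by a per-gene statistic, member
genes ("hits") increment the running sum by |score|^p normalized over all
hit weights, non-members decrement it by 1/(N - N_hits); the enrichment
score (ES) is the signed maximum deviation. Significance comes from a
permutation null — by default resampling random gene sets of the same size
("gene_set" mode), optionally by permuting phenotype labels and
recomputing the signature. The normalized enrichment score (NES) divides
the ES by the mean |ES| of same-sign permutations.

Single-sample signature scores are the mean per-gene z-score (across
samples) over the set's member genes — the simplest reproducible
convention for composite "cell-cycle score" / "immune infiltrate score"
style summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from . import preprocess


@dataclass(frozen=True)
class GeneSet:
    """A named, unordered collection of gene symbols."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GSEAResult:
    es: float
    nes: float
    p_nominal: float
    leading_edge: list[str]
    n_hits: int
    n_perm: int


def rank_signature(scores: pd.Series) -> pd.Series:
    """Sort a gene -> score map into a descending signature.

    Ties are broken lexicographically by gene symbol so the ordering is
    total and reproducible.
    """
    if scores.index.has_duplicates:
        raise ValueError("signature has duplicate genes")
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ValueError("signature scores must be finite")
    frame = scores.rename("score").rename_axis("gene").reset_index()
    frame = frame.sort_values(["score", "gene"], ascending=[False, True])
    return pd.Series(frame["score"].to_numpy(), index=frame["gene"].to_numpy())


def enrichment_score(sig: pd.Series, gene_set: GeneSet, weight_p: float = 1.0):
    """Weighted-KS enrichment score of ``gene_set`` in the ranked signature.

    Returns ``(es, running)`` where ``running`` is the running-sum profile
    over the full ranking.
    """
    sig = rank_signature(sig)
    hits = sig.index.isin(gene_set.members)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no overlap with the signature")
    n = len(sig)
    if n_hits == n:
        raise ValueError("gene set covers the whole signature; ES undefined")
    weights = np.abs(sig.to_numpy(dtype=float)) ** weight_p
    step = np.where(hits, weights / weights[hits].sum(), -1.0 / (n - n_hits))
    running = np.cumsum(step)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_from_hit_positions(
    positions: np.ndarray, sorted_weights: np.ndarray, n: int
) -> float:
    """ES for a set given only its (sorted) hit positions in the ranking.

    O(k) per evaluation; used for the permutation null. ``sorted_weights``
    are |score|^p of the full ranking.
    """
    k = positions.size
    w = sorted_weights[positions]
    wsum = w.sum()
    if wsum <= 0:
        # all-zero hit weights: running sum only decreases between hits
        inc = np.full(k, 1.0 / k)
    else:
        inc = w / wsum
    miss = 1.0 / (n - k)
    cum_inc = np.cumsum(inc)
    j = np.arange(k)
    # value just after each hit, and just before each hit (the troughs)
    after = cum_inc - (positions - j) * miss
    before = (cum_inc - inc) - (positions - j) * miss
    hi = after.max()
    lo = before.min()
    return float(hi if hi >= -lo else lo)


def gsea(
    sig: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    perm_mode: str = "gene_set",
    seed: int = 0,
    weight_p: float = 1.0,
    expr: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
) -> GSEAResult:
    """Permutation GSEA for one gene set.

    ``perm_mode='gene_set'`` resamples random same-size gene sets from the
    signature (the default; appropriate for small cohorts).
    ``perm_mode='phenotype'`` requires ``expr`` and ``groups`` and
    recomputes the Welch-t signature under shuffled group labels.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sig = rank_signature(sig)
    es, running = enrichment_score(sig, gene_set, weight_p=weight_p)
    n = len(sig)
    hits = sig.index.isin(gene_set.members)
    k = int(hits.sum())
    rng = np.random.default_rng(seed)

    if perm_mode == "gene_set":
        weights = np.abs(sig.to_numpy(dtype=float)) ** weight_p
        es_perm = np.empty(n_perm)
        for i in range(n_perm):
            pos = np.sort(rng.choice(n, size=k, replace=False))
            es_perm[i] = _es_from_hit_positions(pos, weights, n)
    elif perm_mode == "phenotype":
        if expr is None or groups is None:
            raise ValueError("phenotype permutation requires expr and groups")
        labels = groups.loc[expr.columns]
        sizes = labels.value_counts()
        if sizes.min() < 3:
            raise ValueError(
                "phenotype permutation needs >= 3 samples per group; "
                "use perm_mode='gene_set' instead"
            )
        values = labels.to_numpy().copy()
        es_perm = np.empty(n_perm)
        for i in range(n_perm):
            rng.shuffle(values)
            shuffled = pd.Series(values, index=labels.index)
            a, b = sorted(sizes.index)
            res = st.ttest_ind(
                expr[shuffled.index[shuffled == b]],
                expr[shuffled.index[shuffled == a]],
                axis=1,
                equal_var=False,
            )
            perm_sig = pd.Series(np.nan_to_num(res.statistic), index=expr.index)
            es_perm[i], _ = enrichment_score(perm_sig, gene_set, weight_p=weight_p)
    else:
        raise ValueError(f"unknown perm_mode {perm_mode!r}")

    same_sign = es_perm > 0 if es >= 0 else es_perm < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = float("nan")
        p_nominal = float("nan")
    else:
        nes = es / np.abs(es_perm[same_sign]).mean()
        p_nominal = float((np.abs(es_perm[same_sign]) >= abs(es)).sum() / n_same)

    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = [g for g, h in zip(sig.index[: peak + 1], hits[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(sig.index[peak:], hits[peak:]) if h]
    return GSEAResult(
        es=es, nes=float(nes), p_nominal=p_nominal, leading_edge=leading,
        n_hits=k, n_perm=n_perm,
    )


def gsea_collection(
    sig: pd.Series,
    gene_sets,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Run gene_set-mode GSEA over a collection; BH FDR within each ES sign class."""
    rows = []
    for i, gs in enumerate(gene_sets):
        res = gsea(sig, gs, n_perm=n_perm, seed=seed + i, weight_p=weight_p)
        rows.append((gs.name, res.es, res.nes, res.p_nominal, res.n_hits))
    out = pd.DataFrame(rows, columns=["name", "es", "nes", "p_nominal", "n_hits"])
    out["fdr_q"] = np.nan
    for mask in (out["es"] >= 0, out["es"] < 0):
        if mask.any():
            valid = mask & out["p_nominal"].notna()
            if valid.any():
                out.loc[valid, "fdr_q"] = preprocess.bh_adjust(out.loc[valid, "p_nominal"])
    return out.set_index("name")


def signature_score(expr: pd.DataFrame, gene_set: GeneSet) -> pd.Series:
    """Mean per-gene z-score over the set's members, per sample.

    Genes are z-scored across samples (ddof=1); constant genes contribute 0.
    """
    present = [g for g in expr.index if g in gene_set.members]
    if not present:
        raise ValueError(f"no members of {gene_set.name!r} present in expression")
    z = preprocess.zscore_rows(expr.loc[present])
    return z.mean(axis=0).rename(gene_set.name)
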