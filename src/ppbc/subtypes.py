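"""Intrinsic-subtype assignment and the 21-gene recurrence score.

Subtype assignment is nearest-centroid: each sample's profile over the
50-gene intrinsic-subtype panel is correlated (Spearman, so any strictly
monotone per-sample transform of expression is irrelevant) with each of
five subtype centroids (LumA, LumB, Her2, Basal, Normal); the subtype with
the highest correlation wins, with ties broken lexicographically and
flagged.

The packaged centroid table is a SYNTHETIC stand-in over the published
50-gene panel symbols (see ``data/pam50_centroids_synthetic.tsv``): it
reproduces the qualitative structure of the published centroids (luminal
genes high in LumA/LumB, ERBB2/GRB7 in Her2, basal keratins in Basal,
proliferation genes high in LumB/Her2/Basal) but not their numeric values.
Any centroid panel with the same layout can be supplied at runtime.

The recurrence score ("pseudo" 21-gene score) normalizes each target gene
by subtracting the per-sample mean of five reference genes and adding 10,
combines the published gene-group scores

    GRB7 group  = 0.9 GRB7 + 0.1 ERBB2          (floored at 8)
    ER group    = (0.8 ESR1 + 1.2 PGR + BCL2 + SCUBE2) / 4
    prolif      = mean(MKI67, AURKA, BIRC5, CCNB1, MYBL2)  (floored at 6.5)
    invasion    = mean(MMP11, CTSV)

with the published coefficients

    RS_u = +0.47 GRB7g - 0.34 ERg + 1.04 prolif + 0.10 inv
           + 0.05 CD68 - 0.08 GSTM1 - 0.07 BAG1

and rescales RS = 20 (RS_u - 6.7), clipped to [0, 100].
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from . import preprocess

SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal")

#: continuous module scores reported next to subtype calls
PAM50_MODULES = {
    "proliferation": [
        "BIRC5", "CCNB1", "CDC20", "NUF2", "CEP55", "NDC80",
        "MKI67", "PTTG1", "RRM2", "TYMS", "UBE2C",
    ],
    "er": ["ESR1", "PGR", "FOXA1", "NAT1"],
    "her2": ["ERBB2", "GRB7"],
}

ONCOTYPE_REFERENCE_GENES = ["ACTB", "GAPDH", "GUSB", "RPLP0", "TFRC"]
ONCOTYPE_TARGET_GENES = [
    "GRB7", "ERBB2", "ESR1", "PGR", "BCL2", "SCUBE2",
    "MKI67", "AURKA", "BIRC5", "CCNB1", "MYBL2",
    "MMP11", "CTSV", "CD68", "GSTM1", "BAG1",
]
#: legacy symbols accepted in input matrices
ONCOTYPE_ALIASES = {"CTSL2": "CTSV", "STK15": "AURKA", "HER2": "ERBB2", "KI67": "MKI67"}


def load_pam50_centroids() -> pd.DataFrame:
    """Packaged synthetic centroid panel (gene x subtype)."""
    with resources.files("ppbc").joinpath("data/pam50_centroids_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def pam50_assign(
    expr: pd.DataFrame,
    centroids: pd.DataFrame | None = None,
    min_overlap: int = 40,
) -> pd.DataFrame:
    """Nearest-centroid subtype per sample by Spearman correlation.

    Returns a frame indexed by sample with ``subtype``, one correlation
    column per centroid, and ``tied`` listing any centroids tied at the
    maximum (the lexicographically first is assigned).
    """
    cents = load_pam50_centroids() if centroids is None else centroids
    shared = [g for g in cents.index if g in expr.index]
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} panel genes present (need >= {min_overlap})"
        )
    sub = expr.loc[shared]
    cent = cents.loc[shared]
    # Spearman = Pearson on within-profile ranks
    rx = sub.rank(axis=0).to_numpy()
    rc = cent.rank(axis=0).to_numpy()
    rx = (rx - rx.mean(axis=0)) / rx.std(axis=0)
    rc = (rc - rc.mean(axis=0)) / rc.std(axis=0)
    corr = pd.DataFrame(
        rx.T @ rc / len(shared), index=expr.columns, columns=cent.columns
    )
    calls, tied = [], []
    for sample in corr.index:
        row = corr.loc[sample]
        best = row.max()
        winners = sorted(row.index[np.isclose(row, best)])
        calls.append(winners[0])
        tied.append(",".join(winners) if len(winners) > 1 else "")
    out = corr.copy()
    out.insert(0, "subtype", calls)
    out["tied"] = tied
    return out


def pam50_module_scores(expr: pd.DataFrame) -> pd.DataFrame:
    """Continuous proliferation / ER / HER2 scores: mean z over module genes."""
    cols = {}
    for name, genes in PAM50_MODULES.items():
        present = [g for g in genes if g in expr.index]
        if not present:
            raise ValueError(f"no {name} module genes present")
        cols[name] = preprocess.zscore_rows(expr.loc[present]).mean(axis=0)
    return pd.DataFrame(cols, index=expr.columns)


def _resolve_aliases(expr: pd.DataFrame) -> pd.DataFrame:
    renames = {old: new for old, new in ONCOTYPE_ALIASES.items()
               if old in expr.index and new not in expr.index}
    return expr.rename(index=renames)


def oncotype_rs(expr: pd.DataFrame, scale: str = "log2") -> pd.DataFrame:
    """Recurrence score per sample from a genes x samples expression matrix.

    ``scale`` records the expression scale fed in (default log2-like
    values); the score is shift-invariant because of the reference-gene
    normalization. Returns per-sample group scores, ``rs_unscaled`` and the
    clipped ``rs``.
    """
    expr = _resolve_aliases(expr)
    needed = ONCOTYPE_TARGET_GENES + ONCOTYPE_REFERENCE_GENES
    missing = [g for g in needed if g not in expr.index]
    if missing:
        raise ValueError(f"expression matrix lacks recurrence-score genes: {missing}")

    ref_mean = expr.loc[ONCOTYPE_REFERENCE_GENES].mean(axis=0)
    norm = expr.loc[ONCOTYPE_TARGET_GENES].sub(ref_mean, axis=1) + 10.0

    grb7_group = (0.9 * norm.loc["GRB7"] + 0.1 * norm.loc["ERBB2"]).clip(lower=8.0)
    er_group = (
        0.8 * norm.loc["ESR1"] + 1.2 * norm.loc["PGR"]
        + norm.loc["BCL2"] + norm.loc["SCUBE2"]
    ) / 4.0
    prolif = norm.loc[["MKI67", "AURKA", "BIRC5", "CCNB1", "MYBL2"]].mean(axis=0).clip(lower=6.5)
    invasion = norm.loc[["MMP11", "CTSV"]].mean(axis=0)

    rs_u = (
        0.47 * grb7_group - 0.34 * er_group + 1.04 * prolif + 0.10 * invasion
        + 0.05 * norm.loc["CD68"] - 0.08 * norm.loc["GSTM1"] - 0.07 * norm.loc["BAG1"]
    )
    rs = (20.0 * (rs_u - 6.7)).clip(0.0, 100.0)
    out = pd.DataFrame(
        {
            "grb7_group": grb7_group,
            "er_group": er_group,
            "proliferation_group": prolif,
            "invasion_group": invasion,
            "cd68": norm.loc["CD68"],
            "gstm1": norm.loc["GSTM1"],
            "bag1": norm.loc["BAG1"],
            "rs_unscaled": rs_u,
            "rs": rs,
        }
    )
    out.attrs["scale"] = scale
    return out


def panel_cluster(expr: pd.DataFrame, panel) -> tuple:
    """Cluster samples on a gene panel (z-score, Euclidean, average linkage)."""
    present = [g for g in panel if g in expr.index]
    if not present:
        raise ValueError("gene panel has no overlap with expression matrix")
    return preprocess.cluster_samples(expr, genes=present)
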