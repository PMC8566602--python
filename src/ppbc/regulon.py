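"""Single-sample transcription-factor regulon activity, master-regulator
ranking, and the composite postpartum signature score.

A regulon is a transcription factor with a list of target genes, each
carrying a mode of regulation m in [-1, 1] (sign: activated vs repressed
target) and a confidence weight w in (0, 1]. Activity in a sample is a
two-tail weighted enrichment of the targets in that sample's expression
profile: genes are rank-transformed across genes to standard-normal
quantile scores z_g, and

    A = sum_t w_t * m_t * z_t / sqrt(sum_t w_t^2).

Because the transform is rank-based, activities are invariant to any
monotone per-sample rescaling of expression, and invariant to uniform
rescaling of the weights. The same weighted sum applied to a group-contrast
t-statistic signature, with a gene-label permutation null, ranks master
regulators of the contrast.

The composite postpartum score adds the immune-exhaustion and E2F1
(proliferation) activities and subtracts the TP53 and ESR1 activities:
    P = A_exhaustion + A_E2F1 - A_TP53 - A_ESR1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

DEFAULT_MIN_TARGETS = 10

#: composite-score component -> default score-table column
COMPOSITE_KEYS = {
    "exhaustion": "EXHAUSTION",
    "e2f1": "E2F1",
    "tp53": "TP53",
    "esr1": "ESR1",
}


@dataclass
class Regulon:
    """A TF and its signed, weighted target table (columns: target, mode, likelihood)."""

    tf: str
    targets: pd.DataFrame

    def __post_init__(self):
        t = self.targets
        if t["target"].duplicated().any():
            raise ValueError(f"regulon {self.tf!r} has duplicate targets")
        if (t["mode"].abs() > 1).any():
            raise ValueError(f"regulon {self.tf!r} has modes outside [-1, 1]")
        if ((t["likelihood"] <= 0) | (t["likelihood"] > 1)).any():
            raise ValueError(f"regulon {self.tf!r} has likelihoods outside (0, 1]")

    @classmethod
    def from_gene_set(cls, gene_set) -> "Regulon":
        """Treat an unsigned gene set as a regulon with m=+1, w=1 members."""
        members = sorted(gene_set.members)
        return cls(
            tf=gene_set.name,
            targets=pd.DataFrame(
                {"target": members, "mode": 1.0, "likelihood": 1.0}
            ),
        )


def rank_normal(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample rank transform of genes to standard-normal quantiles.

    Ranks are mid-ranked on ties and mapped through Phi^-1((rank - 0.5)/N).
    """
    n = expr.shape[0]
    ranks = expr.rank(axis=0, method="average")
    return pd.DataFrame(
        st.norm.ppf((ranks.to_numpy() - 0.5) / n),
        index=expr.index,
        columns=expr.columns,
    )


def _weighted_activity(values: pd.DataFrame | pd.Series, regulon: Regulon) -> pd.Series | float:
    """sum(w * m * value_target) / sqrt(sum(w^2)) over targets present in ``values``."""
    t = regulon.targets
    w = t["likelihood"].to_numpy(dtype=float)
    m = t["mode"].to_numpy(dtype=float)
    denom = np.sqrt((w**2).sum())
    sub = values.loc[t["target"].to_numpy()]
    if isinstance(sub, pd.Series):
        return float((w * m * sub.to_numpy()).sum() / denom)
    return sub.mul(w * m, axis=0).sum(axis=0) / denom


def _present(regulon: Regulon, index: pd.Index, min_targets: int) -> Regulon:
    mask = regulon.targets["target"].isin(index).to_numpy()
    if mask.sum() < min_targets:
        raise ValueError(
            f"regulon {regulon.tf!r}: only {int(mask.sum())} targets present "
            f"(floor {min_targets})"
        )
    return Regulon(tf=regulon.tf, targets=regulon.targets.loc[mask].reset_index(drop=True))


def regulon_activity(
    expr: pd.DataFrame, regulon: Regulon, min_targets: int = DEFAULT_MIN_TARGETS
) -> pd.Series:
    """Per-sample regulon activity on rank-normal quantile scores."""
    reg = _present(regulon, expr.index, min_targets)
    z = rank_normal(expr)
    return _weighted_activity(z, reg).rename(regulon.tf)


def activity_table(
    expr: pd.DataFrame, regulons, min_targets: int = DEFAULT_MIN_TARGETS
) -> pd.DataFrame:
    """Samples x TF activity matrix; rank transform computed once."""
    if not regulons:
        raise ValueError("empty regulon collection")
    z = rank_normal(expr)
    cols = {}
    for reg in regulons:
        cols[reg.tf] = _weighted_activity(z, _present(reg, expr.index, min_targets))
    return pd.DataFrame(cols, index=expr.columns)


def master_regulators(
    sig: pd.Series,
    regulons,
    n_perm: int = 1000,
    seed: int = 0,
    min_targets: int = DEFAULT_MIN_TARGETS,
) -> pd.DataFrame:
    """Rank regulons by weighted activity on a group-contrast signature.

    The signature is a gene -> t-statistic map; the p value is two-sided
    from ``n_perm`` gene-label permutations of the signature (equivalently,
    random draws of target positions), shared across regulons.
    """
    if not list(regulons):
        raise ValueError("empty regulon collection")
    rng = np.random.default_rng(seed)
    values = sig.to_numpy(dtype=float)
    rows = []
    for reg in regulons:
        sub = _present(reg, sig.index, min_targets)
        a = _weighted_activity(sig, sub)
        w = sub.targets["likelihood"].to_numpy()
        m = sub.targets["mode"].to_numpy()
        denom = np.sqrt((w**2).sum())
        k = len(sub.targets)
        idx = rng.integers(0, len(values), size=(n_perm, k))
        a_perm = (values[idx] * (w * m)).sum(axis=1) / denom
        p = float(((np.abs(a_perm) >= abs(a)).sum() + 1) / (n_perm + 1))
        rows.append((reg.tf, a, k, p))
    out = pd.DataFrame(rows, columns=["tf", "activity", "n_targets", "p"])
    return out.sort_values("activity", ascending=False).set_index("tf")


def ppbc_composite(
    scores: pd.DataFrame,
    keys: dict[str, str] | None = None,
    standardize: bool = False,
) -> pd.Series:
    """Composite postpartum score P = exhaustion + E2F1 - TP53 - ESR1.

    ``scores`` is a samples x score-name table; ``keys`` remaps the four
    component names to its columns. With ``standardize=True`` each component
    is z-scored across samples before combination.
    """
    keys = {**COMPOSITE_KEYS, **(keys or {})}
    missing = [keys[k] for k in COMPOSITE_KEYS if keys[k] not in scores.columns]
    if missing:
        raise KeyError(f"score table lacks composite components: {missing}")
    comp = scores[[keys[k] for k in ("exhaustion", "e2f1", "tp53", "esr1")]].copy()
    if standardize:
        comp = (comp - comp.mean()) / comp.std(ddof=1)
    exh, e2f1, tp53, esr1 = (comp.iloc[:, i] for i in range(4))
    return (exh + e2f1 - tp53 - esr1).rename("ppbc_composite")
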