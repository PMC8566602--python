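"""Multi-study expression cohort assembly.

Merges microarray studies from different platforms into one matrix:
probe-level values are collapsed to gene symbols by averaging, the gene
space is intersected across studies, and each gene is centered and scaled
to unit variance *within* each study before concatenation. The per-study
location-scale standardization removes additive and multiplicative batch
effects exactly (it is the no-shrinkage limit of empirical-Bayes batch
correction), at the cost of also removing genuine cross-study location
differences — adequate for rank- and split-based downstream analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class StudyExpression:
    """One study's probe-level matrix with its probe->gene map and metadata."""

    study_id: str
    values: pd.DataFrame       # probes x samples
    probe_map: pd.Series       # probe -> gene symbol
    meta: pd.DataFrame         # indexed by sample_id

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError(f"study {self.study_id!r} has duplicate probes")


def collapse_probes(study: StudyExpression) -> pd.DataFrame:
    """Average probes mapping to the same gene; drop unmapped probes."""
    genes = study.probe_map.reindex(study.values.index)
    mapped = genes.notna() & (genes.astype(str).str.len() > 0)
    if not mapped.any():
        raise ValueError(f"study {study.study_id!r}: probe map matches no probes")
    dropped = int((~mapped).sum())
    if dropped:
        log.info("study %s: dropped %d unmapped probes", study.study_id, dropped)
    collapsed = study.values.loc[mapped].groupby(genes[mapped]).mean()
    collapsed.index.name = "gene"
    return collapsed


def standardize_within(values: pd.DataFrame) -> pd.DataFrame:
    """Center and unit-scale each gene across samples; sd=0 genes -> 0."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flat = sd.index[sd == 0].tolist()
    if flat:
        log.info("flat genes set to 0 within study: %d", len(flat))
    z = values.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def merge_standardize(studies: list[StudyExpression]):
    """Collapse, intersect, standardize per study, and merge.

    Returns ``(expr, meta)``: the merged genes x samples matrix and the
    concatenated metadata with a ``study`` column.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies to merge")
    collapsed = {s.study_id: collapse_probes(s) for s in studies}
    shared = None
    for mat in collapsed.values():
        shared = mat.index if shared is None else shared.intersection(mat.index)
    if len(shared) == 0:
        raise ValueError("studies share no genes after probe collapsing")
    blocks, metas = [], []
    for s in studies:
        blocks.append(standardize_within(collapsed[s.study_id].loc[shared]))
        m = s.meta.copy()
        m["study"] = s.study_id
        metas.append(m)
    expr = pd.concat(blocks, axis=1)
    meta = pd.concat(metas, axis=0)
    return expr, meta


def filter_cohort(
    meta: pd.DataFrame,
    max_age: float = 45,
    inclusive: bool = True,
    require_outcome: bool = False,
    er_status: str | None = None,
) -> pd.DataFrame:
    """Young-women's cohort filter: age rule, outcome availability, ER status.

    ``inclusive=True`` keeps age <= max_age; ``False`` keeps age < max_age
    (both conventions appear in practice; the choice is logged). Per-study
    attrition is logged.
    """
    keep = (
        meta["age_at_diagnosis"] <= max_age
        if inclusive
        else meta["age_at_diagnosis"] < max_age
    )
    log.info("age rule: %s %s", "<=" if inclusive else "<", max_age)
    if require_outcome:
        keep &= meta["time_months"].notna() & meta["event"].notna()
    if er_status is not None:
        keep &= meta["er_status"] == er_status
    out = meta.loc[keep]
    if "study" in meta.columns:
        before = meta["study"].value_counts()
        after = out["study"].value_counts().reindex(before.index, fill_value=0)
        for study in before.index:
            log.info("study %s: %d -> %d samples", study, before[study], after[study])
    if out.empty:
        warnings.warn("cohort filter removed all samples", stacklevel=2)
    return out
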