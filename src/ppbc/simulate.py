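"""Synthetic cohort generator.

Emulates the statistical structure of a small FFPE bulk RNA-seq parity
cohort so every downstream stage (filtering, differential expression,
enrichment, regulon activity, TCR diversity, survival stratification) can
be exercised offline:

* negative-binomial counts with log-normal per-gene baselines and
  log-normal library sizes, with planted parity-group expression programs
  (cell-cycle-like and immunity/exhaustion-like genes up in the postpartum
  group; targets of an ESR1-like and a TP53-like regulon down);
* power-law (Zipf) clonotype frequency distributions, with the postpartum
  group given both more unique clones and a heavier tail, so richness is
  higher while normalized entropy is lower;
* exponential proportional-hazards survival whose log-hazard is linear in
  a supplied per-sample score, with administrative censoring.

Each artifact section (counts / clonotypes / survival) draws from its own
RNG stream derived from the master seed, so sections can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .regulon import Regulon

#: names of the two parity groups; the second one carries the planted programs
GROUPS = ("NPBC", "PPBC")

#: planted program labels -> sign of the planted log2 fold change in PPBC
_PROGRAMS = {
    "cell_cycle": +1,
    "immunity": +1,
    "exhaustion": +1,
    "esr1_targets": -1,
    "tp53_targets": -1,
}

#: heavier-tail multiplier applied to ``clone_alpha`` for the postpartum group
PPBC_TAIL_FACTOR = 1.25

#: sequencing depth of each simulated TCR repertoire (reads per sample)
READS_PER_REPERTOIRE = 5000


class SimConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the conditions the downstream recovery checks assume:
    20 samples per parity group, a planted two-fold-change-squared
    (log2FC = 2) program effect, moderately overdispersed counts
    (NB size 10), ~1e6 reads per library, Zipf clone frequencies and an
    exponential survival model with a two-fold hazard per unit score and a
    15-year (180 month) administrative censoring horizon.
    """

    n_samples_per_group: int = 20
    n_genes: int = 2000
    nb_dispersion: float = 10.0           # NB size parameter (shared across genes)
    library_size_mean: float = 1.0e6      # expected reads per library
    program_effect_log2fc: float = 2.0    # planted |log2 FC| of program genes
    n_regulons: int = 10                  # 3 planted TFs + nulls
    targets_per_regulon: int = 30
    clone_alpha: float = 1.2              # Zipf exponent, nulliparous group
    n_clones_per_group: tuple[int, int] = (150, 400)  # (NPBC, PPBC) richness
    surv_beta: float = float(np.log(2))   # log-hazard per unit composite score
    baseline_hazard: float = 0.01         # events per month at score 0
    censor_horizon_months: float = 180.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 1 or self.n_genes < 1:
            raise SimConfigError("n_samples_per_group and n_genes must be >= 1")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be > 0")
        if self.library_size_mean <= 0:
            raise SimConfigError("library_size_mean must be > 0")
        if self.clone_alpha <= 0:
            raise SimConfigError("clone_alpha must be > 0")
        if min(self.n_clones_per_group) < 1:
            raise SimConfigError("n_clones_per_group entries must be >= 1")
        if self.baseline_hazard <= 0:
            raise SimConfigError("baseline_hazard must be > 0")
        if self.censor_horizon_months < 0:
            raise SimConfigError("censor_horizon_months must be >= 0")
        if self.n_regulons < 3 or self.targets_per_regulon < 1:
            raise SimConfigError("need n_regulons >= 3 and targets_per_regulon >= 1")
        needed = (len(_PROGRAMS) + (self.n_regulons - 3)) * self.targets_per_regulon
        if self.n_genes < needed:
            raise SimConfigError(
                f"n_genes={self.n_genes} too small for "
                f"{self.n_regulons} regulons of {self.targets_per_regulon} targets "
                f"plus planted programs (need >= {needed})"
            )


@dataclass
class SimOutput:
    """Bundle of simulated artifacts plus the planted-effect truth table."""

    counts: pd.DataFrame          # genes x samples, integer
    meta: pd.DataFrame            # indexed by sample_id, column 'parity'
    gene_sets: list[GeneSet]
    regulons: list[Regulon]
    clonotypes: pd.DataFrame
    truth: pd.DataFrame           # columns: gene, program, planted_log2fc


_SECTIONS = {"counts": 0, "clones": 1, "survival": 2, "layout": 3}


def _rng(cfg: SimConfig, section: str) -> np.random.Generator:
    """One independent, reproducible stream per artifact section."""
    return np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(_SECTIONS[section],))
    )


def _sample_frame(cfg: SimConfig) -> pd.DataFrame:
    n = cfg.n_samples_per_group
    sample_ids = [f"{g}_{i + 1:03d}" for g in GROUPS for i in range(n)]
    parity = [g for g in GROUPS for _ in range(n)]
    return pd.DataFrame({"parity": parity}, index=pd.Index(sample_ids, name="sample_id"))


def _planted_layout(cfg: SimConfig):
    """Assign gene blocks to programs and regulons; returns (genes, truth, regulons, sets)."""
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    tpr = cfg.targets_per_regulon
    blocks = {}
    cursor = 0
    for program in _PROGRAMS:
        blocks[program] = genes[cursor : cursor + tpr]
        cursor += tpr

    truth = pd.DataFrame(
        [
            (g, program, sign * cfg.program_effect_log2fc)
            for program, sign in _PROGRAMS.items()
            for g in blocks[program]
        ],
        columns=["gene", "program", "planted_log2fc"],
    )

    rng = _rng(cfg, "layout")

    def _make_regulon(tf: str, targets: list[str]) -> Regulon:
        return Regulon(
            tf=tf,
            targets=pd.DataFrame(
                {
                    "target": targets,
                    "mode": np.ones(len(targets)),
                    "likelihood": rng.uniform(0.5, 1.0, size=len(targets)),
                }
            ),
        )

    regulons = [
        _make_regulon("E2F1", blocks["cell_cycle"]),
        _make_regulon("ESR1", blocks["esr1_targets"]),
        _make_regulon("TP53", blocks["tp53_targets"]),
    ]
    null_pool = genes[cursor:]
    for k in range(cfg.n_regulons - 3):
        picked = rng.choice(null_pool, size=tpr, replace=False)
        regulons.append(_make_regulon(f"TF{k + 4:02d}", list(picked)))

    gene_sets = [
        GeneSet("CELL_CYCLE", frozenset(blocks["cell_cycle"])),
        GeneSet("IMMUNITY", frozenset(blocks["immunity"])),
        GeneSet("EXHAUSTION", frozenset(blocks["exhaustion"])),
    ]
    return genes, truth, regulons, gene_sets


def simulate_cohort(cfg: SimConfig) -> SimOutput:
    """Simulate counts, metadata, gene sets, regulons and clonotypes.

    Counts are NB(mean, size=``nb_dispersion``) with per-gene baseline means
    drawn log-normal (log-mean 4, log-sd 1.5, natural log) to mimic the
    dynamic range of bulk RNA-seq, and library sizes log-normal around
    ``library_size_mean`` with CV 0.2. Planted program genes are shifted by
    ``program_effect_log2fc`` (up or down, see the truth table) in the
    postpartum group.
    """
    cfg.validate()
    genes, truth, regulons, gene_sets = _planted_layout(cfg)
    meta = _sample_frame(cfg)
    rng = _rng(cfg, "counts")

    base = rng.lognormal(mean=4.0, sigma=1.5, size=cfg.n_genes)
    sigma_lib = np.sqrt(np.log(1 + 0.2**2))
    lib = rng.lognormal(
        mean=np.log(cfg.library_size_mean) - sigma_lib**2 / 2,
        sigma=sigma_lib,
        size=len(meta),
    )

    lfc = pd.Series(0.0, index=genes)
    lfc.loc[truth["gene"].to_numpy()] = truth["planted_log2fc"].to_numpy()
    is_ppbc = (meta["parity"] == "PPBC").to_numpy()

    # expected expression per gene and sample; columns renormalized so each
    # library's expected total equals its drawn library size
    rel = base[:, None] * np.power(2.0, lfc.to_numpy()[:, None] * is_ppbc[None, :])
    mean = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]

    size = cfg.nb_dispersion
    p = size / (size + mean)
    values = rng.negative_binomial(size, p)
    counts = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=meta.index)

    meta = meta.copy()
    meta["age_at_diagnosis"] = rng.integers(25, 46, size=len(meta))
    meta["er_status"] = "positive"
    meta["study"] = "synthetic"

    clonotypes = simulate_clonotypes(cfg)
    return SimOutput(
        counts=counts,
        meta=meta,
        gene_sets=gene_sets,
        regulons=regulons,
        clonotypes=clonotypes,
        truth=truth,
    )


def simulate_clonotypes(cfg: SimConfig) -> pd.DataFrame:
    """Simulate per-sample clonotype tables from Zipf clone frequencies.

    Each sample draws ``READS_PER_REPERTOIRE`` reads from a Zipf law over its
    group's clone ranks; the postpartum group has both more clones
    (``n_clones_per_group[1]``) and a heavier tail (alpha scaled by
    ``PPBC_TAIL_FACTOR``), so its expected richness is higher and its
    normalized entropy lower.
    """
    cfg.validate()
    rng = _rng(cfg, "clones")
    meta = _sample_frame(cfg)
    rows = []
    for sample_id, parity in meta["parity"].items():
        g = GROUPS.index(parity)
        n_clones = cfg.n_clones_per_group[g]
        alpha = cfg.clone_alpha * (PPBC_TAIL_FACTOR if parity == "PPBC" else 1.0)
        probs = np.arange(1, n_clones + 1, dtype=float) ** (-alpha)
        probs /= probs.sum()
        draws = rng.multinomial(READS_PER_REPERTOIRE, probs)
        observed = np.nonzero(draws)[0]
        for rank in observed:
            rows.append((sample_id, f"TRBV{rank % 30 + 1:02d}-{sample_id}-C{rank + 1:05d}", int(draws[rank])))
    return pd.DataFrame(rows, columns=["sample_id", "clonotype_key", "duplicate_count"])


def simulate_survival(scores: pd.Series, cfg: SimConfig) -> pd.DataFrame:
    """Draw exponential survival times with hazard lambda0 * exp(beta * score).

    Returns a metadata frame (indexed by sample) with ``time_months`` and
    ``event``; times beyond ``censor_horizon_months`` are administratively
    censored at the horizon.
    """
    cfg.validate()
    if scores.index.has_duplicates:
        raise SimConfigError("scores must carry one value per sample")
    rng = _rng(cfg, "survival")
    hazard = cfg.baseline_hazard * np.exp(cfg.surv_beta * scores.to_numpy(dtype=float))
    t = rng.exponential(1.0 / hazard)
    horizon = cfg.censor_horizon_months
    event = (t <= horizon).astype(int)
    t = np.minimum(t, horizon)
    return pd.DataFrame(
        {"time_months": t, "event": event},
        index=pd.Index(scores.index, name="sample_id"),
    )


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of ``cfg`` with a different master seed."""
    return dataclasses.replace(cfg, seed=seed)
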