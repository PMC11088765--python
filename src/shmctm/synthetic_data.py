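"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the *derived* tables of a multi-cancer single-cell
study, not raw scRNA-seq: per-cancer differential-expression (DEG) tables, a
ligand->target regulatory-potential prior, fibroblast-subcluster marker
tables, and survival cohorts whose hazard depends log-linearly on a planted
signature activity.

Planted structure
-----------------
A configurable number of *planted shared upstream regulators* (URs) are DEGs
in a designated sender cell type (fibroblast) in every cancer, with a
direction of change that is concordant in exactly ``concordance_cancers``
cancers.  Each planted UR drives ``n_planted_ds_per_ur`` downstream target
genes (DSs) that are concordant DEGs in receiver cell types and carry boosted
prior weight.  Two kinds of decoy URs are engineered to fail the consensus
rules in controlled ways:

* *missing* decoys are absent from one cancer (fail the all-cancers rule);
* *sign-flip* decoys are present in all cancers but change direction in two
  of them (fail the >= `min_concordant` concordance rule at the default 4/5).

All decoy targets and background noise DEGs appear with any one sign in at
most three cancers per cell type, so with the default rules the consensus
stage recovers exactly the planted structure.

Seeding: one global seed fans out to per-table child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(counter,))`` with a fixed counter
per artifact (0 = DEG tables, 1 = prior, 2 = cohort, 3 = marker tables), so
generating one artifact never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ligand_activity import DEG_COLUMNS, RegulatoryPrior, filter_degs

__all__ = [
    "SimConfig",
    "child_rng",
    "generate_deg_tables",
    "generate_prior",
    "generate_cohort",
    "generate_mcaf_tables",
    "Cohort",
    "HORIZON_DAYS",
]

#: 10-year administrative-censoring horizon, in days.
HORIZON_DAYS = 3652

_DEFAULT_CELL_TYPES = (
    "fibroblast",
    "cancer cell",
    "macrophage",
    "endothelial",
    "pericyte",
    "T cell",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design being emulated: five cancers, six
    tumor-microenvironment cell types, planted shared-URs concordant in all
    five cancers, DEG thresholds well inside the adjusted-p < 0.05 and
    |log2FC| > 0.25 significance filter, and a cohort whose log hazard rises
    by ``beta_score`` per unit of latent signature activity.
    """

    n_cancers: int = 5
    cell_types: Sequence[str] = _DEFAULT_CELL_TYPES
    n_genes: int = 300
    n_ligands: int = 30
    n_planted_shared_urs: int = 3
    n_planted_ds_per_ur: int = 8
    concordance_cancers: int = 5
    log2fc_effect: float = 1.0
    deg_adj_p: float = 0.01
    prior_signal: float = 1.0
    cohort_n: int = 500
    beta_score: float = math.log(2.0)
    censor_rate: float = 0.2
    missing_rate: float = 0.05
    seed: int = 0
    # secondary knobs (not part of the headline design)
    n_decoy_missing: int = 1
    n_decoy_signflip: int = 1
    noise_deg_fraction: float = 0.6
    gene_noise_sd: float = 0.3
    group_shift: float = 1.0
    sender_cell_type: str = "fibroblast"

    def __post_init__(self):
        counts = {
            "n_cancers": self.n_cancers,
            "n_genes": self.n_genes,
            "n_ligands": self.n_ligands,
            "n_planted_shared_urs": self.n_planted_shared_urs,
            "n_planted_ds_per_ur": self.n_planted_ds_per_ur,
            "concordance_cancers": self.concordance_cancers,
            "cohort_n": self.cohort_n,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, v in (
            ("censor_rate", self.censor_rate),
            ("missing_rate", self.missing_rate),
            ("noise_deg_fraction", self.noise_deg_fraction),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.concordance_cancers > self.n_cancers:
            raise ValueError("concordance_cancers cannot exceed n_cancers")
        if len(self.cell_types) < 2:
            raise ValueError("need at least two cell types")
        if self.sender_cell_type not in self.cell_types:
            raise ValueError("sender_cell_type must be one of cell_types")
        n_urs = self.n_planted_shared_urs + self.n_decoy_missing + self.n_decoy_signflip
        if n_urs > self.n_ligands:
            raise ValueError("planted + decoy URs exceed n_ligands")
        needed = self.n_ligands + n_urs * self.n_planted_ds_per_ur
        if needed >= self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for ligand/target layout ({needed})"
            )

    # ---- derived layout (deterministic partition of the gene universe) ----

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def ligands(self) -> list[str]:
        return self.genes[: self.n_ligands]

    @property
    def planted_urs(self) -> list[str]:
        return self.ligands[: self.n_planted_shared_urs]

    @property
    def decoy_missing_urs(self) -> list[str]:
        a = self.n_planted_shared_urs
        return self.ligands[a : a + self.n_decoy_missing]

    @property
    def decoy_signflip_urs(self) -> list[str]:
        a = self.n_planted_shared_urs + self.n_decoy_missing
        return self.ligands[a : a + self.n_decoy_signflip]

    @property
    def background_ligands(self) -> list[str]:
        a = self.n_planted_shared_urs + self.n_decoy_missing + self.n_decoy_signflip
        return self.ligands[a:]

    @property
    def cancers(self) -> list[str]:
        return [f"cancer_{i:02d}" for i in range(1, self.n_cancers + 1)]

    def planted_targets(self, ur: str) -> list[str]:
        """Targets assigned to a planted or decoy UR (disjoint blocks)."""
        all_urs = self.planted_urs + self.decoy_missing_urs + self.decoy_signflip_urs
        i = all_urs.index(ur)
        k = self.n_planted_ds_per_ur
        start = self.n_ligands + i * k
        return self.genes[start : start + k]

    @property
    def noise_genes(self) -> list[str]:
        n_urs = self.n_planted_shared_urs + self.n_decoy_missing + self.n_decoy_signflip
        return self.genes[self.n_ligands + n_urs * self.n_planted_ds_per_ur :]

    @property
    def receiver_cell_types(self) -> list[str]:
        return [ct for ct in self.cell_types if ct != self.sender_cell_type]


def child_rng(cfg: SimConfig, counter: int) -> np.random.Generator:
    """Per-artifact RNG derived from the global seed via a fixed counter."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(counter,)))


def _magnitude(rng: np.random.Generator, effect: float) -> float:
    # |log2FC| in [effect, 1.5*effect): stays below 0.25 when effect is small
    return effect * (1.0 + 0.5 * rng.random())


def _adj_p(rng: np.random.Generator, cfg: SimConfig) -> float:
    return float(rng.uniform(1e-8, cfg.deg_adj_p))


def generate_deg_tables(cfg: SimConfig) -> dict[str, pd.DataFrame]:
    """One filtered DEG table per cancer, with planted consensus structure.

    Returns a dict cancer label -> DataFrame with columns
    ``cancer, cell_type, gene, log2fc, adj_p``; tables already satisfy the
    adj_p < 0.05 and |log2FC| > 0.25 retention filter (planted records are
    dropped by the filter when ``log2fc_effect`` puts them below 0.25).
    """
    rng = child_rng(cfg, 0)
    cancers = cfg.cancers
    receivers = cfg.receiver_cell_types
    rows: list[tuple] = []

    def emit(cancer, ct, gene, sign):
        rows.append(
            (cancer, ct, gene, sign * _magnitude(rng, cfg.log2fc_effect), _adj_p(rng, cfg))
        )

    # planted shared-URs: sender-cell DEGs in every cancer; "+" in the first
    # `concordance_cancers` cancers, "-" in the rest
    for ur in cfg.planted_urs:
        for i, cancer in enumerate(cancers):
            emit(cancer, cfg.sender_cell_type, ur, +1 if i < cfg.concordance_cancers else -1)
        for j, ds in enumerate(cfg.planted_targets(ur)):
            ct = receivers[j % len(receivers)]
            for i, cancer in enumerate(cancers):
                emit(cancer, ct, ds, +1 if i < cfg.concordance_cancers else -1)

    # missing decoys: absent from the last cancer, "+" wherever present
    for ur in cfg.decoy_missing_urs:
        present = cancers[:-1]
        for cancer in present:
            emit(cancer, cfg.sender_cell_type, ur, +1)
        for j, ds in enumerate(cfg.planted_targets(ur)):
            ct = receivers[j % len(receivers)]
            # mixed signs: at most ceil(n/2) <= 3 cancers share a sign at n<=5
            for i, cancer in enumerate(present):
                emit(cancer, ct, ds, +1 if i % 2 == 0 else -1)

    # sign-flip decoys: present everywhere, direction flipped in two cancers
    for ur in cfg.decoy_signflip_urs:
        n_flip = min(2, cfg.n_cancers - 1)
        for i, cancer in enumerate(cancers):
            emit(cancer, cfg.sender_cell_type, ur, -1 if i >= cfg.n_cancers - n_flip else +1)
        for j, ds in enumerate(cfg.planted_targets(ur)):
            ct = receivers[j % len(receivers)]
            for i, cancer in enumerate(cancers):
                emit(cancer, ct, ds, +1 if i % 2 == 0 else -1)

    # background ligands: sender DEGs in two cancers only (fail universality)
    for lig in cfg.background_ligands:
        k = min(2, cfg.n_cancers - 1)
        for ci in rng.choice(cfg.n_cancers, size=k, replace=False):
            emit(cancers[ci], cfg.sender_cell_type, lig, rng.choice([-1, 1]))

    # noise DEGs: each selected gene appears in one cell type in <= 3 cancers
    max_appear = min(3, max(1, cfg.n_cancers - 1))
    for gene in cfg.noise_genes:
        if rng.random() >= cfg.noise_deg_fraction:
            continue
        ct = cfg.cell_types[rng.integers(len(cfg.cell_types))]
        n_app = int(rng.integers(1, max_appear + 1))
        for ci in rng.choice(cfg.n_cancers, size=n_app, replace=False):
            emit(cancers[ci], ct, gene, rng.choice([-1, 1]))

    table = pd.DataFrame(rows, columns=DEG_COLUMNS)
    table = filter_degs(table)
    table = table.sort_values(["cancer", "cell_type", "gene"]).reset_index(drop=True)
    return {c: sub.reset_index(drop=True) for c, sub in table.groupby("cancer", sort=True)}


def generate_prior(cfg: SimConfig) -> RegulatoryPrior:
    """Regulatory-potential prior with boosted weight on planted ligand->target pairs.

    Background entries are Uniform(0, 0.2); planted (UR, target) entries get
    ``prior_signal`` added on top, so at ``prior_signal=0`` planted and
    background entries are identically distributed.
    """
    rng = child_rng(cfg, 1)
    w = rng.uniform(0.0, 0.2, size=(cfg.n_ligands, cfg.n_genes))
    prior = pd.DataFrame(w, index=cfg.ligands, columns=cfg.genes)
    for ur in cfg.planted_urs + cfg.decoy_missing_urs + cfg.decoy_signflip_urs:
        prior.loc[ur, cfg.planted_targets(ur)] += cfg.prior_signal
    return RegulatoryPrior(prior)


@dataclass
class Cohort:
    """Sample x feature abundance matrix joined to survival data.

    ``values`` holds log2-scale expression (or NPX) with NaN as the explicit
    missing marker; ``samples`` is indexed like ``values`` and carries group,
    survival_time (days), event (0/1) and the covariates sex,
    age_at_diagnosis, cancer_type and sampling_lag.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    COVARIATES = ("sex", "age_at_diagnosis", "cancer_type", "sampling_lag")

    def __post_init__(self):
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share the same sample index")
        if (self.samples["survival_time"] < 0).any():
            raise ValueError("negative survival time")
        if not self.samples["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    def subset(self, mask) -> "Cohort":
        return Cohort(self.values.loc[mask].copy(), self.samples.loc[mask].copy())

    def cases(self) -> "Cohort":
        return self.subset(self.samples["group"] == "case")

    @property
    def features(self) -> pd.Index:
        return self.values.columns

    def to_tsv(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="sample")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "Cohort":
        return cls(
            pd.read_csv(values_path, sep="\t", index_col="sample"),
            pd.read_csv(samples_path, sep="\t", index_col="sample"),
        )


def generate_cohort(
    cfg: SimConfig,
    signature: Sequence[str],
    assay: str = "rna",
    n_background_features: int = 30,
) -> Cohort:
    """Case/control cohort whose hazard is log-linear in a latent signature score.

    Each sample carries a latent activity s ~ N(0,1) shared by all signature
    genes (expression = gene baseline + s + case shift + N(0, gene_noise_sd)),
    so both rank-based and mean-abundance scores track the hazard
    h0 * exp(beta_score * s + covariate effects).  Survival times are
    exponential; independent censoring occurs with probability ``censor_rate``
    (at a Uniform(0, T) time) on top of administrative censoring at 10 years.
    With ``assay="protein"`` the matrix carries MCAR gaps at ``missing_rate``.

    The latent activity is stored in the sample table as ``latent_score`` for
    parameter-recovery checks.
    """
    signature = list(dict.fromkeys(signature))
    if not signature:
        raise ValueError("signature must be nonempty")
    if assay not in ("rna", "protein"):
        raise ValueError("assay must be 'rna' or 'protein'")
    rng = child_rng(cfg, 2)
    n = 2 * cfg.cohort_n
    idx = pd.Index([f"S{i:05d}" for i in range(1, n + 1)], name="sample")
    group = np.array(["case"] * cfg.cohort_n + ["control"] * cfg.cohort_n)

    s = rng.normal(0.0, 1.0, size=n)
    sex = rng.choice(["female", "male"], size=n)
    age = np.clip(rng.normal(60.0, 10.0, size=n), 30.0, 85.0)
    lag = rng.uniform(0.0, 730.0, size=n)
    cancer_type = np.where(
        group == "case",
        np.array(cfg.cancers)[rng.integers(cfg.n_cancers, size=n)],
        "control",
    )

    # exponential survival under proportional hazards; baseline median 5 years
    h0 = math.log(2.0) / (5 * 365.25)
    loghaz = cfg.beta_score * s + 0.2 * (sex == "male") + 0.02 * (age - 60.0)
    t = rng.exponential(1.0, size=n) / (h0 * np.exp(loghaz))
    event = np.ones(n, dtype=int)
    cens = rng.random(n) < cfg.censor_rate
    t = np.where(cens, rng.uniform(0.0, 1.0, size=n) * t, t)
    event[cens] = 0
    admin = t > HORIZON_DAYS
    t[admin] = HORIZON_DAYS
    event[admin] = 0

    baseline = rng.normal(0.0, 1.0, size=len(signature))
    expr = (
        baseline[None, :]
        + s[:, None]
        + cfg.group_shift * (group == "case")[:, None]
        + rng.normal(0.0, cfg.gene_noise_sd, size=(n, len(signature)))
    )
    bg_names = [f"BGP{i:03d}" for i in range(1, n_background_features + 1)]
    bg = rng.normal(0.0, 1.0, size=(n, len(bg_names)))
    values = pd.DataFrame(
        np.hstack([expr, bg]), index=idx, columns=list(signature) + bg_names
    )
    if assay == "protein":
        mask = rng.random(values.shape) < cfg.missing_rate
        values = values.mask(mask)

    samples = pd.DataFrame(
        {
            "group": group,
            "survival_time": t,
            "event": event,
            "sex": sex,
            "age_at_diagnosis": age,
            "cancer_type": cancer_type,
            "sampling_lag": lag,
            "latent_score": s,
        },
        index=idx,
    )
    return Cohort(values, samples)


def generate_mcaf_tables(
    cfg: SimConfig,
    n_markers: int = 40,
    n_top_pass: int = 8,
    top_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fibroblast-subcluster marker table plus mCAF tumor-vs-normal DEG table.

    Emulates the matrix-CAF (mCAF) marker selection inputs: the marker table
    ranks genes by log2FC between the mCAF subcluster and the other CAF
    subclusters; of its ``top_n`` genes, exactly ``n_top_pass`` also appear as
    tumor-vs-normal DEGs in mCAF (the study's rule retains those).  Marker
    genes are drawn from the tail of the noise-gene pool so they never collide
    with planted URs or DSs.
    """
    if n_top_pass > top_n:
        raise ValueError("n_top_pass cannot exceed top_n")
    pool = cfg.noise_genes
    if len(pool) < n_markers:
        raise ValueError("gene universe too small for marker table")
    rng = child_rng(cfg, 3)
    marker_genes = pool[-n_markers:]
    # decreasing marker log2FC so the top-`top_n` set is unambiguous
    lfc = np.sort(rng.uniform(0.3, 3.0, size=n_markers))[::-1]
    markers = pd.DataFrame(
        {
            "gene": marker_genes,
            "log2fc": lfc,
            "adj_p": rng.uniform(1e-8, cfg.deg_adj_p, size=n_markers),
        }
    )
    top = markers.head(top_n)["gene"].tolist()
    passing = top[:n_top_pass]
    extra = [g for g in marker_genes[top_n:] if rng.random() < 0.5]
    tumor_rows = [
        (
            "pooled",
            "mCAF",
            g,
            _magnitude(rng, cfg.log2fc_effect),
            _adj_p(rng, cfg),
        )
        for g in passing + extra
    ]
    tumor_vs_normal = pd.DataFrame(tumor_rows, columns=DEG_COLUMNS)
    return markers, tumor_vs_normal
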