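"""Ligand-activity scoring and per-cancer cell-cell interaction (CCI) inference.

For each ordered (sender, receiver) cell-type pair within one cancer, candidate
ligands are the sender's differentially expressed genes that appear in a
ligand->target regulatory-potential prior.  A ligand's *activity* for a receiver
is the Pearson correlation, across a background gene universe, between the
ligand's prior-weight vector and the 0/1 indicator of membership in the
receiver's DEG set.  Top-ranked ligands (upstream regulators, URs) are linked to
their highest-weight targets (downstream genes, DSs) among the receiver DEGs.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEG_COLUMNS",
    "CCI_COLUMNS",
    "RegulatoryPrior",
    "filter_degs",
    "ligand_activities",
    "ligand_target_links",
    "infer_cci_for_cancer",
]

#: Long-form differential-expression table schema: one row per
#: (cancer, cell type, gene), log2 fold change tumor vs normal, BH-adjusted p.
DEG_COLUMNS = ["cancer", "cell_type", "gene", "log2fc", "adj_p"]

#: Long-form CCI record schema.
CCI_COLUMNS = ["cancer", "sender", "ligand", "receiver", "target", "weight", "activity"]

#: Significance thresholds applied to DEG tables throughout the pipeline.
DEG_MAX_ADJ_P = 0.05
DEG_MIN_ABS_LOG2FC = 0.25


class RegulatoryPrior:
    """Ligand x gene matrix of nonnegative regulatory-potential weights.

    Parameters
    ----------
    weights
        DataFrame with ligand symbols as the index and gene symbols as columns.
        All entries must be finite and >= 0.
    """

    def __init__(self, weights: pd.DataFrame):
        w = weights.astype(float)
        if not np.isfinite(w.to_numpy()).all():
            raise ValueError("regulatory prior contains non-finite weights")
        if (w.to_numpy() < 0).any():
            raise ValueError("regulatory prior contains negative weights")
        if w.index.has_duplicates or w.columns.has_duplicates:
            raise ValueError("duplicate ligand or gene symbols in prior")
        self.weights = w

    @property
    def ligands(self) -> pd.Index:
        return self.weights.index

    @property
    def genes(self) -> pd.Index:
        return self.weights.columns

    def row(self, ligand: str) -> pd.Series:
        if ligand not in self.weights.index:
            raise KeyError(f"ligand {ligand!r} absent from prior")
        return self.weights.loc[ligand]

    def to_tsv(self, path) -> None:
        self.weights.to_csv(path, sep="\t", index_label="ligand")

    @classmethod
    def from_tsv(cls, path) -> "RegulatoryPrior":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegulatoryPrior({len(self.ligands)} ligands x {len(self.genes)} genes)"


def filter_degs(
    degs: pd.DataFrame,
    max_adj_p: float = DEG_MAX_ADJ_P,
    min_abs_log2fc: float = DEG_MIN_ABS_LOG2FC,
) -> pd.DataFrame:
    """Retain records with adj_p < `max_adj_p` and \\|log2fc\\| > `min_abs_log2fc`."""
    mask = (degs["adj_p"] < max_adj_p) & (degs["log2fc"].abs() > min_abs_log2fc)
    return degs.loc[mask].reset_index(drop=True)


def ligand_activities(
    prior: RegulatoryPrior,
    receiver_degs: Iterable[str],
    background: Iterable[str] | None = None,
    candidate_ligands: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Rank candidate ligands by how well prior weights predict receiver DEGs.

    Activity is the Pearson correlation, over `background` genes, between the
    ligand's prior weights and the receiver-DEG membership indicator.  Ligands
    with constant weights over the background have undefined activity and are
    reported with NaN, after all defined activities.

    Parameters
    ----------
    background
        Gene universe over which the correlation is computed; defaults to the
        prior's full gene set.  Must contain both members and non-members of
        `receiver_degs`.

    Returns
    -------
    DataFrame with columns ``ligand`` and ``activity`` sorted by descending
    activity, ties broken by ligand symbol.
    """
    bg = pd.Index(sorted(set(background))) if background is not None else prior.genes
    bg = bg.intersection(prior.genes)
    degs = set(receiver_degs) & set(bg)
    if len(bg) < 2:
        raise ValueError("background must contain at least two genes")
    if len(degs) == 0 or len(degs) == len(bg):
        raise ValueError(
            "degenerate background: receiver DEG indicator is constant "
            f"({len(degs)} of {len(bg)} background genes are DEGs)"
        )
    if candidate_ligands is None:
        cands = list(prior.ligands)
    else:
        cands = sorted(set(candidate_ligands))
        missing = set(cands) - set(prior.ligands)
        if missing:
            raise ValueError(f"candidate ligands absent from prior: {sorted(missing)}")

    W = prior.weights.loc[cands, bg].to_numpy(dtype=float)
    y = np.fromiter((g in degs for g in bg), dtype=float, count=len(bg))
    yc = y - y.mean()
    Wc = W - W.mean(axis=1, keepdims=True)
    denom = np.sqrt((Wc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        act = np.where(denom > 0, Wc @ yc / denom, np.nan)
    out = pd.DataFrame({"ligand": cands, "activity": act})
    out = out.sort_values(
        ["activity", "ligand"], ascending=[False, True], na_position="last"
    )
    return out.reset_index(drop=True)


def ligand_target_links(
    prior: RegulatoryPrior,
    ligand: str,
    receiver_degs: Iterable[str],
    top_k: int = 200,
) -> pd.DataFrame:
    """Up-to-`top_k` receiver DEGs with the highest positive prior weight.

    Ties are broken by gene symbol.  Returns a DataFrame with columns
    ``target`` and ``weight``.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    row = prior.row(ligand)
    targets = sorted(set(receiver_degs) & set(prior.genes))
    w = row.loc[targets]
    w = w[w > 0]
    order = sorted(w.index, key=lambda g: (-w[g], g))[:top_k]
    return pd.DataFrame({"target": order, "weight": w.loc[order].to_numpy()})


def infer_cci_for_cancer(
    degs: pd.DataFrame,
    prior: RegulatoryPrior,
    top_n: int = 20,
    top_k: int = 200,
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Infer weighted ligand->target links for every ordered cell-type pair.

    For each (sender, receiver) pair with sender != receiver the `top_n`
    sender-DEG ligands by activity are retained and each linked to its `top_k`
    highest-weight targets among the receiver DEGs.

    Parameters
    ----------
    degs
        Filtered DEG table for a single cancer (columns `DEG_COLUMNS`).

    Returns
    -------
    Long-form CCI DataFrame (columns `CCI_COLUMNS`).  Empty (with a warning)
    when fewer than two cell types are present.
    """
    empty = pd.DataFrame(columns=CCI_COLUMNS)
    if degs.empty:
        return empty
    cancers = degs["cancer"].unique()
    if len(cancers) != 1:
        raise ValueError("infer_cci_for_cancer expects a single-cancer DEG table")
    cancer = cancers[0]
    cell_types = sorted(degs["cell_type"].unique())
    if len(cell_types) < 2:
        warnings.warn(f"cancer {cancer!r} has fewer than two cell types; empty CCI set")
        return empty

    genes_by_ct = {
        ct: set(sub["gene"]) for ct, sub in degs.groupby("cell_type", sort=False)
    }
    rows: list[tuple] = []
    for sender in cell_types:
        cand = sorted(genes_by_ct[sender] & set(prior.ligands))
        if not cand:
            continue
        for receiver in cell_types:
            if receiver == sender:
                continue
            rdegs = genes_by_ct[receiver] & set(prior.genes)
            if not rdegs:
                continue
            try:
                acts = ligand_activities(
                    prior, rdegs, background=background, candidate_ligands=cand
                )
            except ValueError as exc:
                warnings.warn(f"skipping pair {sender}->{receiver}: {exc}")
                continue
            top = acts.dropna(subset=["activity"]).head(top_n)
            for ligand, activity in zip(top["ligand"], top["activity"]):
                links = ligand_target_links(prior, ligand, rdegs, top_k=top_k)
                for target, weight in zip(links["target"], links["weight"]):
                    rows.append(
                        (cancer, sender, ligand, receiver, target, weight, activity)
                    )
    return pd.DataFrame(rows, columns=CCI_COLUMNS)
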