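"""Signature assembly: prioritized shared-URs plus matrix-CAF markers.

Shared-URs are clustered on their per-cell-type downstream interaction counts
(Euclidean distance, agglomerative linkage, dendrogram cut into two
subclusters); the cluster dominating every downstream cell type supplies the
top shared-URs.  Matrix-CAF (mCAF) candidates are the highest-fold-change
subcluster markers that are also tumor-vs-normal DEGs in the mCAF cluster.
The two lists form the combined gene signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .ligand_activity import filter_degs
from .shared_consensus import SharedMCTM

__all__ = [
    "SignatureSet",
    "interaction_count_matrix",
    "prioritize_urs",
    "select_mcaf_markers",
    "assemble_signature",
]


@dataclass
class SignatureSet:
    """Ordered, unique signature genes with per-gene provenance."""

    genes: list[str]
    provenance: dict[str, str]  # gene -> "top_shared_ur" | "mcaf_marker"

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if set(self.provenance) != set(self.genes):
            raise ValueError("provenance must cover exactly the signature genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes:
            out[self.provenance[g]] = out.get(self.provenance[g], 0) + 1
        return out

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene": self.genes, "provenance": [self.provenance[g] for g in self.genes]}
        ).to_csv(path, sep="\t", index=False)

    def to_gmt(self, path, name: str = "signature", description: str = "") -> None:
        with open(path, "w") as fh:
            fh.write("\t".join([name, description] + self.genes) + "\n")

    @classmethod
    def from_gmt(cls, path, provenance: str = "mcaf_marker") -> "SignatureSet":
        with open(path) as fh:
            fields = fh.readline().rstrip("\n").split("\t")
        genes = [g for g in fields[2:] if g]
        return cls(genes=genes, provenance={g: provenance for g in genes})


def interaction_count_matrix(model: SharedMCTM) -> pd.DataFrame:
    """Shared-UR x downstream-cell-type matrix of shared-DS interaction counts.

    A UR qualifying in several cell types has its edge counts summed per
    downstream cell type; URs without any edge get all-zero rows.
    """
    urs = sorted(set(model.shared_urs["gene"]))
    cts = sorted(set(model.edges["target_cell_type"])) if len(model.edges) else []
    mat = pd.DataFrame(0, index=pd.Index(urs, name="ur"), columns=cts, dtype=int)
    for _, row in model.edges.iterrows():
        mat.loc[row["ur"], row["target_cell_type"]] += int(row["n_shared_ds"])
    return mat


def prioritize_urs(m: pd.DataFrame, linkage: str = "complete") -> list[str]:
    """Select the dominant shared-UR cluster from an interaction-count matrix.

    Rows are clustered under Euclidean distance and the dendrogram is cut into
    two subclusters.  The cluster whose per-cell-type mean counts are at least
    as large in every column (strictly larger in at least one) wins; when
    neither cluster dominates every column, the cluster with the greater total
    count wins (tie: the cluster containing the lexicographically smallest row
    label).  Members are returned sorted by total count descending, ties by
    symbol.
    """
    if m.shape[0] == 0:
        raise ValueError("empty interaction-count matrix")
    if (m.to_numpy() < 0).any():
        raise ValueError("interaction counts must be nonnegative")
    if m.shape[0] == 1:
        warnings.warn("single shared-UR; returning it as the trivial top set")
        return list(m.index)

    X = m.to_numpy(dtype=float)
    Z = scipy_linkage(X, method=linkage, metric="euclidean")
    labels = fcluster(Z, t=2, criterion="maxclust")
    if len(set(labels)) == 1:
        warnings.warn("degenerate clustering (all rows identical); returning all rows")
        members = list(m.index)
    else:
        means = {c: X[labels == c].mean(axis=0) for c in (1, 2)}
        totals = {c: X[labels == c].sum() for c in (1, 2)}
        if (means[1] >= means[2]).all() and (means[1] > means[2]).any():
            top = 1
        elif (means[2] >= means[1]).all() and (means[2] > means[1]).any():
            top = 2
        elif totals[1] != totals[2]:
            top = 1 if totals[1] > totals[2] else 2
        else:
            first = min(m.index)
            top = int(labels[list(m.index).index(first)])
            warnings.warn("cluster tie on total counts; picking by smallest row label")
        members = [g for g, lab in zip(m.index, labels) if lab == top]
    row_tot = m.sum(axis=1)
    return sorted(members, key=lambda g: (-row_tot[g], g))


def select_mcaf_markers(
    markers: pd.DataFrame,
    tumor_vs_normal: pd.DataFrame,
    exclude: Iterable[str] = (),
    top_n: int = 10,
) -> list[str]:
    """Apply the mCAF marker rules: top-`top_n` by marker log2FC, then DEG filter.

    Parameters
    ----------
    markers
        Marker table for the target subcluster with columns gene, log2fc,
        adj_p (log2FC vs the other CAF subclusters).
    tumor_vs_normal
        DEG table restricted to the target subcluster; the standard
        significance filter is applied before membership is checked.
    exclude
        Genes already chosen (e.g. the top shared-URs); dropped at the end.

    Rank-`top_n` ties are truncated with a symbol tie-break; output order
    follows the marker ranking.
    """
    if markers.empty:
        raise ValueError("empty marker table")
    ranked = markers.sort_values(["log2fc", "gene"], ascending=[False, True])
    top = ranked["gene"].head(top_n).tolist()
    degs = set(filter_degs(tumor_vs_normal)["gene"])
    excl = set(exclude)
    out = [g for g in top if g in degs and g not in excl]
    if not out:
        warnings.warn("no mCAF markers survive the DEG/exclusion filters")
    return out


def assemble_signature(
    top_urs: Sequence[str], mcaf_markers: Sequence[str]
) -> SignatureSet:
    """Combine prioritized shared-URs and mCAF markers into one signature.

    A gene on both lists is kept once with provenance ``top_shared_ur`` (a
    warning is emitted).
    """
    if not top_urs or not mcaf_markers:
        raise ValueError("both gene lists must be nonempty")
    genes: list[str] = []
    prov: dict[str, str] = {}
    for g in top_urs:
        if g not in prov:
            genes.append(g)
            prov[g] = "top_shared_ur"
    for g in mcaf_markers:
        if g in prov:
            warnings.warn(f"gene {g} is both a top shared-UR and an mCAF marker")
            continue
        genes.append(g)
        prov[g] = "mcaf_marker"
    return SignatureSet(genes=genes, provenance=prov)
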