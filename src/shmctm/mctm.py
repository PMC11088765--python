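"""Per-cancer multicellular tumor model (MCTM) graphs and gene-set enrichment.

An MCTM is a directed graph over cell types; the edge sender -> receiver is
weighted by the number of distinct ligand->target interactions inferred
between the pair.  The union of all URs and DSs in the graph are the MCTM
genes, which can be tested for enrichment against trait-associated gene sets
with a two-sided Fisher exact test inside a stated background universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import contingency, fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = ["MCTMGraph", "build_mctm", "fisher_enrichment", "enrich_gene_sets"]


@dataclass
class MCTMGraph:
    """Directed cell-type graph with interaction-count edge weights."""

    cancer: str
    graph: nx.DiGraph
    mctm_genes: set[str] = field(default_factory=set)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_weight(self, sender: str, receiver: str) -> int:
        return self.graph.edges[sender, receiver]["weight"]

    def to_edgelist(self) -> pd.DataFrame:
        rows = [
            (self.cancer, u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["cancer", "sender", "receiver", "weight"]).sort_values(
            ["sender", "receiver"]
        ).reset_index(drop=True)

    def to_edgelist_tsv(self, path) -> None:
        self.to_edgelist().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_mctm(cci: pd.DataFrame, cancer: str | None = None) -> MCTMGraph:
    """Aggregate a CCI record set into an MCTM graph.

    Duplicate (sender, ligand, receiver, target) rows are collapsed before
    counting, so an edge weight is the number of distinct interactions
    between the pair.  An empty CCI set yields an empty graph with a warning.
    """
    g = nx.DiGraph()
    if cci.empty:
        warnings.warn("empty CCI set; returning empty MCTM")
        return MCTMGraph(cancer=cancer or "", graph=g)
    if cancer is None:
        cancers = cci["cancer"].unique()
        if len(cancers) != 1:
            raise ValueError("CCI set spans multiple cancers; pass `cancer` explicitly")
        cancer = cancers[0]
    dedup = cci.drop_duplicates(subset=["sender", "ligand", "receiver", "target"])
    g.add_nodes_from(pd.unique(dedup[["sender", "receiver"]].to_numpy().ravel()))
    counts = dedup.groupby(["sender", "receiver"], sort=True).size()
    for (u, v), w in counts.items():
        g.add_edge(u, v, weight=int(w))
    genes = set(dedup["ligand"]) | set(dedup["target"])
    return MCTMGraph(cancer=cancer, graph=g, mctm_genes=genes)


def fisher_enrichment(
    query: Iterable[str],
    trait_genes: Iterable[str],
    background: Iterable[str],
) -> tuple[float, float]:
    """Two-sided Fisher exact test of query vs trait membership in a background.

    Trait genes outside the background are discarded before forming the 2x2
    table (in/out of query x in/out of trait).  Returns the conditional
    maximum-likelihood odds ratio and the two-sided exact p-value.
    """
    bg = set(background)
    q = set(query)
    if not q:
        raise ValueError("empty query gene set")
    if not bg:
        raise ValueError("empty background gene set")
    if not q <= bg:
        raise ValueError("query must be a subset of the background")
    t = set(trait_genes) & bg
    a = len(q & t)
    b = len(q - t)
    c = len(t - q)
    d = len(bg - q - t)
    table = [[a, b], [c, d]]
    _, p = fisher_exact(table, alternative="two-sided")
    oddsr = contingency.odds_ratio(table, kind="conditional").statistic
    return float(oddsr), float(p)


def enrich_gene_sets(
    query: Iterable[str],
    trait_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Run `fisher_enrichment` for every trait set and BH-adjust the batch.

    Returns a DataFrame with columns trait, n_overlap, odds_ratio, p, adj_p.
    """
    q = set(query)
    bg = set(background)
    rows = []
    for name in sorted(trait_sets):
        t = set(trait_sets[name]) & bg
        oddsr, p = fisher_enrichment(q, t, bg)
        rows.append((name, len(q & t), oddsr, p))
    out = pd.DataFrame(rows, columns=["trait", "n_overlap", "odds_ratio", "p"])
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["adj_p"] = []
    return out
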