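"""Cross-cancer consensus: shared upstream regulators and the shared-MCTM.

Consensus proceeds in four steps: (1) URs present in every cancer's CCI set
are kept; (2) each surviving UR must show the same direction of expression
change in the same cell type in at least ``min_concordant`` cancers (default
4 of 5); (3) targets linked to any shared-UR are screened with the identical
concordance rule to yield shared-DSs; (4) shared-URs are connected to each
downstream cell type holding at least one of their shared-DSs, the edge
weighted by the number of such shared-DSs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "SharedMCTM",
    "universal_urs",
    "direction_concordance",
    "build_shared_mctm",
]

_GENE_COLUMNS = ["gene", "cell_type", "sign", "n_concordant"]
_EDGE_COLUMNS = ["ur", "ur_cell_type", "target_cell_type", "n_shared_ds"]


@dataclass
class SharedMCTM:
    """Consensus model: concordant URs/DSs with cell types and count-weighted edges."""

    shared_urs: pd.DataFrame  # columns _GENE_COLUMNS
    shared_dss: pd.DataFrame  # columns _GENE_COLUMNS
    edges: pd.DataFrame  # columns _EDGE_COLUMNS
    cancers: list[str]
    min_concordant: int

    @property
    def ur_genes(self) -> set[str]:
        return set(self.shared_urs["gene"])

    @property
    def ds_genes(self) -> set[str]:
        return set(self.shared_dss["gene"])

    @property
    def role_overlap(self) -> set[str]:
        """Genes qualifying both as shared-UR and shared-DS (counted once in the union)."""
        return self.ur_genes & self.ds_genes

    @property
    def gene_union(self) -> set[str]:
        return self.ur_genes | self.ds_genes

    def summary(self) -> dict:
        return {
            "cancers": self.cancers,
            "min_concordant": self.min_concordant,
            "n_shared_urs": len(self.ur_genes),
            "n_shared_dss": len(self.ds_genes),
            "n_role_overlap": len(self.role_overlap),
            "n_genes": len(self.gene_union),
            "n_edges": int(len(self.edges)),
        }

    def to_files(self, genes_path, edges_path, summary_path=None) -> None:
        urs = self.shared_urs.assign(role="shared_ur")
        dss = self.shared_dss.assign(role="shared_ds")
        pd.concat([urs, dss]).to_csv(genes_path, sep="\t", index=False)
        self.edges.to_csv(edges_path, sep="\t", index=False)
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def universal_urs(cci_sets: Mapping[str, pd.DataFrame]) -> set[str]:
    """Ligands appearing as URs in every cancer's CCI set (strict intersection)."""
    if len(cci_sets) < 2:
        raise ValueError("consensus needs at least two cancers")
    sets = [set(cci["ligand"]) for cci in cci_sets.values()]
    return set.intersection(*sets)


def direction_concordance(
    gene: str,
    deg_tables: Mapping[str, pd.DataFrame],
    min_concordant: int = 4,
) -> list[tuple[str, int, int]]:
    """Cell types where `gene` changes in the same direction in enough cancers.

    For each cell type in which the gene is a DEG, cancers with positive and
    negative log2FC are tallied (a log2FC of exactly 0 counts toward neither
    sign; a cancer lacking the gene in that cell type contributes nothing).
    Cell types whose larger tally reaches ``min_concordant`` are reported as
    ``(cell_type, sign, n_concordant)`` with sign +1/-1; an exact tie between
    the tallies has no majority direction and is not reported.
    """
    if min_concordant < 2:
        raise ValueError("min_concordant must be >= 2")
    pos: dict[str, int] = {}
    neg: dict[str, int] = {}
    for table in deg_tables.values():
        sub = table.loc[table["gene"] == gene]
        for ct, lfc in zip(sub["cell_type"], sub["log2fc"]):
            if lfc > 0:
                pos[ct] = pos.get(ct, 0) + 1
            elif lfc < 0:
                neg[ct] = neg.get(ct, 0) + 1
    out = []
    for ct in sorted(set(pos) | set(neg)):
        p, n = pos.get(ct, 0), neg.get(ct, 0)
        if p == n:
            continue
        sign, count = (+1, p) if p > n else (-1, n)
        if count >= min_concordant:
            out.append((ct, sign, count))
    return out


def build_shared_mctm(
    cci_sets: Mapping[str, pd.DataFrame],
    deg_tables: Mapping[str, pd.DataFrame],
    min_concordant: int = 4,
    ds_linkage: str = "any",
    restrict_ur_cell_types_to_senders: bool = False,
) -> SharedMCTM:
    """Assemble the shared-MCTM from per-cancer CCI sets and DEG tables.

    Parameters
    ----------
    ds_linkage
        ``"any"`` (default): a target is a shared-DS candidate when linked to
        a shared-UR in at least one cancer; ``"all"``: linkage required in
        every cancer.
    restrict_ur_cell_types_to_senders
        When True, a shared-UR's qualifying cell types are limited to cell
        types in which the gene acts as a sender in at least one CCI set.

    Returns an empty model with a warning when no UR survives the rules.
    """
    if ds_linkage not in ("any", "all"):
        raise ValueError("ds_linkage must be 'any' or 'all'")
    cancers = sorted(cci_sets)
    if set(cancers) != set(deg_tables):
        raise ValueError("cci_sets and deg_tables must cover the same cancers")
    uni = universal_urs(cci_sets)

    sender_cts: dict[str, set[str]] = {}
    if restrict_ur_cell_types_to_senders:
        for cci in cci_sets.values():
            for lig, snd in zip(cci["ligand"], cci["sender"]):
                sender_cts.setdefault(lig, set()).add(snd)

    ur_rows = []
    for gene in sorted(uni):
        for ct, sign, n in direction_concordance(gene, deg_tables, min_concordant):
            if restrict_ur_cell_types_to_senders and ct not in sender_cts.get(gene, set()):
                continue
            ur_rows.append((gene, ct, sign, n))
    shared_urs = pd.DataFrame(ur_rows, columns=_GENE_COLUMNS)
    ur_genes = set(shared_urs["gene"])

    if not ur_genes:
        warnings.warn("no shared-URs survive the consensus rules; empty shared-MCTM")
        return SharedMCTM(
            shared_urs=shared_urs,
            shared_dss=pd.DataFrame(columns=_GENE_COLUMNS),
            edges=pd.DataFrame(columns=_EDGE_COLUMNS),
            cancers=cancers,
            min_concordant=min_concordant,
        )

    # step 3: targets linked to any shared-UR, per the linkage quorum
    linked_in: dict[str, set[str]] = {}
    for cancer in cancers:
        cci = cci_sets[cancer]
        hits = cci.loc[cci["ligand"].isin(ur_genes), "target"]
        for t in set(hits):
            linked_in.setdefault(t, set()).add(cancer)
    need = len(cancers) if ds_linkage == "all" else 1
    candidates = {t for t, cs in linked_in.items() if len(cs) >= need}

    ds_rows = []
    for gene in sorted(candidates):
        for ct, sign, n in direction_concordance(gene, deg_tables, min_concordant):
            ds_rows.append((gene, ct, sign, n))
    shared_dss = pd.DataFrame(ds_rows, columns=_GENE_COLUMNS)

    # step 4: shared-UR -> downstream cell-type edges weighted by shared-DS count
    ds_by_ct: dict[str, set[str]] = {}
    for gene, ct in zip(shared_dss["gene"], shared_dss["cell_type"]):
        ds_by_ct.setdefault(ct, set()).add(gene)
    links: set[tuple[str, str, str]] = set()  # (ligand, receiver, target)
    for cci in cci_sets.values():
        sub = cci.loc[cci["ligand"].isin(ur_genes)]
        links.update(zip(sub["ligand"], sub["receiver"], sub["target"]))
    edge_rows = []
    for gene, ur_ct in zip(shared_urs["gene"], shared_urs["cell_type"]):
        for tc in sorted(ds_by_ct):
            n_ds = sum(1 for d in ds_by_ct[tc] if (gene, tc, d) in links)
            if n_ds >= 1:
                edge_rows.append((gene, ur_ct, tc, n_ds))
    edges = pd.DataFrame(edge_rows, columns=_EDGE_COLUMNS)
    edges = edges.sort_values(_EDGE_COLUMNS[:3]).reset_index(drop=True)

    return SharedMCTM(
        shared_urs=shared_urs.reset_index(drop=True),
        shared_dss=shared_dss.reset_index(drop=True),
        edges=edges,
        cancers=cancers,
        min_concordant=min_concordant,
    )
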