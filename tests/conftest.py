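import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from shmctm import (
    SimConfig,
    generate_deg_tables,
    generate_prior,
    infer_cci_for_cancer,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    """Default synthetic study: 5 cancers, 3 planted shared-URs, decoys."""
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def deg_tables(sim_cfg):
    return generate_deg_tables(sim_cfg)


@pytest.fixture(scope="session")
def prior(sim_cfg):
    return generate_prior(sim_cfg)


@pytest.fixture(scope="session")
def cci_sets(sim_cfg, deg_tables, prior):
    return {
        cancer: infer_cci_for_cancer(deg_tables[cancer], prior)
        for cancer in deg_tables
    }


def random_cci_and_degs(rng: np.random.Generator, n_genes: int = 50):
    """Random toy CCI sets + DEG tables for consensus oracle checks.

    Up to `n_genes` genes, 5 cancers, 6 cell types; ligands and targets drawn
    independently per cancer so consensus membership is nontrivial.
    """
    genes = [f"g{i}" for i in range(n_genes)]
    cancers = [f"c{i}" for i in range(5)]
    cts = [f"ct{i}" for i in range(6)]
    cci_sets, deg_frames = {}, {}
    for cancer in cancers:
        n_rows = int(rng.integers(20, 80))
        rows = {
            "cancer": cancer,
            "sender": rng.choice(cts, n_rows),
            "ligand": rng.choice(genes[:20], n_rows),
            "receiver": rng.choice(cts, n_rows),
            "target": rng.choice(genes, n_rows),
            "weight": rng.uniform(0.01, 1.0, n_rows),
            "activity": rng.uniform(-1.0, 1.0, n_rows),
        }
        cci_sets[cancer] = pd.DataFrame(rows)
        n_deg = int(rng.integers(40, 120))
        deg = pd.DataFrame(
            {
                "cancer": cancer,
                "cell_type": rng.choice(cts, n_deg),
                "gene": rng.choice(genes, n_deg),
                "log2fc": rng.choice([-1.0, 1.0], n_deg) * rng.uniform(0.3, 2.0, n_deg),
                "adj_p": rng.uniform(1e-6, 0.049, n_deg),
            }
        ).drop_duplicates(subset=["cancer", "cell_type", "gene"])
        deg_frames[cancer] = deg.reset_index(drop=True)
    return cci_sets, deg_frames


def brute_force_shared_mctm(cci_sets, deg_tables, min_concordant=4, ds_linkage="any"):
    """Nested-loop reference implementation of the consensus rules."""
    cancers = sorted(cci_sets)
    ur_sets = []
    for c in cancers:
        ur_sets.append(set(cci_sets[c]["ligand"]))
    uni = set.intersection(*ur_sets)

    def concordant(gene):
        out = []
        cts = set()
        for c in cancers:
            t = deg_tables[c]
            cts |= set(t.loc[t["gene"] == gene, "cell_type"])
        for ct in sorted(cts):
            pos = neg = 0
            for c in cancers:
                t = deg_tables[c]
                sub = t[(t["gene"] == gene) & (t["cell_type"] == ct)]
                for v in sub["log2fc"]:
                    if v > 0:
                        pos += 1
                    elif v < 0:
                        neg += 1
            if pos == neg:
                continue
            sign, cnt = (1, pos) if pos > neg else (-1, neg)
            if cnt >= min_concordant:
                out.append((ct, sign, cnt))
        return out

    ur_rows = []
    for gene in sorted(uni):
        for ct, sign, cnt in concordant(gene):
            ur_rows.append((gene, ct, sign, cnt))
    ur_genes = {r[0] for r in ur_rows}

    linked = {}
    for c in cancers:
        cci = cci_sets[c]
        for lig, tgt in zip(cci["ligand"], cci["target"]):
            if lig in ur_genes:
                linked.setdefault(tgt, set()).add(c)
    need = len(cancers) if ds_linkage == "all" else 1
    ds_rows = []
    for gene in sorted(t for t, cs in linked.items() if len(cs) >= need):
        for ct, sign, cnt in concordant(gene):
            ds_rows.append((gene, ct, sign, cnt))

    ds_by_ct = {}
    for gene, ct, _, _ in ds_rows:
        ds_by_ct.setdefault(ct, set()).add(gene)
    links = set()
    for c in cancers:
        cci = cci_sets[c]
        for lig, rec, tgt in zip(cci["ligand"], cci["receiver"], cci["target"]):
            if lig in ur_genes:
                links.add((lig, rec, tgt))
    edge_rows = []
    for gene, ur_ct, _, _ in ur_rows:
        for tc in sorted(ds_by_ct):
            n = sum(1 for d in ds_by_ct[tc] if (gene, tc, d) in links)
            if n >= 1:
                edge_rows.append((gene, ur_ct, tc, n))
    return ur_rows, ds_rows, edge_rows
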