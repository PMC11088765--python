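# shmctm

Tools for deriving a **shared multicellular tumor model (shared-MCTM)** from
per-cancer cell–cell interaction inferences, prioritizing a gene signature
from it, and validating the signature's association with 10-year all-cause
mortality in survival cohorts.

## The problem

Single-cell studies of individual cancers produce, per cell type, tables of
differentially expressed genes (DEGs, tumor vs normal). Combining these with
a ligand→target *regulatory-potential* prior yields directed cell–cell
interactions (CCIs): an upstream-regulator ligand (UR) in a sender cell type
predicted to drive downstream target genes (DSs) in a receiver cell type.
The question this package addresses is whether such interactions are *shared
across cancers*, and whether a compact gene signature distilled from the
shared interactions carries prognostic information.

The pipeline, intended for computational biologists working with derived
tables rather than raw reads:

1. **Ligand activity & CCI inference** (`ligand_activity`) — per receiver
   cell type, rank candidate sender ligands by the Pearson correlation
   *r*(**w**ℓ, **1**DEG) between the ligand's prior-weight vector and the
   receiver-DEG membership indicator over a background gene universe; link
   top ligands to their highest-weight targets among the receiver DEGs.
2. **MCTM construction** (`mctm`) — per cancer, a directed cell-type graph
   whose edge weights count the distinct ligand→target interactions between
   each pair; Fisher exact enrichment of MCTM genes against trait gene sets.
3. **Cross-cancer consensus** (`shared_consensus`) — shared-URs are URs
   present in *every* cancer whose expression changes in the same direction
   in the same cell type in ≥ `min_concordant` cancers (default 4 of 5);
   shared-DSs are targets of shared-URs passing the identical rule; edges
   connect each shared-UR to downstream cell types, weighted by shared-DS
   counts.
4. **Signature prioritization** (`signature`) — hierarchical clustering
   (Euclidean distance, dendrogram cut into two) of shared-URs on their
   per-cell-type interaction counts selects the dominant cluster; matrix-CAF
   (mCAF) markers are the top-10 subcluster markers that are also
   tumor-vs-normal DEGs in mCAF; both lists merge into the signature.
5. **Cohort scoring** (`scoring`) — a rank-based single-sample gene-set
   score (weighted Kolmogorov–Smirnov random walk over within-sample gene
   ranks), a mean-NPX protein score after >20%-missingness filtering and
   KNN imputation (k = 10), mean-cutoff high/low dichotomization, and
   Wilcoxon rank-sum differential abundance.
6. **Survival validation** (`survival`) — Cox proportional-hazards models
   (Efron ties) adjusted for sex, age at diagnosis, cancer type and sampling
   lag, with follow-up truncated at 10 years; Kaplan–Meier curves and
   log-rank tests by score level × sex; per-cancer screens excluding cancers
   with < 20 death events; Benjamini–Hochberg FDR control.

A first-class synthetic-data generator (`synthetic_data`) emulates every
input — DEG tables with planted, direction-concordant shared-URs and decoys
engineered to fail the consensus rules, a prior with boosted weight on
planted ligand–target pairs, and cohorts whose hazard is log-linear in a
latent signature activity — so the full pipeline is testable end to end
without restricted data.

## Worked example

```python
from shmctm import *

cfg = SimConfig(seed=1)                      # 5 cancers, 3 planted shared-URs
degs = generate_deg_tables(cfg)
prior = generate_prior(cfg)
cci = {c: infer_cci_for_cancer(degs[c], prior) for c in degs}
shared = build_shared_mctm(cci, degs, min_concordant=4)
print(shared.summary())

counts = interaction_count_matrix(shared)
top = prioritize_urs(counts)
markers, tumor_vs_normal = generate_mcaf_tables(cfg)
signature = assemble_signature(top, select_mcaf_markers(markers, tumor_vs_normal, exclude=top))
print(len(signature), signature.counts())

cohort = generate_cohort(cfg, list(signature))
cases = truncate_followup(cohort.cases())
score = gene_set_score(cases, signature)
res = cox_association(cases, score.scores.rename("score"))
print(f"HR {res.hr:.2f} [{res.ci_low:.2f}-{res.ci_high:.2f}], "
      f"n={res.n}, events={res.n_events}, p={res.p:.2e}")
```

Output:

```
{'cancers': ['cancer_01', ..., 'cancer_05'], 'min_concordant': 4,
 'n_shared_urs': 3, 'n_shared_dss': 24, 'n_role_overlap': 0,
 'n_genes': 27, 'n_edges': 15}
11 {'top_shared_ur': 3, 'mcaf_marker': 8}
HR 3.27 [2.59-4.12], n=500, events=305, p=2.42e-23
```

The consensus stage recovers exactly the three planted shared-URs and their
24 planted targets (the decoy URs fail the all-cancers and concordance
rules); the combined signature holds the 3 prioritized URs plus 8 mCAF
markers; and the rank-based signature score is strongly associated with
mortality in the simulated cohort, as planted (hazard ratio per unit score
with its 95% CI).

## Command line

```bash
shmctm all --seed 3 --out run1          # full demo pipeline + hashed manifest
shmctm consensus --seed 3 --out run2    # stop after the consensus stage
shmctm all --config my.yaml             # parameters from a YAML config
```

Every stage writes TSV tables (schemas in `docs/formats.md`) and registers
them in `manifest.json` with SHA-256 hashes; reruns with the same seed are
byte-identical.

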