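# File formats

All tables are tab-separated with a header row; gene sets are GMT;
configuration is YAML. Missing values use empty fields (read as NaN).

## DEG table (`deg_<cancer>.tsv`)

One row per (cancer, cell type, gene); retained records satisfy
adj_p < 0.05 and |log2fc| > 0.25.

| column    | type  | meaning                                   |
|-----------|-------|-------------------------------------------|
| cancer    | str   | cancer label                              |
| cell_type | str   | annotated cell type                       |
| gene      | str   | gene symbol                               |
| log2fc    | float | tumor vs normal log2 fold change          |
| adj_p     | float | adjusted p-value                          |

## Regulatory prior (`prior.tsv`)

Matrix TSV: first column `ligand` (row labels), remaining columns gene
symbols; entries are nonnegative regulatory-potential weights.

## CCI set (`cci_<cancer>.tsv`)

Long-form records: `cancer, sender, ligand, receiver, target, weight,
activity`. `weight` is the prior weight of the ligand→target link;
`activity` is the ligand's Pearson activity for the (sender, receiver) pair.

## MCTM edge list (`mctm_<cancer>.tsv`)

`cancer, sender, receiver, weight` — weight is the distinct-interaction
count between the cell-type pair.

## Shared-MCTM (`shared_mctm_genes.tsv`, `shared_mctm_edges.tsv`, `shared_mctm_summary.json`)

Genes: `gene, cell_type, sign, n_concordant, role` with role
`shared_ur` / `shared_ds`. Edges: `ur, ur_cell_type, target_cell_type,
n_shared_ds`. The JSON summary holds counts and the parameters used.

## Signature (`signature.tsv`, `signature.gmt`)

TSV: `gene, provenance` (`top_shared_ur` or `mcaf_marker`). GMT: one line,
`name <tab> description <tab> gene...`.

## Cohort (`*_values.tsv` + `*_samples.tsv`)

Values: samples × features matrix, first column `sample`. Samples table:
`sample, group (case|control), survival_time (days), event (0|1), sex,
age_at_diagnosis, cancer_type, sampling_lag` (plus `latent_score` in
synthetic cohorts).

## Scores (`rna_scores.tsv`, `protein_scores.tsv`)

`sample, score, level (high|low), cutoff` — level is high iff score exceeds
the cohort mean, which is stored in `cutoff`.

## Survival results (`survival_results.tsv`)

One row per (exposure, stratum): `name, stratum, hr, ci_low, ci_high, p,
n, n_events, adj_p, flag`; `flag` is `ok`, `skipped:<reason>` or
`failed:<reason>`. KM curves (`km_curves.tsv`): `time, survival, arm`.

## Pipeline config (YAML)

Top-level keys mirror `PipelineConfig`: `seed`, `outdir`, `stages`,
`sim` (SimConfig fields; set to null to read inputs from `deg_dir` /
`prior_path`), `min_concordant`, `top_n`, `top_k`, `linkage`,
`max_missing`, `knn_k`, `horizon_days`, `min_events`. Unknown keys are
rejected.
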