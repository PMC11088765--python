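"""End-to-end orchestration: simulate -> infer -> mctm -> consensus ->
signature -> score -> survive, from a single configuration.

Each stage writes its tables under the output directory and registers them in
a manifest with SHA-256 content hashes, so a rerun with the same
configuration and seed is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

from . import io as shio
from .ligand_activity import RegulatoryPrior, infer_cci_for_cancer, CCI_COLUMNS
from .mctm import build_mctm
from .scoring import differential_abundance, gene_set_score, protein_score, qc_and_impute
from .shared_consensus import build_shared_mctm
from .signature import (
    SignatureSet,
    assemble_signature,
    interaction_count_matrix,
    prioritize_urs,
    select_mcaf_markers,
)
from .survival import cox_association, km_logrank, per_cancer_screen, results_to_frame, truncate_followup
from .synthetic_data import Cohort, SimConfig, generate_cohort, generate_deg_tables, generate_mcaf_tables, generate_prior

log = logging.getLogger("shmctm")

STAGES = ("simulate", "infer", "mctm", "consensus", "signature", "score", "survive")


@dataclass
class PipelineConfig:
    """Single configuration for every stage (see docs/formats.md)."""

    seed: int = 0
    outdir: str = "shmctm_out"
    stages: tuple[str, ...] = STAGES
    # simulation block (None -> inputs must be provided on disk)
    sim: dict | None = field(default_factory=dict)
    # input paths used when simulation is off
    deg_dir: str | None = None
    prior_path: str | None = None
    # stage parameters
    min_concordant: int = 4
    top_n: int = 20
    top_k: int = 200
    linkage: str = "complete"
    max_missing: float = 0.20
    knn_k: int = 10
    horizon_days: int = 3652
    min_events: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = shio.load_config(path)
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        params = dict(self.sim or {})
        params.setdefault("seed", self.seed)
        if "cell_types" in params:
            params["cell_types"] = tuple(params["cell_types"])
        return SimConfig(**params)

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if self.sim is None:
            for name, p in (("deg_dir", self.deg_dir), ("prior_path", self.prior_path)):
                if p is None:
                    raise ValueError(f"simulation off but {name} not set")
                if not Path(p).exists():
                    raise ValueError(f"{name} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, cfg: PipelineConfig):
        cfg.validate()
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, dict] = {}
        self.deg_tables: dict[str, pd.DataFrame] = {}
        self.prior: RegulatoryPrior | None = None
        self.cci_sets: dict[str, pd.DataFrame] = {}
        self.shared = None
        self.signature: SignatureSet | None = None
        self.rna: Cohort | None = None
        self.protein: Cohort | None = None
        self.rna_score = None
        self.protein_score = None

    def _register(self, stage: str, path: Path) -> None:
        self.manifest[str(path.relative_to(self.outdir))] = {
            "stage": stage,
            "sha256": _sha256(path),
        }

    # ---- stages -------------------------------------------------------

    def simulate(self) -> None:
        sim = self.cfg.sim_config()
        self.deg_tables = generate_deg_tables(sim)
        self.prior = generate_prior(sim)
        for p in shio.write_deg_tables(self.deg_tables, self.outdir / "deg"):
            self._register("simulate", p)
        prior_path = self.outdir / "prior.tsv"
        self.prior.to_tsv(prior_path)
        self._register("simulate", prior_path)

    def _load_inputs(self) -> None:
        if not self.deg_tables:
            self.deg_tables = shio.read_deg_tables(self.cfg.deg_dir)
        if self.prior is None:
            self.prior = RegulatoryPrior.from_tsv(self.cfg.prior_path)

    def infer(self) -> None:
        self._load_inputs()
        for cancer in sorted(self.deg_tables):
            cci = infer_cci_for_cancer(
                self.deg_tables[cancer],
                self.prior,
                top_n=self.cfg.top_n,
                top_k=self.cfg.top_k,
            )
            self.cci_sets[cancer] = cci
            p = self.outdir / f"cci_{cancer}.tsv"
            cci.to_csv(p, sep="\t", index=False)
            self._register("infer", p)

    def mctm(self) -> None:
        for cancer, cci in self.cci_sets.items():
            if cci.empty:
                continue
            graph = build_mctm(cci, cancer=cancer)
            p = self.outdir / f"mctm_{cancer}.tsv"
            graph.to_edgelist_tsv(p)
            self._register("mctm", p)

    def consensus(self) -> None:
        self.shared = build_shared_mctm(
            self.cci_sets, self.deg_tables, min_concordant=self.cfg.min_concordant
        )
        genes_p = self.outdir / "shared_mctm_genes.tsv"
        edges_p = self.outdir / "shared_mctm_edges.tsv"
        summary_p = self.outdir / "shared_mctm_summary.json"
        self.shared.to_files(genes_p, edges_p, summary_p)
        for p in (genes_p, edges_p, summary_p):
            self._register("consensus", p)

    def signature_stage(self) -> None:
        if self.shared is None or self.shared.shared_urs.empty:
            raise RuntimeError("consensus produced no shared-URs; cannot build signature")
        counts = interaction_count_matrix(self.shared)
        top = prioritize_urs(counts, linkage=self.cfg.linkage)
        markers, tvn = generate_mcaf_tables(self.cfg.sim_config())
        mcaf = select_mcaf_markers(markers, tvn, exclude=top)
        self.signature = assemble_signature(top, mcaf)
        sig_tsv = self.outdir / "signature.tsv"
        sig_gmt = self.outdir / "signature.gmt"
        self.signature.to_tsv(sig_tsv)
        self.signature.to_gmt(sig_gmt)
        counts_p = self.outdir / "ur_interaction_counts.tsv"
        counts.to_csv(counts_p, sep="\t")
        for p in (sig_tsv, sig_gmt, counts_p):
            self._register("signature", p)

    def score(self) -> None:
        if self.signature is None:
            raise RuntimeError("signature stage has not run")
        sim = self.cfg.sim_config()
        self.rna = generate_cohort(sim, list(self.signature), assay="rna")
        self.protein = qc_and_impute(
            generate_cohort(sim, list(self.signature), assay="protein"),
            max_missing=self.cfg.max_missing,
            k=self.cfg.knn_k,
        )
        self.rna_score = gene_set_score(self.rna, self.signature)
        self.protein_score = protein_score(self.protein, self.signature)
        de = differential_abundance(self.rna, features=list(self.signature))
        for name, obj in (
            ("rna_scores.tsv", self.rna_score),
            ("protein_scores.tsv", self.protein_score),
        ):
            p = self.outdir / name
            obj.to_tsv(p)
            self._register("score", p)
        de_p = self.outdir / "signature_de.tsv"
        de.to_csv(de_p, sep="\t", index=False)
        self._register("score", de_p)

    def survive(self) -> None:
        if self.rna is None or self.rna_score is None:
            raise RuntimeError("score stage has not run")
        cases = truncate_followup(self.rna.cases(), self.cfg.horizon_days)
        score = self.rna_score.scores.loc[cases.samples.index].rename("rna_score")
        pooled = cox_association(cases, score)
        per_cancer = per_cancer_screen(cases, score, min_events=self.cfg.min_events)
        levels = self.rna_score.levels.loc[cases.samples.index]
        curves, chi2, logrank_p = km_logrank(cases, levels, group2="sex")
        res = results_to_frame([pooled] + per_cancer)
        res_p = self.outdir / "survival_results.tsv"
        res.to_csv(res_p, sep="\t", index=False)
        self._register("survive", res_p)
        km_p = self.outdir / "km_curves.tsv"
        pd.concat(
            [c.assign(arm=a) for a, c in curves.items()], ignore_index=True
        ).to_csv(km_p, sep="\t", index=False)
        self._register("survive", km_p)
        lr_p = self.outdir / "logrank.json"
        lr_p.write_text(json.dumps({"chi2": chi2, "p": logrank_p}, indent=2))
        self._register("survive", lr_p)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    A stage failure raises immediately with the stage name in the message;
    downstream stages do not run.
    """
    run = PipelineRun(cfg)
    dispatch = {
        "simulate": run.simulate,
        "infer": run.infer,
        "mctm": run.mctm,
        "consensus": run.consensus,
        "signature": run.signature_stage,
        "score": run.score,
        "survive": run.survive,
    }
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        if stage == "simulate" and cfg.sim is None:
            continue  # inputs come from disk
        log.info("stage %s", stage)
        try:
            dispatch[stage]()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "seed": cfg.seed,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if k not in ("sim",)
        },
        "outputs": run.manifest,
    }
    manifest_p = run.outdir / "manifest.json"
    manifest_p.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
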