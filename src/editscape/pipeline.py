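"""Config-driven orchestration of the full analysis on one run directory.

The pipeline chains: simulate (or load) inputs → event QC → annotation →
re-coding peptide database → TAMPOR batch correction → per-dataset
diagnosis GLMs → two-stage meta-analysis → cis-effect classification →
top-event PCA.  No stage mutates its inputs; every artifact lands in the
run directory and a JSON manifest records the seed, per-stage row counts
and SHA-256 checksums of the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from editscape import io as eio
from editscape.association import (
    DiagnosisModel,
    TwoStageMeta,
    bonferroni_threshold,
    cis_effect,
    top_event_pcs,
)
from editscape.design import SimulationDesign
from editscape.events import annotate_sites, qc_filter, subject_summaries
from editscape.recoding import (
    build_edited_peptide_db,
    coding_effect,
    enumerate_proteoforms,
    peptide_db_fasta,
)
from editscape.simulate import generate_calls, generate_peptide_matrix, generate_reference
from editscape.tampor import Tampor, cull_missing

log = logging.getLogger("editscape")

#: dataset-specific covariate sets, mirroring a ROSMAP/MSBB/MAYO-style cohort
DEFAULT_COVARIATES = {
    "ds1": ["sex", "age", "pmi", "rin", "batch", "study"],
    "ds2": ["sex", "age", "pmi", "rin", "batch", "race"],
    "ds3": ["sex", "age", "pmi", "rin", "tissue_source"],
    "ds4": ["sex", "age", "pmi", "rin", "batch"],
}


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run."""

    design: SimulationDesign = field(default_factory=SimulationDesign)
    min_total: int = 20
    min_alt: int = 5
    min_frequency: float = 0.10
    max_missed: int = 2
    min_peptide_length: int = 6
    max_sites_per_transcript: int = 16
    tampor_tol: float = 1e-8
    tampor_max_iter: int = 250
    suggestive_p: float = 1e-3
    n_top_pcs: int = 7
    covariates: dict[str, list[str]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        design = SimulationDesign(**raw.pop("design", {}))
        if "design" in raw:
            raise ValueError("duplicate design section")
        cfg = cls(design=design, **raw)
        if cfg.min_total < 1 or cfg.min_alt < 0 or not 0 <= cfg.min_frequency <= 1:
            raise ValueError("QC thresholds out of range")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic cohort and write all tables + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "seed": config.design.seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %-10s %s", stage, counts)

    # --- simulate -----------------------------------------------------
    design = config.design
    ref = generate_reference(design)
    callset = generate_calls(design, ref)
    eio.write_fasta(ref.genome, outdir / "genome.fasta")
    eio.write_models_tsv(ref.models, outdir / "models.tsv")
    eio.write_bed(ref.known_variants, outdir / "known_variants.bed", "variant")
    eio.write_bed(ref.reported_sites, outdir / "reported_sites.bed", "reported")
    eio.write_calls_tsv(callset.calls, outdir / "calls.tsv")
    eio.write_phenotypes_tsv(callset.phenotypes, outdir / "phenotypes.tsv")
    callset.truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    record("simulate", n_sites=len(ref.sites), n_calls=len(callset.calls),
           n_subjects=len(callset.phenotypes))

    # --- QC per dataset ----------------------------------------------
    qc_sites = {}
    levels_by_dataset = {}
    audit_lines = []
    first_region = design.region_names[0]
    for ds in design.dataset_names:
        sub = callset.calls[
            (callset.calls["dataset"] == ds)
            & (callset.calls["region"] == first_region)
        ]
        res = qc_filter(sub, ref.known_variants, config.min_total,
                        config.min_alt, config.min_frequency)
        qc_sites[ds] = res
        audit_lines.append(f"[{ds}] " + json.dumps(res.audit))
        passing = res.call_flags[res.call_flags["passes"]]
        passing = passing[passing["site_id"].isin(res.sites["site_id"])]
        levels_by_dataset[ds] = passing.pivot_table(
            index="subject_id", columns="site_id", values="level"
        )
    (outdir / "qc_audit.log").write_text("\n".join(audit_lines) + "\n", encoding="utf-8")
    subject_summaries(
        qc_sites[design.dataset_names[0]].call_flags
    ).to_csv(outdir / "subject_summaries.tsv", sep="\t", index=False)
    record("qc", **{f"sites_pass_{ds}": len(r.sites) for ds, r in qc_sites.items()})

    # --- annotation ---------------------------------------------------
    ds1 = design.dataset_names[0]
    annotated = annotate_sites(qc_sites[ds1].sites, ref.models, ref.reported_sites)
    annotated.to_csv(outdir / "annotated_sites.tsv", sep="\t", index=False)
    record("annotate", n_annotated=len(annotated),
           n_exonic=int((annotated["region_annotation"] == "exonic").sum()))

    # --- re-coding peptide database ----------------------------------
    model_of = {m.chrom: m for m in ref.models}
    recoding_by_tx: dict[str, list[tuple[str, int, str]]] = {}
    n_recoding = 0
    for _, row in annotated.iterrows():
        model = model_of.get(row["chrom"])
        if model is None or not model.in_cds(int(row["pos"])):
            continue
        eff = coding_effect(row["chrom"], int(row["pos"]), row["alt"], model, ref.genome)
        if eff.kind == "recoding":
            recoding_by_tx.setdefault(model.transcript_id, []).append(
                (row["site_id"], int(row["pos"]), row["alt"])
            )
            n_recoding += 1
    proteome = ref.unedited_proteome()
    proteoforms = []
    for m in ref.models:
        sites = recoding_by_tx.get(m.transcript_id, [])
        if sites:
            proteoforms += enumerate_proteoforms(
                m, ref.genome, sites, config.max_sites_per_transcript
            )
    db = build_edited_peptide_db(
        proteoforms, proteome,
        max_missed=config.max_missed, min_length=config.min_peptide_length,
    )
    (outdir / "edited_peptides.fasta").write_text(peptide_db_fasta(db), encoding="utf-8")
    record("recode", n_recoding_sites=n_recoding, n_proteoforms=len(proteoforms),
           n_edited_peptides=len(db))

    # --- TAMPOR -------------------------------------------------------
    pep_ids = [(r.sequence, True) for r in db[:20]]
    pep_ids += [(f"background_{i}", False) for i in range(max(40, 2 * len(pep_ids)))]
    matrix, _truth = generate_peptide_matrix(design, pep_ids)
    culled, cull_report = cull_missing(matrix)
    tampor_res = Tampor(culled, tol=config.tampor_tol,
                        max_iter=config.tampor_max_iter).fit()
    eio.write_abundance_tsv(tampor_res.corrected, outdir / "abundance_corrected.tsv")
    (outdir / "tampor_trace.log").write_text(
        "\n".join(f"iter {i + 1}: max rel change {d:.3e}"
                  for i, d in enumerate(tampor_res.trace)) + "\n",
        encoding="utf-8",
    )
    record("tampor", converged=tampor_res.converged, n_iter=tampor_res.n_iter,
           **cull_report)

    # --- per-dataset diagnosis GLMs + two-stage meta ------------------
    per_ds = []
    pheno_idx = callset.phenotypes.set_index("subject_id")
    for d_i, ds in enumerate(design.dataset_names):
        lv = levels_by_dataset[ds]
        model = DiagnosisModel(
            lv, pheno_idx.loc[lv.index],
            covariates=[c for c in config.covariates.get(ds, [])
                        if c in pheno_idx.columns],
            dataset=ds, allowed_diagnosis=design.diagnosis_codes(d_i),
        )
        res = model.fit()
        res.table.to_csv(outdir / f"assoc_{ds}.tsv", sep="\t", index=False)
        per_ds.append(res)
    meta = TwoStageMeta(per_ds[0], per_ds, suggestive_p=config.suggestive_p).fit()
    meta.table.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    record("assoc", n_stage1=meta.n_stage1, n_suggestive=meta.n_suggestive,
           n_meta=len(meta.table),
           inflation_lambda=round(meta.inflation_lambda, 4)
           if len(meta.table) else None)

    # --- cis effects on synthetic expression --------------------------
    lv1 = levels_by_dataset[ds1]
    status = (lv1 >= 0.10).astype(float)
    rng = np.random.default_rng([design.seed, 3])
    expr = pd.DataFrame(
        rng.normal(0, 1, (len(lv1), len(lv1.columns))),
        index=lv1.index, columns=[f"expr_{s}" for s in lv1.columns],
    )
    pairs = [(s, f"expr_{s}") for s in lv1.columns]
    cis = cis_effect(status, expr, pheno_idx.loc[lv1.index], pairs,
                     covariates=["sex", "age"],
                     genome_wide=bonferroni_threshold(len(pairs)))
    cis.table.to_csv(outdir / "cis.tsv", sep="\t", index=False)
    record("cis", n_tested=len(cis.table), n_skipped=len(cis.skipped_sites))

    # --- PCA of top events --------------------------------------------
    k = min(config.n_top_pcs, lv1.shape[1])
    top = per_ds[0].table.nsmallest(k, "p")["site_id"]
    lv_top = lv1[list(top)].dropna()
    pca = top_event_pcs(lv_top, k=k)
    pca.scores.to_csv(outdir / "top_event_pcs.tsv", sep="\t")
    record("pcs", k=k, var_pc1=round(float(pca.explained_variance_ratio[0]), 4))

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
    )
    return manifest
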