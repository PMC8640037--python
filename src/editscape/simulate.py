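"""Synthetic editing-atlas inputs with known ground truth.

Everything the pipeline consumes can be generated here: a toy genome whose
transcripts carry 5′UTR / CDS exons / intron / 3′UTR structure on both
strands, per-sample editing-call tables whose alternative-read counts are
binomial draws from per-site true editing levels (with planted regional
and diagnosis effects), a phenotype table with dataset-specific covariate
conventions, and a batch-structured TMT peptide matrix with GIS channels
and multiplicative batch effects.  Ground-truth tables emitted alongside
make every downstream estimator scoreable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from editscape.design import SimulationDesign
from editscape.recoding import COMPLEMENT, TranscriptModel
from editscape.tampor import AbundanceMatrix

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# per-transcript layout (bases); CDS totals 240 nt = 79 codons + stop
_FLANK = 1500
_UTR5 = 60
_CDS1 = 90
_INTRON = 200
_CDS2 = 150
_UTR3 = 80


@dataclass
class Reference:
    """Toy genome, gene models and annotation resources, with site truth.

    ``sites`` is the ground-truth site table: one row per planted editing
    site with its genomic substitution, containing transcript, CDS
    membership, reported / known-variant status and planted-effect flags.
    """

    genome: dict[str, str]
    models: list[TranscriptModel]
    known_variants: set[tuple[str, int]]
    reported_sites: set[tuple[str, int]]
    sites: pd.DataFrame

    def unedited_proteome(self) -> dict[str, str]:
        """Translated coding sequences of all coding transcripts."""
        out = {}
        for m in self.models:
            if m.is_coding:
                prot = str(Seq(m.coding_sequence(self.genome)).translate(to_stop=True))
                out[m.transcript_id] = prot
        return out


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _build_transcript(
    idx: int, strand: str, rng: np.random.Generator
) -> tuple[str, TranscriptModel]:
    """One chromosome holding one transcript with the fixed toy layout."""
    utr5 = "".join(rng.choice(list("ACGT"), _UTR5))
    n_codons = (_CDS1 + _CDS2) // 3 - 2
    body = "".join(rng.choice(_NONSTOP_CODONS, n_codons))
    cds = "ATG" + body + "TAA"
    intron_pos_in_cds = _CDS1
    intron = "GT" + "".join(rng.choice(list("ACGT"), _INTRON - 4)) + "AG"
    utr3 = "".join(rng.choice(list("ACGT"), _UTR3))
    flank_l = "".join(rng.choice(list("ACGT"), _FLANK))
    flank_r = "".join(rng.choice(list("ACGT"), _FLANK))

    seq = flank_l + utr5 + cds[:intron_pos_in_cds] + intron + cds[intron_pos_in_cds:] + utr3 + flank_r
    L = len(seq)
    # 1-based closed coordinates on the plus layout
    utr5_s = _FLANK + 1
    cds1_s = utr5_s + _UTR5
    cds1_e = cds1_s + _CDS1 - 1
    cds2_s = cds1_e + _INTRON + 1
    cds2_e = cds2_s + _CDS2 - 1
    utr3_e = cds2_e + _UTR3
    exons = ((utr5_s, cds1_e), (cds2_s, utr3_e))
    cds_iv = ((cds1_s, cds1_e), (cds2_s, cds2_e))

    if strand == "-":
        seq = _revcomp(seq)
        flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
        exons = tuple(sorted(flip(iv) for iv in exons))
        cds_iv = tuple(sorted(flip(iv) for iv in cds_iv))

    chrom = f"chr{idx + 1}"
    model = TranscriptModel(
        gene_id=f"GENE{idx + 1}",
        transcript_id=f"TX{idx + 1}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds_iv,
    )
    return seq, model


def generate_reference(design: SimulationDesign) -> Reference:
    """Toy genome + transcript models + editable-site ground truth.

    Transcripts alternate strand so both orientations are exercised.
    Editing sites are placed at coding-strand adenosines (genomic A>G on
    '+', T>C on '−'); ``design.fraction_recoding`` of them land inside
    CDS exons.  Known-variant and reported-site subsets are disjoint by
    construction; planted regional/diagnosis effect sites avoid the
    known-variant contamination so they survive QC.
    """
    rng = np.random.default_rng([design.seed, 0])
    sites_per_tx = 12
    n_tx = design.n_transcripts or max(2, -(-design.n_sites // sites_per_tx))
    genome: dict[str, str] = {}
    models: list[TranscriptModel] = []
    for i in range(n_tx):
        seq, model = _build_transcript(i, "+-"[i % 2], rng)
        genome[model.chrom] = seq
        models.append(model)

    cds_cand: list[tuple[str, int, str, str]] = []   # chrom,pos,ref,alt
    noncds_cand: list[tuple[str, int, str, str]] = []
    for m in models:
        target = "A" if m.strand == "+" else "T"
        ref, alt = (("A", "G") if m.strand == "+" else ("T", "C"))
        lo, hi = max(1, m.start - 1000), min(len(genome[m.chrom]), m.end + 1000)
        seq = genome[m.chrom]
        for pos in range(lo, hi + 1):
            if seq[pos - 1] != target:
                continue
            cidx = m.cds_index(pos)
            if cidx is not None:
                # keep the start and stop codons intact
                if cidx < 3 or cidx >= _CDS1 + _CDS2 - 3:
                    continue
                cds_cand.append((m.chrom, pos, ref, alt))
            else:
                noncds_cand.append((m.chrom, pos, ref, alt))

    n_cds = int(round(design.fraction_recoding * design.n_sites))
    n_non = design.n_sites - n_cds
    if n_cds > len(cds_cand) or n_non > len(noncds_cand):
        raise ValueError(
            f"n_sites = {design.n_sites} exceeds available editable adenosines "
            f"({len(cds_cand)} CDS, {len(noncds_cand)} non-CDS)"
        )
    pick_cds = [cds_cand[i] for i in rng.choice(len(cds_cand), n_cds, replace=False)]
    pick_non = [noncds_cand[i] for i in rng.choice(len(noncds_cand), n_non, replace=False)]
    chosen = sorted(pick_cds + pick_non)

    df = pd.DataFrame(chosen, columns=["chrom", "pos", "ref", "alt"])
    df["site_id"] = df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["ref"] + ">" + df["alt"]
    model_of = {m.chrom: m for m in models}
    df["transcript_id"] = [model_of[c].transcript_id for c in df["chrom"]]
    df["in_cds"] = [
        model_of[c].cds_index(p) is not None for c, p in zip(df["chrom"], df["pos"])
    ]

    n = len(df)
    order = rng.permutation(n)
    n_kv = int(round(design.fraction_known_variant * n))
    kv_idx = set(order[:n_kv])
    n_rep = int(round(design.fraction_reported * n))
    rep_idx = set(order[n_kv:n_kv + n_rep])  # disjoint from known variants
    df["is_known_variant"] = [i in kv_idx for i in range(n)]
    df["is_reported"] = [i in rep_idx for i in range(n)]

    clean = [i for i in range(n) if i not in kv_idx]
    need = design.n_planted_region + design.n_planted_ad
    if need > len(clean):
        raise ValueError("not enough non-variant sites to plant effects on")
    planted = rng.choice(clean, need, replace=False)
    region_idx = set(planted[: design.n_planted_region].tolist())
    ad_idx = set(planted[design.n_planted_region:].tolist())
    df["planted_region_delta"] = [
        design.planted_region_delta if i in region_idx else 0.0 for i in range(n)
    ]
    df["planted_ad_beta"] = [
        design.planted_ad_beta if i in ad_idx else 0.0 for i in range(n)
    ]
    # headroom so planted shifts do not clip against [0, 1]
    base = rng.uniform(0.05, 0.60, n)
    shifted = (df["planted_region_delta"] > 0) | (df["planted_ad_beta"] != 0)
    base[shifted.to_numpy()] = rng.uniform(0.10, 0.50, int(shifted.sum()))
    df["base_level"] = base

    known_variants = {
        (c, int(p)) for c, p, k in zip(df["chrom"], df["pos"], df["is_known_variant"]) if k
    }
    reported = {
        (c, int(p)) for c, p, r in zip(df["chrom"], df["pos"], df["is_reported"]) if r
    }
    return Reference(
        genome=genome, models=models, known_variants=known_variants,
        reported_sites=reported, sites=df,
    )


@dataclass
class CallSet:
    """Per-sample call tables, phenotypes and subject-level truth."""

    calls: pd.DataFrame
    phenotypes: pd.DataFrame
    truth_sites: pd.DataFrame
    trait_truth: dict[str, float] = field(default_factory=dict)


def generate_calls(design: SimulationDesign, reference: Reference) -> CallSet:
    """Binomial editing calls over the cohort, with planted effects.

    Per subject × site the true level is the site's base level plus a
    subject-level Gaussian wobble, plus the planted regional delta (in the
    last region) and the planted per-diagnosis-step shift, clipped to
    (0, 1).  Total depths are negative-binomial around ``depth_mean`` and
    alternative counts binomial at the true level.  Pathology traits and
    the cognitive slope in the first dataset are linear in the true level
    of the first disease site, with coefficients recorded in
    ``trait_truth``.
    """
    rng = np.random.default_rng([design.seed, 1])
    sites = reference.sites
    n_sites = len(sites)
    base = sites["base_level"].to_numpy()
    delta = sites["planted_region_delta"].to_numpy()
    ad_beta = sites["planted_ad_beta"].to_numpy()
    shifted_region = design.region_names[-1]

    disp = design.depth_dispersion
    p_nb = disp / (disp + design.depth_mean)

    pheno_rows = []
    call_frames = []
    trait_truth: dict[str, float] = {}
    for d_i, ds in enumerate(design.dataset_names):
        codes = design.diagnosis_codes(d_i)
        n_subj = design.n_subjects_per_dataset
        subj_ids = [f"{ds}_S{i:04d}" for i in range(n_subj)]
        dx = rng.choice(codes, n_subj)
        sex = rng.integers(0, 2, n_subj)
        age = np.clip(rng.normal(85, 6, n_subj), 65, 100).round(1)
        pmi = rng.gamma(2.0, 3.0, n_subj).round(2)
        rin = np.clip(rng.normal(7.0, 0.8, n_subj), 4, 10).round(2)
        batch = rng.choice([f"{ds}_b{j}" for j in range(1, 4)], n_subj)
        study = (
            rng.choice(["ROS", "MAP"], n_subj) if d_i == 0
            else np.repeat(ds, n_subj)
        )
        wobble = rng.normal(0.0, design.subject_level_sd, (n_subj, n_sites))
        level_base = np.clip(
            base[None, :] + wobble + ad_beta[None, :] * dx[:, None], 1e-3, 1 - 1e-3
        )

        pheno = pd.DataFrame({
            "subject_id": subj_ids, "dataset": ds, "diagnosis": dx,
            "sex": sex, "age": age, "pmi": pmi, "rin": rin,
            "batch": batch, "study": study,
        })
        if d_i == 1:
            pheno["race"] = rng.choice(["W", "B", "H"], n_subj)
        if design.mayo_like_dataset == d_i:
            pheno["tissue_source"] = rng.choice(["src1", "src2"], n_subj)
        if d_i == 0:
            # pathology / cognition traits driven by the first disease site
            ad_sites = sites.index[sites["planted_ad_beta"] != 0]
            if len(ad_sites) > 0:
                driver = int(ad_sites[0])
                lv = level_base[:, driver]
                trait_truth = {
                    "driver_site": sites.loc[driver, "site_id"],
                    "tangles_beta": 5.0, "amyloid_beta": 4.0,
                    "plaques_beta": 3.0, "cog_slope_beta": -0.2,
                }
                pheno["tangles"] = 1.0 + 5.0 * lv + rng.normal(0, 0.4, n_subj)
                pheno["amyloid"] = 0.5 + 4.0 * lv + rng.normal(0, 0.4, n_subj)
                pheno["plaques"] = 0.8 + 3.0 * lv + rng.normal(0, 0.4, n_subj)
                pheno["cog_slope"] = -0.02 - 0.2 * lv + rng.normal(0, 0.05, n_subj)
        pheno_rows.append(pheno)

        for region in design.region_names:
            level = level_base.copy()
            if region == shifted_region:
                level = np.clip(level + delta[None, :], 1e-3, 1 - 1e-3)
            depth = np.maximum(rng.negative_binomial(disp, p_nb, (n_subj, n_sites)), 1)
            alt = rng.binomial(depth, level)
            frame = pd.DataFrame({
                "chrom": np.tile(sites["chrom"].to_numpy(), n_subj),
                "pos": np.tile(sites["pos"].to_numpy(), n_subj),
                "ref": np.tile(sites["ref"].to_numpy(), n_subj),
                "alt": np.tile(sites["alt"].to_numpy(), n_subj),
                "ref_depth": (depth - alt).ravel(),
                "alt_depth": alt.ravel(),
                "sample_id": np.repeat([f"{s}_{region}" for s in subj_ids], n_sites),
                "subject_id": np.repeat(subj_ids, n_sites),
                "region": region,
                "dataset": ds,
                "site_id": np.tile(sites["site_id"].to_numpy(), n_subj),
            })
            call_frames.append(frame)

    calls = pd.concat(call_frames, ignore_index=True)
    phenotypes = pd.concat(pheno_rows, ignore_index=True)
    return CallSet(
        calls=calls, phenotypes=phenotypes,
        truth_sites=sites.copy(), trait_truth=trait_truth,
    )


@dataclass
class PeptideMatrixTruth:
    batch_factors: pd.Series
    sample_factors: pd.Series
    baselines: pd.Series


def generate_peptide_matrix(
    design: SimulationDesign,
    peptides: Sequence,
    n_gis_per_batch: int = 2,
    missing_fraction: float | None = None,
    noise_sd: float | None = None,
) -> tuple[AbundanceMatrix, PeptideMatrixTruth]:
    """Batch-structured TMT abundance matrix with GIS channels.

    ``peptides`` is a sequence of peptide ids, (id, is_edited) pairs, or
    objects with a ``sequence`` attribute.  Each entry is
    baseline × batch factor × sample factor × log-normal noise, then a
    stated fraction of entries is set missing.  Ground-truth factors come
    back alongside.  A batch without GIS channels is refused.
    """
    if len(design.batch_factors) < 2:
        raise ValueError("need at least 2 batches for batch correction")
    if n_gis_per_batch < 1:
        raise ValueError("every batch needs at least one GIS channel")
    missing_fraction = (
        design.peptide_missing_fraction if missing_fraction is None else missing_fraction
    )
    noise_sd = design.peptide_noise_sd if noise_sd is None else noise_sd

    ids, edited = [], []
    for p in peptides:
        if isinstance(p, tuple):
            ids.append(str(p[0])); edited.append(bool(p[1]))
        elif hasattr(p, "sequence"):
            ids.append(p.sequence); edited.append(True)
        else:
            ids.append(str(p)); edited.append(False)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate peptide identifiers")

    rng = np.random.default_rng([design.seed, 2])
    n_pep = len(ids)
    cols, batches, gis_flags, sfac = [], [], [], []
    for b_i, factor in enumerate(design.batch_factors):
        bname = f"batch{b_i + 1}"
        for g in range(n_gis_per_batch):
            cols.append(f"{bname}.GIS{g + 1}"); batches.append(bname)
            gis_flags.append(True); sfac.append(1.0)
        for c in range(design.n_case_per_batch):
            cols.append(f"{bname}.case{c + 1}"); batches.append(bname)
            gis_flags.append(False)
            sfac.append(float(np.exp(rng.normal(0.0, 0.1))))
    baselines = np.exp(rng.normal(np.log(1e5), 1.0, n_pep))
    bfac = np.array([design.batch_factors[int(b[5:]) - 1] for b in batches])
    noise = np.exp(rng.normal(0.0, noise_sd, (n_pep, len(cols))))
    values = baselines[:, None] * bfac[None, :] * np.array(sfac)[None, :] * noise
    if missing_fraction > 0:
        mask = rng.random((n_pep, len(cols))) < missing_fraction
        values = np.where(mask, np.nan, values)

    mat = AbundanceMatrix(
        values=pd.DataFrame(values, index=ids, columns=cols),
        batch=pd.Series(batches, index=cols),
        is_gis=pd.Series(gis_flags, index=cols),
        is_edited=pd.Series(edited, index=ids),
    )
    truth = PeptideMatrixTruth(
        batch_factors=pd.Series(
            list(design.batch_factors),
            index=[f"batch{i + 1}" for i in range(len(design.batch_factors))],
        ),
        sample_factors=pd.Series(sfac, index=cols),
        baselines=pd.Series(baselines, index=ids),
    )
    return mat, truth
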