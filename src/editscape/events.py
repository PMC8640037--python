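"""Editing-event representation, QC filtering, summaries and annotation.

An editing call is one site observed in one sample as reference/alternative
read depths; its editing level is alt/(ref+alt).  Cohort-level QC applies,
in order: (1) total reads ≥ 20 per call, (2) alternative reads ≥ 5 per
call, (3) site frequency ≥ 10% — by default the proportion of subjects in
the dataset carrying a passing call — and (4) exclusion of sites at known
genomic-variant positions.  Passing sites are annotated to a genomic
region relative to the closest gene model and to reported / not-reported
status against a reference catalogue of published editing sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from editscape.recoding import TranscriptModel

BASES = frozenset("ACGT")
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
CANONICAL_CLASSES = frozenset({"A>G", "T>C"})

#: Region categories in annotation-precedence order (most transcript-internal
#: consequence first).
REGION_PRECEDENCE = (
    "exonic", "5'UTR", "3'UTR", "intronic", "ncRNA",
    "upstream", "downstream", "intergenic",
)

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_depth", "alt_depth", "sample_id"]


@dataclass(frozen=True)
class EditingCall:
    """One editing site observed in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"bases must be A/C/G/T, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth


@dataclass
class EditingSite:
    """A genomic substitution with cohort-level summary and annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    substitution_class: str = ""
    is_canonical_AtoI: bool = False
    frequency: float = float("nan")
    mean_level: float = float("nan")
    region_annotation: str = ""
    closest_gene: str = ""
    reported_status: str = ""
    coding_effect: str = ""

    def __post_init__(self) -> None:
        if not self.substitution_class:
            self.substitution_class, self.is_canonical_AtoI = classify_substitution(
                self.ref, self.alt
            )

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def editing_level(call_or_ref, alt_depth: int | None = None) -> float:
    """Editing level: edited-allele reads over total (ref + alt) reads.

    Accepts an :class:`EditingCall` or a (ref_depth, alt_depth) pair.
    """
    if alt_depth is None:
        ref_d, alt_d = call_or_ref.ref_depth, call_or_ref.alt_depth
    else:
        ref_d, alt_d = call_or_ref, alt_depth
    total = ref_d + alt_d
    if total <= 0:
        raise ValueError("editing level undefined at zero total depth")
    return alt_d / total


def classify_substitution(
    ref: str, alt: str, transcript_strand: str | None = None
) -> tuple[str, bool]:
    """Genome-reported substitution class and canonical A-to-I flag.

    Canonical A-to-I appears as A>G, or as T>C when the editing occurred on
    the minus strand; the decision uses the genome-reported pair alone, so
    ``transcript_strand`` is accepted for interface symmetry but unused.
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    cls = f"{ref}>{alt}"
    return cls, cls in CANONICAL_CLASSES


@dataclass
class QCResult:
    """Outcome of the event-level QC cascade.

    ``sites`` summarises passing sites (frequency, mean level);
    ``call_flags`` carries per-call pass flags and the first failed filter;
    ``audit`` reports removals per filter in application order and
    satisfies input = passing + Σ removed for both calls and sites.
    """

    sites: pd.DataFrame
    call_flags: pd.DataFrame
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def passing_site_ids(self) -> list[str]:
        return list(self.sites["site_id"])


def _as_calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        df = calls.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "chrom": c.chrom, "pos": c.pos, "ref": c.ref, "alt": c.alt,
                    "ref_depth": c.ref_depth, "alt_depth": c.alt_depth,
                    "sample_id": c.sample_id,
                }
                for c in calls
            ],
            columns=CALL_COLUMNS,
        )
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calls table lacks columns: {sorted(missing)}")
    if "site_id" not in df.columns:
        df["site_id"] = (
            df["chrom"].astype(str) + ":" + df["pos"].astype(str)
            + ":" + df["ref"] + ">" + df["alt"]
        )
    if "subject_id" not in df.columns:
        df["subject_id"] = df["sample_id"]
    return df


def qc_filter(
    calls,
    known_variants: Iterable[tuple[str, int]] = (),
    min_total: int = 20,
    min_alt: int = 5,
    min_frequency: float = 0.10,
    n_subjects: int | None = None,
    frequency_mode: str = "prevalence",
) -> QCResult:
    """Apply the four event-level QC filters to a table of calls.

    Filters, in order: (1) per-call total depth ≥ ``min_total``; (2)
    per-call alternative depth ≥ ``min_alt``; (3) site frequency ≥
    ``min_frequency``; (4) site not at a known genomic-variant position.
    A subject carries the event when at least one of their samples has a
    passing call.

    ``frequency_mode='prevalence'`` (default) reads filter (3) as the
    proportion of subjects carrying a passing call, the frequency axis the
    atlas plots against editing level; ``'level'`` instead thresholds each
    call's allele fraction at ``min_frequency`` and a site passes with ≥ 1
    surviving subject.

    Empty input returns an empty result with a zeroed audit.
    """
    if frequency_mode not in ("prevalence", "level"):
        raise ValueError("frequency_mode must be 'prevalence' or 'level'")
    df = _as_calls_frame(calls)
    known = {(str(c), int(p)) for c, p in known_variants}

    audit = {
        "calls_in": int(len(df)),
        "calls_removed_low_total": 0,
        "calls_removed_low_alt": 0,
        "calls_removed_low_level": 0,
        "calls_passing": 0,
        "sites_in": 0,
        "sites_removed_non_frequent": 0,
        "sites_removed_known_variant": 0,
        "sites_passing": 0,
    }
    if df.empty:
        sites = pd.DataFrame(
            columns=["site_id", "chrom", "pos", "ref", "alt", "n_subjects_passing",
                     "frequency", "mean_level", "substitution_class",
                     "is_canonical_AtoI"]
        )
        flags = pd.DataFrame(columns=list(df.columns) + ["passes", "failed_filter"])
        return QCResult(sites=sites, call_flags=flags, audit=audit)

    total = df["ref_depth"] + df["alt_depth"]
    level = np.where(total > 0, df["alt_depth"] / total.replace(0, np.nan), np.nan)
    fail1 = total < min_total
    fail2 = ~fail1 & (df["alt_depth"] < min_alt)
    passes = ~fail1 & ~fail2
    failed = np.where(fail1, "total_depth", np.where(fail2, "alt_depth", ""))
    if frequency_mode == "level":
        fail3_call = passes & (pd.Series(level, index=df.index) < min_frequency)
        passes = passes & ~fail3_call
        failed = np.where(fail3_call, "level", failed)
        audit["calls_removed_low_level"] = int(fail3_call.sum())

    flags = df.copy()
    flags["total_depth"] = total
    flags["level"] = level
    flags["passes"] = passes
    flags["failed_filter"] = failed

    audit["calls_removed_low_total"] = int(fail1.sum())
    audit["calls_removed_low_alt"] = int(fail2.sum())
    audit["calls_passing"] = int(passes.sum())

    all_sites = df.drop_duplicates("site_id")[["site_id", "chrom", "pos", "ref", "alt"]]
    audit["sites_in"] = int(len(all_sites))

    denom = n_subjects if n_subjects is not None else df["subject_id"].nunique()
    passing_calls = flags[flags["passes"]]
    per_site = (
        passing_calls.groupby("site_id")
        .agg(
            n_subjects_passing=("subject_id", "nunique"),
            mean_level=("level", "mean"),
        )
        .reindex(all_sites["site_id"])
        .fillna({"n_subjects_passing": 0})
    )
    per_site["frequency"] = per_site["n_subjects_passing"] / denom

    if frequency_mode == "prevalence":
        frequent = per_site["frequency"] >= min_frequency
    else:
        frequent = per_site["n_subjects_passing"] >= 1

    site_info = all_sites.set_index("site_id")
    in_known = pd.Series(
        [
            (str(site_info.loc[s, "chrom"]), int(site_info.loc[s, "pos"])) in known
            for s in per_site.index
        ],
        index=per_site.index,
    )
    # filter order: non-frequent sites are attributed to filter 3 even when
    # also at a variant position; filter 4 removes the frequent remainder
    removed3 = ~frequent
    removed4 = frequent & in_known
    keep = frequent & ~in_known

    audit["sites_removed_non_frequent"] = int(removed3.sum())
    audit["sites_removed_known_variant"] = int(removed4.sum())
    audit["sites_passing"] = int(keep.sum())

    sites = per_site[keep].join(site_info).reset_index()
    cls = [classify_substitution(r, a) for r, a in zip(sites["ref"], sites["alt"])]
    sites["substitution_class"] = [c for c, _ in cls]
    sites["is_canonical_AtoI"] = [b for _, b in cls]
    sites = sites[
        ["site_id", "chrom", "pos", "ref", "alt", "n_subjects_passing",
         "frequency", "mean_level", "substitution_class", "is_canonical_AtoI"]
    ]
    return QCResult(sites=sites, call_flags=flags, audit=audit)


def subject_summaries(passing_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample overall editing level and event count.

    The overall level divides the sum of per-event editing levels by the
    number of events called in that sample.  Samples with zero passing
    events are absent from the output (a warning lists them if the input
    carries rows flagged non-passing).
    """
    df = _as_calls_frame(passing_calls)
    if "passes" in df.columns:
        dropped = df.loc[~df["passes"], "sample_id"].unique()
        df = df[df["passes"]]
        empty = set(dropped) - set(df["sample_id"])
        if empty:
            warnings.warn(
                f"{len(empty)} sample(s) have no passing events and are excluded",
                stacklevel=2,
            )
    if "level" not in df.columns:
        total = df["ref_depth"] + df["alt_depth"]
        df = df.assign(level=df["alt_depth"] / total)
    out = (
        df.groupby("sample_id")
        .agg(overall_level=("level", "mean"), n_events=("level", "size"))
        .reset_index()
    )
    return out


def _annotate_against_model(pos: int, model: TranscriptModel, flank: int = 1000) -> str | None:
    """Region category of a position relative to one transcript, or None."""
    if model.contains(pos):
        if not model.is_coding:
            return "ncRNA"
        if model.in_cds(pos):
            return "exonic"
        if model.in_exon(pos):
            cds_lo, cds_hi = model.cds[0][0], model.cds[-1][1]
            if pos < cds_lo:
                return "5'UTR" if model.strand == "+" else "3'UTR"
            if pos > cds_hi:
                return "3'UTR" if model.strand == "+" else "5'UTR"
        return "intronic"
    if model.strand == "+":
        if model.start - flank <= pos < model.start:
            return "upstream"
        if model.end < pos <= model.end + flank:
            return "downstream"
    else:
        if model.end < pos <= model.end + flank:
            return "upstream"
        if model.start - flank <= pos < model.start:
            return "downstream"
    return None


def _distance_to_span(pos: int, model: TranscriptModel) -> int:
    if model.contains(pos):
        return 0
    return model.start - pos if pos < model.start else pos - model.end


def annotate_site(
    site: EditingSite,
    models: Sequence[TranscriptModel] | Mapping[str, Sequence[TranscriptModel]],
    reported_sites: Iterable[tuple[str, int]] = (),
    flank: int = 1000,
) -> EditingSite:
    """Assign region annotation, closest gene and reported status to a site.

    When transcripts disagree, the most transcript-internal category wins
    (exonic > 5'UTR > 3'UTR > intronic > ncRNA > upstream > downstream >
    intergenic).  The closest gene is the nearest model span, ties broken
    by lexicographic gene ID; an unknown chromosome yields "intergenic"
    with a warning.
    """
    if isinstance(models, Mapping):
        chrom_models = list(models.get(site.chrom, ()))
        known_chroms = set(models)
    else:
        chrom_models = [m for m in models if m.chrom == site.chrom]
        known_chroms = {m.chrom for m in models}

    reported = {(str(c), int(p)) for c, p in reported_sites}
    site.reported_status = (
        "reported" if (site.chrom, site.pos) in reported else "not_reported"
    )

    if site.chrom not in known_chroms:
        warnings.warn(f"unknown chromosome {site.chrom!r}; annotated intergenic",
                      stacklevel=2)
        site.region_annotation = "intergenic"
        site.closest_gene = ""
        return site

    best = "intergenic"
    rank = {cat: i for i, cat in enumerate(REGION_PRECEDENCE)}
    for model in chrom_models:
        cat = _annotate_against_model(site.pos, model, flank=flank)
        if cat is not None and rank[cat] < rank[best]:
            best = cat
    site.region_annotation = best

    if chrom_models:
        site.closest_gene = min(
            chrom_models, key=lambda m: (_distance_to_span(site.pos, m), m.gene_id)
        ).gene_id
    else:
        site.closest_gene = ""
    return site


def annotate_sites(
    sites: pd.DataFrame,
    models: Sequence[TranscriptModel],
    reported_sites: Iterable[tuple[str, int]] = (),
    flank: int = 1000,
) -> pd.DataFrame:
    """Vector wrapper of :func:`annotate_site` over a QC site table."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    reported = {(str(c), int(p)) for c, p in reported_sites}
    out = sites.copy()
    regions, genes, statuses = [], [], []
    for _, row in out.iterrows():
        s = EditingSite(chrom=row["chrom"], pos=int(row["pos"]),
                        ref=row["ref"], alt=row["alt"])
        annotate_site(s, by_chrom, reported, flank=flank)
        regions.append(s.region_annotation)
        genes.append(s.closest_gene)
        statuses.append(s.reported_status)
    out["region_annotation"] = regions
    out["closest_gene"] = genes
    out["reported_status"] = statuses
    return out


def region_overlap_counts(
    sites_by_region: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], int]:
    """Partition sites by the exact combination of regions they occur in.

    Returns a count for every non-empty region combination (zeroes
    included), so that per-region totals reconstruct the input sets.
    """
    regions = sorted(sites_by_region)
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    sets = {r: set(sites_by_region[r]) for r in regions}
    membership: dict[str, tuple[str, ...]] = {}
    for site in set().union(*sets.values()):
        combo = tuple(r for r in regions if site in sets[r])
        membership[site] = combo
    from itertools import combinations

    counts: dict[tuple[str, ...], int] = {}
    for k in range(1, len(regions) + 1):
        for combo in combinations(regions, k):
            counts[combo] = 0
    for combo in membership.values():
        counts[combo] += 1
    return counts
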