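"""Editing-event QC, levels, summaries, annotation and region overlaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editscape import (
    EditingCall,
    EditingSite,
    annotate_site,
    classify_substitution,
    editing_level,
    qc_filter,
    region_overlap_counts,
    subject_summaries,
)
from editscape.recoding import TranscriptModel


def make_call(ref_depth, alt_depth, sample="s1", pos=100):
    return EditingCall(chrom="chr1", pos=pos, ref="A", alt="G",
                       sample_id=sample, ref_depth=ref_depth, alt_depth=alt_depth)


class TestEditingLevel:
    @pytest.mark.parametrize(
        "ref_d,alt_d,expected",
        [(10, 10, 0.5), (0, 25, 1.0), (90, 10, 0.10)],
    )
    def test_level_is_alt_over_total(self, ref_d, alt_d, expected):
        assert editing_level(make_call(ref_d, alt_d)) == pytest.approx(expected)
        assert editing_level(ref_d, alt_d) == pytest.approx(expected)

    def test_zero_total_depth_is_an_error(self):
        with pytest.raises(ValueError, match="zero total depth"):
            editing_level(0, 0)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_level_always_in_unit_interval(self, r, a):
        if r + a == 0:
            return
        assert 0.0 <= editing_level(r, a) <= 1.0


class TestSubstitutionClass:
    @pytest.mark.parametrize(
        "ref,alt,canonical",
        [("A", "G", True), ("T", "C", True), ("C", "T", False), ("G", "A", False)],
    )
    def test_canonical_AtoI_classes(self, ref, alt, canonical):
        cls, is_can = classify_substitution(ref, alt)
        assert cls == f"{ref}>{alt}" and is_can is canonical

    def test_strand_does_not_change_the_call(self):
        assert classify_substitution("T", "C", "+") == classify_substitution("T", "C", "-")

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("N", "G"), ("A", "x")])
    def test_invalid_substitution_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)


def brute_force_qc(calls_df, known, min_total=20, min_alt=5, min_frequency=0.10):
    """Independent per-call / per-site re-check of the QC cascade."""
    passing_sites = []
    n_subj = calls_df["subject_id"].nunique()
    for site_id, sub in calls_df.groupby("site_id"):
        ok_subjects = set()
        for row in sub.itertuples():
            total = row.ref_depth + row.alt_depth
            if total >= min_total and row.alt_depth >= min_alt:
                ok_subjects.add(row.subject_id)
        freq = len(ok_subjects) / n_subj
        pos = (str(sub["chrom"].iloc[0]), int(sub["pos"].iloc[0]))
        if freq >= min_frequency and pos not in known:
            passing_sites.append(site_id)
    return sorted(passing_sites)


def contaminated_calls(rng, n_sites=50, n_subjects=20):
    """Call table with planted low-depth, low-alt, rare and variant sites."""
    rows = []
    for i in range(n_sites):
        for s in range(n_subjects):
            kind = i % 5
            if kind == 0:      # clean
                ref_d, alt_d = 60, 20
            elif kind == 1:    # low total depth
                ref_d, alt_d = 9, 6
            elif kind == 2:    # low alternative depth
                ref_d, alt_d = 96, 4
            elif kind == 3:    # rare: passes in one subject only
                ref_d, alt_d = (60, 20) if s == 0 else (96, 4)
            else:              # clean but at a known-variant position
                ref_d, alt_d = 50, 30
            ref_d += int(rng.integers(0, 3))
            rows.append({
                "chrom": "chr1", "pos": 1000 + i, "ref": "A", "alt": "G",
                "ref_depth": ref_d, "alt_depth": alt_d,
                "sample_id": f"s{s}", "subject_id": f"s{s}",
            })
    known = {("chr1", 1000 + i) for i in range(n_sites) if i % 5 == 4}
    return pd.DataFrame(rows), known


class TestQCFilter:
    def test_total_depth_filter_boundary(self):
        res = qc_filter(pd.DataFrame([vars(make_call(14, 5)) | {"sample_id": "s1"}]))
        assert res.audit["calls_removed_low_total"] == 1  # total 19 < 20

    def test_alt_depth_filter(self):
        res = qc_filter([make_call(96, 4)])
        assert res.audit["calls_removed_low_alt"] == 1
        assert res.call_flags["failed_filter"].iloc[0] == "alt_depth"

    def test_rare_site_excluded_and_variant_site_excluded(self):
        calls = [make_call(60, 20, sample="s0", pos=1)]
        calls += [make_call(96, 4, sample=f"s{i}", pos=1) for i in range(1, 20)]
        calls += [make_call(60, 20, sample=f"s{i}", pos=2) for i in range(20)]
        res = qc_filter(calls, known_variants={("chr1", 2)})
        assert res.audit["sites_removed_non_frequent"] == 1   # 5% of subjects
        assert res.audit["sites_removed_known_variant"] == 1  # 100% frequent
        assert res.audit["sites_passing"] == 0

    def test_audit_conservation_and_brute_force_agreement(self, rng):
        calls, known = contaminated_calls(rng)
        res = qc_filter(calls, known)
        a = res.audit
        assert a["calls_in"] == (a["calls_passing"] + a["calls_removed_low_total"]
                                 + a["calls_removed_low_alt"])
        assert a["sites_in"] == (a["sites_passing"] + a["sites_removed_non_frequent"]
                                 + a["sites_removed_known_variant"])
        assert sorted(res.passing_site_ids) == brute_force_qc(
            res.call_flags, known
        )

    def test_empty_input_zeroed_audit(self):
        res = qc_filter(pd.DataFrame(columns=["chrom", "pos", "ref", "alt",
                                              "ref_depth", "alt_depth", "sample_id"]))
        assert res.audit["calls_in"] == 0 and res.audit["sites_passing"] == 0
        assert res.sites.empty

    def test_level_mode_thresholds_allele_fraction(self):
        # 4% allele fraction passes depth filters but fails the 10% level read
        calls = [make_call(480, 20, sample=f"s{i}") for i in range(10)]
        res = qc_filter(calls, frequency_mode="level")
        assert res.audit["calls_removed_low_level"] == 10
        assert res.audit["sites_passing"] == 0


class TestSubjectSummaries:
    def test_mean_of_event_levels(self):
        df = pd.DataFrame({
            "chrom": "chr1", "pos": [1, 2, 3], "ref": "A", "alt": "G",
            "ref_depth": [80, 60, 40], "alt_depth": [20, 40, 60],
            "sample_id": "s1",
        })
        out = subject_summaries(df)
        assert out.loc[0, "overall_level"] == pytest.approx(0.4)
        assert out.loc[0, "n_events"] == 3

    def test_single_event_identity(self):
        df = pd.DataFrame({"chrom": "chr1", "pos": [1], "ref": "A", "alt": "G",
                           "ref_depth": [63], "alt_depth": [37], "sample_id": "s1"})
        out = subject_summaries(df)
        assert out.loc[0, "overall_level"] == pytest.approx(0.37)

    def test_identical_subjects_get_identical_summaries(self):
        rows = []
        for s in ("a", "b"):
            rows += [{"chrom": "chr1", "pos": p, "ref": "A", "alt": "G",
                      "ref_depth": 50, "alt_depth": 50, "sample_id": s}
                     for p in (1, 2)]
        out = subject_summaries(pd.DataFrame(rows)).set_index("sample_id")
        assert out.loc["a"].equals(out.loc["b"])

    def test_zero_event_subject_excluded_with_warning(self):
        df = pd.DataFrame({
            "chrom": "chr1", "pos": [1, 1], "ref": "A", "alt": "G",
            "ref_depth": [50, 50], "alt_depth": [50, 50],
            "sample_id": ["a", "b"], "passes": [True, False],
            "level": [0.5, 0.5],
        })
        with pytest.warns(UserWarning, match="no passing events"):
            out = subject_summaries(df)
        assert list(out["sample_id"]) == ["a"]


@pytest.fixture(scope="module")
def plus_model():
    # 5'UTR 100-149, CDS 150-239 & 440-529, intron 240-439, 3'UTR 530-579
    return TranscriptModel(
        gene_id="G1", transcript_id="T1", chrom="chr1", strand="+",
        exons=((100, 239), (440, 579)), cds=((150, 239), (440, 529)),
    )


class TestAnnotation:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (200, "exonic"), (120, "5'UTR"), (560, "3'UTR"), (300, "intronic"),
            (99, "upstream"), (580, "downstream"), (2000, "intergenic"),
        ],
    )
    def test_region_categories_plus_strand(self, plus_model, pos, expected):
        site = EditingSite(chrom="chr1", pos=pos, ref="A", alt="G")
        annotate_site(site, [plus_model])
        assert site.region_annotation == expected

    def test_upstream_is_strand_aware(self):
        minus = TranscriptModel(
            gene_id="G2", transcript_id="T2", chrom="chr1", strand="-",
            exons=((100, 239), (440, 579)), cds=((150, 239), (440, 529)),
        )
        site = EditingSite(chrom="chr1", pos=580, ref="T", alt="C")
        annotate_site(site, [minus])
        assert site.region_annotation == "upstream"  # 5' of a '-' TSS

    def test_500bp_upstream_of_plus_tss(self, plus_model):
        site = EditingSite(chrom="chr1", pos=plus_model.start - 500, ref="A", alt="G")
        annotate_site(site, [plus_model])
        assert site.region_annotation == "upstream"

    def test_ncRNA_and_precedence(self, plus_model):
        nc = TranscriptModel(gene_id="G0", transcript_id="T0", chrom="chr1",
                             strand="+", exons=((190, 210),), cds=())
        site = EditingSite(chrom="chr1", pos=200, ref="A", alt="G")
        annotate_site(site, [nc, plus_model])
        assert site.region_annotation == "exonic"  # CDS beats ncRNA

    def test_reported_status_is_set_membership(self, plus_model):
        site = EditingSite(chrom="chr1", pos=200, ref="A", alt="G")
        annotate_site(site, [plus_model], reported_sites={("chr1", 200)})
        assert site.reported_status == "reported"
        site2 = EditingSite(chrom="chr1", pos=201, ref="A", alt="G")
        annotate_site(site2, [plus_model], reported_sites={("chr1", 200)})
        assert site2.reported_status == "not_reported"

    def test_unknown_chromosome_intergenic_with_warning(self, plus_model):
        site = EditingSite(chrom="chrZ", pos=5, ref="A", alt="G")
        with pytest.warns(UserWarning, match="unknown chromosome"):
            annotate_site(site, [plus_model])
        assert site.region_annotation == "intergenic"

    def test_closest_gene_tie_broken_lexicographically(self, plus_model):
        # plus_model (gene G1) spans 100-579; the twin spans 699-1179, so
        # position 639 is exactly 60 bases from both spans
        twin = TranscriptModel(gene_id="A_GENE", transcript_id="T9", chrom="chr1",
                               strand="+", exons=((699, 1179),), cds=())
        tie = EditingSite(chrom="chr1", pos=639, ref="A", alt="G")
        annotate_site(tie, [plus_model, twin])
        assert tie.closest_gene == "A_GENE"
        nearer = EditingSite(chrom="chr1", pos=610, ref="A", alt="G")
        annotate_site(nearer, [plus_model, twin])
        assert nearer.closest_gene == "G1"


class TestRegionOverlap:
    def test_shared_and_unique_counts(self):
        counts = region_overlap_counts({"A": {"s1", "s2"}, "B": {"s2", "s3"}})
        assert counts[("A",)] == 1 and counts[("B",)] == 1 and counts[("A", "B")] == 1

    def test_identical_sets_all_in_full_intersection(self):
        counts = region_overlap_counts({"A": {"s1", "s2"}, "B": {"s1", "s2"}})
        assert counts[("A", "B")] == 2 and counts[("A",)] == 0

    def test_disjoint_sets_empty_intersection(self):
        counts = region_overlap_counts({"A": {"s1"}, "B": {"s2"}})
        assert counts[("A", "B")] == 0

    def test_partition_reconstructs_region_totals(self, rng):
        universe = [f"s{i}" for i in range(200)]
        sets = {
            r: set(rng.choice(universe, size=rng.integers(20, 150), replace=False))
            for r in ("R1", "R2", "R3")
        }
        counts = region_overlap_counts(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))
        for r in sets:
            total = sum(c for combo, c in counts.items() if r in combo)
            assert total == len(sets[r])
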