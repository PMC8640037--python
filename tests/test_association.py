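"""Association stages: thresholds, GLMs, mixed models, meta-analysis, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editscape import (
    DiagnosisModel,
    RegionalContrastModel,
    TwoStageMeta,
    bonferroni_threshold,
    cis_effect,
    classify_cis_effect,
    genomic_lambda,
    meta_fixed,
    top_event_pcs,
    trait_glm,
)
from editscape.association import AssociationResults, cis_effect_region_summary


class TestBonferroni:
    def test_identity_at_one_test(self):
        assert bonferroni_threshold(1) == 0.05

    def test_regional_and_genomewide_denominators(self):
        assert f"{bonferroni_threshold(33_641):.3g}" == "1.49e-06"
        assert f"{bonferroni_threshold(40_805):.2g}" == "1.2e-06"
        assert f"{bonferroni_threshold(41_254):.3g}" == "1.21e-06"

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestMetaFixed:
    def test_two_study_hand_solution(self):
        beta, se, p = meta_fixed([0.5, 0.3], [0.1, 0.2])
        w1, w2 = 1 / 0.01, 1 / 0.04
        assert beta == pytest.approx((w1 * 0.5 + w2 * 0.3) / (w1 + w2), abs=1e-12)
        assert beta == pytest.approx(0.46, abs=1e-12)
        assert se == pytest.approx((w1 + w2) ** -0.5, abs=1e-12)
        assert se == pytest.approx(0.08944271909999159, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(beta / se), abs=1e-15)

    def test_single_study_is_identity(self):
        beta, se, _ = meta_fixed([0.42], [0.07])
        assert (beta, se) == (pytest.approx(0.42), pytest.approx(0.07))

    def test_pooled_se_never_exceeds_smallest_input_se(self, rng):
        for _ in range(20):
            ses = rng.uniform(0.05, 0.5, rng.integers(2, 6))
            betas = rng.normal(0, 1, len(ses))
            _, se, _ = meta_fixed(betas, ses)
            assert se <= ses.min() + 1e-12

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([0.1, 0.2], [0.1, 0.0])


class TestGenomicLambda:
    def test_uniform_null_is_near_one(self, rng):
        lam = genomic_lambda(rng.uniform(0, 1, 20_000))
        assert 0.95 < lam < 1.05

    def test_inflation_detected(self, rng):
        z = rng.normal(0.7, 1.0, 20_000)
        p = 2 * stats.norm.sf(np.abs(z))
        assert genomic_lambda(p) > 1.2


def _null_cohort(rng, n=200, m=50):
    lv = pd.DataFrame(
        rng.normal(0.3, 0.05, (n, m)),
        index=[f"subj{i}" for i in range(n)],
        columns=[f"site{j}" for j in range(m)],
    )
    pheno = pd.DataFrame({
        "diagnosis": rng.choice([0, 1, 2], n),
        "age": rng.normal(85, 6, n),
        "sex": rng.integers(0, 2, n),
        "batch": rng.choice(["b1", "b2"], n),
    }, index=lv.index)
    return lv, pheno


class TestDiagnosisModel:
    def test_matches_statsmodels_glm_per_site(self, rng):
        import statsmodels.api as sm

        lv, pheno = _null_cohort(rng, n=120, m=5)
        res = DiagnosisModel(lv, pheno, ["age", "sex", "batch"]).fit().table
        X = pd.DataFrame({
            "const": 1.0,
            "diagnosis": pheno["diagnosis"].astype(float),
            "age": pheno["age"],
            "sex": pheno["sex"].astype(float),
            "batch_b2": (pheno["batch"] == "b2").astype(float),
        })
        for site in lv.columns:
            fit = sm.GLM(lv[site], X, family=sm.families.Gaussian()).fit()
            row = res[res["site_id"] == site].iloc[0]
            assert row["beta"] == pytest.approx(fit.params["diagnosis"], rel=1e-10)
            assert row["se"] == pytest.approx(fit.bse["diagnosis"], rel=1e-10)

    def test_planted_effect_recovered(self, rng):
        lv, pheno = _null_cohort(rng, n=600, m=10)
        lv = lv.add(0.05 * pheno["diagnosis"].to_numpy()[:, None])
        res = DiagnosisModel(lv, pheno, ["age", "sex"]).fit().table
        assert abs(res["beta"].mean() - 0.05) < 0.005

    def test_permuted_diagnosis_is_null(self, rng):
        lv, pheno = _null_cohort(rng, n=300, m=200)
        res = DiagnosisModel(lv, pheno, ["age"]).fit().table
        assert abs(res["beta"].median()) < 0.005
        assert 0.01 < (res["p"] <= 0.05).mean() < 0.10

    def test_mayo_coding_enforced(self, rng):
        lv, pheno = _null_cohort(rng, n=50, m=2)
        with pytest.raises(ValueError, match="not in allowed set"):
            DiagnosisModel(lv, pheno, allowed_diagnosis=(0, 2))

    def test_missing_covariates_listwise_deleted(self, rng):
        lv, pheno = _null_cohort(rng, n=100, m=3)
        pheno.loc[pheno.index[:7], "age"] = np.nan
        res = DiagnosisModel(lv, pheno, ["age"]).fit()
        assert res.n_dropped_missing == 7
        assert (res.table["n"] == 93).all()

    def test_constant_site_skipped(self, rng):
        lv, pheno = _null_cohort(rng, n=50, m=2)
        lv["site0"] = 0.5
        res = DiagnosisModel(lv, pheno).fit()
        assert "site0" in res.skipped_sites

    def test_logit_family_runs(self, rng):
        lv, pheno = _null_cohort(rng, n=80, m=3)
        lv = lv.clip(0.01, 0.99)
        res = DiagnosisModel(lv, pheno, family="logit-level").fit()
        assert len(res.table) == 3


def _paired_regional(rng, n_subj=80, beta=0.2, n_sites=3):
    rows = []
    for j in range(n_sites):
        base = rng.uniform(0.2, 0.4)
        for i in range(n_subj):
            u = rng.normal(0, 0.03)
            for r, shift in (("R1", 0.0), ("R2", beta)):
                rows.append({
                    "site_id": f"site{j}", "subject_id": f"s{i}", "region": r,
                    "level": base + u + shift + rng.normal(0, 0.02),
                    "age": rng.normal(85, 5), "sex": float(rng.integers(0, 2)),
                })
    return pd.DataFrame(rows)


class TestRegionalContrast:
    def test_planted_delta_recovered(self, rng):
        df = _paired_regional(rng, beta=0.30)
        res = RegionalContrastModel(df, ("R1", "R2"), ["age", "sex"]).fit()
        assert np.allclose(res.table["beta"], 0.30, atol=0.02)

    def test_identical_regions_beta_zero(self, rng):
        df = _paired_regional(rng, n_subj=30, beta=0.0, n_sites=1)
        r2 = df[df["region"] == "R2"].copy()
        df.loc[df["region"] == "R2", "level"] = df.loc[
            df["region"] == "R1", "level"
        ].to_numpy()
        res = RegionalContrastModel(df, ("R1", "R2")).fit()
        assert res.table["beta"].abs().max() < 1e-8

    def test_null_p_values_are_calibrated(self, rng):
        df = _paired_regional(rng, n_subj=40, beta=0.0, n_sites=40)
        res = RegionalContrastModel(df, ("R1", "R2")).fit()
        stat, p = stats.kstest(res.table["p"], "uniform")
        assert p > 0.01

    def test_constant_level_site_flagged(self, rng):
        df = _paired_regional(rng, n_subj=20, n_sites=1)
        df["level"] = 0.5
        res = RegionalContrastModel(df, ("R1", "R2")).fit()
        assert res.skipped_sites == ["site0"]
        assert len(res.table) == 0


def _results(df_rows, tag):
    t = pd.DataFrame(df_rows, columns=["site_id", "dataset", "beta", "se", "p", "n"])
    t["model_tag"] = tag
    return AssociationResults(t, tag)


class TestTwoStage:
    def test_suggestive_gate_and_pooling(self):
        s1 = _results([("a", "d1", 0.5, 0.1, 1e-4, 100),
                       ("b", "d1", 0.1, 0.1, 0.5, 100)], "d1")
        s2b = _results([("a", "d2", 0.3, 0.2, 0.1, 80)], "d2")
        meta = TwoStageMeta(s1, [s1, s2b]).fit()
        assert list(meta.table["site_id"]) == ["a"]  # only the suggestive site
        row = meta.table.iloc[0]
        assert row["beta_meta"] == pytest.approx(0.46, abs=1e-12)
        assert row["k_datasets"] == 2 and not row["flagged"]

    def test_site_in_single_dataset_flagged(self):
        s1 = _results([("a", "d1", 0.5, 0.1, 1e-4, 100)], "d1")
        meta = TwoStageMeta(s1, [s1]).fit()
        assert bool(meta.table.iloc[0]["flagged"])
        assert meta.table.iloc[0]["beta_meta"] == pytest.approx(0.5)

    def test_null_meta_lambda_in_unit_band(self, rng):
        n, m = 300, 2000
        per = []
        for k in range(4):
            dx = rng.choice([0, 1, 2], n)
            Y = rng.normal(0.3, 0.05, (n, m))
            lv = pd.DataFrame(Y, index=[f"d{k}_{i}" for i in range(n)],
                              columns=[f"s{j}" for j in range(m)])
            ph = pd.DataFrame({"diagnosis": dx}, index=lv.index)
            per.append(DiagnosisModel(lv, ph, dataset=f"d{k}").fit())
        meta = TwoStageMeta(per[0], per, suggestive_p=1.01).fit()
        assert 0.9 <= meta.inflation_lambda <= 1.1


class TestTraitGLM:
    def test_planted_trait_slope_recovered(self, rng):
        lv, pheno = _null_cohort(rng, n=400, m=5)
        trait = 1.0 + 5.0 * lv["site0"] + rng.normal(0, 0.3, 400)
        res = trait_glm(trait, lv, pheno, ["age", "sex"], trait_name="tangles")
        row = res.table.set_index("site_id").loc["site0"]
        assert row["beta"] == pytest.approx(5.0, abs=0.3)

    def test_zero_variance_trait_rejected(self, rng):
        lv, pheno = _null_cohort(rng, n=50, m=2)
        with pytest.raises(ValueError, match="zero variance"):
            trait_glm(pd.Series(1.0, index=lv.index), lv, pheno)


class TestCisEffect:
    @pytest.mark.parametrize(
        "p,beta,expected",
        [
            (0.20, 1.0, "positive,non"),
            (0.01, -1.0, "negative,nominal"),
            (1e-9, -1.0, "negative,genome-wide"),
            (1e-9, 1.0, "positive,genome-wide"),
        ],
    )
    def test_effect_classification(self, p, beta, expected):
        assert classify_cis_effect(p, beta, genome_wide=1e-6) == expected

    def test_partition_conserves_tested_pairs(self, rng):
        n, m = 150, 12
        status = pd.DataFrame(rng.integers(0, 2, (n, m)).astype(float),
                              index=[f"s{i}" for i in range(n)],
                              columns=[f"site{j}" for j in range(m)])
        status["site0"] = 1.0  # constant -> skipped
        expr = pd.DataFrame(rng.normal(0, 1, (n, m)), index=status.index,
                            columns=[f"e{j}" for j in range(m)])
        pheno = pd.DataFrame({"age": rng.normal(85, 5, n)}, index=status.index)
        pairs = [(f"site{j}", f"e{j}") for j in range(m)]
        res = cis_effect(status, expr, pheno, pairs, ["age"])
        assert len(res.table) + len(res.skipped_sites) == m
        ann = pd.Series("exonic", index=[f"site{j}" for j in range(m)])
        summary = cis_effect_region_summary(res, ann)
        assert summary["count"].sum() == len(res.table)


class TestTopEventPCs:
    def test_isotropic_events_share_variance(self, rng):
        lv = pd.DataFrame(rng.normal(0, 1, (5000, 7)),
                          columns=[f"e{j}" for j in range(7)])
        res = top_event_pcs(lv, k=7)
        assert np.allclose(res.explained_variance_ratio, 1 / 7, atol=0.02)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_correlated_pair_absorbed_by_first_pc(self, rng):
        a = rng.normal(0, 1, 500)
        lv = pd.DataFrame({"e1": a, "e2": a * 2 + 1e-9 * rng.normal(size=500)})
        res = top_event_pcs(lv, k=2)
        assert res.explained_variance_ratio[0] > 0.999

    def test_sign_convention_makes_scores_reproducible(self, rng):
        lv = pd.DataFrame(rng.normal(0, 1, (100, 4)),
                          columns=list("abcd"))
        r1 = top_event_pcs(lv, k=4)
        r2 = top_event_pcs(lv.copy(), k=4)
        assert np.allclose(r1.scores, r2.scores)
        for col in r1.loadings.columns:
            lead = r1.loadings[col].abs().idxmax()
            assert r1.loadings.loc[lead, col] > 0

    def test_k_exceeding_events_rejected(self, rng):
        lv = pd.DataFrame(rng.normal(0, 1, (50, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            top_event_pcs(lv, k=7)
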