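"""Disease-association statistics for editing events.

The framework mirrors a two-stage transcriptome-wide scan: within each
dataset a Gaussian identity-link GLM relates a site's editing level to
ordinal diagnosis (0 control / 1 MCI / 2 AD) with dataset-specific
covariates; sites reaching a suggestive Stage-I p-value are carried into a
Stage-II inverse-variance-weighted fixed-effects meta-analysis, whose
calibration is summarised by the genomic inflation factor λ.  Paired
brain-region contrasts use a linear mixed model with a subject random
intercept.  Pathology/cognition GLMs flip the direction (editing level as
exposure), cis-effect models regress expression on binary editing status,
and a small PCA summarises the top disease-associated events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # ≈ 0.4549


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def genomic_lambda(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median association χ²₁ over the null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def meta_fixed(betas, ses) -> tuple[float, float, float]:
    """Inverse-variance-weighted fixed-effects pooling of (beta, se) pairs.

    Returns (beta_meta, se_meta, p_meta):
    beta = Σ(βᵢ/seᵢ²)/Σ(1/seᵢ²), se = (Σ1/seᵢ²)^(−1/2), p from the normal z.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0 or b.size != s.size:
        raise ValueError("betas and ses must be equal-length, non-empty")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return beta, se, p


def _design_matrix(pheno: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Intercept + covariates, categoricals one-hot encoded (first level dropped)."""
    X = pd.DataFrame({"const": 1.0}, index=pheno.index)
    for cov in covariates:
        col = pheno[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = col.astype(float)
    return X


def _multi_ols(Y: np.ndarray, X: np.ndarray, coef_index: int):
    """OLS of many responses on one shared design matrix.

    Y is n × m (one column per site), X is n × p.  Returns beta, se and
    two-sided p for the coefficient at ``coef_index`` of every response,
    identical to fitting each column with a Gaussian identity-link GLM.
    """
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"n = {n} too small for {p} parameters")
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    B = H @ Y                                     # p × m
    resid = Y - X @ B
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(sigma2 * XtX_inv[coef_index, coef_index])
    beta = B[coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, pvals, dof


@dataclass
class AssociationResults:
    """Per-site effect estimates from one association model.

    ``table`` columns: site_id, dataset, beta, se, p, n, model_tag (beta in
    editing-level units per predictor unit unless the model says
    otherwise).
    """

    table: pd.DataFrame
    model_tag: str
    n_dropped_missing: int = 0
    skipped_sites: list[str] = field(default_factory=list)

    def threshold(self, alpha: float = 0.05) -> float:
        return bonferroni_threshold(len(self.table), alpha)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] <= self.threshold(alpha)]

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p").head(top)
        lines = [
            f"{self.model_tag}: {len(self.table)} sites tested",
            f"listwise-deleted rows: {self.n_dropped_missing}; "
            f"skipped sites: {len(self.skipped_sites)}",
            f"Bonferroni threshold: {self.threshold():.3e}",
            "",
            t.to_string(index=False,
                        float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class DiagnosisModel:
    """Per-dataset GLM of editing level on ordinal clinical diagnosis.

    Editing level (the response) is regressed on diagnosis coded 0/1/2
    (ordinal numeric) plus dataset-specific covariates; the reported beta
    is the change in mean editing level per diagnosis step.  Rows with
    missing covariates are listwise-deleted (count reported); sites with
    additional missing levels are refitted on their own complete cases.

    Parameters
    ----------
    levels : DataFrame, samples × sites.
    phenotypes : DataFrame indexed like ``levels`` with a ``diagnosis``
        column and the covariates.
    covariates : list of phenotype columns to adjust for.
    dataset : label stored in the results.
    allowed_diagnosis : acceptable codes, e.g. ``(0, 2)`` for a MAYO-like
        dataset without MCI subjects.
    family : "gaussian" (identity link, default) or "logit-level"
        (levels transformed by the empirical logit before the fit).
    """

    def __init__(
        self,
        levels: pd.DataFrame,
        phenotypes: pd.DataFrame,
        covariates: list[str] | None = None,
        dataset: str = "dataset",
        allowed_diagnosis: tuple[int, ...] = (0, 1, 2),
        family: str = "gaussian",
    ) -> None:
        if family not in ("gaussian", "logit-level"):
            raise ValueError("family must be 'gaussian' or 'logit-level'")
        pheno = phenotypes.loc[levels.index]
        bad = set(pheno["diagnosis"].dropna().unique()) - set(allowed_diagnosis)
        if bad:
            raise ValueError(
                f"diagnosis codes {sorted(bad)} not in allowed set {allowed_diagnosis}"
            )
        self.levels = levels
        self.phenotypes = pheno
        self.covariates = list(covariates or [])
        self.dataset = dataset
        self.family = family

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        sites: list[str],
        covariates: list[str] | None = None,
        **kwargs,
    ) -> "DiagnosisModel":
        """Build from one wide table holding both levels and phenotypes."""
        return cls(data[sites], data.drop(columns=sites), covariates, **kwargs)

    def fit(self) -> AssociationResults:
        pheno = self.phenotypes
        need = ["diagnosis"] + self.covariates
        complete = pheno[need].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        pheno = pheno[complete]
        Y_df = self.levels[complete.to_numpy()]
        if self.family == "logit-level":
            eps = 1e-4
            Y_df = np.log((Y_df + eps) / (1 - Y_df + eps))
        X_df = _design_matrix(pheno, self.covariates)
        X_df.insert(1, "diagnosis", pheno["diagnosis"].astype(float))
        X = X_df.to_numpy(dtype=float)

        rows = []
        skipped: list[str] = []
        site_missing = Y_df.isna().any(axis=0)
        complete_sites = list(Y_df.columns[~site_missing])
        if complete_sites:
            Y = Y_df[complete_sites].to_numpy(dtype=float)
            var0 = Y.std(axis=0) == 0
            keep = [s for s, z in zip(complete_sites, var0) if not z]
            skipped += [s for s, z in zip(complete_sites, var0) if z]
            if keep:
                Yk = Y_df[keep].to_numpy(dtype=float)
                beta, se, p, _ = _multi_ols(Yk, X, coef_index=1)
                for s, b_, se_, p_ in zip(keep, beta, se, p):
                    rows.append((s, self.dataset, b_, se_, p_, len(X)))
        for s in Y_df.columns[site_missing]:
            y = Y_df[s]
            ok = y.notna().to_numpy()
            if ok.sum() < X.shape[1] + 2 or y[ok].std() == 0:
                skipped.append(s)
                continue
            b_, se_, p_, _ = _multi_ols(y.to_numpy(dtype=float)[ok, None], X[ok], 1)
            rows.append((s, self.dataset, float(b_[0]), float(se_[0]), float(p_[0]),
                         int(ok.sum())))
        table = pd.DataFrame(
            rows, columns=["site_id", "dataset", "beta", "se", "p", "n"]
        )
        table["model_tag"] = f"diagnosis_glm[{self.family}]"
        return AssociationResults(
            table=table,
            model_tag=f"diagnosis_glm[{self.dataset}]",
            n_dropped_missing=n_dropped,
            skipped_sites=skipped,
        )


class RegionalContrastModel:
    """Mixed linear model contrasting editing levels between two brain regions.

    Per site: level ~ region + covariates with a subject random intercept,
    fitted on subjects sampled in both regions.  beta is the level
    difference of ``region_pair[1]`` minus ``region_pair[0]``; singular or
    constant fits are flagged and excluded from the multiplicity count.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        region_pair: tuple[str, str],
        covariates: list[str] | None = None,
        site_col: str = "site_id",
        level_col: str = "level",
        subject_col: str = "subject_id",
        region_col: str = "region",
    ) -> None:
        self.data = data
        self.region_pair = region_pair
        self.covariates = list(covariates or [])
        self.cols = (site_col, level_col, subject_col, region_col)

    def fit(self) -> AssociationResults:
        import statsmodels.formula.api as smf

        site_col, level_col, subject_col, region_col = self.cols
        r0, r1 = self.region_pair
        df = self.data[self.data[region_col].isin(self.region_pair)].copy()
        df["_region01"] = (df[region_col] == r1).astype(float)
        # paired design: keep subjects observed in both regions
        rows, skipped = [], []
        formula = "level ~ _region01" + "".join(f" + {c}" for c in self.covariates)
        for site, sub in df.groupby(site_col):
            both = sub.groupby(subject_col)[region_col].nunique()
            sub = sub[sub[subject_col].isin(both[both == 2].index)]
            if sub.empty or sub[level_col].std() == 0:
                skipped.append(site)
                continue
            sub = sub.rename(columns={level_col: "level"})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = smf.mixedlm(formula, sub, groups=sub[subject_col]).fit(reml=True)
                    beta = float(fit.params["_region01"])
                    se = float(fit.bse["_region01"])
                    p = float(fit.pvalues["_region01"])
                except Exception:
                    skipped.append(site)
                    continue
            if not np.isfinite(se) or se <= 0:
                skipped.append(site)
                continue
            rows.append((site, f"{r0}-vs-{r1}", beta, se, p,
                         sub[subject_col].nunique()))
        table = pd.DataFrame(
            rows, columns=["site_id", "dataset", "beta", "se", "p", "n"]
        )
        table["model_tag"] = "regional_mixed_lm"
        return AssociationResults(
            table=table, model_tag=f"regional_contrast[{r0} vs {r1}]",
            skipped_sites=skipped,
        )


@dataclass
class MetaResults:
    """Stage-II fixed-effects meta-analysis results.

    ``table`` columns: site_id, beta_meta, se_meta, p_meta, k_datasets,
    q_het, p_het, flagged (True for sites observed in < 2 datasets and
    carried forward unmeta-analysed).
    """

    table: pd.DataFrame
    suggestive_p: float
    n_stage1: int
    n_suggestive: int

    @property
    def inflation_lambda(self) -> float:
        ok = self.table[~self.table["flagged"]]
        return genomic_lambda(ok["p_meta"].to_numpy())

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p_meta").head(top)
        lines = [
            f"two-stage meta-analysis: {self.n_stage1} Stage-I sites, "
            f"{self.n_suggestive} suggestive (p <= {self.suggestive_p:g})",
            f"genomic inflation lambda = {self.inflation_lambda:.3f}",
            "",
            t.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class TwoStageMeta:
    """Two-stage scan: suggestive Stage-I sites meta-analysed across datasets.

    Stage I is one dataset's :class:`AssociationResults`; sites with
    Stage-I p ≤ ``suggestive_p`` proceed to the fixed-effects pooling of
    per-dataset (beta, se) across every dataset in ``stage2`` (which, as
    in the original design, includes the Stage-I dataset itself, without
    overlap correction).  Cochran's Q heterogeneity is reported, not used
    for filtering.
    """

    def __init__(
        self,
        stage1: AssociationResults,
        stage2: list[AssociationResults],
        suggestive_p: float = 1e-3,
    ) -> None:
        self.stage1 = stage1
        self.stage2 = stage2
        self.suggestive_p = suggestive_p

    def fit(self) -> MetaResults:
        s1 = self.stage1.table
        chosen = s1.loc[s1["p"] <= self.suggestive_p, "site_id"]
        per_ds = pd.concat([r.table for r in self.stage2], ignore_index=True)
        per_ds = per_ds[per_ds["site_id"].isin(set(chosen))]
        groups = dict(iter(per_ds.groupby("site_id", sort=False)))
        rows = []
        for site in chosen:
            sub = groups.get(site)
            if sub is None:
                continue
            k = len(sub)
            if k < 2:
                rows.append((site, float(sub["beta"].iloc[0]),
                             float(sub["se"].iloc[0]), float(sub["p"].iloc[0]),
                             k, np.nan, np.nan, True))
                continue
            beta, se, p = meta_fixed(sub["beta"], sub["se"])
            w = 1.0 / sub["se"] ** 2
            q = float(np.sum(w * (sub["beta"] - beta) ** 2))
            p_het = float(stats.chi2.sf(q, k - 1))
            rows.append((site, beta, se, p, k, q, p_het, False))
        table = pd.DataFrame(
            rows,
            columns=["site_id", "beta_meta", "se_meta", "p_meta",
                     "k_datasets", "q_het", "p_het", "flagged"],
        )
        return MetaResults(
            table=table,
            suggestive_p=self.suggestive_p,
            n_stage1=len(s1),
            n_suggestive=len(chosen),
        )


def trait_glm(
    trait: pd.Series,
    levels: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: list[str] | None = None,
    trait_name: str | None = None,
) -> AssociationResults:
    """GLM of a quantitative trait on editing level (editing as exposure).

    One fit per site: trait ~ level + covariates; beta is in trait units
    per unit editing level (positive beta = higher trait with more
    editing).  Pathology traits (tangle/amyloid/plaque burden) and the
    cognitive slope are the intended outcomes.
    """
    covariates = list(covariates or [])
    name = trait_name or (trait.name or "trait")
    trait = trait.loc[levels.index]
    if trait.dropna().std() == 0:
        raise ValueError(f"trait {name!r} has zero variance")
    pheno = phenotypes.loc[levels.index]
    need = pheno[covariates].notna().all(axis=1) if covariates else pd.Series(
        True, index=levels.index
    )
    complete = need & trait.notna()
    n_dropped = int((~complete).sum())
    base_X = _design_matrix(pheno[complete], covariates)
    y_all = trait[complete].to_numpy(dtype=float)
    rows, skipped = [], []
    for site in levels.columns:
        lv = levels.loc[complete, site]
        ok = lv.notna().to_numpy()
        X = base_X[ok].copy()
        X.insert(1, "level", lv[ok].to_numpy(dtype=float))
        if ok.sum() < X.shape[1] + 2 or lv[ok].std() == 0:
            skipped.append(site)
            continue
        b, se, p, _ = _multi_ols(y_all[ok, None], X.to_numpy(dtype=float), 1)
        rows.append((site, name, float(b[0]), float(se[0]), float(p[0]),
                     int(ok.sum())))
    table = pd.DataFrame(rows, columns=["site_id", "dataset", "beta", "se", "p", "n"])
    table["model_tag"] = f"trait_glm[{name}]"
    return AssociationResults(
        table=table, model_tag=f"trait_glm[{name}]",
        n_dropped_missing=n_dropped, skipped_sites=skipped,
    )


def classify_cis_effect(p: float, beta: float, genome_wide: float) -> str:
    """Direction × significance tier of one cis-effect fit.

    Tiers: "non" (p > 0.05), "nominal" (genome_wide < p ≤ 0.05),
    "genome-wide" (p ≤ genome_wide); prefixed with the sign of beta.
    """
    if p <= genome_wide:
        tier = "genome-wide"
    elif p <= 0.05:
        tier = "nominal"
    else:
        tier = "non"
    sign = "positive" if beta >= 0 else "negative"
    return f"{sign},{tier}"


def cis_effect(
    status: pd.DataFrame,
    expression: pd.DataFrame,
    phenotypes: pd.DataFrame,
    pairs: list[tuple[str, str]],
    covariates: list[str] | None = None,
    genome_wide: float | None = None,
) -> AssociationResults:
    """Cis-effect GLMs: expression of the annotated gene on binary editing status.

    ``status`` is samples × sites with 0/1 editing presence; ``pairs``
    maps each site to its expression column.  Sites with constant status
    are skipped and counted.  Each fit's effect class (direction ×
    significance tier) lands in an ``effect_class`` column.
    """
    covariates = list(covariates or [])
    if genome_wide is None:
        genome_wide = bonferroni_threshold(max(len(pairs), 1))
    pheno = phenotypes.loc[status.index]
    base_X = _design_matrix(pheno, covariates)
    rows, skipped = [], []
    for site, expr_col in pairs:
        st = status[site]
        ex = expression[expr_col].loc[status.index]
        ok = st.notna() & ex.notna() & base_X.notna().all(axis=1)
        if st[ok].nunique() < 2:
            skipped.append(site)
            continue
        X = base_X[ok.to_numpy()].copy()
        X.insert(1, "status", st[ok].to_numpy(dtype=float))
        b, se, p, _ = _multi_ols(
            ex[ok].to_numpy(dtype=float)[:, None], X.to_numpy(dtype=float), 1
        )
        rows.append((site, expr_col, float(b[0]), float(se[0]), float(p[0]),
                     int(ok.sum())))
    table = pd.DataFrame(rows, columns=["site_id", "dataset", "beta", "se", "p", "n"])
    table["model_tag"] = "cis_effect_glm"
    table["effect_class"] = [
        classify_cis_effect(p_, b_, genome_wide)
        for p_, b_ in zip(table["p"], table["beta"])
    ]
    return AssociationResults(
        table=table, model_tag="cis_effect_glm", skipped_sites=skipped
    )


def cis_effect_region_summary(
    results: AssociationResults, annotations: pd.Series
) -> pd.DataFrame:
    """Counts of cis-effect classes within each genomic-region annotation."""
    t = results.table.copy()
    t["region"] = annotations.reindex(t["site_id"]).to_numpy()
    out = (
        t.groupby(["region", "effect_class"]).size().rename("count").reset_index()
    )
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def top_event_pcs(levels: pd.DataFrame, k: int = 7) -> PCAResult:
    """Principal components of standardised editing levels of the top events.

    Columns are standardised to mean 0 / SD 1 before the decomposition and
    ``k`` components are returned with explained-variance fractions
    summing to 1 over all components.  Signs are fixed so the largest-
    magnitude loading of each component is positive.
    """
    if k > levels.shape[1]:
        raise ValueError(f"k = {k} exceeds the {levels.shape[1]} available events")
    if levels.isna().any().any():
        raise ValueError("complete cases required: drop subjects with missing levels")
    Z = (levels - levels.mean()) / levels.std(ddof=1)
    U, S, Vt = np.linalg.svd(Z.to_numpy(dtype=float), full_matrices=False)
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = S**2 / np.sum(S**2)
    names = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame((U * S)[:, :k], index=levels.index, columns=names[:k])
    loadings = pd.DataFrame(Vt[:k].T, index=levels.columns, columns=names[:k])
    return PCAResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=var[:k])
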