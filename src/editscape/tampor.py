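"""TAMPOR: batch-wise median-polish normalisation of TMT peptide abundances.

Each iteration applies, per peptide and sample, the two-term correction

    abundance / median(GIS of the sample's batch)
      × grand median of batch medians / median(centred abundances of the batch)

where the first-term denominator is the batch's pooled global-internal-
standard (GIS) channels and the second-term median runs over the batch's
case (non-GIS) samples; the matrix is then log2-transformed, each sample
column is centred on its median log2 ratio, anti-logged, and rows are
rescaled to the row-wise geometric means extracted before the first
iteration.  Iteration continues until the largest entry-wise relative
change falls below tolerance.  The surrounding steps — the ≥50%-missing
cull that spares editing-specific peptides, connectivity-based sample
outlier removal, and edited/non-edited within-sample ratios — live here
too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AbundanceMatrix:
    """Peptides × samples abundance matrix with batch and GIS annotations.

    ``values`` holds positive abundances with NaN for missing entries;
    ``batch`` labels each sample column; ``is_gis`` flags the pooled
    global-internal-standard channels; ``is_edited`` flags peptides that
    arise only from RNA-edited proteoforms.
    """

    values: pd.DataFrame
    batch: pd.Series
    is_gis: pd.Series
    is_edited: pd.Series | None = None

    def __post_init__(self) -> None:
        self.batch = pd.Series(self.batch).reindex(self.values.columns)
        self.is_gis = pd.Series(self.is_gis).reindex(self.values.columns).astype(bool)
        if self.batch.isna().any():
            raise ValueError("every sample column needs a batch label")
        if self.is_edited is None:
            self.is_edited = pd.Series(False, index=self.values.index)
        else:
            self.is_edited = (
                pd.Series(self.is_edited).reindex(self.values.index).fillna(False).astype(bool)
            )
        for b, cols in self.batch.groupby(self.batch):
            if not self.is_gis[cols.index].any():
                raise ValueError(f"batch {b!r} has no GIS channel")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("abundances must be positive where present")

    @property
    def batches(self) -> list:
        return list(pd.unique(self.batch))

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(), self.batch.copy(), self.is_gis.copy(),
            self.is_edited.copy(),
        )


def cull_missing(
    matrix: AbundanceMatrix, max_missing: float = 0.50
) -> tuple[AbundanceMatrix, dict[str, int]]:
    """Drop peptides with ≥ ``max_missing`` missing values across all samples.

    Editing-specific peptides are kept regardless of missingness, since
    they are sparse by nature and are the object of study.
    """
    frac_missing = matrix.values.isna().mean(axis=1)
    drop = (frac_missing >= max_missing) & ~matrix.is_edited
    kept = matrix.values.loc[~drop]
    report = {
        "peptides_in": int(len(matrix.values)),
        "peptides_dropped": int(drop.sum()),
        "edited_retained_despite_missing": int(
            ((frac_missing >= max_missing) & matrix.is_edited).sum()
        ),
        "peptides_out": int(len(kept)),
    }
    out = AbundanceMatrix(kept, matrix.batch, matrix.is_gis,
                          matrix.is_edited.loc[kept.index])
    return out, report


def _row_geomean(values: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean over present entries."""
    with np.errstate(invalid="ignore"):
        return np.exp(np.nanmean(np.log(values), axis=1))


@dataclass
class TamporResults:
    """Corrected matrix plus the convergence trace of the polish."""

    corrected: AbundanceMatrix
    raw: AbundanceMatrix
    trace: list[float]
    converged: bool
    n_iter: int
    gis_mode: bool

    def estimated_batch_factors(self) -> pd.Series:
        """Per-batch multiplicative factor removed, relative to the first batch.

        The median raw/corrected ratio over a batch's GIS entries estimates
        the scale the polish took out of that batch; GIS channels are used
        because they are replicates of one pool, free of sample effects.
        """
        ratio = self.raw.values / self.corrected.values
        out = {}
        for b in self.raw.batches:
            cols = self.raw.batch[(self.raw.batch == b) & self.raw.is_gis].index
            out[b] = float(np.nanmedian(ratio[cols].to_numpy()))
        s = pd.Series(out)
        return s / s.iloc[0]

    def batch_median_table(self) -> pd.DataFrame:
        """Per-row medians of the corrected matrix within each batch."""
        meds = {}
        for b in self.corrected.batches:
            cols = self.corrected.batch[self.corrected.batch == b].index
            meds[b] = self.corrected.values[cols].median(axis=1)
        return pd.DataFrame(meds)

    def summary(self) -> str:
        dev = self.batch_median_table()
        spread = float(np.nanmax(dev.max(axis=1) / dev.min(axis=1))) if len(dev) else float("nan")
        lines = [
            "TAMPOR normalisation",
            "--------------------",
            f"peptides x samples : {self.corrected.values.shape[0]} x {self.corrected.values.shape[1]}",
            f"batches            : {len(self.corrected.batches)}",
            f"GIS-restricted     : {self.gis_mode}",
            f"iterations         : {self.n_iter} ({'converged' if self.converged else 'NOT converged'})",
            f"final max rel change: {self.trace[-1]:.3e}" if self.trace else "no iterations run",
            f"max post-correction batch-median ratio: {spread:.6f}",
        ]
        return "\n".join(lines)


class Tampor:
    """Iterated two-way median polish removing batch-specific variance.

    Parameters
    ----------
    matrix : AbundanceMatrix
        Culled abundance matrix with batch and GIS labels.
    gis_mode : bool
        When True (default) the first-term denominator is the median over
        the batch's GIS channels and the second-term median over its case
        samples; when False both run over all samples of the batch.
    tol : float
        Convergence tolerance on the maximum entry-wise relative change.
    max_iter : int
        Iteration cap; non-convergence is flagged on the results, with a
        warning, never silently.
    """

    def __init__(
        self,
        matrix: AbundanceMatrix,
        gis_mode: bool = True,
        tol: float = 1e-8,
        max_iter: int = 250,
    ) -> None:
        self.matrix = matrix
        self.gis_mode = gis_mode
        self.tol = tol
        self.max_iter = max_iter

    def fit(self) -> TamporResults:
        raw = self.matrix
        A = raw.values.to_numpy(dtype=float).copy()
        cols = raw.values.columns
        batches = raw.batches
        batch_of = raw.batch.to_numpy()
        gis = raw.is_gis.to_numpy()

        first_cols = {}   # column masks for the first-term median
        second_cols = {}  # column masks for the second-term median
        for b in batches:
            in_b = batch_of == b
            if self.gis_mode:
                first_cols[b] = in_b & gis
                case = in_b & ~gis
                second_cols[b] = case if case.any() else in_b
            else:
                first_cols[b] = in_b
                second_cols[b] = in_b

        g = _row_geomean(A)
        trace: list[float] = []
        converged = False
        n_iter = 0
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # rows whose GIS channels are all missing in a batch legitimately
            # produce all-NaN medians; the entries stay missing
            warnings.filterwarnings("ignore", message="All-NaN slice")
            warnings.filterwarnings("ignore", message="Mean of empty slice")
            for n_iter in range(1, self.max_iter + 1):
                R = np.empty_like(A)
                d = np.empty((A.shape[0], len(batches)))
                for j, b in enumerate(batches):
                    m1 = np.nanmedian(A[:, first_cols[b]], axis=1)
                    in_b = batch_of == b
                    R[:, in_b] = A[:, in_b] / m1[:, None]
                    d[:, j] = np.nanmedian(R[:, second_cols[b]], axis=1)
                grand = np.nanmedian(d, axis=1)
                for j, b in enumerate(batches):
                    in_b = batch_of == b
                    R[:, in_b] *= (grand / d[:, j])[:, None]
                L = np.log2(R)
                L -= np.nanmedian(L, axis=0)[None, :]
                R = 2.0 ** L
                # restore the row-wise geometric means extracted up front
                A_new = R / _row_geomean(R)[:, None] * g[:, None]
                delta = np.nanmax(np.abs(A_new - A) / np.abs(A))
                trace.append(float(delta))
                A = A_new
                if delta < self.tol:
                    converged = True
                    break
        if not converged:
            warnings.warn(
                f"TAMPOR did not converge in {self.max_iter} iterations "
                f"(last max relative change {trace[-1]:.3e})",
                stacklevel=2,
            )
        corrected = AbundanceMatrix(
            pd.DataFrame(A, index=raw.values.index, columns=cols),
            raw.batch, raw.is_gis, raw.is_edited,
        )
        return TamporResults(
            corrected=corrected, raw=raw, trace=trace,
            converged=converged, n_iter=n_iter, gis_mode=self.gis_mode,
        )


def connectivity_outliers(
    values: pd.DataFrame,
    z_cut: float = 3.0,
    log_transform: bool = True,
) -> list[str]:
    """Samples whose network connectivity is beyond ``z_cut`` SD from the mean.

    Connectivity is the per-sample sum of pairwise Pearson correlations of
    log2 abundances over shared-present peptides.  After an initial pass,
    flagged samples are removed and the criterion re-applied once.  Fewer
    than four samples is refused; zero connectivity variance flags nothing.
    """
    if values.shape[1] < 4:
        raise ValueError("need at least 4 samples for connectivity outlier removal")

    def _flag(df: pd.DataFrame) -> list[str]:
        x = np.log2(df) if log_transform else df
        corr = x.corr(method="pearson", min_periods=2)
        connectivity = corr.sum(axis=1) - 1.0  # drop self-correlation
        sd = connectivity.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return []
        z = (connectivity - connectivity.mean()) / sd
        return list(z.index[np.abs(z) > z_cut])

    flagged = _flag(values)
    if flagged:
        remaining = values.drop(columns=flagged)
        if remaining.shape[1] >= 4:
            flagged += _flag(remaining)
    return flagged


def edited_ratio(
    matrix: AbundanceMatrix,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-sample edited/non-edited abundance ratios for peptide pairs.

    Each row is one (edited, unedited-counterpart) pair; the ratio is
    missing wherever either member is.  Because relative TMT abundances
    carry peptide-specific ionisation efficiencies, these ratios compare
    samples within a pair only — never across different pairs.
    """
    rows = {}
    for edited, unedited in pairs:
        if edited not in matrix.values.index or unedited not in matrix.values.index:
            raise KeyError(f"pair ({edited}, {unedited}) not in matrix")
        rows[f"{edited}/{unedited}"] = matrix.values.loc[edited] / matrix.values.loc[unedited]
    out = pd.DataFrame(rows).T
    out.index.name = "pair"
    return out
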