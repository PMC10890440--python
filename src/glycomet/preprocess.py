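"""Data preparation: sum normalization, presence filtering, percent change,
standardization, half-minimum imputation, and covariate residualization.

Order of operations used by the pipeline: normalize -> presence-filter ->
impute -> (for scans) percent change on the normalized positive abundances
-> standardize the exposure last. Standardization last because the percent
change of a mean-zero variable is ill-defined.

The stateful steps are also exposed as scikit-learn style transformers
(:class:`SumNormalizer`, :class:`PresenceFilter`,
:class:`CovariateResidualizer`) so they compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import GROUPS, DataError, MetaboliteMatrix

#: Clinical covariates adjusted for throughout (scans and networks).
COVARIATE_COLUMNS = ("female", "age", "bmi_baseline", "weight_loss")


def sum_normalize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Divide each sample by its summed intensity over *known* metabolites.

    After normalization the known metabolites of every sample sum to 1.
    Idempotent. Raises :class:`DataError` naming the first sample whose
    known-metabolite sum is zero (or all-missing).
    """
    known = matrix.known_ids
    if len(known) == 0:
        raise DataError("no known metabolites to normalize against")
    sums = matrix.values.loc[:, known].sum(axis=1, min_count=1)
    bad = sums.isna() | (sums <= 0)
    if bad.any():
        raise DataError(
            f"sample {bad.idxmax()!r} has zero summed intensity over known metabolites")
    out = matrix.copy()
    out.values = out.values.div(sums, axis=0)
    return out


def presence_filter(
    matrix: MetaboliteMatrix,
    threshold: float = 0.5,
    groups: pd.Series | None = None,
) -> MetaboliteMatrix:
    """Keep metabolites present (non-missing, > 0) in >= ``threshold`` of the
    samples of *every* group.

    ``groups`` defaults to the matrix's own sample->group annotation. The
    retained set is invariant to sample order.
    """
    if not (0.0 <= threshold <= 1.0):
        raise DataError("threshold must be a fraction in [0, 1]")
    if groups is None:
        groups = matrix.group_of_samples()
    groups = groups.reindex(matrix.values.index)
    if groups.isna().any():
        raise DataError("every sample must be mapped to a group")
    present = matrix.values.notna() & (matrix.values > 0)
    frac = present.groupby(groups.to_numpy()).mean()
    if frac.empty:
        raise DataError("no groups found")
    if threshold == 0:
        keep = (present.groupby(groups.to_numpy()).sum() >= 1).all(axis=0)
    else:
        keep = (frac >= threshold).all(axis=0)
    return matrix.subset_features(matrix.values.columns[keep])


def impute_half_min(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace missing values by half the metabolite's minimum observed value
    (limit-of-detection convention). Columns with no observed value raise."""
    out = matrix.copy()
    if not out.values.isna().any().any():
        return out
    mins = out.values.min(axis=0, skipna=True)
    if mins.isna().any():
        raise DataError("cannot impute a metabolite with no observed values")
    out.values = out.values.fillna(mins / 2.0)
    return out


def percent_change(baseline, followup):
    """(follow-up - baseline) / baseline; baseline must be > 0.

    Works elementwise on arrays/Series.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if (baseline <= 0).any():
        raise DataError("percent change undefined for baseline <= 0")
    out = (followup - baseline) / baseline
    return float(out) if out.ndim == 0 else out


def standardize(x) -> np.ndarray:
    """Center to mean 0 and scale to unit sample SD (ddof=1).

    Constant vectors raise; idempotent; affine-equivariant up to sign.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DataError("standardize needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataError("cannot standardize a constant (or non-finite) vector")
    return (x - x.mean()) / sd


def residualize(X: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each column of ``X`` by its OLS residual on the covariates.

    An intercept is always included. Residuals are orthogonal to every
    covariate column; the operation is a projection (idempotent). Raises on
    rank-deficient designs, listing the collinear columns.
    """
    if not X.index.equals(covariates.index):
        covariates = covariates.reindex(X.index)
        if covariates.isna().any().any():
            raise DataError("covariate rows do not align with samples")
    C = np.column_stack([np.ones(len(X)), covariates.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify columns whose removal restores full rank
        cols = ["intercept", *covariates.columns]
        collinear = [
            cols[j] for j in range(C.shape[1])
            if np.linalg.matrix_rank(np.delete(C, j, axis=1)) == rank
        ]
        raise DataError(f"rank-deficient covariate design; collinear columns: {collinear}")
    Y = X.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return pd.DataFrame(Y - C @ beta, index=X.index, columns=X.columns)


def weight_loss_fraction(cohort: pd.DataFrame) -> pd.Series:
    """Fractional body-weight change (follow-up - baseline)/baseline.

    Negative when weight is lost; this signed fraction is the "weight loss"
    covariate used in all adjusted models.
    """
    return pd.Series(
        percent_change(cohort["weight_baseline"], cohort["weight_year1"]),
        index=cohort.index, name="weight_loss",
    )


def covariate_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-participant covariates: sex (female), age, baseline BMI, weight loss."""
    return pd.DataFrame(
        {
            "female": cohort["female"].astype(float),
            "age": cohort["age"].astype(float),
            "bmi_baseline": cohort["bmi_baseline"].astype(float),
            "weight_loss": weight_loss_fraction(cohort),
        },
        index=cohort.index,
    )


def build_change_table(matrix: MetaboliteMatrix, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-participant percent changes: glycemic outcomes, weight loss, and
    every metabolite (on the supplied — normally normalized — matrix)."""
    base = matrix.timepoint_values("baseline")
    year1 = matrix.timepoint_values("year1")
    cohort = cohort.loc[base.index]
    out = pd.DataFrame(
        {
            "pct_change_fpg": percent_change(cohort["fpg_baseline"], cohort["fpg_year1"]),
            "pct_change_hba1c": percent_change(
                cohort["hba1c_baseline"], cohort["hba1c_year1"]),
            "weight_loss": weight_loss_fraction(cohort),
        },
        index=base.index,
    )
    met = (year1 - base) / base
    return pd.concat([out, met], axis=1)


# -- sklearn-style transformer facade ---------------------------------------


class SumNormalizer(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`sum_normalize`."""

    def fit(self, X: MetaboliteMatrix, y=None):
        self.n_features_in_ = X.n_metabolites
        return self

    def transform(self, X: MetaboliteMatrix) -> MetaboliteMatrix:
        return sum_normalize(X)


class PresenceFilter(BaseEstimator, TransformerMixin):
    """Learns the retained metabolite set on fit; transform subsets."""

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold

    def fit(self, X: MetaboliteMatrix, y=None):
        self.retained_ = presence_filter(X, self.threshold).values.columns
        return self

    def transform(self, X: MetaboliteMatrix) -> MetaboliteMatrix:
        return X.subset_features(self.retained_)


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """Learns OLS coefficients of each feature on the covariates at fit time
    and subtracts the fitted values on transform.

    ``fit_transform(X, covariates=C)`` on the same data reproduces
    :func:`residualize` exactly.
    """

    def fit(self, X: pd.DataFrame, y=None, covariates: pd.DataFrame = None):
        if covariates is None:
            raise DataError("covariates are required")
        res = residualize(X, covariates)  # validates rank/alignment
        C = np.column_stack([np.ones(len(X)), covariates.to_numpy(dtype=float)])
        self.coef_, *_ = np.linalg.lstsq(C, X.to_numpy(dtype=float), rcond=None)
        self.covariate_columns_ = list(covariates.columns)
        self._fit_residuals = res
        return self

    def transform(self, X: pd.DataFrame, covariates: pd.DataFrame = None) -> pd.DataFrame:
        if covariates is None:
            raise DataError("covariates are required")
        C = np.column_stack([np.ones(len(X)), covariates.to_numpy(dtype=float)])
        return pd.DataFrame(
            X.to_numpy(dtype=float) - C @ self.coef_, index=X.index, columns=X.columns)

    def fit_transform(self, X, y=None, covariates: pd.DataFrame = None):
        self.fit(X, covariates=covariates)
        return self._fit_residuals
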