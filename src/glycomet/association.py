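"""Per-metabolite treatment-by-metabolite interaction regression scans.

For each metabolite, one pooled OLS model is fitted:

    y ~ 1 + m + G + m:G + covariates

where y is the percent change in a glycemic outcome (FPG or HbA1c), m is
the standardized exposure (baseline metabolite level, or its percent
change), and G are intervention-group indicators with IMI as reference.
The within-group slope is beta*(g) = beta_m + delta_g and the pairwise
contrast beta-dagger(g2 vs g1) = delta_{g2} - delta_{g1}; every contrast
(including RYGB vs BAND) comes from the same fit via the linear-combination
rule on the coefficient covariance, so the three contrasts are mutually
consistent by subtraction.

Multiple testing across metabolites is controlled with Storey q-values,
computed separately within each outcome x contrast family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import DataError, MetaboliteMatrix
from .preprocess import COVARIATE_COLUMNS, covariate_frame, percent_change, standardize

GROUP_ORDER = ("IMI", "BAND", "RYGB")

OUTCOME_COLUMNS = {
    "fpg": ("fpg_baseline", "fpg_year1"),
    "hba1c": ("hba1c_baseline", "hba1c_year1"),
}


@dataclass
class ScanSpec:
    """Configuration of one scan: outcome, exposure and adjustment set."""

    outcome: str = "fpg"                  # 'fpg' or 'hba1c' (percent change)
    exposure: str = "baseline"            # 'baseline' or 'change'
    covariates: tuple[str, ...] = COVARIATE_COLUMNS
    reference_group: str = "IMI"
    extra_covariates: tuple[str, ...] = ()  # e.g. a hypoglycemic-drug flag

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise DataError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
        if self.exposure not in ("baseline", "change"):
            raise DataError("exposure must be 'baseline' or 'change'")

    @property
    def name(self) -> str:
        return f"{self.exposure}_{self.outcome}"


@dataclass
class AssociationRecord:
    metabolite: str
    outcome: str
    beta_star: dict[str, tuple[float, float]]          # group -> (est, se)
    contrasts: dict[str, tuple[float, float, float]]   # 'A_vs_B' -> (est, se, p)
    n_obs: int = 0
    error: str | None = None


def _group_sequence(groups: pd.Series, reference: str) -> list[str]:
    present = list(pd.unique(groups))
    if reference not in present:
        raise DataError(f"reference group {reference!r} absent from data")
    ordered = [g for g in GROUP_ORDER if g in present]
    ordered += sorted(g for g in present if g not in GROUP_ORDER)
    return [reference] + [g for g in ordered if g != reference]


def fit_interaction_model(
    y,
    m,
    group,
    covariates: pd.DataFrame | None = None,
    reference: str = "IMI",
    metabolite: str = "",
    outcome: str = "",
) -> AssociationRecord:
    """Fit the pooled interaction model and return slopes and contrasts.

    Parameters are aligned vectors (observations = participants). Raises
    :class:`DataError` for rank-deficient designs, groups with fewer than 3
    observations, or a group whose exposure has zero variance.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    group = pd.Series(np.asarray(group, dtype=object))
    seq = _group_sequence(group, reference)

    for g in seq:
        mg = m[(group == g).to_numpy()]
        if mg.size < 3:
            raise DataError(f"group {g} has fewer than 3 observations")
        if np.ptp(mg) == 0:
            raise DataError(f"group {g} has constant exposure")

    cols = ["const", "m"]
    blocks = [np.ones_like(m), m]
    for g in seq[1:]:
        ind = (group == g).to_numpy(dtype=float)
        blocks += [ind, m * ind]
        cols += [f"g_{g}", f"m:g_{g}"]
    if covariates is not None and covariates.shape[1] > 0:
        blocks += [covariates.to_numpy(dtype=float).T[i] for i in range(covariates.shape[1])]
        cols += list(covariates.columns)
    X = np.column_stack(blocks)
    if y.size < X.shape[1] + 1:
        raise DataError("too few observations for the model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("rank-deficient design matrix")

    res = sm.OLS(y, pd.DataFrame(X, columns=cols)).fit()
    params = res.params
    cov = res.cov_params()
    df_resid = int(res.df_resid)

    def combo(vec: dict[str, float]) -> tuple[float, float]:
        c = np.array([vec.get(col, 0.0) for col in cols])
        est = float(c @ params.to_numpy())
        var = float(c @ cov.to_numpy() @ c)
        return est, float(np.sqrt(max(var, 0.0)))

    beta_star: dict[str, tuple[float, float]] = {}
    delta_vec: dict[str, dict[str, float]] = {}
    for g in seq:
        vec = {"m": 1.0}
        if g != reference:
            vec[f"m:g_{g}"] = 1.0
        beta_star[g] = combo(vec)
        delta_vec[g] = {} if g == reference else {f"m:g_{g}": 1.0}

    def rank(g: str) -> int:
        return GROUP_ORDER.index(g) if g in GROUP_ORDER else len(GROUP_ORDER)

    contrasts: dict[str, tuple[float, float, float]] = {}
    for i, g2 in enumerate(seq):
        for g1 in seq[:i]:
            # canonical direction: later group in GROUP_ORDER vs earlier
            a, b = (g2, g1) if rank(g2) >= rank(g1) else (g1, g2)
            vec = dict(delta_vec[a])
            for k, v in delta_vec[b].items():
                vec[k] = vec.get(k, 0.0) - v
            est, se = combo(vec)
            if se > 0 and df_resid > 0:
                p = float(2.0 * stats.t.sf(abs(est / se), df_resid))
            else:
                p = float("nan")
            contrasts[f"{a}_vs_{b}"] = (est, se, p)

    return AssociationRecord(
        metabolite=metabolite, outcome=outcome, beta_star=beta_star,
        contrasts=contrasts, n_obs=int(y.size),
    )


# ---------------------------------------------------------------------------


def estimate_pi0(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's null-proportion estimate via the lambda-grid smoother.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a grid
    lambda = 0.05, 0.10, ..., 0.95; a cubic least-squares smooth of
    pi0(lambda) is evaluated at the largest lambda and clamped to (0, 1].
    For short vectors (m < 100) the smoother is unstable and pi0 = 1 is
    returned (the Benjamini-Hochberg limit).
    """
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    if m < 100:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(pvals > lam).mean() / (1.0 - lam) for lam in lambdas])
    coef = np.polynomial.polynomial.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(lambdas.max(), coef))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(pvals, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = pi0 * min_{p_j >= p_i} (m p_j / rank_j).

    With ``pi0=1`` this reduces exactly to Benjamini-Hochberg adjusted
    p-values. Output is monotone nondecreasing in p and clipped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise DataError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not (0.0 < pi0 <= 1.0):
        raise DataError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------

CONTRAST_NAMES = ("RYGB_vs_IMI", "RYGB_vs_BAND", "BAND_vs_IMI")


def scan_columns(contrast_names=CONTRAST_NAMES, groups=GROUP_ORDER) -> list[str]:
    cols = ["known"]
    cols += [f"beta_star_{g.lower()}" for g in groups]
    cols += [f"se_star_{g.lower()}" for g in groups]
    cols += [f"beta_{c.lower()}" for c in contrast_names]
    cols += [f"se_{c.lower()}" for c in contrast_names]
    cols += [f"p_{c.lower()}" for c in contrast_names]
    cols += [f"q_{c.lower()}" for c in contrast_names]
    cols += ["error"]
    return cols


def run_scan(
    cohort: pd.DataFrame,
    matrix: MetaboliteMatrix,
    spec: ScanSpec,
) -> pd.DataFrame:
    """Scan every metabolite of a preprocessed matrix under one ScanSpec.

    Returns one row per metabolite (fixed column order: known flag, three
    beta*, three SE, three contrasts beta-dagger with SE/p/q, error flag).
    Metabolites whose fit fails are flagged in the ``error`` column and
    excluded from the q-value families, never silently dropped.
    """
    if matrix.n_metabolites == 0:
        raise DataError("empty metabolite set")
    base_col, year_col = OUTCOME_COLUMNS[spec.outcome]
    base = matrix.timepoint_values("baseline")
    cohort = cohort.loc[base.index]
    y = percent_change(cohort[base_col], cohort[year_col])
    groups = cohort["group"]

    cov = covariate_frame(cohort)[[c for c in spec.covariates if c != "group"]]
    for extra in spec.extra_covariates:
        cov[extra] = cohort[extra].astype(float)

    if spec.exposure == "baseline":
        expo = base
    else:
        year1 = matrix.timepoint_values("year1")
        expo = (year1 - base) / base

    records: dict[str, AssociationRecord] = {}
    for met in expo.columns:
        x = expo[met].to_numpy(dtype=float)
        try:
            if np.ptp(x) == 0:
                raise DataError("constant exposure")
            rec = fit_interaction_model(
                y, standardize(x), groups, covariates=cov,
                reference=spec.reference_group, metabolite=met, outcome=spec.outcome,
            )
        except DataError as exc:
            rec = AssociationRecord(met, spec.outcome, {}, {}, n_obs=len(y), error=str(exc))
        records[met] = rec

    rows = {}
    for met, rec in records.items():
        row: dict[str, object] = {"known": bool(matrix.feature_meta.loc[met, "known"])}
        for g in GROUP_ORDER:
            est, se = rec.beta_star.get(g, (np.nan, np.nan))
            row[f"beta_star_{g.lower()}"] = est
            row[f"se_star_{g.lower()}"] = se
        for c in CONTRAST_NAMES:
            est, se, p = rec.contrasts.get(c, (np.nan, np.nan, np.nan))
            row[f"beta_{c.lower()}"] = est
            row[f"se_{c.lower()}"] = se
            row[f"p_{c.lower()}"] = p
        row["error"] = rec.error or ""
        rows[met] = row
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("metabolite")

    for c in CONTRAST_NAMES:
        pcol, qcol = f"p_{c.lower()}", f"q_{c.lower()}"
        valid = table[pcol].notna()
        table[qcol] = np.nan
        if valid.any():
            table.loc[valid, qcol] = storey_qvalues(table.loc[valid, pcol].to_numpy())
    return table[scan_columns()]


def volcano_table(scan_table: pd.DataFrame, contrast: str) -> pd.DataFrame:
    """Per-contrast volcano view of a scan table: effect, p, q, known flag."""
    c = contrast.lower()
    if f"beta_{c}" not in scan_table.columns:
        raise DataError(f"unknown contrast {contrast!r}")
    out = scan_table[["known", f"beta_{c}", f"p_{c}", f"q_{c}"]].copy()
    return out.rename(columns={f"beta_{c}": "beta", f"p_{c}": "p", f"q_{c}": "q"})


class InteractionScanner(BaseEstimator):
    """Estimator facade over :func:`run_scan`.

    Parameters mirror :class:`ScanSpec`; after ``fit(matrix, cohort)`` the
    scan table is available as ``results_`` and the flagged metabolites as
    ``failed_``.
    """

    def __init__(self, outcome: str = "fpg", exposure: str = "baseline",
                 reference_group: str = "IMI", extra_covariates: tuple = ()):
        self.outcome = outcome
        self.exposure = exposure
        self.reference_group = reference_group
        self.extra_covariates = extra_covariates

    def fit(self, matrix: MetaboliteMatrix, cohort: pd.DataFrame):
        spec = ScanSpec(
            outcome=self.outcome, exposure=self.exposure,
            reference_group=self.reference_group,
            extra_covariates=tuple(self.extra_covariates),
        )
        self.results_ = run_scan(cohort, matrix, spec)
        self.failed_ = list(self.results_.index[self.results_["error"] != ""])
        self.n_features_in_ = matrix.n_metabolites
        return self
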