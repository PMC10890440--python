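"""Synthetic three-arm weight-loss cohort generator.

Emulates the statistical structure of a longitudinal metabolomics study of
severe obesity with three intervention arms (intensive medical intervention
IMI, adjustable gastric banding BAND, Roux-en-Y gastric bypass RYGB):

* one cohort row per participant with sex, age, baseline BMI, baseline and
  1-year body weight, and baseline/1-year fasting plasma glucose (FPG) and
  HbA1c;
* a sample x metabolite peak-height matrix with two samples per participant
  (baseline, year1), a subset of metabolites flagged "known";
* group-specific correlated metabolite modules (equicorrelated latent
  Gaussian blocks, so differential connectivity between arms is planted by
  construction);
* planted metabolite-by-intervention interaction effects on the
  percent-change glycemic outcomes, on top of a common weight-loss term, so
  the downstream interaction scan has a known truth to recover.

Percent-change outcomes are generated directly from the linear predictor

    pct_change = intercept(group) + sum_e slope_e(group) * exposure_e
                 + weight_loss_coef * weight_change_fraction + noise

where each exposure is the standardized (ddof=1) baseline level or percent
change of one metabolite after sum-normalization to known metabolites —
exactly the variable the association scan later reconstructs, so the fitted
model is the generating model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GROUPS, MetaboliteMatrix

OUTCOMES = ("FPG", "HbA1c")
EXPOSURES = ("baseline", "change")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class PlantedModule:
    """Equicorrelated metabolite block with group-specific correlation."""

    member_ids: tuple[str, ...]
    rho_by_group: dict[str, float]

    def __post_init__(self) -> None:
        self.member_ids = tuple(self.member_ids)
        if len(self.member_ids) < 3:
            raise ConfigurationError("planted module needs >= 3 members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ConfigurationError("duplicate member ids in planted module")
        for g, rho in self.rho_by_group.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if not (0.0 <= rho < 1.0):
                raise ConfigurationError(f"rho must be in [0, 1); got {rho} for {g}")


@dataclass
class PlantedEffect:
    """True per-group slope of a percent-change outcome on one exposure."""

    metabolite_id: str
    outcome: str
    exposure: str
    slope_by_group: dict[str, float]

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ConfigurationError(f"outcome must be one of {OUTCOMES}")
        if self.exposure not in EXPOSURES:
            raise ConfigurationError(f"exposure must be one of {EXPOSURES}")
        for g, b in self.slope_by_group.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if not np.isfinite(b):
                raise ConfigurationError("planted slopes must be finite")


# Table-style cohort moments used as generator defaults: mean fractional
# weight loss, mean percent-change of the glycemic outcomes, and baseline
# medians / BMI means per arm.
DEFAULT_WEIGHT_LOSS = {"IMI": 0.117, "BAND": 0.195, "RYGB": 0.353}
DEFAULT_FPG_PCT_CHANGE = {"IMI": -0.051, "BAND": -0.107, "RYGB": -0.220}
DEFAULT_HBA1C_PCT_CHANGE = {"IMI": -0.070, "BAND": -0.085, "RYGB": -0.236}
DEFAULT_FPG_MEDIAN = {"IMI": 98.0, "BAND": 103.0, "RYGB": 118.0}
DEFAULT_HBA1C_MEDIAN = {"IMI": 5.7, "BAND": 5.9, "RYGB": 7.2}
DEFAULT_BMI_MEAN = {"IMI": 43.3, "BAND": 45.7, "RYGB": 48.5}
DEFAULT_WEIGHT_MEAN = {"IMI": 120.0, "BAND": 123.0, "RYGB": 133.0}
DEFAULT_WEIGHT_SD = {"IMI": 26.0, "BAND": 16.0, "RYGB": 20.0}


def metabolite_id(i: int) -> str:
    return f"M{i + 1:04d}"


def _default_modules() -> list[PlantedModule]:
    ids = [metabolite_id(i) for i in range(40)]
    return [
        # tight co-regulation in RYGB only: a gain-of-connectivity module
        PlantedModule(tuple(ids[0:12]), {"IMI": 0.2, "BAND": 0.2, "RYGB": 0.8}),
        # shared module, similar in all arms
        PlantedModule(tuple(ids[12:22]), {"IMI": 0.6, "BAND": 0.6, "RYGB": 0.6}),
        # loss of connectivity in RYGB
        PlantedModule(tuple(ids[22:30]), {"IMI": 0.7, "BAND": 0.7, "RYGB": 0.1}),
    ]


def _default_effects() -> list[PlantedEffect]:
    return [
        PlantedEffect(metabolite_id(0), "FPG", "baseline",
                      {"IMI": 0.1, "BAND": 0.0, "RYGB": 1.5}),
        PlantedEffect(metabolite_id(30), "HbA1c", "baseline",
                      {"IMI": -0.1, "BAND": 0.15, "RYGB": 0.8}),
        PlantedEffect(metabolite_id(31), "FPG", "change",
                      {"IMI": 0.0, "BAND": 0.1, "RYGB": -0.6}),
    ]


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults emulate the study conditions."""

    n_per_group: int = 25
    n_metabolites: int = 364
    n_known: int = 153
    modules: list[PlantedModule] = field(default_factory=_default_modules)
    effects: list[PlantedEffect] = field(default_factory=_default_effects)
    outcome_noise_sd: float = 0.1
    weight_loss_mean_by_group: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_LOSS))
    weight_loss_sd: float = 0.05
    weight_loss_coef: float = 0.3
    fpg_pct_change_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FPG_PCT_CHANGE))
    hba1c_pct_change_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HBA1C_PCT_CHANGE))
    abundance_log_mean: float = 8.0
    abundance_log_mean_sd: float = 1.0
    abundance_log_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0 or self.n_metabolites <= 0:
            raise ConfigurationError("dimensions must be positive")
        if not (0 < self.n_known <= self.n_metabolites):
            raise ConfigurationError("need 0 < n_known <= n_metabolites")
        if self.outcome_noise_sd <= 0 or self.weight_loss_sd <= 0 \
                or self.abundance_log_sd <= 0:
            raise ConfigurationError("all SDs must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        ids = {metabolite_id(i) for i in range(self.n_metabolites)}
        seen: set[str] = set()
        for mod in self.modules:
            members = set(mod.member_ids)
            if not members <= ids:
                raise ConfigurationError("module references unknown metabolite ids")
            if members & seen:
                raise ConfigurationError("module memberships must be disjoint")
            seen |= members
        for eff in self.effects:
            if eff.metabolite_id not in ids:
                raise ConfigurationError(
                    f"effect references unknown metabolite {eff.metabolite_id!r}")
        for g in GROUPS:
            if g not in self.weight_loss_mean_by_group:
                raise ConfigurationError(f"weight loss mean missing for group {g}")


@dataclass
class GroundTruth:
    """What was planted: needed by recovery tests, emitted as JSON."""

    effects: list[PlantedEffect]
    modules: list[PlantedModule]
    group_intercepts: dict[str, dict[str, float]]
    weight_loss_coef: float

    def module_labels(self, all_ids) -> pd.Series:
        labels = pd.Series("none", index=pd.Index(all_ids), name="planted_module")
        for i, mod in enumerate(self.modules):
            labels.loc[list(mod.member_ids)] = f"planted_{i}"
        return labels

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "modules": [
                {"member_ids": list(m.member_ids), "rho_by_group": m.rho_by_group}
                for m in self.modules
            ],
            "group_intercepts": self.group_intercepts,
            "weight_loss_coef": self.weight_loss_coef,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------


def sample_module_block(
    m: int,
    rho: float,
    n: int,
    rng: np.random.Generator | int,
    log_mean: float = 8.0,
    log_sd: float = 0.5,
) -> np.ndarray:
    """Draw an n x m block of positive abundances with equicorrelated columns.

    Columns share a latent factor: z_j = sqrt(rho) * g + sqrt(1-rho) * e_j
    with g, e_j standard normal, then values are mapped to a positive scale
    as exp(log_mean + log_sd * z). On the log scale the pairwise correlation
    is exactly ``rho``; exponentiation attenuates it slightly (at
    log_sd = 0.5 and rho = 0.8 the abundance-scale correlation is ~0.78).
    """
    if m < 2:
        raise ConfigurationError("module block needs m >= 2 columns")
    if not (0.0 <= rho < 1.0):
        raise ConfigurationError(f"rho must be in [0, 1); got {rho}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    shared = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, m))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
    return np.exp(log_mean + log_sd * z)


def _truncated_normal(rng, mean, sd, low, high, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (size,))
    out = rng.normal(mean, sd)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = (out < low) | (out > high)
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, MetaboliteMatrix, GroundTruth]:
    """Generate (cohort table, metabolite matrix, ground truth).

    Deterministic given ``config.seed``: one seed sequence is spawned into
    per-stage child streams (covariates, matrix, outcomes, missingness).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_mat, rng_out, rng_miss = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    n = config.n_per_group
    participants = [f"P{i + 1:03d}" for i in range(3 * n)]
    group = np.repeat(list(GROUPS), n)

    # --- covariates ---------------------------------------------------------
    age = _truncated_normal(rng_cov, 51.0, 8.0, 21.0, 70.0, 3 * n)
    female = (rng_cov.random(3 * n) < 0.84).astype(int)
    bmi = _truncated_normal(
        rng_cov, np.array([DEFAULT_BMI_MEAN[g] for g in group]), 6.0, 33.0, 75.0, 3 * n)
    weight0 = _truncated_normal(
        rng_cov, np.array([DEFAULT_WEIGHT_MEAN[g] for g in group]),
        np.array([DEFAULT_WEIGHT_SD[g] for g in group]), 60.0, 250.0, 3 * n)
    loss_mean = np.array([config.weight_loss_mean_by_group[g] for g in group])
    loss = np.clip(rng_cov.normal(loss_mean, config.weight_loss_sd), 0.01, 0.60)
    weight1 = weight0 * (1.0 - loss)
    weight_change = (weight1 - weight0) / weight0  # = -loss, the covariate convention

    # --- metabolite matrix ---------------------------------------------------
    met_ids = [metabolite_id(i) for i in range(config.n_metabolites)]
    known = np.zeros(config.n_metabolites, dtype=bool)
    known[: config.n_known] = True
    log_means = rng_mat.normal(config.abundance_log_mean, config.abundance_log_mean_sd,
                               size=config.n_metabolites)

    sample_ids = [f"{p}_{tp}" for p in participants for tp in ("baseline", "year1")]
    sample_part = np.repeat(participants, 2)
    sample_tp = np.tile(["baseline", "year1"], 3 * n)
    sample_group = np.repeat(group, 2)

    values = np.empty((6 * n, config.n_metabolites))
    col_of = {mid: j for j, mid in enumerate(met_ids)}
    in_module = np.zeros(config.n_metabolites, dtype=bool)
    for mod in config.modules:
        cols = [col_of[mid] for mid in mod.member_ids]
        in_module[cols] = True
        for g in GROUPS:
            rows = np.flatnonzero(sample_group == g)
            rho = mod.rho_by_group.get(g, 0.0)
            block = sample_module_block(
                len(cols), rho, rows.size, rng_mat,
                log_mean=0.0, log_sd=1.0)  # positive-scale mapping applied below
            values[np.ix_(rows, cols)] = np.log(block)  # recover latent z
    free = np.flatnonzero(~in_module)
    values[:, free] = rng_mat.standard_normal((6 * n, free.size))
    values = np.exp(log_means[None, :] + config.abundance_log_sd * values)

    if config.missing_rate > 0:
        mask = rng_miss.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = MetaboliteMatrix(
        pd.DataFrame(values, index=sample_ids, columns=met_ids),
        pd.DataFrame(
            {"participant_id": sample_part, "timepoint": sample_tp, "group": sample_group},
            index=sample_ids,
        ),
        pd.DataFrame({"name": met_ids, "known": known}, index=pd.Index(met_ids)),
    )

    # --- outcomes ------------------------------------------------------------
    # exposures rebuilt exactly as the scan will see them: sum-normalize to
    # known metabolites, take baseline level or percent change, standardize
    norm = matrix.values.div(matrix.values.loc[:, matrix.known_ids].sum(axis=1), axis=0)
    base = norm.loc[sample_tp == "baseline"].set_axis(participants, axis=0)
    year1 = norm.loc[sample_tp == "year1"].set_axis(participants, axis=0)

    mean_pct = {"FPG": config.fpg_pct_change_mean, "HbA1c": config.hba1c_pct_change_mean}
    intercepts = {
        out: {g: mean_pct[out][g] + config.weight_loss_coef
              * config.weight_loss_mean_by_group[g] for g in GROUPS}
        for out in OUTCOMES
    }
    lin = {out: np.array([intercepts[out][g] for g in group]) for out in OUTCOMES}
    for out in OUTCOMES:
        lin[out] = lin[out] + config.weight_loss_coef * weight_change
    for eff in config.effects:
        if eff.exposure == "baseline":
            x = base[eff.metabolite_id].to_numpy()
        else:
            b = base[eff.metabolite_id].to_numpy()
            x = (year1[eff.metabolite_id].to_numpy() - b) / b
        x = _standardize(x)
        slopes = np.array([eff.slope_by_group.get(g, 0.0) for g in group])
        lin[eff.outcome] = lin[eff.outcome] + slopes * x

    pct_fpg = lin["FPG"] + rng_out.normal(0.0, config.outcome_noise_sd, 3 * n)
    pct_hba1c = lin["HbA1c"] + rng_out.normal(0.0, config.outcome_noise_sd, 3 * n)

    fpg0 = np.exp(rng_out.normal(
        np.log([DEFAULT_FPG_MEDIAN[g] for g in group]), 0.20))
    hba1c0 = np.exp(rng_out.normal(
        np.log([DEFAULT_HBA1C_MEDIAN[g] for g in group]), 0.08))

    cohort = pd.DataFrame(
        {
            "group": group,
            "female": female,
            "age": age,
            "bmi_baseline": bmi,
            "weight_baseline": weight0,
            "weight_year1": weight1,
            "fpg_baseline": fpg0,
            "fpg_year1": fpg0 * (1.0 + pct_fpg),
            "hba1c_baseline": hba1c0,
            "hba1c_year1": hba1c0 * (1.0 + pct_hba1c),
        },
        index=pd.Index(participants, name="participant_id"),
    )

    truth = GroundTruth(
        effects=list(config.effects),
        modules=list(config.modules),
        group_intercepts=intercepts,
        weight_loss_coef=config.weight_loss_coef,
    )
    return cohort, matrix, truth
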