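"""In-memory containers and file formats shared across the pipeline.

The two central objects are the cohort table (one row per participant,
plain :class:`pandas.DataFrame`) and :class:`MetaboliteMatrix`, a thin
wrapper bundling a sample x metabolite abundance matrix with its sample
and feature annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("IMI", "BAND", "RYGB")
TIMEPOINTS = ("baseline", "year1")

#: Columns of the cohort table, one row per participant (index: participant id).
COHORT_COLUMNS = (
    "group",
    "female",
    "age",
    "bmi_baseline",
    "weight_baseline",
    "weight_year1",
    "fpg_baseline",
    "fpg_year1",
    "hba1c_baseline",
    "hba1c_year1",
)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class MetaboliteMatrix:
    """Sample x metabolite abundance matrix with annotations.

    Parameters
    ----------
    values : DataFrame
        Nonnegative peak heights, rows indexed by sample id, columns by
        metabolite id. NaN marks a missing (undetected) value.
    sample_meta : DataFrame
        Indexed by sample id, columns ``participant_id``, ``timepoint``
        (``baseline`` or ``year1``) and ``group``.
    feature_meta : DataFrame
        Indexed by metabolite id, columns ``name`` and boolean ``known``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.validate:
            self._check()

    def _check(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            raise DataError("values rows and sample_meta index do not align")
        if not self.values.columns.equals(self.feature_meta.index):
            raise DataError("values columns and feature_meta index do not align")
        bad_tp = set(self.sample_meta["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise DataError(f"unknown timepoints: {sorted(bad_tp)}")
        counts = self.sample_meta.groupby("participant_id")["timepoint"].nunique()
        per = self.sample_meta.groupby("participant_id").size()
        if not ((counts == 2).all() and (per == 2).all()):
            offenders = sorted(per.index[(per != 2) | (counts != 2)])
            raise DataError(
                f"each participant needs exactly one baseline and one year1 sample; "
                f"offenders: {offenders[:5]}"
            )
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise DataError("abundances must be nonnegative where present")
        if self.feature_meta["known"].dtype != bool:
            self.feature_meta = self.feature_meta.assign(
                known=self.feature_meta["known"].astype(bool)
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def known_ids(self) -> pd.Index:
        return self.feature_meta.index[self.feature_meta["known"]]

    @property
    def participants(self) -> pd.Index:
        return pd.Index(self.sample_meta["participant_id"].unique())

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.values.copy(), self.sample_meta.copy(), self.feature_meta.copy(),
            validate=False,
        )

    def subset_features(self, ids) -> "MetaboliteMatrix":
        ids = pd.Index(ids)
        return MetaboliteMatrix(
            self.values.loc[:, ids], self.sample_meta, self.feature_meta.loc[ids],
            validate=False,
        )

    def timepoint_values(self, timepoint: str) -> pd.DataFrame:
        """Values at one timepoint, re-indexed by participant id."""
        if timepoint not in TIMEPOINTS:
            raise DataError(f"unknown timepoint {timepoint!r}")
        mask = self.sample_meta["timepoint"] == timepoint
        out = self.values.loc[mask].copy()
        out.index = self.sample_meta.loc[mask, "participant_id"]
        return out.sort_index()

    def group_of_samples(self) -> pd.Series:
        return self.sample_meta["group"]

    # -- IO --------------------------------------------------------------------

    def write(self, out_dir: str | Path, prefix: str = "metabolites") -> dict[str, Path]:
        """Write matrix CSV plus annotation TSV; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        matrix_path = out_dir / f"{prefix}_matrix.csv"
        ann_path = out_dir / f"{prefix}_annotations.tsv"
        self.values.rename_axis("sample_id").to_csv(matrix_path)
        ann = self.sample_meta.rename_axis("sample_id").reset_index()
        feat = self.feature_meta.rename_axis("metabolite_id").reset_index()
        with open(ann_path, "w") as fh:
            fh.write("#samples\n")
            ann.to_csv(fh, sep="\t", index=False)
            fh.write("#features\n")
            feat.to_csv(fh, sep="\t", index=False)
        return {"matrix": matrix_path, "annotations": ann_path}

    @classmethod
    def read(cls, matrix_path: str | Path, annotations_path: str | Path) -> "MetaboliteMatrix":
        values = pd.read_csv(matrix_path, index_col=0)
        text = Path(annotations_path).read_text().splitlines()
        split = text.index("#features")
        ann = pd.read_csv(
            pd.io.common.StringIO("\n".join(text[1:split])), sep="\t", index_col="sample_id"
        )
        feat = pd.read_csv(
            pd.io.common.StringIO("\n".join(text[split + 1:])), sep="\t",
            index_col="metabolite_id",
        )
        feat["known"] = feat["known"].astype(bool)
        return cls(values, ann.loc[values.index], feat.loc[values.columns])


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, index_col=0)
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise DataError(f"cohort table missing columns: {sorted(missing)}")
    return cohort


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.rename_axis("participant_id").to_csv(path)
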