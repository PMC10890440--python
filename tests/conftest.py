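import numpy as np
import pandas as pd
import pytest

from glycomet import (MetaboliteMatrix, PlantedEffect, PlantedModule,
                      SynthConfig, generate_cohort)


def make_matrix(values, known, groups, metabolite_ids=None):
    """Toy MetaboliteMatrix: one participant per entry of ``groups``, the
    same row of ``values`` duplicated at baseline and year1 unless a
    (2*n_participants) x m array is given."""
    values = np.asarray(values, dtype=float)
    n_part = len(groups)
    if values.shape[0] == n_part:
        values = np.repeat(values, 2, axis=0)
    assert values.shape[0] == 2 * n_part
    m = values.shape[1]
    mids = list(metabolite_ids) if metabolite_ids else [f"M{j + 1:04d}" for j in range(m)]
    parts = [f"P{i + 1:03d}" for i in range(n_part)]
    sample_ids = [f"{p}_{tp}" for p in parts for tp in ("baseline", "year1")]
    meta = pd.DataFrame(
        {
            "participant_id": np.repeat(parts, 2),
            "timepoint": ["baseline", "year1"] * n_part,
            "group": np.repeat(list(groups), 2),
        },
        index=sample_ids,
    )
    feat = pd.DataFrame(
        {"name": mids, "known": list(known)}, index=pd.Index(mids))
    return MetaboliteMatrix(
        pd.DataFrame(values, index=sample_ids, columns=mids), meta, feat)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        n_per_group=10,
        n_metabolites=30,
        n_known=12,
        modules=[PlantedModule(
            tuple(f"M{i + 1:04d}" for i in range(5)),
            {"IMI": 0.2, "BAND": 0.2, "RYGB": 0.8})],
        effects=[PlantedEffect("M0006", "FPG", "baseline",
                               {"IMI": 0.0, "BAND": 0.0, "RYGB": 1.0})],
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
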