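import numpy as np
import pandas as pd
import pytest

from epicohort import CohortConfig, CohortTable, CovariateSpec, EffectSpec


def noise_covariates(k: int) -> list[CovariateSpec]:
    return [
        CovariateSpec(
            f"noise_{i + 1}",
            kind="continuous",
            family="normal",
            mean_group1=0.0,
            sd_group1=1.0,
            mean_group2=0.0,
            sd_group2=1.0,
        )
        for i in range(k)
    ]


def dnmt1_effect() -> EffectSpec:
    """The headline expression effect: an ~8-fold group difference."""
    return EffectSpec(
        "dnmt1_expression",
        family="lognormal",
        mean_group1=10.11,
        sd_group1=4.366,
        mean_group2=1.277,
        sd_group2=0.946,
    )


@pytest.fixture
def dnmt1_config():
    """48 + 50 cohort with 10 inert covariates and the headline effect."""
    return CohortConfig(
        n_group1=48,
        n_group2=50,
        covariates=noise_covariates(10),
        effects=[dnmt1_effect()],
        master_seed=0,
    )


def make_cohort(
    group,
    *,
    continuous=None,
    ordinal=None,
    dependent=None,
    restricted=(),
) -> CohortTable:
    """Assemble a CohortTable directly from column arrays."""
    group = np.asarray(group)
    data = {"participant_id": [f"P{i}" for i in range(len(group))], "group": group}
    for block in (continuous, ordinal, dependent):
        if block:
            data.update(block)
    return CohortTable(
        data=pd.DataFrame(data),
        continuous=tuple(continuous or ()),
        ordinal=tuple(ordinal or ()),
        dependent=tuple(dependent or ()),
        restricted=tuple(restricted),
    )
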