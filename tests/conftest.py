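import numpy as np
import pandas as pd
import pytest

from ksirt.data import RatingsMatrix
from ksirt.grm import (
    CohortConfig,
    SeverityDistribution,
    make_archetype,
    simulate_cohort,
)
from ksirt.scale import ScaleDefinition, panss


@pytest.fixture(scope="session")
def panss_scale() -> ScaleDefinition:
    return panss()


@pytest.fixture(scope="session")
def mini_scale() -> ScaleDefinition:
    """A 3-item, 4-option instrument for hand-computable cases."""
    return ScaleDefinition(
        items=("A", "B", "C"),
        subscales={"S": ("A", "B", "C")},
        option_min=1,
        option_max=4,
    )


def make_ratings(values: dict, scale: ScaleDefinition, covariates: dict | None = None):
    vals = pd.DataFrame(values)
    cov = pd.DataFrame(covariates, index=vals.index) if covariates else None
    return RatingsMatrix(vals, scale, cov)


@pytest.fixture(scope="session")
def ideal_cohort():
    """300 subjects x 7 ideal items; small but structured."""
    items = tuple(f"I{k + 1}" for k in range(7))
    scale = ScaleDefinition(items=items, subscales={"S": items})
    config = CohortConfig(
        scale=scale,
        item_params={it: make_archetype("ideal", 7) for it in items},
        n=300,
        seed=7,
        severity=SeverityDistribution("normal", (0.0, 1.0)),
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def panss_cohort():
    """A small PANSS-like cohort with covariates for pipeline tests."""
    from ksirt.grm import panss_like_config

    return simulate_cohort(panss_like_config(n=800, seed=3))
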