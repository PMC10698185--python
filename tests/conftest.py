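"""Shared fixtures: the reference scenario and derived pipeline artefacts.

Everything is generated programmatically and seeded; the heavyweight
objects are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pestemis import features, pipeline, synthetic
from pestemis.datatypes import DesignMatrix


@pytest.fixture(scope="session")
def scenario():
    """Noise-free reference scenario: 8 reporting + 4 silent countries."""
    return synthetic.reference_fixture(42)


@pytest.fixture(scope="session")
def climate_features(scenario):
    return features.summarize_climate(scenario.climate_cells)


@pytest.fixture(scope="session")
def pipeline_result(scenario):
    return pipeline.run_pipeline(
        scenario.regions,
        scenario.climate_cells,
        scenario.reports,
        scenario.catalog,
        scenario.auth,
        scenario.grouping,
        scenario.group_to_class,
    )


def make_design(
    X: pd.DataFrame,
    y,
    country=None,
    substance_id: str = "S",
    lcc: str = "arable land",
    crop_columns=None,
    climate_columns=(),
) -> DesignMatrix:
    """Small hand-rolled design matrices for model unit tests."""
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="kg")
    if country is None:
        country = pd.Series("AAA", index=X.index, name="country")
    else:
        country = pd.Series(country, index=X.index, name="country")
    crop_columns = list(X.columns) if crop_columns is None else list(crop_columns)
    return DesignMatrix(
        substance_id=substance_id,
        lcc=lcc,
        X=X,
        y=y,
        country=country,
        crop_columns=crop_columns,
        climate_columns=list(climate_columns),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
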