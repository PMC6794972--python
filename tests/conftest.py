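import numpy as np
import pytest

from occlufit import (
    LogisticParams,
    OcclusionSeries,
    bundled_fixture_letters,
    bundled_fixture_table1,
    trajectory_on_grid,
)


@pytest.fixture(scope="session")
def table1():
    return bundled_fixture_table1()


@pytest.fixture(scope="session")
def letters():
    return bundled_fixture_letters()


@pytest.fixture(scope="session")
def table1_by_cell(table1):
    return {(s.paste, s.condition): s for s in table1}


@pytest.fixture
def make_series():
    """Series whose means lie exactly on a logistic trajectory."""

    def _make(params: LogisticParams, days=None, sds=None, n=7, paste="toy",
              condition="without_saliva"):
        days = np.arange(1, 8, dtype=float) if days is None else np.asarray(days, float)
        means = trajectory_on_grid(params, days)
        sds = np.full_like(days, 2.0) if sds is None else np.asarray(sds, float)
        return OcclusionSeries(
            paste=paste, condition=condition, days=days, means=means, sds=sds, n=n
        )

    return _make
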