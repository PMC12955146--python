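import numpy as np
import pytest

from adrtrend.series import ADRSeries
from adrtrend.simulate import SimulationSpec, simulate_series


@pytest.fixture
def make_series():
    """Factory for an ADRSeries from annual counts (years start 2000)."""

    def _make(annual, drug_id="X", **kwargs):
        annual = np.asarray(annual, dtype=float)
        years = np.arange(2000, 2000 + len(annual))
        return ADRSeries(drug_id=drug_id, years=years, annual_counts=annual, **kwargs)

    return _make


@pytest.fixture
def noise_free():
    """Factory for a noise-free series from a growth family."""

    def _make(family, params, n_years, drug_id="sim"):
        return simulate_series(
            SimulationSpec(family=family, params=params, n_years=n_years, drug_id=drug_id)
        )

    return _make
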