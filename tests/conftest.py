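import numpy as np
import pandas as pd
import pytest

from mhwkelp import Climatology, TemperatureSeries


@pytest.fixture
def flat_clim():
    """Constant climatology: mean 10 °C, 90th-percentile threshold 12 °C."""
    return Climatology.flat(mean=10.0, p90=12.0)


@pytest.fixture
def make_series():
    """Daily series factory: constant base with per-day overrides."""

    def _make(year=2018, base=10.0, overrides=None, site_id="fix", n_days=365):
        dates = pd.date_range(f"{year}-01-01", periods=n_days, freq="D")
        values = np.full(n_days, float(base))
        for day_index, temp in (overrides or {}).items():
            values[day_index] = temp
        return TemperatureSeries.from_arrays(dates, values, site_id=site_id)

    return _make
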