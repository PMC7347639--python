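import numpy as np
import pytest

from pollenproxy.series import POLLEN, DailySeries, year_length


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_series(year=2015, kind=POLLEN, fill=None, day_values=None, window=None):
    """Dense series builder: constant fill plus explicit (day, value) overrides."""
    values = np.full(year_length(year), np.nan if fill is None else float(fill))
    for day, value in (day_values or {}).items():
        values[day - 1] = value
    return DailySeries(year=year, values=values, kind=kind, window=window)


@pytest.fixture
def series_factory():
    return make_series
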