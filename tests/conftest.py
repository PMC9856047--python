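import pandas as pd
import pytest

from ddphen import (BreedingSeasonWindow, TemperatureSeries, ThermalThresholds,
                    kerguelen_rearing_table)


@pytest.fixture
def thresholds():
    return ThermalThresholds()  # 2 / 28 degC, 439 DD


@pytest.fixture
def rearing_table():
    return kerguelen_rearing_table()


@pytest.fixture
def window():
    return BreedingSeasonWindow()  # day 200 -> end of February


def constant_series(temp_c, start="1999-01-01", end="2001-12-31"):
    dates = pd.date_range(start, end, freq="D")
    return TemperatureSeries(data=pd.DataFrame({"date": dates, "temp_c": temp_c}))


@pytest.fixture
def const5():
    return constant_series(5.0)
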