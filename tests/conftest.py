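import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make reference_values importable

from shelfkin import IndicatorSeries
from shelfkin.synthetic import make_paper_like_fixture


@pytest.fixture
def zero_order_series() -> IndicatorSeries:
    """Noise-free line: A = 10 + 2 t."""
    t = (0.0, 1.0, 2.0, 3.0, 4.0)
    return IndicatorSeries(
        indicator="TVB-N",
        unit="mg/100 g",
        temperature_c=25.0,
        times_days=t,
        values=tuple(10.0 + 2.0 * ti for ti in t),
        direction="increasing",
    )


@pytest.fixture
def first_order_decay_series() -> IndicatorSeries:
    """Noise-free exponential decay: A = 100 exp(-0.3 t)."""
    t = (0.0, 1.0, 2.0, 3.0)
    return IndicatorSeries(
        indicator="hardness",
        unit="g",
        temperature_c=25.0,
        times_days=t,
        values=tuple(100.0 * np.exp(-0.3 * ti) for ti in t),
        direction="decreasing",
    )


@pytest.fixture
def csv_factory(tmp_path):
    """Write an indicator CSV from (indicator, temp, time, unit, value) rows."""

    def _write(rows, name="data.csv", header="indicator,temperature_c,time,time_unit,value"):
        path = tmp_path / name
        lines = [header] + [",".join(str(c) for c in row) for row in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write


@pytest.fixture(scope="session")
def paper_like_fixture(tmp_path_factory):
    """Five-indicator synthetic study fixture (CSV + config), low noise."""
    out = tmp_path_factory.mktemp("fixture")
    return make_paper_like_fixture(out, seed=11, noise_sd_scale=0.3)
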