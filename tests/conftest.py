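import numpy as np
import pytest

from d3map.delay_density import DensityGrid
from d3map.rr_io import RRSeries


def make_grid(values, lo=0.0, hi=1.0, normalized=False) -> DensityGrid:
    """Wrap a raw value matrix in a DensityGrid on [lo, hi]^2."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    edges = np.linspace(lo, hi, n + 1)
    total = int(round(values.sum())) if not normalized else int(values.sum() > 0)
    return DensityGrid(
        x_edges=edges,
        y_edges=edges,
        values=values,
        total_count=max(total, int(values.sum() > 0)),
        max_count_m=float(values.max()) if values.size else 0.0,
        normalized=normalized,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng) -> RRSeries:
    """A short positively-valued RR series with mild autocorrelation."""
    rr = 0.8 + 0.05 * np.cumsum(rng.standard_normal(200)) * 0.1
    rr = np.clip(rr, 0.4, 1.4)
    return RRSeries.from_intervals(rr, label="small")
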