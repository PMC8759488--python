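import numpy as np
import pytest

from titracurve import ConcentrationSeries, SigmoidParams, eval_sigmoid
from titracurve.synthetic import DEFAULT_GRID

GRID = np.array(DEFAULT_GRID)


def series_from_values(values, gene="g", reps=4, grid=GRID, noise_cv=0.0, rng=None):
    """Replicated ConcentrationSeries from per-concentration true values."""
    values = np.asarray(values, dtype=float)
    conc = np.repeat(grid, reps)
    y = np.repeat(values, reps)
    if noise_cv > 0:
        rng = rng or np.random.default_rng(0)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        y = y * rng.lognormal(-sigma**2 / 2, sigma, y.size)
    return ConcentrationSeries(gene, conc, y)


def sigmoid_series(params: SigmoidParams, **kw) -> ConcentrationSeries:
    return series_from_values(eval_sigmoid(params, GRID), **kw)


@pytest.fixture
def ref_sigmoid() -> SigmoidParams:
    """The worked-example parameter set: 100 -> 1000 counts, inflection 0.2 uM."""
    return SigmoidParams(a=100, b=1000, k=20, th=0.2)
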