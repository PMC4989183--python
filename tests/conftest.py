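import numpy as np
import pytest

from chronovar.rhythmometry import ExpressionSeries


@pytest.fixture
def six_point_design() -> np.ndarray:
    """The study's sampling grid: every 4 h over 24 h, 3 replicates."""
    return np.repeat(np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0]), 3)


def make_series(t, y, gene="g", tissue="liver", genotype="A", light="DD"):
    return ExpressionSeries(gene=gene, tissue=tissue, genotype=genotype,
                            light=light, times=np.asarray(t, dtype=float),
                            values=np.asarray(y, dtype=float))


@pytest.fixture
def cosine():
    def _cosine(t, mesor, amplitude, acrophase, period=24.0):
        return mesor + amplitude * np.cos(
            2.0 * np.pi * (np.asarray(t, dtype=float) - acrophase) / period)
    return _cosine
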