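import numpy as np
import pytest

from selhuff import ChannelSpec, CompressionTable, build_table
from selhuff.histograms import build_base_histogram, sorted_classes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, m, M, k):
    """A table learned from random geometric-ish class counts."""
    n_classes = max(k, min(1 << (M - m), 4 * k))
    classes = rng.choice(n_classes, size=k, replace=False)
    counts = rng.integers(1, 1000, size=k)
    ranked = sorted(zip(classes.tolist(), counts.tolist()), key=lambda t: (-t[1], t[0]))
    return build_table(ranked, k, m, M)


def table_from_magnitudes(magnitudes, m, M, k):
    """Top-k table at bin width 2**m straight from residual magnitudes."""
    hist = build_base_histogram(np.asarray(magnitudes) >> m)
    hist.m = m
    ranked = sorted_classes(hist)
    return build_table(ranked, min(k, len(ranked)), m, M)
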