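"""Zero-aligned sparse histograms of residual magnitudes.

The histogram at bin-width exponent ``m`` counts probability classes
``floor(z / 2**m)``. Because ``floor(z / 2**(m+1)) = floor(floor(z / 2**m) / 2)``
for every non-negative integer ``z``, the histogram at ``m + 1`` can be
obtained from the one at ``m`` by merging pairs of adjacent bins — a single
pass over the sparse support, with no second look at the data. The
hyperparameter search exploits this to score every bin width from one base
histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SparseHistogram",
    "build_base_histogram",
    "update",
    "downsample",
    "support_size",
    "sorted_classes",
    "residual_magnitudes",
]


@dataclass
class SparseHistogram:
    """Sparse counts of probability classes at bin width ``2**m``.

    ``counts`` maps bin index -> positive count; zero-count bins are absent.
    ``total`` is the number of samples histogrammed.
    """

    m: int
    counts: dict[int, int] = field(default_factory=dict)
    total: int = 0

    def copy(self) -> "SparseHistogram":
        return SparseHistogram(self.m, dict(self.counts), self.total)


def residual_magnitudes(samples: Sequence[int] | np.ndarray) -> np.ndarray:
    """Magnitudes of the first backward difference of ``samples``.

    A fictitious predecessor 0 is assumed for the first sample, so the
    result has the same length as the input and histogram totals equal
    sample counts. The same convention is used by the encoder's cost
    accounting, so the two always agree.
    """
    arr = np.asarray(samples, dtype=np.int64)
    if arr.size == 0:
        return np.zeros(0, dtype=np.int64)
    return np.abs(np.diff(arr, prepend=0))


def build_base_histogram(magnitudes: Iterable[int]) -> SparseHistogram:
    """Histogram of magnitudes at bin width 1 (``m = 0``)."""
    arr = np.asarray(list(magnitudes) if not isinstance(magnitudes, np.ndarray) else magnitudes,
                     dtype=np.int64)
    if arr.size and arr.min() < 0:
        raise ValueError("magnitudes must be non-negative")
    values, counts = np.unique(arr, return_counts=True)
    return SparseHistogram(
        m=0,
        counts={int(v): int(c) for v, c in zip(values, counts)},
        total=int(arr.size),
    )


def update(hist: SparseHistogram, magnitude: int) -> SparseHistogram:
    """Add one magnitude to a base (``m = 0``) histogram, in place.

    O(1) regardless of the total count, which is what makes streaming
    histogram construction cheap.
    """
    if hist.m != 0:
        raise ValueError("streaming updates only apply to the base histogram (m=0)")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    hist.counts[magnitude] = hist.counts.get(magnitude, 0) + 1
    hist.total += 1
    return hist


def downsample(hist: SparseHistogram) -> SparseHistogram:
    """Histogram at ``m + 1`` by merging bin pairs ``(2x, 2x+1) -> x``.

    Equivalent to rebuilding from ``floor(z / 2**(m+1))`` but touches only
    the sparse support of the current histogram. Total count is preserved.
    """
    out: dict[int, int] = {}
    for y, c in hist.counts.items():
        x = y >> 1
        out[x] = out.get(x, 0) + c
    return SparseHistogram(m=hist.m + 1, counts=out, total=hist.total)


def support_size(hist: SparseHistogram) -> int:
    """Number of bins with nonzero counts."""
    return len(hist.counts)


def sorted_classes(hist: SparseHistogram) -> list[tuple[int, int]]:
    """(class, count) pairs by count descending, ties by class ascending.

    The deterministic tie-break makes tables reproducible across runs and
    platforms.
    """
    return sorted(hist.counts.items(), key=lambda kv: (-kv[1], kv[0]))
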