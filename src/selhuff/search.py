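"""Hyperparameter learning for the selective-Huffman codec.

The bin-width exponent ``m`` and table size ``k`` are learned by model
validation: the channel's samples are split in half (training first,
validation second), candidate tables are built from the k most frequent
training classes, and each candidate is scored by Φ — the exact number of
bits the encoder would spend on the validation data. The winning pair
minimizes Φ over ``0 <= m < M`` and ``k1 <= k <= k2``.

Φ has a naive O(N) form (sum the per-sample code lengths) and an exact
histogram form

    Φ = N(1+M) − Σ_a H[a]·(λ_m − len(code_a)),   λ_m = M − m − 1,

summed over classes present in both the validation histogram and the table.
The two are identical bit-for-bit; the histogram form costs
O(min(k, support)) per pair, independent of N. Histograms at successive m
come from halving bin pairs of the m=0 histogram, so the whole grid is
scored from two passes over the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .histograms import (
    SparseHistogram,
    build_base_histogram,
    downsample,
    residual_magnitudes,
    sorted_classes,
    support_size,
)
from .huffman import CompressionTable, build_table

__all__ = [
    "DatasetPartition",
    "SearchSpec",
    "SearchResult",
    "partition",
    "phi_naive",
    "phi_fast",
    "grid_search",
    "grid_search_naive",
]


@dataclass(frozen=True)
class DatasetPartition:
    """Equal-length train/validation halves, training samples first."""

    training: np.ndarray
    validation: np.ndarray

    @property
    def N(self) -> int:
        return len(self.validation)


@dataclass(frozen=True)
class SearchSpec:
    """Search range for the table size; defaults match the deployed system."""

    k1: int = 10
    k2: int = 30
    M: int = 14

    def __post_init__(self) -> None:
        if not 1 <= self.k1 <= self.k2:
            raise ValueError(f"need 1 <= k1 <= k2, got k1={self.k1}, k2={self.k2}")
        if not 1 <= self.M <= 32:
            raise ValueError("M must be in [1, 32]")


@dataclass
class SearchResult:
    m_star: int
    k_star: int
    table: CompressionTable
    grid: dict[tuple[int, int], int]
    evaluated_pairs: int

    @property
    def phi_star(self) -> int:
        return self.grid[(self.m_star, self.k_star)]


def partition(series: Sequence[int] | np.ndarray) -> DatasetPartition:
    """Split into equal non-overlapping halves; an odd trailing sample is
    dropped so |T| = |V|."""
    arr = np.asarray(series, dtype=np.int64)
    if arr.size < 2:
        raise ValueError("need at least 2 samples to partition")
    half = arr.size // 2
    return DatasetPartition(training=arr[:half], validation=arr[half : 2 * half])


def phi_naive(
    validation: Sequence[int] | np.ndarray,
    m: int,
    M: int,
    table: CompressionTable,
    first_raw: bool = False,
) -> int:
    """Total encoded bits over the validation data, by direct summation.

    Assumes a fictitious predecessor 0 for the first sample — the same
    convention as histogram construction, so the fast form agrees exactly.
    With ``first_raw=True`` the first sample is charged the raw cost
    ``1 + M`` instead, matching the self-contained block encoder's
    first-sample-raw rule. Serves as the O(N) testing oracle for
    :func:`phi_fast`.
    """
    if table.m != m:
        raise ValueError("table bin width must match m")
    z = residual_magnitudes(validation)
    classes = z >> m
    lengths = np.full(classes.shape, 1 + M, dtype=np.int64)
    for cls, code in table.entries.items():
        lengths[classes == cls] = 2 + len(code) + m
    if first_raw and lengths.size:
        lengths[0] = 1 + M
    return int(lengths.sum())


def phi_fast(
    validation_hist: SparseHistogram,
    table: CompressionTable,
    m: int,
    M: int,
    N: int,
) -> int:
    """Φ from the validation histogram at ``m`` — exact, O(min(k, support))."""
    if validation_hist.m != m or table.m != m:
        raise ValueError("histogram, table and m must agree")
    lam = M - m - 1
    total = N * (1 + M)
    hist = validation_hist.counts
    entries = table.entries
    # iterate over the smaller associative structure
    if len(hist) < len(entries):
        for cls, count in hist.items():
            code = entries.get(cls)
            if code is not None:
                total -= count * (lam - len(code))
    else:
        for cls, code in entries.items():
            count = hist.get(cls)
            if count is not None:
                total -= count * (lam - len(code))
    return total


def grid_search(
    part: DatasetPartition,
    spec: SearchSpec,
    table_id: int = 1,
) -> SearchResult:
    """Fast (m, k) grid search over histogram pyramids.

    Base histograms of training and validation residual magnitudes are built
    once; every coarser bin width comes from the halving recurrence. For each
    m the k-range is clamped to the training support, and the m-loop stops
    early once the support drops below ``k1``. Ties resolve toward smaller m,
    then smaller k (smaller tables, less decoder memory).
    """
    if part.training.size == 0 or part.validation.size == 0:
        raise ValueError("training and validation must be non-empty")
    M = spec.M
    h_train = build_base_histogram(residual_magnitudes(part.training))
    h_val = build_base_histogram(residual_magnitudes(part.validation))
    N = part.N

    grid: dict[tuple[int, int], int] = {}
    best: Optional[tuple[int, int, int]] = None  # (phi, m, k)
    evaluated = 0
    m = 0
    while m < M:
        supp = support_size(h_train)
        if spec.k1 > supp:
            break  # coarser bin widths only shrink the support further
        ranked = sorted_classes(h_train)
        k_max = min(spec.k2, supp)
        for k in range(spec.k1, k_max + 1):
            table = build_table(ranked, k, m, M, table_id)
            phi = phi_fast(h_val, table, m, M, N)
            grid[(m, k)] = phi
            evaluated += 1
            if best is None or phi < best[0]:
                best = (phi, m, k)
        if m + 1 < M:
            h_train = downsample(h_train)
            h_val = downsample(h_val)
        m += 1

    if best is None:
        raise ValueError(
            "training residual support is smaller than k1 at every bin width; "
            "lower k1 for this channel"
        )
    _, m_star, k_star = best
    # rebuild the winning table from the training data at m_star
    h = build_base_histogram(residual_magnitudes(part.training))
    for _ in range(m_star):
        h = downsample(h)
    table = build_table(sorted_classes(h), k_star, m_star, M, table_id)
    return SearchResult(m_star, k_star, table, grid, evaluated)


def grid_search_naive(
    part: DatasetPartition,
    spec: SearchSpec,
    table_id: int = 1,
) -> SearchResult:
    """Brute-force reference: rebuild every histogram directly from the data
    and score every candidate with :func:`phi_naive`. Same clamping,
    early-termination and tie-break rules as :func:`grid_search`; used as the
    independent oracle in tests."""
    M = spec.M
    z_train = residual_magnitudes(part.training)
    grid: dict[tuple[int, int], int] = {}
    best: Optional[tuple[int, int, int]] = None
    evaluated = 0
    for m in range(M):
        h_train = build_base_histogram(z_train >> m)
        h_train.m = m
        supp = support_size(h_train)
        if spec.k1 > supp:
            break
        ranked = sorted_classes(h_train)
        for k in range(spec.k1, min(spec.k2, supp) + 1):
            table = build_table(ranked, k, m, M, table_id)
            phi = phi_naive(part.validation, m, M, table)
            grid[(m, k)] = phi
            evaluated += 1
            if best is None or phi < best[0]:
                best = (phi, m, k)
    if best is None:
        raise ValueError("training residual support is smaller than k1 at every m")
    _, m_star, k_star = best
    h = build_base_histogram(z_train >> m_star)
    h.m = m_star
    table = build_table(sorted_classes(h), k_star, m_star, M, table_id)
    return SearchResult(m_star, k_star, table, grid, evaluated)
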