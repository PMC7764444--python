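import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selhuff import (
    CompressionTable,
    DatasetPartition,
    SearchSpec,
    SparseHistogram,
    grid_search,
    partition,
    phi_fast,
    phi_naive,
)
from selhuff.search import grid_search_naive
from conftest import table_from_magnitudes


@pytest.mark.parametrize(
    "series, training, validation",
    [
        ([1, 2, 3, 4], [1, 2], [3, 4]),
        ([1, 2, 3, 4, 5], [1, 2], [3, 4]),  # odd trailing sample dropped
        ([10, 20], [10], [20]),
    ],
)
def test_partition_equal_halves_training_first(series, training, validation):
    part = partition(series)
    assert part.training.tolist() == training
    assert part.validation.tolist() == validation
    assert part.N == len(validation)


def test_partition_needs_two_samples():
    with pytest.raises(ValueError):
        partition([1])


class TestObjective:
    def test_empty_table_charges_raw_cost_for_every_sample(self):
        t = CompressionTable(m=0, entries={}, M=14)
        assert phi_naive([3, 1, 4, 1, 5], 0, 14, t) == 5 * 15

    def test_fully_covered_constant_signal(self):
        t = CompressionTable(m=0, entries={0: "0"}, M=14)
        # first sample's fictitious predecessor is 0, so all residuals are 0
        assert phi_naive([0, 0, 0], 0, 14, t) == 9

    def test_mixed_hit_miss_accounting(self):
        # magnitudes [1, 1, 0, 5] at m=1 -> classes [0, 0, 0, 2]; class 0 coded
        t = CompressionTable(m=1, entries={0: "0"}, M=4)
        v = [1, 2, 2, 7]
        assert phi_naive(v, 1, 4, t) == 3 * (2 + 1 + 1) + 1 * 5

    def test_phi_fast_matches_each_naive_example(self):
        t = CompressionTable(m=0, entries={}, M=14)
        h = SparseHistogram(0, {0: 2, 1: 2, 3: 1}, 5)
        assert phi_fast(h, t, 0, 14, 5) == 75
        t2 = CompressionTable(m=0, entries={0: "0"}, M=14)
        assert phi_fast(SparseHistogram(0, {0: 3}, 3), t2, 0, 14, 3) == 9
        t3 = CompressionTable(m=1, entries={0: "0"}, M=4)
        assert phi_fast(SparseHistogram(1, {0: 3, 2: 1}, 4), t3, 1, 4, 4) == 17

    def test_phi_fast_cost_is_independent_of_sample_count(self):
        # astronomically large counts are fine: the formula never scans data
        scale = 10**20
        h = SparseHistogram(0, {0: 3 * scale, 2: scale}, 4 * scale)
        t = CompressionTable(m=0, entries={0: "0"}, M=14)
        assert phi_fast(h, t, 0, 14, 4 * scale) == 4 * scale * 15 - 3 * scale * 12

    def test_first_raw_convention_charges_first_sample_fully(self):
        t = CompressionTable(m=0, entries={0: "0"}, M=14)
        assert phi_naive([0, 0, 0], 0, 14, t, first_raw=True) == 15 + 6


@given(data=st.data())
@settings(max_examples=250, deadline=None)
def test_phi_fast_equals_phi_naive_exactly(data):
    M = data.draw(st.integers(3, 14))
    m = data.draw(st.integers(0, M - 1))
    seed = data.draw(st.integers(0, 2**31 - 1))
    n = data.draw(st.integers(1, 200))
    k = data.draw(st.integers(1, 25))
    rng = np.random.default_rng(seed)
    v = rng.integers(0, 1 << M, size=n)
    # table trained on different data so hits and misses both occur
    w = rng.integers(0, 1 << M, size=n)
    zw = np.abs(np.diff(w, prepend=0))
    table = table_from_magnitudes(zw, m, M, k)

    from selhuff.histograms import build_base_histogram, residual_magnitudes

    hist = build_base_histogram(residual_magnitudes(v) >> m)
    hist.m = m
    assert phi_fast(hist, table, m, M, n) == phi_naive(v, m, M, table)


def test_grid_search_prefers_wider_bins_for_two_valued_magnitudes():
    # residual magnitudes uniformly 0/1: with k1=k2=1, m=0 leaves half the
    # samples raw while m=1 encodes everything at 4 bits -> m* must be 1
    rng = np.random.default_rng(0)
    steps = rng.integers(0, 2, size=400)
    series = np.cumsum(steps)
    part = partition(series)
    res = grid_search(part, SearchSpec(k1=1, k2=1, M=14))
    assert res.m_star == 1 and res.k_star == 1
    phi_m0 = res.grid[(0, 1)]
    phi_m1 = res.grid[(1, 1)]
    assert phi_m1 < phi_m0
    # first validation sample: fictitious predecessor 0 gives a huge
    # magnitude whose class is absent -> raw 15 bits; the rest cost 4 each
    assert phi_m1 == 4 * (part.N - 1) + 15


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_grid_search_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    M = int(rng.integers(4, 11))
    n = int(rng.integers(4, 500))
    kind = rng.integers(0, 3)
    if kind == 0:
        series = rng.integers(0, 1 << M, size=n)
    elif kind == 1:
        series = np.clip(np.cumsum(rng.integers(-3, 4, size=n)) + (1 << (M - 1)),
                         0, (1 << M) - 1)
    else:
        series = np.clip(rng.geometric(0.3, size=n), 0, (1 << M) - 1)
    k1 = int(rng.integers(1, 4))
    k2 = k1 + int(rng.integers(0, 10))
    part = partition(series)
    spec = SearchSpec(k1=k1, k2=k2, M=M)
    try:
        fast = grid_search(part, spec)
    except ValueError:
        with pytest.raises(ValueError):
            grid_search_naive(part, spec)
        return
    slow = grid_search_naive(part, spec)
    assert (fast.m_star, fast.k_star) == (slow.m_star, slow.k_star)
    assert fast.grid == slow.grid
    assert fast.evaluated_pairs == slow.evaluated_pairs
    assert fast.table.entries == slow.table.entries


def test_full_support_table_at_m0_is_in_the_feasible_set():
    rng = np.random.default_rng(5)
    series = np.clip(np.cumsum(rng.integers(-2, 3, size=300)) + 100, 0, 16383)
    part = DatasetPartition(series, series)  # validation identical to training
    from selhuff.histograms import build_base_histogram, residual_magnitudes, support_size

    supp = support_size(build_base_histogram(residual_magnitudes(series)))
    res = grid_search(part, SearchSpec(k1=1, k2=supp, M=14))
    assert res.phi_star <= res.grid[(0, supp)]


def test_phi_bounded_by_all_raw_cost_when_codes_are_short():
    """Whenever every codeword is no longer than lambda_m = M - m - 1, a
    table can only save bits, so phi never exceeds the all-raw cost."""
    rng = np.random.default_rng(7)
    M = 10
    v = rng.integers(0, 1 << M, size=400)
    for m in (0, 1, 3):
        zv = np.abs(np.diff(v, prepend=0))
        table = table_from_magnitudes(zv, m, M, k=4)  # k=4 -> lengths <= 3
        assert all(len(c) <= M - m - 1 for c in table.entries.values())
        phi = phi_naive(v, m, M, table)
        assert len(v) <= phi <= len(v) * (1 + M)


def test_search_returns_smaller_k_when_extra_entries_hurt():
    """Training has 6 classes but validation only ever uses the top two;
    extra table entries lengthen the top codes, so k* < k2."""
    t_mag = [0] * 60 + [1] * 50 + [2, 3, 4, 5] * 2
    v_mag = [0] * 60 + [1] * 58
    training = np.cumsum(t_mag)
    validation = training[-1] + np.cumsum(v_mag)
    part = DatasetPartition(np.asarray(training), np.asarray(validation))
    res = grid_search(part, SearchSpec(k1=2, k2=6, M=14))
    assert res.k_star < 6
    assert res.grid[(0, 6)] > res.grid[(0, res.k_star)]


def test_search_spec_validation():
    with pytest.raises(ValueError):
        SearchSpec(k1=5, k2=3)
    with pytest.raises(ValueError):
        SearchSpec(k1=0, k2=3)


def test_grid_search_reports_unlearnable_channel():
    part = partition(np.zeros(100, dtype=np.int64))
    with pytest.raises(ValueError):
        grid_search(part, SearchSpec(k1=10, k2=30, M=14))
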