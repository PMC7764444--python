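"""Compression metrics, the full-table baseline, and packet/bandwidth math.

The "standard" baseline is the proposed scheme's limiting case: bin width 1
(``m = 0``) and a Huffman codeword for *every* residual magnitude seen in
training. It keeps the 1-bit encoded/raw indicator so it stays lossless on
magnitudes never seen in training, which also keeps the bit accounting
comparable between the two methods.

Compression ratios count only sample-payload bits relative to the ADC
resolution; packet headers are fixed overhead common to both methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .codec import encode_block
from .histograms import (
    build_base_histogram,
    residual_magnitudes,
    sorted_classes,
    support_size,
)
from .huffman import CompressionTable, build_table
from .residuals import ChannelSpec
from .search import SearchSpec, grid_search, partition

__all__ = [
    "ChannelReport",
    "compression_ratio",
    "baseline_table",
    "packet_size_bytes",
    "required_bandwidth",
    "encodable_magnitudes",
    "magnitude_cdf",
    "EmpiricalCDF",
    "evaluate_channels",
]

#: header + trailer size of the deployed system's packets, used only by the
#: packet-size arithmetic (this package's own frame layout differs).
DEPLOYED_OVERHEAD_BYTES = 19


def compression_ratio(
    samples: Sequence[int] | np.ndarray,
    table: CompressionTable,
    adc_bits: int,
) -> float:
    """``(N x adc_bits) / payload bits`` for the actual encoded payload."""
    arr = np.asarray(samples, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot compute a compression ratio of an empty input")
    if adc_bits < 1:
        raise ValueError("adc_bits must be >= 1")
    spec = ChannelSpec("_ratio", table.M, samples_per_packet=max(1, arr.size))
    _, nbits = encode_block(arr, table, spec)
    return arr.size * adc_bits / nbits


def baseline_table(
    training: Sequence[int] | np.ndarray, M: int, table_id: int = 1
) -> CompressionTable:
    """Full-table Huffman gold standard: every observed residual magnitude
    (bin width 1) gets a codeword."""
    arr = np.asarray(training, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("training data must be non-empty")
    hist = build_base_histogram(residual_magnitudes(arr))
    return build_table(sorted_classes(hist), support_size(hist), 0, M, table_id)


def packet_size_bytes(
    channel_specs: Sequence[ChannelSpec],
    samples_per_packet: int = 50,
    header_trailer_bytes: int = DEPLOYED_OVERHEAD_BYTES,
) -> int:
    """Uncompressed (all-raw) packet size in bytes: every sample costs
    ``1 + M`` bits (raw indicator included)."""
    bits = samples_per_packet * sum(1 + s.bit_depth for s in channel_specs)
    return math.ceil(bits / 8) + header_trailer_bytes


def required_bandwidth(
    packet_bytes: int, sampling_rate: float, samples_per_packet: int = 50
) -> int:
    """Sustained bandwidth in kB/s, rounded to the nearest integer."""
    if min(packet_bytes, sampling_rate, samples_per_packet) <= 0:
        raise ValueError("arguments must be positive")
    return round(packet_bytes * sampling_rate / samples_per_packet / 1000)


def encodable_magnitudes(table: CompressionTable) -> int:
    """Distinct residual magnitudes that receive non-raw codes: ``k * 2**m``."""
    return table.k * (1 << table.m)


class EmpiricalCDF:
    """Right-continuous empirical CDF of residual magnitudes."""

    def __init__(self, magnitudes: np.ndarray) -> None:
        self.values = np.sort(np.asarray(magnitudes, dtype=np.int64))
        self.n = len(self.values)

    def __call__(self, x: float) -> float:
        return float(np.searchsorted(self.values, x, side="right")) / self.n


def magnitude_cdf(samples: Sequence[int] | np.ndarray) -> EmpiricalCDF:
    """Empirical CDF of the DPCM residual magnitudes of ``samples``."""
    arr = np.asarray(samples, dtype=np.int64)
    if arr.size < 2:
        raise ValueError("need at least 2 samples")
    return EmpiricalCDF(residual_magnitudes(arr))


@dataclass(frozen=True)
class ChannelReport:
    channel: str
    m_star: int
    k_star: int
    baseline_size: int
    ratio_proposed: float
    ratio_baseline: float
    table_reduction_percent: float
    bits_per_sample: float


def evaluate_channels(
    channels: dict[str, np.ndarray],
    specs: dict[str, ChannelSpec],
    search: SearchSpec | None = None,
    train_fraction: float = 0.5,
) -> list[ChannelReport]:
    """Train on a leading fraction of each channel, report held-out metrics.

    The proposed table comes from the (m, k) search on the training segment
    (itself split in half internally); the baseline table is computed from
    all residuals of the same training segment. Ratios are measured on the
    remaining samples.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    reports = []
    for name, series in channels.items():
        M = specs[name].bit_depth
        cut = int(len(series) * train_fraction)
        train_seg, eval_seg = series[:cut], series[cut:]
        if len(train_seg) < 2 or len(eval_seg) < 1:
            raise ValueError(f"channel {name!r} too short to evaluate")
        sspec = search or SearchSpec(M=M)
        if sspec.M != M:
            sspec = SearchSpec(k1=sspec.k1, k2=sspec.k2, M=M)
        result = grid_search(partition(train_seg), sspec)
        base = baseline_table(train_seg, M)
        r_prop = compression_ratio(eval_seg, result.table, M)
        r_base = compression_ratio(eval_seg, base, M)
        reports.append(
            ChannelReport(
                channel=name,
                m_star=result.m_star,
                k_star=result.k_star,
                baseline_size=base.k,
                ratio_proposed=r_prop,
                ratio_baseline=r_base,
                table_reduction_percent=100.0 * (1 - result.k_star / base.k),
                bits_per_sample=M / r_prop,
            )
        )
    return reports
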