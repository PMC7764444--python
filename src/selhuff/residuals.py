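"""DPCM residual arithmetic.

Each sample is predicted by its predecessor; the residual ``r = d[n] - d[n-1]``
is what gets entropy-coded. A residual is decomposed into a sign flag, a
*probability class* ``p = floor(|r| / 2**m)`` (the upper ``M - m`` bits of the
magnitude) and an *intra-class index* ``q = |r| mod 2**m`` (the lower ``m``
bits). The class receives a Huffman code; the index is transmitted verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ChannelSpec",
    "ResidualDecomposition",
    "CorruptStreamError",
    "decompose",
    "recompose",
]


class CorruptStreamError(Exception):
    """A bitstream decoded to something impossible (bad bits, bad framing)."""


@dataclass(frozen=True)
class ChannelSpec:
    """Static description of one acquisition channel.

    Parameters
    ----------
    name : str
        Short channel identifier (e.g. ``"ecg"``, ``"gcg_x"``).
    bit_depth : int
        ADC resolution ``M`` in bits; samples are unsigned codes in
        ``[0, 2**M)``. A raw (uncoded) sample costs ``1 + M`` bits on the
        wire because of the encoded/raw indicator bit.
    samples_per_packet : int
        Number of samples of this channel carried by each packet.
    """

    name: str
    bit_depth: int
    samples_per_packet: int = 50

    def __post_init__(self) -> None:
        if not 1 <= self.bit_depth <= 32:
            raise ValueError(f"bit_depth must be in [1, 32], got {self.bit_depth}")
        if self.samples_per_packet < 1:
            raise ValueError("samples_per_packet must be >= 1")

    @property
    def raw_code_bits(self) -> int:
        """Bits per uncompressed sample, indicator included (``1 + M``)."""
        return 1 + self.bit_depth


@dataclass(frozen=True)
class ResidualDecomposition:
    """A DPCM residual split into sign, probability class and index."""

    r: int  # signed residual, ADC counts
    z: int  # magnitude |r|
    s: int  # 1 if r >= 0 else 0
    p: int  # probability class floor(z / 2**m)
    q: int  # intra-class index z mod 2**m
    m: int  # bin-width exponent


def _check_sample(value: int, M: int, what: str) -> None:
    if not 0 <= value < (1 << M):
        raise ValueError(f"{what} {value} outside [0, 2**{M})")


def decompose(current: int, previous: int, m: int, M: int) -> ResidualDecomposition:
    """Compute the DPCM residual of ``current`` against ``previous`` and split
    it into (sign, class, index) at bin-width exponent ``m``.

    ``s = 1`` for ``r >= 0`` (zero counts as positive). Requires
    ``0 <= m < M`` and both samples in ``[0, 2**M)``.
    """
    if not 0 <= m < M:
        raise ValueError(f"need 0 <= m < M, got m={m}, M={M}")
    _check_sample(current, M, "current sample")
    _check_sample(previous, M, "previous sample")
    r = current - previous
    z = abs(r)
    s = 1 if r >= 0 else 0
    p = z >> m
    q = z & ((1 << m) - 1)
    return ResidualDecomposition(r=r, z=z, s=s, p=p, q=q, m=m)


def recompose(s: int, p: int, q: int, m: int, previous: int) -> int:
    """Invert :func:`decompose`: rebuild the sample from its coded fields.

    Raises ``ValueError`` if ``q`` is not a valid ``m``-bit index, and a
    :class:`CorruptStreamError` if the reconstructed value is negative
    (which can only happen on a corrupted stream).
    """
    if not 0 <= q < (1 << m) and m > 0:
        raise ValueError(f"index {q} outside [0, 2**{m})")
    if m == 0 and q != 0:
        raise ValueError("index must be 0 when m=0")
    z = (p << m) | q
    r = z if s == 1 else -z
    value = previous + r
    if value < 0:
        raise CorruptStreamError(f"reconstructed sample {value} is negative")
    return value
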