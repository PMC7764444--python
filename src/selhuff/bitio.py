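"""MSB-first bit-level writer and reader used by the codec.

Bits are packed into bytes left to right: the first bit written lands in the
most significant bit of the first byte. Padding (to reach a byte boundary)
is zero bits at the end.
"""

from __future__ import annotations

__all__ = ["BitWriter", "BitReader"]


class BitWriter:
    """Append-only bit buffer."""

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0  # bits accumulated, MSB-first in the low `_nacc` bits
        self._nacc = 0
        self._nbits = 0

    def __len__(self) -> int:
        return self._nbits

    def write_bit(self, bit: int) -> None:
        self._acc = (self._acc << 1) | (bit & 1)
        self._nacc += 1
        self._nbits += 1
        if self._nacc == 8:
            self._buf.append(self._acc)
            self._acc = 0
            self._nacc = 0

    def write_bits(self, value: int, width: int) -> None:
        """Write the ``width`` low bits of ``value``, most significant first."""
        for shift in range(width - 1, -1, -1):
            self.write_bit((value >> shift) & 1)

    def write_bitstring(self, bits: str) -> None:
        for ch in bits:
            self.write_bit(ch == "1")

    def to_bytes(self) -> bytes:
        """Byte string with zero padding in the final partial byte."""
        out = bytes(self._buf)
        if self._nacc:
            out += bytes([(self._acc << (8 - self._nacc)) & 0xFF])
        return out


class BitReader:
    """Sequential MSB-first reader over a byte string."""

    def __init__(self, data: bytes, nbits: int | None = None) -> None:
        self._data = data
        self._nbits = 8 * len(data) if nbits is None else nbits
        if self._nbits > 8 * len(data):
            raise ValueError("declared bit length exceeds the buffer")
        self._pos = 0

    @property
    def remaining(self) -> int:
        return self._nbits - self._pos

    def read_bit(self) -> int:
        if self._pos >= self._nbits:
            raise EOFError("bit stream exhausted")
        byte = self._data[self._pos >> 3]
        bit = (byte >> (7 - (self._pos & 7))) & 1
        self._pos += 1
        return bit

    def read_bits(self, width: int) -> int:
        value = 0
        for _ in range(width):
            value = (value << 1) | self.read_bit()
        return value
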