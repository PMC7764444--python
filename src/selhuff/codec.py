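"""Sample encoder/decoder, per-channel block coding and packet framing.

Every sample code starts with a 1-bit indicator: ``1`` means the residual's
probability class had a codeword (sign bit, class codeword, then the m-bit
intra-class index follow); ``0`` means the raw M-bit sample follows. The
first sample of every channel block is always sent raw so each packet
decodes in isolation, in any order.

Frame layout (all integers big-endian, versioned in docs/formats.md)::

    magic "SH" (2 B) | seq (4 B) | table_id (1 B) | channel count (1 B)
    per channel: name index (1 B) | sample count (2 B) | bit length (4 B)
    payloads, each zero-padded to a byte boundary
    crc32 over everything above (4 B)

The 19-byte header/trailer figure used in the bandwidth arithmetic of the
deployed system is a separate constant handled by the evaluation module;
this frame layout is this package's own.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .bitio import BitReader, BitWriter
from .huffman import CompressionTable, DecodeTree, build_decode_tree
from .residuals import ChannelSpec, CorruptStreamError, decompose

__all__ = [
    "SampleCode",
    "ChannelBlock",
    "EncodedPacket",
    "ReassemblyReport",
    "encode_sample",
    "decode_sample",
    "encode_block",
    "decode_block",
    "build_packet",
    "parse_packet",
    "split_stream",
    "packetize",
    "reassemble_stream",
    "EMPTY_TABLE_ID",
]

MAGIC = b"SH"
HEADER_FMT = ">2sIBB"  # magic, seq, table_id, nchannels
CHAN_FMT = ">BHI"  # name index, sample count, payload bit length
EMPTY_TABLE_ID = 0  # packets encoded before any table exists (all-raw)


@dataclass(frozen=True)
class SampleCode:
    """One sample's code as a bit string; ``is_raw`` marks the fallback path."""

    bits: str
    is_raw: bool


def encode_sample(
    current: int, previous: int, table: CompressionTable, M: int
) -> SampleCode:
    """Code for one sample given its predecessor and the channel's table.

    Total and never fails: classes absent from the table take the raw
    branch (1 indicator bit + M sample bits).
    """
    d = decompose(current, previous, table.m, M)
    code = table.entries.get(d.p)
    if code is None:
        return SampleCode(bits="0" + format(current, f"0{M}b"), is_raw=True)
    q_bits = format(d.q, f"0{table.m}b") if table.m else ""
    return SampleCode(bits=f"1{d.s}{code}{q_bits}", is_raw=False)


def decode_sample(
    reader: BitReader, tree: Optional[DecodeTree], m: int, M: int, previous: int
) -> int:
    """Read exactly one sample code from ``reader`` and reconstruct it."""
    try:
        indicator = reader.read_bit()
        if indicator == 0:
            return reader.read_bits(M)
        s = reader.read_bit()
        if tree is None:
            raise CorruptStreamError("encoded sample but no table available")
        node = tree
        while not node.is_leaf:
            node = node.children[reader.read_bit()]
            if node is None:
                raise CorruptStreamError("bit pattern not in the decode tree")
        q = reader.read_bits(m) if m else 0
        z = (node.cls << m) | q
        value = previous + (z if s else -z)
    except EOFError as exc:
        raise CorruptStreamError("bit stream ended mid-sample") from exc
    if not 0 <= value < (1 << M):
        raise CorruptStreamError(f"decoded sample {value} outside [0, 2**{M})")
    return value


def encode_block(
    samples: Sequence[int] | np.ndarray, table: CompressionTable, spec: ChannelSpec
) -> tuple[bytes, int]:
    """Encode one channel block; returns (payload bytes, exact bit length).

    The first sample is always raw so the block is self-contained; each
    later sample is coded against its predecessor.
    """
    arr = np.asarray(samples, dtype=np.int64)
    if arr.size < 1:
        raise ValueError("a block needs at least one sample")
    M = spec.bit_depth
    if arr.min() < 0 or arr.max() >= (1 << M):
        raise ValueError(f"samples outside [0, 2**{M})")
    if table.m >= M:
        raise ValueError("table bin width exponent must be < bit depth")

    m = table.m
    entries = table.entries
    w = BitWriter()
    w.write_bit(0)
    w.write_bits(int(arr[0]), M)
    # hot loop: inline the decompose arithmetic
    z_arr = np.abs(np.diff(arr))
    s_arr = (np.diff(arr) >= 0).astype(np.int8)
    mask = (1 << m) - 1
    for z, s, cur in zip(z_arr.tolist(), s_arr.tolist(), arr[1:].tolist()):
        code = entries.get(z >> m)
        if code is None:
            w.write_bit(0)
            w.write_bits(cur, M)
        else:
            w.write_bit(1)
            w.write_bit(s)
            w.write_bitstring(code)
            if m:
                w.write_bits(z & mask, m)
    return w.to_bytes(), len(w)


def decode_block(
    payload: bytes,
    nbits: int,
    count: int,
    table: Optional[CompressionTable],
    spec: ChannelSpec,
) -> np.ndarray:
    """Invert :func:`encode_block`; must consume exactly ``nbits`` bits."""
    if count == 0:
        if nbits:
            raise CorruptStreamError("empty block with a non-empty payload")
        return np.zeros(0, dtype=np.int64)
    M = spec.bit_depth
    m = table.m if table is not None else 0
    tree = build_decode_tree(table) if table is not None and table.k else None
    reader = BitReader(payload, nbits)
    out = np.empty(count, dtype=np.int64)
    previous = 0
    for i in range(count):
        previous = decode_sample(reader, tree, m, M, previous)
        out[i] = previous
    if reader.remaining:
        raise CorruptStreamError(f"{reader.remaining} unread bits after block")
    return out


@dataclass(frozen=True)
class ChannelBlock:
    """One channel's payload inside a packet."""

    name: str
    sample_count: int
    bit_length: int
    payload: bytes


@dataclass(frozen=True)
class EncodedPacket:
    sequence_number: int
    table_id: int
    blocks: tuple[ChannelBlock, ...]


def build_packet(
    seq: int,
    table_id: int,
    blocks: Sequence[ChannelBlock],
    roster: Sequence[str],
) -> bytes:
    """Serialize a packet; ``roster`` maps channel names to 1-byte indices."""
    if not 0 <= seq < (1 << 32):
        raise ValueError("sequence number must fit 32 bits")
    if not 0 <= table_id < (1 << 8):
        raise ValueError("table_id must fit 8 bits")
    if len(blocks) > 255:
        raise ValueError("at most 255 channels per packet")
    index = {name: i for i, name in enumerate(roster)}
    out = bytearray(struct.pack(HEADER_FMT, MAGIC, seq, table_id, len(blocks)))
    for b in blocks:
        if b.name not in index:
            raise ValueError(f"channel {b.name!r} not in roster")
        if not 0 <= b.sample_count < (1 << 16):
            raise ValueError("sample count must fit 16 bits")
        if not 0 <= b.bit_length < (1 << 32):
            raise ValueError("bit length must fit 32 bits")
        if len(b.payload) != (b.bit_length + 7) // 8:
            raise ValueError("payload length does not match declared bit length")
        out += struct.pack(CHAN_FMT, index[b.name], b.sample_count, b.bit_length)
    for b in blocks:
        out += b.payload
    out += struct.pack(">I", zlib.crc32(bytes(out)))
    return bytes(out)


def parse_packet(frame: bytes, roster: Sequence[str]) -> EncodedPacket:
    """Parse and CRC-check one frame; raises :class:`CorruptStreamError`."""
    hdr_size = struct.calcsize(HEADER_FMT)
    if len(frame) < hdr_size + 4:
        raise CorruptStreamError("frame shorter than header + CRC")
    crc_stored = struct.unpack(">I", frame[-4:])[0]
    if zlib.crc32(frame[:-4]) != crc_stored:
        raise CorruptStreamError("CRC32 mismatch")
    magic, seq, table_id, nchan = struct.unpack_from(HEADER_FMT, frame)
    if magic != MAGIC:
        raise CorruptStreamError("bad magic")
    chan_size = struct.calcsize(CHAN_FMT)
    pos = hdr_size
    descs = []
    for _ in range(nchan):
        if pos + chan_size > len(frame) - 4:
            raise CorruptStreamError("truncated channel descriptors")
        descs.append(struct.unpack_from(CHAN_FMT, frame, pos))
        pos += chan_size
    blocks = []
    for name_idx, count, nbits in descs:
        if name_idx >= len(roster):
            raise CorruptStreamError(f"channel index {name_idx} not in roster")
        nbytes = (nbits + 7) // 8
        if pos + nbytes > len(frame) - 4:
            raise CorruptStreamError("truncated payload")
        blocks.append(
            ChannelBlock(roster[name_idx], count, nbits, frame[pos : pos + nbytes])
        )
        pos += nbytes
    if pos != len(frame) - 4:
        raise CorruptStreamError("trailing bytes after payloads")
    return EncodedPacket(seq, table_id, tuple(blocks))


def frame_length(buffer: bytes, offset: int = 0) -> int:
    """Length in bytes of the frame starting at ``offset`` (from its header)."""
    hdr_size = struct.calcsize(HEADER_FMT)
    magic, _, _, nchan = struct.unpack_from(HEADER_FMT, buffer, offset)
    if magic != MAGIC:
        raise CorruptStreamError("bad magic")
    chan_size = struct.calcsize(CHAN_FMT)
    total = hdr_size + nchan * chan_size
    for i in range(nchan):
        _, _, nbits = struct.unpack_from(CHAN_FMT, buffer, offset + hdr_size + i * chan_size)
        total += (nbits + 7) // 8
    return total + 4


def split_stream(buffer: bytes) -> list[bytes]:
    """Split a concatenated frame stream into individual frames.

    Frame boundaries come from the declared lengths, so a corrupted length
    field can lose the remainder of the stream; per-frame corruption is
    caught later by the CRC.
    """
    frames = []
    pos = 0
    while pos < len(buffer):
        try:
            n = frame_length(buffer, pos)
        except (CorruptStreamError, struct.error) as exc:
            raise CorruptStreamError(f"unparseable frame at byte {pos}") from exc
        if pos + n > len(buffer):
            raise CorruptStreamError("truncated final frame")
        frames.append(buffer[pos : pos + n])
        pos += n
    return frames


def packetize(
    channels: dict[str, np.ndarray],
    specs: dict[str, ChannelSpec],
    tables: dict[str, CompressionTable],
    table_id: Optional[int] = None,
) -> list[bytes]:
    """Encode a multichannel dataset into a list of self-contained frames.

    Channels missing from ``tables`` are encoded with an empty table
    (every sample raw). ``table_id`` defaults to the tables' common ID, or
    ``EMPTY_TABLE_ID`` when no tables are given.
    """
    if not channels:
        raise ValueError("no channels to packetize")
    roster = list(channels)
    lengths = {len(v) for v in channels.values()}
    if len(lengths) != 1:
        raise ValueError("all channels must have the same length")
    (n_total,) = lengths
    if table_id is None:
        ids = {t.table_id for t in tables.values()}
        table_id = ids.pop() if len(ids) == 1 and tables else EMPTY_TABLE_ID

    frames = []
    seq = 0
    offset = 0
    spp = {name: specs[name].samples_per_packet for name in roster}
    step = spp[roster[0]]
    if any(v != step for v in spp.values()):
        raise ValueError("channels must share samples_per_packet to align packets")
    while offset < n_total:
        blocks = []
        for name in roster:
            chunk = channels[name][offset : offset + step]
            spec = specs[name]
            table = tables.get(name) or CompressionTable(
                m=0, entries={}, M=spec.bit_depth, table_id=EMPTY_TABLE_ID
            )
            payload, nbits = encode_block(chunk, table, spec)
            blocks.append(ChannelBlock(name, len(chunk), nbits, payload))
        frames.append(build_packet(seq, table_id, blocks, roster))
        seq += 1
        offset += step
    return frames


@dataclass
class ReassemblyReport:
    received: int = 0
    decoded: int = 0
    duplicates: int = 0
    corrupt: int = 0
    gaps: list[int] = field(default_factory=list)


def reassemble_stream(
    frames: Iterable[bytes],
    roster: Sequence[str],
    specs: dict[str, ChannelSpec],
    tables_by_id: dict[int, dict[str, CompressionTable]],
) -> tuple[dict[str, np.ndarray], ReassemblyReport]:
    """Decode an unordered multiset of frames back into per-channel series.

    Frames are CRC-checked, sorted by sequence number, exact duplicates
    dropped and gaps reported; bad frames are counted, never fatal.
    ``tables_by_id`` maps a packet's table ID to its per-channel tables
    (ID 0, the all-raw state, needs no entry).
    """
    report = ReassemblyReport()
    by_seq: dict[int, EncodedPacket] = {}
    for frame in frames:
        report.received += 1
        try:
            pkt = parse_packet(frame, roster)
        except CorruptStreamError:
            report.corrupt += 1
            continue
        if pkt.sequence_number in by_seq:
            report.duplicates += 1
            continue
        by_seq[pkt.sequence_number] = pkt

    series: dict[str, list[np.ndarray]] = {name: [] for name in roster}
    seqs = sorted(by_seq)
    if seqs:
        expected = set(range(seqs[0], seqs[-1] + 1))
        report.gaps = sorted(expected - set(seqs))
    for seq in seqs:
        pkt = by_seq[seq]
        tables = tables_by_id.get(pkt.table_id, {})
        try:
            decoded = {
                b.name: decode_block(
                    b.payload, b.bit_length, b.sample_count,
                    tables.get(b.name), specs[b.name],
                )
                for b in pkt.blocks
            }
        except CorruptStreamError:
            report.corrupt += 1
            continue
        for name, values in decoded.items():
            series[name].append(values)
        report.decoded += 1
    out = {
        name: (np.concatenate(parts) if parts else np.zeros(0, dtype=np.int64))
        for name, parts in series.items()
    }
    return out, report
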