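import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selhuff import (
    ChannelBlock,
    ChannelSpec,
    CompressionTable,
    CorruptStreamError,
    build_decode_tree,
    build_packet,
    decode_block,
    decode_sample,
    encode_block,
    encode_sample,
    parse_packet,
    reassemble_stream,
    split_stream,
)
from selhuff.bitio import BitReader, BitWriter
from selhuff.codec import packetize
from conftest import table_from_magnitudes

FIG3_STYLE_TABLE = CompressionTable(m=3, entries={2: "0"}, M=14)
EMPTY14 = CompressionTable(m=0, entries={}, M=14)
EMPTY16 = CompressionTable(m=0, entries={}, M=16)


class TestSampleCodes:
    def test_encoded_sample_is_indicator_sign_code_index(self):
        # residual +20 at m=3: class 2 (code "0"), index 4 -> 1,1,0,100
        code = encode_sample(100, 80, FIG3_STYLE_TABLE, M=14)
        assert not code.is_raw
        assert code.bits == "110100"

    def test_class_missing_from_table_falls_back_to_raw_15_bits(self):
        code = encode_sample(4000, 80, FIG3_STYLE_TABLE, M=14)
        assert code.is_raw and len(code.bits) == 15

    def test_empty_table_16_bit_channel_costs_17_bits(self):
        code = encode_sample(1234, 999, EMPTY16, M=16)
        assert code.is_raw and len(code.bits) == 17

    def _decode(self, bits, table, M, previous):
        w = BitWriter()
        w.write_bitstring(bits)
        tree = build_decode_tree(table) if table.k else None
        return decode_sample(BitReader(w.to_bytes(), len(bits)), tree, table.m, M, previous)

    def test_decode_inverts_the_hand_traced_code(self):
        assert self._decode("110100", FIG3_STYLE_TABLE, 14, previous=80) == 100

    def test_raw_code_ignores_previous_sample(self):
        bits = "0" + format(9999, "014b")
        for previous in (0, 5000):
            assert self._decode(bits, FIG3_STYLE_TABLE, 14, previous) == 9999

    def test_truncated_stream_raises_corrupt(self):
        with pytest.raises(CorruptStreamError):
            self._decode("1", FIG3_STYLE_TABLE, 14, previous=0)

    def test_decoded_value_outside_range_raises_corrupt(self):
        # s=0 makes the reconstruction negative
        with pytest.raises(CorruptStreamError):
            self._decode("100100", FIG3_STYLE_TABLE, 14, previous=3)


class TestBlocks:
    SPEC14 = ChannelSpec("ch", 14, samples_per_packet=50)

    def test_all_raw_block_is_15_bits_per_sample(self):
        _, nbits = encode_block([1, 5000, 10000], EMPTY14, self.SPEC14)
        assert nbits == 45

    def test_single_sample_block_is_raw(self):
        _, nbits = encode_block([123], FIG3_STYLE_TABLE, self.SPEC14)
        assert nbits == 15

    def test_raw_encoded_raw_pattern(self):
        # d0 raw (self-containment), d1 in-table, d2's class absent -> raw
        samples = [80, 100, 2000]
        payload, nbits = encode_block(samples, FIG3_STYLE_TABLE, self.SPEC14)
        assert nbits == 15 + 6 + 15
        out = decode_block(payload, nbits, 3, FIG3_STYLE_TABLE, self.SPEC14)
        assert out.tolist() == samples

    def test_empty_count_decodes_to_empty(self):
        assert decode_block(b"", 0, 0, FIG3_STYLE_TABLE, self.SPEC14).size == 0

    def test_undeclared_leftover_bits_raise_corrupt(self):
        payload, nbits = encode_block([80, 100], FIG3_STYLE_TABLE, self.SPEC14)
        with pytest.raises(CorruptStreamError):
            decode_block(payload, nbits, 1, FIG3_STYLE_TABLE, self.SPEC14)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_round_trip_on_random_blocks_and_tables(self, data):
        M = data.draw(st.integers(4, 16))
        m = data.draw(st.integers(0, M - 1))
        n = data.draw(st.integers(1, 80))
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        samples = rng.integers(0, 1 << M, size=n)
        z = np.abs(np.diff(samples, prepend=0))
        table = table_from_magnitudes(z, m, M, k=data.draw(st.integers(1, 20)))
        spec = ChannelSpec("ch", M)
        payload, nbits = encode_block(samples, table, spec)
        out = decode_block(payload, nbits, n, table, spec)
        assert np.array_equal(out, samples)


class TestPackets:
    ROSTER = ["ecg", "ppg"]

    def _blocks(self):
        spec = ChannelSpec("ecg", 14)
        payload, nbits = encode_block([80, 100, 2000], FIG3_STYLE_TABLE, spec)
        return [ChannelBlock("ecg", 3, nbits, payload)]

    def test_empty_packet_is_12_bytes(self):
        frame = build_packet(0, 1, [], self.ROSTER)
        assert len(frame) == 12

    def test_parse_inverts_build(self):
        frame = build_packet(7, 1, self._blocks(), self.ROSTER)
        pkt = parse_packet(frame, self.ROSTER)
        assert pkt.sequence_number == 7
        assert pkt.table_id == 1
        assert pkt.blocks[0].name == "ecg"
        assert pkt.blocks[0].sample_count == 3

    def test_corrupted_byte_fails_crc(self):
        frame = bytearray(build_packet(7, 1, self._blocks(), self.ROSTER))
        frame[10] ^= 0xFF
        with pytest.raises(CorruptStreamError):
            parse_packet(bytes(frame), self.ROSTER)

    def test_field_overflow_rejected(self):
        with pytest.raises(ValueError):
            build_packet(1 << 32, 1, [], self.ROSTER)
        with pytest.raises(ValueError):
            build_packet(0, 256, [], self.ROSTER)

    def test_split_stream_recovers_frame_boundaries(self):
        frames = [build_packet(i, 1, self._blocks(), self.ROSTER) for i in range(4)]
        assert split_stream(b"".join(frames)) == frames


class TestReassembly:
    def _make_frames(self, seqs, specs, tables, data):
        frames = []
        roster = list(data)
        for seq in seqs:
            blocks = []
            for name in roster:
                payload, nbits = encode_block(data[name], tables[name], specs[name])
                blocks.append(ChannelBlock(name, len(data[name]), nbits, payload))
            frames.append(build_packet(seq, 1, blocks, roster))
        return frames

    def setup_method(self):
        self.specs = {"ecg": ChannelSpec("ecg", 14, 4)}
        self.tables = {"ecg": FIG3_STYLE_TABLE}
        self.data = {"ecg": np.array([80, 100, 2000, 2001])}

    def test_out_of_order_and_duplicates(self):
        frames = self._make_frames([2, 1, 1, 3], self.specs, self.tables, self.data)
        series, report = reassemble_stream(
            frames, ["ecg"], self.specs, {1: self.tables}
        )
        assert report.duplicates == 1 and report.gaps == []
        assert report.decoded == 3
        assert series["ecg"].size == 12

    def test_gap_reporting(self):
        frames = self._make_frames([1, 3], self.specs, self.tables, self.data)
        _, report = reassemble_stream(frames, ["ecg"], self.specs, {1: self.tables})
        assert report.gaps == [2]

    def test_one_corrupt_frame_among_five_is_counted_not_fatal(self):
        frames = self._make_frames([0, 1, 2, 3, 4], self.specs, self.tables, self.data)
        bad = bytearray(frames[2])
        bad[-1] ^= 0x01
        frames[2] = bytes(bad)
        series, report = reassemble_stream(
            frames, ["ecg"], self.specs, {1: self.tables}
        )
        assert report.corrupt == 1 and report.decoded == 4
        assert report.gaps == [2]


def test_packetize_requires_aligned_channels():
    specs = {
        "a": ChannelSpec("a", 14, 50),
        "b": ChannelSpec("b", 14, 50),
    }
    with pytest.raises(ValueError):
        packetize(
            {"a": np.zeros(10, dtype=np.int64), "b": np.zeros(9, dtype=np.int64)},
            specs, {},
        )
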