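# File formats

All formats are versioned; the current version of every schema is 1.

## Channel sidecar (JSON)

Describes the channels of a raw sample file.

```json
{
 "format": "selhuff-channels",
 "version": 1,
 "sampling_rate": 1600.0,
 "channels": [
  {"name": "ecg", "bit_depth": 14, "samples_per_packet": 50},
  {"name": "gcg_x", "bit_depth": 16, "samples_per_packet": 50}
 ]
}
```

`sampling_rate` (Hz) is optional metadata. Channel order is significant: it
fixes the column order of raw files and the 1-byte name indices used in
packet frames.

## Raw sample files

* **Delimited text** (any extension except `.bin`/`.raw`): first line is the
  tab-separated channel names, then one row of unsigned decimal integers per
  time step, one column per channel in sidecar order.
* **Raw binary** (`.bin`/`.raw`): little-endian unsigned 16-bit samples,
  interleaved by channel in sidecar order. Only valid for bit depths up
  to 16.

## Compression table file (JSON)

One document holds the tables of all channels, keyed by channel name.
Codewords are explicit bit strings; no canonical-Huffman compaction is
applied because tables are tiny (k ≤ 30).

```json
{
 "format": "selhuff-tables",
 "version": 1,
 "channels": {
  "ecg": {
   "table_id": 1,
   "M": 14,
   "m": 2,
   "k": 3,
   "entries": {"0": "0", "1": "10", "2": "11"}
  }
 }
}
```

Keys of `entries` are probability classes (decimal strings); values are the
prefix-free codewords. `M` is the channel bit depth, `m` the bin-width
exponent. `table_id` tags encoded packets so encoder and decoder can agree
on which tables were in force (ID 1 is used for tables computed online; ID
0 means "no table yet", i.e. all-raw encoding).

## Packet frame (binary)

All multi-byte integers are big-endian.

| field                 | size | notes                                   |
|-----------------------|------|-----------------------------------------|
| magic                 | 2 B  | ASCII `SH`                              |
| sequence number       | 4 B  | monotone per stream                     |
| table ID              | 1 B  |                                         |
| channel count         | 1 B  |                                         |
| per channel: name idx | 1 B  | index into the sidecar's channel order  |
| per channel: samples  | 2 B  | sample count in this frame              |
| per channel: bits     | 4 B  | exact payload bit length                |
| payloads              | var  | each zero-padded to a byte boundary     |
| CRC32                 | 4 B  | zlib CRC32 over all preceding bytes     |

An empty frame (0 channels) is exactly 12 bytes. A stream file is a plain
concatenation of frames; boundaries are recovered from the declared
lengths.

## Sample bitstream

Within a payload, bits are packed most-significant-bit first. Each sample
code is either:

* `1 | sign (1 bit) | class codeword | index (m bits, MSB first)` — the
  residual's probability class is in the table; sign bit 1 means a
  non-negative residual;
* `0 | raw sample (M bits, MSB first)` — fallback when the class has no
  codeword.

The first sample of every channel block is always written in the raw form
so each packet decodes without reference to any other packet.
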