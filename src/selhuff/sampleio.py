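"""Raw sample files, the channel-spec sidecar, and encoded stream files.

Two raw formats are supported (schemas in docs/formats.md):

* delimited text — a header line of channel names, then one row of unsigned
  integers per time step, tab-separated;
* raw binary — little-endian unsigned 16-bit samples, interleaved by
  channel in sidecar order (bit depths above 16 need the text format).

Both rely on a JSON sidecar describing the channels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .residuals import ChannelSpec

__all__ = [
    "write_sidecar",
    "read_sidecar",
    "write_text",
    "read_text",
    "write_binary",
    "read_binary",
    "read_samples",
    "write_samples",
]


def write_sidecar(path: str | Path, specs: dict[str, ChannelSpec],
                  sampling_rate: float | None = None) -> None:
    doc = {
        "format": "selhuff-channels",
        "version": 1,
        "channels": [
            {
                "name": s.name,
                "bit_depth": s.bit_depth,
                "samples_per_packet": s.samples_per_packet,
            }
            for s in specs.values()
        ],
    }
    if sampling_rate is not None:
        doc["sampling_rate"] = sampling_rate
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_sidecar(path: str | Path) -> dict[str, ChannelSpec]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "selhuff-channels":
        raise ValueError(f"{path}: not a selhuff channel sidecar")
    specs = {}
    for c in doc["channels"]:
        specs[c["name"]] = ChannelSpec(
            c["name"], int(c["bit_depth"]), int(c.get("samples_per_packet", 50))
        )
    return specs


def write_text(path: str | Path, channels: dict[str, np.ndarray]) -> None:
    names = list(channels)
    data = np.column_stack([channels[n] for n in names])
    header = "\t".join(names)
    np.savetxt(path, data, fmt="%d", delimiter="\t", header=header, comments="")


def read_text(path: str | Path) -> dict[str, np.ndarray]:
    with open(path) as fh:
        names = fh.readline().split()
    data = np.loadtxt(path, dtype=np.int64, skiprows=1, ndmin=2)
    if data.shape[1] != len(names):
        raise ValueError(f"{path}: column count does not match header")
    return {name: data[:, i] for i, name in enumerate(names)}


def write_binary(path: str | Path, channels: dict[str, np.ndarray],
                 specs: dict[str, ChannelSpec]) -> None:
    for name, arr in channels.items():
        if specs[name].bit_depth > 16:
            raise ValueError("binary format is limited to 16-bit samples")
        if arr.min(initial=0) < 0 or arr.max(initial=0) >= (1 << 16):
            raise ValueError(f"channel {name!r} does not fit uint16")
    data = np.column_stack([channels[n] for n in specs]).astype("<u2")
    data.tofile(path)


def read_binary(path: str | Path, specs: dict[str, ChannelSpec]) -> dict[str, np.ndarray]:
    flat = np.fromfile(path, dtype="<u2")
    n_chan = len(specs)
    if flat.size % n_chan:
        raise ValueError(f"{path}: size is not a multiple of {n_chan} channels")
    data = flat.reshape(-1, n_chan).astype(np.int64)
    return {name: data[:, i] for i, name in enumerate(specs)}


def read_samples(path: str | Path, specs: dict[str, ChannelSpec]) -> dict[str, np.ndarray]:
    """Dispatch on extension: ``.bin``/``.raw`` binary, anything else text."""
    path = Path(path)
    if path.suffix in {".bin", ".raw"}:
        return read_binary(path, specs)
    return read_text(path)


def write_samples(path: str | Path, channels: dict[str, np.ndarray],
                  specs: dict[str, ChannelSpec]) -> None:
    path = Path(path)
    if path.suffix in {".bin", ".raw"}:
        write_binary(path, channels, specs)
    else:
        write_text(path, channels)
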