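"""Huffman code construction over the top-k probability classes.

Only the ``k`` most frequent classes get codewords ("selective" coding);
everything else falls back to a raw sample behind a 1-bit indicator. Tables
are tiny (``k <= 30`` in practice) and are serialized as explicit
class -> bitstring pairs so that an embedded decoder can load them directly.

Tie-breaking is fully deterministic: when two subtrees have equal weight the
one containing the smaller class index merges first and receives bit 0, so
identical inputs produce bit-identical tables on any platform.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "CompressionTable",
    "DecodeTree",
    "CorruptTableError",
    "build_table",
    "build_decode_tree",
    "code_length",
    "tables_to_json",
    "tables_from_json",
]


class CorruptTableError(Exception):
    """A compression table violates the prefix-free invariant."""


@dataclass(frozen=True)
class CompressionTable:
    """Prefix-free code ``T_{m,k}`` from probability class to codeword.

    ``entries`` maps class index -> codeword bit string (e.g. ``"010"``).
    ``m`` is the bin-width exponent the table was trained at, ``M`` the bit
    depth of the channel, ``table_id`` the small integer used to tag packets
    (tables computed online carry ID 1).
    """

    m: int
    entries: dict[int, str]
    M: int
    table_id: int = 1

    @property
    def k(self) -> int:
        return len(self.entries)

    def __post_init__(self) -> None:
        max_class = (1 << (self.M - self.m)) - 1
        for cls, code in self.entries.items():
            if not code or set(code) - {"0", "1"}:
                raise ValueError(f"invalid codeword {code!r} for class {cls}")
            if not 0 <= cls <= max_class:
                raise ValueError(
                    f"class {cls} not representable in {self.M - self.m} bits"
                )

    def __contains__(self, cls: int) -> bool:
        return cls in self.entries


@dataclass
class DecodeTree:
    """Binary prefix tree; leaves carry the decoded probability class."""

    cls: Optional[int] = None
    children: list[Optional["DecodeTree"]] = field(default_factory=lambda: [None, None])

    @property
    def is_leaf(self) -> bool:
        return self.cls is not None


def build_table(
    sorted_class_counts: Sequence[tuple[int, int]],
    k: int,
    m: int,
    M: int,
    table_id: int = 1,
) -> CompressionTable:
    """Huffman table over the first ``k`` (class, count) pairs.

    The input must already be sorted most-frequent-first (see
    :func:`selhuff.histograms.sorted_classes`). For the degenerate ``k = 1``
    the single class gets codeword ``"0"`` (one bit) so the stream stays
    self-delimiting.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(sorted_class_counts):
        raise ValueError(
            f"k={k} exceeds the {len(sorted_class_counts)} available classes"
        )
    chosen = sorted_class_counts[:k]
    if any(c <= 0 for _, c in chosen):
        raise ValueError("counts must be positive")

    if k == 1:
        cls = chosen[0][0]
        return CompressionTable(m=m, entries={cls: "0"}, M=M, table_id=table_id)

    # Heap items: (weight, min contained class, payload). Payload is either a
    # leaf class or a pair of already-merged items; bit 0 goes to the item
    # popped first (lower weight / lower min class).
    counter = 0  # heap needs a total order; payloads are not comparable
    heap: list[tuple[int, int, int, object]] = []
    for cls, cnt in chosen:
        heapq.heappush(heap, (cnt, cls, counter, cls))
        counter += 1
    while len(heap) > 1:
        w0, mc0, _, p0 = heapq.heappop(heap)
        w1, mc1, _, p1 = heapq.heappop(heap)
        heapq.heappush(heap, (w0 + w1, min(mc0, mc1), counter, (p0, p1)))
        counter += 1

    entries: dict[int, str] = {}

    def assign(payload: object, prefix: str) -> None:
        if isinstance(payload, tuple):
            assign(payload[0], prefix + "0")
            assign(payload[1], prefix + "1")
        else:
            entries[payload] = prefix

    assign(heap[0][3], "")
    return CompressionTable(m=m, entries=entries, M=M, table_id=table_id)


def build_decode_tree(table: CompressionTable) -> DecodeTree:
    """Prefix tree for instantaneous decoding; raises on prefix violations."""
    root = DecodeTree()
    for cls, code in sorted(table.entries.items()):
        node = root
        for i, bit in enumerate(code):
            if node.is_leaf:
                raise CorruptTableError(
                    f"codeword for class {cls} extends past a leaf"
                )
            b = int(bit)
            if node.children[b] is None:
                node.children[b] = DecodeTree()
            node = node.children[b]
            if i == len(code) - 1:
                if node.cls is not None or node.children != [None, None]:
                    raise CorruptTableError(
                        f"codeword for class {cls} is a prefix of another"
                    )
                node.cls = cls
    return root


def code_length(table: CompressionTable, cls: int) -> Optional[int]:
    """Length in bits of the codeword for ``cls``, or ``None`` if absent."""
    code = table.entries.get(cls)
    return None if code is None else len(code)


# ---------------------------------------------------------------------------
# Text serialization (one JSON document holding the tables for all channels,
# keyed by channel name; schema documented in docs/formats.md).

def tables_to_json(tables: dict[str, CompressionTable]) -> str:
    doc = {
        "format": "selhuff-tables",
        "version": 1,
        "channels": {
            name: {
                "table_id": t.table_id,
                "M": t.M,
                "m": t.m,
                "k": t.k,
                "entries": {str(cls): code for cls, code in sorted(t.entries.items())},
            }
            for name, t in tables.items()
        },
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def tables_from_json(text: str) -> dict[str, CompressionTable]:
    doc = json.loads(text)
    if doc.get("format") != "selhuff-tables":
        raise ValueError("not a selhuff table file")
    out: dict[str, CompressionTable] = {}
    for name, spec in doc["channels"].items():
        table = CompressionTable(
            m=int(spec["m"]),
            entries={int(c): str(code) for c, code in spec["entries"].items()},
            M=int(spec["M"]),
            table_id=int(spec["table_id"]),
        )
        if table.k != int(spec["k"]):
            raise ValueError(f"table for {name!r}: k does not match entry count")
        build_decode_tree(table)  # validates prefix-freeness
        out[name] = table
    return out
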