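"""Binned interval index over genomic records.

A single-level fixed-width bin index: the chromosome is cut into bins of
``bin_size`` bases and each record ordinal is registered in *every* bin its
half-open span overlaps. A region query therefore touches only
``ceil(region length / bin_size) + 1`` bins instead of scanning the whole
record table, which is what makes multi-resolution browsing over large files
responsive. Duplicates from multi-bin registration are removed at query
time with a seen-set.

The index persists as a plain-text JSON sidecar (``<dataset>.gvx``) carrying
a checksum of the source file (size plus a hash of its first and last
64 KiB) so a stale index against an edited source is detected on load.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

from .genome_model import Region

__all__ = [
    "IndexError_",
    "StaleIndexError",
    "BinIndex",
    "DEFAULT_BIN_SIZE",
    "build_index",
    "query_index",
    "persist_index",
    "load_index",
    "source_checksum",
]

DEFAULT_BIN_SIZE = 4096

_MAGIC = "GVX"
_VERSION = 1
_HASH_WINDOW = 64 * 1024


class IndexError_(ValueError):
    """Malformed or unreadable index file."""


class StaleIndexError(IndexError_):
    """The source file changed since the index was built."""


def source_checksum(path: str) -> str:
    """Cheap content fingerprint: file size + SHA-256 of head and tail 64 KiB."""
    size = os.path.getsize(path)
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read(_HASH_WINDOW))
        if size > _HASH_WINDOW:
            fh.seek(max(_HASH_WINDOW, size - _HASH_WINDOW))
            h.update(fh.read(_HASH_WINDOW))
    return f"{size}:{h.hexdigest()}"


@dataclass
class BinIndex:
    bin_size: int
    #: chrom -> {bin number -> list of record ordinals}
    bins: dict[str, dict[int, list[int]]] = field(default_factory=dict)
    #: ordinal -> (region, byte offset into the source file)
    records: list[tuple[Region, int]] = field(default_factory=list)
    checksum: str | None = None
    #: instrumentation: bins inspected by the most recent query
    last_query_bins_touched: int = 0

    @property
    def record_count(self) -> int:
        return len(self.records)


def _bin_range(start: int, end: int, bin_size: int) -> range:
    # every bin a half-open span [start, end) crosses
    return range(start // bin_size, (end - 1) // bin_size + 1)


def build_index(
    records: list[tuple[Region, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
    checksum: str | None = None,
) -> BinIndex:
    """Build a :class:`BinIndex` from ``(region, byte_offset)`` pairs.

    Construction is order-independent up to ordinal relabeling: the same
    records in any permutation index the same spans.
    """
    if bin_size <= 0:
        raise IndexError_(f"bin_size must be positive, got {bin_size}")
    index = BinIndex(bin_size=bin_size, checksum=checksum)
    for ordinal, (region, offset) in enumerate(records):
        index.records.append((region, offset))
        chrom_bins = index.bins.setdefault(region.chrom, {})
        for b in _bin_range(region.start, region.end, bin_size):
            chrom_bins.setdefault(b, []).append(ordinal)
    return index


def query_index(index: BinIndex, region: Region) -> list[int]:
    """Ordinals of all records overlapping ``region`` (half-open test).

    Result is deduplicated and sorted by ``(start, end, ordinal)``. An
    unknown chromosome yields an empty list, not an error.
    """
    chrom_bins = index.bins.get(region.chrom)
    index.last_query_bins_touched = 0
    if not chrom_bins:
        return []
    seen: set[int] = set()
    hits: list[tuple[int, int, int]] = []
    for b in _bin_range(region.start, region.end, index.bin_size):
        index.last_query_bins_touched += 1
        for ordinal in chrom_bins.get(b, ()):
            if ordinal in seen:
                continue
            seen.add(ordinal)
            r, _ = index.records[ordinal]
            if r.start < region.end and region.start < r.end:
                hits.append((r.start, r.end, ordinal))
    hits.sort()
    return [ordinal for _, _, ordinal in hits]


def persist_index(index: BinIndex, path: str) -> int:
    """Write the index sidecar; returns bytes written.

    Only the record table is stored — bins are rebuilt on load, which keeps
    the sidecar small and trivially versionable.
    """
    doc = {
        "magic": _MAGIC,
        "version": _VERSION,
        "bin_size": index.bin_size,
        "checksum": index.checksum,
        "records": [
            [r.chrom, r.start, r.end, r.strand, offset]
            for r, offset in index.records
        ],
    }
    text = json.dumps(doc, separators=(",", ":"))
    with open(path, "w") as fh:
        fh.write(text)
    return len(text)


def load_index(path: str, source_path: str | None = None) -> BinIndex:
    """Load a persisted index, verifying the source checksum if given."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise IndexError_(f"cannot read index {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("magic") != _MAGIC:
        raise IndexError_(f"{path} is not a genoviz index file")
    if doc.get("version") != _VERSION:
        raise IndexError_(
            f"{path}: unsupported index version {doc.get('version')!r}"
        )
    if source_path is not None and doc.get("checksum") is not None:
        current = source_checksum(source_path)
        if current != doc["checksum"]:
            raise StaleIndexError(
                f"index {path} is stale: source {source_path} changed "
                f"(expected {doc['checksum']}, found {current})"
            )
    try:
        records = [
            (Region(chrom, start, end, strand), offset)
            for chrom, start, end, strand, offset in doc["records"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise IndexError_(f"{path}: corrupt record table: {exc}") from exc
    return build_index(records, bin_size=doc["bin_size"], checksum=doc.get("checksum"))


def sidecar_path(dataset_path: str) -> str:
    return dataset_path + ".gvx"
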