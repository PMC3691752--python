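"""Region-parameterized data providers: detail vs summary payloads.

A provider answers "give me the data in this window" for one dataset. When
the window holds few records they are returned individually (*detail* mode);
when it holds more than ``max_detail`` of them the provider switches to
*summary* mode and returns per-bin aggregates instead, because shipping a
million individual reads to a renderer is neither feasible nor useful. The
flip threshold and bin count are configuration with documented defaults
(``max_detail=5000``, ``nbins=1000``); a region holding exactly
``max_detail`` records still returns detail.

Summary statistics:

``count``
    records overlapping each bin (a record spanning k bins contributes to
    each of the k — coverage semantics, not start-bin binning).
``mean`` / ``max`` / ``min``
    for quantitative (signal) datasets only; ``mean`` is base-weighted so
    the result does not depend on how the signal was segmented.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import format_io, indexing
from .format_io import FEATURE_FORMATS, SIGNAL_FORMATS, Feature, Table
from .genome_model import Genome, Region

__all__ = [
    "ProviderError",
    "OverLimitError",
    "Dataset",
    "SummaryBins",
    "DataPayload",
    "FilterSpec",
    "ProviderCache",
    "DEFAULT_MAX_DETAIL",
    "DEFAULT_NBINS",
    "count_in_region",
    "get_detail",
    "get_summary",
    "get_data",
    "get_genome_wide",
    "composite_summary",
    "apply_filters",
    "column_stats",
    "cached_get_data",
    "payload_to_json",
]

DEFAULT_MAX_DETAIL = 5000
DEFAULT_NBINS = 1000

SUMMARY_STATS = ("count", "max", "mean", "min")


class ProviderError(ValueError):
    pass


class OverLimitError(ProviderError):
    """Detail was requested for a region holding more than max_detail records."""


class Dataset:
    """A dataset on disk plus the machinery to query it by region."""

    def __init__(
        self,
        path: str,
        format: str,
        columns: format_io.IntervalColumns | None = None,
    ):
        if format not in FEATURE_FORMATS + SIGNAL_FORMATS + ("vcf",):
            raise ProviderError(f"unsupported dataset format {format!r}")
        self.path = path
        self.format = format
        self.columns = columns
        self._records: list | None = None

    @property
    def kind(self) -> str:
        if self.format in SIGNAL_FORMATS:
            return "signal"
        if self.format == "vcf":
            return "variant"
        return "feature"

    def records(self) -> list:
        """All records, parsed once and cached in memory."""
        if self._records is None:
            if self.kind == "signal":
                self._records = format_io.read_signal(self.path, self.format)
            elif self.kind == "variant":
                self._records = format_io.read_variants(self.path)
            else:
                self._records = format_io.read_features(
                    self.path, self.format, columns=self.columns
                )
        return self._records

    def scan(self):
        return format_io.scan_records(self.path, self.format, columns=self.columns)

    def build_index(self, bin_size: int = indexing.DEFAULT_BIN_SIZE) -> indexing.BinIndex:
        return indexing.build_index(
            list(self.scan()),
            bin_size=bin_size,
            checksum=indexing.source_checksum(self.path),
        )

    def ensure_index(
        self, bin_size: int = indexing.DEFAULT_BIN_SIZE, persist: bool = True
    ) -> indexing.BinIndex:
        """Load the ``.gvx`` sidecar if fresh, else (re)build and persist it."""
        import os

        sidecar = indexing.sidecar_path(self.path)
        if os.path.exists(sidecar):
            try:
                return indexing.load_index(sidecar, source_path=self.path)
            except indexing.IndexError_:
                pass  # stale or corrupt: rebuild below
        index = self.build_index(bin_size=bin_size)
        if persist:
            try:
                indexing.persist_index(index, sidecar)
            except OSError:
                pass  # read-only location: serve from memory
        return index

    def materialize(self, index: indexing.BinIndex, ordinals: Sequence[int]) -> list:
        """Fetch full records for the given ordinals.

        Cold path: one forward pass over the file, seeking to each record's
        byte offset. When the record table is already parsed in memory
        (``records()`` was called), ordinals are served from it directly.
        """
        if self._records is not None:
            records = [self._records[o] for o in ordinals]
        else:
            records = []
            by_offset = sorted((index.records[o][1], o) for o in ordinals)
            memory = None
            for offset, ordinal in by_offset:
                if offset < 0:  # wiggle: no per-record offsets, use parsed list
                    if memory is None:
                        memory = self.records()
                    records.append(memory[ordinal])
                else:
                    records.append(
                        format_io.record_at_offset(
                            self.path, self.format, offset, columns=self.columns
                        )
                    )
        records.sort(key=lambda r: (r.region.start, r.region.end))
        return records

    def values_by_ordinal(self) -> list[float]:
        if self.kind != "signal":
            raise ProviderError(
                f"dataset {self.path} ({self.format}) carries no per-record "
                "values; mean/max/min summaries need a quantitative dataset"
            )
        return [p.value for p in self.records()]


@dataclass
class SummaryBins:
    """Per-bin aggregate values over a region.

    Bin ``i`` covers ``[start + i*w, start + (i+1)*w)`` with ``w = region
    length // nbins``; the last bin absorbs the remainder. When ``nbins``
    exceeds the region length it is clamped to one bin per base.
    Empty bins hold 0 under ``count`` and ``None`` under mean/max/min.
    """

    region: Region
    nbins: int
    stat: str
    values: list

    def bin_bounds(self, i: int) -> tuple[int, int]:
        w = self.region.length // self.nbins
        lo = self.region.start + i * w
        hi = self.region.end if i == self.nbins - 1 else lo + w
        return lo, hi


@dataclass
class DataPayload:
    """What a provider returns: records (detail) or bins (summary)."""

    mode: str  # "detail" | "summary"
    records: list | SummaryBins
    total_in_region: int
    message: str | None = None

    def __post_init__(self):
        if self.mode not in ("detail", "summary"):
            raise ProviderError(f"bad payload mode {self.mode!r}")
        if self.mode == "detail" and len(self.records) != self.total_in_region:
            raise ProviderError(
                "detail payload record count must equal total_in_region"
            )


@dataclass(frozen=True)
class FilterSpec:
    """A numeric range filter on a record attribute.

    ``attribute`` is ``score``, ``mapq``, or a named GFF/GTF attribute. A
    record passes when ``min <= value <= max``; records missing the
    attribute (or with a non-numeric value) pass iff ``missing_passes``
    (default true — filters are opt-in restrictive).
    """

    attribute: str
    min: float = -math.inf
    max: float = math.inf
    missing_passes: bool = True

    def __post_init__(self):
        if self.min > self.max:
            raise ProviderError(
                f"filter on {self.attribute!r}: min {self.min} > max {self.max}"
            )

    def value_of(self, record) -> float | None:
        if self.attribute == "score":
            return getattr(record, "score", None)
        if self.attribute == "qual":
            return getattr(record, "qual", None)
        attrs = getattr(record, "attributes", None) or {}
        raw = attrs.get(self.attribute)
        if raw is None:
            return None
        try:
            return float(raw)
        except (TypeError, ValueError):
            return None

    def passes(self, record) -> bool:
        value = self.value_of(record)
        if value is None:
            return self.missing_passes
        return self.min <= value <= self.max

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "min": None if self.min == -math.inf else self.min,
            "max": None if self.max == math.inf else self.max,
            "missing_passes": self.missing_passes,
        }

    @classmethod
    def from_dict(cls, d) -> "FilterSpec":
        return cls(
            attribute=d["attribute"],
            min=-math.inf if d.get("min") is None else float(d["min"]),
            max=math.inf if d.get("max") is None else float(d["max"]),
            missing_passes=bool(d.get("missing_passes", True)),
        )


# ---------------------------------------------------------------------------
# core queries


def count_in_region(
    dataset: Dataset, index: indexing.BinIndex, region: Region
) -> int:
    return len(indexing.query_index(index, region))


def get_detail(
    dataset: Dataset,
    index: indexing.BinIndex,
    region: Region,
    max_detail: int = DEFAULT_MAX_DETAIL,
) -> DataPayload:
    """Individual records overlapping ``region``, sorted by (start, end).

    Raises :class:`OverLimitError` when the region holds more than
    ``max_detail`` records; the caller should ask for a summary instead.
    """
    ordinals = indexing.query_index(index, region)
    if len(ordinals) > max_detail:
        raise OverLimitError(
            f"{len(ordinals)} records in {region.chrom}:{region.start}-"
            f"{region.end} exceed max_detail={max_detail}; request a summary"
        )
    records = dataset.materialize(index, ordinals)
    return DataPayload(mode="detail", records=records, total_in_region=len(records))


def _effective_bins(region: Region, nbins: int) -> tuple[int, int]:
    if nbins < 1:
        raise ProviderError(f"nbins must be >= 1, got {nbins}")
    nbins = min(nbins, region.length)
    return nbins, region.length // nbins


def _bin_of(pos: int, region: Region, nbins: int, w: int) -> int:
    return min((pos - region.start) // w, nbins - 1)


def get_summary(
    dataset: Dataset,
    index: indexing.BinIndex,
    region: Region,
    nbins: int = DEFAULT_NBINS,
    stat: str = "count",
) -> SummaryBins:
    """Per-bin aggregate over ``region`` (see module docstring for semantics)."""
    if stat not in SUMMARY_STATS:
        raise ProviderError(f"unknown summary stat {stat!r}")
    nbins, w = _effective_bins(region, nbins)
    ordinals = indexing.query_index(index, region)

    if stat == "count":
        values = [0.0] * nbins
        for o in ordinals:
            r, _ = index.records[o]
            b0 = _bin_of(max(r.start, region.start), region, nbins, w)
            b1 = _bin_of(min(r.end, region.end) - 1, region, nbins, w)
            for b in range(b0, b1 + 1):
                values[b] += 1
        return SummaryBins(region, nbins, stat, values)

    point_values = dataset.values_by_ordinal()
    if stat == "mean":
        weighted = [0.0] * nbins
        covered = [0] * nbins
    else:
        extremes: list[float | None] = [None] * nbins
    bins = SummaryBins(region, nbins, stat, [])
    for o in ordinals:
        r, _ = index.records[o]
        v = point_values[o]
        b0 = _bin_of(max(r.start, region.start), region, nbins, w)
        b1 = _bin_of(min(r.end, region.end) - 1, region, nbins, w)
        for b in range(b0, b1 + 1):
            lo, hi = bins.bin_bounds(b)
            overlap = min(r.end, hi, region.end) - max(r.start, lo)
            if overlap <= 0:
                continue
            if stat == "mean":
                weighted[b] += v * overlap
                covered[b] += overlap
            elif stat == "max":
                extremes[b] = v if extremes[b] is None else max(extremes[b], v)
            else:
                extremes[b] = v if extremes[b] is None else min(extremes[b], v)
    if stat == "mean":
        bins.values = [
            weighted[b] / covered[b] if covered[b] else None for b in range(nbins)
        ]
    else:
        bins.values = extremes
    return bins


def get_data(
    dataset: Dataset,
    index: indexing.BinIndex,
    region: Region,
    max_detail: int = DEFAULT_MAX_DETAIL,
    nbins: int = DEFAULT_NBINS,
) -> DataPayload:
    """Detail when the region holds ``<= max_detail`` records, else summary."""
    total = count_in_region(dataset, index, region)
    if total <= max_detail:
        payload = get_detail(dataset, index, region, max_detail=max_detail)
        return payload
    bins = get_summary(dataset, index, region, nbins=nbins, stat="count")
    return DataPayload(
        mode="summary",
        records=bins,
        total_in_region=total,
        message=(
            f"{total} records exceed the {max_detail}-record detail limit; "
            f"returning {bins.nbins}-bin coverage counts"
        ),
    )


def get_genome_wide(
    dataset: Dataset,
    index: indexing.BinIndex,
    genome: Genome,
    bins_per_chrom: int = 100,
    stat: str = "count",
) -> list[SummaryBins]:
    """One :class:`SummaryBins` per chromosome — the whole-genome first view."""
    return [
        get_summary(
            dataset, index, Region(name, 0, length), nbins=bins_per_chrom, stat=stat
        )
        for name, length in genome.chromosomes
    ]


def composite_summary(
    datasets: Sequence[Dataset],
    indexes: Sequence[indexing.BinIndex],
    region: Region,
    nbins: int = DEFAULT_NBINS,
    stat: str = "mean",
) -> np.ndarray:
    """Aligned per-bin summaries for several tracks as one matrix.

    This backs composite ("rainbow") displays: row k is exactly
    ``get_summary(datasets[k], ...)`` and all rows share bin boundaries.
    Missing bins are NaN.
    """
    if len(datasets) != len(indexes):
        raise ProviderError("datasets and indexes must align")
    if stat != "count":
        for ds in datasets:
            if ds.kind != "signal":
                raise ProviderError(
                    f"composite {stat} needs quantitative datasets; "
                    f"{ds.path} is {ds.kind}"
                )
    rows = []
    nbins_eff, _ = _effective_bins(region, nbins)
    for ds, idx in zip(datasets, indexes):
        bins = get_summary(ds, idx, region, nbins=nbins, stat=stat)
        rows.append([math.nan if v is None else float(v) for v in bins.values])
    return np.array(rows, dtype=float).reshape(len(datasets), nbins_eff)


def apply_filters(payload: DataPayload, filters: Sequence[FilterSpec]) -> DataPayload:
    """Retain records passing *every* filter (conjunction). Idempotent.

    Only detail payloads can be filtered — summary bins no longer carry the
    attributes filters act on.
    """
    if payload.mode != "detail":
        raise ProviderError(
            "filters act on individual records; summarize after filtering "
            "or request a detail payload"
        )
    kept = [r for r in payload.records if all(f.passes(r) for f in filters)]
    return DataPayload(
        mode="detail",
        records=kept,
        total_in_region=len(kept),
        message=payload.message,
    )


def column_stats(table: Table, columns: Sequence[str]) -> dict[str, dict]:
    """Per-column min/max/mean/sd/n/n_missing for numeric table columns.

    Missing cells are excluded from every statistic; ``sd`` uses the n-1
    denominator and is None when fewer than two values remain.
    """
    out: dict[str, dict] = {}
    for name in columns:
        if name not in table.names:
            raise ProviderError(f"no such column {name!r}")
        if table.column_type(name) != "numeric":
            raise ProviderError(f"column {name!r} is not numeric")
        cells = table.column(name)
        values = np.array([c for c in cells if c is not None], dtype=float)
        n = len(values)
        out[name] = {
            "min": float(values.min()) if n else None,
            "max": float(values.max()) if n else None,
            "mean": float(values.mean()) if n else None,
            "sd": float(values.std(ddof=1)) if n >= 2 else None,
            "n": n,
            "n_missing": len(cells) - n,
        }
    return out


# ---------------------------------------------------------------------------
# caching


class ProviderCache:
    """LRU cache of payloads keyed by (dataset, region, max_detail, nbins).

    Beyond exact-key hits, a cached *detail* payload whose region contains
    the queried region (same max_detail) is reused by sub-selecting its
    records — panning within an already-fetched window never refetches.
    """

    def __init__(self, capacity: int = 64):
        if capacity < 1:
            raise ProviderError("cache capacity must be >= 1")
        self.capacity = capacity
        self._entries: OrderedDict[tuple, DataPayload] = OrderedDict()
        self.hits = 0
        self.misses = 0

    @staticmethod
    def _key(dataset: Dataset, region: Region, max_detail: int, nbins: int) -> tuple:
        return (dataset.path, region.chrom, region.start, region.end, max_detail, nbins)

    def _store(self, key: tuple, payload: DataPayload) -> None:
        self._entries[key] = payload
        self._entries.move_to_end(key)
        while len(self._entries) > self.capacity:
            self._entries.popitem(last=False)

    def lookup(
        self, dataset: Dataset, region: Region, max_detail: int, nbins: int
    ) -> DataPayload | None:
        key = self._key(dataset, region, max_detail, nbins)
        if key in self._entries:
            self._entries.move_to_end(key)
            self.hits += 1
            return self._entries[key]
        # containment reuse: sub-select from a larger cached detail window
        for (path, chrom, start, end, md, nb), payload in self._entries.items():
            if (
                path == dataset.path
                and md == max_detail
                and payload.mode == "detail"
                and chrom == region.chrom
                and start <= region.start
                and region.end <= end
            ):
                sub = [r for r in payload.records if r.region.overlaps(region)]
                derived = DataPayload(
                    mode="detail", records=sub, total_in_region=len(sub)
                )
                self._entries.move_to_end((path, chrom, start, end, md, nb))
                self.hits += 1
                self._store(key, derived)
                return derived
        self.misses += 1
        return None


def cached_get_data(
    cache: ProviderCache,
    dataset: Dataset,
    index: indexing.BinIndex,
    region: Region,
    max_detail: int = DEFAULT_MAX_DETAIL,
    nbins: int = DEFAULT_NBINS,
) -> DataPayload:
    """:func:`get_data` through the cache; bit-identical to the uncached path."""
    found = cache.lookup(dataset, region, max_detail, nbins)
    if found is not None:
        return found
    payload = get_data(dataset, index, region, max_detail=max_detail, nbins=nbins)
    cache._store(cache._key(dataset, region, max_detail, nbins), payload)
    return payload


# ---------------------------------------------------------------------------
# serialization


def _record_to_json(record) -> list:
    r = record.region
    if isinstance(record, Feature):
        return [r.start, r.end, record.name, record.score, r.strand, record.attributes]
    if isinstance(record, format_io.SignalPoint):
        return [r.start, r.end, record.value]
    if isinstance(record, format_io.Variant):
        return [r.start, r.end, record.ref, record.alts, record.qual]
    raise ProviderError(f"cannot serialize record type {type(record).__name__}")


def payload_to_json(payload: DataPayload) -> dict:
    """The documented payload JSON schema (what the CLI `query` emits)."""
    doc: dict = {
        "mode": payload.mode,
        "total": payload.total_in_region,
        "message": payload.message,
    }
    if payload.mode == "detail":
        doc["data"] = [_record_to_json(rec) for rec in payload.records]
    else:
        bins = payload.records
        doc["data"] = {
            "chrom": bins.region.chrom,
            "start": bins.region.start,
            "end": bins.region.end,
            "nbins": bins.nbins,
            "stat": bins.stat,
            "values": bins.values,
        }
    return doc
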