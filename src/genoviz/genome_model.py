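"""Core coordinate system: genomes, regions, bookmarks, and saved view state.

All coordinates are 0-based half-open internally (``[start, end)``, BED
convention). Display strings — what a user types into a location box, e.g.
``chr17:7,569,899-7,591,385`` — are 1-based inclusive (UCSC convention) and
are converted exactly once, at the parse/format boundary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

__all__ = [
    "GenomeModelError",
    "Genome",
    "Region",
    "Bookmark",
    "TrackConfig",
    "VisualizationState",
    "parse_region_string",
    "format_region_string",
    "zoom",
    "pan",
]

#: Apps whose saved state this schema understands.
KNOWN_APPS = ("trackster", "circster", "sweepster", "phyloviz", "scatterplot")

SCHEMA_VERSION = 1

#: Highest schema version decode will accept. Documents one version ahead are
#: decoded with unknown top-level keys preserved (forward-compat window);
#: anything beyond is rejected outright.
SCHEMA_VERSION_MAX_COMPAT = 2

#: Dataset formats a track may declare.
TRACK_FORMATS = (
    "bed",
    "gff3",
    "gtf",
    "interval",
    "wiggle",
    "bedgraph",
    "vcf",
    "sam",
    "table",
)

DISPLAY_MODES = ("dense", "squish", "pack", "coverage", "auto")


class GenomeModelError(ValueError):
    """Raised for malformed regions, region strings, or state documents."""


class Genome:
    """A named genome build: an *ordered* registry of chromosome lengths.

    Chromosome order is preserved as given (file order of a chrom.sizes
    input) because it is the layout order for genome-wide views.
    """

    def __init__(self, id: str, chromosomes: Iterable[tuple[str, int]]):
        self.id = id
        self._lengths: dict[str, int] = {}
        for name, length in chromosomes:
            if name in self._lengths:
                raise GenomeModelError(f"duplicate chromosome name: {name!r}")
            if length <= 0:
                raise GenomeModelError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
            self._lengths[name] = int(length)
        if not self._lengths:
            raise GenomeModelError("genome has no chromosomes")

    @classmethod
    def from_chrom_sizes(cls, path: str, id: str | None = None) -> "Genome":
        """Read a two-column tab-separated ``name<TAB>length`` file."""
        chroms = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise GenomeModelError(
                        f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}"
                    )
                try:
                    length = int(parts[1])
                except ValueError:
                    raise GenomeModelError(
                        f"{path}:{lineno}: length is not an integer: {parts[1]!r}"
                    ) from None
                chroms.append((parts[0], length))
        return cls(id or path, chroms)

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return list(self._lengths.items())

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise GenomeModelError(
                f"unknown chromosome {chrom!r} in genome {self.id!r}"
            ) from None

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Genome({self.id!r}, {len(self)} chromosomes)"


@dataclass(frozen=True, order=True)
class Region:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise GenomeModelError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise GenomeModelError(
                f"empty or inverted region: start={self.start}, end={self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeModelError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        """Half-open overlap: abutting intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def validate_against(self, genome: Genome) -> "Region":
        if self.end > genome.length(self.chrom):
            raise GenomeModelError(
                f"region {format_region_string(self)} exceeds {self.chrom} "
                f"length {genome.length(self.chrom)}"
            )
        return self


_REGION_RE = re.compile(r"^\s*([^:\s]+?)(?::([\d,]+)-([\d,]+))?\s*$")


def parse_region_string(text: str, genome: Genome | None = None) -> Region:
    """Parse a display-format region string into an internal :class:`Region`.

    Display strings are 1-based inclusive: ``chr17:7569899-7591385`` maps to
    internal ``[7569898, 7591385)``. Commas in numbers are permitted. A bare
    chromosome name yields the whole chromosome when a genome is supplied.
    """
    m = _REGION_RE.match(text)
    if not m:
        raise GenomeModelError(f"malformed region string: {text!r}")
    chrom, s, e = m.groups()
    if genome is not None and chrom not in genome:
        raise GenomeModelError(f"unknown chromosome {chrom!r}")
    if s is None:
        if genome is None:
            raise GenomeModelError(
                f"bare chromosome {chrom!r} needs a genome to resolve its length"
            )
        return Region(chrom, 0, genome.length(chrom))
    start = int(s.replace(",", "")) - 1  # 1-based inclusive -> 0-based
    end = int(e.replace(",", ""))
    if start < 0:
        raise GenomeModelError(f"display start must be >= 1 in {text!r}")
    if end <= start:
        raise GenomeModelError(f"start > end after conversion in {text!r}")
    region = Region(chrom, start, end)
    if genome is not None:
        region.validate_against(genome)
    return region


def format_region_string(region: Region) -> str:
    """Inverse of :func:`parse_region_string` (1-based inclusive display)."""
    return f"{region.chrom}:{region.start + 1}-{region.end}"


def _clamp_window(start: float, end: float, chrom_len: int) -> tuple[int, int]:
    start_i = max(0, int(round(start)))
    end_i = min(chrom_len, int(round(end)))
    if end_i <= start_i:  # enforce width >= 1 base
        start_i = max(0, min(start_i, chrom_len - 1))
        end_i = start_i + 1
    return start_i, end_i


def zoom(view: Region, factor: float, genome: Genome) -> Region:
    """Scale the view width by ``factor`` about its center.

    The result is truncated to ``[0, chromosome length]``; width never drops
    below one base. ``factor < 1`` zooms in, ``> 1`` zooms out.
    """
    if factor <= 0:
        raise GenomeModelError(f"zoom factor must be positive, got {factor}")
    chrom_len = genome.length(view.chrom)
    center = (view.start + view.end) / 2.0
    half = view.length * factor / 2.0
    start, end = _clamp_window(center - half, center + half, chrom_len)
    return Region(view.chrom, start, end, view.strand)


def pan(view: Region, delta_fraction: float, genome: Genome) -> Region:
    """Shift the view by ``delta_fraction`` of its width, preserving width.

    Shifts past a chromosome end are absorbed by clamping: the window slides
    flush against the boundary instead of erroring.
    """
    chrom_len = genome.length(view.chrom)
    width = view.length
    shift = int(round(delta_fraction * width))
    start = view.start + shift
    start = max(0, min(start, chrom_len - width)) if width <= chrom_len else 0
    end = min(start + width, chrom_len)
    return Region(view.chrom, start, end, view.strand)


@dataclass
class Bookmark:
    """A saved, annotated region (used e.g. to select sweep regions)."""

    region: Region
    annotation: str = ""

    def to_dict(self) -> dict:
        return {
            "region": format_region_string(self.region),
            "strand": self.region.strand,
            "annotation": self.annotation,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Bookmark":
        region = parse_region_string(d["region"])
        strand = d.get("strand", ".")
        if strand != ".":
            region = Region(region.chrom, region.start, region.end, strand)
        return cls(region, d.get("annotation", ""))


@dataclass
class TrackConfig:
    """Display configuration for one dataset shown as a track."""

    dataset_path: str
    format: str
    display_mode: str = "auto"
    color: str = "#338855"
    filters: list = field(default_factory=list)
    group: str | None = None

    def __post_init__(self):
        if self.format not in TRACK_FORMATS:
            raise GenomeModelError(
                f"unsupported track format {self.format!r}; "
                f"expected one of {TRACK_FORMATS}"
            )
        if self.display_mode not in DISPLAY_MODES:
            raise GenomeModelError(
                f"unsupported display mode {self.display_mode!r}"
            )

    def to_dict(self) -> dict:
        return {
            "dataset_path": self.dataset_path,
            "format": self.format,
            "display_mode": self.display_mode,
            "color": self.color,
            "filters": [
                f.to_dict() if hasattr(f, "to_dict") else dict(f)
                for f in self.filters
            ],
            "group": self.group,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TrackConfig":
        from .providers import FilterSpec  # deferred: providers imports us

        return cls(
            dataset_path=d["dataset_path"],
            format=d["format"],
            display_mode=d.get("display_mode", "auto"),
            color=d.get("color", "#338855"),
            filters=[FilterSpec.from_dict(f) for f in d.get("filters", [])],
            group=d.get("group"),
        )


@dataclass
class VisualizationState:
    """Everything needed to restore a saved visualization.

    ``extra`` holds unknown top-level keys seen when decoding a document
    written by a newer minor schema, so round trips are lossless in both
    directions.
    """

    app: str
    genome_id: str
    view: Region | None = None
    tracks: list[TrackConfig] = field(default_factory=list)
    bookmarks: list[Bookmark] = field(default_factory=list)
    settings: dict[str, Any] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.app not in KNOWN_APPS:
            raise GenomeModelError(
                f"unsupported app {self.app!r}; expected one of {KNOWN_APPS}"
            )


def encode_state(state: VisualizationState) -> str:
    """Serialize a :class:`VisualizationState` to a JSON document."""
    doc: dict[str, Any] = {
        "schema_version": state.schema_version,
        "app": state.app,
        "genome_id": state.genome_id,
        "view": format_region_string(state.view) if state.view else None,
        "tracks": [t.to_dict() for t in state.tracks],
        "bookmarks": [b.to_dict() for b in state.bookmarks],
        "settings": dict(state.settings),
    }
    doc.update(state.extra)
    return json.dumps(doc, indent=2, sort_keys=False)


def decode_state(document: str) -> VisualizationState:
    """Inverse of :func:`encode_state`.

    Rejects documents with no ``schema_version`` or an unknown ``app``;
    preserves unknown top-level keys (forward compatibility).
    """
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise GenomeModelError(f"state document is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise GenomeModelError("state document must be a JSON object")
    if "schema_version" not in doc:
        raise GenomeModelError("state document is missing 'schema_version'")
    version = int(doc["schema_version"])
    if version > SCHEMA_VERSION_MAX_COMPAT:
        raise GenomeModelError(
            f"state document has schema_version {version}, but this library "
            f"only understands versions up to {SCHEMA_VERSION_MAX_COMPAT}"
        )
    app = doc.get("app")
    if app not in KNOWN_APPS:
        raise GenomeModelError(
            f"cannot decode state for unsupported app {app!r}; "
            f"this library understands {KNOWN_APPS}"
        )
    known = {
        "schema_version",
        "app",
        "genome_id",
        "view",
        "tracks",
        "bookmarks",
        "settings",
    }
    view = doc.get("view")
    return VisualizationState(
        app=app,
        genome_id=doc.get("genome_id", ""),
        view=parse_region_string(view) if view else None,
        tracks=[TrackConfig.from_dict(t) for t in doc.get("tracks", [])],
        bookmarks=[Bookmark.from_dict(b) for b in doc.get("bookmarks", [])],
        settings=dict(doc.get("settings", {})),
        schema_version=version,
        extra={k: v for k, v in doc.items() if k not in known},
    )
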