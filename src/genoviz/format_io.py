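"""Readers and writers for the supported plain-text genomic formats.

Every reader normalizes records to the internal 0-based half-open coordinate
convention exactly once:

========  ==========================  =============================
format    source convention           conversion
========  ==========================  =============================
BED       0-based half-open           none
Interval  0-based half-open           none
GFF3/GTF  1-based closed [start,end]  start - 1
VCF       1-based POS                 POS - 1
Wiggle    1-based starts              start - 1
BedGraph  0-based half-open           none
SAM       1-based POS                 POS - 1
========  ==========================  =============================

Readers also report the byte offset of each record's source line, which is
what the binned index stores so that providers can re-materialize individual
records with a seek instead of a full scan.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator

from .genome_model import Region

__all__ = [
    "FormatError",
    "Feature",
    "SignalPoint",
    "Variant",
    "Table",
    "FileStats",
    "IntervalColumns",
    "FEATURE_FORMATS",
    "SIGNAL_FORMATS",
    "read_features",
    "write_features",
    "read_signal",
    "read_variants",
    "read_table",
    "scan_records",
    "record_at_offset",
]

FEATURE_FORMATS = ("bed", "gff3", "gtf", "interval", "sam")
SIGNAL_FORMATS = ("wiggle", "bedgraph")


class FormatError(ValueError):
    """Malformed input; message names the file, line number, and field."""


@dataclass
class Feature:
    """One annotation record (BED/GFF/GTF/Interval/SAM read)."""

    region: Region
    name: str | None = None
    score: float | None = None
    thick_start: int | None = None
    thick_end: int | None = None
    blocks: list[tuple[int, int]] | None = None  # (start, size), region-relative
    attributes: dict[str, str] = field(default_factory=dict)
    source_line: int = 0

    @property
    def strand(self) -> str:
        return self.region.strand


@dataclass
class SignalPoint:
    """A constant-valued interval from a quantitative (wiggle-like) track."""

    region: Region
    value: float

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise FormatError(f"non-finite signal value {self.value!r}")


@dataclass
class Variant:
    """A site-level variant record. Region spans the reference allele."""

    region: Region
    ref: str
    alts: list[str]
    qual: float | None = None
    info: dict[str, str] = field(default_factory=dict)
    id: str | None = None


@dataclass
class Table:
    """A rectangular delimited-text table with inferred column types."""

    names: list[str]
    types: list[str]  # "numeric" | "string"
    rows: list[list]  # numeric cells are floats, missing cells are None

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list:
        i = self.names.index(name)
        return [row[i] for row in self.rows]

    def column_type(self, name: str) -> str:
        return self.types[self.names.index(name)]


@dataclass
class FileStats:
    """Line accounting for one parse: records + skipped = lines."""

    n_lines: int = 0
    n_records: int = 0
    n_skipped: int = 0


@dataclass
class IntervalColumns:
    """Column layout (0-based indices) for the tab-separated Interval format.

    The format is positional and installation-specific, so the layout is
    configuration, not a guess.
    """

    chrom: int = 0
    start: int = 1
    end: int = 2
    name: int | None = 3
    strand: int | None = 5


_SKIP_PREFIXES = ("#", "track", "browser")


def _is_skippable(line: str) -> bool:
    stripped = line.strip()
    if not stripped:
        return True
    return any(stripped.startswith(p) for p in _SKIP_PREFIXES)


def _parse_coord(text: str, path: str, lineno: int, what: str) -> int:
    try:
        value = int(text)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: {what} is not an integer: {text!r}"
        ) from None
    if value < 0:
        raise FormatError(f"{path}:{lineno}: negative {what}: {value}")
    return value


def _parse_score(text: str) -> float | None:
    # "." means absent; never fabricate a 0.
    if text == "." or text == "":
        return None
    return float(text)


def _parse_bed_line(line: str, path: str, lineno: int) -> Feature:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FormatError(
            f"{path}:{lineno}: BED needs >= 3 tab-separated fields, got {len(fields)}"
        )
    start = _parse_coord(fields[1], path, lineno, "start")
    end = _parse_coord(fields[2], path, lineno, "end")
    if end <= start:
        raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4:
        try:
            score = _parse_score(fields[4])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: score is not numeric: {fields[4]!r}"
            ) from None
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    thick_start = thick_end = None
    if len(fields) > 7:
        thick_start = _parse_coord(fields[6], path, lineno, "thickStart")
        thick_end = _parse_coord(fields[7], path, lineno, "thickEnd")
    blocks = None
    if len(fields) > 11:
        try:
            sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in fields[11].rstrip(",").split(",") if x]
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: malformed blockSizes/blockStarts"
            ) from None
        blocks = sorted(zip(starts, sizes))
        for (bs, sz) in blocks:
            if bs < 0 or bs + sz > end - start:
                raise FormatError(
                    f"{path}:{lineno}: block [{bs},{bs + sz}) outside feature"
                )
    return Feature(
        Region(fields[0], start, end, strand),
        name=name,
        score=score,
        thick_start=thick_start,
        thick_end=thick_end,
        blocks=blocks,
        source_line=lineno,
    )


_GTF_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')


def _parse_gff_attributes(text: str, dialect: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    text = text.strip()
    if not text or text == ".":
        return attrs
    if dialect == "gtf":
        for key, value in _GTF_ATTR_RE.findall(text):
            attrs[key] = value
    else:  # gff3: key=value;key=value
        for part in text.split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def _parse_gff_line(line: str, path: str, lineno: int, dialect: str) -> Feature:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise FormatError(
            f"{path}:{lineno}: GFF needs >= 8 tab-separated fields, got {len(fields)}"
        )
    start1 = _parse_coord(fields[3], path, lineno, "start")
    end1 = _parse_coord(fields[4], path, lineno, "end")
    if start1 < 1:
        raise FormatError(f"{path}:{lineno}: GFF start must be >= 1")
    if end1 < start1:
        raise FormatError(f"{path}:{lineno}: end {end1} < start {start1}")
    start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
    try:
        score = _parse_score(fields[5])
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: score is not numeric: {fields[5]!r}"
        ) from None
    strand = fields[6] if fields[6] in ("+", "-") else "."
    attrs = _parse_gff_attributes(fields[8] if len(fields) > 8 else "", dialect)
    name = attrs.get("Name") or attrs.get("ID") or attrs.get("gene_id")
    return Feature(
        Region(fields[0], start, end, strand),
        name=name,
        score=score,
        attributes=attrs,
        source_line=lineno,
    )


def _parse_interval_line(
    line: str, path: str, lineno: int, columns: IntervalColumns
) -> Feature:
    fields = line.rstrip("\n").split("\t")
    needed = max(columns.chrom, columns.start, columns.end)
    if len(fields) <= needed:
        raise FormatError(
            f"{path}:{lineno}: interval line has {len(fields)} fields, "
            f"layout needs at least {needed + 1}"
        )
    start = _parse_coord(fields[columns.start], path, lineno, "start")
    end = _parse_coord(fields[columns.end], path, lineno, "end")
    if end <= start:
        raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
    name = None
    if columns.name is not None and columns.name < len(fields):
        name = fields[columns.name] or None
    strand = "."
    if columns.strand is not None and columns.strand < len(fields):
        if fields[columns.strand] in ("+", "-"):
            strand = fields[columns.strand]
    return Feature(
        Region(fields[columns.chrom], start, end, strand),
        name=name,
        source_line=lineno,
    )


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_REF_CONSUMING = frozenset("MDN=X")


def _parse_sam_line(line: str, path: str, lineno: int) -> Feature | None:
    """One aligned read -> Feature with a ``mapq`` attribute.

    Unmapped reads (FLAG & 4) yield None. Reference span is computed from the
    CIGAR (M/D/N/=/X consume reference; I/S do not).
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise FormatError(
            f"{path}:{lineno}: SAM alignment needs >= 11 fields, got {len(fields)}"
        )
    try:
        flag = int(fields[1])
        pos1 = int(fields[3])
        mapq = int(fields[4])
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer FLAG/POS/MAPQ") from None
    if flag & 0x4 or fields[2] == "*" or pos1 == 0:
        return None
    ref_len = 0
    cigar = fields[5]
    if cigar != "*":
        if not re.fullmatch(r"(?:\d+[MIDNSHP=X])+", cigar):
            raise FormatError(f"{path}:{lineno}: malformed CIGAR {cigar!r}")
        for n, op in _CIGAR_RE.findall(cigar):
            if op in _CIGAR_REF_CONSUMING:
                ref_len += int(n)
    if ref_len == 0:
        ref_len = len(fields[9]) if fields[9] != "*" else 1
    strand = "-" if flag & 0x10 else "+"
    start = pos1 - 1
    return Feature(
        Region(fields[2], start, start + ref_len, strand),
        name=fields[0],
        attributes={"mapq": str(mapq)},
        source_line=lineno,
    )


def _feature_line_parser(format: str, columns: IntervalColumns | None):
    if format == "bed":
        return _parse_bed_line
    if format == "gff3":
        return lambda line, path, lineno: _parse_gff_line(line, path, lineno, "gff3")
    if format == "gtf":
        return lambda line, path, lineno: _parse_gff_line(line, path, lineno, "gtf")
    if format == "interval":
        cols = columns or IntervalColumns()
        return lambda line, path, lineno: _parse_interval_line(line, path, lineno, cols)
    if format == "sam":
        return _parse_sam_line
    raise FormatError(f"unsupported feature format {format!r}")


def _sam_skippable(line: str) -> bool:
    return not line.strip() or line.startswith("@")


def read_features(
    path: str,
    format: str,
    columns: IntervalColumns | None = None,
    with_stats: bool = False,
):
    """Read a feature file into :class:`Feature` records (internal coords).

    Track/browser/comment lines are skipped; ``with_stats=True`` additionally
    returns a :class:`FileStats` with the line accounting.
    """
    parse = _feature_line_parser(format, columns)
    skippable = _sam_skippable if format == "sam" else _is_skippable
    features: list[Feature] = []
    stats = FileStats()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stats.n_lines += 1
            if skippable(line):
                stats.n_skipped += 1
                continue
            feat = parse(line, path, lineno)
            if feat is None:  # unmapped SAM read
                stats.n_skipped += 1
                continue
            features.append(feat)
            stats.n_records += 1
    return (features, stats) if with_stats else features


def scan_records(
    path: str, format: str, columns: IntervalColumns | None = None
) -> Iterator[tuple[Region, int]]:
    """Yield ``(region, byte_offset)`` per record — the indexer's input.

    Works for feature, signal, and variant formats alike. For wiggle,
    ``record_at_offset`` cannot re-materialize values (the declaration line
    context is lost), so wiggle datasets are summarized from a full pass.
    """
    if format in FEATURE_FORMATS:
        parse = _feature_line_parser(format, columns)
        skippable = _sam_skippable if format == "sam" else _is_skippable
        with open(path, "rb") as fh:
            lineno = 0
            while True:
                offset = fh.tell()
                raw = fh.readline()
                if not raw:
                    break
                lineno += 1
                line = raw.decode()
                if skippable(line):
                    continue
                feat = parse(line, path, lineno)
                if feat is not None:
                    yield feat.region, offset
    elif format == "bedgraph":
        with open(path, "rb") as fh:
            lineno = 0
            while True:
                offset = fh.tell()
                raw = fh.readline()
                if not raw:
                    break
                lineno += 1
                line = raw.decode()
                if _is_skippable(line):
                    continue
                point = _parse_bedgraph_line(line, path, lineno)
                yield point.region, offset
    elif format == "wiggle":
        for point in read_signal(path, "wiggle"):
            yield point.region, -1  # no per-record offset available
    elif format == "vcf":
        with open(path, "rb") as fh:
            lineno = 0
            while True:
                offset = fh.tell()
                raw = fh.readline()
                if not raw:
                    break
                lineno += 1
                line = raw.decode()
                if not line.strip() or line.startswith("#"):
                    continue
                var = _parse_vcf_line(line, path, lineno)
                yield var.region, offset
    else:
        raise FormatError(f"cannot scan records for format {format!r}")


def record_at_offset(
    path: str, format: str, offset: int, columns: IntervalColumns | None = None
):
    """Materialize the single record whose line starts at ``offset``."""
    if offset < 0:
        raise FormatError(
            f"format {format!r} does not support per-record offsets"
        )
    with open(path, "rb") as fh:
        fh.seek(offset)
        line = fh.readline().decode()
    if format in FEATURE_FORMATS:
        record = _feature_line_parser(format, columns)(line, path, 0)
    elif format == "bedgraph":
        record = _parse_bedgraph_line(line, path, 0)
    elif format == "vcf":
        record = _parse_vcf_line(line, path, 0)
    else:
        raise FormatError(f"cannot materialize records for format {format!r}")
    if record is None:
        raise FormatError(f"{path}: offset {offset} is not a record line")
    return record


# ---------------------------------------------------------------------------
# writers


def _format_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def _bed_fields(feat: Feature) -> list[str]:
    fields = [
        feat.region.chrom,
        str(feat.region.start),
        str(feat.region.end),
        feat.name if feat.name is not None else ".",
        _format_score(feat.score),
        feat.region.strand if feat.region.strand in ("+", "-") else ".",
    ]
    if feat.thick_start is not None and feat.thick_end is not None:
        fields += [str(feat.thick_start), str(feat.thick_end), "0"]
        if feat.blocks:
            starts = ",".join(str(bs) for bs, _ in feat.blocks)
            sizes = ",".join(str(sz) for _, sz in feat.blocks)
            fields += [str(len(feat.blocks)), sizes, starts]
    return fields


def _gff3_fields(feat: Feature) -> list[str]:
    attrs = dict(feat.attributes)
    if feat.name is not None and "Name" not in attrs:
        attrs["Name"] = feat.name
    attr_text = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
    return [
        feat.region.chrom,
        "genoviz",
        "feature",
        str(feat.region.start + 1),  # back to 1-based closed
        str(feat.region.end),
        _format_score(feat.score),
        feat.region.strand if feat.region.strand in ("+", "-") else ".",
        ".",
        attr_text,
    ]


def write_features(features: list[Feature], path: str, format: str) -> int:
    """Write features as BED or GFF3; returns the record count.

    Writing attribute-bearing features to BED drops the attributes with a
    warning (BED has no attribute column); it is not an error.
    """
    if format not in ("bed", "gff3"):
        raise FormatError(f"unsupported output format {format!r}")
    n_with_attrs = 0
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
        for feat in features:
            if format == "bed":
                if feat.attributes:
                    n_with_attrs += 1
                fh.write("\t".join(_bed_fields(feat)) + "\n")
            else:
                fh.write("\t".join(_gff3_fields(feat)) + "\n")
    if n_with_attrs:
        warnings.warn(
            f"{n_with_attrs} feature(s) had attributes that BED cannot carry; "
            "attributes were dropped",
            stacklevel=2,
        )
    return len(features)


# ---------------------------------------------------------------------------
# signal


def _parse_bedgraph_line(line: str, path: str, lineno: int) -> SignalPoint:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 4:
        raise FormatError(
            f"{path}:{lineno}: bedgraph needs 4 fields, got {len(fields)}"
        )
    start = _parse_coord(fields[1], path, lineno, "start")
    end = _parse_coord(fields[2], path, lineno, "end")
    if end <= start:
        raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
    try:
        value = float(fields[3])
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: value is not numeric: {fields[3]!r}"
        ) from None
    return SignalPoint(Region(fields[0], start, end), value)


_WIG_DECL_RE = re.compile(r"(\w+)=(\S+)")


def read_signal(path: str, format: str) -> list[SignalPoint]:
    """Read wiggle (fixedStep/variableStep) or bedgraph into SignalPoints.

    Wiggle 1-based starts are converted; each fixedStep value becomes one
    point of length ``span`` placed every ``step`` bases.
    """
    if format == "bedgraph":
        points = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if _is_skippable(line):
                    continue
                points.append(_parse_bedgraph_line(line, path, lineno))
        return points
    if format != "wiggle":
        raise FormatError(f"unsupported signal format {format!r}")

    points = []
    mode = None  # ("fixed", chrom, next_start0, step, span) or ("variable", chrom, span)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            if stripped.startswith(("fixedStep", "variableStep")):
                decl = dict(_WIG_DECL_RE.findall(stripped))
                if "chrom" not in decl:
                    raise FormatError(f"{path}:{lineno}: declaration lacks chrom=")
                span = int(decl.get("span", 1))
                if span <= 0:
                    raise FormatError(f"{path}:{lineno}: span must be > 0")
                if stripped.startswith("fixedStep"):
                    if "start" not in decl:
                        raise FormatError(
                            f"{path}:{lineno}: fixedStep declaration lacks start="
                        )
                    step = int(decl.get("step", span))
                    if step <= 0:
                        raise FormatError(f"{path}:{lineno}: step must be > 0")
                    start0 = int(decl["start"]) - 1
                    if start0 < 0:
                        raise FormatError(
                            f"{path}:{lineno}: wiggle start must be >= 1"
                        )
                    mode = ["fixed", decl["chrom"], start0, step, span]
                else:
                    mode = ["variable", decl["chrom"], span]
                continue
            if mode is None:
                raise FormatError(
                    f"{path}:{lineno}: data line before any "
                    "fixedStep/variableStep declaration"
                )
            if mode[0] == "fixed":
                try:
                    value = float(stripped)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: value is not numeric: {stripped!r}"
                    ) from None
                _, chrom, start0, step, span = mode
                points.append(SignalPoint(Region(chrom, start0, start0 + span), value))
                mode[2] = start0 + step
            else:
                parts = stripped.split()
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: variableStep data needs 'pos value'"
                    )
                try:
                    pos0 = int(parts[0]) - 1
                    value = float(parts[1])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: malformed variableStep data: {stripped!r}"
                    ) from None
                if pos0 < 0:
                    raise FormatError(f"{path}:{lineno}: wiggle position must be >= 1")
                _, chrom, span = mode
                points.append(SignalPoint(Region(chrom, pos0, pos0 + span), value))
    return points


# ---------------------------------------------------------------------------
# variants


def _parse_vcf_line(line: str, path: str, lineno: int) -> Variant:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 8:
        raise FormatError(
            f"{path}:{lineno}: VCF needs 8 mandatory columns, got {len(fields)}"
        )
    try:
        pos1 = int(fields[1])
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: POS is not an integer: {fields[1]!r}"
        ) from None
    if pos1 < 1:
        raise FormatError(f"{path}:{lineno}: POS must be >= 1")
    ref = fields[3]
    start = pos1 - 1
    region = Region(fields[0], start, start + max(len(ref), 1))
    alts = [] if fields[4] == "." else fields[4].split(",")
    qual = None if fields[5] == "." else float(fields[5])
    info: dict[str, str] = {}
    if fields[7] not in (".", ""):
        for part in fields[7].split(";"):
            key, _, value = part.partition("=")
            info[key] = value
    vid = None if fields[2] == "." else fields[2]
    return Variant(region, ref=ref, alts=alts, qual=qual, info=info, id=vid)


def read_variants(path: str) -> list[Variant]:
    """Read a plain-text VCF (site level). Multi-allelic ALTs stay one record."""
    variants = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            variants.append(_parse_vcf_line(line, path, lineno))
    return variants


# ---------------------------------------------------------------------------
# tables

_MISSING_MARKERS = frozenset({"", "NA", "N/A", "na", "nan", "NaN", "null", "."})


def _try_float(cell: str) -> float | None:
    try:
        return float(cell)
    except ValueError:
        return None


def read_table(path: str, delimiter: str = "\t") -> Table:
    """Read a delimited text table, inferring a header row and column types.

    The first line is taken as a header when any of its cells is
    non-numeric and non-missing. A column is numeric when every non-missing
    cell parses as a float; otherwise it is a string column.
    """
    raw_rows: list[list[str]] = []
    with open(path) as fh:
        lines = [
            (lineno, line.rstrip("\n"))
            for lineno, line in enumerate(fh, 1)
            if line.strip() and not line.startswith("#")
        ]
    if not lines:
        raise FormatError(f"{path}: no data rows")
    width = len(lines[0][1].split(delimiter))
    for lineno, line in lines:
        cells = line.split(delimiter)
        if len(cells) != width:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {width})"
            )
        raw_rows.append(cells)

    first = raw_rows[0]
    has_header = any(
        cell not in _MISSING_MARKERS and _try_float(cell) is None for cell in first
    )
    if has_header:
        names = first
        body = raw_rows[1:]
    else:
        names = [f"c{i + 1}" for i in range(width)]
        body = raw_rows
    if not body:
        raise FormatError(f"{path}: no data rows")

    types = []
    for col in range(width):
        numeric = all(
            cell in _MISSING_MARKERS or _try_float(cell) is not None
            for cell in (row[col] for row in body)
        )
        types.append("numeric" if numeric else "string")
    rows: list[list] = []
    for raw in body:
        row: list = []
        for col, cell in enumerate(raw):
            if cell in _MISSING_MARKERS:
                row.append(None)
            elif types[col] == "numeric":
                row.append(float(cell))
            else:
                row.append(cell)
        rows.append(row)
    return Table(names=names, types=types, rows=rows)
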