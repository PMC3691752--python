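"""Geometry engines: linear feature packing, circular genome layout, SVG.

The circular layout follows the Circos convention: chromosomes are arcs on
a circle, placed in genome order clockwise from an origin at 12 o'clock,
separated by a fixed angular gap; each dataset occupies one annulus
(concentric band), histogram values mapped radially; interaction chords run
through the interior, below the innermost annulus.

SVG rendering is deliberately static and pure: the same inputs always
produce byte-identical output, and a summary track contributes exactly one
``<path>`` per chromosome regardless of its bin count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence
from xml.sax.saxutils import escape

from .format_io import Feature
from .genome_model import Genome, Region
from .providers import DataPayload, SummaryBins

__all__ = [
    "LayoutError",
    "SlotAssignment",
    "CircularLayout",
    "Annulus",
    "ChordPath",
    "pack_features",
    "circular_chromosome_layout",
    "position_to_angle",
    "angle_to_point",
    "allocate_annuli",
    "chord_endpoints",
    "render_svg",
]

TWO_PI = 2.0 * math.pi

DEFAULT_GAP = 0.01  # radians between adjacent chromosome arcs
DEFAULT_ORIGIN = 0.0  # 12 o'clock; angles grow clockwise


class LayoutError(ValueError):
    pass


# ---------------------------------------------------------------------------
# linear packing


@dataclass
class SlotAssignment:
    """Feature ordinal -> display row, plus the number of rows used."""

    slots: dict[int, int]
    n_slots: int


def pack_features(features: Sequence[Feature], label_pad: int = 0) -> SlotAssignment:
    """Assign features to non-overlapping rows (the "pack" display mode).

    Greedy first-fit over features sorted by (start, end, name). Each
    feature's interval is extended by ``label_pad`` bases on the right to
    reserve room for its label. On interval graphs first-fit in start order
    is optimal, so ``n_slots`` equals the maximum overlap depth of the
    padded intervals.
    """
    if label_pad < 0:
        raise LayoutError("label_pad must be >= 0")
    order = sorted(
        range(len(features)),
        key=lambda i: (
            features[i].region.start,
            features[i].region.end,
            features[i].name or "",
        ),
    )
    slot_ends: list[int] = []  # per slot, padded end of its last feature
    slots: dict[int, int] = {}
    for i in order:
        start = features[i].region.start
        end = features[i].region.end + label_pad
        for s, slot_end in enumerate(slot_ends):
            if slot_end <= start:  # half-open: abutting features can share
                slots[i] = s
                slot_ends[s] = end
                break
        else:
            slots[i] = len(slot_ends)
            slot_ends.append(end)
    return SlotAssignment(slots=slots, n_slots=len(slot_ends))


# ---------------------------------------------------------------------------
# circular layout


@dataclass
class CircularLayout:
    """Angular extent of every chromosome on the circle.

    Angles are radians measured clockwise from ``origin`` (12 o'clock by
    default). ``arcs`` maps chromosome name -> (start_angle, end_angle),
    in genome order, with ``gap`` radians between consecutive arcs.
    """

    arcs: dict[str, tuple[float, float]]
    lengths: dict[str, int]
    gap: float
    origin: float = DEFAULT_ORIGIN
    direction: str = "clockwise"


def circular_chromosome_layout(
    genome: Genome, gap: float = DEFAULT_GAP, origin: float = DEFAULT_ORIGIN
) -> CircularLayout:
    """Lay chromosomes on the circle, arc width proportional to length.

    Chromosome c gets ``(2*pi - n*gap) * length(c) / total_length`` radians;
    arcs are placed in genome order clockwise from ``origin``. The trailing
    gap closes the circle, so sum(arcs) + n*gap == 2*pi.
    """
    n = len(genome)
    if gap < 0 or n * gap >= TWO_PI:
        raise LayoutError(
            f"gap {gap} rad with {n} chromosomes does not fit on the circle"
        )
    usable = TWO_PI - n * gap
    total = genome.total_length
    arcs: dict[str, tuple[float, float]] = {}
    angle = origin
    for name, length in genome.chromosomes:
        arc = usable * length / total
        arcs[name] = (angle, angle + arc)
        angle += arc + gap
    return CircularLayout(
        arcs=arcs,
        lengths=dict(genome.chromosomes),
        gap=gap,
        origin=origin,
    )


def position_to_angle(layout: CircularLayout, chrom: str, pos: int) -> float:
    """Affine map of a base position to its angle on the circle."""
    if chrom not in layout.arcs:
        raise LayoutError(f"chromosome {chrom!r} not in layout")
    length = layout.lengths[chrom]
    if not 0 <= pos <= length:
        raise LayoutError(f"position {pos} outside {chrom} (length {length})")
    start, end = layout.arcs[chrom]
    return start + (pos / length) * (end - start)


def angle_to_point(
    angle: float, radius: float, center: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Polar -> cartesian with angle measured clockwise from 12 o'clock."""
    cx, cy = center
    return (cx + radius * math.sin(angle), cy - radius * math.cos(angle))


@dataclass
class Annulus:
    """Radial bands assigned to tracks, ordered inside-out and disjoint."""

    bands: list[tuple[float, float]]  # track ordinal -> (r_inner, r_outer)

    def __post_init__(self):
        prev_outer = 0.0
        for k, (r_in, r_out) in enumerate(self.bands):
            if r_in < prev_outer or r_out <= r_in:
                raise LayoutError(
                    f"annulus {k} [{r_in}, {r_out}] overlaps or is inverted"
                )
            prev_outer = r_out

    @property
    def innermost_radius(self) -> float:
        return self.bands[0][0] if self.bands else math.inf


def allocate_annuli(
    n_tracks: int, r_min: float, r_max: float, band_gap_fraction: float = 0.1
) -> Annulus:
    """Divide [r_min, r_max] into n equal bands with fractional gaps."""
    if n_tracks < 1:
        raise LayoutError("need at least one track")
    if not 0 < r_min < r_max:
        raise LayoutError("need 0 < r_min < r_max")
    step = (r_max - r_min) / n_tracks
    gap = step * band_gap_fraction
    return Annulus(
        bands=[
            (r_min + k * step, r_min + (k + 1) * step - gap)
            for k in range(n_tracks)
        ]
    )


@dataclass
class ChordPath:
    """A quadratic curve between two loci through the circle interior."""

    a: tuple[float, float]
    b: tuple[float, float]
    control: tuple[float, float]
    radius: float


def chord_endpoints(
    layout: CircularLayout,
    region_a: Region,
    region_b: Region,
    r_chord: float,
    annuli: Annulus | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> ChordPath:
    """Anchor points for an interaction chord between two regions.

    Anchors sit at the angle of each region's midpoint on radius
    ``r_chord``; the control point is the circle center, bowing the chord
    through the interior. ``r_chord`` must stay below the innermost annulus
    so chords never cross data bands.
    """
    if r_chord <= 0:
        raise LayoutError("r_chord must be positive")
    if annuli is not None and r_chord >= annuli.innermost_radius:
        raise LayoutError(
            f"r_chord {r_chord} reaches into the innermost annulus "
            f"(r_inner {annuli.innermost_radius})"
        )
    angles = []
    for region in (region_a, region_b):
        mid = (region.start + region.end) // 2
        angles.append(position_to_angle(layout, region.chrom, mid))
    return ChordPath(
        a=angle_to_point(angles[0], r_chord, center),
        b=angle_to_point(angles[1], r_chord, center),
        control=center,
        radius=r_chord,
    )


# ---------------------------------------------------------------------------
# SVG rendering


@dataclass
class Style:
    """Rendering knobs; every field has a sane default."""

    background: str = "#ffffff"
    track_colors: tuple = ("#338855", "#884433", "#334488", "#888833", "#663388")
    track_height: float = 60.0
    slot_height: float = 10.0
    margin: float = 20.0
    r_min_fraction: float = 0.35  # innermost annulus, as fraction of radius
    r_max_fraction: float = 0.95
    precision: int = 2

    def color(self, k: int) -> str:
        return self.track_colors[k % len(self.track_colors)]


def _fmt(value: float, precision: int) -> str:
    return f"{value:.{precision}f}"


def _linear_track_svg(
    payload: DataPayload,
    region: Region,
    y0: float,
    width: float,
    style: Style,
    color: str,
) -> list[str]:
    p = style.precision
    x_of = lambda pos: (pos - region.start) / region.length * width
    parts = []
    if payload.mode == "summary":
        bins: SummaryBins = payload.records
        finite = [v for v in bins.values if v is not None]
        vmax = max(finite) if finite else 1.0
        vmax = vmax or 1.0
        # one path per track: a histogram outline across all bins
        d = [f"M {_fmt(0, p)} {_fmt(y0 + style.track_height, p)}"]
        for i, v in enumerate(bins.values):
            lo, hi = bins.bin_bounds(i)
            h = 0.0 if v is None else (v / vmax) * style.track_height
            top = y0 + style.track_height - h
            d.append(f"L {_fmt(x_of(lo), p)} {_fmt(top, p)}")
            d.append(f"L {_fmt(x_of(hi), p)} {_fmt(top, p)}")
        d.append(f"L {_fmt(width, p)} {_fmt(y0 + style.track_height, p)} Z")
        parts.append(f'<path d="{" ".join(d)}" fill="{color}" stroke="none"/>')
    else:
        feats = payload.records
        packing = pack_features(feats)
        for i, feat in enumerate(feats):
            slot = packing.slots[i]
            x1 = max(0.0, x_of(max(feat.region.start, region.start)))
            x2 = min(width, x_of(min(feat.region.end, region.end)))
            y = y0 + slot * style.slot_height
            parts.append(
                f'<rect x="{_fmt(x1, p)}" y="{_fmt(y, p)}" '
                f'width="{_fmt(max(x2 - x1, 0.5), p)}" '
                f'height="{_fmt(style.slot_height * 0.8, p)}" fill="{color}"/>'
            )
    return parts


def _arc_path(
    a0: float, a1: float, radius: float, center: tuple[float, float], p: int
) -> str:
    x0, y0 = angle_to_point(a0, radius, center)
    x1, y1 = angle_to_point(a1, radius, center)
    large = 1 if (a1 - a0) > math.pi else 0
    return (
        f"M {_fmt(x0, p)} {_fmt(y0, p)} "
        f"A {_fmt(radius, p)} {_fmt(radius, p)} 0 {large} 1 "
        f"{_fmt(x1, p)} {_fmt(y1, p)}"
    )


def _circular_track_svg(
    per_chrom: Sequence[SummaryBins],
    layout: CircularLayout,
    band: tuple[float, float],
    center: tuple[float, float],
    style: Style,
    color: str,
) -> list[str]:
    """Radial histogram: exactly one path per chromosome for this track."""
    p = style.precision
    r_in, r_out = band
    all_values = [
        v for bins in per_chrom for v in bins.values if v is not None
    ]
    vmax = max(all_values) if all_values else 1.0
    vmax = vmax or 1.0
    parts = []
    for bins in per_chrom:
        chrom = bins.region.chrom
        a_start, _ = layout.arcs[chrom]
        base = angle_to_point(a_start, r_in, center)
        d = [f"M {_fmt(base[0], p)} {_fmt(base[1], p)}"]
        for i, v in enumerate(bins.values):
            lo, hi = bins.bin_bounds(i)
            r = r_in if v is None else r_in + (v / vmax) * (r_out - r_in)
            for pos in (lo, hi):
                x, y = angle_to_point(
                    position_to_angle(layout, chrom, pos), r, center
                )
                d.append(f"L {_fmt(x, p)} {_fmt(y, p)}")
        end_pt = angle_to_point(layout.arcs[chrom][1], r_in, center)
        d.append(f"L {_fmt(end_pt[0], p)} {_fmt(end_pt[1], p)} Z")
        parts.append(f'<path d="{" ".join(d)}" fill="{color}" stroke="none"/>')
    return parts


def render_svg(
    tracks: Sequence,
    payloads: Sequence,
    mode: str,
    dimensions: tuple[float, float] = (800.0, 600.0),
    style: Style | None = None,
    region: Region | None = None,
    layout: CircularLayout | None = None,
    chords: Sequence[ChordPath] = (),
) -> str:
    """Render tracks to a static SVG 1.1 document (pure, deterministic).

    ``mode="linear"`` stacks tracks vertically over ``region``; payloads are
    :class:`DataPayload` (detail payloads are packed into slots, summaries
    drawn as histograms). ``mode="circular"`` needs a
    :class:`CircularLayout`; each payload is the per-chromosome
    ``SummaryBins`` list from ``get_genome_wide``.
    """
    width, height = dimensions
    if width <= 0 or height <= 0:
        raise LayoutError(f"zero-area dimensions {dimensions}")
    if len(tracks) != len(payloads):
        raise LayoutError("tracks and payloads must align")
    style = style or Style()
    p = style.precision
    body: list[str] = [
        f'<rect x="0" y="0" width="{_fmt(width, p)}" height="{_fmt(height, p)}" '
        f'fill="{style.background}"/>'
    ]
    if mode == "linear":
        if region is None and payloads:
            raise LayoutError("linear mode needs the rendered region")
        inner_w = width - 2 * style.margin
        y = style.margin
        lines = []
        for k, payload in enumerate(payloads):
            lines.extend(
                _linear_track_svg(
                    payload, region, y, inner_w, style, style.color(k)
                )
            )
            y += style.track_height + style.margin
        body.append(
            f'<g transform="translate({_fmt(style.margin, p)} 0)">'
            + "".join(lines)
            + "</g>"
        )
    elif mode == "circular":
        if layout is None:
            raise LayoutError("circular mode needs a CircularLayout")
        center = (width / 2.0, height / 2.0)
        radius = min(width, height) / 2.0 - style.margin
        # chromosome backbone arcs
        for chrom, (a0, a1) in layout.arcs.items():
            body.append(
                f'<path d="{_arc_path(a0, a1, radius, center, p)}" '
                'fill="none" stroke="#333333" stroke-width="2"/>'
            )
        if payloads:
            annuli = allocate_annuli(
                len(payloads),
                radius * style.r_min_fraction,
                radius * style.r_max_fraction,
            )
            for k, per_chrom in enumerate(payloads):
                body.extend(
                    _circular_track_svg(
                        per_chrom,
                        layout,
                        annuli.bands[k],
                        center,
                        style,
                        style.color(k),
                    )
                )
        for chord in chords:
            ax, ay = chord.a
            bx, by = chord.b
            cx, cy = chord.control
            body.append(
                f'<path d="M {_fmt(center[0] + ax, p)} {_fmt(center[1] + ay, p)} '
                f'Q {_fmt(center[0] + cx, p)} {_fmt(center[1] + cy, p)} '
                f'{_fmt(center[0] + bx, p)} {_fmt(center[1] + by, p)}" '
                'fill="none" stroke="#cc6600" stroke-width="1"/>'
            )
    else:
        raise LayoutError(f"unknown render mode {mode!r}")
    title = escape(f"genoviz {mode} view")
    return (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width, p)}" height="{_fmt(height, p)}">'
        f"<title>{title}</title>" + "".join(body) + "</svg>\n"
    )
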