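"""Bundled command-line toy tools for exercising the sweep engine.

All three tools are *region-local*: their output inside a region depends
only on the input records overlapping that region. That property is what
lets the sweep engine run them on region subsets and get exactly the
result a full-data run would give inside those regions.

Invoked as ``python -m genoviz.toy_tools <tool> ...``.
"""

from __future__ import annotations

import sys

import click

from . import format_io
from .genome_model import parse_region_string


@click.group()
def cli():
    """Toy tools: identity, score_filter, counter."""


@cli.command()
@click.argument("input", type=click.Path(exists=True))
@click.argument("output", type=click.Path())
def identity(input: str, output: str) -> None:
    """Copy INPUT to OUTPUT unchanged."""
    with open(input, "rb") as src, open(output, "wb") as dst:
        dst.write(src.read())


@cli.command("score_filter")
@click.argument("input", type=click.Path(exists=True))
@click.argument("output", type=click.Path())
@click.option("--min-score", type=float, required=True)
def score_filter(input: str, output: str, min_score: float) -> None:
    """Keep BED features whose score is present and >= MIN_SCORE."""
    feats = format_io.read_features(input, "bed")
    kept = [f for f in feats if f.score is not None and f.score >= min_score]
    format_io.write_features(kept, output, "bed")


@cli.command()
@click.argument("input", type=click.Path(exists=True))
@click.argument("output", type=click.Path())
@click.option("--regions", required=True, help="comma-separated chrom:start-end")
@click.option("--min-score", type=float, default=None)
def counter(input: str, output: str, regions: str, min_score: float | None) -> None:
    """Per-region feature counter.

    Writes one BED line per region: the region itself, named region<i>,
    scored with the number of input features overlapping it (optionally
    restricted to scores >= --min-score).
    """
    feats = format_io.read_features(input, "bed")
    if min_score is not None:
        feats = [f for f in feats if f.score is not None and f.score >= min_score]
    region_list = [parse_region_string(r) for r in regions.split(",") if r]
    out = []
    for i, region in enumerate(region_list):
        count = sum(1 for f in feats if f.region.overlaps(region))
        out.append(
            format_io.Feature(region, name=f"region{i}", score=float(count))
        )
    format_io.write_features(out, output, "bed")


def main() -> int:
    try:
        cli(standalone_mode=False)
    except click.ClickException as exc:
        exc.show()
        return 2
    return 0


if __name__ == "__main__":
    sys.exit(main())
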