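# genoviz

Server-side building blocks for genomic *visual analysis* — the machinery a
web genome browser, a Circos-style whole-genome viewer, or a tool
parameter-sweep application needs behind its renderer:

- **Multi-resolution data providers** over indexed plain-text formats
  (BED 3–12, GFF3/GTF, Interval, minimal SAM, Wiggle, BedGraph, site-level
  VCF, delimited tables). A region query returns individual records
  (*detail* mode) when the window holds at most `max_detail` of them, and
  per-bin aggregates (*summary* mode: coverage counts, or base-weighted
  mean / max / min for quantitative tracks) when it holds more — a million
  mapped reads on one chromosome are never shipped record by record.
- **Binned interval indexing**: a single-level fixed-width bin index
  (default 4096 bases) in which each record is registered in every bin its
  half-open span overlaps, so a query inspects only
  `ceil(L / bin_size) + 1` bins. Indices persist as `.gvx` JSON sidecars
  with a source checksum, and a stale index against an edited file is
  detected on load.
- **Layout engines**: greedy first-fit feature packing into display rows
  (provably optimal on interval graphs — the row count equals the maximum
  overlap depth), and a Circos-convention circular layout (chromosome
  arcs proportional to length, clockwise from 12 o'clock, with angular
  gaps that close the circle to `2*pi` exactly), plus deterministic static
  SVG rendering of both, with interaction chords through the interior.
- **Dynamic filters** on record attributes (scores, mapping quality,
  GFF/GTF attributes) with conjunction semantics and configurable handling
  of missing values.
- **A parameter-sweep engine**: numeric tool parameters sampled on an
  inclusive grid `v_i = min + i*(max-min)/(n-1)`, categorical parameters
  enumerated, the sampled space arranged as a tree (levels = parameters,
  nodes = values), and one tool run per leaf under any selected node. Runs
  execute on a cached *subset* of the dataset — exactly the records
  overlapping the regions of interest — which is exact for region-local
  tools and is what keeps interactive sweeps fast.
- **Phylogenetic trees**: Newick / PhyloXML-subset / Nexus parsing (all
  iterative; 10,000-node trees are fine), rectangular dendrogram layout
  (leaf rows 0,1,2,…; internal nodes at the mean of their children; x =
  cumulative branch length), substring and distance search, and editing.
- **Seeded synthetic fixtures** for all of the above, so everything is
  testable offline.

All coordinates are 0-based half-open internally; display strings
(`chr17:7,569,899-7,591,385`) are 1-based inclusive and converted once at
the parse boundary.

## Worked example

```sh
# 1. generate a seeded synthetic workspace
genoviz fixtures /tmp/demo --seed 11
# 2. index the feature file (written as /tmp/demo/features.bed.gvx)
genoviz index /tmp/demo/features.bed --format bed
# 3. query a window
genoviz query /tmp/demo/features.bed chr1:1-30000 --format bed
```

The query prints a payload such as (abridged):

```json
{
  "mode": "detail",
  "total": 39,
  "message": null,
  "data": [[172, 1375, "f94", 408.722, "+", {}], ...]
}
```

`mode` is `"detail"` because the window holds 39 ≤ 5000 records; each
record is `[start, end, name, score, strand, attributes]` in internal
coordinates. Ask for a coarse view instead:

```sh
genoviz summary /tmp/demo/features.bed chr1:1-30000 --format bed --nbins 8
```

```json
{"mode": "summary", "total": 39, "message": null,
 "data": {"chrom": "chr1", "start": 0, "end": 30000,
          "nbins": 8, "stat": "count",
          "values": [7.0, 4.0, 5.0, 6.0, 9.0, 5.0, 7.0, 6.0]}}
```

`values[i]` counts the records overlapping bin *i* (a record spanning k
bins contributes to each — coverage semantics). A whole-genome circular
SVG and a parameter sweep complete the tour:

```sh
genoviz render /tmp/demo/features.bed --format bed --mode circular \
    --genome /tmp/demo/genome.chrom.sizes --out /tmp/demo/circ.svg
genoviz sweep /tmp/demo/features.bed --region chr1:1-25000 \
    --region chr2:1-10000 --workdir /tmp/demo/sweep
```

The sweep runs the bundled per-region counter tool once per parameter
assignment and writes `manifest.json` mapping each run's tree path and
assignment to its output and per-region record counts.

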