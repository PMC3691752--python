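# Methods

This note documents the models, conventions, numerical choices, and
deliberate design decisions behind genoviz, and what its test suite does
and does not demonstrate.

## Coordinate model

All in-memory coordinates are 0-based half-open intervals `[start, end)`,
the BED convention. Every other convention is converted exactly once at
the parse boundary: GFF3/GTF and wiggle (1-based, closed / 1-based starts)
subtract 1 from the start, VCF subtracts 1 from POS, and a variant's
region spans its reference allele (`max(len(ref), 1)` bases). Display
strings such as `chr17:7569899-7591385` are 1-based inclusive (what users
type into a browser location box); `parse_region_string` and
`format_region_string` are exact inverses on valid regions. The half-open
overlap test `a.start < b.end and b.start < a.end` is used uniformly, so
abutting intervals never overlap.

A genome is an *ordered* chromosome → length registry; order is the file
order of the chrom.sizes input, not lexicographic, because chromosome
order is the layout order of genome-wide views and must stay under user
control. A linear view is confined to one chromosome; navigation past an
end clamps (window truncated at the boundary, width floor one base)
rather than erroring, so `pan`/`zoom` are total functions. Zoom-out
followed by the inverse zoom-in restores the view exactly whenever no
clamping occurs and the view width is even (odd widths have half-integer
centers, which a single integer rounding cannot preserve).

## Saved state

Visualization state (app, genome, view, track configurations, bookmarks,
settings) serializes to a JSON document with an integer `schema_version`
starting at 1. Decoding preserves unknown top-level keys up to one version
ahead (forward-compatibility window) and rejects anything newer, missing
version fields, or unknown app identifiers. Round trips are lossless in
both directions; this is property-tested over randomized states.

## Binned interval index

The index is a single-level fixed-width bin table: bin `b` of size `w`
(default 4096 bases) holds the ordinals of all records whose span
overlaps `[b*w, (b+1)*w)`. A record spanning `[s, e)` is registered in
bins `floor(s/w) .. floor((e-1)/w)` — every bin it crosses — so a query
need only inspect the bins its own span crosses (at most
`ceil(L/w) + 1`), deduplicate with a seen-set, and apply the exact
overlap test. This is deliberately simpler than hierarchical binning:
it is oracle-verifiable line by line, adequate at the dataset sizes the
package targets, and `bin_size` is configurable when record length
distributions warrant it. Query results are sorted by
`(start, end, ordinal)` for deterministic downstream rendering.

Indices persist as a JSON sidecar (`<dataset>.gvx`) holding the record
table only; bins are rebuilt on load (cheap, and it keeps the sidecar
format trivial). The sidecar carries a source checksum — file size plus a
SHA-256 over the first and last 64 KiB — and loading against a changed
source raises a stale-index error. Modification time is deliberately not
part of the checksum: copying or checking out a dataset refreshes mtime
without changing content, and a content-identical file should not
invalidate its index.

## Providers: detail vs summary

`get_data` returns individual records when the region holds at most
`max_detail` of them and per-bin summaries otherwise. Both knobs are
configuration with defaults `max_detail = 5000` records and
`nbins = 1000`; the threshold is a tie-at-detail rule (exactly
`max_detail` records still returns detail), so the flip happens at
`max_detail + 1`. The defaults are pragmatic renderer-payload sizes, not
biology.

Summary bins partition the region with integer width `w = L // nbins`,
the last bin absorbing the remainder; when `nbins > L`, `nbins` is
clamped to one bin per base so `w >= 1`. Under the `count` statistic a
record contributes to *every* bin it overlaps (coverage semantics, not
start-bin binning). `mean` is base-weighted — each overlapped base
contributes its value once — so the result is invariant to how a
piecewise-constant signal was segmented; `max`/`min` are taken over all
points overlapping the bin. Empty bins are 0 under `count` and null under
the others. `mean`/`max`/`min` require a quantitative (signal) dataset;
requesting them on a feature dataset is an error rather than a silent
score aggregation. Strand is ignored in summarization.

Composite ("rainbow") summaries stack the per-bin vectors of several
tracks into one matrix with shared bin boundaries; each row equals the
track's individual summary by construction.

Filters are conjunctions of numeric range tests on `score`, `mapq`, or a
named GFF/GTF attribute. A record missing the attribute (or carrying a
non-numeric value) passes by default (`missing_passes = true`): filters
are opt-in restrictive, and hiding records because an annotation is
absent is rarely what an analyst wants. Filters apply to detail payloads
only — summary bins no longer carry attributes.

The provider cache is LRU over exact query keys, with one extra reuse
rule: a cached *detail* payload whose region contains the query (same
`max_detail`) is answered by sub-selecting its records, which is exact
because every record overlapping the sub-region is present in the
superset payload. Cache transparency (cached and uncached pipelines give
identical payload sequences) is property-tested.

Column statistics for tables exclude missing cells from every statistic
and use the n−1 denominator for the standard deviation (null when n < 2).

## Layout

Feature packing is greedy first-fit over features sorted by
`(start, end, name)` — the deterministic tie-break — with each interval
extended on the right by a caller-supplied label pad in bases (geometry
stays pixel-agnostic; the caller knows its font). On interval graphs,
first-fit in start order uses exactly as many rows as the maximum overlap
depth, so the slot count is optimal; the suite verifies this against a
sweep-line oracle on randomized instances.

The circular layout places chromosome arcs in genome order, clockwise
from an origin at 12 o'clock (the Circos convention; both configurable),
with arc width `(2*pi − n*gap) * length / total_length` and a default gap
of 0.01 rad. The trailing gap closes the circle, giving the conservation
invariant `sum(arcs) + n*gap = 2*pi` to 1e-9. Position-to-angle mapping
is affine per chromosome, hence strictly monotone. Tracks occupy
disjoint annuli allocated inside-out; interaction chords anchor at region
midpoints on a radius required to stay below the innermost annulus, with
the circle center as the quadratic control point. Histogram values map
linearly from `[0, max bin value]` to the annulus radii per track.

SVG output is a pure function of its inputs: coordinates are emitted at
fixed decimal precision, iteration orders are deterministic, and reruns
are byte-identical. A summary track contributes a single path element per
chromosome regardless of bin count, which is what keeps documents small
at thousands of bins.

## Parameter sweeps

Numeric parameters sample an inclusive evenly spaced grid
`v_i = min + i*(max−min)/(n−1)`; the last sample is assigned the exact
maximum so endpoints never drift; `n = 1` yields `[min]` (a documented
choice — the minimum is what the user typed first, and a midpoint would
be an invention). Categorical parameters contribute their declared values
in order. In-tree parameters form an ordered tree whose levels are
parameters and whose nodes are sampled values; leaf count is the product
of per-parameter sample counts. Selecting any node enumerates one run per
leaf beneath it — ancestors pin their values, deeper levels vary, and
out-of-tree parameters take their fixed values — so with two parameters,
fixing the first at one value launches exactly one run per sample of the
second. (Whether an interior selection should mean "all descendant
leaves" or "immediate children only" is genuinely ambiguous; leaves-under-
node is implemented because it makes the child counts of any node sum to
the node's own count.)

Tools are declared as command templates with `{input}`, `{output}`,
optional `{regions}`, and `{param:name}` placeholders — a minimal
contract that captures what a sweep needs without a workflow system.
Sweeps run each assignment once over the *union subset* of the selected
regions and slice outputs per region afterwards, rather than one process
per (assignment, region); for region-local tools the results are
identical and the process count is lower. The subset file preserves the
source format byte-for-byte (header lines, then the raw lines of records
overlapping any region, in source order) and is cached keyed by source
checksum plus the canonicalized region set, so repeated sweeps reuse it
without rewriting. Failed runs are recorded with diagnostics and do not
abort the sweep. Execution is sequential by default; the executor is a
callable the caller may replace, provided per-run output isolation and
result ordering are preserved.

The three bundled toy tools (identity, score filter, per-region counter)
are all region-local by construction — per-record maps, or counts over
records overlapping an explicitly passed region — which is what makes
the subset-equals-restricted-full-run check exact rather than
approximate.

## Phylogenetic trees

The newick parser is an iterative tokenizer/stack machine (no recursion
limits; a 10,000-node tree parses and lays out in well under a second),
handling quoted labels with doubled-quote escapes and skipping bracketed
comments. Unquoted underscores are kept literal rather than converted to
spaces, matching the behavior of the Bio.Phylo reader used as the
cross-check oracle in the tests. The writer quotes labels containing
structural characters and formats branch lengths at full precision;
parse∘write∘parse is the identity on the written text. PhyloXML support
covers clade nesting, names, and branch lengths, warning about skipped
elements; Nexus support reads the first tree of the TREES block and
honors translate tables, warning about ignored blocks.

Dendrogram layout: visible leaves take rows 0, 1, 2, … in traversal
order; an internal node sits at the arithmetic mean of its children's
rows (mean, not median — the standard dendrogram choice, and exact under
the mean-rule invariant the tests assert); x is the cumulative branch
length from the root, with missing lengths *displayed* as one unit but
preserved as null in the data (display and data are separate concerns).
A collapsed node is treated as a leaf when the layout is asked to respect
collapse state. Distance search defaults to cumulative-from-root (with an
edge-length mode behind a flag, since either reading of "search by
distance" is defensible) and ignores collapse state, as does substring
search. Edits are local: untouched subtrees are structurally unchanged.

## Synthetic fixtures

Each generator draws from its own pseudorandom stream derived from
`(seed, generator name)` via SHA-256, so generators are mutually
independent and adding one never perturbs another; identical
configuration yields byte-identical files. Defaults: 3 chromosomes of
50–200 kb; 500 features of 50–2000 bases with uniform scores in
[0, 1000], placed proportionally to chromosome length (an
`overlap_factor = 0` mode places them pairwise disjoint); 200 signal
segments of 500 bases with uniform values in [0, 100], tiling contiguous
runs; trees grown by splitting a uniformly chosen leaf into a cherry,
which keeps them binary with logarithmic expected depth. These sizes are
desk-scale: large enough to exercise multi-bin indexing, mode flips, and
packing depth, small enough that the whole suite runs in seconds.

What the fixtures deliberately do not model: read errors, coverage
biases, evolutionary processes, or any biological signal structure.
Passing tests therefore demonstrate *algorithmic* correctness —
coordinate arithmetic, index/oracle equivalence, layout invariants,
sweep cardinalities — on data with the right shapes and scales, not
fidelity to any particular assay.

## Problem sizes used in verification

The oracle-equivalence check runs 100 generated datasets of up to 10^4
records with 100 random regions each (regions log-uniform in length, so
both few-record and many-record windows are exercised); packing
optimality runs 1000 random instances; index persistence 20 randomized
indices × 25 queries; newick round trips 50–100 random trees; the
large-tree check uses ~10,000 nodes. `scripts/acceptance.py` re-runs the
same families of checks at comparable sizes and reports agreement
percentages, worst-case errors, and timings.

## Known limitations

- BAM/BigWig/BigBed binary codecs are out of scope (the format surface is
  plain text; the SAM reader is a minimal text-mode mapper that extracts
  span, strand, and mapping quality).
- Wiggle records carry no per-record byte offsets (values depend on their
  declaration line), so wiggle datasets are summarized from a full parse
  and cannot be subset for sweeps; BedGraph is the offset-capable
  quantitative format.
- The optional HTTP serve mode is not built; the CLI `query`/`summary`
  commands emit the same payload JSON the endpoint would.
- One linear view spans one chromosome; multi-chromosome linear viewports
  and strand-split summaries are non-goals.
- The Galaxy "Interval" column layout is installation-specific and is
  therefore exposed as configuration (`IntervalColumns`) rather than
  guessed.
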