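"""Parameter-space sweeps: sample tool parameters, build the parameter
tree, enumerate runs, subset data to regions of interest, and execute.

A tool's numeric parameters are sampled on an evenly spaced grid
(min/max/number of samples, endpoints inclusive); categorical parameters
contribute every declared value. The sampled in-tree parameters form an
ordered tree whose levels are parameters and whose nodes are sampled
values, so every root-to-leaf path is one complete in-tree assignment.
Selecting an interior node sweeps all leaf assignments beneath it — fixing
the ancestor parameters at that node's path and varying the rest — e.g.
with two parameters, picking a value of the first launches one run per
sample of the second.

To keep runs fast the tool is executed on a *subset* of the dataset: the
records overlapping the selected regions (the current view plus bookmarked
regions), extracted once and cached on disk keyed by source checksum and
region set. For region-local tools this is exact: restricting a full-data
run to the regions gives the same output as running on the subset.
"""

from __future__ import annotations

import hashlib
import json
import os
import re
import shlex
import subprocess
import sys
from dataclasses import dataclass, field
from typing import Callable, Sequence

from . import format_io, indexing
from .genome_model import Region, format_region_string
from .providers import Dataset

__all__ = [
    "SweepError",
    "ParameterSpec",
    "ToolSpec",
    "ParamNode",
    "ParamTree",
    "SweepRun",
    "sample_parameter",
    "build_param_tree",
    "enumerate_runs",
    "subset_dataset",
    "execute_sweep",
    "run_full",
    "builtin_tool",
    "write_manifest",
    "load_tool_config",
]


class SweepError(ValueError):
    pass


@dataclass
class ParameterSpec:
    """One tool parameter: a sampled numeric range or a categorical set.

    ``in_tree=False`` parameters are held at ``fixed_value`` in every run.
    """

    name: str
    kind: str  # "numeric" | "categorical"
    min: float | None = None
    max: float | None = None
    n_samples: int | None = None
    values: list | None = None
    in_tree: bool = True
    fixed_value: object = None

    def __post_init__(self):
        if self.kind == "numeric":
            if self.min is None or self.max is None or self.n_samples is None:
                raise SweepError(
                    f"numeric parameter {self.name!r} needs min, max, n_samples"
                )
            self.min = float(self.min)
            self.max = float(self.max)
            if self.min > self.max:
                raise SweepError(f"{self.name!r}: min {self.min} > max {self.max}")
            if self.n_samples < 1:
                raise SweepError(f"{self.name!r}: n_samples must be >= 1")
        elif self.kind == "categorical":
            if not self.values:
                raise SweepError(f"categorical parameter {self.name!r} has no values")
            if len(set(map(str, self.values))) != len(self.values):
                raise SweepError(f"{self.name!r}: categorical values must be unique")
        else:
            raise SweepError(f"unknown parameter kind {self.kind!r}")


def sample_parameter(spec: ParameterSpec) -> list:
    """Ordered sample values for one parameter.

    Numeric with n >= 2: evenly spaced, endpoints inclusive,
    ``value_i = min + i*(max-min)/(n-1)``. n == 1 yields ``[min]``.
    Categorical: declared order.
    """
    if spec.kind == "categorical":
        return list(spec.values)
    n = spec.n_samples
    if n == 1:
        return [spec.min]
    step = (spec.max - spec.min) / (n - 1)
    samples = [spec.min + i * step for i in range(n)]
    samples[-1] = spec.max  # endpoints exact despite float accumulation
    return samples


_PLACEHOLDER_RE = re.compile(r"\{(input|output|regions|param:[A-Za-z0-9_.-]+)\}")


@dataclass
class ToolSpec:
    """A tool as a command template plus declared parameters.

    Reserved placeholders ``{input}``, ``{output}``, and (optionally)
    ``{regions}`` are filled by the engine; ``{param:name}`` placeholders
    must match a declared parameter.
    """

    id: str
    command: str
    input_format: str
    output_format: str
    parameters: list[ParameterSpec] = field(default_factory=list)

    def __post_init__(self):
        declared = {p.name for p in self.parameters}
        for token in _PLACEHOLDER_RE.findall(self.command):
            if token.startswith("param:") and token[6:] not in declared:
                raise SweepError(
                    f"tool {self.id!r}: placeholder {{{token}}} has no "
                    "matching declared parameter"
                )

    @property
    def in_tree_parameters(self) -> list[ParameterSpec]:
        return [p for p in self.parameters if p.in_tree]

    def render_command(
        self, assignment: dict, input_path: str, output_path: str,
        regions: Sequence[Region] = (),
    ) -> list[str]:
        def sub(match: re.Match) -> str:
            token = match.group(1)
            if token == "input":
                return input_path
            if token == "output":
                return output_path
            if token == "regions":
                return ",".join(format_region_string(r) for r in regions)
            name = token[6:]
            if name not in assignment:
                raise SweepError(f"assignment lacks parameter {name!r}")
            return str(assignment[name])

        return shlex.split(_PLACEHOLDER_RE.sub(sub, self.command))


# ---------------------------------------------------------------------------
# parameter tree


@dataclass
class ParamNode:
    """A node in the parameter-space tree; root has no parameter/value."""

    param_name: str | None = None
    value: object = None
    children: list["ParamNode"] = field(default_factory=list)
    parent: "ParamNode | None" = None

    @property
    def label(self) -> str:
        if self.param_name is None:
            return "root"
        return f"{self.param_name}={self.value}"

    def path_labels(self) -> list[str]:
        """Ancestry labels from root (exclusive) down to this node."""
        labels: list[str] = []
        node = self
        while node is not None and node.param_name is not None:
            labels.append(node.label)
            node = node.parent
        return labels[::-1]

    def leaves(self) -> list["ParamNode"]:
        if not self.children:
            return [self]
        out: list[ParamNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.children:
                stack.extend(reversed(node.children))
            else:
                out.append(node)
        return out


@dataclass
class ParamTree:
    """Levels are in-tree parameters (in declared order); nodes are values."""

    root: ParamNode
    specs: list[ParameterSpec]

    @property
    def leaf_count(self) -> int:
        return len(self.root.leaves())

    @property
    def depth(self) -> int:
        return len(self.specs)

    def node_at(self, indices: Sequence[int]) -> ParamNode:
        node = self.root
        for i in indices:
            node = node.children[i]
        return node


def build_param_tree(specs: Sequence[ParameterSpec]) -> ParamTree:
    """Build the full sampled tree over the in-tree parameters, in order."""
    in_tree = [s for s in specs if s.in_tree]
    if not in_tree:
        raise SweepError("no in-tree parameters: nothing to sweep")
    root = ParamNode()
    frontier = [root]
    for spec in in_tree:
        samples = sample_parameter(spec)
        next_frontier = []
        for node in frontier:
            for value in samples:
                child = ParamNode(param_name=spec.name, value=value, parent=node)
                node.children.append(child)
                next_frontier.append(child)
        frontier = next_frontier
    return ParamTree(root=root, specs=in_tree)


def enumerate_runs(
    tree: ParamTree, node: ParamNode, tool: ToolSpec | None = None
) -> list[dict]:
    """One full assignment per leaf under ``node``.

    The node's ancestry (itself included) fixes the upper-level parameters;
    descendant levels vary over their samples; parameters outside the tree
    take their ``fixed_value``.
    """
    fixed: dict = {}
    if tool is not None:
        for spec in tool.parameters:
            if not spec.in_tree:
                fixed[spec.name] = spec.fixed_value
    assignments = []
    for leaf in node.leaves():
        assignment = dict(fixed)
        walk = leaf
        while walk is not None and walk.param_name is not None:
            assignment[walk.param_name] = walk.value
            walk = walk.parent
        assignments.append(assignment)
    return assignments


# ---------------------------------------------------------------------------
# data subsetting


def _canonical_regions(regions: Sequence[Region]) -> list[Region]:
    return sorted(set(Region(r.chrom, r.start, r.end) for r in regions))


def subset_dataset(
    dataset: Dataset,
    index: indexing.BinIndex,
    regions: Sequence[Region],
    cache_dir: str,
) -> str:
    """Extract records overlapping any region into a cached subset file.

    The subset keeps the source format byte-for-byte: header lines are
    copied, then the raw source lines of the selected records in source
    order. Repeat calls with the same (source content, region set) return
    the cached path without rewriting it.
    """
    if not regions:
        raise SweepError("no regions to subset to")
    canon = _canonical_regions(regions)
    checksum = index.checksum or indexing.source_checksum(dataset.path)
    key_text = checksum + "|" + ";".join(
        f"{r.chrom}:{r.start}-{r.end}" for r in canon
    )
    key = hashlib.sha1(key_text.encode()).hexdigest()[:16]
    ext = os.path.splitext(dataset.path)[1] or f".{dataset.format}"
    os.makedirs(cache_dir, exist_ok=True)
    out_path = os.path.join(cache_dir, f"subset-{key}{ext}")
    if os.path.exists(out_path):
        return out_path

    ordinals: set[int] = set()
    for region in canon:
        ordinals.update(indexing.query_index(index, region))
    offsets = []
    for o in sorted(ordinals):
        offset = index.records[o][1]
        if offset < 0:
            raise SweepError(
                f"dataset format {dataset.format!r} has no per-record offsets; "
                "cannot subset it"
            )
        offsets.append(offset)
    offsets.sort()  # source order

    tmp_path = out_path + ".tmp"
    with open(dataset.path, "rb") as src, open(tmp_path, "wb") as out:
        # leading header/comment lines carry over
        while True:
            pos = src.tell()
            line = src.readline()
            if not line:
                break
            text = line.decode()
            if dataset.format == "sam":
                is_header = text.startswith("@")
            elif dataset.format == "vcf":
                is_header = text.startswith("#")
            else:
                is_header = format_io._is_skippable(text)
            if not is_header or pos in offsets:
                break
            out.write(line)
        for offset in offsets:
            src.seek(offset)
            out.write(src.readline())
    os.replace(tmp_path, out_path)
    return out_path


# ---------------------------------------------------------------------------
# execution


@dataclass
class SweepRun:
    """Outcome of one tool invocation in a sweep."""

    assignment: dict
    path_labels: list[str]
    output_path: str | None
    status: str  # "ok" | "failed" | "dry-run"
    region_payloads: dict[str, list] = field(default_factory=dict)
    diagnostics: str = ""


def _default_executor(cmd: list[str]) -> subprocess.CompletedProcess:
    return subprocess.run(cmd, capture_output=True, text=True)


def _slice_by_region(records: list, regions: Sequence[Region]) -> dict[str, list]:
    tiles: dict[str, list] = {}
    for region in regions:
        tiles[format_region_string(region)] = [
            rec for rec in records if rec.region.overlaps(region)
        ]
    return tiles


def execute_sweep(
    tool: ToolSpec,
    dataset: Dataset,
    index: indexing.BinIndex,
    node: ParamNode,
    regions: Sequence[Region],
    tree: ParamTree,
    workdir: str,
    cache_dir: str | None = None,
    executor: Callable[[list[str]], subprocess.CompletedProcess] | None = None,
    dry_run: bool = False,
) -> list[SweepRun]:
    """Run the tool once per assignment under ``node``, on the region subset.

    Each run's output is parsed in the tool's declared output format and
    sliced into one payload per selected region (the track tiles). A failed
    run is recorded with its diagnostics; it does not abort the sweep.
    """
    if tool.input_format != dataset.format:
        raise SweepError(
            f"tool {tool.id!r} consumes {tool.input_format!r} but dataset "
            f"is {dataset.format!r}"
        )
    regions = _canonical_regions(regions)
    assignments = enumerate_runs(tree, node, tool)
    leaves = node.leaves()
    executor = executor or _default_executor
    os.makedirs(workdir, exist_ok=True)
    subset_path = subset_dataset(
        dataset, index, regions, cache_dir or os.path.join(workdir, "subsets")
    )
    runs: list[SweepRun] = []
    for k, (assignment, leaf) in enumerate(zip(assignments, leaves)):
        labels = leaf.path_labels()
        if dry_run:
            runs.append(
                SweepRun(assignment, labels, output_path=None, status="dry-run")
            )
            continue
        out_path = os.path.join(workdir, f"run-{k:04d}.{tool.output_format}")
        cmd = tool.render_command(assignment, subset_path, out_path, regions)
        proc = executor(cmd)
        if proc.returncode != 0:
            runs.append(
                SweepRun(
                    assignment,
                    labels,
                    output_path=out_path,
                    status="failed",
                    diagnostics=f"exit {proc.returncode}: {proc.stderr}",
                )
            )
            continue
        try:
            records = format_io.read_features(out_path, tool.output_format)
        except (format_io.FormatError, OSError) as exc:
            runs.append(
                SweepRun(
                    assignment,
                    labels,
                    output_path=out_path,
                    status="failed",
                    diagnostics=f"unparseable output: {exc}",
                )
            )
            continue
        runs.append(
            SweepRun(
                assignment,
                labels,
                output_path=out_path,
                status="ok",
                region_payloads=_slice_by_region(records, regions),
            )
        )
    return runs


def run_full(
    tool: ToolSpec,
    dataset: Dataset,
    assignment: dict,
    workdir: str,
    regions: Sequence[Region] = (),
    executor: Callable[[list[str]], subprocess.CompletedProcess] | None = None,
) -> str:
    """Single tool invocation on the complete (un-subset) dataset.

    This is the "settings look good, now run for real" step; the output
    path can be registered as a new dataset for the providers.
    """
    executor = executor or _default_executor
    os.makedirs(workdir, exist_ok=True)
    out_path = os.path.join(workdir, f"full-{tool.id}.{tool.output_format}")
    cmd = tool.render_command(
        assignment, dataset.path, out_path, _canonical_regions(regions)
    )
    proc = executor(cmd)
    if proc.returncode != 0:
        raise SweepError(
            f"tool {tool.id!r} failed with exit {proc.returncode}: {proc.stderr}"
        )
    return out_path


def write_manifest(runs: Sequence[SweepRun], path: str) -> None:
    """JSON manifest mapping tree paths -> assignments -> outputs."""
    doc = [
        {
            "path": run.path_labels,
            "assignment": run.assignment,
            "output": run.output_path,
            "status": run.status,
            "regions": {
                region: len(records)
                for region, records in run.region_payloads.items()
            },
            "diagnostics": run.diagnostics,
        }
        for run in runs
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


# ---------------------------------------------------------------------------
# tool declarations


def load_tool_config(path: str) -> ToolSpec:
    """Read a tool declaration (JSON; see docs for the schema)."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        params = [ParameterSpec(**p) for p in doc.get("parameters", [])]
        return ToolSpec(
            id=doc["id"],
            command=doc["command"],
            input_format=doc["input_format"],
            output_format=doc["output_format"],
            parameters=params,
        )
    except (KeyError, TypeError) as exc:
        raise SweepError(f"{path}: bad tool config: {exc}") from exc


def builtin_tool(tool_id: str, parameters: list[ParameterSpec] | None = None) -> ToolSpec:
    """Bundled toy tools used to exercise and verify the sweep machinery.

    - ``identity``: copies its input (BED in, BED out).
    - ``score_filter``: keeps features with score >= min_score.
    - ``counter``: writes one BED line per selected region whose score is
      the number of input features overlapping that region.
    """
    python = shlex.quote(sys.executable)
    if tool_id == "identity":
        return ToolSpec(
            id="identity",
            command=f"{python} -m genoviz.toy_tools identity {{input}} {{output}}",
            input_format="bed",
            output_format="bed",
            parameters=parameters or [],
        )
    if tool_id == "score_filter":
        return ToolSpec(
            id="score_filter",
            command=(
                f"{python} -m genoviz.toy_tools score_filter {{input}} {{output}} "
                "--min-score {param:min_score}"
            ),
            input_format="bed",
            output_format="bed",
            parameters=parameters
            or [
                ParameterSpec(
                    name="min_score", kind="numeric", min=0, max=1000, n_samples=3
                )
            ],
        )
    if tool_id == "counter":
        return ToolSpec(
            id="counter",
            command=(
                f"{python} -m genoviz.toy_tools counter {{input}} {{output}} "
                "--regions {regions} --min-score {param:min_score}"
            ),
            input_format="bed",
            output_format="bed",
            parameters=parameters
            or [
                ParameterSpec(
                    name="min_score", kind="numeric", min=0, max=0, n_samples=1
                )
            ],
        )
    raise SweepError(f"unknown builtin tool {tool_id!r}")
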