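"""Seeded synthetic data: genomes, feature files, signal files, trees.

Every generator draws from its own pseudorandom stream derived from
``(seed, generator name)``, so adding or reordering generators never
perturbs the output of the others, and identical configuration always
produces byte-identical files. The generated data is structural, not
biological: it exercises coordinate arithmetic, indexing, summarization,
and layout, not read-error or evolutionary models.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import format_io, phylo
from .genome_model import Genome, Region

__all__ = [
    "GenomeSpec",
    "FeatureSpec",
    "SignalSpec",
    "TreeSpec",
    "rng_for",
    "generate_genome",
    "generate_features",
    "generate_signal",
    "generate_tree",
    "write_chrom_sizes",
]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """A named stream: one generator's draws never shift another's."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big") & 0x7FFFFFFF)


@dataclass
class GenomeSpec:
    n_chromosomes: int = 3
    min_length: int = 50_000
    max_length: int = 200_000


@dataclass
class FeatureSpec:
    count: int = 500
    min_length: int = 50
    max_length: int = 2_000
    min_score: float = 0.0
    max_score: float = 1000.0
    #: 0 forces pairwise-disjoint features; 1 places them uniformly at random
    overlap_factor: float = 1.0


@dataclass
class SignalSpec:
    n_segments: int = 200
    segment_length: int = 500
    min_value: float = 0.0
    max_value: float = 100.0


@dataclass
class TreeSpec:
    n_leaves: int = 32
    min_branch_length: float = 0.01
    max_branch_length: float = 2.0


def generate_genome(
    spec: GenomeSpec, seed: int, path: str | None = None
) -> Genome:
    """A genome of ``n_chromosomes`` with lengths drawn in the given range;
    optionally also writes a chrom.sizes file."""
    if spec.n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    rng = rng_for(seed, "genome")
    lengths = rng.integers(
        spec.min_length, spec.max_length + 1, size=spec.n_chromosomes
    )
    genome = Genome(
        f"synth{seed}",
        [(f"chr{i + 1}", int(n)) for i, n in enumerate(lengths)],
    )
    if path is not None:
        write_chrom_sizes(genome, path)
    return genome


def write_chrom_sizes(genome: Genome, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def _disjoint_starts(
    rng: np.random.Generator, n: int, lengths: np.ndarray, chrom_len: int
) -> np.ndarray:
    """Starts such that [start_i, start_i + len_i) are pairwise disjoint."""
    total = int(lengths.sum())
    slack = chrom_len - total
    if slack < 0:
        raise ValueError(
            f"cannot place {n} disjoint features of total length {total} "
            f"on a chromosome of {chrom_len} bases"
        )
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    return gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))


def generate_features(
    spec: FeatureSpec,
    genome: Genome,
    seed: int,
    path: str | None = None,
    format: str = "bed",
) -> list[format_io.Feature]:
    """Random features within chromosome bounds, optionally written to disk.

    Chromosome assignment is proportional to chromosome length. With
    ``overlap_factor == 0`` the features on each chromosome are pairwise
    disjoint (placed into sorted non-overlapping slots).
    """
    rng = rng_for(seed, "features")
    chrom_names = genome.names
    chrom_lengths = np.array([genome.length(c) for c in chrom_names], dtype=float)
    probs = chrom_lengths / chrom_lengths.sum()
    assignment = rng.choice(len(chrom_names), size=spec.count, p=probs)
    features: list[format_io.Feature] = []
    idx = 0
    for ci, chrom in enumerate(chrom_names):
        n = int((assignment == ci).sum())
        if n == 0:
            continue
        chrom_len = genome.length(chrom)
        max_len = min(spec.max_length, chrom_len)
        min_len = min(spec.min_length, max_len)
        lengths = rng.integers(min_len, max_len + 1, size=n)
        if spec.overlap_factor == 0:
            starts = _disjoint_starts(rng, n, lengths, chrom_len)
        else:
            starts = rng.integers(0, chrom_len - lengths + 1)
        scores = rng.uniform(spec.min_score, spec.max_score, size=n)
        strands = rng.choice(["+", "-"], size=n)
        for k in range(n):
            features.append(
                format_io.Feature(
                    Region(chrom, int(starts[k]), int(starts[k] + lengths[k]), strands[k]),
                    name=f"f{idx}",
                    score=round(float(scores[k]), 3),
                )
            )
            idx += 1
    if path is not None:
        format_io.write_features(features, path, format)
    return features


def generate_signal(
    spec: SignalSpec,
    genome: Genome,
    seed: int,
    path: str | None = None,
    format: str = "bedgraph",
) -> list[format_io.SignalPoint]:
    """Piecewise-constant signal segments tiling random chromosome stretches."""
    rng = rng_for(seed, "signal")
    chrom_names = genome.names
    points: list[format_io.SignalPoint] = []
    per_chrom = np.bincount(
        rng.integers(0, len(chrom_names), size=spec.n_segments),
        minlength=len(chrom_names),
    )
    for ci, chrom in enumerate(chrom_names):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        chrom_len = genome.length(chrom)
        seg = min(spec.segment_length, chrom_len)
        # contiguous run of n abutting segments starting at a random offset
        run = min(n * seg, chrom_len)
        n_fit = run // seg
        start = int(rng.integers(0, chrom_len - n_fit * seg + 1))
        values = rng.uniform(spec.min_value, spec.max_value, size=n_fit)
        for k in range(n_fit):
            lo = start + k * seg
            points.append(
                format_io.SignalPoint(
                    Region(chrom, lo, lo + seg), round(float(values[k]), 4)
                )
            )
    if path is not None:
        _write_signal(points, path, format)
    return points


def _write_signal(
    points: list[format_io.SignalPoint], path: str, format: str
) -> None:
    with open(path, "w") as fh:
        if format == "bedgraph":
            for p in points:
                fh.write(
                    f"{p.region.chrom}\t{p.region.start}\t{p.region.end}\t{p.value}\n"
                )
        elif format == "wiggle":
            for p in points:  # variableStep with span, one declaration per point
                fh.write(
                    f"variableStep chrom={p.region.chrom} span={p.region.length}\n"
                )
                fh.write(f"{p.region.start + 1} {p.value}\n")
        else:
            raise ValueError(f"unsupported signal format {format!r}")


def generate_tree(
    spec: TreeSpec, seed: int, path: str | None = None
) -> phylo.PhyloNode:
    """Random tree by sequential leaf attachment, with drawn branch lengths.

    Each new leaf splits a uniformly chosen existing leaf into a cherry,
    which keeps the tree binary and its expected depth logarithmic.
    """
    if spec.n_leaves < 1:
        raise ValueError("need at least one leaf")
    rng = rng_for(seed, "tree")

    def bl() -> float:
        return round(
            float(rng.uniform(spec.min_branch_length, spec.max_branch_length)), 6
        )

    root = phylo.PhyloNode(name="L0", branch_length=None)
    leaves = [root]
    for i in range(1, spec.n_leaves):
        idx = int(rng.integers(0, len(leaves)))
        target = leaves[idx]
        # split: target becomes internal with two fresh leaves
        left = phylo.PhyloNode(name=target.name, branch_length=bl())
        right = phylo.PhyloNode(name=f"L{i}", branch_length=bl())
        target.name = None
        target.children = [left, right]
        leaves[idx] = left
        leaves.append(right)
    text = phylo.write_newick(root)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return root
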