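import math

import pytest
from hypothesis import HealthCheck, settings

from genoviz import fixtures as fx
from genoviz.genome_model import Genome, Region
from genoviz.providers import Dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def genome():
    return Genome("toy", [("chr1", 100_000), ("chr2", 60_000), ("chr3", 40_000)])


@pytest.fixture
def bed_dataset(tmp_path, genome):
    """A seeded 400-feature BED dataset with its index."""
    path = tmp_path / "features.bed"
    feats = fx.generate_features(
        fx.FeatureSpec(count=400), genome, seed=7, path=str(path)
    )
    ds = Dataset(str(path), "bed")
    return ds, ds.build_index(), feats


@pytest.fixture
def signal_dataset(tmp_path, genome):
    path = tmp_path / "signal.bedgraph"
    points = fx.generate_signal(
        fx.SignalSpec(n_segments=120), genome, seed=7, path=str(path)
    )
    ds = Dataset(str(path), "bedgraph")
    return ds, ds.build_index(), points


def brute_force_overlaps(records, region: Region):
    """Reference linear scan with the half-open overlap test."""
    out = []
    for i, rec in enumerate(records):
        r = rec.region if hasattr(rec, "region") else rec
        if r.chrom == region.chrom and r.start < region.end and region.start < r.end:
            out.append(i)
    return out


def brute_force_summary_count(records, region: Region, nbins: int):
    """Per-bin overlap counts computed directly from bin boundaries."""
    nbins = min(nbins, region.length)
    w = region.length // nbins
    bounds = [
        (
            region.start + i * w,
            region.end if i == nbins - 1 else region.start + (i + 1) * w,
        )
        for i in range(nbins)
    ]
    values = []
    for lo, hi in bounds:
        n = 0
        for rec in records:
            r = rec.region if hasattr(rec, "region") else rec
            if r.chrom == region.chrom and r.start < hi and lo < r.end:
                n += 1
        values.append(float(n))
    return values


def brute_force_summary_mean(points, region: Region, nbins: int):
    """Base-weighted per-bin mean of piecewise-constant signal."""
    nbins = min(nbins, region.length)
    w = region.length // nbins
    values = []
    for i in range(nbins):
        lo = region.start + i * w
        hi = region.end if i == nbins - 1 else lo + w
        total = 0.0
        covered = 0
        for p in points:
            r = p.region
            if r.chrom != region.chrom:
                continue
            ov = min(r.end, hi) - max(r.start, lo)
            if ov > 0:
                total += p.value * ov
                covered += ov
        values.append(total / covered if covered else None)
    return values


def max_overlap_depth(intervals):
    """Sweep-line maximum depth of half-open intervals (packing oracle)."""
    events = []
    for start, end in intervals:
        events.append((start, 1))
        events.append((end, -1))
    events.sort()  # at equal coordinate, ends (-1) precede starts (+1)
    depth = best = 0
    for _, delta in events:
        depth += delta
        best = max(best, depth)
    return best


def angles_sum(layout):
    return sum(e - s for s, e in layout.arcs.values()) + len(layout.arcs) * layout.gap


def assert_close(a, b, tol=1e-9):
    assert a is not None and b is not None and math.isfinite(a)
    assert abs(a - b) <= tol, f"{a} != {b} (tol {tol})"
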