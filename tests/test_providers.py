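import math

import numpy as np
import pytest

from genoviz import format_io as fio
from genoviz import indexing as ix
from genoviz import providers as pv
from genoviz.genome_model import Genome, Region

from conftest import (
    assert_close,
    brute_force_overlaps,
    brute_force_summary_count,
    brute_force_summary_mean,
)


def make_bed(tmp_path, rows, name="d.bed"):
    path = tmp_path / name
    path.write_text("".join(f"{c}\t{s}\t{e}\t{n}\t{sc}\t{st}\n" for c, s, e, n, sc, st in rows))
    ds = pv.Dataset(str(path), "bed")
    return ds, ds.build_index()


class TestCountAndDetail:
    def test_empty_dataset_counts_zero(self, tmp_path):
        ds, idx = make_bed(tmp_path, [])
        assert pv.count_in_region(ds, idx, Region("chr1", 0, 100)) == 0

    def test_count_matches_linear_scan(self, bed_dataset):
        ds, idx, feats = bed_dataset
        rng = np.random.default_rng(2)
        for _ in range(50):
            start = int(rng.integers(0, 90_000))
            region = Region("chr1", start, start + int(rng.integers(1, 30_000)))
            assert pv.count_in_region(ds, idx, region) == len(
                brute_force_overlaps(feats, region)
            )

    def test_detail_returns_sorted_overlaps_only(self, tmp_path):
        rows = [
            ("chr1", 0, 50, "a", 1, "+"),
            ("chr1", 100, 150, "b", 2, "+"),
            ("chr1", 120, 130, "c", 3, "-"),
            ("chr1", 500, 600, "d", 4, "+"),
            ("chr2", 100, 150, "e", 5, "+"),
        ]
        ds, idx = make_bed(tmp_path, rows)
        payload = pv.get_detail(ds, idx, Region("chr1", 110, 140))
        assert [f.name for f in payload.records] == ["b", "c"]
        assert payload.total_in_region == 2
        starts = [f.region.start for f in payload.records]
        assert starts == sorted(starts)

    def test_empty_intersection_is_fine(self, tmp_path):
        ds, idx = make_bed(tmp_path, [("chr1", 0, 10, "a", 1, "+")])
        payload = pv.get_detail(ds, idx, Region("chr1", 5000, 6000))
        assert payload.records == [] and payload.total_in_region == 0

    def test_over_limit_raises_directing_to_summary(self, tmp_path):
        rows = [("chr1", i, i + 5, f"f{i}", 1, "+") for i in range(0, 60, 2)]
        ds, idx = make_bed(tmp_path, rows)
        with pytest.raises(pv.OverLimitError, match="summary"):
            pv.get_detail(ds, idx, Region("chr1", 0, 100), max_detail=10)


class TestSummary:
    def test_spanning_feature_counts_in_all_bins(self, tmp_path):
        ds, idx = make_bed(tmp_path, [("chr1", 0, 1000, "a", 1, "+")])
        bins = pv.get_summary(ds, idx, Region("chr1", 0, 1000), nbins=4)
        assert bins.values == [1, 1, 1, 1]

    def test_hand_computed_two_bin_counts(self, tmp_path):
        ds, idx = make_bed(
            tmp_path, [("chr1", 0, 10, "a", 1, "+"), ("chr1", 5, 15, "b", 1, "+")]
        )
        bins = pv.get_summary(ds, idx, Region("chr1", 0, 20), nbins=2)
        assert bins.values == [2, 1]

    def test_count_matches_brute_force_on_random_fixture(self, bed_dataset):
        ds, idx, feats = bed_dataset
        rng = np.random.default_rng(4)
        for _ in range(20):
            start = int(rng.integers(0, 50_000))
            region = Region("chr1", start, start + int(rng.integers(100, 40_000)))
            nbins = int(rng.integers(1, 50))
            bins = pv.get_summary(ds, idx, region, nbins=nbins)
            assert bins.values == brute_force_summary_count(feats, region, nbins)

    def test_mean_matches_brute_force_within_1e9(self, signal_dataset):
        ds, idx, points = signal_dataset
        rng = np.random.default_rng(6)
        for _ in range(15):
            start = int(rng.integers(0, 50_000))
            region = Region("chr1", start, start + int(rng.integers(500, 40_000)))
            nbins = int(rng.integers(1, 30))
            got = pv.get_summary(ds, idx, region, nbins=nbins, stat="mean")
            expected = brute_force_summary_mean(points, region, nbins)
            for g, e in zip(got.values, expected):
                if e is None:
                    assert g is None
                else:
                    assert_close(g, e, 1e-9)

    def test_min_max_bound_the_mean(self, signal_dataset):
        ds, idx, _ = signal_dataset
        region = Region("chr1", 0, 100_000)
        lo = pv.get_summary(ds, idx, region, nbins=10, stat="min").values
        mid = pv.get_summary(ds, idx, region, nbins=10, stat="mean").values
        hi = pv.get_summary(ds, idx, region, nbins=10, stat="max").values
        for a, m, b in zip(lo, mid, hi):
            if m is not None:
                assert a - 1e-12 <= m <= b + 1e-12

    def test_mean_on_feature_dataset_is_an_error(self, bed_dataset):
        ds, idx, _ = bed_dataset
        with pytest.raises(pv.ProviderError, match="quantitative"):
            pv.get_summary(ds, idx, Region("chr1", 0, 1000), nbins=4, stat="mean")

    def test_summary_conservation_for_single_bin_features(self, tmp_path):
        # features confined to one bin each: bin counts sum to the total
        rows = [("chr1", 10 * i, 10 * i + 5, f"f{i}", 1, "+") for i in range(40)]
        ds, idx = make_bed(tmp_path, rows)
        region = Region("chr1", 0, 400)
        bins = pv.get_summary(ds, idx, region, nbins=40)
        assert sum(bins.values) == pv.count_in_region(ds, idx, region) == 40


class TestModeSelection:
    def _dataset(self, tmp_path, n):
        rows = [("chr1", 2 * i, 2 * i + 1, f"f{i}", 1, "+") for i in range(n)]
        return make_bed(tmp_path, rows)

    def test_few_records_stay_detail(self, tmp_path):
        ds, idx = self._dataset(tmp_path, 10)
        payload = pv.get_data(ds, idx, Region("chr1", 0, 1000))
        assert payload.mode == "detail" and payload.message is None

    def test_boundary_exactly_max_detail_is_detail(self, tmp_path):
        ds, idx = self._dataset(tmp_path, 20)
        payload = pv.get_data(ds, idx, Region("chr1", 0, 1000), max_detail=20)
        assert payload.mode == "detail"
        assert payload.total_in_region == 20

    def test_one_over_threshold_flips_to_summary(self, tmp_path):
        ds, idx = self._dataset(tmp_path, 21)
        payload = pv.get_data(ds, idx, Region("chr1", 0, 1000), max_detail=20, nbins=8)
        assert payload.mode == "summary"
        assert payload.total_in_region == 21
        assert payload.message is not None and "20" in payload.message


class TestGenomeWide:
    def test_per_chromosome_matches_direct_summary(self, genome, bed_dataset):
        ds, idx, _ = bed_dataset
        wide = pv.get_genome_wide(ds, idx, genome, bins_per_chrom=25)
        assert len(wide) == len(genome)
        for bins, (name, length) in zip(wide, genome.chromosomes):
            direct = pv.get_summary(ds, idx, Region(name, 0, length), nbins=25)
            assert bins.values == direct.values

    def test_single_bin_gives_per_chromosome_totals(self, genome, bed_dataset):
        ds, idx, feats = bed_dataset
        wide = pv.get_genome_wide(ds, idx, genome, bins_per_chrom=1)
        for bins, (name, _) in zip(wide, genome.chromosomes):
            assert bins.values == [
                sum(1 for f in feats if f.region.chrom == name)
            ]

    def test_empty_dataset_gives_zero_bins(self, tmp_path, genome):
        ds, idx = make_bed(tmp_path, [])
        wide = pv.get_genome_wide(ds, idx, genome, bins_per_chrom=5)
        assert all(v == 0 for bins in wide for v in bins.values)


class TestComposite:
    def _signals(self, tmp_path, genome, k):
        from genoviz import fixtures as fx

        out = []
        for i in range(k):
            path = tmp_path / f"s{i}.bedgraph"
            fx.generate_signal(
                fx.SignalSpec(n_segments=60), genome, seed=100 + i, path=str(path)
            )
            ds = pv.Dataset(str(path), "bedgraph")
            out.append((ds, ds.build_index()))
        return out

    def test_rows_equal_individual_summaries(self, tmp_path, genome):
        pairs = self._signals(tmp_path, genome, 3)
        region = Region("chr1", 0, 80_000)
        matrix = pv.composite_summary(
            [d for d, _ in pairs], [i for _, i in pairs], region, nbins=40
        )
        assert matrix.shape == (3, 40)
        for row, (ds, idx) in zip(matrix, pairs):
            single = pv.get_summary(ds, idx, region, nbins=40, stat="mean").values
            expected = [math.nan if v is None else v for v in single]
            np.testing.assert_allclose(row, expected, rtol=0, atol=1e-12)

    def test_single_dataset_degenerate(self, tmp_path, genome):
        ((ds, idx),) = self._signals(tmp_path, genome, 1)
        region = Region("chr2", 0, 50_000)
        matrix = pv.composite_summary([ds], [idx], region, nbins=10)
        assert matrix.shape == (1, 10)

    def test_disjoint_chromosome_row_is_all_nan(self, tmp_path, genome):
        pairs = self._signals(tmp_path, genome, 1)
        path = tmp_path / "other.bedgraph"
        path.write_text("chrOnlyHere\t0\t100\t5.0\n")
        other = pv.Dataset(str(path), "bedgraph")
        dss = [pairs[0][0], other]
        idxs = [pairs[0][1], other.build_index()]
        matrix = pv.composite_summary(dss, idxs, Region("chr1", 0, 10_000), nbins=5)
        assert np.isnan(matrix[1]).all()

    def test_mean_composite_rejects_feature_dataset(self, tmp_path, genome, bed_dataset):
        ds, idx, _ = bed_dataset
        with pytest.raises(pv.ProviderError, match="quantitative"):
            pv.composite_summary([ds], [idx], Region("chr1", 0, 1000), nbins=2)


class TestFilters:
    def test_score_range_retains_matching_feature(self, tmp_path):
        ds, idx = make_bed(tmp_path, [("chr1", 100, 200, "fA", 960, "+")])
        payload = pv.get_detail(ds, idx, Region("chr1", 0, 1000))
        spec = pv.FilterSpec("score", min=500, max=1000)
        assert len(pv.apply_filters(payload, [spec]).records) == 1

    def test_inverted_range_is_a_construction_error(self):
        with pytest.raises(pv.ProviderError, match="min"):
            pv.FilterSpec("score", min=1001, max=1000)

    def test_filters_on_summary_payload_rejected(self, tmp_path):
        ds, idx = make_bed(
            tmp_path, [("chr1", i, i + 1, "x", 1, "+") for i in range(0, 40, 2)]
        )
        payload = pv.get_data(ds, idx, Region("chr1", 0, 100), max_detail=3, nbins=4)
        assert payload.mode == "summary"
        with pytest.raises(pv.ProviderError, match="detail|records"):
            pv.apply_filters(payload, [pv.FilterSpec("score")])

    def test_missing_passes_semantics(self, tmp_path):
        rows = [("chr1", 0, 10, "a", 5, "+"), ("chr1", 20, 30, "b", ".", "+")]
        ds, idx = make_bed(tmp_path, rows)
        payload = pv.get_detail(ds, idx, Region("chr1", 0, 100))
        lenient = pv.FilterSpec("score", min=0, max=10, missing_passes=True)
        strict = pv.FilterSpec("score", min=0, max=10, missing_passes=False)
        assert len(pv.apply_filters(payload, [lenient]).records) == 2
        assert len(pv.apply_filters(payload, [strict]).records) == 1

    def test_random_filters_match_brute_force_predicate(self, bed_dataset):
        ds, idx, _ = bed_dataset
        payload = pv.get_detail(ds, idx, Region("chr1", 0, 100_000))
        rng = np.random.default_rng(8)
        for _ in range(25):
            lo = float(rng.uniform(0, 800))
            hi = lo + float(rng.uniform(0, 400))
            specs = [
                pv.FilterSpec("score", min=lo, max=hi, missing_passes=False),
                pv.FilterSpec("mapq", min=-1e9, max=1e9),
            ]
            got = pv.apply_filters(payload, specs).records
            expected = [
                f
                for f in payload.records
                if f.score is not None and lo <= f.score <= hi
            ]
            assert got == expected

    def test_idempotent_and_monotone(self, bed_dataset):
        ds, idx, _ = bed_dataset
        payload = pv.get_detail(ds, idx, Region("chr1", 0, 100_000))
        wide = pv.FilterSpec("score", min=100, max=900, missing_passes=False)
        narrow = pv.FilterSpec("score", min=200, max=800, missing_passes=False)
        once = pv.apply_filters(payload, [wide])
        twice = pv.apply_filters(once, [wide])
        assert once.records == twice.records
        tightened = pv.apply_filters(payload, [narrow])
        assert set(f.name for f in tightened.records) <= set(
            f.name for f in once.records
        )

    def test_gff_attribute_filter(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "chr1\ts\tg\t1\t100\t.\t+\t.\tID=a;depth=7\n"
            "chr1\ts\tg\t200\t300\t.\t+\t.\tID=b;depth=99\n"
        )
        ds = pv.Dataset(str(path), "gff3")
        idx = ds.build_index()
        payload = pv.get_detail(ds, idx, Region("chr1", 0, 1000))
        spec = pv.FilterSpec("depth", min=0, max=50, missing_passes=False)
        assert [f.attributes["ID"] for f in pv.apply_filters(payload, [spec]).records] == ["a"]


class TestColumnStats:
    def _table(self, cells):
        return fio.Table(names=["v"], types=["numeric"], rows=[[c] for c in cells])

    def test_two_value_column(self):
        stats = pv.column_stats(self._table([1.0, 3.0]), ["v"])["v"]
        assert stats["min"] == 1 and stats["max"] == 3 and stats["mean"] == 2
        assert_close(stats["sd"], math.sqrt(2), 1e-12)

    def test_single_value_has_no_sd(self):
        stats = pv.column_stats(self._table([5.0]), ["v"])["v"]
        assert stats["sd"] is None and stats["n"] == 1

    def test_missing_values_excluded(self):
        stats = pv.column_stats(self._table([1.0, None, 3.0]), ["v"])["v"]
        assert stats["n"] == 2 and stats["n_missing"] == 1 and stats["mean"] == 2

    def test_against_independent_two_pass_computation(self):
        rng = np.random.default_rng(13)
        values = list(rng.normal(50, 12, size=1000))
        stats = pv.column_stats(self._table(values), ["v"])["v"]
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
        assert_close(stats["mean"], mean, 1e-12)
        assert_close(stats["sd"], math.sqrt(var), 1e-12)
        assert stats["min"] == min(values) and stats["max"] == max(values)

    def test_string_column_rejected(self):
        table = fio.Table(names=["s"], types=["string"], rows=[["x"]])
        with pytest.raises(pv.ProviderError, match="numeric"):
            pv.column_stats(table, ["s"])


class TestCache:
    def test_repeat_query_is_served_from_cache(self, bed_dataset):
        ds, idx, _ = bed_dataset
        cache = pv.ProviderCache(capacity=8)
        region = Region("chr1", 1000, 9000)
        first = pv.cached_get_data(cache, ds, idx, region)
        assert (cache.hits, cache.misses) == (0, 1)
        second = pv.cached_get_data(cache, ds, idx, region)
        assert (cache.hits, cache.misses) == (1, 1)
        assert first == second

    def test_subregion_served_by_subselection(self, bed_dataset):
        ds, idx, _ = bed_dataset
        cache = pv.ProviderCache(capacity=8)
        big = Region("chr1", 0, 50_000)
        small = Region("chr1", 10_000, 20_000)
        pv.cached_get_data(cache, ds, idx, big)
        from_cache = pv.cached_get_data(cache, ds, idx, small)
        assert cache.hits == 1
        direct = pv.get_data(ds, idx, small)
        assert from_cache == direct

    def test_capacity_one_lru_eviction(self, bed_dataset):
        ds, idx, _ = bed_dataset
        cache = pv.ProviderCache(capacity=1)
        a = Region("chr1", 0, 1000)
        b = Region("chr2", 0, 1000)
        pv.cached_get_data(cache, ds, idx, a)
        pv.cached_get_data(cache, ds, idx, b)
        pv.cached_get_data(cache, ds, idx, a)  # evicted: miss again
        assert cache.misses == 3 and cache.hits == 0

    def test_cache_transparency_over_query_sequence(self, bed_dataset):
        ds, idx, _ = bed_dataset
        rng = np.random.default_rng(21)
        regions = []
        for _ in range(30):
            start = int(rng.integers(0, 60_000))
            regions.append(Region("chr1", start, start + int(rng.integers(500, 30_000))))
        regions += regions[:10]  # revisits
        cache = pv.ProviderCache(capacity=5)
        for region in regions:
            cached = pv.cached_get_data(cache, ds, idx, region)
            direct = pv.get_data(ds, idx, region)
            assert cached == direct
        assert cache.hits > 0


def test_payload_json_schema_shape(bed_dataset):
    ds, idx, _ = bed_dataset
    doc = pv.payload_to_json(pv.get_data(ds, idx, Region("chr1", 0, 50_000)))
    assert set(doc) == {"mode", "total", "message", "data"}
    assert doc["mode"] == "detail"
    start, end, name, score, strand, attrs = doc["data"][0]
    assert isinstance(start, int) and isinstance(end, int)
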