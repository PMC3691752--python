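import json
import os

import numpy as np
import pytest

from genoviz import fixtures as fx
from genoviz import format_io as fio
from genoviz import sweep as sw
from genoviz.genome_model import Genome, Region
from genoviz.providers import Dataset


def numeric(name, lo, hi, n, in_tree=True, fixed=None):
    return sw.ParameterSpec(
        name=name, kind="numeric", min=lo, max=hi, n_samples=n,
        in_tree=in_tree, fixed_value=fixed,
    )


class TestSampling:
    def test_five_point_range_zero_to_point_two(self):
        values = sw.sample_parameter(numeric("pre_mrna_fraction", 0.0, 0.2, 5))
        assert values[0] == 0.0 and values[-1] == 0.2
        assert values == pytest.approx([0.0, 0.05, 0.1, 0.15, 0.2], abs=1e-12)

    def test_categorical_keeps_declared_order(self):
        spec = sw.ParameterSpec(name="x", kind="categorical", values=["Yes", "No"])
        assert sw.sample_parameter(spec) == ["Yes", "No"]

    def test_single_sample_is_the_minimum(self):
        assert sw.sample_parameter(numeric("x", 0.1, 0.9, 1)) == [0.1]

    def test_endpoints_exact_and_spacing_uniform(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            lo = float(rng.uniform(-100, 100))
            hi = lo + float(rng.uniform(0, 100))
            n = int(rng.integers(2, 40))
            values = sw.sample_parameter(numeric("x", lo, hi, n))
            assert values[0] == lo and values[-1] == hi
            gaps = [b - a for a, b in zip(values, values[1:])]
            for g in gaps:
                assert abs(g - (hi - lo) / (n - 1)) < 1e-12

    def test_invalid_specs_rejected(self):
        with pytest.raises(sw.SweepError):
            numeric("x", 5, 1, 3)
        with pytest.raises(sw.SweepError):
            numeric("x", 0, 1, 0)
        with pytest.raises(sw.SweepError):
            sw.ParameterSpec(name="x", kind="categorical", values=[])
        with pytest.raises(sw.SweepError):
            sw.ParameterSpec(name="x", kind="categorical", values=["a", "a"])


class TestParamTree:
    def test_three_by_five_shape(self):
        tree = sw.build_param_tree(
            [numeric("a", 0, 1, 3), numeric("b", 0, 1, 5)]
        )
        assert len(tree.root.children) == 3
        assert all(len(c.children) == 5 for c in tree.root.children)
        assert tree.leaf_count == 15
        assert tree.depth == 2

    def test_one_categorical_two_leaves(self):
        spec = sw.ParameterSpec(name="x", kind="categorical", values=["Yes", "No"])
        assert sw.build_param_tree([spec]).leaf_count == 2

    def test_three_binary_levels(self):
        tree = sw.build_param_tree([numeric(c, 0, 1, 2) for c in "abc"])
        assert tree.leaf_count == 8 and tree.depth == 3

    def test_no_in_tree_parameters_is_an_error(self):
        with pytest.raises(sw.SweepError, match="in-tree"):
            sw.build_param_tree([numeric("a", 0, 1, 3, in_tree=False)])

    def test_levels_labeled_by_parameter_names(self):
        tree = sw.build_param_tree([numeric("outer", 0, 1, 2), numeric("inner", 0, 1, 2)])
        leaf = tree.node_at([1, 0])
        assert leaf.path_labels() == ["outer=1.0", "inner=0.0"]


class TestEnumerateRuns:
    def _tool(self):
        return sw.ToolSpec(
            id="t",
            command="true {input} {output}",
            input_format="bed",
            output_format="bed",
            parameters=[
                numeric("min_isoform_fraction", 0.0, 0.5, 3),
                numeric("pre_mrna_fraction", 0.0, 0.2, 5),
                numeric("threads", 4, 4, 1, in_tree=False, fixed=4),
            ],
        )

    def test_interior_node_sweeps_the_inner_parameter(self):
        """Fixing the first parameter at one value runs one job per sample
        of the second."""
        tool = self._tool()
        tree = sw.build_param_tree(tool.parameters)
        node = tree.node_at([1])  # min_isoform_fraction fixed at its 2nd sample
        runs = sw.enumerate_runs(tree, node, tool)
        assert len(runs) == 5
        assert {r["min_isoform_fraction"] for r in runs} == {0.25}
        assert [r["pre_mrna_fraction"] for r in runs] == pytest.approx(
            [0.0, 0.05, 0.1, 0.15, 0.2], abs=1e-12
        )
        assert all(r["threads"] == 4 for r in runs)

    def test_root_enumerates_the_full_product(self):
        tool = self._tool()
        tree = sw.build_param_tree(tool.parameters)
        assert len(sw.enumerate_runs(tree, tree.root, tool)) == 15

    def test_leaf_is_a_single_assignment(self):
        tool = self._tool()
        tree = sw.build_param_tree(tool.parameters)
        runs = sw.enumerate_runs(tree, tree.node_at([2, 4]), tool)
        assert runs == [
            {"threads": 4, "min_isoform_fraction": 0.5, "pre_mrna_fraction": 0.2}
        ]

    def test_children_partition_the_parent(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            specs = [
                numeric(f"p{i}", 0, 1, int(rng.integers(1, 5)))
                for i in range(int(rng.integers(1, 4)))
            ]
            tree = sw.build_param_tree(specs)
            expected = 1
            for s in specs:
                expected *= s.n_samples
            assert tree.leaf_count == expected
            node = tree.root
            while node.children:
                total = sum(
                    len(sw.enumerate_runs(tree, c)) for c in node.children
                )
                assert total == len(sw.enumerate_runs(tree, node))
                node = node.children[0]


class TestToolSpec:
    def test_undeclared_placeholder_rejected(self):
        with pytest.raises(sw.SweepError, match="placeholder"):
            sw.ToolSpec(
                id="t", command="x {param:ghost} {input} {output}",
                input_format="bed", output_format="bed", parameters=[],
            )

    def test_command_rendering_substitutes_everything(self):
        tool = sw.ToolSpec(
            id="t",
            command="run {input} {output} --k {param:k}",
            input_format="bed",
            output_format="bed",
            parameters=[numeric("k", 1, 9, 3)],
        )
        cmd = tool.render_command({"k": 5.0}, "in.bed", "out.bed")
        assert cmd == ["run", "in.bed", "out.bed", "--k", "5.0"]

    def test_config_round_trip(self, tmp_path):
        doc = {
            "id": "demo",
            "command": "demo {input} {output} --alpha {param:alpha}",
            "input_format": "bed",
            "output_format": "bed",
            "parameters": [
                {"name": "alpha", "kind": "numeric", "min": 0, "max": 1, "n_samples": 3}
            ],
        }
        path = tmp_path / "tool.json"
        path.write_text(json.dumps(doc))
        tool = sw.load_tool_config(str(path))
        assert tool.id == "demo" and tool.parameters[0].n_samples == 3


@pytest.fixture
def sweep_fixture(tmp_path):
    genome = Genome("g", [("chr1", 80_000), ("chr2", 40_000)])
    path = tmp_path / "data.bed"
    feats = fx.generate_features(
        fx.FeatureSpec(count=300), genome, seed=5, path=str(path)
    )
    ds = Dataset(str(path), "bed")
    idx = ds.build_index()
    regions = [Region("chr1", 5_000, 25_000), Region("chr2", 0, 15_000)]
    return ds, idx, feats, regions, tmp_path


class TestSubsetting:
    def test_subset_equals_brute_force_overlap_filter(self, sweep_fixture):
        ds, idx, feats, regions, tmp = sweep_fixture
        path = sw.subset_dataset(ds, idx, regions, str(tmp / "cache"))
        subset = fio.read_features(path, "bed")
        expected = [
            f for f in feats if any(f.region.overlaps(r) for r in regions)
        ]
        key = lambda f: (f.region.chrom, f.region.start, f.region.end, f.name)
        assert sorted(map(key, subset)) == sorted(map(key, expected))

    def test_empty_region_set_yields_empty_subset(self, sweep_fixture):
        ds, idx, _, _, tmp = sweep_fixture
        nowhere = [Region("chr1", 79_990, 79_991)]
        path = sw.subset_dataset(ds, idx, nowhere, str(tmp / "cache"))
        assert fio.read_features(path, "bed") == []

    def test_repeat_call_reuses_cached_file(self, sweep_fixture):
        ds, idx, _, regions, tmp = sweep_fixture
        p1 = sw.subset_dataset(ds, idx, regions, str(tmp / "cache"))
        mtime = os.path.getmtime(p1)
        p2 = sw.subset_dataset(ds, idx, regions, str(tmp / "cache"))
        assert p1 == p2
        assert os.path.getmtime(p2) == mtime

    def test_region_order_does_not_change_the_key(self, sweep_fixture):
        ds, idx, _, regions, tmp = sweep_fixture
        p1 = sw.subset_dataset(ds, idx, regions, str(tmp / "cache"))
        p2 = sw.subset_dataset(ds, idx, list(reversed(regions)), str(tmp / "cache"))
        assert p1 == p2


class TestExecution:
    def test_identity_tool_reproduces_subset(self, sweep_fixture):
        ds, idx, feats, regions, tmp = sweep_fixture
        tool = sw.builtin_tool("identity")
        tool.parameters = [numeric("dummy", 0, 0, 1)]
        tree = sw.build_param_tree(tool.parameters)
        runs = sw.execute_sweep(
            tool, ds, idx, tree.root, regions, tree, workdir=str(tmp / "w")
        )
        assert len(runs) == 1 and runs[0].status == "ok"
        for region in regions:
            tile = runs[0].region_payloads[
                f"{region.chrom}:{region.start + 1}-{region.end}"
            ]
            expected = [f for f in feats if f.region.overlaps(region)]
            assert len(tile) == len(expected)

    def test_counter_tool_matches_brute_force_counts(self, sweep_fixture):
        ds, idx, feats, regions, tmp = sweep_fixture
        tool = sw.builtin_tool("counter")
        tree = sw.build_param_tree(tool.parameters)
        runs = sw.execute_sweep(
            tool, ds, idx, tree.root, regions, tree, workdir=str(tmp / "w")
        )
        (run,) = runs
        assert run.status == "ok"
        for region in regions:
            (tile_feat,) = run.region_payloads[
                f"{region.chrom}:{region.start + 1}-{region.end}"
            ]
            brute = sum(1 for f in feats if f.region.overlaps(region))
            assert tile_feat.score == brute

    def test_run_and_tile_cardinality(self, sweep_fixture):
        ds, idx, _, regions, tmp = sweep_fixture
        tool = sw.builtin_tool(
            "score_filter", [numeric("min_score", 0, 1000, 5)]
        )
        tree = sw.build_param_tree(tool.parameters)
        runs = sw.execute_sweep(
            tool, ds, idx, tree.root, regions, tree, workdir=str(tmp / "w")
        )
        assert len(runs) == 5
        assert all(len(r.region_payloads) == 2 for r in runs)
        assert all(r.status == "ok" for r in runs)

    def test_score_filter_monotone_across_sweep(self, sweep_fixture):
        ds, idx, _, regions, tmp = sweep_fixture
        tool = sw.builtin_tool("score_filter", [numeric("min_score", 0, 1000, 4)])
        tree = sw.build_param_tree(tool.parameters)
        runs = sw.execute_sweep(
            tool, ds, idx, tree.root, regions, tree, workdir=str(tmp / "w")
        )
        sizes = [
            sum(len(t) for t in run.region_payloads.values()) for run in runs
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_failed_run_recorded_without_aborting(self, sweep_fixture):
        ds, idx, _, regions, tmp = sweep_fixture
        tool = sw.ToolSpec(
            id="broken",
            command=f"{os.sys.executable} -c 'import sys; sys.exit(3)' {{input}} {{output}}",
            input_format="bed",
            output_format="bed",
            parameters=[numeric("p", 0, 1, 2)],
        )
        tree = sw.build_param_tree(tool.parameters)
        runs = sw.execute_sweep(
            tool, ds, idx, tree.root, regions, tree, workdir=str(tmp / "w")
        )
        assert len(runs) == 2
        assert all(r.status == "failed" for r in runs)
        assert all("exit 3" in r.diagnostics for r in runs)

    def test_dry_run_executes_nothing(self, sweep_fixture):
        ds, idx, _, regions, tmp = sweep_fixture
        tool = sw.builtin_tool("counter")
        tree = sw.build_param_tree(tool.parameters)
        runs = sw.execute_sweep(
            tool, ds, idx, tree.root, regions, tree,
            workdir=str(tmp / "dry"), dry_run=True,
        )
        assert all(r.status == "dry-run" and r.output_path is None for r in runs)

    def test_format_mismatch_rejected(self, sweep_fixture):
        ds, idx, _, regions, tmp = sweep_fixture
        tool = sw.builtin_tool("counter")
        tool.input_format = "gff3"
        tree = sw.build_param_tree(tool.parameters)
        with pytest.raises(sw.SweepError, match="consumes"):
            sw.execute_sweep(
                tool, ds, idx, tree.root, regions, tree, workdir=str(tmp / "w")
            )


class TestRunFull:
    def test_identity_on_full_dataset_reproduces_input(self, sweep_fixture):
        ds, idx, feats, _, tmp = sweep_fixture
        tool = sw.builtin_tool("identity")
        out = sw.run_full(tool, ds, {}, workdir=str(tmp / "full"))
        assert fio.read_features(out, "bed") == fio.read_features(ds.path, "bed")

    def test_counter_subset_run_equals_restricted_full_run(self, sweep_fixture):
        """Region-locality: for the per-region counter, running on the subset
        gives exactly the full-data answer inside the selected regions."""
        ds, idx, feats, regions, tmp = sweep_fixture
        tool = sw.builtin_tool("counter")
        tree = sw.build_param_tree(tool.parameters)
        (sub_run,) = sw.execute_sweep(
            tool, ds, idx, tree.root, regions, tree, workdir=str(tmp / "sub")
        )
        full_out = sw.run_full(
            tool, ds, {"min_score": 0}, workdir=str(tmp / "full"), regions=regions
        )
        full_records = fio.read_features(full_out, "bed")
        for region in regions:
            key = f"{region.chrom}:{region.start + 1}-{region.end}"
            restricted = [f for f in full_records if f.region.overlaps(region)]
            assert [f.score for f in restricted] == [
                f.score for f in sub_run.region_payloads[key]
            ]

    def test_failing_tool_raises_with_diagnostics(self, sweep_fixture):
        ds, _, _, _, tmp = sweep_fixture
        tool = sw.ToolSpec(
            id="boom",
            command=(
                f"{os.sys.executable} -c "
                "'import sys; sys.stderr.write(\"kaput\"); sys.exit(9)' "
                "{input} {output}"
            ),
            input_format="bed",
            output_format="bed",
        )
        with pytest.raises(sw.SweepError, match="kaput"):
            sw.run_full(tool, ds, {}, workdir=str(tmp / "f"))


def test_manifest_is_valid_json(sweep_fixture):
    ds, idx, _, regions, tmp = sweep_fixture
    tool = sw.builtin_tool("counter")
    tree = sw.build_param_tree(tool.parameters)
    runs = sw.execute_sweep(
        tool, ds, idx, tree.root, regions, tree, workdir=str(tmp / "w")
    )
    manifest = tmp / "manifest.json"
    sw.write_manifest(runs, str(manifest))
    doc = json.loads(manifest.read_text())
    assert len(doc) == len(runs)
    assert doc[0]["status"] == "ok"
    assert set(doc[0]["regions"]) == {
        f"{r.chrom}:{r.start + 1}-{r.end}" for r in regions
    }
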