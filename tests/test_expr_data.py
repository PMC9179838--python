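"""I/O, probe collapsing, merging, and gene-wise scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnbckit import (
    ExpressionMatrix,
    ProbeMap,
    ScalingSpec,
    collapse_probes,
    merge_datasets,
    read_matrix,
    scale_genes,
    write_matrix,
)
from tnbckit.expr_data import ParseError

from .conftest import make_matrix


class TestReadWrite:
    def test_tsv_identity_read_back(self, tmp_path, small_matrix):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        m = read_matrix(path)
        assert list(m.gene_ids) == ["g1", "g2", "g3"]
        np.testing.assert_array_equal(m.values.to_numpy(), small_matrix.values.to_numpy())

    def test_gct_equals_tsv(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n")
        (tmp_path / "m.gct").write_text(
            "#1.2\n3\t2\nName\tDescription\ts1\ts2\n"
            "g1\tg1\t1\t2\ng2\tg2\t3\t4\ng3\tg3\t5\t6\n"
        )
        a = read_matrix(tmp_path / "m.tsv")
        b = read_matrix(tmp_path / "m.gct")
        pd.testing.assert_frame_equal(a.values, b.values)

    @pytest.mark.parametrize("fmt", ["tsv", "gct"])
    def test_round_trip_50x20(self, tmp_path, random_matrix, fmt):
        path = tmp_path / f"m.{fmt}"
        write_matrix(random_matrix, path, format=fmt)
        back = read_matrix(path, format=fmt)
        assert np.abs(back.values.to_numpy() - random_matrix.values.to_numpy()).max() < 1e-12
        assert list(back.gene_ids) == list(random_matrix.gene_ids)

    def test_metadata_round_trip_exact(self, tmp_path, random_matrix):
        m = random_matrix
        m.sample_meta["batch"] = ["b1"] * 10 + ["b2"] * 10
        m.sample_meta["platform"] = "HTA20"
        write_matrix(m, tmp_path / "m.tsv", meta_path=tmp_path / "meta.tsv")
        back = read_matrix(tmp_path / "m.tsv", meta_path=tmp_path / "meta.tsv")
        assert list(back.sample_meta["batch"]) == list(m.sample_meta["batch"])
        assert (back.sample_meta["platform"] == "HTA20").all()

    def test_missing_meta_rows_get_default_levels(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene_id\ts1\ts2\ng1\t1\t2\n")
        (tmp_path / "meta.tsv").write_text("sample_id\tbatch\ns1\tb1\n")
        m = read_matrix(tmp_path / "m.tsv", meta_path=tmp_path / "meta.tsv")
        assert m.sample_meta.loc["s2", "batch"] == "unspecified"

    def test_non_numeric_cell_names_location(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene_id\ts1\ng1\t1\ng2\toops\n")
        with pytest.raises(ParseError, match="g2"):
            read_matrix(tmp_path / "m.tsv")

    def test_duplicate_gene_row_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("gene_id\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(ParseError, match="g1"):
            read_matrix(tmp_path / "m.tsv")

    def test_malformed_gct_header(self, tmp_path):
        (tmp_path / "m.gct").write_text("#9.9\n1\t1\nName\tDescription\ts1\ng1\tg1\t1\n")
        with pytest.raises(ParseError, match="1.2"):
            read_matrix(tmp_path / "m.gct")

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            make_matrix([[1.0, np.nan]])


class TestCollapseProbes:
    def test_one_probe_per_gene_renames_only(self):
        m = make_matrix([[1, 2], [3, 4]], genes=["p1", "p2"])
        pm = ProbeMap(gene_of={"p1": "GA", "p2": "GB"})
        out = collapse_probes(m, pm)
        assert list(out.gene_ids) == ["GA", "GB"]
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_highest_mean_probe_represents_gene(self):
        m = make_matrix([[5.0, 5.0], [7.0, 7.0]], genes=["p1", "p2"])
        pm = ProbeMap(gene_of={"p1": "G", "p2": "G"})
        out = collapse_probes(m, pm)
        np.testing.assert_array_equal(out.values.loc["G"], [7.0, 7.0])

    def test_tie_breaks_to_smaller_probe_id(self):
        m = make_matrix([[6.0, 6.0], [6.0, 6.0]], genes=["p2", "p1"])
        pm = ProbeMap(gene_of={"p1": "G", "p2": "G"})
        out = collapse_probes(m, pm)
        # equal means: p1 < p2 lexicographically, so p1's row is retained
        assert out.values.loc["G"].tolist() == m.values.loc["p1"].tolist()

    def test_gene_mean_equals_max_probe_mean(self, random_matrix):
        # property: each output gene's mean is the max of its probes' means
        genes = [f"G{i % 10}" for i in range(random_matrix.n_genes)]
        pm = ProbeMap(gene_of=dict(zip(random_matrix.gene_ids, genes)))
        out = collapse_probes(random_matrix, pm)
        probe_means = random_matrix.values.mean(axis=1)
        for gene in out.gene_ids:
            probes = [p for p, g in pm.gene_of.items() if g == gene]
            assert out.values.loc[gene].mean() == pytest.approx(probe_means[probes].max())

    def test_unmapped_probes_dropped_and_empty_map_errors(self):
        m = make_matrix([[1, 2], [3, 4]], genes=["p1", "p2"])
        out = collapse_probes(m, ProbeMap(gene_of={"p1": "GA"}))
        assert list(out.gene_ids) == ["GA"]
        with pytest.raises(ValueError, match="probe map"):
            collapse_probes(m, ProbeMap(gene_of={"px": "GA"}))

    def test_multi_gene_annotation_takes_first_gene(self):
        table = pd.DataFrame({"probe_id": ["p1"], "gene_id": ["GA /// GB"]})
        pm = ProbeMap.from_table(table)
        assert pm.gene_of["p1"] == "GA"


class TestMergeDatasets:
    def test_identical_gene_sets_concatenate(self):
        a = make_matrix(np.zeros((100, 10)), samples=[f"a{i}" for i in range(10)])
        b = make_matrix(np.ones((100, 10)), samples=[f"b{i}" for i in range(10)])
        a.sample_meta["dataset_id"] = "dsA"
        b.sample_meta["dataset_id"] = "dsB"
        merged = merge_datasets([a, b], min_genes=50)
        assert merged.values.shape == (100, 20)
        assert set(merged.sample_meta["batch"]) == {"dsA", "dsB"}

    def test_gene_intersection_in_first_matrix_order(self):
        a = make_matrix([[1, 1], [2, 2], [3, 3]], genes=["A", "B", "C"], samples=["s1", "s2"])
        b = make_matrix([[9, 9], [8, 8], [7, 7]], genes=["B", "C", "D"], samples=["t1", "t2"])
        merged = merge_datasets([a, b], min_genes=1)
        assert list(merged.gene_ids) == ["B", "C"]

    def test_discovery_shaped_trio_sample_count(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(600)]
        ms = []
        for name, n in [("dsA", 200), ("dsB", 30), ("dsC", 227)]:
            m = make_matrix(
                rng.normal(size=(600, n)), genes=genes, samples=[f"{name}_{i}" for i in range(n)]
            )
            m.sample_meta["dataset_id"] = name
            ms.append(m)
        merged = merge_datasets(ms)
        assert merged.n_samples == 457
        assert merged.sample_meta["batch"].nunique() == 3

    def test_duplicate_sample_ids_rejected(self):
        a = make_matrix(np.zeros((600, 2)))
        b = make_matrix(np.ones((600, 2)))
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_datasets([a, b])

    def test_small_intersection_errors_with_sizes(self):
        a = make_matrix(np.zeros((10, 2)), genes=[f"a{i}" for i in range(10)])
        b = make_matrix(np.zeros((10, 2)), genes=[f"b{i}" for i in range(10)],
                        samples=["t0", "t1"])
        with pytest.raises(ValueError, match="intersection"):
            merge_datasets([a, b], min_genes=5)


class TestScaleGenes:
    def test_mode_none_is_identity(self, random_matrix):
        out = scale_genes(random_matrix, ScalingSpec(mode="none"))
        np.testing.assert_array_equal(out.values.to_numpy(), random_matrix.values.to_numpy())

    def test_standard_closed_form(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        out = scale_genes(m, ScalingSpec(mode="standard"))
        np.testing.assert_allclose(out.values.to_numpy()[0], [-1.0, 0.0, 1.0])

    def test_standard_rows_mean0_sd1(self, random_matrix):
        out = scale_genes(random_matrix, ScalingSpec(mode="standard")).values
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_robust_maps_anchor_quantiles_to_unit_interval(self):
        # 1001 equally spaced values on [0,1]: the 0.025/0.975 quantiles are
        # exactly 0.025 and 0.975, which must map to -1 and +1
        row = np.linspace(0.0, 1.0, 1001)
        m = make_matrix(row[None, :])
        out = scale_genes(m, ScalingSpec(mode="robust")).values.to_numpy()[0]
        i_lo, i_hi = 25, 975
        assert out[i_lo] == pytest.approx(-1.0, abs=1e-12)
        assert out[i_hi] == pytest.approx(1.0, abs=1e-12)
        assert out.max() > 1.0  # no clipping beyond the anchors

    def test_scaling_commutes_with_gene_permutation(self, random_matrix):
        rng = np.random.default_rng(1)
        perm = rng.permutation(random_matrix.n_genes)
        permuted = ExpressionMatrix(random_matrix.values.iloc[perm])
        for mode in ("standard", "robust"):
            direct = scale_genes(permuted, ScalingSpec(mode=mode)).values
            via = scale_genes(random_matrix, ScalingSpec(mode=mode)).values.iloc[perm]
            pd.testing.assert_frame_equal(direct, via)

    def test_zero_sd_names_offending_gene(self):
        m = make_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], genes=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            scale_genes(m, ScalingSpec(mode="standard"))
        with pytest.raises(ValueError, match="flat"):
            scale_genes(m, ScalingSpec(mode="robust"))

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=40, unique=True),
        st.floats(0.01, 0.3),
    )
    @settings(max_examples=50, deadline=None)
    def test_robust_anchors_map_to_plus_minus_one(self, row, q_lo):
        # property: whatever the data, the q_lo/q_hi quantiles land on -1/+1
        q_hi = 1.0 - q_lo
        vals = np.asarray(row)
        m = make_matrix(vals[None, :])
        out = scale_genes(m, ScalingSpec(mode="robust", q_lo=q_lo, q_hi=q_hi)).values.to_numpy()[0]
        # invert with independently computed anchors: must recover the data
        lo, hi = np.quantile(vals, q_lo), np.quantile(vals, q_hi)
        np.testing.assert_allclose((out + 1) / 2 * (hi - lo) + lo, vals, rtol=1e-9, atol=1e-9)
        # monotonicity is preserved by the affine map (non-strict: float
        # rounding can collapse near-equal inputs)
        order = np.argsort(vals)
        assert (np.diff(out[order]) >= 0).all()

    def test_invalid_quantile_order_rejected(self):
        with pytest.raises(ValueError):
            ScalingSpec(mode="robust", q_lo=0.9, q_hi=0.1)
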