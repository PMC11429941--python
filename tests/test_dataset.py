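import numpy as np
import pandas as pd
import pytest

from velogrn.dataset import (
    TimeSeriesDataset,
    bin_pseudotime,
    load_dataset,
    log1p_transform,
    normalize_total_counts,
    read_dataset_dir,
    top_variance_genes,
    write_dataset,
)
from conftest import make_dataset


def _long_table():
    rows = []
    rng = np.random.default_rng(0)
    for t in (0, 1):
        for c in range(3):
            for g in range(4):
                rows.append(
                    {"gene": f"g{g}", "cell": f"c{t}{c}", "count": int(rng.poisson(4))}
                )
    meta = pd.DataFrame(
        {"cell_id": [f"c{t}{c}" for t in (0, 1) for c in range(3)],
         "time": [t for t in (0, 1) for _ in range(3)]}
    )
    return pd.DataFrame(rows), meta


class TestLoad:
    def test_long_table_grouping(self):
        long, meta = _long_table()
        ds = load_dataset(long, meta)
        assert ds.n_timepoints == 2
        assert ds.n_genes == 4
        assert ds.n_cells == [3, 3]
        assert list(ds.time_points) == [0.0, 1.0]

    def test_metadata_cell_absent_from_matrix(self):
        long, meta = _long_table()
        meta = pd.concat(
            [meta, pd.DataFrame([{"cell_id": "ghost", "time": 0}])], ignore_index=True
        )
        with pytest.raises(ValueError, match="ghost"):
            load_dataset(long, meta)

    def test_matrix_cell_without_time_label(self):
        long, meta = _long_table()
        meta = meta[meta.cell_id != "c01"]
        with pytest.raises(ValueError, match="c01"):
            load_dataset(long, meta)

    def test_permuted_gene_orders_canonicalised(self, tmp_path):
        rng = np.random.default_rng(1)
        genes = ["a", "b", "c"]
        X0 = pd.DataFrame(rng.poisson(4, (3, 2)), index=genes, columns=["c0", "c1"])
        X1 = pd.DataFrame(
            rng.poisson(4, (3, 2)), index=["c", "a", "b"], columns=["c2", "c3"]
        )
        X0.to_csv(tmp_path / "t0.tsv", sep="\t")
        X1.to_csv(tmp_path / "t1.tsv", sep="\t")
        meta = pd.DataFrame(
            {"cell_id": ["c0", "c1", "c2", "c3"], "time": [0, 0, 1, 1]}
        )
        ds = load_dataset([tmp_path / "t0.tsv", tmp_path / "t1.tsv"], meta)
        assert ds.gene_names == genes
        # column for cell c2 must match X1's, reordered to canonical genes
        np.testing.assert_array_equal(
            ds.expression[1][:, 0], X1.loc[genes, "c2"].to_numpy()
        )

    def test_inconsistent_gene_sets_rejected(self, tmp_path):
        X0 = pd.DataFrame([[1]], index=["a"], columns=["c0"])
        X1 = pd.DataFrame([[1]], index=["b"], columns=["c1"])
        X0.to_csv(tmp_path / "t0.tsv", sep="\t")
        X1.to_csv(tmp_path / "t1.tsv", sep="\t")
        meta = pd.DataFrame({"cell_id": ["c0", "c1"], "time": [0, 1]})
        with pytest.raises(ValueError, match=r"\['a', 'b'\]"):
            load_dataset([tmp_path / "t0.tsv", tmp_path / "t1.tsv"], meta)

    def test_single_time_point_rejected(self):
        long, meta = _long_table()
        meta["time"] = 0
        with pytest.raises(ValueError, match="2 time points"):
            load_dataset(long, meta)

    def test_non_numeric_time_labels_become_ranks(self):
        long, meta = _long_table()
        meta["time"] = np.where(meta["time"] == 0, "early", "late")
        ds = load_dataset(long, meta)
        assert list(ds.time_points) == [0.0, 1.0]


class TestInvariants:
    def test_decreasing_times_rejected(self):
        ds = make_dataset()
        with pytest.raises(ValueError, match="increasing"):
            TimeSeriesDataset(
                gene_names=ds.gene_names,
                time_points=[1.0, 0.0, 2.0],
                expression=ds.expression,
                cell_ids=ds.cell_ids,
            )

    def test_negative_counts_rejected(self):
        ds = make_dataset()
        ds.expression[0][0, 0] = -1
        with pytest.raises(ValueError, match="negative"):
            TimeSeriesDataset(
                gene_names=ds.gene_names,
                time_points=ds.time_points,
                expression=ds.expression,
                cell_ids=ds.cell_ids,
            )


class TestLog1p:
    def test_elementwise_values(self):
        ds = make_dataset(m=2, ns=(2, 2))
        ds.expression[0] = np.array([[0.0, 3.0], [7.0, 0.0]])
        out = log1p_transform(ds)
        np.testing.assert_allclose(
            out.expression[0], [[0.0, np.log(4)], [np.log(8), 0.0]]
        )
        assert out.transformed and not ds.transformed

    def test_maps_zero_to_zero_and_e_minus_1_to_one(self):
        ds = make_dataset(m=1, ns=(1, 1))
        ds.expression = [np.array([[0.0]]), np.array([[np.e - 1]])]
        out = log1p_transform(ds)
        np.testing.assert_allclose(out.expression[0], [[0.0]])
        np.testing.assert_allclose(out.expression[1], [[1.0]])

    def test_monotone(self, rng):
        x = np.sort(rng.random(50) * 10)
        assert np.all(np.diff(np.log1p(x)) >= 0)

    def test_double_transform_rejected(self):
        out = log1p_transform(make_dataset())
        with pytest.raises(ValueError, match="already"):
            log1p_transform(out)


class TestRoundTrip:
    def test_write_read_bit_exact(self, tmp_path):
        ds = log1p_transform(make_dataset(seed=3))
        write_dataset(ds, tmp_path / "d")
        back = read_dataset_dir(tmp_path / "d")
        assert back.gene_names == ds.gene_names
        assert back.transformed == ds.transformed
        np.testing.assert_array_equal(back.time_points, ds.time_points)
        for A, B in zip(back.expression, ds.expression):
            np.testing.assert_array_equal(A, B)
        assert back.cell_ids == ds.cell_ids


class TestBinPseudotime:
    def _with_pt(self, pt, ns=None):
        pt = np.asarray(pt, dtype=float)
        n = len(pt)
        ds = make_dataset(m=2, ns=(n - n // 2, n // 2))
        ds.pseudotime = [pt[: n - n // 2], pt[n - n // 2 :]]
        return ds

    def test_uniform_quantiles_exact_occupancy(self):
        ds = self._with_pt(np.arange(100) / 100)
        out = bin_pseudotime(ds, 5)
        assert out.n_cells == [20] * 5
        assert list(out.time_points) == [0.0, 1.0, 2.0, 3.0, 4.0]

    @pytest.mark.parametrize("k,n_per", [(2, 10), (4, 5), (5, 4)])
    def test_uniform_spacing_property(self, k, n_per):
        ds = self._with_pt(np.linspace(0, 1, k * n_per))
        out = bin_pseudotime(ds, k)
        assert out.n_cells == [n_per] * k

    def test_single_bin_rejected_as_degenerate(self):
        ds = self._with_pt(np.arange(10) / 10)
        with pytest.raises(ValueError, match="2 time points"):
            bin_pseudotime(ds, 1)

    def test_ties_at_edge_go_to_lower_bin(self):
        ds = self._with_pt([0.0, 1.0, 1.0, 2.0])
        out = bin_pseudotime(ds, 2)
        # median is exactly 1.0; both ties belong to the lower bin
        assert out.n_cells == [3, 1]

    def test_fewer_distinct_values_than_bins_rejected(self):
        ds = self._with_pt([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="distinct"):
            bin_pseudotime(ds, 3)


class TestMTX:
    def test_sparse_matrix_market_input(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(3, 4)).astype(float)
        mmwrite(tmp_path / "m.mtx", csr_matrix(X))
        (tmp_path / "m.rows.txt").write_text("ga gb gc")
        (tmp_path / "m.cols.txt").write_text("c0 c1 c2 c3")
        meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(4)],
                             "time": [0, 0, 1, 1]})
        ds = load_dataset([tmp_path / "m.mtx"], meta)
        assert ds.gene_names == ["ga", "gb", "gc"]
        np.testing.assert_array_equal(
            np.concatenate(ds.expression, axis=1), X
        )


class TestOptionalPreprocessing:
    def test_total_count_normalization_equalises_cell_totals(self):
        ds = make_dataset(seed=5)
        out = normalize_total_counts(ds, target_sum=100.0)
        for X in out.expression:
            np.testing.assert_allclose(X.sum(axis=0), 100.0)

    def test_top_variance_filter_keeps_k_most_variable(self):
        ds = make_dataset(m=6, seed=7)
        ds.expression[0][2, :] += np.arange(ds.expression[0].shape[1]) * 50.0
        out = top_variance_genes(ds, 2)
        assert out.n_genes == 2
        assert "g2" in out.gene_names
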