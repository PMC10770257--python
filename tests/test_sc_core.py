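import numpy as np
import pandas as pd
import pytest

from bomscope import sc_core
from bomscope.bulk_de import GenePanel
from bomscope.sc_core import (
    MarkerConfig,
    dot_profile,
    find_markers,
    lognormalize,
    panel_marker_overlap,
    read_counts,
    write_counts_mtx,
)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(11)
    return pd.DataFrame(
        rng.poisson(3, size=(6, 10)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"c{i}" for i in range(10)],
    )


class TestReadCounts:
    def test_mtx_roundtrip(self, toy_counts, tmp_path):
        write_counts_mtx(toy_counts, tmp_path)
        back = read_counts(tmp_path, "mtx_triplet")
        pd.testing.assert_frame_equal(back, toy_counts.astype(np.int64))

    def test_tsv_roundtrip(self, toy_counts, tmp_path):
        toy_counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        back = read_counts(tmp_path / "counts.tsv", "tsv")
        pd.testing.assert_frame_equal(back, toy_counts.astype(np.int64))

    def test_dimension_mismatch_raises(self, toy_counts, tmp_path):
        write_counts_mtx(toy_counts, tmp_path)
        genes = (tmp_path / "genes.tsv").read_text()
        (tmp_path / "genes.tsv").write_text(genes + "extra_gene\n")
        with pytest.raises(ValueError, match="gene names"):
            read_counts(tmp_path, "mtx_triplet")

    def test_zero_cells_raises(self, tmp_path):
        empty = pd.DataFrame(index=["g1", "g2"])
        empty.to_csv(tmp_path / "empty.tsv", sep="\t")
        with pytest.raises(ValueError, match="0 cells"):
            read_counts(tmp_path / "empty.tsv", "tsv")

    def test_duplicate_genes_suffixed(self, toy_counts, tmp_path):
        dup = toy_counts.copy()
        dup.index = ["g0", "g0", "g1", "g2", "g3", "g4"]
        write_counts_mtx(dup, tmp_path)
        back = read_counts(tmp_path, "mtx_triplet")
        assert back.index.is_unique
        assert "g0.1" in back.index

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            read_counts(tmp_path, "h5")


class TestLognormalize:
    def test_hand_computed_values(self):
        counts = pd.DataFrame({"c1": [10, 0]}, index=["g1", "g2"])
        expr = lognormalize(counts)
        assert expr.values.loc["g1", "c1"] == pytest.approx(np.log(10001), abs=1e-9)
        assert expr.values.loc["g2", "c1"] == 0.0

    def test_all_zero_gene_stays_zero(self, toy_counts):
        counts = toy_counts.copy()
        counts.loc["g3"] = 0
        expr = lognormalize(counts)
        assert (expr.values.loc["g3"] == 0).all()

    def test_cell_scaling_invariance(self, toy_counts):
        doubled = toy_counts.copy()
        doubled["c1"] = doubled["c1"] * 2
        a = lognormalize(toy_counts).values["c1"]
        b = lognormalize(doubled).values["c1"]
        assert np.allclose(a, b)

    def test_zero_total_cell_dropped(self, toy_counts, caplog):
        counts = toy_counts.copy()
        counts["c5"] = 0
        expr = lognormalize(counts)
        assert "c5" not in expr.cells
        assert any("zero-total" in r.message for r in caplog.records)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"c1": [1, -2]})
        with pytest.raises(ValueError, match="nonnegative"):
            lognormalize(counts)


def _cell_table(subgroups, conditions=None):
    n = len(subgroups)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": "s1",
            "sample_type": conditions or ["BoM"] * n,
            "condition": conditions or ["BoM"] * n,
            "subgroup": subgroups,
        }
    ).set_index("cell_id")


class TestDotProfile:
    def test_z_scores_of_three_groups(self):
        # means 1, 2, 3 across groups -> z = -1, 0, 1 (sample SD = 1)
        counts = pd.DataFrame(
            [[1, 2, 3]], index=["g"], columns=["c0", "c1", "c2"], dtype=int
        )
        expr = sc_core.ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["c0", "c1", "c2"]),
            norm="lognorm",
        )
        cells = _cell_table(["a", "b", "c"])
        prof = dot_profile(expr, counts, cells, ["g"]).set_index("subgroup")
        assert prof.loc["a", "z_expr"] == pytest.approx(-1.0)
        assert prof.loc["b", "z_expr"] == pytest.approx(0.0)
        assert prof.loc["c", "z_expr"] == pytest.approx(1.0)

    def test_zero_variance_gene_gets_zero_z(self):
        counts = pd.DataFrame([[2, 2, 2]], index=["g"], columns=["c0", "c1", "c2"])
        expr = sc_core.ExpressionMatrix(
            values=pd.DataFrame([[1.0, 1.0, 1.0]], index=["g"], columns=["c0", "c1", "c2"]),
            norm="lognorm",
        )
        prof = dot_profile(expr, counts, _cell_table(["a", "b", "c"]), ["g"])
        assert (prof["z_expr"] == 0).all()

    def test_pos_ratio(self):
        counts = pd.DataFrame([[0, 0, 0, 3, 5]], index=["g"], columns=[f"c{i}" for i in range(5)])
        expr = lognormalize(counts + 0)  # keep zero-total cells out of the way
        counts2 = counts.copy()
        counts2.loc["pad"] = 1  # avoid zero-total cells
        expr = lognormalize(counts2)
        prof = dot_profile(expr, counts2, _cell_table(["a"] * 5), ["g"])
        assert prof["pos_ratio"].iloc[0] == pytest.approx(0.4)

    def test_unknown_gene_skipped(self, caplog):
        counts = pd.DataFrame([[1, 2]], index=["g"], columns=["c0", "c1"])
        expr = lognormalize(counts)
        prof = dot_profile(expr, counts, _cell_table(["a", "b"]), ["g", "nope"])
        assert set(prof["gene"]) == {"g"}
        assert any("unknown genes" in r.message for r in caplog.records)

    def test_z_rows_standardized(self, breast_fixture, breast_expr):
        counts, cells, _ = breast_fixture
        genes = list(counts.index[:25])
        prof = dot_profile(breast_expr, counts, cells, genes)
        for gene, sub in prof.groupby("gene"):
            z = sub["z_expr"].to_numpy()
            if np.allclose(z, 0):
                continue
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestFindMarkers:
    def test_perfectly_separated_gene_is_marker(self):
        rng = np.random.default_rng(2)
        n_in, n_rest = 50, 500
        counts = pd.DataFrame(
            rng.poisson(2, size=(5, n_in + n_rest)) + 1,
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(n_in + n_rest)],
        )
        counts.loc["g0"] = np.concatenate([np.full(n_in, 50), np.zeros(n_rest, int)])
        cells = _cell_table(["s"] * n_in + ["rest"] * n_rest)
        expr = lognormalize(counts)
        markers = find_markers(expr, counts, cells)
        hit = markers[(markers["gene"] == "g0") & markers["is_marker"]]
        assert set(hit["subgroup"]) == {"s"}

    def test_exchangeable_gene_not_marker(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.poisson(5, size=(4, 200)),
            index=[f"g{i}" for i in range(4)],
            columns=[f"c{i}" for i in range(200)],
        )
        cells = _cell_table(["a"] * 100 + ["b"] * 100)
        markers = find_markers(lognormalize(counts), counts, cells)
        assert not markers["is_marker"].any()

    def test_planted_marker_recovery(self, breast_fixture, breast_expr):
        counts, cells, truth = breast_fixture
        markers = find_markers(breast_expr, counts, cells)
        called = {(r.subgroup, r.gene) for r in markers.loc[markers["is_marker"]].itertuples()}
        planted_genes = {g for gs in truth.planted_markers.values() for g in gs}
        for sg, genes in truth.planted_markers.items():
            for g in genes:
                assert (sg, g) in called
        wrong = {
            (sg, g)
            for sg, g in called
            if g in planted_genes and g not in truth.planted_markers.get(sg, ())
        }
        assert wrong == set()

    def test_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(
            rng.poisson(4, size=(8, 120)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"c{i}" for i in range(120)],
        )
        counts.iloc[0, :60] += 8
        cells = _cell_table(["a"] * 60 + ["b"] * 60)
        expr = lognormalize(counts)
        base = find_markers(expr, counts, cells)

        perm = rng.permutation(counts.columns)
        counts_p = counts[perm]
        expr_p = lognormalize(counts_p)
        cells_p = cells.loc[perm]
        permuted = find_markers(expr_p, counts_p, cells_p)
        pd.testing.assert_frame_equal(base, permuted)

    def test_single_subgroup_rejected(self):
        counts = pd.DataFrame([[1, 2, 3]], index=["g"], columns=["c0", "c1", "c2"])
        with pytest.raises(ValueError, match="2 subgroups"):
            find_markers(lognormalize(counts), counts, _cell_table(["a"] * 3))

    def test_tiny_subgroup_excluded(self, caplog):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.poisson(4, size=(3, 52)),
            index=[f"g{i}" for i in range(3)],
            columns=[f"c{i}" for i in range(52)],
        )
        cells = _cell_table(["a"] * 25 + ["b"] * 25 + ["tiny"] * 2)
        markers = find_markers(lognormalize(counts), counts, cells, MarkerConfig())
        assert "tiny" not in set(markers["subgroup"])
        assert any("excluded" in r.message for r in caplog.records)


class TestPanelMarkerOverlap:
    @staticmethod
    def _markers(rows):
        return pd.DataFrame(rows, columns=["subgroup", "gene", "is_marker"])

    def test_disjoint_panel_empty_sets(self):
        markers = self._markers([("a", "g1", True), ("b", "g2", True)])
        panel = GenePanel(genes=("x", "y"))
        overlap = panel_marker_overlap(panel, markers)
        assert all(v == [] for v in overlap.values())

    def test_panel_equals_markers(self):
        markers = self._markers([("a", "g1", True), ("a", "g2", True), ("b", "g3", True)])
        panel = GenePanel(genes=("g1", "g2"))
        assert panel_marker_overlap(panel, markers)["a"] == ["g1", "g2"]

    def test_fixture_overlap_matches_truth_sets(self, breast_fixture, breast_expr):
        counts, cells, truth = breast_fixture
        markers = find_markers(breast_expr, counts, cells)
        # panel = a slice of planted markers plus decoys absent from markers
        some = [gs[0] for gs in truth.planted_markers.values()]
        panel = GenePanel(genes=tuple(sorted(some + ["ZZZ1"])))
        overlap = panel_marker_overlap(panel, markers)
        for sg, genes in truth.planted_markers.items():
            expected = sorted(set(panel) & set(genes))
            assert [g for g in overlap.get(sg, []) if g in set(genes)] == expected
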