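import itertools

import numpy as np
import pandas as pd
import pytest

from bomscope import bom_screen, sc_core
from bomscope import synthetic_data as syn
from bomscope.bom_screen import (
    ScreenConfig,
    pairwise_condition_test,
    ranksum_rows,
    screen_condition_genes,
    wilcoxon_rank_sum,
)


def exact_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    w_obs = sum(ranks[v] for v in x)
    mu = n * (N + 1) / 2
    dev = abs(w_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        w = sum(ranks[pooled[i]] for i in combo)
        total += 1
        hits += abs(w - mu) >= dev - 1e-9
    return hits / total


class TestWilcoxonRankSum:
    def test_printed_case_3v3(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]).pvalue == pytest.approx(0.1, abs=1e-12)

    def test_printed_case_4v4(self):
        p = wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8]).pvalue
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5]).pvalue == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n,m", [(1, 3), (2, 2), (3, 3), (2, 6), (4, 4), (5, 5),
                                     (3, 8), (7, 7), (8, 8), (1, 15), (6, 10)])
    def test_matches_enumeration_oracle_no_ties(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            got = wilcoxon_rank_sum(x, y).pvalue
            assert got == pytest.approx(exact_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tied_inputs_match_permutation_estimate(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, size=25).astype(float)
        y = rng.integers(0, 4, size=30).astype(float)
        got = wilcoxon_rank_sum(x, y).pvalue

        pooled = np.concatenate([x, y])
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        w_obs = ranks[: len(x)].sum()
        mu = len(x) * (len(pooled) + 1) / 2
        dev = abs(w_obs - mu)
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pooled))
            hits += abs(ranks[perm[: len(x)]].sum() - mu) >= dev - 1e-9
        est = hits / n_perm
        se = np.sqrt(max(est * (1 - est), 1e-6) / n_perm)
        assert abs(got - est) <= 3 * se + 0.01

    def test_rows_helper_matches_scalar(self):
        rng = np.random.default_rng(3)
        values = np.round(rng.normal(size=(40, 50)), 1)  # rounding induces ties
        mask = np.zeros(50, dtype=bool)
        mask[:20] = True
        _, p_rows = ranksum_rows(values, mask)
        for i in range(40):
            assert p_rows[i] == pytest.approx(
                wilcoxon_rank_sum(values[i, mask], values[i, ~mask]).pvalue, abs=1e-12
            )


class TestScreenConditionGenes:
    def test_null_up_rate_near_half_alpha(self):
        counts, cells, _ = syn.simulate_sc(
            syn.null_sc_config(seed=3, n_genes=2000, n_cells_per_sample=100)
        )
        expr = sc_core.lognormalize(counts)
        scr = screen_condition_genes(expr, counts, cells, "all")
        frac = scr["up_in_bom"].mean()
        assert 0.01 <= frac <= 0.045

    def test_planted_recovery_recall_and_precision(self, condition_fixture):
        counts, cells, truth = condition_fixture
        expr = sc_core.lognormalize(counts)
        scr = screen_condition_genes(expr, counts, cells, "fibroblast")
        up = set(scr.loc[scr["up_in_bom"], "gene"])
        planted = set(truth.planted_condition_up["fibroblast"])
        assert planted <= up  # recall 1.0
        assert len(up & planted) / len(up) >= 0.9

    def test_low_ratio_gene_excluded(self):
        rng = np.random.default_rng(0)
        n_cells = 100
        counts = pd.DataFrame(
            rng.poisson(5, size=(3, n_cells)),
            index=["g_ok", "g_sparse", "g2"],
            columns=[f"c{i}" for i in range(n_cells)],
        )
        sparse_row = np.zeros(n_cells, int)
        sparse_row[:5] = 50  # 5% of cells, huge values
        counts.loc["g_sparse"] = sparse_row
        cells = pd.DataFrame(
            {
                "cell_id": counts.columns,
                "sample_id": "s",
                "sample_type": ["BoM"] * 50 + ["Other"] * 50,
                "condition": ["BoM"] * 50 + ["Other"] * 50,
                "subgroup": "sg",
            }
        ).set_index("cell_id")
        expr = sc_core.lognormalize(counts)
        scr = screen_condition_genes(expr, counts, cells, "sg")
        assert "g_sparse" not in set(scr["gene"])

    def test_monotone_in_thresholds(self, condition_fixture):
        counts, cells, _ = condition_fixture
        expr = sc_core.lognormalize(counts)
        loose = screen_condition_genes(
            expr, counts, cells, "fibroblast", ScreenConfig(alpha=0.05, min_ratio=0.10)
        )
        tight = screen_condition_genes(
            expr, counts, cells, "fibroblast", ScreenConfig(alpha=0.01, min_ratio=0.20)
        )
        up_loose = set(loose.loc[loose["up_in_bom"], "gene"])
        up_tight = set(tight.loc[tight["up_in_bom"], "gene"])
        assert up_tight <= up_loose

    def test_label_swap_inverts_delta_and_preserves_p(self, condition_fixture):
        counts, cells, _ = condition_fixture
        expr = sc_core.lognormalize(counts)
        fwd = screen_condition_genes(expr, counts, cells, "fibroblast")
        swapped = cells.copy()
        swapped["condition"] = np.where(swapped["condition"] == "BoM", "Other", "BoM")
        rev = screen_condition_genes(expr, counts, swapped, "fibroblast")
        fwd = fwd.set_index("gene").sort_index()
        rev = rev.set_index("gene").sort_index()
        assert np.allclose(fwd["delta_mean"], -rev["delta_mean"])
        assert np.allclose(fwd["p_raw"], rev["p_raw"])

    def test_missing_condition_gives_empty_with_reason(self, condition_fixture):
        counts, cells, _ = condition_fixture
        expr = sc_core.lognormalize(counts)
        only_bom = cells.loc[cells["condition"] == "BoM"]
        scr = screen_condition_genes(expr, counts, only_bom, "fibroblast")
        assert scr.empty
        assert "lacks a testable condition split" in scr.attrs["reason"]

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            ScreenConfig(alpha=1.5).validate()
        with pytest.raises(ValueError, match="min_ratio"):
            ScreenConfig(min_ratio=1.0).validate()


class TestPairwiseConditionTest:
    @staticmethod
    def _toy(levels_per_cell):
        n = len(levels_per_cell)
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(10, size=(2, n)), index=["g1", "g2"], columns=[f"c{i}" for i in range(n)]
        )
        cells = pd.DataFrame(
            {
                "cell_id": counts.columns,
                "sample_id": "s",
                "sample_type": levels_per_cell,
                "condition": "BoM",
                "subgroup": "sg",
            }
        ).set_index("cell_id")
        return counts, cells

    def test_two_levels_no_correction(self):
        counts, cells = self._toy(["A"] * 10 + ["B"] * 10)
        expr = sc_core.lognormalize(counts)
        out = pairwise_condition_test(expr, cells, "sg", "g1")
        assert len(out) == 1
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_three_levels_bonferroni_k3(self):
        counts, cells = self._toy(["A"] * 8 + ["B"] * 8 + ["C"] * 8)
        expr = sc_core.lognormalize(counts)
        out = pairwise_condition_test(expr, cells, "sg", "g1")
        assert len(out) == 3
        assert np.allclose(out["p_adj"], np.minimum(1.0, out["p_raw"] * 3))

    def test_p_adj_capped_at_one(self):
        counts, cells = self._toy(["A"] * 5 + ["B"] * 5 + ["C"] * 5 + ["D"] * 5)
        counts.loc["g1"] = 7  # constant -> p = 1 everywhere
        expr = sc_core.lognormalize(counts)
        out = pairwise_condition_test(expr, cells, "sg", "g1")
        assert (out["p_adj"] <= 1.0).all()
        assert (out.loc[out["status"] == "tested", "stars"] == "ns").all()

    def test_small_level_skipped(self):
        counts, cells = self._toy(["A"] * 10 + ["B"] * 10 + ["C"])
        expr = sc_core.lognormalize(counts)
        out = pairwise_condition_test(expr, cells, "sg", "g1")
        skipped = out.loc[out["status"] == "skipped"]
        assert len(skipped) == 2
        assert all("C" in pair for pair in zip(skipped["level_a"], skipped["level_b"]))
        # Bonferroni k counts only tested pairs
        tested = out.loc[out["status"] == "tested"]
        assert np.allclose(tested["p_adj"], np.minimum(1.0, tested["p_raw"] * len(tested)))

    def test_single_level_rejected(self):
        counts, cells = self._toy(["A"] * 10)
        expr = sc_core.lognormalize(counts)
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            pairwise_condition_test(expr, cells, "sg", "g1")
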