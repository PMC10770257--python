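"""Condition-stratified upregulation screens.

Implements the Wilcoxon rank-sum primitive (exact enumeration for small
untied inputs, tie/continuity-corrected normal approximation otherwise),
the per-subgroup BoM-vs-Other gene screen with the >10%-expressing
pre-filter, and multi-level pairwise sample-type comparisons with
Bonferroni correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 16


class RankSumResult(NamedTuple):
    statistic: float  # rank sum of x in the pooled ordering
    pvalue: float


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds shared by the condition screens.

    ``adjustment`` applies to the per-subgroup screen; the multi-level
    pairwise test always uses Bonferroni across the level pairs it runs.
    """

    alpha: float = 0.05
    min_ratio: float = 0.10
    adjustment: str = "none"  # none | bh | bonferroni
    high_corr_threshold: float = 0.2
    bom_label: str = "BoM"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha out of range (0,1): {self.alpha}")
        if not (0.0 <= self.min_ratio < 1.0):
            raise ValueError(f"min_ratio out of range [0,1): {self.min_ratio}")
        if self.adjustment not in ("none", "bh", "bonferroni"):
            raise ValueError(f"unknown adjustment: {self.adjustment!r}")

    def with_overrides(self, **kwargs) -> "ScreenConfig":
        return replace(self, **kwargs)


def _ranksum_null_counts(n: int, N: int) -> np.ndarray:
    """Counts of subsets of size n from ranks 1..N by rank sum (index = sum)."""
    max_sum = n * N
    dp = np.zeros((n + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return dp[n]


def _exact_two_sided_p(n: int, N: int, w: float) -> float:
    counts = _ranksum_null_counts(n, N)
    mu = n * (N + 1) / 2.0
    dev = abs(w - mu)
    sums = np.arange(counts.size)
    tail = counts[np.abs(sums - mu) >= dev - 1e-9].sum()
    return float(min(1.0, tail / counts.sum()))


def _tie_sum(values: np.ndarray) -> float:
    _, t = np.unique(values, return_counts=True)
    return float((t.astype(float) ** 3 - t).sum())


def _approx_two_sided_p(w: float, n: int, m: int, tie_sum: float) -> float:
    N = n + m
    u = w - n * (n + 1) / 2.0
    mu = n * m / 2.0
    sigma2 = n * m / 12.0 * ((N + 1) - tie_sum / (N * (N - 1)))
    if sigma2 <= 0:
        return 1.0
    diff = u - mu
    if diff == 0:
        return 1.0
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    Exact enumeration of the rank-sum null when ``len(x)+len(y) <= 16``
    and the pooled values are tie-free; otherwise a normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty vectors")
    n, m = x.size, y.size
    N = n + m
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n].sum())
    has_ties = np.unique(pooled).size < N
    if N <= _EXACT_MAX_N and not has_ties:
        p = _exact_two_sided_p(n, N, w)
    else:
        p = _approx_two_sided_p(w, n, m, _tie_sum(pooled))
    return RankSumResult(w, p)


def ranksum_rows(values: np.ndarray, in_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rank-sum tests of ``values[:, in_mask]`` vs the rest.

    Matches :func:`wilcoxon_rank_sum` exactly: the exact branch is used per
    row when the total sample is small and untied, the corrected normal
    approximation otherwise. Returns (rank-sum statistics, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    in_mask = np.asarray(in_mask, dtype=bool)
    n = int(in_mask.sum())
    m = int((~in_mask).sum())
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    N = n + m
    ranks = sps.rankdata(values, axis=1)
    w = ranks[:, in_mask].sum(axis=1)
    pvals = np.empty(values.shape[0])
    if N <= _EXACT_MAX_N:
        for i in range(values.shape[0]):
            if np.unique(values[i]).size == N:
                pvals[i] = _exact_two_sided_p(n, N, w[i])
            else:
                pvals[i] = _approx_two_sided_p(w[i], n, m, _tie_sum(values[i]))
    else:
        for i in range(values.shape[0]):
            pvals[i] = _approx_two_sided_p(w[i], n, m, _tie_sum(values[i]))
    return w, pvals


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    from .bulk_de import bh_adjust

    if method == "none":
        return np.asarray(p, dtype=float).copy()
    if method == "bh":
        return bh_adjust(p)
    if method == "bonferroni":
        return np.minimum(1.0, np.asarray(p, dtype=float) * p.size)
    raise ValueError(f"unknown adjustment: {method!r}")


def screen_condition_genes(
    expr,
    counts: pd.DataFrame,
    cell_table: pd.DataFrame,
    subgroup: str,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """BoM-vs-Other upregulation screen within one subgroup.

    Cells of ``subgroup`` are split by condition (``cfg.bom_label`` vs all
    others). Genes expressed (raw count > 0) in more than ``cfg.min_ratio``
    of the subgroup's cells are tested with a two-sided rank-sum on
    log-normalized values; ``up_in_bom`` requires the (optionally adjusted)
    p below alpha, positive mean difference, and a BoM-side positive ratio
    above ``min_ratio``. Rows are ordered by raw p then gene id.
    """
    cfg = cfg or ScreenConfig()
    cfg.validate()
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "norm") else expr
    sub = cell_table.loc[cell_table["subgroup"] == subgroup]
    if sub.empty:
        raise ValueError(f"subgroup {subgroup!r} has no cells")
    bom_cells = sub.index[sub["condition"] == cfg.bom_label]
    other_cells = sub.index[sub["condition"] != cfg.bom_label]

    columns = [
        "subgroup", "gene", "n_bom", "n_other", "pos_ratio_bom",
        "pos_ratio_other", "delta_mean", "p_raw", "p_adj", "up_in_bom",
    ]
    if len(bom_cells) < 3 or len(other_cells) < 3:
        reason = (
            f"subgroup {subgroup!r} lacks a testable condition split: "
            f"{len(bom_cells)} {cfg.bom_label} vs {len(other_cells)} other cells"
        )
        logger.warning(reason)
        out = pd.DataFrame(columns=columns)
        out.attrs["reason"] = reason
        return out

    sub_counts = counts.loc[:, sub.index]
    pos_ratio_all = (sub_counts.to_numpy() > 0).mean(axis=1)
    tested = pos_ratio_all > cfg.min_ratio
    genes = counts.index[tested]

    vals = values.loc[genes, sub.index]
    in_mask = sub["condition"].to_numpy() == cfg.bom_label
    _, p_raw = ranksum_rows(vals.to_numpy(), in_mask)
    mean_bom = vals.loc[:, bom_cells].to_numpy().mean(axis=1)
    mean_other = vals.loc[:, other_cells].to_numpy().mean(axis=1)
    ratio_bom = (counts.loc[genes, bom_cells].to_numpy() > 0).mean(axis=1)
    ratio_other = (counts.loc[genes, other_cells].to_numpy() > 0).mean(axis=1)
    p_adj = _adjust(p_raw, cfg.adjustment)
    delta = mean_bom - mean_other
    up = (p_adj < cfg.alpha) & (delta > 0) & (ratio_bom > cfg.min_ratio)

    out = pd.DataFrame(
        {
            "subgroup": subgroup,
            "gene": genes,
            "n_bom": len(bom_cells),
            "n_other": len(other_cells),
            "pos_ratio_bom": ratio_bom,
            "pos_ratio_other": ratio_other,
            "delta_mean": delta,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "up_in_bom": up,
        }
    )
    out = out.sort_values(["p_raw", "gene"], kind="mergesort").reset_index(drop=True)
    return out[columns]


_STAR_CUTS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p_adj: float) -> str:
    for cut, mark in _STAR_CUTS:
        if p_adj < cut:
            return mark
    return "ns"


def pairwise_condition_test(
    expr,
    cell_table: pd.DataFrame,
    subgroup: str,
    gene: str,
    levels: Sequence[str] | None = None,
    level_col: str = "sample_type",
) -> pd.DataFrame:
    """All unordered pairwise rank-sum tests of one gene across sample types.

    Bonferroni-corrects over the number of pairs actually tested; level
    pairs with a side below 2 cells are skipped and reported with
    status ``skipped``.
    """
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "norm") else expr
    sub = cell_table.loc[cell_table["subgroup"] == subgroup]
    if gene not in values.index:
        raise KeyError(f"gene {gene!r} not found")
    present = [lv for lv in (levels or sorted(sub[level_col].unique())) if (sub[level_col] == lv).any()]
    if len(present) < 2:
        raise ValueError(f"subgroup {subgroup!r} has fewer than 2 levels of {level_col!r}")

    by_level = {lv: values.loc[gene, sub.index[sub[level_col] == lv]].to_numpy() for lv in present}
    rows = []
    for a, b in itertools.combinations(present, 2):
        xa, xb = by_level[a], by_level[b]
        if xa.size < 2 or xb.size < 2:
            logger.warning("pair (%s, %s) skipped: a level has < 2 cells", a, b)
            rows.append((a, b, xa.size, xb.size, np.nan, np.nan, "skipped"))
            continue
        stat, p = wilcoxon_rank_sum(xa, xb)
        rows.append((a, b, xa.size, xb.size, stat, p, "tested"))
    out = pd.DataFrame(
        rows, columns=["level_a", "level_b", "n_a", "n_b", "statistic", "p_raw", "status"]
    )
    k = int((out["status"] == "tested").sum())
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * max(k, 1))
    out["stars"] = [
        _stars(pa) if st == "tested" else "ns" for pa, st in zip(out["p_adj"], out["status"])
    ]
    return out
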