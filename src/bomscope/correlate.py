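"""Pearson correlation validation within subgroups and across bulk groups."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

EMT_PANEL = ("CDH1", "CDH2", "VIM", "SNAI2", "TWIST1", "CTNNB1")

RESULT_COLUMNS = ["context", "gene_a", "gene_b", "n", "r", "p", "high_corr", "status"]


class PearsonResult(NamedTuple):
    r: float
    p: float


@dataclass(frozen=True)
class CorrConfig:
    alpha: float = 0.05
    high_corr_threshold: float = 0.2
    expressing_only: bool = False  # restrict to cells with raw count > 0 in both genes


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Sample Pearson correlation with the two-sided t-test p-value.

    ``t = r * sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of freedom; r is
    clamped to [-1, 1] against rounding. Raises on zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson requires at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    r = float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return PearsonResult(r, 0.0)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2)))
    return PearsonResult(r, p)


def _pair_rows(
    context: str,
    values: pd.DataFrame,
    raw: pd.DataFrame | None,
    anchors: Sequence[str],
    targets: Sequence[str],
    cfg: CorrConfig,
) -> list[tuple]:
    rows = []
    known = set(values.index)
    for gene in list(anchors) + list(targets):
        if gene not in known:
            logger.warning("gene %r absent from %s; skipped", gene, context)
    for a in anchors:
        if a not in known:
            continue
        for b in targets:
            if b not in known or a == b:
                continue
            x = values.loc[a].to_numpy()
            y = values.loc[b].to_numpy()
            if cfg.expressing_only and raw is not None:
                keep = (raw.loc[a].to_numpy() > 0) & (raw.loc[b].to_numpy() > 0)
                x, y = x[keep], y[keep]
            n = x.size
            try:
                r, p = pearson(x, y)
                high = bool(r > cfg.high_corr_threshold and p < cfg.alpha)
                rows.append((context, a, b, n, r, p, high, "ok"))
            except ValueError as exc:
                rows.append((context, a, b, n, np.nan, np.nan, False, str(exc)))
    return rows


def subgroup_gene_correlations(
    expr,
    cell_table: pd.DataFrame,
    subgroup: str,
    anchor_genes: Sequence[str],
    target_genes: Sequence[str],
    cfg: CorrConfig | None = None,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Anchor-vs-target Pearson correlations on one subgroup's cells.

    Works on log-normalized values; anchor == target pairs are skipped;
    ``high_corr`` flags r above the threshold with p below alpha.
    Zero-variance pairs are reported with an explicit status.
    """
    cfg = cfg or CorrConfig()
    values = expr.values if hasattr(expr, "values") and hasattr(expr, "norm") else expr
    cells = cell_table.index[cell_table["subgroup"] == subgroup].intersection(values.columns)
    if len(cells) < 3:
        raise ValueError(f"subgroup {subgroup!r} has fewer than 3 cells")
    sub_values = values.loc[:, cells]
    sub_raw = counts.loc[:, cells] if counts is not None else None
    rows = _pair_rows(subgroup, sub_values, sub_raw, anchor_genes, target_genes, cfg)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def bulk_panel_correlations(
    bulk_expr_by_group: Mapping[str, pd.DataFrame],
    anchors: Sequence[str],
    targets: Sequence[str],
    cfg: CorrConfig | None = None,
) -> pd.DataFrame:
    """Per-group anchor-vs-target correlations on z-scored bulk expression.

    Genes are z-scored across each group's samples before correlating;
    Pearson r is invariant to this per-gene standardization, it is kept so
    emitted values match z-scored downstream consumers. Groups with fewer
    than 3 samples are skipped with a logged reason.
    """
    cfg = cfg or CorrConfig()
    frames = []
    for label in sorted(bulk_expr_by_group):
        table = bulk_expr_by_group[label]
        if table.shape[1] < 3:
            logger.warning("group %r skipped: only %d samples", label, table.shape[1])
            continue
        mat = table.to_numpy(dtype=float)
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            zmat = np.where(sd > 0, (mat - mu) / sd, 0.0)
        zdf = pd.DataFrame(zmat, index=table.index, columns=table.columns)
        frames.append(pd.DataFrame(_pair_rows(label, zdf, None, anchors, targets, cfg),
                                   columns=RESULT_COLUMNS))
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def correlation_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format results to an anchor x target matrix of r values."""
    return results.pivot_table(index="gene_a", columns="gene_b", values="r", aggfunc="first")
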