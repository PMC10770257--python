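"""Single-cell I/O, log-normalization, dot-profiles, and marker detection.

Counts are genes x cells integer tables; annotations travel in a cell
table indexed by cell id with ``sample_id``, ``sample_type``,
``condition`` and ``subgroup`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .bulk_de import bh_adjust
from .bom_screen import ranksum_rows

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 1e4
LNFC_PSEUDO = 1e-9

CELL_TABLE_COLUMNS = ("sample_id", "sample_type", "condition", "subgroup")


@dataclass
class ExpressionMatrix:
    """Genes x cells real-valued matrix with a normalization tag."""

    values: pd.DataFrame
    norm: str = "raw"  # raw | lognorm
    scale: float = DEFAULT_SCALE

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class MarkerConfig:
    alpha: float = 0.05
    min_lnfc: float = 0.25
    min_ratio: float = 0.10
    min_cells: int = 3


def _dedupe(names: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            logger.warning("duplicate %s id %r renamed to %r", what, name, new)
            out.append(new)
            seen[new] = 0
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_counts(path: str | Path, format: str = "mtx_triplet") -> pd.DataFrame:
    """Read a genes x cells integer count matrix.

    ``mtx_triplet`` expects a directory with ``matrix.mtx`` (genes as
    rows), ``genes.tsv`` and ``barcodes.tsv``; ``tsv`` expects a single
    table with gene ids in the first column. Duplicate gene symbols are
    disambiguated by suffixing.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mat = spio.mmread(path / "matrix.mtx")
        genes = (path / "genes.tsv").read_text().splitlines()
        genes = [line.split("\t")[0] for line in genes if line]
        cells = [line for line in (path / "barcodes.tsv").read_text().splitlines() if line]
        mat = sparse.coo_matrix(mat).toarray()
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix is {mat.shape} but {len(genes)} gene names and {len(cells)} barcodes given"
            )
        df = pd.DataFrame(mat, index=_dedupe(genes, "gene"), columns=_dedupe(cells, "cell"))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = _dedupe([str(g) for g in df.index], "gene")
    else:
        raise ValueError(f"unknown format {format!r}")
    if df.shape[1] == 0:
        raise ValueError(f"count matrix at {path} has 0 cells")
    values = df.to_numpy()
    if not np.allclose(values, np.round(values)) or (values < 0).any():
        raise ValueError("count matrix must contain nonnegative integers")
    return df.astype(np.int64)


def write_counts_mtx(counts: pd.DataFrame, outdir: str | Path) -> None:
    """Write the MTX + genes.tsv + barcodes.tsv triplet (genes as rows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(counts.to_numpy()))
    (outdir / "genes.tsv").write_text("".join(f"{g}\n" for g in counts.index))
    (outdir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.columns))


def read_cell_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col="cell_id", dtype=str)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    return table


def lognormalize(counts: pd.DataFrame, scale: float = DEFAULT_SCALE) -> ExpressionMatrix:
    """Per-cell library normalization: ln(1 + scale * count / cell_total).

    Cells with zero total count are dropped (logged).
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = mat.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d zero-total cells", int((~keep).sum()))
    mat = mat[:, keep]
    totals = totals[keep]
    values = np.log1p(scale * mat / totals[None, :])
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns[keep]),
        norm="lognorm",
        scale=scale,
    )


def dot_profile(
    expr: ExpressionMatrix,
    counts: pd.DataFrame,
    cell_table: pd.DataFrame,
    genes: Sequence[str],
    group_col: str = "subgroup",
) -> pd.DataFrame:
    """Dot-plot statistics per (group, gene).

    ``mean_expr`` is the group mean of log-normalized values, ``z_expr``
    its z-score across groups (sample SD, ddof=1; 0 when variance is 0),
    ``pos_ratio`` the fraction of group cells with raw count > 0.
    """
    known = [g for g in genes if g in expr.genes]
    unknown = [g for g in genes if g not in expr.genes]
    if unknown:
        logger.warning("skipping %d unknown genes: %s", len(unknown), unknown[:10])
    cells = cell_table.index.intersection(expr.cells)
    groups = sorted(cell_table.loc[cells, group_col].unique())

    means = np.empty((len(groups), len(known)))
    ratios = np.empty((len(groups), len(known)))
    for i, grp in enumerate(groups):
        gcells = cells[cell_table.loc[cells, group_col] == grp]
        means[i] = expr.values.loc[known, gcells].mean(axis=1)
        ratios[i] = (counts.loc[known, gcells].to_numpy() > 0).mean(axis=1)

    if len(groups) >= 2:
        sd = means.std(axis=0, ddof=1)
        center = means.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (means - center) / sd, 0.0)
    else:
        z = np.zeros_like(means)

    rows = []
    for i, grp in enumerate(groups):
        for j, gene in enumerate(known):
            rows.append((grp, gene, means[i, j], z[i, j], ratios[i, j]))
    return pd.DataFrame(rows, columns=[group_col, "gene", "mean_expr", "z_expr", "pos_ratio"])


def find_markers(
    expr: ExpressionMatrix,
    counts: pd.DataFrame,
    cell_table: pd.DataFrame,
    cfg: MarkerConfig | None = None,
) -> pd.DataFrame:
    """One-vs-rest positive marker detection per subgroup.

    For each subgroup, genes passing the pre-filters (natural-log fold
    change of mean log-normalized expression >= ``min_lnfc`` and in-group
    positive ratio >= ``min_ratio``) are tested with a two-sided rank-sum
    against all remaining cells; p-values are BH-adjusted within the
    subgroup and ``is_marker`` requires ``p_adj < alpha``.
    """
    cfg = cfg or MarkerConfig()
    cells = cell_table.index.intersection(expr.cells)
    subgroups = sorted(cell_table.loc[cells, "subgroup"].unique())
    if len(subgroups) < 2:
        raise ValueError("find_markers needs at least 2 subgroups")

    values = expr.values.loc[:, cells].to_numpy()
    raw = counts.loc[:, cells].to_numpy()
    labels = cell_table.loc[cells, "subgroup"].to_numpy()

    frames = []
    for grp in subgroups:
        in_mask = labels == grp
        if int(in_mask.sum()) < cfg.min_cells:
            logger.warning("subgroup %r has < %d cells; excluded", grp, cfg.min_cells)
            continue
        mean_in = values[:, in_mask].mean(axis=1)
        mean_rest = values[:, ~in_mask].mean(axis=1)
        lnfc = np.log(mean_in + LNFC_PSEUDO) - np.log(mean_rest + LNFC_PSEUDO)
        ratio_in = (raw[:, in_mask] > 0).mean(axis=1)
        ratio_rest = (raw[:, ~in_mask] > 0).mean(axis=1)
        tested = (lnfc >= cfg.min_lnfc) & (ratio_in >= cfg.min_ratio)
        if not tested.any():
            continue
        _, p_raw = ranksum_rows(values[tested], in_mask)
        p_adj = bh_adjust(p_raw)
        frames.append(
            pd.DataFrame(
                {
                    "subgroup": grp,
                    "gene": expr.genes[tested],
                    "lnfc": lnfc[tested],
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                    "pos_ratio_in": ratio_in[tested],
                    "pos_ratio_rest": ratio_rest[tested],
                    "is_marker": p_adj < cfg.alpha,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["subgroup", "gene", "lnfc", "p_raw", "p_adj",
                     "pos_ratio_in", "pos_ratio_rest", "is_marker"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subgroup", "p_adj", "gene"], kind="mergesort").reset_index(drop=True)


def panel_marker_overlap(panel, markers: pd.DataFrame) -> dict[str, list[str]]:
    """Per-subgroup intersection of a gene panel with called markers."""
    panel_set = set(panel)
    out: dict[str, list[str]] = {}
    for grp, sub in markers.groupby("subgroup"):
        called = set(sub.loc[sub["is_marker"], "gene"])
        out[str(grp)] = sorted(panel_set & called)
    return out
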