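"""Five-step ligand-receptor candidate screen between two subgroups.

Ligands are screened in the sender subgroup and receptors in the receiver
subgroup with the same rule: upregulated in BoM-derived cells (two-sided
rank-sum p below alpha with positive mean difference) and expressed in
more than ``min_ratio`` of the subgroup's BoM cells. Database pairs whose
two genes both qualify are the candidate interactions.

The database reader accepts simple gene-gene pairs only; multi-subunit
complex rows must be pre-expanded into one row per member pair upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bom_screen import ScreenConfig, ranksum_rows
from .sc_core import ExpressionMatrix, dot_profile

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "ligand", "receptor", "subgroup_a", "subgroup_b",
    "ligand_p_raw", "ligand_pos_ratio_bom", "ligand_delta_mean",
    "receptor_p_raw", "receptor_pos_ratio_bom", "receptor_delta_mean",
    "passed",
]


@dataclass(frozen=True)
class LRDatabase:
    """Deduplicated ligand-receptor pair table (upper-cased symbols)."""

    pairs: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def ligands(self) -> tuple[str, ...]:
        return tuple(sorted({l for l, _ in self.pairs}))

    @property
    def receptors(self) -> tuple[str, ...]:
        return tuple(sorted({r for _, r in self.pairs}))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["ligand", "receptor"])

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "LRDatabase":
        seen = []
        uniq = set()
        for lig, rec in pairs:
            lig, rec = str(lig).upper(), str(rec).upper()
            if not lig or not rec:
                raise ValueError("empty gene id in ligand-receptor pair")
            if (lig, rec) in uniq:
                logger.warning("duplicate pair (%s, %s) dropped", lig, rec)
                continue
            if lig == rec:
                logger.warning("self-pair (%s, %s) retained but flagged", lig, rec)
            uniq.add((lig, rec))
            seen.append((lig, rec))
        return cls(pairs=tuple(seen))


def read_lr_db(path: str | Path) -> LRDatabase:
    """Read a CSV with ``ligand`` and ``receptor`` columns."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"ligand-receptor database {path} is empty")
    missing = [c for c in ("ligand", "receptor") if c not in df.columns]
    if missing:
        raise ValueError(f"ligand-receptor database missing columns: {missing}")
    return LRDatabase.from_pairs(zip(df["ligand"], df["receptor"]))


def write_lr_db(db: LRDatabase, path: str | Path) -> None:
    db.to_frame().to_csv(path, index=False)


def _gene_condition_stats(
    expr: ExpressionMatrix,
    counts: pd.DataFrame,
    cell_table: pd.DataFrame,
    subgroup: str,
    genes: Sequence[str],
    cfg: ScreenConfig,
) -> pd.DataFrame | None:
    """BoM-vs-Other stats for ``genes`` within one subgroup.

    The positive ratio is taken among BoM cells only (cells of the
    subgroup from BoM samples with raw count > 0, over all its BoM cells).
    Returns None when the subgroup lacks a testable condition split.
    """
    sub = cell_table.loc[cell_table["subgroup"] == subgroup]
    cells = sub.index.intersection(expr.cells)
    in_mask = cell_table.loc[cells, "condition"].to_numpy() == cfg.bom_label
    if in_mask.sum() < 1 or (~in_mask).sum() < 1:
        logger.warning(
            "subgroup %r lacks both conditions (%d BoM vs %d other cells)",
            subgroup, int(in_mask.sum()), int((~in_mask).sum()),
        )
        return None
    present = [g for g in genes if g in expr.genes]
    if not present:
        return pd.DataFrame(columns=["gene", "p_raw", "pos_ratio_bom", "delta_mean", "qualifies"])
    values = expr.values.loc[present, cells].to_numpy()
    raw = counts.loc[present, cells].to_numpy()
    _, p_raw = ranksum_rows(values, in_mask)
    delta = values[:, in_mask].mean(axis=1) - values[:, ~in_mask].mean(axis=1)
    ratio_bom = (raw[:, in_mask] > 0).mean(axis=1)
    qualifies = (p_raw < cfg.alpha) & (delta > 0) & (ratio_bom > cfg.min_ratio)
    return pd.DataFrame(
        {
            "gene": present,
            "p_raw": p_raw,
            "pos_ratio_bom": ratio_bom,
            "delta_mean": delta,
            "qualifies": qualifies,
        }
    ).set_index("gene")


def screen_lr(
    expr: ExpressionMatrix,
    counts: pd.DataFrame,
    cell_table: pd.DataFrame,
    subgroup_a: str,
    subgroup_b: str,
    db: LRDatabase,
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Screen database pairs: ligand in ``subgroup_a``, receptor in ``subgroup_b``.

    Returns one row per database pair with both genes present in the
    expression data, carrying the per-gene screen statistics and a
    ``passed`` flag; rows are ordered (ligand, receptor) lexicographically.
    """
    cfg = cfg or ScreenConfig()
    cfg.validate()
    if len(db) == 0:
        logger.warning("empty ligand-receptor database; no candidates")
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)

    lig_stats = _gene_condition_stats(expr, counts, cell_table, subgroup_a, db.ligands, cfg)
    rec_stats = _gene_condition_stats(expr, counts, cell_table, subgroup_b, db.receptors, cfg)
    if lig_stats is None or rec_stats is None:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS)

    rows = []
    for lig, rec in sorted(db.pairs):
        if lig not in lig_stats.index or rec not in rec_stats.index:
            continue
        ls = lig_stats.loc[lig]
        rs = rec_stats.loc[rec]
        rows.append(
            (
                lig, rec, subgroup_a, subgroup_b,
                ls["p_raw"], ls["pos_ratio_bom"], ls["delta_mean"],
                rs["p_raw"], rs["pos_ratio_bom"], rs["delta_mean"],
                bool(ls["qualifies"] and rs["qualifies"]),
            )
        )
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def passed_pairs(candidates: pd.DataFrame) -> list[tuple[str, str]]:
    return [tuple(r) for r in candidates.loc[candidates["passed"], ["ligand", "receptor"]].itertuples(index=False)]


def lr_summary(
    candidates: pd.DataFrame,
    expr: ExpressionMatrix,
    counts: pd.DataFrame,
    cell_table: pd.DataFrame,
    bom_label: str = "BoM",
) -> pd.DataFrame:
    """Dot-plot statistics per candidate gene and condition.

    For each passed candidate, the ligand is profiled within its sender
    subgroup and the receptor within its receiver subgroup, split by
    condition (BoM vs Other), reusing the dot-profile semantics.
    """
    rows = []
    for cand in candidates.loc[candidates["passed"]].itertuples(index=False):
        for gene, role, subgroup in (
            (cand.ligand, "ligand", cand.subgroup_a),
            (cand.receptor, "receptor", cand.subgroup_b),
        ):
            sub = cell_table.loc[cell_table["subgroup"] == subgroup].copy()
            sub["condition_group"] = np.where(sub["condition"] == bom_label, bom_label, "Other")
            prof = dot_profile(expr, counts, sub, [gene], group_col="condition_group")
            for rec in prof.itertuples(index=False):
                rows.append(
                    (cand.ligand, cand.receptor, gene, role, subgroup,
                     rec.condition_group, rec.mean_expr, rec.z_expr, rec.pos_ratio)
                )
    return pd.DataFrame(
        rows,
        columns=["ligand", "receptor", "gene", "role", "subgroup",
                 "condition", "mean_expr", "z_expr", "pos_ratio"],
    )
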