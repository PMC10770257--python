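"""Bulk differential expression and the two-comparison overlap panel.

A self-contained negative-binomial Wald test: median-of-ratios size
factors, method-of-moments gene dispersion, delta-method standard error on
the log2 fold change, Benjamini-Hochberg adjustment. The panel is the
intersection of the up-regulated sets of two such comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8
_LN2 = np.log(2.0)


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene set surviving both up-regulation filters."""

    genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    Only genes with a positive geometric mean across samples (i.e. no
    zero anywhere) enter the median.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise ValueError("counts must be a genes x samples table")
    eligible = (mat > 0).all(axis=1)
    if not eligible.any():
        raise ValueError("no gene has positive counts in every sample; cannot normalize")
    log_geo = np.log(mat[eligible]).mean(axis=1)
    ratios = np.log(mat[eligible]) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _check_integer_counts(mat: np.ndarray) -> None:
    if not np.isfinite(mat).all():
        raise ValueError("counts must be finite")
    if (mat < 0).any() or not np.allclose(mat, np.round(mat)):
        raise ValueError("counts must be nonnegative integers")


def nb_wald_de(
    counts: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    reference: str,
    treatment: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``treatment`` over ``reference``.

    Counts are scaled by median-of-ratios size factors; the log2 fold
    change uses pseudo-count 0.5; a per-group method-of-moments dispersion
    (floored at 1e-8) feeds the delta-method SE; two-sided p-values come
    from a Welch-Satterthwaite t reference; ``p_adj`` is BH. Genes with
    zero counts everywhere get direction ``ns`` with p = 1.
    """
    groups = pd.Series(np.asarray(groups), index=counts.columns)
    cols1 = counts.columns[groups == reference]
    cols2 = counts.columns[groups == treatment]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("each group needs at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    _check_integer_counts(mat)

    sf = size_factors(counts)
    norm = mat / sf.to_numpy()[None, :]
    idx1 = counts.columns.get_indexer(cols1)
    idx2 = counts.columns.get_indexer(cols2)
    n1, n2 = len(idx1), len(idx2)
    m1 = norm[:, idx1].mean(axis=1)
    m2 = norm[:, idx2].mean(axis=1)
    v1 = norm[:, idx1].var(axis=1, ddof=1)
    v2 = norm[:, idx2].var(axis=1, ddof=1)

    # per-group method-of-moments dispersion: var = mu + a*mu^2; the plug-in
    # group-mean variance (mu + a*mu^2)/n then equals the sample variance / n
    # wherever the floor is inactive, which keeps the z statistic stable under
    # per-sample library rescaling.
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, np.maximum((v1 - m1) / np.square(m1), DISPERSION_FLOOR), DISPERSION_FLOOR)
        a2 = np.where(m2 > 0, np.maximum((v2 - m2) / np.square(m2), DISPERSION_FLOOR), DISPERSION_FLOOR)

    log2fc = np.log2((m2 + PSEUDOCOUNT) / (m1 + PSEUDOCOUNT))
    var_m1 = (m1 + a1 * np.square(m1)) / n1
    var_m2 = (m2 + a2 * np.square(m2)) / n2
    t1 = var_m1 / np.square(_LN2 * (m1 + PSEUDOCOUNT))
    t2 = var_m2 / np.square(_LN2 * (m2 + PSEUDOCOUNT))
    se = np.sqrt(t1 + t2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
        # Welch-Satterthwaite df: the variance is moment-estimated, so a t
        # reference keeps the test calibrated at small group sizes
        df = np.where(
            se > 0,
            np.square(t1 + t2) / (np.square(t1) / (n1 - 1) + np.square(t2) / (n2 - 1)),
            1.0,
        )
    p_raw = 2.0 * sps.t.sf(np.abs(z), df)
    p_raw = np.minimum(p_raw, 1.0)

    all_zero = (mat == 0).all(axis=1)
    p_raw[all_zero] = 1.0
    log2fc[all_zero] = 0.0

    p_adj = bh_adjust(p_raw)
    direction = np.where(
        (p_adj < alpha) & (log2fc > 0), "up", np.where((p_adj < alpha) & (log2fc < 0), "down", "ns")
    )
    direction[all_zero] = "ns"

    return pd.DataFrame(
        {
            "gene": counts.index,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "mean_norm_g1": m1,
            "mean_norm_g2": m2,
            "direction": direction,
        }
    ).set_index("gene", drop=False)


def derive_panel(
    de_meta: pd.DataFrame,
    de_bom: pd.DataFrame,
    alpha: float = 0.05,
    labels: tuple[str, str] = ("meta_vs_nonmeta", "bom_vs_nonbom"),
) -> GenePanel:
    """Genes up-regulated (p_adj < alpha, log2fc > 0) in both comparisons.

    Output order is lexicographic; disjoint gene namespaces yield an
    empty panel with a warning, not a failure.
    """
    up1 = set(de_meta.loc[(de_meta["p_adj"] < alpha) & (de_meta["log2fc"] > 0), "gene"])
    up2 = set(de_bom.loc[(de_bom["p_adj"] < alpha) & (de_bom["log2fc"] > 0), "gene"])
    if not (set(de_meta["gene"]) & set(de_bom["gene"])):
        logger.warning("DE tables share no genes; panel is empty")
    genes = tuple(sorted(up1 & up2))
    return GenePanel(
        genes=genes,
        provenance={"comparisons": list(labels), "alpha": alpha,
                    "n_up_meta": len(up1), "n_up_bom": len(up2)},
    )


def bone_site_mask(text: pd.Series, token: str = "bone") -> pd.Series:
    """Case-insensitive substring phenotype helper (e.g. anatomic-site text)."""
    return text.fillna("").str.contains(token, case=False, regex=False)
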