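"""Hypergeometric over-representation analysis against GMT gene sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps

from .bulk_de import bh_adjust

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["set_name", "k", "K", "n", "N", "p_raw", "p_adj", "overlap_genes"]


@dataclass(frozen=True)
class GeneSetCollection:
    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, members = fields[0], fields[1], fields[2:]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(m for m in members if m)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "")
        members = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{desc}\t{members}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def ora_hypergeometric(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set, within ``universe``.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n); query genes outside
    the universe are dropped with a warning; sets vanishing after
    intersection with the universe are skipped; BH across tested sets;
    sorted by (p_adj, set name).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query:
        raise ValueError("empty query")
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
    query &= universe
    if not query:
        raise ValueError("no query gene is in the universe")

    N = len(universe)
    n = len(query)
    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(members & query)
        k = len(overlap)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0), overlap))
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_raw", "overlap_genes"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_adj", "set_name"], kind="mergesort").reset_index(drop=True)
    return out[RESULT_COLUMNS]


def top_terms(results: pd.DataFrame, k: int, alpha: float = 0.05) -> pd.DataFrame:
    """First ``k`` results with p_adj below alpha (fewer if not enough pass)."""
    if k <= 0:
        raise ValueError("k must be positive")
    passing = results.loc[results["p_adj"] < alpha]
    return passing.head(k).reset_index(drop=True)
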