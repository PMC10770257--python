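"""Planted-truth simulators for bulk and single-cell counts and L-R databases.

All counts are negative binomial (variance = mu + dispersion * mu^2); zeros
arise from the NB itself. Effects are planted multiplicatively on the mean,
and every planted signal is returned in a :class:`SimTruth` ledger so
downstream screens can be scored against ground truth.

Bulk planting is contrast-balanced: genes planted up in BoM samples are
compensated down in non-BoM metastatic samples so their metastatic-group
average stays at baseline. This keeps the two bulk comparisons orthogonal
(the overlap panel then equals the planted overlap set by construction
rather than absorbing every BoM-only gene).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lr_screen import LRDatabase
from .sc_core import DEFAULT_SCALE, write_counts_mtx

logger = logging.getLogger(__name__)

META, NONMETA = "Meta", "nonMeta"
BOM, NONBOM, NA = "BoM", "nonBoM", "NA"
OTHER = "Other"


def gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# bulk


@dataclass(frozen=True)
class BulkSimConfig:
    n_genes: int = 2000
    n_samples_per_group: int = 20
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    n_meta_up: int = 0
    n_bom_up: int = 0
    n_overlap: int = 0
    log2fc: float = 2.0
    libsize_sigma: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("n_genes and n_samples_per_group must be positive")
        for name in ("baseline_mean", "dispersion"):
            val = getattr(self, name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and positive, got {val}")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be nonnegative")
        if self.n_overlap > min(self.n_meta_up, self.n_bom_up):
            raise ValueError("n_overlap exceeds a planted set size")
        if self.n_meta_up + self.n_bom_up - self.n_overlap > self.n_genes:
            raise ValueError("planted sets exceed n_genes")
        if self.log2fc < 0:
            raise ValueError("log2fc must be nonnegative")


@dataclass(frozen=True)
class SimTruth:
    """Ledger of every planted signal of a simulation."""

    planted_meta_up: tuple[str, ...] = ()
    planted_bom_up: tuple[str, ...] = ()
    planted_overlap: tuple[str, ...] = ()
    planted_markers: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_condition_up: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_lr_pairs: tuple[tuple[str, str, str, str], ...] = ()
    planted_correlated_pairs: tuple[tuple[str, str, str, float], ...] = ()

    def to_dict(self) -> dict:
        return {
            "planted_meta_up": list(self.planted_meta_up),
            "planted_bom_up": list(self.planted_bom_up),
            "planted_overlap": list(self.planted_overlap),
            "planted_markers": {k: list(v) for k, v in self.planted_markers.items()},
            "planted_condition_up": {k: list(v) for k, v in self.planted_condition_up.items()},
            "planted_lr_pairs": [list(p) for p in self.planted_lr_pairs],
            "planted_correlated_pairs": [list(p) for p in self.planted_correlated_pairs],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def simulate_bulk(cfg: BulkSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate bulk NB counts across nonMeta / Meta-nonBoM / Meta-BoM groups.

    Planted meta genes gain 2**log2fc in every metastatic sample; planted
    BoM genes are contrast-balanced: up by ``2F/(F+1)`` in BoM samples and
    down by ``2/(F+1)`` in non-BoM metastatic samples (``F = 2**log2fc``),
    so the BoM / non-BoM mean ratio is F while the metastatic-group
    average stays at baseline.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = gene_names(cfg.n_genes)
    npg = cfg.n_samples_per_group

    sample_ids = (
        [f"nonMeta_{i + 1:02d}" for i in range(npg)]
        + [f"MetaNonBoM_{i + 1:02d}" for i in range(npg)]
        + [f"MetaBoM_{i + 1:02d}" for i in range(npg)]
    )
    meta_status = [NONMETA] * npg + [META] * (2 * npg)
    bom_status = [NA] * npg + [NONBOM] * npg + [BOM] * npg
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "meta_status": meta_status, "bom_status": bom_status}
    ).set_index("sample_id", drop=False)

    n_extra = cfg.n_meta_up + cfg.n_bom_up - cfg.n_overlap
    chosen = rng.choice(cfg.n_genes, size=n_extra, replace=False) if n_extra else np.array([], int)
    meta_idx = chosen[: cfg.n_meta_up]
    bom_idx = np.concatenate([chosen[: cfg.n_overlap], chosen[cfg.n_meta_up:]]).astype(int)
    overlap_idx = chosen[: cfg.n_overlap]

    F = 2.0 ** cfg.log2fc
    mu = np.full((cfg.n_genes, len(sample_ids)), cfg.baseline_mean)
    is_meta = samples["meta_status"].to_numpy() == META
    is_bom = samples["bom_status"].to_numpy() == BOM
    is_nonbom = samples["bom_status"].to_numpy() == NONBOM
    if meta_idx.size:
        mu[np.ix_(meta_idx, is_meta)] *= F
    if bom_idx.size:
        mu[np.ix_(bom_idx, is_bom)] *= 2.0 * F / (F + 1.0)
        mu[np.ix_(bom_idx, is_nonbom)] *= 2.0 / (F + 1.0)

    libfactors = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=len(sample_ids)))
    mu = mu * libfactors[None, :]
    counts = rng.negative_binomial(1.0 / cfg.dispersion, 1.0 / (1.0 + cfg.dispersion * mu))

    garr = np.asarray(genes)
    truth = SimTruth(
        planted_meta_up=tuple(sorted(garr[meta_idx])),
        planted_bom_up=tuple(sorted(garr[bom_idx])),
        planted_overlap=tuple(sorted(garr[overlap_idx])),
    )
    return pd.DataFrame(counts, index=genes, columns=sample_ids), samples, truth


# ---------------------------------------------------------------------------
# single cell


@dataclass(frozen=True)
class SubgroupSpec:
    label: str
    n_cells_per_sample: int
    marker_genes: tuple = ()


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    condition: str  # "BoM" or "Other" (or a multi-level sample type)
    sample_type: str | None = None  # defaults to condition


@dataclass(frozen=True)
class ConditionEffect:
    subgroup: str
    gene: str | int
    log2fc: float


@dataclass(frozen=True)
class LRProgram:
    ligand: str | int
    subgroup_a: str
    receptor: str | int
    subgroup_b: str
    log2fc: float = 2.0
    rho: float = 0.0


@dataclass(frozen=True)
class ScSimConfig:
    subgroups: tuple[SubgroupSpec, ...]
    samples: tuple[SampleSpec, ...]
    n_genes: int = 1500
    baseline_log_mean: float = 0.0
    gene_log_sigma: float = 1.0
    dispersion: float = 0.3
    marker_log2fc: float = 2.5
    condition_effects: tuple[ConditionEffect, ...] = ()
    lr_programs: tuple[LRProgram, ...] = ()
    sparsity: float | None = 0.8
    planted_base_mean: float | None = None  # override baseline mean of planted genes
    seed: int = 0

    def validate(self) -> None:
        if not self.subgroups:
            raise ValueError("at least one subgroup required")
        labels = [s.label for s in self.subgroups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate subgroup labels")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        if len({s.condition for s in self.samples}) < 2:
            raise ValueError("condition labels must cover at least 2 levels")
        if self.n_genes <= 0 or self.dispersion <= 0:
            raise ValueError("n_genes and dispersion must be positive")
        if self.sparsity is not None and not (0.0 <= self.sparsity < 1.0):
            raise ValueError("sparsity must be in [0, 1)")
        known = set(labels)
        for eff in self.condition_effects:
            if eff.subgroup not in known:
                raise ValueError(f"condition effect references unknown subgroup {eff.subgroup!r}")
            self._check_gene(eff.gene)
        for prog in self.lr_programs:
            for sg in (prog.subgroup_a, prog.subgroup_b):
                if sg not in known:
                    raise ValueError(f"lr program references unknown subgroup {sg!r}")
            if not (0.0 <= prog.rho < 1.0):
                raise ValueError(f"co-expression rho out of [0, 1): {prog.rho}")
            self._check_gene(prog.ligand)
            self._check_gene(prog.receptor)
        for sub in self.subgroups:
            for g in sub.marker_genes:
                self._check_gene(g)

    def _check_gene(self, gene: str | int) -> None:
        if isinstance(gene, (int, np.integer)):
            if not (0 <= int(gene) < self.n_genes):
                raise ValueError(f"gene index {gene} out of range [0, {self.n_genes})")
        elif gene not in gene_names(self.n_genes):
            raise ValueError(f"gene {gene!r} not among the simulated gene names")

    def resolve_gene(self, gene: str | int) -> str:
        if isinstance(gene, (int, np.integer)):
            return gene_names(self.n_genes)[int(gene)]
        return str(gene)


def _nb_zero_fraction(mu: np.ndarray, disp: float) -> float:
    return float(np.mean((1.0 + disp * mu) ** (-1.0 / disp)))


def _sparsity_multiplier(base: np.ndarray, disp: float, target: float) -> float:
    """Bisect a global mean multiplier so the expected NB zero fraction hits target."""
    lo, hi = -25.0, 25.0
    if _nb_zero_fraction(base * np.exp(lo), disp) < target:
        logger.warning("sparsity target %.2f unreachable from below; using floor", target)
        return float(np.exp(lo))
    if _nb_zero_fraction(base * np.exp(hi), disp) > target:
        logger.warning("sparsity target %.2f unreachable from above; using ceiling", target)
        return float(np.exp(hi))
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if _nb_zero_fraction(base * np.exp(mid), disp) > target:
            lo = mid  # too sparse -> need larger means
        else:
            hi = mid
    return float(np.exp((lo + hi) / 2.0))


def _observed_rho(
    tau: float, mu_a: float, mu_b: float, disp: float, norm_factor: float,
    rng: np.random.Generator, size: int = 4000,
) -> float:
    """Monte-Carlo Pearson correlation of log1p-scaled NB draws sharing exp(z)."""
    z = np.exp(rng.normal(0.0, tau, size=size))
    a = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu_a * z))
    b = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu_b * z))
    va, vb = np.log1p(norm_factor * a), np.log1p(norm_factor * b)
    if va.std() == 0 or vb.std() == 0:
        return 0.0
    return float(np.corrcoef(va, vb)[0, 1])


def _calibrate_tau(
    rho: float, mu_a: float, mu_b: float, disp: float, norm_factor: float,
    rng: np.random.Generator,
) -> float:
    """Bisect the latent-factor SD to plant a target log-scale Pearson rho."""
    lo, hi = 0.0, 3.0
    if _observed_rho(hi, mu_a, mu_b, disp, norm_factor, rng) < rho:
        logger.warning("co-expression rho %.2f unreachable at these means; using cap", rho)
        return hi
    for _ in range(20):
        mid = (lo + hi) / 2.0
        if _observed_rho(mid, mu_a, mu_b, disp, norm_factor, rng) < rho:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_sc(cfg: ScSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a gene x cell NB count matrix with planted structure.

    Markers gain ``2**marker_log2fc`` in their subgroup (all samples);
    condition effects apply only to the subgroup's cells from BoM samples;
    each L-R program elevates the ligand in the sender subgroup's BoM
    cells and the receptor in both the receiver subgroup's BoM cells (for
    the screen) and the sender subgroup's BoM cells (where a shared
    log-normal latent factor plants the requested Pearson correlation
    between the two genes).
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_main, rng_calib = [np.random.default_rng(s) for s in ss.spawn(2)]
    genes = gene_names(cfg.n_genes)

    cell_rows = []
    for samp in cfg.samples:
        for sub in cfg.subgroups:
            for k in range(sub.n_cells_per_sample):
                cell_rows.append(
                    (
                        f"{samp.sample_id}_{sub.label}_{k + 1:04d}",
                        samp.sample_id,
                        samp.sample_type or samp.condition,
                        samp.condition,
                        sub.label,
                    )
                )
    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "sample_id", "sample_type", "condition", "subgroup"]
    ).set_index("cell_id", drop=False)
    if cells.index.duplicated().any():
        raise ValueError("duplicate cell ids")

    base = np.exp(rng_main.normal(cfg.baseline_log_mean, cfg.gene_log_sigma, size=cfg.n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}

    planted: set[int] = set()
    for sub in cfg.subgroups:
        planted.update(gene_pos[cfg.resolve_gene(g)] for g in sub.marker_genes)
    for eff in cfg.condition_effects:
        planted.add(gene_pos[cfg.resolve_gene(eff.gene)])
    for prog in cfg.lr_programs:
        planted.add(gene_pos[cfg.resolve_gene(prog.ligand)])
        planted.add(gene_pos[cfg.resolve_gene(prog.receptor)])
    if planted and cfg.planted_base_mean is not None:
        base[sorted(planted)] = cfg.planted_base_mean

    if cfg.sparsity is not None:
        base = base * _sparsity_multiplier(base, cfg.dispersion, cfg.sparsity)

    subgroup_arr = cells["subgroup"].to_numpy()
    bom_arr = cells["condition"].to_numpy() == BOM

    mu = np.tile(base[:, None], (1, len(cells)))
    for sub in cfg.subgroups:
        mask = subgroup_arr == sub.label
        for g in sub.marker_genes:
            mu[gene_pos[cfg.resolve_gene(g)], mask] *= 2.0 ** cfg.marker_log2fc
    for eff in cfg.condition_effects:
        mask = (subgroup_arr == eff.subgroup) & bom_arr
        mu[gene_pos[cfg.resolve_gene(eff.gene)], mask] *= 2.0 ** eff.log2fc

    expected_total = mu.sum(axis=0).mean()
    norm_factor = DEFAULT_SCALE / max(expected_total, 1.0)
    for prog in cfg.lr_programs:
        lig = gene_pos[cfg.resolve_gene(prog.ligand)]
        rec = gene_pos[cfg.resolve_gene(prog.receptor)]
        fold = 2.0 ** prog.log2fc
        sender_bom = (subgroup_arr == prog.subgroup_a) & bom_arr
        receiver_bom = (subgroup_arr == prog.subgroup_b) & bom_arr & ~(
            subgroup_arr == prog.subgroup_a
        )
        mu[lig, sender_bom] *= fold
        mu[rec, receiver_bom] *= fold
        mu[rec, sender_bom] *= fold
        if prog.rho > 0 and sender_bom.any():
            tau = _calibrate_tau(
                prog.rho, base[lig] * fold, base[rec] * fold,
                cfg.dispersion, norm_factor, rng_calib,
            )
            # median-preserving latent factor: exp(z) keeps the planted fold on
            # the median, which is what the rank-sum screen responds to
            z = rng_main.normal(0.0, tau, size=int(sender_bom.sum()))
            factor = np.exp(z)
            mu[lig, sender_bom] *= factor
            mu[rec, sender_bom] *= factor

    counts = rng_main.negative_binomial(
        1.0 / cfg.dispersion, 1.0 / (1.0 + cfg.dispersion * mu)
    )
    counts = pd.DataFrame(counts, index=genes, columns=cells.index)

    truth = SimTruth(
        planted_markers={
            sub.label: tuple(sorted(cfg.resolve_gene(g) for g in sub.marker_genes))
            for sub in cfg.subgroups
            if sub.marker_genes
        },
        planted_condition_up=_condition_truth(cfg),
        planted_lr_pairs=tuple(
            sorted(
                (cfg.resolve_gene(p.ligand), cfg.resolve_gene(p.receptor), p.subgroup_a, p.subgroup_b)
                for p in cfg.lr_programs
            )
        ),
        planted_correlated_pairs=tuple(
            sorted(
                (cfg.resolve_gene(p.ligand), cfg.resolve_gene(p.receptor), p.subgroup_a, p.rho)
                for p in cfg.lr_programs
                if p.rho > 0
            )
        ),
    )
    return counts, cells, truth


def _condition_truth(cfg: ScSimConfig) -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {}
    for eff in cfg.condition_effects:
        if eff.log2fc > 0:
            out.setdefault(eff.subgroup, []).append(cfg.resolve_gene(eff.gene))
    return {k: tuple(sorted(v)) for k, v in out.items()}


# ---------------------------------------------------------------------------
# ligand-receptor database


def simulate_lr_db(
    true_pairs: Iterable[tuple[str, str]],
    n_decoys: int,
    gene_universe: Sequence[str],
    seed: int = 0,
) -> LRDatabase:
    """True pairs plus ``n_decoys`` distinct non-true, non-self decoy pairs."""
    universe = list(dict.fromkeys(gene_universe))
    uni_set = set(universe)
    true_pairs = sorted({(str(a).upper(), str(b).upper()) for a, b in true_pairs})
    for a, b in true_pairs:
        if a not in uni_set or b not in uni_set:
            raise ValueError(f"true pair ({a}, {b}) outside the gene universe")
    n_u = len(universe)
    available = n_u * (n_u - 1) - len(true_pairs)
    if n_decoys > available:
        raise ValueError(f"n_decoys={n_decoys} exceeds {available} available distinct pairs")

    rng = np.random.default_rng(seed)
    forbidden = set(true_pairs)
    decoys: list[tuple[str, str]] = []
    while len(decoys) < n_decoys:
        i, j = rng.integers(0, n_u, size=2)
        if i == j:
            continue
        pair = (universe[i], universe[j])
        if pair in forbidden:
            continue
        forbidden.add(pair)
        decoys.append(pair)
    return LRDatabase.from_pairs(true_pairs + decoys)


# ---------------------------------------------------------------------------
# default fixtures


def default_bulk_config(seed: int = 42, **overrides) -> BulkSimConfig:
    """Desk-scale bulk fixture: 2000 genes, 20 samples per group, planted overlap."""
    params = dict(
        n_genes=2000,
        n_samples_per_group=20,
        baseline_mean=50.0,
        dispersion=0.1,
        n_meta_up=150,
        n_bom_up=80,
        n_overlap=40,
        log2fc=2.0,
        libsize_sigma=0.2,
        seed=seed,
    )
    params.update(overrides)
    return BulkSimConfig(**params)


def null_bulk_config(seed: int = 0, **overrides) -> BulkSimConfig:
    return default_bulk_config(seed=seed, n_meta_up=0, n_bom_up=0, n_overlap=0, **overrides)


_BREAST_SUBGROUPS = (
    "fibroblast", "tumor1", "tumor2", "tcell",
    "myeloid1", "myeloid2", "stroma", "cycling",
)


def breast_like_config(seed: int = 42) -> ScSimConfig:
    """Breast-like single-cell fixture: 4 samples (2 Other, 2 BoM), 8 subgroups,
    1500 genes, ~4000 cells, planted markers, fibroblast condition genes and
    10 fibroblast-to-tumor L-R programs."""
    n_genes = 1500
    names = gene_names(n_genes)
    subgroups = tuple(
        SubgroupSpec(
            label=label,
            n_cells_per_sample=125,
            marker_genes=tuple(names[i * 5 : i * 5 + 5]),
        )
        for i, label in enumerate(_BREAST_SUBGROUPS)
    )
    samples = (
        SampleSpec("PDX1", OTHER),
        SampleSpec("PDX2", OTHER),
        SampleSpec("BOM1", BOM),
        SampleSpec("BOM2", BOM),
    )
    condition_genes = names[40:70]  # 30 genes up in BoM fibroblasts
    condition_effects = tuple(
        ConditionEffect("fibroblast", g, log2fc=3.0) for g in condition_genes
    )
    lr_programs = tuple(
        LRProgram(
            ligand=names[100 + i],
            subgroup_a="fibroblast",
            receptor=names[120 + i],
            subgroup_b="tumor1",
            log2fc=2.0,
            rho=0.5,
        )
        for i in range(10)
    )
    return ScSimConfig(
        subgroups=subgroups,
        samples=samples,
        n_genes=n_genes,
        baseline_log_mean=0.0,
        gene_log_sigma=1.2,
        dispersion=0.3,
        marker_log2fc=2.5,
        condition_effects=condition_effects,
        lr_programs=lr_programs,
        sparsity=0.75,
        planted_base_mean=3.0,
        seed=seed,
    )


def condition_screen_config(seed: int = 42, log2fc: float = 3.0, n_planted: int = 100) -> ScSimConfig:
    """Single-subgroup fixture: 200 BoM vs 200 Other cells, planted condition genes."""
    n_genes = 800
    names = gene_names(n_genes)
    return ScSimConfig(
        subgroups=(SubgroupSpec("fibroblast", 100),),
        samples=(
            SampleSpec("PDX1", OTHER),
            SampleSpec("PDX2", OTHER),
            SampleSpec("BOM1", BOM),
            SampleSpec("BOM2", BOM),
        ),
        n_genes=n_genes,
        gene_log_sigma=1.2,
        dispersion=0.3,
        condition_effects=tuple(
            ConditionEffect("fibroblast", g, log2fc=log2fc) for g in names[:n_planted]
        ),
        sparsity=0.6,
        planted_base_mean=2.0,
        seed=seed,
    )


def lr_fixture_config(seed: int = 42) -> tuple[ScSimConfig, LRDatabase]:
    """Two-subgroup fixture with 10 planted L-R programs plus 40 decoy pairs."""
    n_genes = 600
    names = gene_names(n_genes)
    programs = tuple(
        LRProgram(
            ligand=names[i],
            subgroup_a="sender",
            receptor=names[10 + i],
            subgroup_b="receiver",
            log2fc=2.0,
            rho=0.5,
        )
        for i in range(10)
    )
    cfg = ScSimConfig(
        subgroups=(SubgroupSpec("sender", 100), SubgroupSpec("receiver", 100)),
        samples=(
            SampleSpec("PDX1", OTHER),
            SampleSpec("PDX2", OTHER),
            SampleSpec("BOM1", BOM),
            SampleSpec("BOM2", BOM),
        ),
        n_genes=n_genes,
        gene_log_sigma=1.0,
        dispersion=0.3,
        lr_programs=programs,
        sparsity=0.6,
        planted_base_mean=2.0,
        seed=seed,
    )
    db = simulate_lr_db(
        [(names[i], names[10 + i]) for i in range(10)],
        n_decoys=40,
        gene_universe=names[:220],
        seed=seed,
    )
    return cfg, db


def correlation_fixture_config(seed: int = 42, rho: float = 0.5, n_pairs: int = 3) -> ScSimConfig:
    """Single-subgroup fixture with 500 BoM cells and planted correlated pairs."""
    n_genes = 200
    names = gene_names(n_genes)
    programs = tuple(
        LRProgram(
            ligand=names[i], subgroup_a="fib",
            receptor=names[10 + i], subgroup_b="fib",
            log2fc=2.0, rho=rho,
        )
        for i in range(n_pairs)
    )
    return ScSimConfig(
        subgroups=(SubgroupSpec("fib", 250),),
        samples=(
            SampleSpec("PDX1", OTHER),
            SampleSpec("PDX2", OTHER),
            SampleSpec("BOM1", BOM),
            SampleSpec("BOM2", BOM),
        ),
        n_genes=n_genes,
        gene_log_sigma=1.0,
        dispersion=0.3,
        lr_programs=programs,
        sparsity=0.6,
        planted_base_mean=2.0,
        seed=seed,
    )


def null_sc_config(seed: int = 0, n_genes: int = 2000, n_cells_per_sample: int = 100) -> ScSimConfig:
    """No planted effects: a single subgroup, balanced BoM/Other samples."""
    return ScSimConfig(
        subgroups=(SubgroupSpec("all", n_cells_per_sample),),
        samples=(
            SampleSpec("PDX1", OTHER),
            SampleSpec("PDX2", OTHER),
            SampleSpec("BOM1", BOM),
            SampleSpec("BOM2", BOM),
        ),
        n_genes=n_genes,
        gene_log_sigma=1.0,
        dispersion=0.3,
        sparsity=0.6,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# writers and config parsing


def write_bulk(counts: pd.DataFrame, samples: pd.DataFrame, truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.to_csv(outdir / "bulk_counts.tsv", sep="\t")
    samples.to_csv(outdir / "bulk_samples.tsv", sep="\t", index=False)
    truth.write_json(outdir / "bulk_truth.json")


def write_sc(counts: pd.DataFrame, cells: pd.DataFrame, truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(counts, outdir)
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    truth.write_json(outdir / "sc_truth.json")


def bulk_config_from_dict(d: dict) -> BulkSimConfig:
    return BulkSimConfig(**d)


def sc_config_from_dict(d: dict) -> ScSimConfig:
    d = dict(d)
    d["subgroups"] = tuple(
        SubgroupSpec(s["label"], int(s["n_cells_per_sample"]), tuple(s.get("marker_genes", ())))
        for s in d.get("subgroups", ())
    )
    d["samples"] = tuple(
        SampleSpec(s["sample_id"], s["condition"], s.get("sample_type"))
        for s in d.get("samples", ())
    )
    d["condition_effects"] = tuple(
        ConditionEffect(e["subgroup"], e["gene"], float(e["log2fc"]))
        for e in d.get("condition_effects", ())
    )
    d["lr_programs"] = tuple(
        LRProgram(
            p["ligand"], p["subgroup_a"], p["receptor"], p["subgroup_b"],
            float(p.get("log2fc", 2.0)), float(p.get("rho", 0.0)),
        )
        for p in d.get("lr_programs", ())
    )
    return ScSimConfig(**d)
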