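"""Full-study orchestration: bulk panel -> profiling -> screens -> L-R ->
correlations -> enrichment, from a single YAML config, with a manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, bulk_de, correlate, enrich, lr_screen, sc_core
from .bom_screen import ScreenConfig, screen_condition_genes

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass(frozen=True)
class PipelineConfig:
    bulk_counts: str
    bulk_samples: str
    sc_counts: str
    sc_cells: str
    out_dir: str
    lr_db: str | None = None
    gmt: str | None = None
    sc_format: str = "mtx_triplet"
    alpha: float = 0.05
    min_ratio: float = 0.10
    adjustment: str = "none"
    high_corr_threshold: float = 0.2
    bom_label: str = "BoM"
    screen_subgroups: tuple[str, ...] = ()
    lr_pairs: tuple[tuple[str, str], ...] = ()
    corr_subgroup: str | None = None
    corr_anchors: tuple[str, ...] = ()
    corr_targets: tuple[str, ...] = ()
    seed: int = 0

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            alpha=self.alpha,
            min_ratio=self.min_ratio,
            adjustment=self.adjustment,
            high_corr_threshold=self.high_corr_threshold,
            bom_label=self.bom_label,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "bulk_counts": self.bulk_counts,
            "bulk_samples": self.bulk_samples,
            "sc_counts": self.sc_counts,
            "sc_cells": self.sc_cells,
            "out_dir": self.out_dir,
            "lr_db": self.lr_db,
            "gmt": self.gmt,
            "sc_format": self.sc_format,
            "alpha": self.alpha,
            "min_ratio": self.min_ratio,
            "adjustment": self.adjustment,
            "high_corr_threshold": self.high_corr_threshold,
            "bom_label": self.bom_label,
            "screen_subgroups": list(self.screen_subgroups),
            "lr_pairs": [list(p) for p in self.lr_pairs],
            "corr_subgroup": self.corr_subgroup,
            "corr_anchors": list(self.corr_anchors),
            "corr_targets": list(self.corr_targets),
            "seed": self.seed,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        def respath(value):
            if value is None:
                return None
            p = Path(value)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            return str(p)

        known = {
            "bulk_counts", "bulk_samples", "sc_counts", "sc_cells", "out_dir",
            "lr_db", "gmt", "sc_format", "alpha", "min_ratio", "adjustment",
            "high_corr_threshold", "bom_label", "screen_subgroups", "lr_pairs",
            "corr_subgroup", "corr_anchors", "corr_targets", "seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        required = ["bulk_counts", "bulk_samples", "sc_counts", "sc_cells", "out_dir"]
        missing = [k for k in required if k not in raw]
        if missing:
            raise ConfigError(f"missing required config keys: {missing}")
        return cls(
            bulk_counts=respath(raw["bulk_counts"]),
            bulk_samples=respath(raw["bulk_samples"]),
            sc_counts=respath(raw["sc_counts"]),
            sc_cells=respath(raw["sc_cells"]),
            out_dir=respath(raw["out_dir"]),
            lr_db=respath(raw.get("lr_db")),
            gmt=respath(raw.get("gmt")),
            sc_format=raw.get("sc_format", "mtx_triplet"),
            alpha=float(raw.get("alpha", 0.05)),
            min_ratio=float(raw.get("min_ratio", 0.10)),
            adjustment=str(raw.get("adjustment", "none")),
            high_corr_threshold=float(raw.get("high_corr_threshold", 0.2)),
            bom_label=str(raw.get("bom_label", "BoM")),
            screen_subgroups=tuple(raw.get("screen_subgroups", ())),
            lr_pairs=tuple(tuple(p) for p in raw.get("lr_pairs", ())),
            corr_subgroup=raw.get("corr_subgroup"),
            corr_anchors=tuple(raw.get("corr_anchors", ())),
            corr_targets=tuple(raw.get("corr_targets", ())),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class ReportBundle:
    panel: bulk_de.GenePanel
    de_meta: pd.DataFrame
    de_bom: pd.DataFrame
    dot_profile: pd.DataFrame
    markers: pd.DataFrame
    marker_overlap: dict[str, list[str]]
    condition_screens: dict[str, pd.DataFrame]
    lr_candidates: dict[str, pd.DataFrame]
    lr_summary: pd.DataFrame
    correlations: pd.DataFrame
    enrichment: pd.DataFrame
    manifest: dict[str, Any]


def validate_config(config: PipelineConfig) -> ValidationReport:
    """Check paths, label references, and threshold ranges; never raises."""
    report = ValidationReport()
    err, warn = report.errors.append, report.warnings.append

    for name in ("bulk_counts", "bulk_samples", "sc_cells"):
        path = getattr(config, name)
        if not Path(path).exists():
            err(f"{name} path does not exist: {path}")
    if not Path(config.sc_counts).exists():
        err(f"sc_counts path does not exist: {config.sc_counts}")
    if config.lr_pairs and config.lr_db is None:
        err("lr_pairs requested but no lr_db configured")
    for name in ("lr_db", "gmt"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            err(f"{name} path does not exist: {path}")

    if not (0.0 < config.alpha < 1.0):
        err(f"alpha out of range (0,1): {config.alpha}")
    if not (0.0 <= config.min_ratio < 1.0):
        err(f"min_ratio out of range [0,1): {config.min_ratio}")
    if config.adjustment not in ("none", "bh", "bonferroni"):
        err(f"unknown adjustment: {config.adjustment!r}")
    if config.sc_format not in ("mtx_triplet", "tsv"):
        err(f"unknown sc_format: {config.sc_format!r}")
    if not (-1.0 <= config.high_corr_threshold <= 1.0):
        err(f"high_corr_threshold out of range [-1,1]: {config.high_corr_threshold}")

    if Path(config.sc_cells).exists():
        try:
            cells = sc_core.read_cell_table(config.sc_cells)
            labels = set(cells["subgroup"].unique())
            for sg in config.screen_subgroups:
                if sg not in labels:
                    err(f"screen subgroup not in cell table: {sg!r}")
            for a, b in config.lr_pairs:
                for sg in (a, b):
                    if sg not in labels:
                        err(f"lr pair subgroup not in cell table: {sg!r}")
            if config.corr_subgroup is not None and config.corr_subgroup not in labels:
                err(f"correlation subgroup not in cell table: {config.corr_subgroup!r}")
            if config.bom_label not in set(cells["condition"].unique()):
                warn(f"condition label {config.bom_label!r} absent from cell table")
        except Exception as exc:  # malformed table is an error, not a crash
            err(f"cell table unreadable: {exc}")
    if config.corr_anchors and config.corr_subgroup is None:
        err("corr_anchors given without corr_subgroup")
    return report


def _upper_dedupe(df: pd.DataFrame) -> pd.DataFrame:
    upper = df.index.astype(str).str.upper()
    if upper.duplicated().any():
        dups = upper[upper.duplicated()].unique().tolist()
        logger.warning("gene symbol collisions after upper-casing: %s", dups[:10])
        upper = pd.Index(sc_core._dedupe(list(upper), "gene"))
    out = df.copy()
    out.index = upper
    return out


def run_full(config: PipelineConfig) -> ReportBundle:
    """Execute every configured stage in order and write all outputs.

    Reruns with identical inputs and seed are byte-identical; a stage
    failure aborts with the stage name after writing a partial manifest.
    """
    report = validate_config(config)
    if not report.ok:
        raise ConfigError("; ".join(report.errors))
    for msg in report.warnings:
        logger.warning(msg)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scfg = config.screen_config()
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "stages": {},
        "completed": [],
    }
    stage = "init"

    def save(df: pd.DataFrame, name: str, rows_key: str) -> None:
        df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.10g")
        manifest["stages"][rows_key] = int(len(df))

    try:
        stage = "bulk_de"
        counts = _upper_dedupe(pd.read_csv(config.bulk_counts, sep="\t", index_col=0))
        samples = pd.read_csv(config.bulk_samples, sep="\t", index_col="sample_id", dtype=str)
        samples = samples.loc[counts.columns]
        de_meta = bulk_de.nb_wald_de(counts, samples["meta_status"], "nonMeta", "Meta", config.alpha)
        meta_cols = samples.index[samples["meta_status"] == "Meta"]
        de_bom = bulk_de.nb_wald_de(
            counts.loc[:, meta_cols],
            samples.loc[meta_cols, "bom_status"],
            "nonBoM",
            "BoM",
            config.alpha,
        )
        panel = bulk_de.derive_panel(de_meta, de_bom, config.alpha)
        save(de_meta, "de_meta.tsv", "de_meta_rows")
        save(de_bom, "de_bom.tsv", "de_bom_rows")
        pd.DataFrame({"gene": list(panel)}).to_csv(out_dir / "panel.tsv", sep="\t", index=False)
        (out_dir / "panel.json").write_text(
            json.dumps({"genes": list(panel), "provenance": panel.provenance}, indent=2, sort_keys=True) + "\n"
        )
        manifest["stages"]["panel_genes"] = len(panel)
        manifest["completed"].append(stage)

        stage = "sc_load"
        sc_counts = _upper_dedupe(sc_core.read_counts(config.sc_counts, config.sc_format))
        cells = sc_core.read_cell_table(config.sc_cells)
        cells = cells.loc[cells.index.intersection(sc_counts.columns)]
        expr = sc_core.lognormalize(sc_counts)
        manifest["stages"]["sc_genes"] = int(sc_counts.shape[0])
        manifest["stages"]["sc_cells"] = int(sc_counts.shape[1])
        manifest["completed"].append(stage)

        stage = "profile"
        profile = sc_core.dot_profile(expr, sc_counts, cells, list(panel))
        save(profile, "dot_profile.tsv", "dot_profile_rows")
        markers = sc_core.find_markers(expr, sc_counts, cells)
        save(markers, "markers.tsv", "marker_rows")
        overlap = sc_core.panel_marker_overlap(panel, markers)
        (out_dir / "panel_marker_overlap.json").write_text(
            json.dumps(overlap, indent=2, sort_keys=True) + "\n"
        )
        manifest["completed"].append(stage)

        stage = "condition_screen"
        screens: dict[str, pd.DataFrame] = {}
        for sg in config.screen_subgroups:
            screens[sg] = screen_condition_genes(expr, sc_counts, cells, sg, scfg)
            save(screens[sg], f"screen_{sg}.tsv", f"screen_{sg}_rows")
        manifest["completed"].append(stage)

        stage = "lr_screen"
        lr_tables: dict[str, pd.DataFrame] = {}
        summaries = []
        if config.lr_pairs:
            db = lr_screen.read_lr_db(config.lr_db)
            for a, b in config.lr_pairs:
                key = f"{a}__{b}"
                lr_tables[key] = lr_screen.screen_lr(expr, sc_counts, cells, a, b, db, scfg)
                save(lr_tables[key], f"lr_{key}.tsv", f"lr_{key}_rows")
                summaries.append(
                    lr_screen.lr_summary(lr_tables[key], expr, sc_counts, cells, scfg.bom_label)
                )
        lr_sum = (
            pd.concat(summaries, ignore_index=True)
            if summaries
            else pd.DataFrame(
                columns=["ligand", "receptor", "gene", "role", "subgroup",
                         "condition", "mean_expr", "z_expr", "pos_ratio"]
            )
        )
        save(lr_sum, "lr_summary.tsv", "lr_summary_rows")
        manifest["completed"].append(stage)

        stage = "correlate"
        if config.corr_subgroup and config.corr_anchors and config.corr_targets:
            corr = correlate.subgroup_gene_correlations(
                expr,
                cells,
                config.corr_subgroup,
                list(config.corr_anchors),
                list(config.corr_targets),
                correlate.CorrConfig(
                    alpha=config.alpha, high_corr_threshold=config.high_corr_threshold
                ),
                counts=sc_counts,
            )
        else:
            corr = pd.DataFrame(columns=correlate.RESULT_COLUMNS)
        save(corr, "correlations.tsv", "correlation_rows")
        manifest["completed"].append(stage)

        stage = "enrich"
        if config.gmt and len(panel):
            collection = enrich.read_gmt(config.gmt)
            enr = enrich.ora_hypergeometric(set(panel), collection, set(counts.index))
            enr = enr.assign(overlap_genes=enr["overlap_genes"].map(";".join))
        else:
            enr = pd.DataFrame(columns=enrich.RESULT_COLUMNS)
        save(enr, "enrichment.tsv", "enrichment_rows")
        manifest["completed"].append(stage)
    except ConfigError:
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return ReportBundle(
        panel=panel,
        de_meta=de_meta,
        de_bom=de_bom,
        dot_profile=profile,
        markers=markers,
        marker_overlap=overlap,
        condition_screens=screens,
        lr_candidates=lr_tables,
        lr_summary=lr_sum,
        correlations=corr,
        enrichment=enr,
        manifest=manifest,
    )
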