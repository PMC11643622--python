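"""End-to-end orchestration: QC -> normalize -> classify -> thresholds ->
calls -> patterns -> dosage -> subtypes -> DE -> ORA (-> axis profiles).

Every stage is a pure function of its inputs and the configuration, so
two runs with the same config and input files produce byte-identical
output tables. A JSON run manifest records parameters, versions, the
seed, and per-stage row counts.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from vrcall import axis_profile as ap
from vrcall import coexpression as cx
from vrcall import diffexp_enrich as de_mod
from vrcall import io_catalog as io
from vrcall import preprocess as pp
from vrcall import threshold_detect as td
from vrcall.errors import ConfigurationError, VrcallError

logger = logging.getLogger("vrcall")


def metadata_version() -> str:
    try:
        from importlib.metadata import version

        return version("vrcall")
    except Exception:  # pragma: no cover - uninstalled source tree
        return "unknown"


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    Defaults follow the reference analysis contract: 200-7000 detected
    genes, scale factor 10,000, pinned thresholds 2.5 (V1R) / 1.25 (V2R,
    H2-Mv) available as fallbacks, min_cells 2 for pattern filtering,
    and DE significance at |log2FC| > 1 with Bonferroni-adjusted
    p < 1e-6.
    """

    counts_path: str = ""
    counts_format: str = "mtx_triplet"
    catalog_path: str = ""
    labels_path: str | None = None
    gene_sets_path: str | None = None
    profiles_path: str | None = None
    out_dir: str = "vrcall_out"
    seed: int = 0
    # qc
    min_genes: int = 200
    max_genes: int = 7000
    max_pct_mito: float = 20.0
    drop_hbb: bool = True
    # normalization
    scale: float = 10000.0
    # classification
    marker_cut: float = 1.0
    role_map: dict[str, str] = field(default_factory=dict)
    # thresholds
    threshold_mode: str = "auto"  # auto | fixed
    fixed_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(td.DEFAULT_THRESHOLDS)
    )
    min_separation: float = 0.2
    threshold_cells: str = "mature"  # mature | all
    # coexpression
    min_cells: int = 2
    pattern_scopes: tuple = ("V1R", "ABD", "C", "H2Mv", ("ABD", "C", "H2Mv"))
    control_gene_gnao1: str = "Gnao1"
    control_gene_gnai2: str = "Gnai2"
    # differential expression
    de_group_a: str = "mature_Gnao1"
    de_group_b: str = "mature_Gnai2"
    lfc_cut: float = 1.0
    alpha: float = 1e-6
    min_pct: float = 0.01
    # ORA
    ora_alpha: float = 0.05
    # axis profiles
    span: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write(df: pd.DataFrame | pd.Series, path: Path, manifest: dict, stage: str) -> None:
    io.write_table(df, path)
    manifest["stages"][stage] = {"rows": int(len(df)), "file": path.name}
    logger.info("stage %-12s -> %s (%d rows)", stage, path.name, len(df))


def run_all(
    config: PipelineConfig,
    counts: io.CountMatrix | None = None,
    catalog: io.GeneCatalog | None = None,
    labels: pd.Series | None = None,
) -> Path:
    """Run every applicable stage; returns the output directory.

    Inputs may be passed in memory (for tests and library use) or loaded
    from the configured paths. Externally supplied labels bypass the
    marker-based classifier.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": metadata_version(),
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not k.endswith("_path")
        },
        "stages": {},
    }

    stage = "load"
    try:
        if counts is None:
            counts = io.load_counts(config.counts_path, config.counts_format)
        if catalog is None:
            catalog = io.load_gene_catalog(config.catalog_path)
        if labels is None and config.labels_path:
            labels = io.load_labels(config.labels_path)

        stage = "qc"
        qc = pp.compute_qc(counts, catalog)
        _write(qc, out / "qc.tsv", manifest, stage)

        stage = "filter"
        filtered = pp.filter_cells(
            counts,
            qc,
            min_genes=config.min_genes,
            max_genes=config.max_genes,
            drop_hbb=config.drop_hbb,
            max_pct_mito=config.max_pct_mito,
        )
        manifest["stages"][stage] = {
            "cells_in": counts.n_cells,
            "cells_kept": filtered.n_cells,
        }
        logger.info("stage filter: %d -> %d cells", counts.n_cells, filtered.n_cells)

        stage = "normalize"
        norm = pp.lognormalize(filtered, scale=config.scale)

        stage = "classify"
        if labels is not None:
            labels = labels.reindex(norm.barcodes).fillna("other")
        cell_labels = pp.classify_cells(
            norm,
            catalog,
            labels=labels,
            marker_cut=config.marker_cut,
            role_map=config.role_map or None,
        )
        _write(cell_labels, out / "labels.tsv", manifest, stage)

        mature_gnao1 = [b for b in norm.barcodes if cell_labels.get(b) == "mature_Gnao1"]
        mature_gnai2 = [b for b in norm.barcodes if cell_labels.get(b) == "mature_Gnai2"]
        mature = mature_gnao1 + mature_gnai2

        stage = "thresholds"
        cells_for_thr = mature if (config.threshold_cells == "mature" and mature) else None
        thresholds = td.detect_family_thresholds(
            norm,
            catalog,
            cells=cells_for_thr,
            defaults=config.fixed_thresholds,
            mode=config.threshold_mode,
            min_separation=config.min_separation,
        )
        thr_df = pd.DataFrame(
            [
                {
                    "family": fam,
                    "threshold": t.threshold,
                    "kde_bandwidth": t.kde_bandwidth,
                    "n_values": t.n_values,
                    "modes_found": t.modes_found,
                    "fallback_used": t.fallback_used,
                }
                for fam, t in thresholds.items()
            ]
        )
        _write(thr_df, out / "thresholds.tsv", manifest, stage)

        stage = "calls"
        calls = cx.call_receptors(norm, catalog, thresholds, cells=mature or None)
        _write(calls.to_flat_frame(), out / "calls.tsv", manifest, stage)

        stage = "patterns"
        pattern_frames = []
        for scope in config.pattern_scopes:
            scope_key = list(scope) if isinstance(scope, (list, tuple)) else scope
            df = cx.enumerate_patterns(calls, scope_key, min_cells=config.min_cells)
            if len(df):
                df = df.assign(
                    gene_combination=df["gene_combination"].map(lambda t: ",".join(t))
                )
            pattern_frames.append(df)
        patterns = pd.concat(pattern_frames, ignore_index=True)
        _write(patterns, out / "patterns.tsv", manifest, stage)

        stage = "dosage"
        dosage_frames = []
        for scope, ctrl, cells in (
            ("C", config.control_gene_gnao1, mature_gnao1),
            ("ABD", config.control_gene_gnao1, mature_gnao1),
            ("H2Mv", config.control_gene_gnao1, mature_gnao1),
            ("V1R", config.control_gene_gnai2, mature_gnai2),
        ):
            if not cells:
                continue
            scoped = cx.ReceptorCalls(calls.table.loc[cells])
            summary, _ = cx.dosage_analysis(norm, scoped, catalog, scope, ctrl)
            dosage_frames.append(summary.assign(family_scope=scope))
        if dosage_frames:
            _write(pd.concat(dosage_frames, ignore_index=True), out / "dosage.tsv", manifest, stage)

        stage = "subtypes"
        if mature_gnao1:
            subtype_classes, subtype_summary = cx.classify_gnao1_subsets(
                calls, cells=mature_gnao1
            )
            _write(subtype_classes, out / "subtypes.tsv", manifest, stage)
            manifest["stages"]["subtypes"].update(subtype_summary)

        stage = "de"
        if len(mature_gnao1) >= 3 and len(mature_gnai2) >= 3:
            group_a = [b for b in norm.barcodes if cell_labels.get(b) == config.de_group_a]
            group_b = [b for b in norm.barcodes if cell_labels.get(b) == config.de_group_b]
            de = de_mod.wilcoxon_de(
                norm,
                group_a,
                group_b,
                min_pct=config.min_pct,
                lfc_cut=config.lfc_cut,
                alpha=config.alpha,
            )
            _write(de, out / "de.tsv", manifest, stage)
            significant = de_mod.filter_significant(de, config.lfc_cut, config.alpha)
            _write(significant, out / "de_significant.tsv", manifest, "de_significant")

            stage = "ora"
            if config.gene_sets_path:
                gene_sets = de_mod.read_gmt(config.gene_sets_path)
                query = list(
                    significant.index[
                        (significant["direction"] == "A_enriched")
                        & (significant["log2FC"] > config.lfc_cut)
                    ]
                )
                universe = list(de.index[de["tested"]])
                ora = de_mod.hypergeom_ora(query, gene_sets, universe)
                ora["enriched"] = ora["p_value"] < config.ora_alpha
                _write(ora, out / "ora.tsv", manifest, stage)

        stage = "profile"
        if config.profiles_path:
            profiles = ap.load_profiles(config.profiles_path)
            normed = [ap.normalize_profile(p) for p in profiles]
            ap.write_profiles(normed, out / "profiles_normalized.tsv")
            channels = sorted({c for p in normed for c in p.channels})
            curves = {}
            for ch in channels:
                grid, fit = ap.fit_trendline(normed, ch, span=config.span)
                curves[ch] = fit
            trend = pd.DataFrame({"position": grid, **curves})
            _write(trend, out / "profile_trends.tsv", manifest, stage)
    except VrcallError as err:
        raise VrcallError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
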