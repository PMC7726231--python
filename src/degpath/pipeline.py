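"""End-to-end orchestration: filter → normalize → test → enrich → cluster.

:func:`run_pipeline` wires the stages together from one
:class:`PipelineConfig`, writes every stage output as TSV/Newick, and records
a JSON manifest (config, input checksums, stage row counts, output
checksums). Runs are deterministic: identical config and inputs give
byte-identical outputs and a stable manifest checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import clustering, diffexpr, enrichment, preprocess, protein_corr
from .errors import ConfigurationError, ValidationError
from .matrix_io import (
    read_design,
    read_expression_matrix,
    read_gmt,
    filter_by_quality,
    write_expression_matrix,
    write_results_table,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds, options and paths of a pipeline run in one place."""

    matrix: str
    design: str
    gmt: str
    outdir: str
    quality: str | None = None
    densitometry: str | None = None
    transport: str | None = None
    control_group: str = "scramble"
    densitometry_control: str = "AGA"
    alpha: float = 0.05
    z_threshold: float = 2.0
    quality_threshold: float = 0.95
    background: str | int = "auto"  # "auto" = genes surviving the filter
    test_variant: str = "student"
    metric: str = "correlation"
    linkage: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be > 0")
        if not (0.0 <= self.quality_threshold <= 1.0):
            raise ValidationError("quality_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written as JSON).

    Stage order: quality filter, median/log2 normalization, per-gene t-tests
    and the DEG partition, directional set enrichment against the measured
    universe, hierarchical clustering of the DEGs, and — when densitometry
    and transport tables are given — the protein-correlation stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "inputs": {}, "stages": {}, "outputs": {}}
    t0 = time.perf_counter()

    inputs = {"matrix": cfg.matrix, "design": cfg.design, "gmt": cfg.gmt}
    if cfg.quality:
        inputs["quality"] = cfg.quality
    if cfg.densitometry:
        inputs["densitometry"] = cfg.densitometry
    if cfg.transport:
        inputs["transport"] = cfg.transport
    for name, p in inputs.items():
        manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    try:
        # --- filter ---------------------------------------------------
        m = read_expression_matrix(cfg.matrix, cfg.quality)
        n_before = m.n_genes
        if m.quality is not None:
            m = filter_by_quality(m, cfg.quality_threshold)
        manifest["stages"]["filter"] = {
            "genes_in": n_before, "genes_retained": m.n_genes,
        }
        logger.info("filter: %d of %d genes retained", m.n_genes, n_before)

        # --- normalize ------------------------------------------------
        norm, report = preprocess.normalize(m)
        write_expression_matrix(norm, outdir / "normalized.tsv")
        report_df = report.per_sample_median_before.to_frame().join(
            [report.offset_applied, report.per_sample_median_after])
        report_df.rename_axis("sample_id").to_csv(
            outdir / "normalization_report.tsv", sep="\t",
            float_format="%.8g", lineterminator="\n")
        manifest["stages"]["normalize"] = {"samples": norm.n_samples}

        # --- differential expression ----------------------------------
        design = read_design(cfg.design, control=cfg.control_group)
        results, partition = diffexpr.run_differential(
            norm, design, alpha=cfg.alpha, variant=cfg.test_variant)
        write_results_table(results, outdir / "deg_table.tsv")
        write_results_table(
            [{"n_up": partition.n_up, "n_down": partition.n_down,
              "n_total": partition.n_total, "alpha": partition.alpha}],
            outdir / "deg_summary.tsv")
        manifest["stages"]["deg"] = {
            "n_up": partition.n_up, "n_down": partition.n_down,
            "n_total": partition.n_total,
        }
        logger.info("deg: %d up, %d down of %d genes",
                    partition.n_up, partition.n_down, norm.n_genes)

        # --- enrichment -----------------------------------------------
        sets = read_gmt(cfg.gmt)
        universe = norm.gene_ids
        if cfg.background != "auto":
            manifest["stages"].setdefault("enrich", {})["fixed_background"] = int(cfg.background)
        enr = enrichment.enrich_collection(
            partition, sets, universe, z_threshold=cfg.z_threshold)
        rows = [{
            "set": e.set_name, "direction": e.query.direction,
            "N": e.query.N, "R": e.query.R, "n_measured": e.query.n,
            "n_catalog": e.n_catalog, "r": e.query.r, "n_diff": e.n_diff,
            "z": e.z, "significant": e.significant,
        } for e in enr]
        write_results_table(rows, outdir / "enrichment.tsv",
                            columns=["set", "direction", "N", "R", "n_measured",
                                     "n_catalog", "r", "n_diff", "z", "significant"])
        manifest["stages"].setdefault("enrich", {}).update({
            "n_sets_scored": len({e.set_name for e in enr}),
            "n_significant": sum(e.significant for e in enr),
            "background_N": len(universe),
        })

        # --- clustering -----------------------------------------------
        if partition.n_total >= 1:
            ordering = clustering.hierarchical_order(
                norm, partition, metric=cfg.metric, linkage=cfg.linkage)
            clustering.ordered_matrix(norm, ordering).to_csv(
                outdir / "heatmap_matrix.tsv", sep="\t",
                float_format="%.8g", lineterminator="\n", index_label="gene_id")
            if ordering.gene_tree is not None:
                deg_ids = list(partition.down) + list(partition.up)
                (outdir / "gene_tree.nwk").write_text(
                    clustering.to_newick(ordering.gene_tree, deg_ids) + "\n")
                (outdir / "sample_tree.nwk").write_text(
                    clustering.to_newick(ordering.sample_tree,
                                         norm.sample_ids) + "\n")
            manifest["stages"]["cluster"] = {"n_genes": partition.n_total}
        else:
            manifest["stages"]["cluster"] = {"n_genes": 0, "skipped": True}

        # --- protein correlation (optional) ---------------------------
        if cfg.densitometry and cfg.transport:
            import pandas as pd

            dens = pd.read_csv(cfg.densitometry, sep="\t")
            transport = pd.read_csv(cfg.transport, sep="\t")
            rel = protein_corr.normalize_densitometry(
                dens, control_group=cfg.densitometry_control)
            cmp_rows, corr_rows = [], []
            for target, sub in rel.groupby("target"):
                gc = protein_corr.group_compare(
                    sub["relative_expression"], sub["group"])
                cmp_rows.append({
                    "target": target,
                    **{f"mean_{g}": v for g, v in gc.means.items()},
                    **{f"sem_{g}": v for g, v in gc.sems.items()},
                    "t_stat": gc.t_stat, "p_value": gc.p_value,
                })
                paired = protein_corr.pair_by_subject(
                    sub, transport, "relative_expression", "uptake")
                res = protein_corr.correlate(
                    paired["relative_expression"], paired["uptake"],
                    pair=(str(target), "uptake"))
                corr_rows.append({
                    "pair": f"{target}~uptake", "r_pearson": res.r_pearson,
                    "n_subjects": res.n_subjects, "p_value": res.p_value,
                })
            write_results_table(cmp_rows, outdir / "group_comparison.tsv")
            write_results_table(corr_rows, outdir / "correlations.tsv")
            manifest["stages"]["correlate"] = {"n_targets": len(cmp_rows)}
    except Exception as exc:
        manifest["failed_stage"] = type(exc).__name__
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise

    for out in sorted(outdir.iterdir()):
        if out.name != "manifest.json":
            manifest["outputs"][out.name] = _sha256(out)
    manifest["elapsed_s"] = round(time.perf_counter() - t0, 3)
    manifest_for_checksum = {k: v for k, v in manifest.items() if k != "elapsed_s"}
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(manifest_for_checksum, sort_keys=True).encode()).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
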