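"""End-to-end pipeline: expand -> annotate/filter -> tag -> predict -> survive.

Each stage reads flat files (or the previous stage's TSV), writes its own
result sheet into the output directory, and logs input/output record
counts into the run manifest.  Stages are plain functions over the library
modules; the manifest makes a run resumable and auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, genotypes, ld, network, prediction, survival

logger = logging.getLogger("netsnp")

__all__ = ["RunConfig", "run_pipeline", "write_result_sheet"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: str
    # inputs
    proteins: list[str] = field(default_factory=list)
    pathway_names: list[str] = field(default_factory=list)
    pathway_db: str | None = None
    ppi: str | None = None
    aliases: str | None = None
    snp_annotations: str | None = None
    genotypes: str | None = None
    confidence: str | None = None
    clinical: str | None = None
    predictor_tables: dict[str, str] = field(default_factory=dict)
    # parameters
    filter_mode: str = "any_transcript"
    r2_threshold: float = 0.8
    r2_method: str = "em"
    qc: survival.QCParams = field(default_factory=survival.QCParams)
    seed: int | None = None

    def validate(self) -> None:
        if not self.proteins and not self.pathway_names:
            raise ValueError("need a protein list or a pathway-name list")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0,1]")
        if self.r2_method not in {"em", "allelic_corr"}:
            raise ValueError(f"unknown r2 method {self.r2_method!r}")
        if self.filter_mode not in {"any_transcript", "first_transcript"}:
            raise ValueError(f"unknown filter mode {self.filter_mode!r}")
        for name, path in [
            ("pathway_db", self.pathway_db),
            ("ppi", self.ppi),
            ("snp_annotations", self.snp_annotations),
            ("genotypes", self.genotypes),
            ("clinical", self.clinical),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def write_result_sheet(df: pd.DataFrame, path: str | Path) -> None:
    """Stable-order, header-first, UTF-8 TSV with plain decimal numbers."""
    import numpy as np

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(
                lambda x: "" if pd.isna(x) else np.format_float_positional(x, trim="-")
            )
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def _stage(manifest: dict, name: str, n_in: int, n_out: int, outfile: str | None) -> None:
    logger.info("stage %-10s in=%d out=%d -> %s", name, n_in, n_out, outfile or "-")
    manifest["stages"].append({"stage": name, "n_in": n_in, "n_out": n_out, "output": outfile})


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all configured stages in order; returns the run manifest.

    The prediction stage is skipped with a warning when no predictor tables
    are configured; the survival stage is skipped when genotype or clinical
    inputs are absent.  Any stage failure aborts with the stage name in the
    raised error; prior outputs remain on disk.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(cfg.to_json())
    manifest: dict = {"stages": [], "counts": {}}

    stage = "expand"
    try:
        pathways = network.load_pathway_db(cfg.pathway_db) if cfg.pathway_db else []
        edges = network.load_ppi(cfg.ppi) if cfg.ppi else []
        aliases = network.load_aliases(cfg.aliases) if cfg.aliases else {}
        if cfg.proteins:
            symbols, _ = network.resolve_aliases(cfg.proteins, aliases)
            focal = network.expand_from_proteins(symbols, pathways, edges)
        else:
            focal = network.expand_from_pathways(cfg.pathway_names, pathways)
        focal_df = network.focal_to_frame(focal)
        write_result_sheet(focal_df, outdir / "focal_genes.tsv")
        _stage(manifest, stage, len(cfg.proteins) + len(cfg.pathway_names), len(focal), "focal_genes.tsv")
        manifest["counts"]["focal_genes"] = len(focal)
        dist = network.source_distribution(focal)
        write_result_sheet(dist.rename_axis("source").reset_index(), outdir / "source_distribution.tsv")

        stage = "annotate"
        central: list[annotation.CentralSNP] = []
        if cfg.snp_annotations:
            records = annotation.load_snp_table(cfg.snp_annotations)
            focal_symbols = {f.gene for f in focal}
            records = [r for r in records if r.gene in focal_symbols]
            central = annotation.filter_central(records, mode=cfg.filter_mode)
            cdf = pd.DataFrame(
                {
                    "rsid": [c.rsid for c in central],
                    "gene": [c.gene for c in central],
                    "retained": [";".join(t.value for _, t in c.retained_consequences) for c in central],
                }
            )
            write_result_sheet(cdf, outdir / "central_snps.tsv")
            _stage(manifest, stage, len(records), len(central), "central_snps.tsv")
            manifest["counts"]["annotated_snps"] = len(records)
            manifest["counts"]["central_snps"] = len(central)

        stage = "tag"
        links: list[ld.TagLink] = []
        gm = None
        if cfg.genotypes:
            gm = genotypes.load_genotype_tsv(cfg.genotypes, cfg.confidence)
            central_ids = {c.rsid for c in central}
            candidates = set(gm.snps)
            links, _ = ld.select_tags(central_ids, candidates, gm, cfg.r2_threshold, cfg.r2_method)
            write_result_sheet(ld.links_to_frame(links), outdir / "tag_links.tsv")
            n_c, n_t, n_b, n_u = ld.snp_universe(central_ids, {l.tag for l in links})
            manifest["counts"]["tag_links"] = len(links)
            manifest["counts"]["snp_universe"] = {
                "n_central": n_c, "n_tags": n_t, "n_both": n_b, "n_union": n_u,
            }
            _stage(manifest, stage, len(central_ids), len(links), "tag_links.tsv")

        stage = "predict"
        if cfg.predictor_tables:
            rows: list[prediction.PredictorRow] = []
            for pname, ppath in cfg.predictor_tables.items():
                rows.extend(prediction.load_predictor_table(ppath, pname))
            agg = prediction.aggregate(rows)
            write_result_sheet(prediction.aggregate_to_frame(agg), outdir / "predictions.tsv")
            cset = prediction.consensus_set(agg)
            manifest["counts"]["consensus_functional"] = len(cset)
            _stage(manifest, stage, len(rows), len(agg), "predictions.tsv")
        else:
            logger.warning("no predictor tables configured; prediction stage skipped")
            _stage(manifest, stage, 0, 0, None)

        stage = "survive"
        if gm is not None and cfg.clinical:
            clinical = survival.load_clinical(cfg.clinical)
            snr = clinical["snr"] if "snr" in clinical.columns else None
            gm_qc, qc_report = survival.qc_genotypes(gm, cfg.qc, snr)
            write_result_sheet(qc_report.to_frame(), outdir / "qc_report.tsv")
            results, untestable = survival.screen(set(gm_qc.snps), gm_qc, clinical, cfg.qc)
            sheet = survival.results_to_frame(results, links)
            write_result_sheet(sheet, outdir / "survival_results.tsv")
            if untestable:
                write_result_sheet(pd.DataFrame({"rsid": untestable}), outdir / "untestable_snps.tsv")
            manifest["counts"]["snps_tested"] = len(results)
            manifest["counts"]["snps_significant"] = int(sheet["significant"].sum()) if len(sheet) else 0
            _stage(manifest, stage, gm_qc.n_snps, len(results), "survival_results.tsv")

            stage = "map_to_central"
            central_ids = {c.rsid for c in central}
            direct, tagged, n_total = survival.map_to_central(results, links, central_ids)
            mdf = pd.DataFrame(
                {
                    "central_snp": sorted(direct | tagged),
                    "direct_hit": [int(r in direct) for r in sorted(direct | tagged)],
                    "tagged_hit": [int(r in tagged) for r in sorted(direct | tagged)],
                }
            )
            write_result_sheet(mdf, outdir / "central_hits.tsv")
            manifest["counts"]["central_hits"] = {
                "direct": len(direct), "tagged": len(tagged), "total": n_total,
            }
            _stage(manifest, stage, len(results), n_total, "central_hits.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
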