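"""Config-driven end-to-end orchestration.

``run_all`` executes simulate/load -> DMP ranking -> cross-group validation
-> VMP classification -> enrichment, writing per-stage TSVs plus a single
machine-readable JSON run report. Every stage is a pure function of
(inputs, config, seed), so re-running a config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field

from . import __version__
from .datamodel import BetaMatrix, GeneSetCollection, ProbeAnnotation, TwinDesign
from .dmp import DmpConfig, annotate_dmps, rank_dmps, top_dmps
from .dmp_validate import validate_dmps
from .enrich import hypergeometric_enrichment, map_probes_to_genes
from .errors import StageError, TwinMethError
from .io import (
    read_beta_matrix,
    read_gene_sets,
    read_probe_annotation,
    read_twin_design,
)
from .simulate import SimConfig, simulate
from .vmp import (
    VmpConfig,
    abs_diff_matrix,
    classify_vmps,
    exceedance_fraction,
    feature_category_summary,
    group_medians,
)

logger = logging.getLogger(__name__)


class InputPaths(BaseModel):
    beta: str
    design: str
    annotation: str | None = None


class SimulateSection(BaseModel):
    n_pairs: dict[str, int] = {"concordant": 4, "discordant": 6, "healthy": 7}
    n_probes: int = 10_000
    pair_noise_sd: float = 0.02
    baseline_low_mean: float = 0.15
    baseline_high_mean: float = 0.85
    baseline_sd: float = 0.05
    baseline_high_weight: float = 0.5
    baseline_bounds: tuple[float, float] = (0.01, 0.99)
    n_dmp: int = 0
    dmp_effect: float = -0.08
    n_vmp: dict[str, int] = {"concordant": 0, "discordant": 0, "healthy": 0}
    vmp_magnitude: float = 0.3


class RunConfig(BaseModel):
    """Top-level pipeline configuration (YAML-serializable)."""

    seed: int = 0
    output_dir: str = "twinmeth_out"
    input: InputPaths | None = None
    simulate: SimulateSection | None = None
    top_k: int = 10
    vmp_threshold: float = 0.1
    alpha_level: float = 0.05
    gmt: str | None = None
    write_inputs: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


class ExceedanceReport(BaseModel):
    fraction: float
    numerator: int
    denominator: int


class TopDmpEntry(BaseModel):
    probe_id: str
    p_value: float
    mean_delta: float
    combined_score: float
    rank: int
    validated_vs_concordant: bool
    validated_vs_healthy: bool


class RunReport(BaseModel):
    """Schema of the machine-readable run report (bundled as JSON schema)."""

    package_version: str
    config_hash: str
    seed: int
    n_probes_input: int
    n_samples: int
    group_pair_counts: dict[str, int]
    n_probes_dmp: int
    n_degenerate_probes: int
    top_dmps: list[TopDmpEntry]
    venn_counts: dict[str, int]
    exceedance: ExceedanceReport
    feature_category_percentages: dict[str, dict[str, float]]
    enrichment_queries: dict[str, int] = Field(
        default_factory=dict, description="query gene-list sizes per enriched list"
    )
    outputs: dict[str, str]


def config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _load_inputs(
    cfg: RunConfig,
) -> tuple[BetaMatrix, TwinDesign, ProbeAnnotation | None]:
    if (cfg.input is None) == (cfg.simulate is None):
        raise StageError("load", "exactly one of 'input' or 'simulate' must be set")
    if cfg.simulate is not None:
        sim_cfg = SimConfig(seed=cfg.seed, **cfg.simulate.model_dump())
        result = simulate(sim_cfg)
        return result.beta, result.design, result.annotation
    paths = cfg.input
    beta = read_beta_matrix(paths.beta)
    design = read_twin_design(paths.design)
    ann = read_probe_annotation(paths.annotation) if paths.annotation else None
    return beta, design, ann


def run_all(cfg: RunConfig) -> RunReport:
    """Execute all stages; returns the report (also written as JSON)."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
                logger.info("stage %s: done", name)

        return _Ctx()

    with _stage("load"):
        beta, design, annotation = _load_inputs(cfg)
        if cfg.write_inputs:
            from .io import write_beta_matrix, write_probe_annotation, write_twin_design

            write_beta_matrix(beta, out_dir / "beta.tsv")
            write_twin_design(design, out_dir / "design.csv")
            outputs["beta"] = "beta.tsv"
            outputs["design"] = "design.csv"
            if annotation is not None:
                write_probe_annotation(annotation, out_dir / "annotation.csv")
                outputs["annotation"] = "annotation.csv"

    with _stage("dmp"):
        dmp_cfg = DmpConfig(top_k=cfg.top_k)
        records = rank_dmps(beta, design, dmp_cfg)
        annotated = annotate_dmps(records, annotation)
        annotated.to_csv(out_dir / "dmp.tsv", sep="\t", index=False)
        outputs["dmp"] = "dmp.tsv"
        top = top_dmps(records, dmp_cfg)

    with _stage("dmp_validate"):
        validation = validate_dmps(
            beta, design, top["probe_id"].tolist(), alpha_level=cfg.alpha_level
        )
        validation.to_csv(out_dir / "dmp_validation.tsv", sep="\t", index=False)
        outputs["dmp_validation"] = "dmp_validation.tsv"

    with _stage("vmp"):
        vmp_cfg = VmpConfig(threshold=cfg.vmp_threshold)
        absdiff = abs_diff_matrix(beta, design)
        medians = group_medians(absdiff, design)
        classification, venn_counts = classify_vmps(medians, vmp_cfg)
        exceed = exceedance_fraction(absdiff, vmp_cfg)
        feature_pcts = feature_category_summary(classification, annotation)
        vmp_table = medians.reset_index().merge(classification, on="probe_id")
        vmp_table.to_csv(out_dir / "vmp.tsv", sep="\t", index=False)
        outputs["vmp"] = "vmp.tsv"
        summary = {
            "venn_counts": venn_counts,
            "exceedance": exceed._asdict(),
            "feature_category_percentages": feature_pcts,
            "threshold": cfg.vmp_threshold,
        }
        with open(out_dir / "vmp_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        outputs["vmp_summary"] = "vmp_summary.json"

    enrichment_queries: dict[str, int] = {}
    if cfg.gmt is not None and annotation is not None:
        with _stage("enrich"):
            sets = read_gene_sets(cfg.gmt)
            universe = sets.universe or annotation.all_genes()
            queries: dict[str, list[str]] = {}
            for label in ("concordant-only", "discordant-only", "healthy-only"):
                probes = classification.loc[
                    classification["exclusivity"] == label, "probe_id"
                ].tolist()
                queries[f"vmp_{label}"] = map_probes_to_genes(probes, annotation)
            queries["dmp_top"] = map_probes_to_genes(
                top["probe_id"].tolist(), annotation
            )
            for name, genes in queries.items():
                enrichment_queries[name] = len(genes)
                if not genes:
                    logger.info("enrich: skipping %s (no genes)", name)
                    continue
                try:
                    result = hypergeometric_enrichment(genes, sets, universe)
                except TwinMethError as exc:
                    logger.warning("enrich: %s skipped: %s", name, exc)
                    continue
                fname = f"enrichment_{name}.tsv"
                result.to_csv(out_dir / fname, sep="\t", index=False)
                outputs[f"enrichment_{name}"] = fname

    with _stage("report"):
        top_entries = []
        val_by_probe = validation.set_index("probe_id")
        for _, rec in top.iterrows():
            v = val_by_probe.loc[rec["probe_id"]]
            top_entries.append(
                TopDmpEntry(
                    probe_id=rec["probe_id"],
                    p_value=float(rec["p_value"]),
                    mean_delta=float(rec["mean_delta"]),
                    combined_score=float(rec["combined_score"]),
                    rank=int(rec["rank"]),
                    validated_vs_concordant=bool(v["validated_vs_concordant"]),
                    validated_vs_healthy=bool(v["validated_vs_healthy"]),
                )
            )
        report = RunReport(
            package_version=__version__,
            config_hash=config_hash(cfg),
            seed=cfg.seed,
            n_probes_input=beta.n_probes,
            n_samples=beta.n_samples,
            group_pair_counts=design.group_pair_counts(),
            n_probes_dmp=len(records),
            n_degenerate_probes=int(records["degenerate"].sum()),
            top_dmps=top_entries,
            venn_counts=venn_counts,
            exceedance=ExceedanceReport(**exceed._asdict()),
            feature_category_percentages=feature_pcts,
            enrichment_queries=enrichment_queries,
            outputs=outputs,
        )
        with open(out_dir / "run_report.json", "w") as fh:
            fh.write(report.model_dump_json(indent=2))
    return report
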