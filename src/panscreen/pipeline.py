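"""End-to-end orchestration: prevalence -> lineage test -> annotation
scoring -> co-occurrence/ordination, with TSV outputs and a static HTML
report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import RuleTable, annotate_gene, load_rule_table, range_score
from .cooccurrence import MIN_GENES, heatmap_order, jaccard_matrix, ordinate
from .data_io import (
    AbundanceMatrix,
    AnnotationTable,
    LineageTable,
    PangenomeMap,
    SampleMetadata,
    align_samples,
    read_annotations,
    read_lineages,
    read_matrix,
    read_metadata,
    read_pangenome_map,
)
from .lineage import LineageTestConfig, reports_to_frame, run_lineage_test
from .prevalence import (
    differential_prevalence_pooled,
    presence_from_copynum,
    results_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run."""

    species_relabund: Path
    gene_reads: Path
    lineages: Path
    metadata: Path
    pangenome_map: Path
    out_dir: Path
    gene_presence: Path | None = None
    gene_copynum: Path | None = None
    annotations: Path | None = None
    rule_table: Path | None = None
    alpha: float = 0.05
    presence_threshold: float = 0.35
    min_detected: int = 5
    flag_rank_threshold: int = 50
    per_species_adjust: bool = False
    ordination_methods: tuple[str, ...] = ("NMDS", "UMAP", "PCoA")
    umap_n_neighbors: int | None = None
    umap_min_dist: float = 0.1
    seed: int = 42
    make_figures: bool = True

    def validate(self) -> None:
        for name in (
            "species_relabund",
            "gene_reads",
            "lineages",
            "metadata",
            "pangenome_map",
            "gene_presence",
            "gene_copynum",
            "annotations",
            "rule_table",
        ):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: no such file: {path}")
        if self.gene_presence is None and self.gene_copynum is None:
            raise ValueError(
                "need a gene presence matrix or a copy-number matrix to derive it"
            )

    def config_hash(self) -> str:
        payload = {
            k: str(v)
            for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    prevalence: pd.DataFrame
    lineage: pd.DataFrame
    significant_genes: list[str]
    flagged_genes: list[str]
    ordinations: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    report_path: Path | None = None


def _write_log(config: RunConfig, out_dir: Path) -> None:
    log = {
        "tool": "panscreen",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full flagging workflow and write the report bundle."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        relabund = read_matrix(config.species_relabund, "species_relabund")
        reads = read_matrix(config.gene_reads, "gene_reads")
        metadata = read_metadata(config.metadata)
        lineages = read_lineages(config.lineages)
        pmap = read_pangenome_map(config.pangenome_map)
        if config.gene_presence is not None:
            presence = read_matrix(config.gene_presence, "gene_presence")
        else:
            copynum = read_matrix(config.gene_copynum, "gene_copynum")
            presence = presence_from_copynum(copynum, config.presence_threshold)
        annotations = (
            read_annotations(config.annotations) if config.annotations else None
        )
        rules = load_rule_table(config.rule_table)

        stage = "align samples"
        relabund, reads, presence = align_samples(
            [relabund, reads, presence], metadata
        )

        stage = "differential prevalence"
        presence_by_species: dict[str, AbundanceMatrix] = {}
        for species_id in pmap.species_ids:
            genes = [
                g for g in presence.feature_ids
                if pmap.species_of.get(g) == species_id
            ]
            if genes:
                presence_by_species[species_id] = presence.subset_features(genes)
        prevalence = differential_prevalence_pooled(
            presence_by_species,
            metadata,
            alpha=config.alpha,
            per_species_adjust=config.per_species_adjust,
        )
        prevalence_frame = results_to_frame(prevalence)
        prevalence_frame.to_csv(out_dir / "prevalence.tsv", sep="\t", index=False)
        significant = [r.gene_id for r in prevalence if r.significant]
        logger.info("%d significant gene(s) at q <= %g", len(significant), config.alpha)

        stage = "correlation lineage test"
        reports = run_lineage_test(
            significant,
            reads,
            relabund,
            lineages,
            pmap,
            LineageTestConfig(
                min_detected=config.min_detected,
                flag_rank_threshold=config.flag_rank_threshold,
            ),
            presence=presence,
        )
        lineage_frame = reports_to_frame(reports)

        stage = "annotation scoring"
        if annotations is not None:
            scopes, names, scores = [], [], []
            for gene in lineage_frame["gene_id"]:
                scope, name = annotate_gene(gene, pmap, annotations)
                scopes.append(scope or "")
                names.append(name or "")
                scores.append(range_score(scope, rules))
            lineage_frame["eggnog_tax_scope"] = scopes
            lineage_frame["eggnog_name"] = names
            lineage_frame["eggnog_range_score"] = scores
        lineage_frame.to_csv(out_dir / "lineage_test.tsv", sep="\t", index=False)

        stage = "co-occurrence and ordination"
        ordinations: dict[str, dict[str, pd.DataFrame]] = {}
        heatmaps: dict[str, tuple[list[str], np.ndarray]] = {}
        by_species: dict[str, list[str]] = {}
        for gene in significant:
            by_species.setdefault(pmap.species_of[gene], []).append(gene)
        for species_id, genes in sorted(by_species.items()):
            if len(genes) < MIN_GENES:
                logger.info(
                    "species %s: %d significant gene(s) < %d; ordination skipped",
                    species_id,
                    len(genes),
                    MIN_GENES,
                )
                continue
            jac = jaccard_matrix(presence.subset_features(genes))
            order = heatmap_order(jac)
            idx = [jac.gene_ids.index(g) for g in order]
            heatmaps[species_id] = (order, jac.similarity[np.ix_(idx, idx)])
            ordinations[species_id] = {}
            for method in config.ordination_methods:
                params = {}
                if method.upper() == "UMAP":
                    if config.umap_n_neighbors is not None:
                        params["n_neighbors"] = config.umap_n_neighbors
                    params["min_dist"] = config.umap_min_dist
                try:
                    result = ordinate(
                        jac.dissimilarity, jac.gene_ids, method,
                        params=params, seed=config.seed,
                    )
                except ValueError as exc:
                    logger.warning(
                        "species %s: %s ordination failed: %s", species_id, method, exc
                    )
                    continue
                frame = pd.DataFrame(
                    result.coordinates, columns=["axis1", "axis2"]
                )
                frame.insert(0, "gene_id", result.gene_ids)
                if result.stress is not None:
                    frame["stress"] = result.stress
                frame.to_csv(
                    out_dir / f"ordination_{species_id}_{result.method}.tsv",
                    sep="\t",
                    index=False,
                )
                ordinations[species_id][result.method] = frame

        stage = "report"
        from .report import render_report

        report_path = render_report(
            out_dir,
            prevalence_frame,
            lineage_frame,
            heatmaps,
            ordinations,
            config,
            make_figures=config.make_figures,
        )
        _write_log(config, out_dir)
    except Exception:
        logger.error("pipeline failed at stage: %s", stage)
        raise

    flagged = list(lineage_frame.loc[lineage_frame["flagged"], "gene_id"])
    return RunResult(
        prevalence=prevalence_frame,
        lineage=lineage_frame,
        significant_genes=significant,
        flagged_genes=flagged,
        ordinations=ordinations,
        report_path=report_path,
    )
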