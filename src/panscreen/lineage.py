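"""Correlation lineage test.

Each flagged gene's read counts are correlated (Spearman) with the relative
abundance of every quantified species; species are ranked by descending
correlation and the report records the best rank whose species shares the
gene's pangenome lineage at the family and at the species level. A gene
whose best family-level match sits deep in the ranking (or is absent) is a
likely pangenome contaminant. A "conditional" variant restricts the
correlation to samples where the gene was detected, to accommodate accessory
genes absent from some strains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data_io import AbundanceMatrix, LineageTable, PangenomeMap

logger = logging.getLogger(__name__)

DEFAULT_MIN_DETECTED = 5
DEFAULT_FLAG_RANK_THRESHOLD = 50


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation: Pearson on average-fractional ranks.

    Returns NaN (missing) when either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def correlate_gene(
    gene_counts: np.ndarray,
    species_relabund: AbundanceMatrix,
    conditional: bool = False,
    min_detected: int = DEFAULT_MIN_DETECTED,
) -> dict[str, float]:
    """Spearman rho of a gene's counts against every species' abundance.

    In conditional mode only samples with gene count > 0 enter the
    correlation; with fewer than ``min_detected`` such samples the result is
    all-missing (NaN) and a warning is logged. Species with undefined rho
    (zero variance) are NaN.
    """
    gene_counts = np.asarray(gene_counts, dtype=float)
    if len(gene_counts) != len(species_relabund.sample_ids):
        raise ValueError(
            f"gene vector length {len(gene_counts)} != "
            f"{len(species_relabund.sample_ids)} samples"
        )
    if conditional:
        mask = gene_counts > 0
        if int(mask.sum()) < min_detected:
            logger.warning(
                "conditional correlation skipped: gene detected in %d < %d samples",
                int(mask.sum()),
                min_detected,
            )
            return {sp: float("nan") for sp in species_relabund.feature_ids}
        counts = gene_counts[mask]
        abund = species_relabund.values[:, mask]
    else:
        counts = gene_counts
        abund = species_relabund.values
    # vectorized rank-then-Pearson over all species rows
    rx = rankdata(counts)
    if np.ptp(rx) == 0:
        return {sp: float("nan") for sp in species_relabund.feature_ids}
    ry = rankdata(abund, axis=1)
    rx = rx - rx.mean()
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx @ rx) * (ry * ry).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, ry @ rx / np.where(denom > 0, denom, 1.0), np.nan)
    return dict(zip(species_relabund.feature_ids, rho.astype(float)))


def rank_species(rho_by_species: dict[str, float]) -> list[tuple[str, int]]:
    """Rank species by descending rho with competition ("min") ranks.

    Tied species share a rank; within a tie species are listed
    lexicographically. Missing (NaN) correlations are excluded; an
    all-missing input yields an empty list.
    """
    valid = [(sp, r) for sp, r in rho_by_species.items() if not np.isnan(r)]
    valid.sort(key=lambda item: (-item[1], item[0]))
    ranked: list[tuple[str, int]] = []
    for i, (sp, r) in enumerate(valid):
        if i > 0 and r == valid[i - 1][1]:
            rank = ranked[-1][1]
        else:
            rank = i + 1
        ranked.append((sp, rank))
    return ranked


def lineage_match_rank(
    ranked: list[tuple[str, int]],
    lineages: LineageTable,
    pangenome_species: str,
    level: str,
) -> int | None:
    """Smallest rank whose species matches the pangenome species at ``level``.

    ``level`` is ``"family"`` or ``"species"``. Returns None when no ranked
    species matches.
    """
    if level not in ("family", "species"):
        raise ValueError(f"level must be 'family' or 'species', got {level!r}")
    if pangenome_species not in lineages:
        raise KeyError(f"pangenome species {pangenome_species!r} not in lineage table")
    best: int | None = None
    for species_id, rank in ranked:
        if species_id not in lineages:
            continue
        if lineages.matches_at(species_id, pangenome_species, level):
            if best is None or rank < best:
                best = rank
    return best


@dataclass
class CorrelationReport:
    """Lineage-test outcome for one gene."""

    gene_id: str
    pangenome_species_id: str
    rho_overall: dict[str, float]
    rho_conditional: dict[str, float]
    ranked_overall: list[tuple[str, int]]
    ranked_conditional: list[tuple[str, int]]
    top_species_overall: str | None
    family_match_rank_overall: int | None
    species_match_rank_overall: int | None
    family_match_rank_conditional: int | None
    species_match_rank_conditional: int | None
    n_samples_total: int
    n_samples_detected: int
    flagged: bool = field(default=False)


@dataclass
class LineageTestConfig:
    min_detected: int = DEFAULT_MIN_DETECTED
    flag_rank_threshold: int = DEFAULT_FLAG_RANK_THRESHOLD
    # "counts" (> 0) or "presence" (use the presence matrix)
    detection_source: str = "counts"


def run_lineage_test(
    significant_genes: list[str],
    gene_reads: AbundanceMatrix,
    species_relabund: AbundanceMatrix,
    lineages: LineageTable,
    pangenome_map: PangenomeMap,
    config: LineageTestConfig | None = None,
    presence: AbundanceMatrix | None = None,
) -> list[CorrelationReport]:
    """Run overall and conditional lineage tests for each significant gene.

    A gene is flagged as a putative contaminant when its overall family
    match rank exceeds ``config.flag_rank_threshold``; a missing family rank
    (no family member among quantified species) is treated as worse than any
    finite rank and is also flagged.
    """
    config = config or LineageTestConfig()
    if gene_reads.sample_ids != species_relabund.sample_ids:
        raise ValueError("gene reads and species abundances are not sample-aligned")
    n_total = len(gene_reads.sample_ids)
    reports: list[CorrelationReport] = []
    for gene in significant_genes:
        try:
            counts = gene_reads.sample_vector(gene)
        except KeyError:
            raise KeyError(f"gene {gene!r} missing from the reads matrix") from None
        pangenome_species = pangenome_map.species_of.get(gene)
        if pangenome_species is None:
            raise KeyError(f"gene {gene!r} has no pangenome species mapping")
        if config.detection_source == "presence" and presence is not None:
            detected = presence.sample_vector(gene) > 0
        else:
            detected = counts > 0
        rho_all = correlate_gene(counts, species_relabund, conditional=False)
        # conditional variant restricts to detected samples
        if config.detection_source == "presence" and presence is not None:
            if int(detected.sum()) < config.min_detected:
                logger.warning(
                    "gene %s: detected in %d < %d samples; conditional test skipped",
                    gene,
                    int(detected.sum()),
                    config.min_detected,
                )
                rho_cond = {sp: float("nan") for sp in species_relabund.feature_ids}
            else:
                sub = species_relabund.subset_samples(
                    [s for s, m in zip(species_relabund.sample_ids, detected) if m]
                )
                rho_cond = correlate_gene(counts[detected], sub, conditional=False)
        else:
            rho_cond = correlate_gene(
                counts,
                species_relabund,
                conditional=True,
                min_detected=config.min_detected,
            )
        ranked_all = rank_species(rho_all)
        ranked_cond = rank_species(rho_cond)
        fam_all = lineage_match_rank(ranked_all, lineages, pangenome_species, "family")
        sp_all = lineage_match_rank(ranked_all, lineages, pangenome_species, "species")
        fam_cond = lineage_match_rank(ranked_cond, lineages, pangenome_species, "family")
        sp_cond = lineage_match_rank(ranked_cond, lineages, pangenome_species, "species")
        flagged = fam_all is None or fam_all > config.flag_rank_threshold
        reports.append(
            CorrelationReport(
                gene_id=gene,
                pangenome_species_id=pangenome_species,
                rho_overall=rho_all,
                rho_conditional=rho_cond,
                ranked_overall=ranked_all,
                ranked_conditional=ranked_cond,
                top_species_overall=ranked_all[0][0] if ranked_all else None,
                family_match_rank_overall=fam_all,
                species_match_rank_overall=sp_all,
                family_match_rank_conditional=fam_cond,
                species_match_rank_conditional=sp_cond,
                n_samples_total=n_total,
                n_samples_detected=int(np.sum(detected)),
                flagged=flagged,
            )
        )
    return reports


def reports_to_frame(reports: list[CorrelationReport]):
    import pandas as pd

    def _fmt(rank: int | None):
        return rank if rank is not None else pd.NA

    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "pangenome_species": r.pangenome_species_id,
                "top_corr_species": r.top_species_overall or "",
                "family_rank": _fmt(r.family_match_rank_overall),
                "species_rank": _fmt(r.species_match_rank_overall),
                "family_rank_conditional": _fmt(r.family_match_rank_conditional),
                "species_rank_conditional": _fmt(r.species_match_rank_conditional),
                "n_detected": r.n_samples_detected,
                "n_total": r.n_samples_total,
                "flagged": r.flagged,
            }
            for r in reports
        ]
    )
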