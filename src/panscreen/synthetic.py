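"""Synthetic case/control communities with planted pangenome contamination.

The generative story: each species' relative abundance is log-normal with a
group-specific mean (the target family depleted in cases, the contamination
source enriched). Reads for a genuine gene scale with its own species'
abundance times strain carriage; reads for a planted contaminant scale with
the *source* species' abundance while the gene sits in the target species'
pangenome — so its copy-number estimate (reads over the pangenome species'
abundance) diverges, and its prevalence tracks the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    AbundanceMatrix,
    LineageTable,
    PangenomeMap,
    SampleMetadata,
)


@dataclass
class SpeciesSpec:
    """One species in the simulated community."""

    species_id: str
    family: str
    base_log_abundance: float  # natural-log mean of the (unnormalized) abundance
    case_log2_fold: float = 0.0
    n_core_genes: int = 0
    n_accessory_genes: int = 0
    accessory_carriage: float = 0.5


@dataclass
class ContaminantSpec:
    """A gene planted in ``target_species``'s pangenome whose reads follow
    ``source_species``."""

    gene_id: str
    target_species: str
    source_species: str


@dataclass
class ScenarioConfig:
    n_cases: int
    n_controls: int
    species: list[SpeciesSpec]
    target_family: str
    contaminants: list[ContaminantSpec] = field(default_factory=list)
    depth: float = 1e6
    log_sd: float = 0.8
    seed: int = 42

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("need samples in both groups")
        if not self.species:
            raise ValueError("need at least one species")
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species IDs")
        for spec in self.species:
            if not 0.0 <= spec.accessory_carriage <= 1.0:
                raise ValueError(
                    f"{spec.species_id}: carriage probability must be in [0, 1]"
                )
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        known = set(ids)
        for contam in self.contaminants:
            if contam.source_species not in known:
                raise ValueError(
                    f"contaminant {contam.gene_id}: unknown source species "
                    f"{contam.source_species!r}"
                )
            if contam.target_species not in known:
                raise ValueError(
                    f"contaminant {contam.gene_id}: unknown target species "
                    f"{contam.target_species!r}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth for every emitted gene."""

    origin_species: dict[str, str]
    pangenome_species: dict[str, str]
    is_planted_contaminant: dict[str, bool]
    carriage: pd.DataFrame  # genes x samples, 0/1

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.origin_species)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "pangenome_species": [self.pangenome_species[g] for g in genes],
                "origin_species": [self.origin_species[g] for g in genes],
                "is_planted_contaminant": [
                    self.is_planted_contaminant[g] for g in genes
                ],
            }
        )


def simulate_community(
    config: ScenarioConfig,
) -> tuple[AbundanceMatrix, SampleMetadata]:
    """Draw per-sample species relative abundances and sample metadata."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    sample_ids = [f"case_{i:03d}" for i in range(config.n_cases)] + [
        f"control_{i:03d}" for i in range(config.n_controls)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    is_case = np.array([g == "case" for g in groups.values()])
    log2 = np.log(2.0)
    mu = np.array(
        [
            [
                spec.base_log_abundance + (spec.case_log2_fold * log2 if c else 0.0)
                for c in is_case
            ]
            for spec in config.species
        ]
    )
    raw = np.exp(rng.normal(mu, config.log_sd, size=(len(config.species), n)))
    relabund = raw / raw.sum(axis=0, keepdims=True)
    matrix = AbundanceMatrix(
        [s.species_id for s in config.species],
        sample_ids,
        relabund,
        "species_relabund",
    )
    return matrix, SampleMetadata(groups=groups)


def simulate_gene_reads(
    relabund: AbundanceMatrix, config: ScenarioConfig
) -> tuple[AbundanceMatrix, AbundanceMatrix, AbundanceMatrix, SyntheticTruth]:
    """Emit per-gene read counts, copy numbers and presence, plus truth.

    Expected reads for gene g in sample j are
    ``depth * abundance(origin(g), j) * carriage(g, j)``; observed reads are
    Poisson. Copy number divides reads by ``depth * abundance(pangenome
    species, j)`` — for contaminants this uses the *target* species, so the
    estimate diverges from 1. Presence is simply reads > 0.
    """
    config.validate()
    # independent stream from the community draw, still fully seeded
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    abund = relabund.to_frame()
    n = len(relabund.sample_ids)

    gene_ids: list[str] = []
    origin: dict[str, str] = {}
    pangenome: dict[str, str] = {}
    contaminant: dict[str, bool] = {}
    carriage_rows: list[np.ndarray] = []

    for spec in config.species:
        for i in range(spec.n_core_genes):
            gid = f"{spec.species_id}_core{i:03d}"
            gene_ids.append(gid)
            origin[gid] = spec.species_id
            pangenome[gid] = spec.species_id
            contaminant[gid] = False
            carriage_rows.append(np.ones(n))
        for i in range(spec.n_accessory_genes):
            gid = f"{spec.species_id}_acc{i:03d}"
            gene_ids.append(gid)
            origin[gid] = spec.species_id
            pangenome[gid] = spec.species_id
            contaminant[gid] = False
            carriage_rows.append(
                (rng.random(n) < spec.accessory_carriage).astype(float)
            )
    for contam in config.contaminants:
        gene_ids.append(contam.gene_id)
        origin[contam.gene_id] = contam.source_species
        pangenome[contam.gene_id] = contam.target_species
        contaminant[contam.gene_id] = True
        carriage_rows.append(np.ones(n))

    carriage = np.vstack(carriage_rows)
    origin_abund = abund.loc[[origin[g] for g in gene_ids]].to_numpy()
    pangenome_abund = abund.loc[[pangenome[g] for g in gene_ids]].to_numpy()
    lam = config.depth * origin_abund * carriage
    reads = rng.poisson(lam).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = config.depth * pangenome_abund
        copynum = np.where(denom > 0, reads / np.where(denom > 0, denom, 1.0), 0.0)
    presence = (reads > 0).astype(float)

    samples = list(relabund.sample_ids)
    truth = SyntheticTruth(
        origin_species=origin,
        pangenome_species=pangenome,
        is_planted_contaminant=contaminant,
        carriage=pd.DataFrame(carriage, index=gene_ids, columns=samples),
    )
    return (
        AbundanceMatrix(gene_ids, samples, reads, "gene_reads"),
        AbundanceMatrix(gene_ids, samples, copynum, "gene_copynum"),
        AbundanceMatrix(gene_ids, samples, presence, "gene_presence"),
        truth,
    )


def lineages_for(config: ScenarioConfig) -> LineageTable:
    """Seven-rank lineages consistent with the configured families."""
    lineages = {
        spec.species_id: (
            "Bacteria",
            f"phylum_of_{spec.family}",
            f"class_of_{spec.family}",
            f"order_of_{spec.family}",
            spec.family,
            f"genus_of_{spec.species_id}",
            spec.species_id,
        )
        for spec in config.species
    }
    return LineageTable(lineages=lineages)


def pangenome_map_for(truth: SyntheticTruth) -> PangenomeMap:
    return PangenomeMap(species_of=dict(truth.pangenome_species))


def default_scenario(seed: int = 42) -> ScenarioConfig:
    """Reference scenario: 100 + 100 samples, 30 species in 4 families,
    50 genes per target-family species, 10 planted contaminants sourced from
    a rare-in-controls, strongly case-enriched foreign-family species."""
    species: list[SpeciesSpec] = []
    target_family = "FamilyA"
    # 8 abundant target-family species, depleted in cases
    for i in range(8):
        species.append(
            SpeciesSpec(
                species_id=f"A{i:02d}",
                family=target_family,
                base_log_abundance=np.log(5e-3) - 0.25 * i,
                case_log2_fold=-1.0,
                n_core_genes=40,
                n_accessory_genes=10,
                accessory_carriage=0.5,
            )
        )
    # foreign families; B00 is the contamination source: rare in controls,
    # strongly enriched in cases
    families = ["FamilyB"] * 8 + ["FamilyC"] * 7 + ["FamilyD"] * 7
    for i, family in enumerate(families):
        sid = f"{family[-1]}{i % 8:02d}" if family != "FamilyB" else f"B{i:02d}"
        effect = 0.0
        base = np.log(2e-3) - 0.15 * i
        if family == "FamilyB" and i == 0:
            base = np.log(2e-8)
            effect = 6.0
        species.append(
            SpeciesSpec(
                species_id=sid,
                family=family,
                base_log_abundance=base,
                case_log2_fold=effect,
            )
        )
    contaminants = [
        ContaminantSpec(
            gene_id=f"A00_contam{i:03d}",
            target_species="A00",
            source_species="B00",
        )
        for i in range(10)
    ]
    return ScenarioConfig(
        n_cases=100,
        n_controls=100,
        species=species,
        target_family=target_family,
        contaminants=contaminants,
        depth=1e6,
        log_sd=0.8,
        seed=seed,
    )
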