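"""Tabular I/O for abundance matrices, taxonomy, metadata and annotation maps.

All matrices follow the MIDAS2 ``merge`` layout: TSV with a header row,
first column the feature ID, remaining columns one per sample, features as
rows. This orientation is preserved end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

MATRIX_KINDS = frozenset(
    {"species_relabund", "gene_reads", "gene_copynum", "gene_presence"}
)


class MatrixValidationError(ValueError):
    """Raised when a matrix violates a structural invariant."""


@dataclass
class AbundanceMatrix:
    """Features-by-samples numeric matrix with a declared kind.

    Parameters
    ----------
    feature_ids : sequence of str
        Row identifiers (gene or species IDs). Must be unique.
    sample_ids : sequence of str
        Column identifiers. Must be unique.
    values : ndarray of shape (n_features, n_samples)
        Non-negative values; binary for ``gene_presence``.
    kind : str
        One of ``species_relabund``, ``gene_reads``, ``gene_copynum``,
        ``gene_presence``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in MATRIX_KINDS:
            raise MatrixValidationError(
                f"unknown matrix kind {self.kind!r}; expected one of "
                f"{sorted(MATRIX_KINDS)}"
            )
        if self.values.ndim != 2 or self.values.shape != (
            len(self.feature_ids),
            len(self.sample_ids),
        ):
            raise MatrixValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.feature_ids)
        if dup:
            raise MatrixValidationError(f"duplicate feature IDs: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise MatrixValidationError(f"duplicate sample IDs: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            raise MatrixValidationError("matrix contains non-finite values")
        if np.any(self.values < 0):
            raise MatrixValidationError("matrix contains negative values")
        if self.kind == "gene_presence":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                bad = np.unique(self.values[~np.isin(self.values, (0.0, 1.0))])
                raise MatrixValidationError(
                    f"presence matrix contains non-binary values: {bad[:5]}"
                )
        if self.kind == "species_relabund":
            colsums = self.values.sum(axis=0)
            if np.any(colsums > 1.0 + 1e-6):
                raise MatrixValidationError(
                    "relative-abundance columns must sum to <= 1; max sum "
                    f"{colsums.max():.6g}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str) -> "AbundanceMatrix":
        return cls(
            feature_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            kind=kind,
        )

    def subset_features(self, keep: Sequence[str]) -> "AbundanceMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in keep if f not in index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        rows = [index[f] for f in keep]
        return AbundanceMatrix(
            list(keep), list(self.sample_ids), self.values[rows, :], self.kind
        )

    def subset_samples(self, keep: Sequence[str]) -> "AbundanceMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in keep]
        return AbundanceMatrix(
            list(self.feature_ids), list(keep), self.values[:, cols], self.kind
        )

    def sample_vector(self, feature_id: str) -> np.ndarray:
        try:
            row = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None
        return self.values[row, :]


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for item in items:
        if item in seen:
            dup.add(item)
        seen.add(item)
    return dup


def read_matrix(path: str | Path, kind: str) -> AbundanceMatrix:
    """Read a TSV matrix (header row; first column = feature ID).

    Duplicate feature/sample IDs, negative values and non-binary presence
    values are hard errors. Unparseable cells report the offending line.
    """
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        dup = _duplicates(sample_ids)
        if dup:
            raise MatrixValidationError(
                f"{path}: duplicate sample column header(s): {sorted(dup)}"
            )
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise MatrixValidationError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            feature_ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise MatrixValidationError(f"{path}:{lineno}: {exc}") from None
    try:
        return AbundanceMatrix(feature_ids, sample_ids, np.array(rows), kind)
    except MatrixValidationError as exc:
        raise MatrixValidationError(f"{path}: {exc}") from None


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with feature IDs in the first column."""
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


@dataclass
class SampleMetadata:
    """Per-sample case/control assignment."""

    groups: dict[str, str]
    subject_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.groups.values() if g not in ("case", "control")}
        if bad:
            raise ValueError(f"groups must be 'case' or 'control', got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups)

    def group_mask(self, sample_ids: Sequence[str], group: str) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise KeyError(f"samples without metadata: {missing[:5]}")
        return np.array([self.groups[s] == group for s in sample_ids], dtype=bool)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read metadata TSV with columns ``sample_id``, ``group``
    (optionally ``subject_id``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{path}: metadata needs columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    dup = _duplicates(frame["sample_id"])
    if dup:
        raise ValueError(f"{path}: duplicate sample IDs: {sorted(dup)}")
    groups = dict(zip(frame["sample_id"], frame["group"].str.strip().str.lower()))
    subjects = {}
    if "subject_id" in frame.columns:
        subjects = dict(zip(frame["sample_id"], frame["subject_id"]))
    return SampleMetadata(groups=groups, subject_ids=subjects)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"sample_id": list(metadata.groups), "group": list(metadata.groups.values())}
    )
    if metadata.subject_ids:
        frame["subject_id"] = [
            metadata.subject_ids.get(s, "") for s in metadata.groups
        ]
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class LineageTable:
    """Species ID -> ordered 7-rank GTDB-style lineage."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for sp, lin in self.lineages.items():
            if len(lin) != len(RANKS):
                raise ValueError(
                    f"species {sp!r}: lineage has {len(lin)} ranks, "
                    f"expected {len(RANKS)}"
                )

    def rank_of(self, species_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        try:
            lineage = self.lineages[species_id]
        except KeyError:
            raise KeyError(f"species {species_id!r} not in lineage table") from None
        return lineage[RANKS.index(rank)]

    def matches_at(self, species_a: str, species_b: str, rank: str) -> bool:
        """True when the two species share a non-empty name at ``rank``."""
        a = self.rank_of(species_a, rank)
        b = self.rank_of(species_b, rank)
        return bool(a) and a == b

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.lineages


def read_lineages(path: str | Path) -> LineageTable:
    """Read a taxonomy TSV.

    Accepts either 8 columns (species_id + the 7 ranks) or 2 columns
    (species_id + semicolon-joined lineage string, ``d__...;p__...`` prefixes
    tolerated).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lineages: dict[str, tuple[str, ...]] = {}
    if frame.shape[1] >= 8:
        for _, row in frame.iterrows():
            lineages[str(row.iloc[0])] = tuple(
                str(v).strip() for v in row.iloc[1:8]
            )
    elif frame.shape[1] == 2:
        for _, row in frame.iterrows():
            parts = [p.strip() for p in str(row.iloc[1]).split(";")]
            parts = [p.split("__", 1)[1] if "__" in p else p for p in parts]
            if len(parts) != 7:
                raise ValueError(
                    f"{path}: lineage for {row.iloc[0]!r} has {len(parts)} "
                    "ranks, expected 7"
                )
            lineages[str(row.iloc[0])] = tuple(parts)
    else:
        raise ValueError(f"{path}: expected 2 or >=8 columns")
    return LineageTable(lineages=lineages)


def write_lineages(table: LineageTable, path: str | Path) -> None:
    frame = pd.DataFrame(
        [(sp, *lin) for sp, lin in table.lineages.items()],
        columns=["species_id", *RANKS],
    )
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class PangenomeMap:
    """Gene ID -> (pangenome species, optional UHGP-90 cluster)."""

    species_of: dict[str, str]
    uhgp90_of: dict[str, str] = field(default_factory=dict)

    def genes_of_species(self, species_id: str) -> list[str]:
        return [g for g, sp in self.species_of.items() if sp == species_id]

    @property
    def species_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.species_of.values():
            seen.setdefault(sp)
        return list(seen)


def read_pangenome_map(path: str | Path) -> PangenomeMap:
    """Read a gene map TSV with columns ``gene_id``, ``species_id``
    (optionally ``uhgp90_cluster_id``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene_id", "species_id"}.issubset(frame.columns):
        raise ValueError(
            f"{path}: need columns gene_id, species_id; found {list(frame.columns)}"
        )
    dup = _duplicates(frame["gene_id"])
    if dup:
        raise ValueError(f"{path}: genes mapped more than once: {sorted(dup)[:5]}")
    species_of = dict(zip(frame["gene_id"], frame["species_id"]))
    uhgp90_of = {}
    if "uhgp90_cluster_id" in frame.columns:
        uhgp90_of = {
            g: c
            for g, c in zip(frame["gene_id"], frame["uhgp90_cluster_id"])
            if c != ""
        }
    return PangenomeMap(species_of=species_of, uhgp90_of=uhgp90_of)


def write_pangenome_map(pmap: PangenomeMap, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": list(pmap.species_of),
            "species_id": list(pmap.species_of.values()),
            "uhgp90_cluster_id": [
                pmap.uhgp90_of.get(g, "") for g in pmap.species_of
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationTable:
    """UHGP-90 cluster -> EggNOG scope/name/description; lookups never fail."""

    records: dict[str, tuple[str | None, str | None, str | None]]

    def lookup(self, cluster_id: str | None) -> tuple[str | None, str | None, str | None]:
        if cluster_id is None:
            return (None, None, None)
        return self.records.get(cluster_id, (None, None, None))


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a UHGP-90 annotation table from TSV or Parquet.

    Expected columns: ``uhgp90_cluster_id``, ``eggnog_tax_scope``,
    ``predicted_name``, ``description`` (the latter three optional per row).
    """
    path = Path(path)
    if path.suffix == ".parquet":
        frame = pd.read_parquet(path)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    if "uhgp90_cluster_id" not in frame.columns:
        raise ValueError(f"{path}: need a uhgp90_cluster_id column")

    def _clean(value: object) -> str | None:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        text = str(value).strip()
        return text or None

    records = {}
    for _, row in frame.iterrows():
        records[str(row["uhgp90_cluster_id"])] = (
            _clean(row.get("eggnog_tax_scope")),
            _clean(row.get("predicted_name")),
            _clean(row.get("description")),
        )
    return AnnotationTable(records=records)


def align_samples(
    matrices: Sequence[AbundanceMatrix], metadata: SampleMetadata
) -> list[AbundanceMatrix]:
    """Restrict all matrices (and metadata) to their common samples.

    The shared order is the first matrix's sample order filtered to the
    intersection; dropped samples are logged. Empty intersection is an error.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    common = set(matrices[0].sample_ids) & set(metadata.sample_ids)
    for matrix in matrices[1:]:
        common &= set(matrix.sample_ids)
    order = [s for s in matrices[0].sample_ids if s in common]
    if not order:
        raise ValueError("no samples shared across matrices and metadata")
    for matrix in matrices:
        dropped = sorted(set(matrix.sample_ids) - common)
        if dropped:
            logger.info(
                "align_samples: dropping %d sample(s) from %s matrix: %s",
                len(dropped),
                matrix.kind,
                dropped[:10],
            )
    return [m.subset_samples(order) for m in matrices]


TABLE1_COLUMNS = [
    "gene_id",
    "n_isolate",
    "n_mag",
    "eggnog_group",
    "eggnog_name",
    "fdr_q",
    "pangenome_species",
    "top_corr_species",
    "family_rank",
    "species_rank",
    "blast_contam",
    "notes",
]


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged 86-gene evaluation fixture.

    Returns a DataFrame with one row per significant gene: gene ID, isolate
    and MAG genome counts, EggNOG group/name, the FDR q-value, pangenome
    species, top-correlated species, family- and species-level correlation
    match ranks, the BLAST contamination label (``yes``/``no``) and free-text
    notes.
    """
    with resources.files("panscreen.data").joinpath("table1_fixture.tsv").open(
        "rt", encoding="utf-8"
    ) as fh:
        frame = pd.read_csv(
            fh,
            sep="\t",
            dtype={
                "gene_id": str,
                "eggnog_group": str,
                "eggnog_name": str,
                "pangenome_species": str,
                "top_corr_species": str,
                "blast_contam": str,
                "notes": str,
            },
            keep_default_na=False,
        )
    frame["n_isolate"] = frame["n_isolate"].astype(int)
    frame["n_mag"] = frame["n_mag"].astype(int)
    frame["fdr_q"] = frame["fdr_q"].astype(float)
    frame["family_rank"] = frame["family_rank"].astype(int)
    frame["species_rank"] = frame["species_rank"].astype(int)
    if list(frame.columns) != TABLE1_COLUMNS:
        raise RuntimeError("packaged fixture has unexpected columns")
    if len(frame) != 86:
        raise RuntimeError(f"packaged fixture has {len(frame)} rows, expected 86")
    return frame
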