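"""EggNOG taxonomic-scope lookup and numeric contamination scoring.

A gene's UHGP-90 cluster carries an EggNOG orthologous-group annotation
whose taxonomic scope either clearly excludes the target family (score 1,
contamination-indicating), is consistent with it (score 0), or is missing /
too broad to judge (score 0.5). The taxon lists are data, not code; the
packaged default covers a Lachnospiraceae target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .data_io import AnnotationTable, PangenomeMap

logger = logging.getLogger(__name__)

SCORE_CONTAMINANT = 1.0
SCORE_CONSISTENT = 0.0
SCORE_AMBIGUOUS = 0.5

_VALID_CLASSES = {"contaminant", "consistent", "ambiguous"}


@dataclass
class RuleTable:
    """Taxon -> class mapping used by :func:`range_score`."""

    classes: dict[str, str]
    target_family: str = "Lachnospiraceae"

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in _VALID_CLASSES}
        if bad:
            raise ValueError(
                f"rule classes must be one of {sorted(_VALID_CLASSES)}, got {sorted(bad)}"
            )


def load_rule_table(path: str | Path | None = None) -> RuleTable:
    """Load a rule table TSV (columns ``taxon``, ``class``).

    With no path, the packaged Lachnospiraceae default is returned.
    """
    if path is None:
        with resources.files("panscreen.data").joinpath(
            "lachnospiraceae_rules.tsv"
        ).open("rt", encoding="utf-8") as fh:
            frame = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon", "class"}.issubset(frame.columns):
        raise ValueError("rule table needs columns: taxon, class")
    return RuleTable(classes=dict(zip(frame["taxon"], frame["class"])))


def annotate_gene(
    gene_id: str,
    pangenome_map: PangenomeMap,
    annotations: AnnotationTable,
) -> tuple[str | None, str | None]:
    """Return (eggnog_tax_scope, predicted_name) via the gene's UHGP-90
    cluster; missing at any step propagates as None."""
    cluster = pangenome_map.uhgp90_of.get(gene_id)
    if cluster is None:
        logger.info("gene %s has no UHGP-90 mapping", gene_id)
        return (None, None)
    scope, name, _ = annotations.lookup(cluster)
    return (scope, name)


def range_score(tax_scope: str | None, rule_table: RuleTable) -> float:
    """Score a taxonomic scope: 1 contamination-indicating, 0 consistent,
    0.5 missing/"Bacteria"/unlisted (unlisted logs a warning)."""
    if tax_scope is None or str(tax_scope).strip() == "":
        return SCORE_AMBIGUOUS
    scope = str(tax_scope).strip()
    if scope == "Bacteria":
        return SCORE_AMBIGUOUS
    cls = rule_table.classes.get(scope)
    if cls is None:
        logger.warning(
            "taxonomic scope %r not in the rule table; scored 0.5", scope
        )
        return SCORE_AMBIGUOUS
    if cls == "contaminant":
        return SCORE_CONTAMINANT
    if cls == "consistent":
        return SCORE_CONSISTENT
    return SCORE_AMBIGUOUS
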