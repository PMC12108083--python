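"""ROC/AUROC machinery and the fixture evaluation harness."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import RuleTable, load_rule_table, range_score


def auroc(
    scores, labels, positive_means_higher: bool = True
) -> float:
    """Probability a random positive outranks a random negative (ties 0.5).

    Computed as the tie-corrected Mann-Whitney statistic. The direction is
    fixed by the caller: with ``positive_means_higher`` (default), higher
    scores predict the positive label; set False to invert. Never
    auto-flipped.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if len(scores) < 2:
        raise ValueError("need at least 2 observations")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    if not positive_means_higher:
        scores = -scores
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auroc_auto_direction(scores, labels) -> float:
    """AUROC with automatic direction selection (max of the two directions).

    This mirrors common ROC tooling defaults (e.g. R's pROC with
    ``direction="auto"``), which pick whichever direction gives an area
    >= 0.5. Prefer :func:`auroc` with an explicit direction when
    reproducibility of the direction matters.
    """
    a = auroc(scores, labels, positive_means_higher=True)
    return float(max(a, 1.0 - a))


@dataclass
class ContaminationEvaluation:
    """Recomputed evaluation metrics for a labelled gene table."""

    n_genes: int
    n_contaminants: int
    metrics: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(self.metrics), "value": list(self.metrics.values())}
        )


REQUIRED_FIXTURE_COLUMNS = [
    "gene_id",
    "eggnog_group",
    "fdr_q",
    "family_rank",
    "species_rank",
    "blast_contam",
]


def evaluate_table1(
    fixture: pd.DataFrame, rule_table: RuleTable | None = None
) -> ContaminationEvaluation:
    """Recompute every evaluation metric from a labelled gene table.

    Expects the packaged fixture's columns (``blast_contam`` in
    {``yes``, ``no``}). Scores: family/species match rank (higher rank =>
    contaminant), the FDR q-value (higher => contaminant), and the EggNOG
    range score. Deterministic; runs in well under a second.
    """
    missing = [c for c in REQUIRED_FIXTURE_COLUMNS if c not in fixture.columns]
    if missing:
        raise ValueError(f"fixture is missing columns: {missing}")
    if len(fixture) == 0:
        raise ValueError("fixture is empty")
    rule_table = rule_table or load_rule_table()
    labels = (
        fixture["blast_contam"].astype(str).str.strip().str.lower() == "yes"
    ).to_numpy()
    fam = fixture["family_rank"].to_numpy(dtype=float)
    spr = fixture["species_rank"].to_numpy(dtype=float)
    q = fixture["fdr_q"].to_numpy(dtype=float)
    egg = np.array(
        [range_score(s, rule_table) for s in fixture["eggnog_group"]], dtype=float
    )

    n = len(fixture)
    n_contam = int(labels.sum())

    def frac_contam(mask: np.ndarray) -> float:
        return float(labels[mask].mean()) if mask.any() else float("nan")

    fam1 = fam == 1
    fam10 = fam <= 10
    fam50 = fam > 50
    q01 = q < 0.01

    metrics = {
        "n_genes": float(n),
        "n_contaminants": float(n_contam),
        "contaminant_fraction": n_contam / n,
        "n_family_rank_1": float(fam1.sum()),
        "fpr_family_rank_1": frac_contam(fam1),
        "n_family_rank_le_10": float(fam10.sum()),
        "fpr_family_rank_le_10": frac_contam(fam10),
        "n_family_rank_gt_50": float(fam50.sum()),
        "tpr_family_rank_gt_50": frac_contam(fam50),
        "n_q_lt_0.01": float(q01.sum()),
        "contaminant_fraction_q_lt_0.01": frac_contam(q01),
        "auroc_family_rank": auroc(fam, labels),
        "auroc_species_rank": auroc(spr, labels),
        # reference convention for the species-rank metric: automatic
        # direction selection; the fixed-direction value is above
        "auroc_species_rank_auto": auroc_auto_direction(spr, labels),
        "auroc_fdr_q": auroc(q, labels),
        "auroc_eggnog_score": auroc(egg, labels),
    }
    return ContaminationEvaluation(
        n_genes=n, n_contaminants=n_contam, metrics=metrics
    )
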