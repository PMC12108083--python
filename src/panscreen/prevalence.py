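"""Differential gene prevalence: Fisher's exact test with a discrete
Benjamini-Hochberg (step-up) false-discovery-rate adjustment.

Exact tests on 2x2 tables have discrete p-value distributions whose support
depends only on the table margins. The discrete step-up procedure replaces
each hypothesis's contribution to the classical BH bound (the threshold
itself) with the largest attainable p-value at or below the threshold, which
is never larger — so the adjusted values it produces are uniformly at most
the classical BH values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .data_io import AbundanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

# Relative slack when comparing table probabilities to the observed one, to
# avoid float-ordering artifacts in the "sum of <=-probability tables" rule.
_REL_TOL = 1e-7


def presence_from_copynum(
    copynum: AbundanceMatrix, threshold: float = 0.35
) -> AbundanceMatrix:
    """Binarize a copy-number matrix: present where copy number >= threshold."""
    if copynum.kind != "gene_copynum":
        raise ValueError(f"expected gene_copynum matrix, got {copynum.kind}")
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    presence = (copynum.values >= threshold).astype(float)
    return AbundanceMatrix(
        list(copynum.feature_ids), list(copynum.sample_ids), presence, "gene_presence"
    )


def _table_probs(n_cases: int, n_controls: int, k_present: int) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric pmf over all tables with the given margins.

    Returns (support of a = present-in-cases, pmf at each a).
    """
    a_min = max(0, k_present - n_controls)
    a_max = min(n_cases, k_present)
    support = np.arange(a_min, a_max + 1)
    pmf = hypergeom.pmf(support, n_cases + n_controls, k_present, n_cases)
    return support, pmf


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the probabilities of all tables with the observed margins whose
    hypergeometric probability is at most the observed table's (with a small
    relative tolerance).
    """
    for name, value in (("a", a), ("b", b), ("c", c), ("d", d)):
        if value < 0 or int(value) != value:
            raise ValueError(f"count {name} must be a non-negative integer")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_cases, n_controls = a + b, c + d
    if n_cases == 0 or n_controls == 0:
        raise ValueError("both group margins must be positive")
    support, pmf = _table_probs(n_cases, n_controls, a + c)
    p_obs = pmf[np.searchsorted(support, a)]
    p = float(pmf[pmf <= p_obs * (1 + _REL_TOL)].sum())
    return _snap(p)


def _snap(p: float) -> float:
    """Clamp to (0, 1], absorbing float error at the top of the scale."""
    return 1.0 if p > 1.0 - 1e-12 else p


@lru_cache(maxsize=100_000)
def fisher_support(n_cases: int, n_controls: int, k_present: int) -> tuple[float, ...]:
    """All attainable two-sided Fisher p-values for the given margins, ascending.

    The support depends only on (n_cases, n_controls, k_present); its largest
    element is always 1.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("both group margins must be positive")
    if not 0 <= k_present <= n_cases + n_controls:
        raise ValueError("k_present out of range for the margins")
    support, pmf = _table_probs(n_cases, n_controls, k_present)
    tol = 1 + _REL_TOL
    pvals = {_snap(float(pmf[pmf <= p_obs * tol].sum())) for p_obs in pmf}
    return tuple(sorted(pvals))


def discrete_fdr_adjust(
    p_raw: Sequence[float],
    supports: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> np.ndarray:
    """Adjusted values for the non-adaptive discrete BH step-up procedure.

    For a rejection threshold ``t``, hypothesis ``j`` contributes
    ``F_j(t)`` = its largest attainable p-value <= ``t`` (0 if none); the sum
    of these surrogates replaces ``m * t`` in the classical BH bound. The
    adjusted value of the k-th smallest raw p is::

        q_(k) = min_{l >= k}  sum_j F_j(p_(l)) / l      (capped at 1)

    Because ``F_j(t) <= t``, every ``q`` is at most the classical BH adjusted
    value. ``alpha`` is accepted for interface symmetry; the adjusted values
    themselves do not depend on it.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    if len(p_raw) != len(supports):
        raise ValueError(
            f"{len(p_raw)} p-values but {len(supports)} supports"
        )
    m = len(p_raw)
    if m == 0:
        return np.array([])
    sorted_supports = [np.asarray(sorted(s), dtype=float) for s in supports]
    order = np.argsort(p_raw, kind="stable")
    p_sorted = p_raw[order]
    # surrogate_sum[l] = sum_j F_j(p_(l))
    surrogate_sum = np.empty(m)
    for l, t in enumerate(p_sorted):
        total = 0.0
        for sup in sorted_supports:
            idx = np.searchsorted(sup, t * (1 + _REL_TOL), side="right")
            if idx > 0:
                total += sup[idx - 1]
        surrogate_sum[l] = total
    ratios = surrogate_sum / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ratios[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class PrevalenceResult:
    """Per-gene 2x2 prevalence test outcome."""

    gene_id: str
    species_id: str | None
    a: int  # present in cases
    b: int  # absent in cases
    c: int  # present in controls
    d: int  # absent in controls
    p_raw: float
    q: float
    significant: bool


def _contingency(
    presence: AbundanceMatrix, metadata: SampleMetadata
) -> tuple[np.ndarray, np.ndarray, int, int]:
    case_mask = metadata.group_mask(presence.sample_ids, "case")
    control_mask = metadata.group_mask(presence.sample_ids, "control")
    n_cases = int(case_mask.sum())
    n_controls = int(control_mask.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"need samples in both groups; got {n_cases} cases, "
            f"{n_controls} controls"
        )
    a = presence.values[:, case_mask].sum(axis=1).astype(int)
    c = presence.values[:, control_mask].sum(axis=1).astype(int)
    return a, c, n_cases, n_controls


def differential_prevalence(
    presence: AbundanceMatrix,
    metadata: SampleMetadata,
    alpha: float = 0.05,
    species_id: str | None = None,
) -> list[PrevalenceResult]:
    """Test every gene for differential prevalence between cases and controls.

    Returns one result per gene, sorted by adjusted value then gene ID.
    Genes present (or absent) in all samples are still tested (p = 1).
    """
    if presence.kind != "gene_presence":
        raise ValueError(f"expected gene_presence matrix, got {presence.kind}")
    a_vec, c_vec, n_cases, n_controls = _contingency(presence, metadata)
    p_raw = np.array(
        [
            fisher_two_sided(a, n_cases - a, c, n_controls - c)
            for a, c in zip(a_vec, c_vec)
        ]
    )
    supports = [
        fisher_support(n_cases, n_controls, int(a + c))
        for a, c in zip(a_vec, c_vec)
    ]
    q = discrete_fdr_adjust(p_raw, supports, alpha=alpha)
    results = [
        PrevalenceResult(
            gene_id=gene,
            species_id=species_id,
            a=int(a),
            b=n_cases - int(a),
            c=int(c),
            d=n_controls - int(c),
            p_raw=float(p),
            q=float(qv),
            significant=bool(qv <= alpha),
        )
        for gene, a, c, p, qv in zip(presence.feature_ids, a_vec, c_vec, p_raw, q)
    ]
    results.sort(key=lambda r: (r.q, r.gene_id))
    return results


def differential_prevalence_pooled(
    presence_by_species: dict[str, AbundanceMatrix],
    metadata: SampleMetadata,
    alpha: float = 0.05,
    per_species_adjust: bool = False,
) -> list[PrevalenceResult]:
    """Run the prevalence test per species and adjust for multiplicity.

    Each species' matrix is tested over its own (already aligned) samples, so
    group sizes may differ across species. By default all genes across all
    species form one multiplicity universe; with ``per_species_adjust`` the
    adjustment runs separately within each species.
    """
    if per_species_adjust:
        results: list[PrevalenceResult] = []
        for species_id, presence in presence_by_species.items():
            results.extend(
                differential_prevalence(
                    presence, metadata, alpha=alpha, species_id=species_id
                )
            )
        results.sort(key=lambda r: (r.q, r.gene_id))
        return results

    genes: list[tuple[str, str, int, int, int, int]] = []
    for species_id, presence in presence_by_species.items():
        if presence.kind != "gene_presence":
            raise ValueError(
                f"species {species_id}: expected gene_presence matrix, "
                f"got {presence.kind}"
            )
        a_vec, c_vec, n_cases, n_controls = _contingency(presence, metadata)
        for gene, a, c in zip(presence.feature_ids, a_vec, c_vec):
            genes.append(
                (gene, species_id, int(a), n_cases - int(a), int(c), n_controls - int(c))
            )
    p_raw = np.array([fisher_two_sided(a, b, c, d) for _, _, a, b, c, d in genes])
    supports = [
        fisher_support(a + b, c + d, a + c) for _, _, a, b, c, d in genes
    ]
    q = discrete_fdr_adjust(p_raw, supports, alpha=alpha)
    results = [
        PrevalenceResult(
            gene_id=g,
            species_id=sp,
            a=a,
            b=b,
            c=c,
            d=d,
            p_raw=float(p),
            q=float(qv),
            significant=bool(qv <= alpha),
        )
        for (g, sp, a, b, c, d), p, qv in zip(genes, p_raw, q)
    ]
    results.sort(key=lambda r: (r.q, r.gene_id))
    return results


def results_to_frame(results: Sequence[PrevalenceResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "species_id": r.species_id or "",
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "p_raw": r.p_raw,
                "q": r.q,
                "significant": r.significant,
            }
            for r in results
        ]
    )
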