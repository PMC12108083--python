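"""Copy-number cluster / phenotype association.

Genes are clustered on Pearson correlation distance with partitioning
around medoids (PAM), the cluster count chosen by maximizing average
silhouette width; each retained cluster is summarized by an eigengene (first
right-singular vector of its genes-by-samples submatrix) which is tested for
a case/control shift with the Wilcoxon rank-sum test (BH-adjusted). A
bootstrap mean t-statistic quantifies each gene's enrichment direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .data_io import AbundanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

MIN_CLUSTER_SIZE = 3


def correlation_distance(copynum: AbundanceMatrix) -> np.ndarray:
    """Gene-by-gene Pearson correlation distance, d = 1 - r.

    Zero-variance genes get the maximal distance 1 to every other gene (0 to
    themselves), with a warning.
    """
    x = np.asarray(copynum.values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "correlation_distance: %d zero-variance gene(s); distance set to 1",
            int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    d[degenerate, :] = 1.0
    d[:, degenerate] = 1.0
    np.fill_diagonal(d, 0.0)
    # clip tiny negatives from float error
    return np.clip(d, 0.0, 2.0)


@dataclass
class ClusterModel:
    """PAM clustering outcome."""

    labels: np.ndarray  # medoid index per item
    medoids: list[int]
    k: int
    asw_by_k: dict[int, float] = field(default_factory=dict)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam_cluster(d: np.ndarray, k: int, exact_limit: int = 2000) -> ClusterModel:
    """Minimize the PAM objective (sum of distances to nearest medoid).

    ``d`` is a square dissimilarity matrix. Tiny instances (at most
    ``exact_limit`` candidate medoid sets) are solved by exhaustive
    enumeration — the global optimum is itself a SWAP fixed point; larger
    ones use deterministic BUILD followed by best-improvement SWAP until no
    single medoid/non-medoid exchange lowers the total cost.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("d must be a square dissimilarity matrix")
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n; got k={k}, n={n}")

    from math import comb

    if comb(n, k) <= exact_limit:
        from itertools import combinations

        best = min(
            combinations(range(n), k),
            key=lambda medoids: (_pam_cost(d, list(medoids)), medoids),
        )
        medoids = sorted(best)
        labels = np.asarray(medoids)[np.argmin(d[:, medoids], axis=1)]
        return ClusterModel(labels=labels, medoids=medoids, k=k)

    # BUILD: start from the 1-medoid optimum, then greedily add the point
    # giving the largest cost decrease (smallest index on ties).
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    # SWAP: best-improvement with a deterministic tie rule.
    cost = _pam_cost(d, medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                delta = _pam_cost(d, trial) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids[best[1]] = best[2]
            cost += best[0]
            improved = True
    medoids = sorted(medoids)
    labels = np.asarray(medoids)[np.argmin(d[:, medoids], axis=1)]
    return ClusterModel(labels=labels, medoids=medoids, k=k)


def select_k_by_asw(
    d: np.ndarray, k_min: int = 2, k_max: int = 25
) -> ClusterModel:
    """Run PAM for each k in [k_min, k_max] and keep the ASW-maximizing fit.

    Ties go to the smallest k. ``k_max`` is truncated to n - 1.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n <= 3:
        raise ValueError(f"need more than 3 items to scan k, got {n}")
    k_max = min(k_max, n - 1)
    if k_min > k_max:
        raise ValueError(f"empty k range [{k_min}, {k_max}]")
    best_model: ClusterModel | None = None
    best_asw = -np.inf
    asw_by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        model = pam_cluster(d, k)
        if len(set(model.labels.tolist())) < 2:
            continue
        asw = float(silhouette_score(d, model.labels, metric="precomputed"))
        asw_by_k[k] = asw
        if asw > best_asw + 1e-12:
            best_asw = asw
            best_model = model
    if best_model is None:
        raise RuntimeError("no valid clustering found on the scan range")
    best_model.asw_by_k = asw_by_k
    return best_model


def eigengene(submatrix: np.ndarray) -> np.ndarray:
    """First right-singular vector of a genes-by-samples submatrix.

    Unit Euclidean norm; sign chosen so the correlation with the per-sample
    mean profile is non-negative.
    """
    x = np.atleast_2d(np.asarray(submatrix, dtype=float))
    if x.size == 0 or not np.any(x != 0):
        raise ValueError("eigengene of an all-zero or empty submatrix is undefined")
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    v = vt[0]
    mean_profile = x.mean(axis=0)
    centred_v = v - v.mean()
    centred_m = mean_profile - mean_profile.mean()
    orient = centred_v @ centred_m
    if orient == 0:  # flat mean profile: fall back to raw alignment
        orient = v @ mean_profile
    if orient < 0:
        v = -v
    return v


@dataclass
class ClusterAssociation:
    cluster_id: int
    gene_ids: list[str]
    eigengene: np.ndarray
    wilcoxon_p: float
    bh_q: float
    significant: bool
    mean_bootstrap_t: dict[str, float]


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for groups of <= 50 (without
    ties), else normal approximation with continuity correction."""
    method = "exact" if (len(x) <= 50 and len(y) <= 50) else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def _bootstrap_t(
    x: np.ndarray,
    case_idx: np.ndarray,
    control_idx: np.ndarray,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean two-sample t statistic (case minus control) over bootstrap
    resamples of the samples, per gene row. Zero-variance replicates give
    t = 0 for the affected genes."""
    n_genes = x.shape[0]
    total = np.zeros(n_genes)
    warned = False
    for _ in range(reps):
        ci = rng.choice(case_idx, size=len(case_idx), replace=True)
        ki = rng.choice(control_idx, size=len(control_idx), replace=True)
        xc, xk = x[:, ci], x[:, ki]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, _ = stats.ttest_ind(xc, xk, axis=1)
        bad = ~np.isfinite(t)
        if bad.any() and not warned:
            logger.warning(
                "bootstrap t: zero-variance replicate(s); t set to 0"
            )
            warned = True
        t = np.where(np.isfinite(t), t, 0.0)
        total += t
    return total / reps


def cluster_association(
    model: ClusterModel,
    copynum: AbundanceMatrix,
    metadata: SampleMetadata,
    fdr: float = 0.05,
    boot_reps: int = 500,
    seed: int = 0,
) -> list[ClusterAssociation]:
    """Test each retained cluster's eigengene for a case/control shift.

    Clusters with fewer than 3 genes are discarded. Wilcoxon rank-sum
    p-values are BH-adjusted across retained clusters; per-gene mean
    bootstrap t statistics (case minus control) are computed with a seeded
    generator.
    """
    case_idx = np.flatnonzero(metadata.group_mask(copynum.sample_ids, "case"))
    control_idx = np.flatnonzero(metadata.group_mask(copynum.sample_ids, "control"))
    if len(case_idx) < 2 or len(control_idx) < 2:
        raise ValueError(
            f"need >= 2 samples per group; got {len(case_idx)} cases, "
            f"{len(control_idx)} controls"
        )
    rng = np.random.default_rng(seed)
    retained: list[tuple[int, np.ndarray]] = []
    for cluster_id in sorted(set(model.labels.tolist())):
        members = model.members(cluster_id)
        if len(members) < MIN_CLUSTER_SIZE:
            logger.info(
                "cluster %d discarded (%d gene(s) < %d)",
                cluster_id,
                len(members),
                MIN_CLUSTER_SIZE,
            )
            continue
        retained.append((cluster_id, members))
    if not retained:
        return []
    pvals = []
    eigs = []
    for cluster_id, members in retained:
        eig = eigengene(copynum.values[members, :])
        eigs.append(eig)
        # an (effectively) constant eigengene carries no group information;
        # SVD noise at machine precision must not masquerade as signal
        if np.ptp(eig) <= 1e-10 * max(1.0, float(np.abs(eig).max())):
            pvals.append(1.0)
        else:
            pvals.append(_wilcoxon_rank_sum(eig[case_idx], eig[control_idx]))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out: list[ClusterAssociation] = []
    for (cluster_id, members), eig, p, q in zip(retained, eigs, pvals, qvals):
        mean_t = _bootstrap_t(
            copynum.values[members, :], case_idx, control_idx, boot_reps, rng
        )
        out.append(
            ClusterAssociation(
                cluster_id=int(cluster_id),
                gene_ids=[copynum.feature_ids[i] for i in members],
                eigengene=eig,
                wilcoxon_p=float(p),
                bh_q=float(q),
                significant=bool(q <= fdr),
                mean_bootstrap_t={
                    copynum.feature_ids[i]: float(t)
                    for i, t in zip(members, mean_t)
                },
            )
        )
    return out


def filter_genes_by_annotation(
    descriptions: dict[str, str | None],
    pattern: str = "flag",
    extra_genes: list[str] | None = None,
) -> list[str]:
    """Select genes whose free-text annotation contains ``pattern``
    (case-insensitive), plus any explicitly listed genes."""
    needle = pattern.lower()
    keep = [
        g
        for g, desc in descriptions.items()
        if desc is not None and needle in str(desc).lower()
    ]
    for g in extra_genes or []:
        if g not in keep:
            keep.append(g)
    return keep
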