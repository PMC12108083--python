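"""Gene co-occurrence structure: Jaccard similarity, clustered heatmap
ordering, and 2-D ordination (NMDS / UMAP / PCoA)."""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .data_io import AbundanceMatrix

logger = logging.getLogger(__name__)

MIN_GENES = 3


@dataclass
class JaccardMatrix:
    """Pairwise Jaccard similarity of gene presence profiles."""

    gene_ids: list[str]
    similarity: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.similarity


def jaccard_matrix(presence: AbundanceMatrix) -> JaccardMatrix | None:
    """Jaccard similarity J(g, h) = |both present| / |either present|.

    Needs at least 3 genes; smaller inputs are skipped (None) with a log
    message. A pair with an empty union gets J = 0 (with a warning); the
    diagonal is always 1.
    """
    if presence.kind != "gene_presence":
        raise ValueError(f"expected gene_presence matrix, got {presence.kind}")
    n = len(presence.feature_ids)
    if n < MIN_GENES:
        logger.info("jaccard_matrix: skipping, only %d gene(s) (< %d)", n, MIN_GENES)
        return None
    x = presence.values.astype(bool)
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2).astype(float)
    union = (x[:, None, :] | x[None, :, :]).sum(axis=2).astype(float)
    empty = union == 0
    if empty.any():
        logger.warning(
            "jaccard_matrix: %d gene pair(s) have empty unions; J set to 0",
            int(empty.sum()) // 2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(empty, 0.0, inter / np.where(empty, 1.0, union))
    np.fill_diagonal(sim, 1.0)
    return JaccardMatrix(gene_ids=list(presence.feature_ids), similarity=sim)


def heatmap_order(jaccard: JaccardMatrix) -> list[str]:
    """Dendrogram leaf order for the heatmap.

    Complete-linkage hierarchical clustering of the similarity matrix's rows
    under Euclidean distance.
    """
    n = len(jaccard.gene_ids)
    if n < MIN_GENES:
        return list(jaccard.gene_ids)
    tree = linkage(pdist(jaccard.similarity, metric="euclidean"), method="complete")
    return [jaccard.gene_ids[i] for i in leaves_list(tree)]


@dataclass
class OrdinationResult:
    method: str
    gene_ids: list[str]
    coordinates: np.ndarray  # (n, 2)
    stress: float | None = None  # NMDS only (Kruskal stress-1)
    eigenvalues: np.ndarray | None = None  # PCoA only, descending
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _check_square(dissimilarity: np.ndarray, n_ids: int) -> np.ndarray:
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != n_ids:
        raise ValueError("dissimilarity must be square and match gene_ids")
    return d


def umap_n_neighbors_range(n_genes: int) -> tuple[int, int]:
    """Valid UMAP n_neighbors range: 2 to ceil(n/3)."""
    return 2, max(2, math.ceil(n_genes / 3))


def ordinate(
    dissimilarity: np.ndarray,
    gene_ids: list[str],
    method: str,
    params: dict | None = None,
    seed: int = 42,
) -> OrdinationResult:
    """2-D ordination of a dissimilarity matrix.

    method:
        ``"NMDS"`` — non-metric MDS minimizing Kruskal stress-1 from 20
        random starts (overridable via ``params["n_init"]``);
        ``"PCoA"`` — classical scaling (exact for Euclidean-embeddable
        input);
        ``"UMAP"`` — with ``n_neighbors`` restricted to [2, ceil(n/3)] and
        ``min_dist`` to [0.1, 0.9].
    """
    params = dict(params or {})
    d = _check_square(dissimilarity, len(gene_ids))
    n = len(gene_ids)
    method = method.upper()
    if method == "NMDS":
        from sklearn.manifold import MDS

        n_init = int(params.pop("n_init", 20))
        max_iter = int(params.pop("max_iter", 300))
        model = MDS(
            n_components=2,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_init,
            max_iter=max_iter,
            random_state=seed,
            normalized_stress=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = model.fit_transform(d)
        return OrdinationResult(
            method="NMDS",
            gene_ids=list(gene_ids),
            coordinates=coords,
            stress=float(model.stress_),
            params={"n_init": n_init, "max_iter": max_iter},
            seed=seed,
        )
    if method == "PCOA":
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = pcoa(DistanceMatrix(d, ids=gene_ids), number_of_dimensions=0)
        coords = result.samples.to_numpy()
        if coords.shape[1] < 2:
            coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])
        eigvals = np.sort(result.eigvals.to_numpy())[::-1]
        return OrdinationResult(
            method="PCoA",
            gene_ids=list(gene_ids),
            coordinates=coords[:, :2],
            eigenvalues=eigvals,
            params={},
            seed=seed,
        )
    if method == "UMAP":
        lo, hi = umap_n_neighbors_range(n)
        n_neighbors = int(params.pop("n_neighbors", min(15, hi)))
        min_dist = float(params.pop("min_dist", 0.1))
        if not lo <= n_neighbors <= hi:
            raise ValueError(
                f"n_neighbors={n_neighbors} outside valid range [{lo}, {hi}] "
                f"for {n} genes"
            )
        if not 0.1 <= min_dist <= 0.9:
            raise ValueError(
                f"min_dist={min_dist} outside valid range [0.1, 0.9]"
            )
        import umap

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = umap.UMAP(
                n_components=2,
                n_neighbors=n_neighbors,
                min_dist=min_dist,
                metric="precomputed",
                random_state=seed,
            )
            coords = model.fit_transform(d)
        return OrdinationResult(
            method="UMAP",
            gene_ids=list(gene_ids),
            coordinates=np.asarray(coords, dtype=float),
            params={"n_neighbors": n_neighbors, "min_dist": min_dist},
            seed=seed,
        )
    raise ValueError(f"unknown ordination method {method!r}")
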