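import numpy as np
import pytest

from oracles import pam_optimal_cost, power_iteration_eigengene, silhouette_oracle
from panscreen.cluster_phenotype import (
    _pam_cost,
    cluster_association,
    correlation_distance,
    eigengene,
    filter_genes_by_annotation,
    pam_cluster,
    select_k_by_asw,
)
from panscreen.data_io import AbundanceMatrix, SampleMetadata
from sklearn.metrics import silhouette_score


def _copynum(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return AbundanceMatrix(genes, samples, values, "gene_copynum")


class TestCorrelationDistance:
    def test_self_distance_zero(self):
        m = _copynum(np.random.default_rng(0).random((3, 5)))
        d = correlation_distance(m)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_negation_distance_two(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        m = _copynum(np.vstack([x, x.max() + x.min() - x]))
        d = correlation_distance(m)
        assert d[0, 1] == pytest.approx(2.0)

    def test_affine_invariance(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        m = _copynum(np.vstack([x, 2 * x + 7]))
        assert correlation_distance(m)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_gene_maximal(self, caplog):
        m = _copynum([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with caplog.at_level("WARNING"):
            d = correlation_distance(m)
        assert d[0, 1] == 1.0
        assert d[0, 0] == 0.0
        assert any("zero-variance" in r.message for r in caplog.records)


def _two_blobs(rng, n_per=5, n_samples=12):
    a = rng.normal(0, 0.05, (n_per, n_samples)) + rng.normal(0, 1, n_samples)
    b = rng.normal(0, 0.05, (n_per, n_samples)) + rng.normal(0, 1, n_samples)
    values = np.vstack([a, b])
    return values - values.min() + 0.1  # copy numbers are non-negative


class TestPamCluster:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        d = correlation_distance(_copynum(_two_blobs(rng)))
        model = pam_cluster(d, 2)
        labels = model.labels
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_cost_equals_bruteforce_optimum_small(self):
        # acceptance property: exact optimum on n <= 8
        rng = np.random.default_rng(1)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, min(4, n)))
            points = rng.random((n, 2))
            d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
            model = pam_cluster(d, k)
            assert _pam_cost(d, model.medoids) == pytest.approx(
                pam_optimal_cost(d, k), abs=1e-9
            ), trial

    def test_duplicates_co_clustered(self):
        rng = np.random.default_rng(2)
        base = rng.random((4, 6))
        values = np.vstack([base, base[0]])  # g4 duplicates g0
        d = np.sqrt(((values[:, None] - values[None, :]) ** 2).sum(-1))
        model = pam_cluster(d, 2)
        assert model.labels[0] == model.labels[4]

    def test_invalid_k(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            pam_cluster(d, 4)
        with pytest.raises(ValueError):
            pam_cluster(d, 1)


class TestSelectKByAsw:
    def test_three_blobs(self):
        rng = np.random.default_rng(3)
        centers = rng.normal(0, 3, (3, 10))
        values = np.vstack(
            [c + rng.normal(0, 0.05, (6, 10)) for c in centers]
        )
        d = np.sqrt(((values[:, None] - values[None, :]) ** 2).sum(-1))
        model = select_k_by_asw(d, k_min=2, k_max=6)
        assert model.k == 3
        assert model.asw_by_k[3] > 0.9

    def test_asw_matches_hand_silhouette(self):
        rng = np.random.default_rng(4)
        points = rng.random((6, 2))
        d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
        model = pam_cluster(d, 2)
        asw_sklearn = silhouette_score(d, model.labels, metric="precomputed")
        assert asw_sklearn == pytest.approx(
            silhouette_oracle(d, model.labels), abs=1e-12
        )

    def test_uniform_random_low_asw(self):
        rng = np.random.default_rng(5)
        d = rng.random((30, 30))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        model = select_k_by_asw(d, k_min=2, k_max=6)
        assert all(asw < 0.25 for asw in model.asw_by_k.values())

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            select_k_by_asw(np.zeros((3, 3)))


class TestEigengene:
    def test_rank_one_recovery(self):
        rng = np.random.default_rng(6)
        v = np.abs(rng.random(8))
        v /= np.linalg.norm(v)
        u = rng.random(4) + 0.5
        x = np.outer(u, v)
        np.testing.assert_allclose(eigengene(x), v, atol=1e-8)

    def test_single_gene_normalized(self):
        x = np.array([[3.0, 4.0]])
        np.testing.assert_allclose(eigengene(x), [0.6, 0.8])

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.random((5, 8))
        got = eigengene(x)
        want = power_iteration_eigengene(x)
        if want @ got < 0:
            want = -want
        np.testing.assert_allclose(got, want, atol=1e-6)
        assert np.linalg.norm(got) == pytest.approx(1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.random((4, 7))
        base = eigengene(x)
        gene_perm = rng.permutation(4)
        np.testing.assert_allclose(eigengene(x[gene_perm]), base, atol=1e-9)
        sample_perm = rng.permutation(7)
        np.testing.assert_allclose(
            eigengene(x[:, sample_perm]), base[sample_perm], atol=1e-9
        )

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            eigengene(np.zeros((2, 3)))


def _assoc_setup(rng, shift=0.0, n_per_group=40, n_genes=4):
    base = rng.normal(1.0, 0.3, (n_genes, 2 * n_per_group))
    base[:, :n_per_group] += shift
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    meta = SampleMetadata(
        groups={
            s: ("case" if i < n_per_group else "control")
            for i, s in enumerate(samples)
        }
    )
    matrix = AbundanceMatrix(
        [f"g{i}" for i in range(n_genes)],
        samples,
        np.clip(base, 0, None),
        "gene_copynum",
    )
    from panscreen.cluster_phenotype import ClusterModel

    model = ClusterModel(
        labels=np.zeros(n_genes, dtype=int), medoids=[0], k=1
    )
    return model, matrix, meta


class TestClusterAssociation:
    def test_no_shift_not_significant(self):
        rng = np.random.default_rng(9)
        model, matrix, meta = _assoc_setup(rng, shift=0.0)
        (assoc,) = cluster_association(model, matrix, meta, boot_reps=50, seed=0)
        assert assoc.wilcoxon_p > 0.05
        assert not assoc.significant

    def test_strong_shift_significant_with_matching_t_sign(self):
        rng = np.random.default_rng(10)
        model, matrix, meta = _assoc_setup(rng, shift=0.9)  # 3 SD
        (assoc,) = cluster_association(model, matrix, meta, boot_reps=100, seed=0)
        assert assoc.significant
        assert all(t > 0 for t in assoc.mean_bootstrap_t.values())

    def test_constant_eigengene_p_one(self):
        model, matrix, meta = _assoc_setup(np.random.default_rng(11))
        matrix.values[:] = 1.0  # identical across groups
        (assoc,) = cluster_association(model, matrix, meta, boot_reps=10, seed=0)
        assert assoc.wilcoxon_p == pytest.approx(1.0)
        assert not assoc.significant

    def test_bootstrap_deterministic_under_seed(self):
        rng = np.random.default_rng(12)
        model, matrix, meta = _assoc_setup(rng, shift=0.5)
        a1 = cluster_association(model, matrix, meta, boot_reps=50, seed=3)[0]
        a2 = cluster_association(model, matrix, meta, boot_reps=50, seed=3)[0]
        assert a1.mean_bootstrap_t == a2.mean_bootstrap_t

    def test_bootstrap_mean_converges(self):
        rng = np.random.default_rng(13)
        model, matrix, meta = _assoc_setup(rng, shift=0.5, n_genes=3)
        gene = matrix.feature_ids[0]

        def spread(reps, seeds):
            means = [
                cluster_association(
                    model, matrix, meta, boot_reps=reps, seed=s
                )[0].mean_bootstrap_t[gene]
                for s in seeds
            ]
            return np.std(means)

        assert spread(200, range(5)) < spread(10, range(5, 10)) + 0.05

    def test_small_clusters_discarded(self):
        rng = np.random.default_rng(14)
        model, matrix, meta = _assoc_setup(rng, n_genes=5)
        model.labels = np.array([0, 0, 0, 1, 1])  # cluster 1 has 2 genes
        model.medoids = [0, 3]
        model.k = 2
        assocs = cluster_association(model, matrix, meta, boot_reps=10, seed=0)
        assert [a.cluster_id for a in assocs] == [0]

    def test_tiny_group_errors(self):
        rng = np.random.default_rng(15)
        model, matrix, meta = _assoc_setup(rng)
        meta.groups = {s: "control" for s in matrix.sample_ids}
        meta.groups[matrix.sample_ids[0]] = "case"
        with pytest.raises(ValueError, match="2 samples"):
            cluster_association(model, matrix, meta, boot_reps=10, seed=0)

    def test_eigengene_unit_norm(self):
        rng = np.random.default_rng(16)
        model, matrix, meta = _assoc_setup(rng, shift=0.2)
        (assoc,) = cluster_association(model, matrix, meta, boot_reps=10, seed=0)
        assert np.linalg.norm(assoc.eigengene) == pytest.approx(1.0)
        assert 0 < assoc.bh_q <= 1


class TestAnnotationFilter:
    def test_case_insensitive_match_plus_extras(self):
        descriptions = {
            "g1": "Flagellar hook protein",
            "g2": "ABC transporter",
            "g3": "flagellin",
            "g4": None,
        }
        assert filter_genes_by_annotation(descriptions, "flag", ["g4"]) == [
            "g1",
            "g3",
            "g4",
        ]
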