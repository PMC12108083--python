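import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_oracle, dbh_oracle, fisher_oracle, support_oracle
from panscreen.data_io import AbundanceMatrix, SampleMetadata
from panscreen.prevalence import (
    differential_prevalence,
    differential_prevalence_pooled,
    discrete_fdr_adjust,
    fisher_support,
    fisher_two_sided,
    presence_from_copynum,
)


class TestPresenceFromCopynum:
    def test_threshold_inclusive(self):
        m = AbundanceMatrix(
            ["g"], ["s1", "s2", "s3", "s4"],
            np.array([[0.0, 0.34, 0.35, 2.0]]), "gene_copynum",
        )
        out = presence_from_copynum(m, threshold=0.35)
        np.testing.assert_array_equal(out.values, [[0, 0, 1, 1]])
        assert out.kind == "gene_presence"

    def test_zero_threshold_all_present(self):
        m = AbundanceMatrix(
            ["g"], ["s1", "s2"], np.array([[0.0, 0.1]]), "gene_copynum"
        )
        np.testing.assert_array_equal(
            presence_from_copynum(m, threshold=0.0).values, [[1, 1]]
        )

    def test_all_zero_matrix(self):
        m = AbundanceMatrix(
            ["g1", "g2"], ["s1", "s2"], np.zeros((2, 2)), "gene_copynum"
        )
        np.testing.assert_array_equal(
            presence_from_copynum(m, 0.35).values, np.zeros((2, 2))
        )

    def test_negative_threshold_errors(self):
        m = AbundanceMatrix(["g"], ["s"], np.array([[1.0]]), "gene_copynum")
        with pytest.raises(ValueError, match="non-negative"):
            presence_from_copynum(m, -0.1)


class TestFisherTwoSided:
    def test_symmetric_table(self):
        assert fisher_two_sided(5, 5, 5, 5) == 1.0

    def test_fliw_counts_significant(self):
        # 0/51 cases vs 20/77 controls
        p = fisher_two_sided(0, 51, 20, 57)
        assert p < 1e-3
        assert p == pytest.approx(fisher_oracle(0, 51, 20, 57), rel=1e-10)

    def test_perfect_separation(self):
        assert fisher_two_sided(10, 0, 0, 10) == pytest.approx(
            fisher_oracle(10, 0, 0, 10), rel=1e-10
        )

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            fisher_two_sided(0, 0, 3, 4)

    def test_matches_oracle_all_margins_up_to_12(self):
        # acceptance property: exhaustive agreement on all tables with
        # n_cases + n_controls <= 12
        for n1 in range(1, 12):
            for n2 in range(1, 13 - n1):
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        got = fisher_two_sided(a, n1 - a, c, n2 - c)
                        want = fisher_oracle(a, n1 - a, c, n2 - c)
                        assert got == pytest.approx(want, rel=1e-9), (a, n1, c, n2)

    @given(
        st.integers(1, 25),
        st.integers(1, 25),
        st.data(),
    )
    @settings(max_examples=60, deadline=None)
    def test_group_swap_invariance(self, n1, n2, data):
        a = data.draw(st.integers(0, n1))
        c = data.draw(st.integers(0, n2))
        p1 = fisher_two_sided(a, n1 - a, c, n2 - c)
        p2 = fisher_two_sided(c, n2 - c, a, n1 - a)
        assert p1 == pytest.approx(p2, rel=1e-9)

    @given(st.integers(1, 25), st.integers(1, 25), st.data())
    @settings(max_examples=60, deadline=None)
    def test_present_absent_swap_invariance(self, n1, n2, data):
        a = data.draw(st.integers(0, n1))
        c = data.draw(st.integers(0, n2))
        p1 = fisher_two_sided(a, n1 - a, c, n2 - c)
        p2 = fisher_two_sided(n1 - a, a, n2 - c, c)
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestFisherSupport:
    def test_degenerate_margins(self):
        assert fisher_support(1, 1, 1) == (1.0,)

    def test_support_contains_observed(self):
        for n1, n2 in [(4, 7), (6, 6), (10, 3)]:
            for k in range(n1 + n2 + 1):
                support = fisher_support(n1, n2, k)
                assert support[-1] == pytest.approx(1.0)
                for a in range(max(0, k - n2), min(n1, k) + 1):
                    p = fisher_two_sided(a, n1 - a, k - a, n2 - (k - a))
                    assert any(abs(p - s) < 1e-12 for s in support)

    def test_matches_enumeration_oracle(self):
        got = fisher_support(5, 5, 5)
        want = support_oracle(5, 5, 5)
        np.testing.assert_allclose(got, want, rtol=1e-12)


class TestDiscreteFdrAdjust:
    def test_all_ones(self):
        q = discrete_fdr_adjust([1.0, 1.0, 1.0], [(1.0,), (0.5, 1.0), (1.0,)])
        np.testing.assert_allclose(q, 1.0)

    def test_single_hypothesis_closed_form(self):
        # with m = 1 the adjusted value of the smallest attainable p is itself
        support = (0.02, 0.4, 1.0)
        q = discrete_fdr_adjust([0.02], [support])
        assert q[0] == pytest.approx(0.02)

    def test_three_hypotheses_vs_bruteforce(self):
        supports = [
            (0.01, 0.2, 1.0),
            (0.05, 0.3, 1.0),
            (0.02, 0.5, 1.0),
        ]
        p = [0.01, 0.3, 0.02]
        got = discrete_fdr_adjust(p, supports)
        want = dbh_oracle(p, supports)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="supports"):
            discrete_fdr_adjust([0.5], [(1.0,), (1.0,)])

    def test_random_instances_match_oracle_and_dominate_bh(self):
        # acceptance property: q_dbh <= q_bh on 200 random instances
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = int(rng.integers(1, 8))
            n1 = int(rng.integers(2, 9))
            n2 = int(rng.integers(2, 9))
            supports = []
            p = []
            for _ in range(m):
                k = int(rng.integers(0, n1 + n2 + 1))
                sup = fisher_support(n1, n2, k)
                supports.append(sup)
                p.append(float(rng.choice(sup)))
            got = discrete_fdr_adjust(p, supports)
            np.testing.assert_allclose(got, dbh_oracle(p, supports), rtol=1e-9)
            assert np.all(got <= bh_oracle(p) + 1e-12)
            assert np.all((got > 0) & (got <= 1))

    def test_rejections_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        supports = [fisher_support(6, 6, int(k)) for k in rng.integers(0, 13, 10)]
        p = [float(rng.choice(s)) for s in supports]
        q = discrete_fdr_adjust(p, supports)
        previous = set()
        for alpha in (0.01, 0.05, 0.1, 0.5, 1.0):
            rejected = {i for i, qi in enumerate(q) if qi <= alpha}
            assert previous.issubset(rejected)
            previous = rejected


def _presence_matrix(values, n_cases, n_controls):
    n = n_cases + n_controls
    samples = [f"s{i}" for i in range(n)]
    genes = [f"g{i}" for i in range(values.shape[0])]
    meta = SampleMetadata(
        groups={
            s: ("case" if i < n_cases else "control")
            for i, s in enumerate(samples)
        }
    )
    return (
        AbundanceMatrix(genes, samples, values.astype(float), "gene_presence"),
        meta,
    )


class TestDifferentialPrevalence:
    def test_ubiquitous_gene_not_significant(self):
        presence, meta = _presence_matrix(np.ones((1, 10)), 5, 5)
        (res,) = differential_prevalence(presence, meta)
        assert res.p_raw == 1.0
        assert not res.significant

    def test_counts_and_margins(self):
        values = np.array([[1, 1, 0, 1, 0, 0]])
        presence, meta = _presence_matrix(values, 3, 3)
        (res,) = differential_prevalence(presence, meta)
        assert (res.a, res.b, res.c, res.d) == (2, 1, 1, 2)
        assert res.a + res.b == 3 and res.c + res.d == 3

    def test_fliq_like_gene_flagged_in_null_ensemble(self):
        # a 41/51 vs 37/77 signal gene inside a 100-gene group-balanced
        # ensemble comes out significant at alpha = 0.05
        rng = np.random.default_rng(11)
        n_cases, n_controls = 51, 77
        rows = []
        for _ in range(100):
            prob = rng.uniform(0.2, 0.8)
            rows.append(rng.random(n_cases + n_controls) < prob)
        signal = np.concatenate(
            [
                np.r_[np.ones(41), np.zeros(10)],
                np.r_[np.ones(37), np.zeros(40)],
            ]
        )
        values = np.vstack([np.array(rows), signal])
        presence, meta = _presence_matrix(values, n_cases, n_controls)
        results = {r.gene_id: r for r in differential_prevalence(presence, meta)}
        assert results["g100"].significant
        assert (results["g100"].a, results["g100"].c) == (41, 37)

    def test_null_permutation_fdr(self):
        # on label-permuted null data the rejection count stays small
        rng = np.random.default_rng(5)
        m, n = 120, 60
        values = (rng.random((m, n)) < 0.5).astype(float)
        total_rejections = 0
        n_perms = 8
        for _ in range(n_perms):
            perm = rng.permutation(n)
            presence, meta = _presence_matrix(values[:, perm], 30, 30)
            results = differential_prevalence(presence, meta)
            total_rejections += sum(r.significant for r in results)
        assert total_rejections / n_perms <= 0.05 * m

    def test_zero_group_errors(self):
        presence = AbundanceMatrix(
            ["g"], ["s1", "s2"], np.array([[1.0, 0.0]]), "gene_presence"
        )
        meta = SampleMetadata(groups={"s1": "case", "s2": "case"})
        with pytest.raises(ValueError, match="both groups"):
            differential_prevalence(presence, meta)

    def test_sorted_by_q_then_gene(self):
        rng = np.random.default_rng(2)
        values = (rng.random((20, 30)) < 0.5).astype(float)
        presence, meta = _presence_matrix(values, 15, 15)
        results = differential_prevalence(presence, meta)
        keys = [(r.q, r.gene_id) for r in results]
        assert keys == sorted(keys)

    def test_pooled_matches_single_when_one_species(self):
        rng = np.random.default_rng(4)
        values = (rng.random((10, 20)) < 0.5).astype(float)
        presence, meta = _presence_matrix(values, 10, 10)
        single = differential_prevalence(presence, meta, species_id="sp1")
        pooled = differential_prevalence_pooled({"sp1": presence}, meta)
        assert [(r.gene_id, r.p_raw, r.q) for r in single] == [
            (r.gene_id, r.p_raw, r.q) for r in pooled
        ]
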