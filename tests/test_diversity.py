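"""Oracle and property tests for Hill numbers and the C_qN overlap family.

Classic pairwise closed forms (Sørensen, Horn, Morisita–Horn) are
implemented here independently of the package and used as oracles.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grainbeta.community import AbundanceMatrix, ValidationError
from grainbeta.diversity import (
    beta_ratio,
    hill_number,
    mean_alpha,
    mean_pairwise_between,
    multi_alpha,
    multi_gamma,
    overlap_cqn,
    pairwise_matrix,
    pairwise_similarity,
    remove_singletons,
    top_biomass_ranks,
)

from conftest import random_community


# ---------------------------------------------------------------------------
# independent classic oracles
# ---------------------------------------------------------------------------

def classic_sorensen(p, q):
    a, b = np.asarray(p) > 0, np.asarray(q) > 0
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


def _shannon(p):
    p = np.asarray(p, float)
    p = p[p > 0]
    return -(p * np.log(p)).sum()


def classic_horn(p, q):
    p, q = np.asarray(p, float), np.asarray(q, float)
    mix = (p + q) / 2.0
    return 1.0 - (_shannon(mix) - 0.5 * (_shannon(p) + _shannon(q))) / math.log(2.0)


def classic_morisita_horn(p, q):
    p, q = np.asarray(p, float), np.asarray(q, float)
    return 2.0 * (p * q).sum() / ((p**2).sum() + (q**2).sum())


CLASSIC = {0.0: classic_sorensen, 1.0: classic_horn, 2.0: classic_morisita_horn}


# ---------------------------------------------------------------------------
# Hill numbers
# ---------------------------------------------------------------------------

class TestHillNumber:
    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0, 5.0])
    def test_equal_abundances_give_richness(self, q):
        s = 7
        assert hill_number(np.full(s, 1.0 / s), q) == pytest.approx(s, rel=1e-12)

    def test_shannon_and_simpson_closed_forms(self):
        p = np.array([0.8, 0.2])
        assert hill_number(p, 1) == pytest.approx(
            math.exp(-(0.8 * math.log(0.8) + 0.2 * math.log(0.2))), rel=1e-12
        )
        assert hill_number(p, 2) == pytest.approx(1.0 / 0.68, rel=1e-12)

    def test_zero_entries_contribute_nothing(self):
        assert hill_number([0.5, 0.5, 0.0], 0) == 2.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            hill_number([0.9, 0.2], 1)  # sums to 1.1
        with pytest.raises(ValidationError):
            hill_number([1.2, -0.2], 2)

    @given(st.integers(0, 2**31 - 1))
    def test_non_increasing_in_q(self, seed):
        rng = np.random.default_rng(seed)
        p = random_community(rng)
        qs = np.sort(rng.uniform(0, 5, size=5))
        vals = [hill_number(p, q) for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
        assert vals[-1] >= 1.0 - 1e-12


# ---------------------------------------------------------------------------
# multi-assemblage gamma / alpha / C_qN
# ---------------------------------------------------------------------------

class TestMultiAssemblage:
    def test_hand_computed_gamma_alpha_q2(self):
        P = [[1.0, 0.0], [0.5, 0.5]]
        assert multi_gamma(P, 2) == pytest.approx(1.6, rel=1e-12)
        assert multi_alpha(P, 2) == pytest.approx(4.0 / 3.0, rel=1e-12)
        assert overlap_cqn(P, 2).cqn == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_disjoint_single_species_communities(self):
        P = [[1.0, 0.0], [0.0, 1.0]]
        assert multi_gamma(P, 0) == 2.0
        assert multi_alpha(P, 0) == 1.0
        res = overlap_cqn(P, 0)
        assert res.cqn == 0.0 and res.beta == 1.0

    @pytest.mark.parametrize("q", [0.0, 0.7, 1.0, 2.0, 3.5])
    def test_identical_communities_fully_overlap(self, q, rng):
        p = random_community(rng, 12)
        P = np.tile(p, (4, 1))
        assert multi_gamma(P, q) == pytest.approx(hill_number(p, q), rel=1e-9)
        assert multi_alpha(P, q) == pytest.approx(hill_number(p, q), rel=1e-9)
        res = overlap_cqn(P, q)
        assert res.cqn == pytest.approx(1.0, abs=1e-9)
        assert res.beta + res.cqn == 1.0

    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.0, 0.5, 1.0, 2.0]))
    def test_beta_ratio_bounds_and_permutation_invariance(self, seed, q):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        P = np.vstack([random_community(rng, 15) for _ in range(n)])
        d = beta_ratio(P, q)
        assert 1.0 - 1e-9 <= d <= n + 1e-9
        perm = rng.permutation(n)
        assert multi_gamma(P[perm], q) == pytest.approx(multi_gamma(P, q), rel=1e-12)
        assert multi_alpha(P[perm], q) == pytest.approx(multi_alpha(P, q), rel=1e-12)
        assert overlap_cqn(P[perm], q).cqn == pytest.approx(
            overlap_cqn(P, q).cqn, abs=1e-12
        )

    def test_sorensen_closed_form_for_shared_fraction(self):
        # N equal-size equally-abundant communities sharing species:
        # brute-force S and S-bar against the q=0 reduction (N - S/Sbar)/(N-1)
        n, per, shared = 3, 8, 4
        species = {}
        cols = shared + n * (per - shared)
        P = np.zeros((n, cols))
        nxt = shared
        for j in range(n):
            own = list(range(shared)) + list(range(nxt, nxt + per - shared))
            nxt += per - shared
            P[j, own] = 1.0 / per
        s_total = (P.sum(axis=0) > 0).sum()
        s_bar = np.mean([(row > 0).sum() for row in P])
        expected = (n - s_total / s_bar) / (n - 1)
        assert overlap_cqn(P, 0).cqn == pytest.approx(expected, rel=1e-12)

    def test_q_to_1_continuity(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 5))
            P = np.vstack([random_community(rng, 12) for _ in range(n)])
            c1 = overlap_cqn(P, 1.0).cqn
            assert overlap_cqn(P, 1.0 + 1e-6).cqn == pytest.approx(c1, abs=1e-4)
            assert overlap_cqn(P, 1.0 - 1e-6).cqn == pytest.approx(c1, abs=1e-4)

    def test_single_assemblage_rejected(self):
        with pytest.raises(ValidationError):
            overlap_cqn([[0.5, 0.5]], 2)


# ---------------------------------------------------------------------------
# pairwise similarity
# ---------------------------------------------------------------------------

class TestPairwise:
    def test_sorensen_on_species_sets(self):
        assert pairwise_similarity([1, 1, 0], [0, 1, 1], 0) == pytest.approx(0.5)

    def test_identical_vectors_morisita_horn_is_one(self, rng):
        p = random_community(rng, 10)
        assert pairwise_similarity(p, p, 2) == pytest.approx(1.0, abs=1e-12)

    def test_printed_richness_sorensen(self):
        # 105 vs 181 species with 63 shared -> 2*63/286
        a = np.r_[np.ones(63), np.ones(42), np.zeros(118)]
        b = np.r_[np.ones(63), np.zeros(42), np.ones(118)]
        assert pairwise_similarity(a, b, 0) == pytest.approx(126 / 286, rel=1e-12)

    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.0, 1.0, 2.0]))
    def test_equals_classic_closed_form(self, seed, q):
        rng = np.random.default_rng(seed)
        s = int(rng.integers(3, 30))
        p1, p2 = random_community(rng, s), random_community(rng, s)
        assert pairwise_similarity(p1, p2, q) == pytest.approx(
            CLASSIC[q](p1, p2), abs=1e-9
        )

    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0, 0.5])
    def test_vectorised_matrix_matches_elementwise(self, q, rng):
        A = np.vstack([random_community(rng, 12) for _ in range(4)])
        B = np.vstack([random_community(rng, 12) for _ in range(3)])
        C = pairwise_matrix(A, B, q)
        for i in range(4):
            for j in range(3):
                assert C[i, j] == pytest.approx(
                    pairwise_similarity(A[i], B[j], q), abs=1e-9
                )


class TestMeanPairwiseBetween:
    def _matrix(self, rows, habs):
        df = pd.DataFrame(
            np.asarray(rows, float),
            index=[f"u{i}" for i in range(len(rows))],
            columns=[f"s{j}" for j in range(len(rows[0]))],
        )
        habitats = pd.Series(habs, index=df.index)
        return AbundanceMatrix(df, "biomass"), habitats

    def test_single_pair_equals_pairwise_value(self, rng):
        m, h = self._matrix([[3, 1, 0], [0, 2, 2]], ["oil_palm", "forest"])
        res = mean_pairwise_between(m, h, 2, b=50, rng=rng)
        assert res.mean == pytest.approx(
            pairwise_similarity([3, 1, 0], [0, 2, 2], 2), abs=1e-12
        )

    def test_mean_matches_enumeration(self, rng):
        rows = [[3, 1, 0], [1, 1, 2], [0, 2, 2], [4, 0, 1]]
        m, h = self._matrix(rows, ["oil_palm", "oil_palm", "forest", "forest"])
        res = mean_pairwise_between(m, h, 1, b=50, rng=rng)
        vals = [
            pairwise_similarity(rows[i], rows[j], 1)
            for i in (0, 1)
            for j in (2, 3)
        ]
        assert res.n_pairs == 4
        assert res.mean == pytest.approx(np.mean(vals), abs=1e-12)

    def test_identical_communities_mean_one_se_zero(self, rng):
        m, h = self._matrix(
            [[2, 1, 1]] * 4, ["oil_palm", "oil_palm", "forest", "forest"]
        )
        res = mean_pairwise_between(m, h, 2, b=200, rng=rng)
        assert res.mean == pytest.approx(1.0, abs=1e-12)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_missing_habitat_is_an_error(self, rng):
        m, h = self._matrix([[1, 0], [0, 1]], ["forest", "forest"])
        with pytest.raises(ValidationError):
            mean_pairwise_between(m, h, 0, b=10, rng=rng)


# ---------------------------------------------------------------------------
# mean alpha, singletons, ranks
# ---------------------------------------------------------------------------

class TestMeanAlpha:
    def test_mean_of_per_sample_hill(self, rng):
        df = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 1, 1]], index=["a", "b"], columns=list("wxyz")
        )
        res = mean_alpha(AbundanceMatrix(df, "count"), 0, b=500, rng=rng)
        assert res.mean == pytest.approx(3.0)  # (2 + 4) / 2

    def test_q0_mean_equals_mean_observed_richness(self, toy_counts, rng):
        res = mean_alpha(toy_counts, 0, b=100, rng=rng)
        richness = (toy_counts.values > 0).sum(axis=1)
        assert res.mean == pytest.approx(richness.mean())

    def test_identical_samples_se_zero(self, rng):
        df = pd.DataFrame([[3, 1]] * 5, index=list("abcde"), columns=["x", "y"])
        res = mean_alpha(AbundanceMatrix(df, "count"), 1, b=300, rng=rng)
        assert res.se == pytest.approx(0.0, abs=1e-12)


class TestSingletons:
    def test_definition_boundary(self):
        df = pd.DataFrame(
            [[1, 1, 5], [0, 1, 5]], index=["a", "b"], columns=["single", "double", "common"]
        )
        out = remove_singletons(AbundanceMatrix(df, "count"))
        assert out.species_ids == ["double", "common"]

    def test_idempotent(self, toy_counts):
        once = remove_singletons(toy_counts)
        assert remove_singletons(once).data.equals(once.data)

    def test_biomass_input_refused(self, toy_counts):
        bio = AbundanceMatrix(toy_counts.data * 0.5, "biomass")
        with pytest.raises(ValidationError, match="count"):
            remove_singletons(bio)


class TestTopBiomassRanks:
    def test_ordering_and_tie_break(self):
        df = pd.DataFrame(
            [[5, 3, 3], [5, 3, 3]], index=["u1", "u2"], columns=["b", "c", "a"]
        )
        table = top_biomass_ranks(AbundanceMatrix(df, "biomass"), k=3)
        assert table["species_id"].tolist() == ["b", "a", "c"]
        assert table["mean_biomass_mg_per_unit"].tolist() == [5.0, 3.0, 3.0]

    def test_k_larger_than_species_count(self):
        df = pd.DataFrame([[5, 3]], index=["u1"], columns=["a", "b"])
        assert len(top_biomass_ranks(AbundanceMatrix(df, "biomass"), k=20)) == 2

    def test_mean_per_unit_denominator_after_pooling(self):
        # 3-species toy: pooling two units halves the unit count, doubling
        # the per-unit means; hand-computed expectations
        df = pd.DataFrame(
            [[4, 1, 0], [0, 1, 6]], index=["u1", "u2"], columns=["a", "b", "c"]
        )
        m = AbundanceMatrix(df, "biomass")
        fine = top_biomass_ranks(m, 3)
        assert fine["mean_biomass_mg_per_unit"].tolist() == [3.0, 2.0, 1.0]
        pooled = AbundanceMatrix(
            pd.DataFrame([[4, 2, 6]], index=["u1+u2"], columns=["a", "b", "c"]),
            "biomass",
        )
        coarse = top_biomass_ranks(pooled, 3)
        assert coarse["species_id"].tolist() == ["c", "a", "b"]
        assert coarse["mean_biomass_mg_per_unit"].tolist() == [6.0, 4.0, 2.0]
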