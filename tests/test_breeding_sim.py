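"""Meiosis, mating designs, DH derivation and random mating."""

import numpy as np
import pytest
from scipy import stats

from gpdva.breeding_sim import (
    CrossPlan,
    Individual,
    Population,
    design_crosses,
    dh_population,
    gametes,
    haldane,
    inverse_haldane,
    make_dh,
    meiosis,
    random_mate,
    run_replication,
    sample_progeny,
)
from gpdva.genotypes import GenotypeMatrix, InvalidInputError

from conftest import make_map


def f1_individual(gmap, phase="coupling"):
    L = gmap.n_loci
    h1 = np.ones(L, dtype=np.uint8)
    h2 = np.zeros(L, dtype=np.uint8)
    if phase == "repulsion":
        h1, h2 = h1.copy(), h2.copy()
        h1[1], h2[1] = 0, 1
    return Individual(np.stack([h1, h2]), gmap, id="F1")


def observed_recomb_fraction(parent, gmap, n, seed):
    tiled = np.repeat(parent.haplotypes[None], n, axis=0)
    g = gametes(tiled, gmap, np.random.default_rng(seed))
    return np.mean(g[:, 0] != g[:, 1])


def binom_ci99(n, p):
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
    return lo / n, hi / n


class TestHaldane:
    def test_known_values(self):
        assert haldane(0.0) == 0.0
        assert haldane(50.0) == pytest.approx(0.5 * (1 - np.exp(-1.0)))
        assert haldane(1e9) == pytest.approx(0.5)

    def test_inverse_roundtrip(self):
        for r in [0.05, 0.25, 0.4]:
            assert haldane(inverse_haldane(r)) == pytest.approx(r)


class TestMeiosis:
    def test_zero_distance_always_cosegregates(self):
        gmap = make_map({"1": [5.0, 5.0]})
        parent = f1_individual(gmap)
        frac = observed_recomb_fraction(parent, gmap, 2000, 0)
        assert frac == 0.0

    def test_unlinked_loci_recombine_at_half(self):
        gmap = make_map({"1": [0.0], "2": [0.0]})
        frac = observed_recomb_fraction(f1_individual(gmap), gmap, 10_000, 1)
        lo, hi = binom_ci99(10_000, 0.5)
        assert lo <= frac <= hi

    def test_fifty_cM_matches_haldane(self):
        gmap = make_map({"1": [0.0, 50.0]})
        frac = observed_recomb_fraction(f1_individual(gmap), gmap, 10_000, 2)
        lo, hi = binom_ci99(10_000, haldane(50.0))
        assert lo <= frac <= hi

    def test_no_interference_composition_over_three_loci(self):
        # r13 = r12 + r23 - 2 r12 r23 must emerge from the per-interval walk
        gmap = make_map({"1": [0.0, 20.0, 50.0]})
        parent = f1_individual(gmap)
        tiled = np.repeat(parent.haplotypes[None], 20_000, axis=0)
        g = gametes(tiled, gmap, np.random.default_rng(3))
        frac13 = np.mean(g[:, 0] != g[:, 2])
        r12, r23 = haldane(20.0), haldane(30.0)
        expected = r12 + r23 - 2 * r12 * r23
        assert expected == pytest.approx(haldane(50.0))  # Haldane composes exactly
        lo, hi = binom_ci99(20_000, expected)
        assert lo <= frac13 <= hi

    def test_unaligned_parent_rejected(self):
        gmap = make_map({"1": [0.0, 10.0]})
        with pytest.raises(InvalidInputError):
            meiosis(f1_individual(gmap), make_map({"1": [0.0, 10.0, 20.0]}))


class TestMakeDh:
    def test_dh_of_homozygote_is_clone(self):
        gmap = make_map({"1": [0.0, 30.0]})
        hom = Individual(np.ones((2, 2), dtype=np.uint8), gmap)
        dh = make_dh(hom, rng=np.random.default_rng(0))
        assert dh.is_homozygous
        np.testing.assert_array_equal(dh.haplotypes, hom.haplotypes)

    def test_dh_of_f1_draws_each_parent_allele_half_the_time(self):
        gmap = make_map({"1": [0.0]})
        pop = Population(np.repeat(f1_individual(gmap).haplotypes[None], 4000, axis=0), gmap)
        dh = dh_population(pop, np.random.default_rng(4))
        frac = dh.haplotypes[:, 0, 0].mean()
        lo, hi = binom_ci99(4000, 0.5)
        assert lo <= frac <= hi
        assert np.array_equal(dh.haplotypes[:, 0], dh.haplotypes[:, 1])

    def test_biparental_dh_gpd_matches_closed_form(self):
        # coupling-phase pair at r = 0.25: E[d_12] = 1 - 2r = 0.5 among DH lines
        r = 0.25
        gmap = make_map({"1": [0.0, float(inverse_haldane(r))]})
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(30):
            pop = Population(np.repeat(f1_individual(gmap).haplotypes[None], 400, axis=0), gmap)
            X = dh_population(pop, rng).to_genotype_matrix()
            from gpdva.genotypes import DisequilibriumDecomposition

            vals.append(DisequilibriumDecomposition.from_genotypes(X).D[0, 1])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - (1 - 2 * r)) <= 3 * se


class TestDesignCrosses:
    @pytest.mark.parametrize("design, n", [("DC", 2), ("FC", 4), ("HC", 6)])
    def test_four_parent_counts(self, design, n):
        plan = design_crosses(["a", "b", "c", "d"], design, np.random.default_rng(0))
        assert plan.n_crosses == n

    @pytest.mark.parametrize("design", ["DC", "FC", "HC"])
    def test_two_parents_single_cross(self, design):
        plan = design_crosses(["a", "b"], design, np.random.default_rng(0))
        assert plan.pairs == (("a", "b"),)

    def test_halfdiallel_sixteen_parents(self):
        plan = design_crosses([f"p{i}" for i in range(16)], "HC", np.random.default_rng(0))
        assert plan.n_crosses == 120

    def test_disjoint_crosses_use_each_parent_once(self):
        plan = design_crosses(list("abcdefgh"), "DC", np.random.default_rng(1))
        used = [p for pair in plan.pairs for p in pair]
        assert sorted(used) == sorted("abcdefgh")

    def test_factorial_is_full_bipartite(self):
        plan = design_crosses(list("abcd"), "FC", np.random.default_rng(2))
        side_a = {p for p, _ in plan.pairs}
        side_b = {q for _, q in plan.pairs}
        assert side_a.isdisjoint(side_b) and len(plan.pairs) == 4

    def test_no_selfs_in_halfdiallel(self):
        plan = design_crosses(list("abcde"), "HC", np.random.default_rng(3))
        assert all(a != b for a, b in plan.pairs)

    @pytest.mark.parametrize("design", ["DC", "FC"])
    def test_odd_parent_count_rejected(self, design):
        with pytest.raises(InvalidInputError):
            design_crosses(list("abc"), design, np.random.default_rng(0))

    def test_fewer_than_two_parents_rejected(self):
        with pytest.raises(InvalidInputError):
            design_crosses(["a"], "HC", np.random.default_rng(0))


def founder_population(gmap, scores, ids=None):
    X = GenotypeMatrix(np.asarray(scores), gmap, tuple(ids) if ids else ())
    return Population.from_inbred_lines(X)


class TestSampleProgeny:
    def test_biparental_f1s_identical(self):
        gmap = make_map({"1": [0.0, 10.0]})
        parents = founder_population(gmap, [[2, 2], [0, 0]], ["A", "B"])
        plan = design_crosses(parents.ids, "DC", np.random.default_rng(0))
        pop = sample_progeny(plan, parents, 50, np.random.default_rng(1))
        assert pop.size == 50
        ref = np.sort(pop.haplotypes[0], axis=0)
        for n in range(50):
            np.testing.assert_array_equal(np.sort(pop.haplotypes[n], axis=0), ref)

    def test_crosses_receive_multinomial_shares(self):
        gmap = make_map({"1": [0.0]})
        parents = founder_population(gmap, [[2], [2], [0], [0]], list("abcd"))
        plan = design_crosses(parents.ids, "HC", np.random.default_rng(2))
        N = 6000
        pop = sample_progeny(plan, parents, N, np.random.default_rng(3))
        pairs = list(zip(pop.mother_idx, pop.father_idx))
        counts = np.array([pairs.count(k) for k in sorted(set(pairs))])
        assert counts.sum() == N and len(counts) == 6
        se = np.sqrt(N * (1 / 6) * (5 / 6))
        assert np.all(np.abs(counts - N / 6) <= 4 * se)

    def test_single_cross_pedigree(self):
        gmap = make_map({"1": [0.0]})
        parents = founder_population(gmap, [[2], [0]], ["A", "B"])
        plan = CrossPlan("DC", parents.ids, (("A", "B"),))
        pop = sample_progeny(plan, parents, 50, np.random.default_rng(4))
        assert set(pop.mother_idx) == {0} and set(pop.father_idx) == {1}

    def test_invalid_N_rejected(self):
        gmap = make_map({"1": [0.0]})
        parents = founder_population(gmap, [[2], [0]], ["A", "B"])
        plan = CrossPlan("DC", parents.ids, (("A", "B"),))
        with pytest.raises(InvalidInputError):
            sample_progeny(plan, parents, 0, np.random.default_rng(0))


class TestRandomMate:
    def test_no_selfing(self):
        gmap = make_map({"1": [0.0, 10.0]})
        pop = founder_population(gmap, [[2, 2], [0, 0], [2, 0]])
        nxt = random_mate(pop, 500, np.random.default_rng(0))
        assert np.all(nxt.mother_idx != nxt.father_idx)

    def test_parent_pair_is_unordered_uniform(self):
        gmap = make_map({"1": [0.0]})
        pop = founder_population(gmap, [[2], [0], [2]])
        nxt = random_mate(pop, 30_000, np.random.default_rng(1))
        pairs = np.sort(np.stack([nxt.mother_idx, nxt.father_idx]), axis=0)
        _, counts = np.unique(pairs.T, axis=0, return_counts=True)
        assert len(counts) == 3
        assert stats.chisquare(counts).pvalue > 0.01

    def test_allele_frequency_conserved_in_expectation(self):
        rng = np.random.default_rng(2)
        gmap = make_map({"1": [0.0]})
        N = 10_000
        scores = 2 * (rng.random((N, 1)) < 0.3).astype(np.int16)
        pop = founder_population(gmap, scores)
        p0 = pop.haplotypes[:, :, 0].mean()
        nxt = random_mate(pop, N, rng)
        p1 = nxt.haplotypes[:, :, 0].mean()
        assert abs(p1 - p0) <= 3 * np.sqrt(p0 * (1 - p0) / (2 * N))

    def test_tiny_population_rejected(self):
        gmap = make_map({"1": [0.0]})
        pop = founder_population(gmap, [[2]])
        with pytest.raises(InvalidInputError):
            random_mate(pop, 10, np.random.default_rng(0))


class TestRunReplication:
    def make_founders(self, seed=0, n=10, L=12):
        rng = np.random.default_rng(seed)
        gmap = make_map({"1": list(np.linspace(0, 80, L // 2)), "2": list(np.linspace(0, 80, L // 2))})
        scores = 2 * (rng.random((n, L)) < 0.5).astype(np.int16)
        return GenotypeMatrix(scores, gmap)

    def test_dh_matrices_are_homozygous_scores(self):
        gens = run_replication(self.make_founders(), "HC", 4, 30, rng=np.random.default_rng(1))
        assert set(gens.dh_matrices) == {"G1-DH", "G2-DH", "G3-DH", "G4-DH"}
        for X in gens.dh_matrices.values():
            assert X.n_individuals == 30
            assert set(np.unique(X.scores)) <= {0, 2}

    def test_biparental_fixed_loci_stay_fixed(self):
        founders = self.make_founders(3)
        gens = run_replication(founders, "DC", 2, 40, rng=np.random.default_rng(2))
        parents = founders.scores[gens.parent_indices]
        fixed = parents[0] == parents[1]
        for X in gens.dh_matrices.values():
            np.testing.assert_array_equal(
                X.scores[:, fixed], np.broadcast_to(parents[0][fixed], (40, fixed.sum()))
            )

    def test_seeded_determinism(self):
        f = self.make_founders(4)
        g1 = run_replication(f, "FC", 4, 25, rng=np.random.default_rng(9))
        g2 = run_replication(f, "FC", 4, 25, rng=np.random.default_rng(9))
        for k in g1.dh_matrices:
            np.testing.assert_array_equal(g1.dh_matrices[k].scores, g2.dh_matrices[k].scores)

    def test_too_many_parents_rejected(self):
        with pytest.raises(InvalidInputError):
            run_replication(self.make_founders(), "HC", 99, 10, rng=np.random.default_rng(0))
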