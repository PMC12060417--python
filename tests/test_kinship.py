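import numpy as np
import pytest

import pedforge as pf

from _oracles import monte_carlo_kinship
from conftest import census_family


class TestExpectedKinship:
    @pytest.mark.parametrize("a,b,phi", [
        ("A", "C", 0.25),     # parent-child
        ("C", "D", 0.25),     # full siblings
        ("GF", "C", 0.125),   # grandparent
        ("B", "C", 0.125),    # avuncular
        ("C", "E", 1 / 16),   # first cousins
        ("C", "H", 0.125),    # half siblings
        ("GF", "GM", 0.0),    # spouses
    ])
    def test_textbook_values(self, three_generations, a, b, phi):
        completed, _ = pf.resolve_founders(three_generations)
        assert pf.expected_kinship(completed, a, b) == pytest.approx(phi)

    def test_non_inbred_self_kinship(self, three_generations):
        completed, _ = pf.resolve_founders(three_generations)
        assert pf.expected_kinship(completed, "C", "C") == 0.5

    def test_inbred_child_of_full_siblings(self):
        """F = 0.25, self-kinship 0.625, kinship to father 0.375.

        phi(K, father S) = 1/4 (1 + F_S) + 1/2 phi(S, mother D)
                         = 1/4 + 1/2 * 1/4 = 0.375,
        confirmed by the single-locus Monte-Carlo oracle.
        """
        ped = pf.Pedigree()
        for iid, sex in [("GF", pf.MALE), ("GM", pf.FEMALE), ("S", pf.MALE), ("D", pf.FEMALE), ("K", pf.FEMALE)]:
            ped.add_individual(iid, sex=sex)
        for p, c in [("GF", "S"), ("GM", "S"), ("GF", "D"), ("GM", "D"), ("S", "K"), ("D", "K")]:
            ped.add_edge(p, c)
        for iid, tick in pf.assign_generation_ticks(ped).items():
            ped.set_tick(iid, tick)
        calc = pf.KinshipCalculator(ped)
        assert calc.inbreeding("K") == pytest.approx(0.25)
        assert calc.phi("K", "K") == pytest.approx(0.625)
        assert calc.phi("K", "S") == pytest.approx(0.375)

    def test_agrees_with_monte_carlo_gene_drop(self, three_generations):
        """Recursion matches a single-locus allele-drop oracle within 3 SE."""
        completed, _ = pf.resolve_founders(three_generations)
        calc = pf.KinshipCalculator(completed)
        rng = np.random.default_rng(5)
        for a, b in [("A", "C"), ("C", "E"), ("C", "H"), ("GF", "C")]:
            n = 3000
            mc = monte_carlo_kinship(completed, a, b, rng, n_reps=n)
            exact = calc.phi(a, b)
            se = np.sqrt(exact * (1 - exact) / n) + 1e-9
            assert abs(mc - exact) < 3 * se + 0.01


class TestRobustEstimator:
    def test_self_comparison_is_half(self):
        g = np.array([1, 0, 1, 2, 1])
        assert pf.estimate_kinship_robust(g, g) == 0.5

    def test_hand_computed_example(self):
        # a=[Aa, AA], b=[Aa, aa]: (1 - 2*1) / (1 + 1) = -0.5
        assert pf.estimate_kinship_robust([1, 0], [1, 2]) == -0.5

    def test_no_heterozygotes_gives_nan(self):
        assert np.isnan(pf.estimate_kinship_robust([0, 2], [2, 0]))

    def test_symmetric(self, rng):
        a = rng.integers(0, 3, size=500)
        b = rng.integers(0, 3, size=500)
        assert pf.estimate_kinship_robust(a, b) == pf.estimate_kinship_robust(b, a)

    def test_matrix_matches_pairwise(self, rng):
        G = rng.integers(0, 3, size=(5, 400))
        K = pf.kinship_matrix_robust(G)
        for i in range(5):
            for j in range(5):
                assert K[i, j] == pytest.approx(pf.estimate_kinship_robust(G[i], G[j]))

    def test_parent_child_converges_to_quarter(self, trio, rng):
        """At 50k independent sites the parent-child estimate is 0.25."""
        panel = pf.generate_synthetic_founders(2, 50_000, 10**8, rng)
        asg = pf.assign_founder_genomes(["P", "M"], panel.samples, rng)
        gs = pf.drop_genomes(trio, None, asg, panel,
                             pf.GenomeParams(10**8, 0.0, 1e-8), rng)
        ids, _, G = gs.genotype_matrix()
        idx = {i: k for k, i in enumerate(ids)}
        est = pf.estimate_kinship_robust(G[idx["P"]], G[idx["C"]])
        assert est == pytest.approx(0.25, abs=0.005)


class TestKinshipReport:
    def test_founder_only_pedigree_all_expected_zero(self, rng):
        ped = pf.Pedigree()
        for i in range(4):
            ped.add_individual(f"F{i}", sex=pf.MALE if i % 2 else pf.FEMALE, tick=1)
        panel = pf.generate_synthetic_founders(4, 500, 10**6, rng)
        asg = pf.assign_founder_genomes(ped.individuals, panel.samples, rng)
        gs = pf.drop_genomes(ped, None, asg, panel, pf.GenomeParams(10**6, 0.0, 1e-7), rng)
        table, summary = pf.kinship_report(ped, gs)
        assert (table.expected_phi == 0).all()
        assert summary["n_related_pairs"] == 0

    def test_expected_matches_true_ibd_oracle_over_replicates(self):
        """Mean segment-based IBD kinship equals pedigree expectation
        within 3 SE over 200 gene drops (module consistency)."""
        ped, rng = census_family(31, num_generations=3, lo=10, hi=40)
        completed, fs = pf.resolve_founders(ped)
        pairs = pf.classify_all_pairs(completed)
        related = pairs[pairs.grt.isin(["direct", "full", "half"])]
        chosen = related.sample(n=min(6, len(related)), random_state=0)
        calc = pf.KinshipCalculator(completed)
        L = 10**6
        params = pf.GenomeParams(L, 0.0, 1e-6)
        sums = {(r.id_a, r.id_b): [] for r in chosen.itertuples(index=False)}
        for _ in range(200):
            panel = pf.generate_synthetic_founders(len(fs.all_founders), 2, L, rng)
            asg = pf.assign_founder_genomes(sorted(fs.all_founders), panel.samples, rng)
            gs = pf.drop_genomes(completed, None, asg, panel, params, rng)
            for a, b in sums:
                sums[(a, b)].append(pf.true_ibd_percent(gs, a, b) / 200.0)
        for (a, b), vals in sums.items():
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals)) + 1e-9
            assert abs(vals.mean() - calc.phi(a, b)) < 3 * se + 0.003
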