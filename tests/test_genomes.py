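import numpy as np
import pytest

import pedforge as pf

from conftest import census_family

L = 1_000_000


@pytest.fixture
def trio_genomes(trio, rng):
    panel = pf.generate_synthetic_founders(2, 500, L, rng)
    assignment = pf.assign_founder_genomes(["P", "M"], panel.samples, rng)
    params = pf.GenomeParams(L, mutation_rate=0.0, recombination_rate=1e-6)
    return pf.drop_genomes(trio, None, assignment, panel, params, rng)


class TestSyntheticFounders:
    def test_single_sample_panel(self, rng):
        panel = pf.generate_synthetic_founders(1, 10, 1000, rng)
        assert panel.n_samples == 1 and panel.haplotypes.shape == (2, 10)

    def test_positions_distinct_and_sorted(self, rng):
        panel = pf.generate_synthetic_founders(3, 200, 1000, rng)
        assert np.all(np.diff(panel.positions) > 0)

    def test_uniform_spectrum_heterozygosity(self, rng):
        """E[2x(1-x)] = 1/3 per site for x ~ U(0,1)."""
        panel = pf.generate_synthetic_founders(20, 10000, 10**6, rng)
        het = (panel.haplotypes[0::2] != panel.haplotypes[1::2]).mean()
        assert het == pytest.approx(1 / 3, abs=0.02)

    def test_neutral_spectrum_skews_rare(self, rng):
        panel = pf.generate_synthetic_founders(50, 5000, 10**6, rng)
        neutral = pf.generate_synthetic_founders(50, 5000, 10**6, rng, spectrum="neutral")
        freq_u = panel.haplotypes.mean()
        freq_n = neutral.haplotypes.mean()
        assert freq_n < freq_u  # 1/x spectrum concentrates near zero

    def test_too_many_sites_rejected(self, rng):
        with pytest.raises(ValueError):
            pf.generate_synthetic_founders(2, 11, 10, rng)


class TestFounderAssignment:
    def test_exact_fit_is_bijection(self, rng):
        asg = pf.assign_founder_genomes(["a", "b", "c"], ["S1", "S2", "S3"], rng)
        assert sorted(asg) == ["a", "b", "c"]
        assert sorted(asg.values()) == ["S1", "S2", "S3"]

    def test_unknown_mapped_sample_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown panel sample"):
            pf.assign_founder_genomes(["F1"], ["S1"], rng, mapping={"F1": "S9"})

    def test_insufficient_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="unused panel samples"):
            pf.assign_founder_genomes(["a", "b"], ["S1"], rng)

    def test_large_injective_draw(self, rng):
        """419 founders drawn from a 454-sample panel stay injective."""
        founders = [f"f{i}" for i in range(419)]
        samples = [f"S{i}" for i in range(454)]
        asg = pf.assign_founder_genomes(founders, samples, rng)
        assert len(set(asg.values())) == 419


class TestRecombinationMap:
    def test_uniform_total_rate(self):
        m = pf.RecombinationMap.uniform(1e-6, L)
        assert m.total_rate == pytest.approx(1.0)

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError):
            pf.RecombinationMap((0, 600), (500, 1000), (1e-8, 1e-8))

    def test_hapmap_conversion(self):
        m = pf.RecombinationMap.from_hapmap([(0, 1.0), (500_000, 3.0)], L)
        assert m.starts == (0, 500_000)
        assert m.rates == pytest.approx((1e-8, 3e-8))

    def test_breakpoint_count_poisson_mean(self, rng):
        m = pf.RecombinationMap.uniform(1e-6, L)
        counts = [len(m.sample_breakpoints(rng)) for _ in range(3000)]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.06)


class TestGeneDrop:
    def test_zero_rates_child_copies_a_parental_haplotype(self, trio, rng):
        panel = pf.generate_synthetic_founders(2, 300, L, rng)
        asg = pf.assign_founder_genomes(["P", "M"], panel.samples, rng)
        params = pf.GenomeParams(L, mutation_rate=0.0, recombination_rate=0.0)
        gs = pf.drop_genomes(trio, None, asg, panel, params, rng)
        child_hap = gs.haplotypes["C"][0].alleles  # paternal gamete
        parent = gs.haplotypes["P"]
        assert any(np.array_equal(child_hap, h.alleles) for h in parent)

    def test_mendelian_consistency_without_mutation(self):
        ped, rng = census_family(21, num_generations=4, lo=30, hi=120)
        completed, fs = pf.resolve_founders(ped)
        panel = pf.generate_synthetic_founders(len(fs.all_founders), 2000, L, rng)
        asg = pf.assign_founder_genomes(sorted(fs.all_founders), panel.samples, rng)
        gs = pf.drop_genomes(completed, None, asg, panel,
                             pf.GenomeParams(L, 0.0, 1e-6), rng)
        ids, _, G = gs.genotype_matrix(gs.individuals)
        idx = {i: k for k, i in enumerate(ids)}
        for child in completed.individuals:
            parents = completed.parents(child)
            if len(parents) != 2:
                continue
            gc, gf, gm = G[idx[child]], G[idx[parents[0]]], G[idx[parents[1]]]
            # impossible: child hom for an allele a parent lacks entirely
            assert not np.any((gc == 2) & ((gf == 0) | (gm == 0)))
            assert not np.any((gc == 0) & ((gf == 2) | (gm == 2)))

    def test_allele_and_label_conservation(self, trio_genomes):
        founder_labels = {lab for pair in ("P", "M")
                          for lab in trio_genomes.founder_hap_labels[pair]}
        for hap in trio_genomes.haplotypes["C"]:
            segs = hap.ancestry
            assert segs[0][0] == 0 and segs[-1][1] == L
            assert all(s1[1] == s2[0] for s1, s2 in zip(segs, segs[1:]))
            assert {lab for _, _, lab in segs} <= founder_labels

    def test_de_novo_mutations_at_fresh_positions(self, trio, rng):
        panel = pf.generate_synthetic_founders(2, 100, L, rng)
        asg = pf.assign_founder_genomes(["P", "M"], panel.samples, rng)
        gs = pf.drop_genomes(trio, None, asg, panel,
                             pf.GenomeParams(L, mutation_rate=5e-5, recombination_rate=0.0), rng)
        muts = gs.mutation_positions()
        assert len(muts) > 0
        assert not set(muts) & set(panel.positions.tolist())


class TestTrueIbd:
    def test_parent_child_exactly_half(self, trio_genomes):
        assert pf.true_ibd_percent(trio_genomes, "P", "C") == 50.0
        assert pf.true_ibd_percent(trio_genomes, "M", "C") == 50.0

    def test_unrelated_founders_share_nothing(self, trio_genomes):
        assert pf.true_ibd_percent(trio_genomes, "P", "M") == 0.0

    def test_self_is_complete(self, trio_genomes):
        assert pf.true_ibd_percent(trio_genomes, "C", "C") == 100.0

    def test_sibling_mean_near_half(self):
        """Full siblings share ~50% on average (exactly 50 in expectation)."""
        ped = pf.Pedigree()
        ped.add_individual("P", sex=pf.MALE, tick=1)
        ped.add_individual("M", sex=pf.FEMALE, tick=1)
        for kid in ("C1", "C2"):
            ped.add_individual(kid, sex=pf.FEMALE, tick=2)
            ped.add_edge("P", kid)
            ped.add_edge("M", kid)
        rng = np.random.default_rng(77)
        shares = []
        for _ in range(60):
            panel = pf.generate_synthetic_founders(2, 10, L, rng)
            asg = pf.assign_founder_genomes(["P", "M"], panel.samples, rng)
            gs = pf.drop_genomes(ped, None, asg, panel, pf.GenomeParams(L, 0.0, 1e-6), rng)
            shares.append(pf.true_ibd_percent(gs, "C1", "C2"))
        assert np.mean(shares) == pytest.approx(50.0, abs=5.0)


class TestVcf:
    def test_implicit_founders_excluded(self, tmp_path, rng):
        ped = pf.Pedigree()
        ped.add_individual("M", sex=pf.FEMALE)
        ped.add_individual("C", sex=pf.FEMALE)
        ped.add_edge("M", "C")
        completed, fs = pf.resolve_founders(ped)
        panel = pf.generate_synthetic_founders(2, 50, L, rng)
        asg = pf.assign_founder_genomes(sorted(fs.all_founders), panel.samples, rng)
        gs = pf.drop_genomes(completed, None, asg, panel, pf.GenomeParams(L, 0.0, 0.0), rng)
        out = tmp_path / "fam.vcf"
        pf.write_vcf(gs, out)
        from cyvcf2 import VCF

        samples = VCF(str(out)).samples
        assert set(samples) == {"M", "C"}

    def test_zero_sites_writes_valid_header_only(self, trio, rng, tmp_path):
        panel = pf.generate_synthetic_founders(2, 0, L, rng)
        asg = pf.assign_founder_genomes(["P", "M"], panel.samples, rng)
        gs = pf.drop_genomes(trio, None, asg, panel, pf.GenomeParams(L, 0.0, 0.0), rng)
        out = tmp_path / "empty.vcf"
        pf.write_vcf(gs, out)
        from cyvcf2 import VCF

        assert list(VCF(str(out))) == []

    def test_round_trip_reproduces_genotypes(self, trio_genomes, tmp_path):
        out = tmp_path / "trio.vcf"
        pf.write_vcf(trio_genomes, out)
        panel = pf.FounderPanel.from_vcf(out)
        ids, positions, H, _, _ = trio_genomes.haplotype_matrix()
        assert panel.samples == ids
        assert np.array_equal(panel.positions, positions)
        assert np.array_equal(panel.haplotypes, H)
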