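"""Breeding-design simulator: pedigrees, meiosis, genotypes, phenotypes."""

import numpy as np
import pytest

from hseqtl.kinship import chromosome_kinship, genome_kinship, matrix_correlation, phenotype_distance
from hseqtl.markers import MarkerMap, default_marker_map
from hseqtl.popsim import (
    AncestryMosaic,
    PhenoModel,
    founder_gamete,
    genotype_from_mosaic,
    hotspot_chromosome_profile,
    interval_true_dosage,
    random_founder_panel,
    random_pheno_model,
    simulate_cross,
    simulate_expression,
    simulate_meiosis,
    simulate_pedigree,
)


class TestPedigree:
    def test_hscc_forms_32_families_at_g3_and_48_after_expansion(self):
        ped = simulate_pedigree("HSCC")
        assert len(ped.families_at(3)) == 32
        assert len(ped.families_at(5)) == 32
        assert len(ped.families_at(6)) == 48
        assert len(ped.families_at(12)) == 48

    def test_f2_two_generations_with_both_founders_in_ancestry(self, small_map):
        ped = simulate_pedigree("F2")
        assert ped.n_generations == 2
        pop = simulate_cross("F2", small_map, seed=0, n_offspring_final=4)
        dosage = pop.true_dosage()
        # every F2 individual carries ancestry from both founders somewhere
        share = dosage.sum(axis=1)  # (n, founders)
        assert (share > 0).all()

    def test_hs4_family_count_constant_through_circle_breeding(self):
        ped = simulate_pedigree("HS4")
        counts = {g: len(ped.families_at(g)) for g in range(3, 20)}
        assert set(counts.values()) == {48}

    def test_every_offspring_has_one_sire_and_one_dam(self):
        ped = simulate_pedigree("HSCC")
        for rec in ped.records:
            assert rec.sire_family and rec.dam_family

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            simulate_pedigree("BC1")

    def test_hscc_with_too_few_families_rejected(self):
        with pytest.raises(ValueError):
            simulate_pedigree("HSCC", n_families=16)


class TestMeiosis:
    def test_zero_distance_markers_never_recombine(self):
        mm = MarkerMap(["a", "b"], np.array(["1", "1"], dtype=object), np.array([0.0, 1e-9]))
        parent = AncestryMosaic((founder_gamete(0, mm), founder_gamete(1, mm)))
        rng = np.random.default_rng(0)
        for _ in range(200):
            g = simulate_meiosis(parent, mm, seed=rng)
            f = g.founder_at("1", mm.pos_cM)
            assert f[0] == f[1]

    def test_recombinant_fraction_matches_haldane_at_20cM(self):
        from hseqtl.experiments import haldane_monte_carlo

        res = haldane_monte_carlo(seed=5, d_cM=20.0, n_gametes=10_000)
        se = np.sqrt(res["expected"] * (1 - res["expected"]) / res["n"])
        assert abs(res["observed"] - res["expected"]) < 3 * se

    def test_distant_markers_approach_half_recombination(self):
        mm = MarkerMap(["a", "b"], np.array(["1", "1"], dtype=object), np.array([0.0, 5000.0]))
        parent = AncestryMosaic((founder_gamete(0, mm), founder_gamete(1, mm)))
        rng = np.random.default_rng(3)
        rec = sum(
            (lambda f: f[0] != f[1])(simulate_meiosis(parent, mm, seed=rng).founder_at("1", mm.pos_cM))
            for _ in range(2000)
        )
        assert abs(rec / 2000 - 0.5) < 0.05

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            MarkerMap([], np.array([], dtype=object), np.array([]))

    def test_mosaics_tile_chromosomes(self, hscc_pop):
        mm = hscc_pop.marker_map
        for mos in hscc_pop.mosaics[:10]:
            for copy in mos.copies:
                for c in mm.chromosomes:
                    ends, founders = copy.segments[c]
                    assert len(ends) == len(founders)
                    assert (np.diff(ends) > 0).all()
                    assert ends[-1] == pytest.approx(mm.chrom_length(c))


class TestGenotypes:
    def test_f2_dosage_frequencies_are_mendelian(self, small_map):
        pop = simulate_cross("F2", small_map, seed=2, n_offspring_final=100)
        g = pop.genotypes(seed=3)
        freqs = np.array([(g == d).mean() for d in (0, 1, 2)])
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.05)

    def test_dosage_values_in_0_1_2(self, hscc_geno):
        assert set(np.unique(hscc_geno)) <= {0, 1, 2}

    def test_error_free_homozygous_segment_doubles_founder_allele(self, small_map):
        panel = random_founder_panel(4, small_map, seed=0)
        mos = [AncestryMosaic((founder_gamete(2, small_map), founder_gamete(2, small_map)))]
        g = genotype_from_mosaic(mos, panel, small_map, genotyping_error=0.0)
        assert (g[0] == 2 * panel.haplotypes[2]).all()

    def test_hscc_founder_shares_near_one_eighth(self, small_map):
        # average over seeds: balanced design symmetry
        shares = []
        for s in range(4):
            pop = simulate_cross("HSCC", small_map, seed=100 + s)
            shares.append(pop.true_dosage().mean(axis=(0, 1)) / 2)
        mean_share = np.mean(shares, axis=0)
        assert np.allclose(mean_share, 1 / 8, atol=0.06)

    def test_fixed_seed_reproduces_bit_identically(self, small_map):
        a = simulate_cross("HSCC", small_map, seed=5).genotypes(seed=6)
        b = simulate_cross("HSCC", small_map, seed=5).genotypes(seed=6)
        assert (a == b).all()

    def test_genotyping_error_flips_expected_fraction(self, hscc_pop):
        g0 = hscc_pop.genotypes(0.0, seed=1)
        g1 = hscc_pop.genotypes(0.3, seed=1)
        frac = (g0 != g1).mean()
        assert abs(frac - 0.3) < 0.03


class TestExpression:
    def test_pure_noise_when_all_effects_zero(self, hscc_pop, hscc_geno):
        pm = PhenoModel(n_probes=50, noise_var=1.0)
        expr, truth, _ = simulate_expression(hscc_pop, pm, None, seed=4)
        assert truth.empty
        # correlations with markers follow the null: |r| rarely beyond 4/sqrt(n)
        r = np.corrcoef(expr.values.T, hscc_geno.T)[:50, 50:]
        assert (np.abs(r) > 4 / np.sqrt(hscc_pop.n)).mean() < 0.01

    def test_planted_additive_effect_recovered_by_ols(self, hscc_pop):
        pm = random_pheno_model(
            hscc_pop.marker_map, 8, 1, n_cis=1, cis_effect_sd=1.0, seed=9, noise_var=1.0
        )
        expr, truth, _ = simulate_expression(hscc_pop, pm, None, seed=10)
        eff = pm.cis_effects[0]
        D = interval_true_dosage(hscc_pop.true_dosage(), hscc_pop.marker_map, eff.interval)
        X = np.column_stack([np.ones(hscc_pop.n), D[:, :-1]])
        beta, res_, rank, _ = np.linalg.lstsq(X, expr.values[:, 0], rcond=None)
        fitted_contrast = X @ beta
        true_contrast = D @ eff.founder_effects
        r = np.corrcoef(fitted_contrast - beta[0], true_contrast)[0, 1]
        assert r > 0.8

    def test_polygenic_component_tracks_kinship(self, hscc_pop, hscc_geno):
        K = genome_kinship(hscc_geno)
        pm = PhenoModel(n_probes=40, polygenic_var=2.0, noise_var=0.5)
        expr, _, _ = simulate_expression(hscc_pop, pm, K, seed=12)
        rs = [matrix_correlation(phenotype_distance(expr.values[:, j]), K) for j in range(40)]
        assert np.mean(rs) > 0

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            PhenoModel(n_probes=5, noise_var=-1.0)

    def test_low_detection_probes_fail_in_most_samples(self, hscc_pop):
        pm = PhenoModel(n_probes=40, undetected_probe_fraction=0.25)
        expr, _, _ = simulate_expression(hscc_pop, pm, None, seed=13)
        low = expr.probes["low_detection"].to_numpy()
        frac_fail = (expr.detection_pvals[:, low] >= 0.01).mean(axis=0)
        assert (frac_fail > 0.75).all()


class TestHotspot:
    def test_uniform_chromosomes_have_exchangeable_kinship_summaries(self, small_map):
        # same map length => chromosome kinship summary statistics agree across chromosomes
        means = {c: [] for c in small_map.chromosomes}
        for s in range(5):
            pop = simulate_cross("HSCC", small_map, seed=200 + s)
            g = pop.genotypes(seed=s)
            K = genome_kinship(g)
            for c in small_map.chromosomes:
                means[c].append(matrix_correlation(chromosome_kinship(g, small_map, c), K))
        avg = [np.mean(v) for v in means.values()]
        assert max(avg) - min(avg) < 0.25

    def test_hotspot_profile_preserves_total_map_length(self, small_map):
        profile = hotspot_chromosome_profile(small_map, "1", intensity=50.0)
        mm2 = small_map
        parent = AncestryMosaic((founder_gamete(0, mm2), founder_gamete(1, mm2)))
        rng = np.random.default_rng(0)
        # crossover count distribution unchanged: compare segment counts
        n_x = []
        for _ in range(500):
            gam = simulate_meiosis(parent, mm2, hotspot_profile=profile, seed=rng)
            n_x.append(len(gam.segments["1"][0]) - 1)
        expected = mm2.chrom_length("1") / 100
        assert abs(np.mean(n_x) - expected) < 0.15 * expected + 0.05
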