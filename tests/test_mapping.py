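"""Mixed-model machinery and the three scans."""

import warnings

import numpy as np
import pytest

import hseqtl.mapping as mapping
from hseqtl.ancestry import true_ancestry_design
from hseqtl.kinship import genome_kinship
from hseqtl.mapping import (
    KinshipEigen,
    classify_cis_trans,
    fit_null_mixed,
    interval_scan,
    jm_scan,
    reml_loglik,
    sm_scan,
)
from hseqtl.markers import default_marker_map
from hseqtl.popsim import random_pheno_model, simulate_cross, simulate_expression


def dense_reml_loglik(y, X, S, sigma_g2, delta):
    """Dense GLS restricted log-likelihood, independent of the spectral path."""
    n, p = X.shape
    V = sigma_g2 * (S + delta * np.eye(n))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = r @ Vi @ r
    _, ld_V = np.linalg.slogdet(V)
    _, ld_XtViX = np.linalg.slogdet(XtViX)
    _, ld_XtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_V + ld_XtViX - ld_XtX + quad)


@pytest.fixture(scope="module")
def kin20():
    g = np.random.default_rng(77).integers(0, 3, size=(20, 60))
    return KinshipEigen.from_distance(genome_kinship(g))


class TestSpectralReml:
    def test_matches_dense_gls_oracle(self, kin20):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(20)
        X = np.ones((20, 1))
        ystar, Xstar = kin20.rotate(y), kin20.rotate(X)
        for delta in (0.1, 1.0, 10.0):
            # profile out sigma_g2 the same way the spectral path does
            w = 1.0 / (kin20.eigenvalues + delta)
            sw = np.sqrt(w)
            beta = np.linalg.lstsq(Xstar * sw[:, None], ystar * sw, rcond=None)[0]
            rss = float(((ystar - Xstar @ beta) ** 2 * w).sum())
            sg2 = rss / (20 - 1)
            ll_spec = reml_loglik(delta, ystar, Xstar, kin20.eigenvalues, reml=True)
            ll_dense = dense_reml_loglik(y, X, kin20.S, sg2, delta)
            assert abs(ll_spec - ll_dense) < 1e-6

    def test_null_heritability_small_for_noise(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(80, 120))
        kin = KinshipEigen.from_distance(genome_kinship(g))
        ok = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(50):
                fit = fit_null_mixed(rng.standard_normal(80), kin)
                ok += fit.genetic_fraction < 0.25
        assert ok >= 40

    def test_identity_kinship_flagged_degenerate(self):
        kin = KinshipEigen(np.eye(12))
        fit = fit_null_mixed(np.random.default_rng(0).standard_normal(12), kin)
        assert fit.degenerate and fit.flagged

    def test_too_few_samples_rejected(self, kin20):
        with pytest.raises(ValueError):
            fit_null_mixed(np.zeros(3), KinshipEigen(np.eye(3) * 1.0))

    def test_eigendecomposition_cached_across_scans(self, hscc_pop, hscc_geno):
        K = genome_kinship(hscc_geno)
        before = mapping.N_EIGENDECOMPOSITIONS
        kin = KinshipEigen.from_distance(K)
        assert mapping.N_EIGENDECOMPOSITIONS == before + 1
        Y = np.random.default_rng(3).standard_normal((hscc_pop.n, 5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_scan(Y, hscc_geno, kin, marker_ids=hscc_pop.marker_map.marker_ids)
        assert mapping.N_EIGENDECOMPOSITIONS == before + 1  # no re-decomposition


class TestSmScan:
    def test_planted_marker_effect_tops_the_scan(self, hscc_pop, hscc_geno):
        rng = np.random.default_rng(8)
        kin = KinshipEigen.from_distance(genome_kinship(hscc_geno))
        hits = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in range(10):
                j = int(rng.integers(hscc_geno.shape[1]))
                y = hscc_geno[:, j] * 0.8 + rng.standard_normal(hscc_pop.n)
                tab, _ = sm_scan(y[:, None], hscc_geno, kin, marker_ids=hscc_pop.marker_map.marker_ids)
                best = tab.loc[tab["p_value"].idxmin(), "locus_id"]
                hits += best == hscc_pop.marker_map.marker_ids[j]
        assert hits >= 9

    def test_monomorphic_marker_reported_as_skipped(self, hscc_pop, hscc_geno):
        g = hscc_geno.copy()
        g[:, 3] = 1
        kin = KinshipEigen.from_distance(genome_kinship(g))
        Y = np.random.default_rng(1).standard_normal((hscc_pop.n, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab, skipped = sm_scan(Y, g, kin, marker_ids=hscc_pop.marker_map.marker_ids)
        assert hscc_pop.marker_map.marker_ids[3] in set(skipped["locus_id"])
        assert hscc_pop.marker_map.marker_ids[3] not in set(tab["locus_id"])

    def test_kinship_correction_improves_null_calibration(self, small_map):
        # polygenic-confounded null probes: mixed-model p-values closer to
        # uniform than naive OLS p-values
        from scipy import stats

        pop = simulate_cross("HSCC", small_map, seed=21)
        geno = pop.genotypes(seed=22)
        K = genome_kinship(geno)
        from hseqtl.popsim import PhenoModel

        pm = PhenoModel(n_probes=150, polygenic_var=3.0, noise_var=1.0)
        expr, _, _ = simulate_expression(pop, pm, K, seed=23)
        kin = KinshipEigen.from_distance(K)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab, _ = sm_scan(expr, geno, kin, marker_ids=small_map.marker_ids)
        identity = KinshipEigen(np.eye(pop.n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab_ols, _ = sm_scan(expr, geno, identity, marker_ids=small_map.marker_ids)
        locus = small_map.marker_ids[2]
        p_mm = tab[tab.locus_id == locus]["p_value"]
        p_ols = tab_ols[tab_ols.locus_id == locus]["p_value"]
        ks_mm = stats.kstest(p_mm, "uniform").statistic
        ks_ols = stats.kstest(p_ols, "uniform").statistic
        assert ks_mm < ks_ols


class TestIntervalScan:
    def test_f2_interval_test_equals_single_dosage_regression(self, small_map):
        from scipy import stats

        pop = simulate_cross("F2", small_map, seed=31, n_offspring_final=24)
        design = true_ancestry_design(pop.true_dosage(), small_map, pop.founder_panel.founder_ids)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(pop.n)
        tab, _ = interval_scan(y[:, None], design)
        k = int(np.where(design.testable)[0][0])
        x = design.dosage[k][:, 0]
        X = np.column_stack([np.ones(pop.n), x])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss1 = r @ r
        rss0 = ((y - y.mean()) ** 2).sum()
        F = (rss0 - rss1) / (rss1 / (pop.n - 2))
        p_ref = stats.f.sf(F, 1, pop.n - 2)
        p_scan = tab[tab.locus_id == design.intervals[k].interval_id]["p_value"].iloc[0]
        assert p_scan == pytest.approx(p_ref, rel=1e-9)

    def test_permuted_phenotypes_give_uniform_pvalues(self, hscc_pop, hscc_geno):
        from scipy import stats

        design = true_ancestry_design(
            hscc_pop.true_dosage(), hscc_pop.marker_map, hscc_pop.founder_panel.founder_ids
        )
        Y = np.random.default_rng(9).standard_normal((hscc_pop.n, 300))
        tab, _ = interval_scan(Y, design)
        p = tab[tab.locus_id == design.intervals[0].interval_id]["p_value"]
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestJointModel:
    def test_identity_kinship_reduces_to_interval_scan(self, hscc_pop, hscc_geno):
        design = true_ancestry_design(
            hscc_pop.true_dosage(), hscc_pop.marker_map, hscc_pop.founder_panel.founder_ids
        )
        Y = np.random.default_rng(2).standard_normal((hscc_pop.n, 4))
        identity = KinshipEigen(np.eye(hscc_pop.n))
        tab_jm, _ = jm_scan(Y, design, identity)
        tab_iv, _ = interval_scan(Y, design)
        merged = tab_jm.merge(tab_iv, on=["probe_id", "locus_id"], suffixes=("_jm", "_iv"))
        assert len(merged) == len(tab_jm)
        assert np.abs(merged["p_value_jm"] - merged["p_value_iv"]).max() < 1e-8

    def test_sm_and_jm_rank_loci_identically_in_f2(self, small_map):
        from scipy import stats as sps

        pop = simulate_cross("F2", small_map, seed=41, n_offspring_final=24)
        geno = pop.genotypes(seed=42)
        design = true_ancestry_design(pop.true_dosage(), small_map, pop.founder_panel.founder_ids)
        rng = np.random.default_rng(5)
        pm = random_pheno_model(small_map, 2, 1, n_cis=1, cis_effect_sd=1.0, seed=6, noise_var=1.0)
        expr, _, _ = simulate_expression(pop, pm, None, seed=7)
        y = expr.values
        identity = KinshipEigen(np.eye(pop.n))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab_sm, _ = sm_scan(y, geno, identity, marker_ids=small_map.marker_ids)
        tab_jm, _ = jm_scan(y, design, identity)
        # compare marker ranks with the mean rank of adjacent intervals
        from hseqtl.concord import build_correspondence

        corr = build_correspondence(small_map)
        sm_p = dict(zip(tab_sm.locus_id, tab_sm.p_value))
        jm_p = dict(zip(tab_jm.locus_id, tab_jm.p_value))
        pairs = []
        for iv_id, (ml, mr) in corr.interval_to_markers.items():
            if iv_id in jm_p and ml in sm_p and mr in sm_p:
                pairs.append((jm_p[iv_id], min(sm_p[ml], sm_p[mr])))
        rho = sps.spearmanr([a for a, _ in pairs], [b for _, b in pairs]).statistic
        assert rho > 0.9


class TestCisTrans:
    def test_rule_application_on_toy_configuration(self):
        import pandas as pd

        mm = default_marker_map(2, 4, 10.0)
        probes = pd.DataFrame(
            {
                "probe_id": ["in_iv", "far", "nocoord"],
                "chromosome": ["1", "2", None],
                "start": [int(15 * 2e6), int(5 * 2e6), None],
                "end": [int(15 * 2e6) + 50, int(5 * 2e6) + 50, None],
                "position_cM": [15.0, 5.0, None],
            }
        )
        iv_id = mm.intervals()[1].interval_id  # chr1, 10-20 cM
        table = pd.DataFrame(
            [
                {"probe_id": "in_iv", "locus_id": iv_id, "locus_kind": "interval",
                 "method": "HAP", "statistic": 1.0, "p_value": 0.5, "cis_flag": None},
                {"probe_id": "in_iv", "locus_id": "m1_1", "locus_kind": "marker",
                 "method": "SM", "statistic": 1.0, "p_value": 0.5, "cis_flag": None},
                {"probe_id": "in_iv", "locus_id": "m1_3", "locus_kind": "marker",
                 "method": "SM", "statistic": 1.0, "p_value": 0.5, "cis_flag": None},
                {"probe_id": "far", "locus_id": iv_id, "locus_kind": "interval",
                 "method": "HAP", "statistic": 1.0, "p_value": 0.5, "cis_flag": None},
                {"probe_id": "nocoord", "locus_id": iv_id, "locus_kind": "interval",
                 "method": "HAP", "statistic": 1.0, "p_value": 0.5, "cis_flag": None},
            ]
        )
        out = classify_cis_trans(table, probes, mm)
        flags = out["cis_flag"].tolist()
        # probe inside the tested interval -> cis; flanking marker -> cis;
        # marker two intervals away -> trans; other chromosome -> trans
        assert flags == ["cis", "cis", "trans", "trans", "unknown"]

    def test_matches_brute_force_rule_evaluation(self, hscc_pop, hscc_geno):
        rng = np.random.default_rng(11)
        mm = hscc_pop.marker_map
        from hseqtl.popsim import random_pheno_model, simulate_expression

        pm = random_pheno_model(mm, 8, 30, n_cis=5, n_trans=5, seed=12)
        expr, _, _ = simulate_expression(hscc_pop, pm, None, seed=13)
        design = true_ancestry_design(hscc_pop.true_dosage(), mm, hscc_pop.founder_panel.founder_ids)
        tab, _ = interval_scan(expr, design)
        out = classify_cis_trans(tab, expr.probes, mm)
        iv_by_id = {iv.interval_id: iv for iv in mm.intervals()}
        pos = dict(zip(expr.probes.probe_id, zip(expr.probes.chromosome, expr.probes.position_cM)))
        for row in out.sample(100, random_state=1).itertuples(index=False):
            chrom, cm = pos[row.probe_id]
            iv = iv_by_id[row.locus_id]
            expect = "cis" if (iv.chrom == str(chrom) and iv.left_cM <= cm <= iv.right_cM) else "trans"
            assert row.cis_flag == expect
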