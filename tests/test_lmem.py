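"""Mixed-model fitter, scan, multiple-testing adjustments, stepwise
selection, variance accounting, and heterogeneity tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import onsetmod as om
from onsetmod.lmem import _ebic, _eig_kinship, reml_fit
from onsetmod.rng import substream


def _phen_frame(y, rng=None):
    n = len(y)
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(n)],
        "adaoo": y,
        "sex": rng.choice(["F", "M"], size=n),
        "edu_years": rng.integers(0, 16, size=n).astype(float),
        "edu_group": rng.choice(["none", "elementary", "highschool", "tertiary"],
                                size=n),
    })


def _null_cohort(cfg_seed, pheno_seed, n=100, m=10, sg2=4.0, se2=4.0):
    """Pedigree cohort with a polygenic + noise phenotype, no marker effects."""
    cfg = om.SimConfig(n_samples=n, n_markers=m, founder_count=12,
                       pedigree_depth=3, maf_vector=np.linspace(0.2, 0.5, m),
                       sigma_g2=sg2, sigma_e2=se2, mu=50.0, seed=cfg_seed)
    ped, K = om.simulate_pedigree(cfg, substream(cfg_seed, "ped"))
    geno = om.simulate_genotypes(ped, cfg, substream(cfg_seed, "geno"))
    phen = om.simulate_phenotype(geno, K, cfg, substream(pheno_seed, "phen"))
    return geno, phen, K


class TestRemlFit:
    def test_identity_kinship_equals_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [50, 2, -1] + rng.normal(size=n)
        fit = reml_fit(y, X, np.eye(n))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.beta, ols.params, atol=1e-6)
        assert np.allclose(fit.se_beta, ols.bse, atol=1e-6)
        assert np.allclose(fit.p_values, ols.pvalues, atol=1e-6)
        # fixing sigma_g2 ~ 0 reproduces OLS coefficients exactly
        fit0 = reml_fit(y, X, np.eye(n), fix_components=(0.0, 1.0))
        assert np.allclose(fit0.beta, ols.params, atol=1e-10)

    def test_fixed_components_match_dense_gls(self):
        rng = np.random.default_rng(5)
        cfg = om.SimConfig(n_samples=80, n_markers=2, founder_count=8,
                           pedigree_depth=3, seed=11)
        _, K = om.simulate_pedigree(cfg)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = rng.normal(size=n) + 48
        sg2, se2 = 5.0, 2.0
        fit = reml_fit(y, X, K.values, fix_components=(sg2, se2))
        V = sg2 * K.values + se2 * np.eye(n)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.abs(fit.beta - beta).max() < 1e-8

    def test_variance_components_recovered_in_simulation(self):
        # median relative error of REML (sg2, se2) under the generative truth
        # founder/depth chosen to give a rich relatedness spectrum; a
        # shallow pedigree (hundreds of sibs from few parents) leaves the
        # two components weakly separated regardless of fitter quality
        sg2_t, se2_t = 16.0, 9.0
        errs_g, errs_e = [], []
        cfg = om.SimConfig(n_samples=400, n_markers=1, founder_count=50,
                           pedigree_depth=4, sigma_g2=sg2_t, sigma_e2=se2_t,
                           mu=48.0, seed=1)
        ped, K = om.simulate_pedigree(cfg)
        eig = _eig_kinship(K.values)
        X = np.ones((400, 1))
        for rep in range(100):
            phen = om.simulate_phenotype(
                om.simulate_genotypes(ped, cfg, substream(rep, "g")),
                K, cfg, substream(rep, "p"))
            fit = reml_fit(phen["adaoo"].to_numpy(), X, eig=eig)
            errs_g.append(abs(fit.sigma_g2 - sg2_t) / sg2_t)
            errs_e.append(abs(fit.sigma_e2 - se2_t) / se2_t)
        assert np.median(errs_g) < 0.25
        assert np.median(errs_e) < 0.25

    def test_rank_deficient_design_names_columns(self):
        n = 30
        X = np.column_stack([np.ones(n), np.arange(n), 2 * np.arange(n)])
        with pytest.raises(ValueError, match="collinear"):
            reml_fit(np.random.default_rng(0).normal(size=n), X, np.eye(n),
                     names=["intercept", "a", "b"])

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            reml_fit(np.zeros(10), np.ones((9, 1)), np.eye(9))


class TestSingleLocusScan:
    def test_null_scan_p_values_uniform(self):
        # 400 null cohorts x 5 markers: kinship-corrected raw p uniform
        pvals = []
        for rep in range(400):
            geno, phen, K = _null_cohort(7, 1000 + rep, n=100, m=5)
            res = om.single_locus_scan(geno, phen, K, coding="additive")
            pvals.extend(res.table["p"].dropna())
        assert len(pvals) > 1500
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_causal_effect_sign_and_ci_coverage(self):
        # dominant beta=8.2: estimates are positive and 95% CIs cover truth.
        # Replicates where drift flipped the marker's minor allele are
        # excluded: a minor-allele dominant scan then addresses a different
        # contrast than the planted one.
        cover, signs, used = 0, 0, 0
        n_reps = 60
        for rep in range(n_reps):
            cfg = om.SimConfig(
                n_samples=300, n_markers=3, founder_count=15, pedigree_depth=3,
                maf_vector=np.array([0.3, 0.4, 0.25]), sigma_g2=4.0,
                sigma_e2=4.0, mu=46.0,
                causal_spec=(om.CausalVariant(0, "dominant", 8.2),), seed=500 + rep)
            cohort = om.simulate_cohort(cfg)
            if cohort.genotypes.markers[0].flipped:
                continue
            used += 1
            res = om.single_locus_scan(cohort.genotypes, cohort.phenotypes,
                                       cohort.kinship_true, coding="dominant")
            row = res.table.iloc[0]
            tcrit = stats.t.ppf(0.975, 300 - 5)
            if row.beta - tcrit * row.se <= 8.2 <= row.beta + tcrit * row.se:
                cover += 1
            signs += row.beta > 0
        assert used >= n_reps * 0.9  # flips are rare at this MAF and depth
        assert signs == used
        assert cover / used >= 0.90

    def test_permuted_phenotype_destroys_association(self):
        cfg = om.default_emulation_config(seed=31)
        cohort = om.simulate_cohort(cfg)
        rng = np.random.default_rng(0)
        phen = cohort.phenotypes.copy()
        hits = 0
        for _ in range(10):
            phen["adaoo"] = rng.permutation(phen["adaoo"].to_numpy())
            res = om.single_locus_scan(cohort.genotypes, phen,
                                       cohort.kinship_true)
            if res.table["p_fdr"].min() < 0.05:
                hits += 1
        assert hits <= 2

    def test_constant_coded_marker_reported_not_crashed(self):
        geno, phen, K = _null_cohort(3, 3, n=50, m=2)
        dos = geno.dosage.copy()
        dos[:, 1] = 2.0  # recessive coding will be constant
        geno2 = om.GenotypeMatrix(dos, geno.markers, geno.samples)
        res = om.single_locus_scan(geno2, phen, K, coding="recessive")
        assert np.isnan(res.table.iloc[1]["p"])
        assert res.table.iloc[1]["note"] == "constant_coded_genotype"

    def test_marker_missingness_drops_samples_per_marker(self):
        geno, phen, K = _null_cohort(9, 9, n=60, m=3)
        dos = geno.dosage.copy()
        dos[:10, 0] = np.nan
        geno2 = om.GenotypeMatrix(dos, geno.markers, geno.samples)
        res = om.single_locus_scan(geno2, phen, K)
        assert res.table.iloc[0]["n_used"] == 50
        assert res.table.iloc[1]["n_used"] == 60


class TestFDR:
    def test_step_up_hand_example(self):
        adj = om.fdr_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_degenerate_inputs(self):
        assert om.fdr_adjust(np.array([])).size == 0
        assert np.allclose(om.fdr_adjust(np.ones(4)), 1.0)
        assert om.fdr_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_matches_statsmodels_reference(self):
        # independent cross-check against statsmodels' BH implementation
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            adj = om.fdr_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(adj, ref, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        assert (om.fdr_adjust(p) >= p - 1e-12).all()
        assert (np.diff(om.fdr_adjust(np.sort(p))) >= -1e-12).all()


@pytest.fixture(scope="module")
def scan_inputs():
    geno, phen, K = _null_cohort(21, 21, n=100, m=12)
    y, X0, _ = om.build_design(phen)
    G = np.column_stack([om.code_genotype(geno.dosage[:, j], "additive")
                         for j in range(12)])
    return y, X0, G, K


class TestEVT:
    def test_weak_observed_statistic_adjusts_to_one(self, scan_inputs):
        y, X0, G, K = scan_inputs
        res = om.evt_adjust(y, X0, G, K=K.values, n_perm=300, seed=0)
        # a null panel: most adjusted p should be large
        assert np.median(res.p_adjusted) > 0.5

    def test_strong_signal_beats_empirical_floor(self, scan_inputs):
        y, X0, G, K = scan_inputs
        y2 = y + 10.0 * G[:, 0]
        res = om.evt_adjust(y2, X0, G, K=K.values, n_perm=300, seed=1)
        assert res.p_adjusted[0] <= res.p_empirical[0]
        assert res.p_empirical[0] == pytest.approx(1 / 301, abs=1e-9)
        if res.converged:
            assert res.p_adjusted[0] < 1 / 300

    def test_single_marker_evt_tracks_empirical(self):
        geno, phen, K = _null_cohort(23, 24, n=100, m=1)
        y, X0, _ = om.build_design(phen)
        G = om.code_genotype(geno.dosage[:, 0], "additive")[:, None]
        res = om.evt_adjust(y, X0, G, K=K.values, n_perm=2000, seed=2)
        p_emp, p_fit = res.p_empirical[0], res.p_adjusted[0]
        if 0.01 < p_emp < 0.5:
            assert 0.5 * p_emp < p_fit < 2.0 * p_emp


class TestMultilocus:
    def test_duplicated_marker_collinearity_guard(self):
        geno, phen, K = _null_cohort(31, 31, n=150, m=4)
        dos = geno.dosage.copy()
        dos[:, 1] = dos[:, 0]  # exact duplicate
        y = phen["adaoo"].to_numpy() + 6.0 * om.code_genotype(dos[:, 0], "dominant")
        phen2 = phen.assign(adaoo=y)
        geno2 = om.GenotypeMatrix(dos, geno.markers, geno.samples)
        model = om.multilocus_select(geno2, phen2, K)
        assert "m0" not in model.markers  # marker ids are snp1..snp4
        assert model.markers.count("snp1") + model.markers.count("snp2") == 1
        assert model.markers[0] == "snp1"  # tie broken by input order

    def test_three_strong_markers_recovered_single_replicate(self):
        cfg = om.SimConfig(
            n_samples=400, n_markers=20, founder_count=25, pedigree_depth=3,
            maf_vector=np.linspace(0.1, 0.5, 20), sigma_g2=6.0, sigma_e2=6.0,
            mu=45.0,
            causal_spec=(om.CausalVariant(0, "dominant", 8.2),
                         om.CausalVariant(5, "dominant", 3.7),
                         om.CausalVariant(10, "dominant", 3.3)), seed=77)
        cohort = om.simulate_cohort(cfg)
        model = om.multilocus_select(cohort.genotypes, cohort.phenotypes,
                                     cohort.kinship_true)
        assert {"snp1", "snp6", "snp11"} <= set(model.markers)
        assert len(model.markers) <= 4

    def test_null_panel_selects_nothing_or_little(self):
        sizes = []
        for rep in range(10):
            geno, phen, K = _null_cohort(41, 4100 + rep, n=150, m=20)
            model = om.multilocus_select(geno, phen, K)
            sizes.append(len(model.markers))
        assert np.median(sizes) == 0
        assert max(sizes) <= 1

    def test_trace_respects_max_steps(self):
        geno, phen, K = _null_cohort(51, 51, n=100, m=10)
        model = om.multilocus_select(geno, phen, K, max_steps=2)
        adds = [t for t in model.trace if t["action"] == "add"]
        assert len(adds) <= 2


class TestPVE:
    def test_single_marker_matches_analytic_value(self):
        rng = np.random.default_rng(8)
        n = 20000
        code = rng.binomial(1, 0.4, size=n).astype(float)
        beta = 3.0
        y = 48 + beta * code + rng.normal(0, 2.0, size=n)
        per, total = om.pve(code[:, None], ["m"], y, np.ones((n, 1)))
        expected = beta**2 * 0.4 * 0.6 / (beta**2 * 0.4 * 0.6 + 4.0)
        assert per["m"] == pytest.approx(expected, rel=0.05)
        assert total == pytest.approx(expected, rel=0.05)

    def test_null_marker_has_near_zero_share(self):
        rng = np.random.default_rng(9)
        n = 2000
        strong = rng.binomial(1, 0.5, n).astype(float)
        null = rng.binomial(1, 0.5, n).astype(float)
        y = 50 + 5 * strong + rng.normal(size=n)
        per, total = om.pve(np.column_stack([strong, null]), ["a", "b"], y,
                            np.ones((n, 1)))
        assert per["b"] < 0.01
        assert per["a"] > 0.5

    def test_shares_nonnegative_and_sum_to_total(self, emulation_cohort):
        geno, _ = om.apply_qc(emulation_cohort.genotypes)
        model = om.multilocus_select(geno, emulation_cohort.phenotypes,
                                     emulation_cohort.kinship_true)
        if model.markers:
            assert all(v >= 0 for v in model.pve_per_marker.values())
            assert sum(model.pve_per_marker.values()) == pytest.approx(
                model.total_pve, abs=1e-8)
            assert model.total_pve <= 1


class TestHeterogeneity:
    def _cohort_with_sex_effects(self, seed, beta_f, beta_m, n=600):
        rng = substream(seed, "het")
        g = rng.binomial(2, 0.3, size=n).astype(float)
        sex = rng.choice(["F", "M"], size=n)
        code = (g >= 1).astype(float)
        y = 48 + np.where(sex == "F", beta_f, beta_m) * code + rng.normal(0, 2, n)
        phen = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)], "adaoo": y, "sex": sex,
            "edu_years": rng.integers(0, 16, n).astype(float),
            "edu_group": ["elementary"] * n})
        markers = [om.MarkerInfo("mk", "1", 1, "A", "G")]
        geno = om.GenotypeMatrix(g[:, None], markers, list(phen["sample_id"]))
        K = om.KinshipMatrix(np.eye(n), list(phen["sample_id"]))
        return geno, phen, K

    def test_null_calibration(self):
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            geno, phen, K = self._cohort_with_sex_effects(rep, 4.0, 4.0, n=150)
            het = om.heterogeneity_test("mk", "sex", geno, phen, K)
            rejections += het.p < 0.05
        assert 0.02 <= rejections / n_reps <= 0.10

    def test_opposite_sign_effects_detected(self):
        geno, phen, K = self._cohort_with_sex_effects(99, 4.0, -4.0)
        het = om.heterogeneity_test("mk", "sex", geno, phen, K)
        assert het.p < 1e-6
        assert het.df == 1

    def test_groups_without_carriers_excluded(self):
        geno, phen, K = self._cohort_with_sex_effects(5, 3.0, 3.0, n=200)
        dos = geno.dosage.copy()
        dos[(phen["sex"] == "M").to_numpy(), 0] = 0.0  # no male carriers
        geno2 = om.GenotypeMatrix(dos, geno.markers, geno.samples)
        het = om.heterogeneity_test("mk", "sex", geno2, phen, K)
        assert het.df == 0 or "fewer than 2 groups" in het.note

    def test_output_mirrors_chi2_df_p_layout(self, emulation_cohort):
        geno, _ = om.apply_qc(emulation_cohort.genotypes)
        het = om.heterogeneity_test(geno.marker_ids[0], "sex", geno,
                                    emulation_cohort.phenotypes,
                                    emulation_cohort.kinship_true)
        assert het.chi2 >= 0 and het.df >= 1 and 0 <= het.p <= 1


class TestEbicCriterion:
    def test_penalty_increases_with_model_size(self):
        assert _ebic(0.0, 2, 100, 65, 0.5) > _ebic(0.0, 1, 100, 65, 0.5)

    def test_reduces_to_bic_at_gamma_zero(self):
        assert _ebic(-10.0, 3, 50, 65, 0.0) == pytest.approx(
            20.0 + 3 * np.log(50))
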