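"""Two-locus cell means, epistatic decomposition, and resampling inference."""

import numpy as np
import pandas as pd
import pytest

import onsetmod as om
from onsetmod.containers import GenotypeMatrix, MarkerInfo
from onsetmod.epistasis import ContrastSpec, adjusted_cell_means, full_two_locus_fit


def _build(ga, gb, y, sex=None, edu=None):
    n = len(y)
    markers = [MarkerInfo("A", "1", 1, "A", "G"), MarkerInfo("B", "1", 2, "A", "G")]
    geno = GenotypeMatrix(np.column_stack([ga, gb]).astype(float), markers,
                          [f"s{i}" for i in range(n)])
    rng = np.random.default_rng(0)
    phen = pd.DataFrame({
        "sample_id": geno.samples,
        "adaoo": np.asarray(y, float),
        "sex": sex if sex is not None else rng.choice(["F", "M"], n),
        "edu_years": edu if edu is not None else rng.integers(0, 16, n).astype(float),
        "edu_group": ["elementary"] * n,
    })
    return geno, phen


def _two_locus_cohort(seed, n=400, aa_coef=0.0, sex_effect=0.0):
    rng = np.random.default_rng(seed)
    ga = rng.binomial(2, 0.4, n)
    gb = rng.binomial(2, 0.35, n)
    sex = rng.choice(["F", "M"], n)
    y = (48 + 2.0 * (ga - 1) + 1.5 * (gb - 1) + aa_coef * (ga - 1) * (gb - 1)
         + sex_effect * (sex == "F") + rng.normal(0, 2, n))
    return _build(ga, gb, y, sex=sex)


class TestAdjustedCellMeans:
    def test_null_covariates_leave_raw_means(self):
        geno, phen = _two_locus_cohort(1, n=300)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        raw = phen.assign(ga=geno.dosage[:, 0], gb=geno.dosage[:, 1]) \
            .groupby(["ga", "gb"])["adaoo"].mean()
        for _, row in design.cells.iterrows():
            assert row["adj_mean"] == pytest.approx(
                raw.loc[(row.g_a, row.g_b)], abs=0.25)

    def test_covariate_effect_removed(self):
        geno, phen = _two_locus_cohort(2, n=2000, sex_effect=6.0)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        # adjusted means should reflect only the genetic surface
        m00 = design.cell_mean(0, 0)
        m20 = design.cell_mean(2, 0)
        assert m20 - m00 == pytest.approx(4.0, abs=0.6)

    def test_additive_truth_gives_additive_surface(self):
        geno, phen = _two_locus_cohort(3, n=4000)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        fit = full_two_locus_fit(design)
        for term in ("aa", "ad", "da", "dd"):
            assert abs(fit.estimates.get(term, 0.0)) < 0.4
        assert fit.p_epistasis > 0.01

    def test_monomorphic_pair_rejected(self):
        geno, phen = _build(np.zeros(30), np.zeros(30), np.linspace(40, 60, 30))
        with pytest.raises(ValueError, match="monomorphic"):
            adjusted_cell_means(("A", "B"), geno, phen)

    def test_one_marker_monomorphic_reduces_to_one_way(self):
        rng = np.random.default_rng(4)
        ga = rng.binomial(2, 0.4, 200)
        y = 48 + 3 * ga + rng.normal(0, 1, 200)
        geno, phen = _build(ga, np.zeros(200), y)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        assert set(design.cells["g_b"]) == {0}
        assert len(design.cells) == 3

    def test_cell_counts_partition_sample(self):
        geno, phen = _two_locus_cohort(5, n=250)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        assert design.cells["n"].sum() == 250


class TestFullTwoLocusFit:
    def test_planted_aa_coefficient_recovered(self):
        geno, phen = _two_locus_cohort(6, n=6000, aa_coef=1.5)
        fit = full_two_locus_fit(adjusted_cell_means(("A", "B"), geno, phen))
        assert fit.estimates["aa"] == pytest.approx(1.5, abs=0.3)
        assert fit.p_epistasis < 1e-4

    def test_marker_swap_symmetry(self):
        geno, phen = _two_locus_cohort(7, n=1500, aa_coef=1.0)
        f_ab = full_two_locus_fit(adjusted_cell_means(("A", "B"), geno, phen))
        f_ba = full_two_locus_fit(adjusted_cell_means(("B", "A"), geno, phen))
        assert f_ab.estimates["aa"] == pytest.approx(f_ba.estimates["aa"], abs=1e-8)
        assert f_ab.estimates["dd"] == pytest.approx(f_ba.estimates["dd"], abs=1e-8)
        assert f_ab.estimates["ad"] == pytest.approx(f_ba.estimates["da"], abs=1e-8)

    def test_sparse_cells_drop_unidentifiable_terms(self):
        # one marker with no heterozygotes: d-terms unidentifiable
        rng = np.random.default_rng(8)
        ga = rng.choice([0, 2], 200)
        gb = rng.binomial(2, 0.4, 200)
        geno, phen = _build(ga, gb, 48 + ga + gb + rng.normal(0, 1, 200))
        fit = full_two_locus_fit(adjusted_cell_means(("A", "B"), geno, phen))
        assert "d1" in fit.dropped


class TestInteractionContrast:
    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(9)
        n = 200
        ga = np.tile([0, 1], n // 2)
        gb = rng.binomial(2, 0.4, n)
        y = np.tile([50.0, 50.0], n // 2) + np.repeat(rng.normal(0, 1, n // 2), 2)
        geno, phen = _build(ga, gb, y)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        res = om.interaction_contrast(design, ContrastSpec("a", None), B=300, seed=0)
        assert abs(res.delta_years) < 0.2
        assert res.p_perm > 0.3

    def test_planted_contrast_estimate_and_ci(self):
        rng = np.random.default_rng(10)
        n = 400
        ga = rng.binomial(2, 0.3, n)
        gb = rng.binomial(2, 0.4, n)
        y = 46 + 8.0 * (ga >= 1) + rng.normal(0, 2, n)
        geno, phen = _build(ga, gb, y)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        res = om.interaction_contrast(design, ContrastSpec("a", stratum=1),
                                      B=500, seed=1)
        assert res.delta_years == pytest.approx(8.0, abs=1.0)
        assert res.ci_low <= res.delta_years <= res.ci_high
        assert res.p_perm < 0.01

    def test_small_cells_flagged_inconclusive(self):
        ga = np.array([0, 0, 0, 0, 1, 0, 0, 0, 1, 0] * 3)
        gb = np.array([0, 1, 2, 0, 1, 0, 1, 2, 0, 1] * 3)
        y = np.linspace(40, 60, 30)
        geno, phen = _build(ga, gb, y)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        res = om.interaction_contrast(design, ContrastSpec("a", stratum=2),
                                      B=100, seed=2)
        assert res.flag.startswith("inconclusive")
        assert np.isnan(res.p_perm)

    def test_permutation_p_has_add_one_floor(self):
        rng = np.random.default_rng(11)
        n = 300
        ga = rng.binomial(2, 0.4, n)
        gb = rng.binomial(2, 0.4, n)
        y = 45 + 10.0 * (ga >= 1) + rng.normal(0, 1, n)
        geno, phen = _build(ga, gb, y)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        res = om.interaction_contrast(design, ContrastSpec("a", None), B=200, seed=3)
        assert res.p_perm >= 1 / 201
        assert res.p_perm == pytest.approx(1 / 201)

    def test_relabeling_samples_leaves_estimates_invariant(self):
        geno, phen = _two_locus_cohort(12, n=200)
        design = adjusted_cell_means(("A", "B"), geno, phen)
        res = om.interaction_contrast(design, ContrastSpec("a", stratum=0),
                                      B=200, seed=4)
        perm = np.random.default_rng(0).permutation(200)
        geno2 = geno.subset_samples(perm)
        phen2 = phen.iloc[perm].reset_index(drop=True)
        design2 = adjusted_cell_means(("A", "B"), geno2, phen2)
        res2 = om.interaction_contrast(design2, ContrastSpec("a", stratum=0),
                                       B=200, seed=4)
        assert res2.delta_years == pytest.approx(res.delta_years, abs=1e-10)

    def test_bootstrap_ci_width_shrinks_with_n(self):
        widths = []
        for n in (100, 400, 1600):
            rng = np.random.default_rng(13)
            ga = rng.binomial(2, 0.4, n)
            gb = rng.binomial(2, 0.4, n)
            y = 48 + 4.0 * (ga >= 1) + rng.normal(0, 3, n)
            geno, phen = _build(ga, gb, y)
            design = adjusted_cell_means(("A", "B"), geno, phen)
            res = om.interaction_contrast(design, ContrastSpec("a", None),
                                          B=400, seed=5)
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]
        assert widths[0] / widths[2] > 2.0  # ~ sqrt(16) ideally, allow slack


class TestPairwiseScreen:
    def test_three_markers_give_three_pairs(self):
        rng = np.random.default_rng(14)
        n = 200
        dosage = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        markers = [MarkerInfo(f"m{j}", "1", j + 1, "A", "G") for j in range(3)]
        geno = GenotypeMatrix(dosage, markers, [f"s{i}" for i in range(n)])
        phen = pd.DataFrame({
            "sample_id": geno.samples, "adaoo": rng.normal(48, 4, n),
            "sex": rng.choice(["F", "M"], n),
            "edu_years": rng.integers(0, 16, n).astype(float),
            "edu_group": ["elementary"] * n})
        res = om.pairwise_screen(["m0", "m1", "m2"], geno, phen, B=100, seed=0)
        pairs = res[["marker_a", "marker_b"]].drop_duplicates()
        assert len(pairs) == 3

    def test_deterministic_given_seed(self):
        geno, phen = _two_locus_cohort(15, n=150)
        r1 = om.pairwise_screen(["A", "B"], geno, phen, B=200, seed=9)
        r2 = om.pairwise_screen(["A", "B"], geno, phen, B=200, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_stratum_without_carriers_flagged_others_reported(self):
        rng = np.random.default_rng(16)
        n = 300
        ga = rng.binomial(2, 0.4, n).astype(float)
        gb = rng.binomial(2, 0.3, n).astype(float)
        ga[gb == 2] = 0.0  # no A-carriers in stratum B=2
        geno, phen = _build(ga, gb, rng.normal(48, 4, n))
        res = om.pairwise_screen(["A", "B"], geno, phen, B=100, seed=1)
        sub = res[(res.contrast.str.startswith("A")) & (res.stratum == "2")]
        assert (sub["flag"] != "").all()
        ok = res[(res.contrast.str.startswith("A")) & (res.stratum == "0")]
        assert (ok["flag"] == "").all()
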