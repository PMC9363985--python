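"""Allele-ratio regression, mapping filters, co-regulation flags,
stage Z-scores and the Mann-Whitney slope comparison."""

import numpy as np
import pandas as pd
import pytest

import hka
from hka.aseqreg import (allele_ratio, compare_slope_distributions,
                         flag_coregulation, gene_ratio_regression,
                         homokaryon_slope_filter, mismap_filter,
                         ratio_regression, stage_zscores)


def _ac(rows):
    return pd.DataFrame(rows, columns=["gene_id", "sample_id",
                                       "matA_count", "mata_count"])


class TestAlleleRatio:
    def test_simple_fraction(self):
        ac = _ac([("g1", "s1", 30, 10)])
        assert allele_ratio(ac, min_total=10).loc["g1", "s1"] == pytest.approx(0.75)

    def test_low_total_is_missing(self):
        ac = _ac([("g1", "s1", 0, 0), ("g1", "s2", 4, 5)])
        out = allele_ratio(ac, min_total=10)
        assert out.loc["g1"].isna().all()

    def test_binomial_sampling_accuracy(self):
        rng = np.random.default_rng(0)
        ks = rng.binomial(1000, 0.6, 50)
        ac = _ac([(f"g{i}", "s1", k, 1000 - k) for i, k in enumerate(ks)])
        out = allele_ratio(ac, min_total=10)
        assert np.abs(out["s1"] - 0.6).max() < 0.05


class TestMismapFilter:
    SAMPLES = pd.DataFrame({
        "sample_id": ["hA1", "ha1", "het1"],
        "lineage": "L1", "stage": "vegetative",
        "karyotype": ["homoA", "homoa", "het"],
        "initial_ratio": [1.0, 0.0, 0.5], "dna_ratio": [1.0, 0.0, 0.5],
        "replicate": 1,
    })

    def test_threshold_boundary(self):
        ac = _ac([("keep", "hA1", 97, 3),    # 3% mismap
                  ("drop", "hA1", 94, 6),    # 6% mismap
                  ("edge", "hA1", 95, 5)])   # exactly 5% -> kept
        kept = mismap_filter(ac, self.SAMPLES, threshold=0.05)
        assert set(kept) == {"keep", "edge"}

    def test_worst_homokaryon_sample_counts(self):
        ac = _ac([("g", "hA1", 99, 1), ("g", "ha1", 10, 90)])
        # in the homoa sample, matA reads are the mismapped ones: 10%
        assert len(mismap_filter(ac, self.SAMPLES, threshold=0.05)) == 0

    def test_no_assignable_reads_dropped(self):
        ac = _ac([("g", "hA1", 0, 0)])
        assert len(mismap_filter(ac, self.SAMPLES, threshold=0.05)) == 0

    def test_heterokaryon_sample_rejected(self):
        ac = _ac([("g", "het1", 50, 50)])
        with pytest.raises(ValueError, match="heterokaryon"):
            mismap_filter(ac, self.SAMPLES)

    def test_decision_boundary_recovered_in_simulation(self):
        # mismap rates ~ U(0, 0.1): genes on either side of 5% split
        # correctly up to binomial noise at ~800 homokaryon reads/gene
        rng = np.random.default_rng(1)
        rates = rng.uniform(0, 0.1, 300)
        rows = []
        for i, m in enumerate(rates):
            for sid, karyo in (("hA1", "homoA"), ("ha1", "homoa")):
                n = 800
                wrong = rng.binomial(n, m)
                a, b = (n - wrong, wrong) if karyo == "homoA" else (wrong, n - wrong)
                rows.append((f"g{i}", sid, a, b))
        kept = set(mismap_filter(_ac(rows), self.SAMPLES, threshold=0.05))
        clear_keep = {f"g{i}" for i in range(300) if rates[i] < 0.04}
        clear_drop = {f"g{i}" for i in range(300) if rates[i] > 0.065}
        assert len(clear_keep - kept) / max(len(clear_keep), 1) < 0.05
        assert len(clear_drop & kept) / max(len(clear_drop), 1) < 0.05


class TestRegression:
    def test_exact_identity_line(self):
        r = gene_ratio_regression([(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)])
        assert r["slope"] == pytest.approx(1.0)
        assert r["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert r["se_slope"] == pytest.approx(0.0, abs=1e-8)

    def test_exact_collinear_points(self):
        r = gene_ratio_regression([(0.1, 0.3), (0.5, 0.5), (0.9, 0.7)])
        assert r["slope"] == pytest.approx(0.5)
        assert r["intercept"] == pytest.approx(0.25)

    def test_too_few_points_flagged_not_raised(self):
        r = gene_ratio_regression([(0.1, 0.3), (0.5, 0.5)])
        assert not r["estimable"]
        assert np.isnan(r["slope"])

    def test_constant_d_flagged(self):
        r = gene_ratio_regression([(0.5, 0.3), (0.5, 0.5), (0.5, 0.7)])
        assert not r["estimable"]

    def test_ci_coverage_gaussian_noise(self):
        # 2000 replicate genes, 9 points, sigma=0.03: the 95% t-interval
        # should cover the true line ~95% of the time
        rng = np.random.default_rng(2)
        D = np.repeat([0.1, 0.5, 0.9], 3)
        G = 2000
        R = 0.25 + 0.5 * D + rng.normal(0, 0.03, (G, 9))
        ratios = pd.DataFrame(R, index=[f"g{i}" for i in range(G)],
                              columns=[f"s{j}" for j in range(9)])
        reg = ratio_regression(ratios, pd.Series(D, index=ratios.columns))
        cov_s = ((reg["ci_slope_lo"] <= 0.5) & (reg["ci_slope_hi"] >= 0.5)).mean()
        cov_i = ((reg["ci_intercept_lo"] <= 0.25) & (reg["ci_intercept_hi"] >= 0.25)).mean()
        assert 0.93 <= cov_s <= 0.97
        assert 0.93 <= cov_i <= 0.97


class TestFilters:
    def test_homokaryon_identity_gene_kept(self):
        pts = [(0.0, 0.01), (0.0, 0.0), (0.0, 0.02),
               (1.0, 0.99), (1.0, 1.0), (1.0, 0.985)]
        reg = ratio_regression(
            pd.DataFrame([[r for _, r in pts]], index=["g"],
                         columns=range(6)),
            pd.Series([d for d, _ in pts], index=range(6)))
        assert list(homokaryon_slope_filter(reg)) == ["g"]

    def test_asymmetric_mismapping_gene_dropped(self):
        # 20% mismapping: observed ratio ~0.2 at D=0, ~0.8 at D=1 -> slope 0.6
        rng = np.random.default_rng(3)
        D = np.array([0.0] * 3 + [1.0] * 3)
        R = np.where(D == 1, 0.8, 0.2) + rng.normal(0, 0.01, 6)
        reg = ratio_regression(pd.DataFrame([R], index=["g"], columns=range(6)),
                               pd.Series(D, index=range(6)))
        assert len(homokaryon_slope_filter(reg)) == 0

    def test_unestimable_gene_dropped(self):
        reg = ratio_regression(pd.DataFrame([[0.5, np.nan, np.nan, np.nan, np.nan, np.nan]],
                                            index=["g"], columns=range(6)),
                               pd.Series([0, 0, 0, 1, 1, 1], index=range(6)))
        assert len(homokaryon_slope_filter(reg)) == 0


class TestCoregulationFlags:
    def _reg_with_ci(self, slo, shi, ilo=-0.1, ihi=0.1):
        return pd.DataFrame({
            "slope": [(slo + shi) / 2], "intercept": [(ilo + ihi) / 2],
            "ci_slope_lo": [slo], "ci_slope_hi": [shi],
            "ci_intercept_lo": [ilo], "ci_intercept_hi": [ihi],
            "estimable": [True]}, index=["g"])

    def test_ci_below_one_flagged(self):
        out = flag_coregulation(self._reg_with_ci(0.4, 0.8))
        assert bool(out["slope_ne_1"].iloc[0])
        assert out["slope_direction"].iloc[0] == "below"

    def test_ci_spanning_one_not_flagged(self):
        out = flag_coregulation(self._reg_with_ci(0.9, 1.2))
        assert not bool(out["slope_ne_1"].iloc[0])

    def test_intercept_above_zero_flagged(self):
        out = flag_coregulation(self._reg_with_ci(0.9, 1.1, 0.05, 0.2))
        assert bool(out["intercept_ne_0"].iloc[0])
        assert out["intercept_direction"].iloc[0] == "above"

    def test_power_at_half_slope(self):
        rng = np.random.default_rng(4)
        D = np.repeat([0.1, 0.5, 0.9], 3)
        R = 0.25 + 0.5 * D + rng.normal(0, 0.03, (500, 9))
        reg = ratio_regression(pd.DataFrame(R, index=[f"g{i}" for i in range(500)],
                                            columns=range(9)),
                               pd.Series(D, index=range(9)))
        out = flag_coregulation(reg)
        assert ((out["slope_ne_1"]) & (out["slope_direction"] == "below")).mean() >= 0.8


class TestStageZscores:
    @staticmethod
    def _regs(slopes, intercepts=None):
        n = len(slopes)
        if intercepts is None:
            intercepts = np.linspace(-0.05, 0.05, n)
        return pd.DataFrame({
            "slope": slopes, "intercept": intercepts,
            "estimable": [True] * n}, index=[f"g{i}" for i in range(n)])

    def test_gene_at_sexual_mean_scores_zero(self):
        sex = self._regs([0.5, 0.6, 0.7])
        veg = self._regs([0.9, 1.0, 1.1])
        z = stage_zscores(sex, veg)
        assert z.loc["g1", "z_slope"] == pytest.approx(0.0, abs=1e-12)

    def test_plug_in_arithmetic(self):
        # sexual slopes ~ N(0.6, 0.1^2), vegetative ~ N(1, 0.1^2):
        # a sexual slope of 0.9 scores z ~ (0.9-0.6)/0.1 = +3
        rng = np.random.default_rng(5)
        sex = self._regs(np.append(rng.normal(0.6, 0.1, 999), 0.9))
        veg = self._regs(rng.normal(1.0, 0.1, 1000))
        z = stage_zscores(sex, veg)
        assert z["z_slope"].iloc[-1] == pytest.approx(3.0, abs=0.45)

    def test_zero_vegetative_sd_rejected(self):
        sex = self._regs([0.5, 0.6, 0.7])
        veg = self._regs([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="SD"):
            stage_zscores(sex, veg)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            stage_zscores(self._regs([0.5, 0.6]), self._regs([1.0, 1.1]))

    def test_genewise_centering_alternative(self):
        sex = self._regs([0.5, 0.6, 0.7])
        veg = self._regs([0.9, 1.0, 1.1])
        z = stage_zscores(sex, veg, center="vegetative_gene")
        assert z.loc["g0", "z_slope"] == pytest.approx((0.5 - 0.9) / 0.1)


class TestSlopeDistributionComparison:
    def test_identical_lists_p_one(self):
        u, p = compare_slope_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.99

    def test_exact_small_sample_enumeration(self):
        # all 20 arrangements: separated triples give two-sided p = 0.1
        u, p = compare_slope_distributions([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert u == 0.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(6)
        u, p = compare_slope_distributions(rng.normal(0.6, 0.1, 1000),
                                           rng.normal(1.0, 0.1, 1000))
        assert p < 1e-16

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            compare_slope_distributions([], [1.0])


class TestPipeline:
    def test_full_ase_pipeline_on_simulation(self):
        cfg = hka.SimulationConfig(
            n_genes=300, lineages=("L1",),
            slope_by_stage={"vegetative": (1.0, 0.0), "sexual": (0.6, 0.05)},
            intercept_by_stage={"vegetative": (0.0, 0.0), "sexual": (0.2, 0.02)},
            mismap_beta=(1.0, 200.0),  # clean mapping so filters keep most genes
            mean_log_expression=7.0, library_size_mean=1e6, seed=44)
        cm, ac, samples, truth = hka.simulate_experiment(cfg)
        res = hka.ase_pipeline(ac, samples)
        assert len(res["kept_genes"]) > 100
        veg = res["regressions"]["vegetative"]
        sex = res["regressions"]["sexual"]
        est = veg["estimable"] & sex["estimable"]
        # vegetative tracks the identity line; sexual is compressed
        assert abs(veg.loc[est, "slope"].mean() - 1.0) < 0.1
        assert sex.loc[est, "slope"].mean() < 0.8
        assert res["mann_whitney"]["p_value"] < 1e-10
        assert res["mann_whitney"]["median_slope_sexual"] < \
            res["mann_whitney"]["median_slope_vegetative"]

    def test_clean_genes_unaffected_by_filter_order(self):
        # for genes that pass both filters, running the filters in either
        # order keeps them and the heterokaryon fits are unchanged
        cfg = hka.SimulationConfig(n_genes=120, lineages=("L1",),
                                   mismap_beta=(1.0, 1e9),
                                   mean_log_expression=7.0,
                                   library_size_mean=1e6, seed=45)
        cm, ac, samples, truth = hka.simulate_experiment(cfg)
        res = hka.ase_pipeline(ac, samples)
        meta = samples.set_index("sample_id")
        homo_ids = meta.index[meta["karyotype"] != "het"]
        # reversed order: slope filter first, then mismap
        ratios = allele_ratio(ac)
        homo_d = meta.loc[homo_ids, "karyotype"].map({"homoA": 1.0, "homoa": 0.0})
        cols = [c for c in ratios.columns if c in set(homo_ids)]
        reg = ratio_regression(ratios[cols], homo_d[cols])
        kept1 = set(homokaryon_slope_filter(reg))
        kept2 = set(mismap_filter(ac[ac["sample_id"].isin(homo_ids)], samples))
        assert set(res["kept_genes"]) == kept1 & kept2
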