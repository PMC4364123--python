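import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import studentized_range

import corticompare as cc
from corticompare import roi_stats


class TestFixtures:
    def test_roi_registry_has_28_regions(self, registry):
        assert len(registry) == 28
        assert registry["roi_id"].is_unique
        assert set(registry["lobe"]) == {"Frontal", "Parietal", "Occipital",
                                         "Limbic", "Temporal"}

    def test_qc_checklist_has_23_sulci(self):
        qc = cc.load_fixture_table("QC23")
        assert len(qc) == 23
        assert qc["name"].is_unique

    def test_demographics_total_185(self):
        t1 = cc.load_fixture_table("T1")
        assert t1["n"].sum() == 185
        assert t1.set_index("group").loc["CTR", "n"] == 69

    def test_longitudinal_flag_counts(self):
        """Printed significance-flag counts: Civet 18/10/28/28 and
        Freesurfer 10/0/22/7 ROIs for the four contrasts."""
        t4 = cc.load_fixture_table("T4")
        counts = {}
        for p in ("CV", "FS"):
            s = t4[t4.pipeline == p]
            counts[p] = (int(s.flag_ctr_pmci.sum()), int(s.flag_smci_pmci.sum()),
                         int(s.flag_ctr_ad.sum()), int(s.flag_smci_ad.sum()))
        assert counts["CV"] == (18, 10, 28, 28)
        assert counts["FS"] == (10, 0, 22, 7)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError):
            cc.load_fixture_table("T9")


class TestAtlas:
    def test_28_labels_cover_every_vertex(self, small_template, small_atlas,
                                          registry):
        assert len(small_atlas) == small_template.n_vertices
        assert set(np.unique(small_atlas)) == set(registry["roi_id"])

    def test_mirrored_and_deterministic(self, small_template, registry):
        a1 = cc.build_synthetic_atlas(small_template, registry, seed=5)
        a2 = cc.build_synthetic_atlas(small_template, registry, seed=5)
        assert np.array_equal(a1, a2)
        # mirrored: label histograms match across hemispheres
        left = a1[small_template.hemisphere == "left"]
        right = a1[small_template.hemisphere == "right"]
        assert np.array_equal(np.sort(np.unique(left)),
                              np.sort(np.unique(right)))

    def test_patch_areas_within_3x(self, registry):
        tmpl = cc.build_cortex_template(3, radius=30.0)
        atlas = cc.build_synthetic_atlas(tmpl, registry, seed=1)
        counts = pd.Series(atlas).value_counts()
        assert counts.max() / counts.min() <= 3.0


class TestAggregate:
    def test_constant_map(self, small_template, small_atlas):
        maps = {("s0", "CV", "BSL"): np.full(small_template.n_vertices, 2.2)}
        t = cc.roi_aggregate(maps, small_atlas, {"s0": "CTR"})
        assert np.allclose(t["thickness"], 2.2)
        assert len(t) == 28

    def test_indicator_map(self, small_template, small_atlas):
        roi = int(np.unique(small_atlas)[0])
        maps = {("s0", "CV", "BSL"): (small_atlas == roi).astype(float)}
        t = cc.roi_aggregate(maps, small_atlas, {}).set_index("roi_id")
        assert t.loc[roi, "thickness"] == 1.0
        assert (t.drop(index=roi)["thickness"] == 0.0).all()

    def test_unweighted_close_to_area_weighted_on_smooth_maps(
            self, small_template, small_atlas):
        rng = np.random.default_rng(0)
        smooth = 2.5 + 0.3 * np.sin(small_template.vertices[:, 2] / 10.0)
        maps = {("s0", "CV", "BSL"): smooth}
        w = roi_stats.vertex_area_weights(small_template)
        t_u = cc.roi_aggregate(maps, small_atlas, {})
        t_w = cc.roi_aggregate(maps, small_atlas, {}, area_weights=w)
        rel = np.abs(t_u["thickness"].to_numpy() - t_w["thickness"].to_numpy()) \
            / t_w["thickness"].to_numpy()
        assert rel.max() < 0.05


class TestTukeyKramer:
    def test_identical_groups_no_flags(self):
        res = cc.tukey_kramer_summary([1.0, 1.0, 1.0], [0.2, 0.2, 0.2],
                                      [20, 30, 25])
        assert not res.significant.any()

    def test_outlier_group_flagged_against_all(self):
        """Means (0,0,0,1) with sd 0.1 at the study's group sizes: the
        last group separates from every other (q >> critical)."""
        res = cc.tukey_kramer_summary(
            [0, 0, 0, 1.0], [0.1] * 4, [69, 37, 27, 52],
            alpha=0.05, labels=list("ABCD"))
        flagged = {pair for pair, sig in zip(res.pairs, res.significant) if sig}
        assert flagged == {("A", "D"), ("B", "D"), ("C", "D")}

    def test_reduces_to_hsd_at_equal_n(self):
        """At equal n the Tukey-Kramer p equals scipy's classic HSD."""
        rng = np.random.default_rng(1)
        g = [rng.normal(m, 0.5, size=15) for m in (0.0, 0.3, 0.55)]
        ref = stats.tukey_hsd(*g)
        res = cc.tukey_kramer_summary([x.mean() for x in g],
                                      [x.std(ddof=1) for x in g],
                                      [15, 15, 15])
        for k, (i, j) in enumerate(res.pairs):
            assert res.p[k] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_q_matches_studentized_range_oracle(self):
        """Adjusted p equals the studentized-range tail at the
        Tukey-Kramer q with unequal n."""
        means, sds, ns = [0.1, -0.2, 0.05], [0.3, 0.25, 0.4], [12, 25, 8]
        res = cc.tukey_kramer_summary(means, sds, ns)
        msw = sum((n - 1) * s ** 2 for n, s in zip(ns, sds)) / (sum(ns) - 3)
        k = 0
        for i in range(3):
            for j in range(i + 1, 3):
                q = abs(means[i] - means[j]) / np.sqrt(
                    msw / 2 * (1 / ns[i] + 1 / ns[j]))
                assert res.p[k] == pytest.approx(
                    studentized_range.sf(q, 3, sum(ns) - 3))
                k += 1

    def test_precuneus_longitudinal_row_reproduces_flags(self):
        """Recomputing from the printed Precuneus summaries
        (-0.01/-0.02/-0.07/-0.11, sigma 0.07/0.07/0.11/0.11, n 69/37/27/52)
        at alpha=0.01 flags CTR-vs-AD and sMCI-vs-AD."""
        res = cc.tukey_kramer_summary(
            [-0.01, -0.02, -0.07, -0.11], [0.07, 0.07, 0.11, 0.11],
            [69, 37, 27, 52], alpha=0.01, labels=list(roi_stats.GROUP_ORDER))
        sig = {pair for pair, s in zip(res.pairs, res.significant) if s}
        assert ("CTR", "AD") in sig
        assert ("sMCI", "AD") in sig

    def test_anova_tukey_from_tidy_table(self):
        rng = np.random.default_rng(2)
        rows = []
        for g, mu, n in (("CTR", 2.5, 30), ("AD", 2.1, 25)):
            for i in range(n):
                rows.append((f"{g}{i}", g, "CV", "BSL", 3,
                             mu + 0.2 * rng.standard_normal()))
        table = pd.DataFrame(rows, columns=["subject", "group", "pipeline",
                                            "timepoint", "roi_id", "thickness"])
        res = cc.anova_tukey(table, groups=("CTR", "AD"), alpha=0.01)
        assert res[3].significant.all()
        assert res[3].omnibus_p < 1e-6

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            cc.tukey_kramer_summary([0, 1], [0.1, 0.1], [5, 1])


class TestHedgesG:
    def test_equal_means_zero(self):
        assert cc.hedges_g(2.0, 0.3, 20, 2.0, 0.3, 25).g == 0.0

    def test_closed_form_small_sample_correction(self):
        """Standardized difference of 1 at n1=n2=10: g = 1 - 3/71."""
        res = cc.hedges_g(1.0, 1.0, 10, 0.0, 1.0, 10)
        assert res.g == pytest.approx(1 - 3 / 71)
        assert res.g == pytest.approx(0.9577, abs=1e-4)
        assert res.J == pytest.approx(1 - 3 / 71)

    def test_published_middle_temporal_magnitude(self):
        """Source-pipeline CTR-vs-AD summaries for the posterior middle
        temporal gyrus (delta 0.33 mm, sigma 0.25, n 69/52) put |g| near
        1.3 — the strong-signature regime."""
        res = cc.hedges_g(0.0, 0.25, 69, -0.33, 0.25, 52)
        assert abs(res.g) == pytest.approx(1.3, abs=0.05)
        assert abs(res.g) > 0.8

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cc.hedges_g(1.0, 0.0, 10, 0.0, 0.0, 10)

    def test_recovers_injected_effect_within_ci(self):
        rng = np.random.default_rng(3)
        inside = 0
        for _ in range(20):
            x1 = rng.normal(0.5, 1.0, 69)
            x2 = rng.normal(0.0, 1.0, 52)
            res = cc.hedges_g_from_samples(x1, x2)
            if abs(res.g - 0.5) < 1.96 * res.se_g:
                inside += 1
        assert inside >= 17


class TestCompareEffectSizes:
    def test_equal_g_zero(self):
        g = cc.hedges_g(1.0, 1.0, 20, 0.0, 1.0, 20)
        z, p = cc.compare_effect_sizes(g, g)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        g1 = cc.hedges_g(1.0, 1.0, 20, 0.0, 1.0, 20)
        g2 = cc.hedges_g(0.4, 1.0, 30, 0.0, 1.0, 25)
        assert cc.compare_effect_sizes(g1, g2)[0] == pytest.approx(
            -cc.compare_effect_sizes(g2, g1)[0])

    def test_null_calibration(self):
        """Same pipeline measured on two independent cohorts: rejection
        rate at alpha=0.05 is nominal."""
        rng = np.random.default_rng(4)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            g1 = cc.hedges_g_from_samples(rng.normal(0.3, 1, 69),
                                          rng.normal(0, 1, 52))
            g2 = cc.hedges_g_from_samples(rng.normal(0.3, 1, 69),
                                          rng.normal(0, 1, 52))
            if cc.compare_effect_sizes(g1, g2)[1] < 0.05:
                rej += 1
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) <= 2 * se + 0.01


class TestThinningPercent:
    def _table(self):
        rows = []
        for g, bsl, m24 in (("CTR", 2.0, 2.0), ("AD", 2.0, 1.9)):
            for i in range(4):
                for tp, v in (("BSL", bsl), ("M24", m24)):
                    rows.append((f"{g}{i}", g, "CV", tp, 3, v))
        return pd.DataFrame(rows, columns=["subject", "group", "pipeline",
                                           "timepoint", "roi_id", "thickness"])

    def test_no_change_zero_percent(self):
        out = cc.thinning_percent(self._table())
        ctr = out[out.group == "CTR"]
        assert np.allclose(ctr["percent"], 0.0)

    def test_uniform_five_percent_thinning(self):
        out = cc.thinning_percent(self._table())
        ad = out[out.group == "AD"]
        assert np.allclose(ad["percent"], -5.0)

    def test_cross_sectional_mode(self):
        out = cc.thinning_percent(self._table(), mode="cross")
        assert np.allclose(out["percent"], 0.0)  # equal baselines


class TestCorrelations:
    def test_covariate_equal_to_thickness_gives_r_one(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(2, 3, 20)
        table = pd.DataFrame({
            "subject": [f"s{i}" for i in range(20)], "roi_id": 3,
            "thickness": vals})
        cov = pd.DataFrame({"x": vals}, index=[f"s{i}" for i in range(20)])
        res = cc.pearson_by_roi(table, cov, "x")
        assert res[0].r == pytest.approx(1.0)

    def test_null_width_at_n69(self):
        """|r| of an independent covariate at n=69 stays under 0.24 in
        ~95% of draws (the null sampling width of Pearson's r)."""
        rng = np.random.default_rng(6)
        subs = [f"s{i}" for i in range(69)]
        inside = 0
        for _ in range(100):
            table = pd.DataFrame({"subject": subs, "roi_id": 1,
                                  "thickness": rng.standard_normal(69)})
            cov = pd.DataFrame({"x": rng.standard_normal(69)}, index=subs)
            if abs(cc.pearson_by_roi(table, cov, "x")[0].r) < 0.24:
                inside += 1
        assert inside >= 88

    def test_constant_covariate_rejected(self):
        table = pd.DataFrame({"subject": ["a", "b", "c", "d"], "roi_id": 1,
                              "thickness": [1.0, 2.0, 3.0, 4.0]})
        cov = pd.DataFrame({"x": [1.0] * 4}, index=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            cc.pearson_by_roi(table, cov, "x")


class TestSteigerZ:
    def test_equal_correlations_zero(self):
        z, p = cc.steiger_z(0.4, 0.4, 0.6, 69)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric(self):
        z1, _ = cc.steiger_z(0.5, 0.2, 0.6, 50)
        z2, _ = cc.steiger_z(0.2, 0.5, 0.6, 50)
        assert z1 == pytest.approx(-z2)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            cc.steiger_z(1.0, 0.5, 0.5, 50)

    def test_null_calibration(self):
        """Dependent triples with equal population correlations: type-I
        error at alpha=0.05 is nominal (2000 reps, n=69)."""
        rng = np.random.default_rng(7)
        rho, r12 = 0.4, 0.5
        cov = np.array([[1, r12, rho], [r12, 1, rho], [rho, rho, 1]])
        L = np.linalg.cholesky(cov)
        n_rep, rej = 2000, 0
        for _ in range(n_rep):
            xyz = rng.standard_normal((69, 3)) @ L.T
            r1 = np.corrcoef(xyz[:, 0], xyz[:, 2])[0, 1]
            r2 = np.corrcoef(xyz[:, 1], xyz[:, 2])[0, 1]
            r12_hat = np.corrcoef(xyz[:, 0], xyz[:, 1])[0, 1]
            if cc.steiger_z(r1, r2, r12_hat, 69)[1] < 0.05:
                rej += 1
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) <= 2 * se + 0.01


class TestKendallConversion:
    def test_perfect_concordance(self):
        tau, z, r_eq = cc.kendall_with_conversion(np.arange(15.0),
                                                  np.arange(15.0) * 2 + 1)
        assert tau == pytest.approx(1.0)
        assert r_eq == pytest.approx(1.0)
        assert z > 4

    def test_greiner_closed_form_at_half(self):
        assert np.sin(np.pi * 0.5 / 2) == pytest.approx(0.7071, abs=1e-4)

    def test_greiner_consistency_under_normality(self):
        """On bivariate normal data with rho=0.6 the converted coefficient
        recovers rho."""
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky([[1, 0.6], [0.6, 1]])
        xy = rng.standard_normal((500, 2)) @ L.T
        _, _, r_eq = cc.kendall_with_conversion(xy[:, 0], xy[:, 1])
        assert r_eq == pytest.approx(0.6, abs=0.05)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            cc.kendall_with_conversion(np.ones(12), np.arange(12.0))
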