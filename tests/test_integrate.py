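"""Peak-gene association, logistic DE-odds model, class tests, regimes."""

import numpy as np
import pandas as pd
import pytest

from notchpulse import integrate, synth


class TestMinDistance:
    def test_overlap_is_zero(self):
        assert integrate.min_distance((100, 200), (150, 300)) == 0

    def test_gap_arithmetic(self):
        assert integrate.min_distance((100, 200), (210, 260)) == 10

    def test_exhaustive_grid_matches_brute_force_base_scan(self):
        for a0 in range(0, 8):
            for a1 in range(a0 + 1, 9):
                for b0 in range(0, 8):
                    for b1 in range(b0 + 1, 9):
                        got = integrate.min_distance((a0, a1), (b0, b1))
                        # brute force over covered bases: 0 on shared base,
                        # else the number of intervening bases
                        brute = min(
                            0 if x == y else abs(x - y) - 1
                            for x in range(a0, a1)
                            for y in range(b0, b1)
                        )
                        assert got == brute


class TestCountPeaksWithin:
    def test_radius_boundary_inclusive(self):
        gene = [(0, 1000)]
        assert integrate.count_peaks_within(gene, [(10_999, 11_100)], radius=10_000) == 1
        assert integrate.count_peaks_within(gene, [(11_001, 11_100)], radius=10_000) == 0

    def test_overlapping_peak_counts(self):
        assert integrate.count_peaks_within([(0, 1000)], [(500, 600)]) >= 1

    def test_monotone_in_radius(self, rng):
        gene = [(5000, 7000)]
        peaks = [(int(s), int(s) + 200) for s in rng.integers(0, 50_000, 30)]
        counts = [
            integrate.count_peaks_within(gene, peaks, radius=r)
            for r in (0, 1000, 5000, 20_000)
        ]
        assert counts == sorted(counts)

    def test_nearest2_assignment_tie_breaks_leftmost(self):
        # peak equidistant from three genes: the two leftmost-starting win
        genes = {
            "gA": [(0, 100)],
            "gB": [(300, 400)],
            "gC": [(150, 160), (340, 350)],  # same min distance as gB
        }
        peak = (200, 250)
        # distances: gA 100, gB 50, gC 0 (overlap? no: 150-160 vs 200-250 gap 40; 340-350 gap 90 -> 40)
        out = integrate.assign_peaks_nearest2(genes, [peak])
        assert len(out[0]) == 2


class TestEffectToOdds:
    def test_printed_conversions(self):
        assert integrate.effect_to_odds(2.78) == 16.12
        assert integrate.effect_to_odds(0.77) == 2.16
        assert integrate.effect_to_odds(-0.49) == 0.61

    def test_identity(self):
        assert integrate.effect_to_odds(0.0) == 1.00

    def test_infinite_rejected(self):
        with pytest.raises(ValueError):
            integrate.effect_to_odds(np.inf)


class TestFitDELogistic:
    def test_null_predictor_coefficient_near_zero(self):
        cfg = synth.SynthConfig(
            n_genes=10,
            cluster_spec=(("flat", 0.0, 10),),
            regression_betas={"const": -0.5, "suh": 0.0, "P": 0.0, "AP": 0.0, "AU": 0.0, "logC0": 0.0},
            seed=51,
        )
        tbl = synth.gen_de_odds_table(cfg, n=2000)
        fit = integrate.fit_de_logistic(tbl)
        assert abs(fit.params["suh"]) < 3 * fit.bse["suh"]

    def test_generating_betas_recovered_within_2se(self):
        cfg = synth.SynthConfig(n_genes=10, cluster_spec=(("flat", 0.0, 10),), seed=52)
        tbl = synth.gen_de_odds_table(cfg, n=5000)
        fit = integrate.fit_de_logistic(tbl)
        for name, true in [("suh", 2.78), ("P", 0.77), ("AU", -0.49)]:
            assert abs(fit.params[name] - true) < 2 * fit.bse[name], name

    def test_constant_column_dropped(self):
        cfg = synth.SynthConfig(n_genes=10, cluster_spec=(("flat", 0.0, 10),), seed=53)
        tbl = synth.gen_de_odds_table(cfg, n=500)
        tbl["allzero"] = 0
        fit = integrate.fit_de_logistic(tbl)
        assert "allzero" in fit.dropped
        assert "allzero" not in fit.params.index

    def test_complete_separation_detected(self):
        rng = np.random.default_rng(54)
        x = rng.binomial(1, 0.5, 200)
        tbl = pd.DataFrame({"x": x, "de": x})
        fit = integrate.fit_de_logistic(tbl)
        assert fit.separation
        assert np.isfinite(fit.params["x"])

    def test_wald_interval_coverage_over_seeded_datasets(self):
        """95% Wald CIs cover the generating coefficient 90-99% of the time."""
        hits = {"suh": 0, "P": 0, "AU": 0}
        true = {"suh": 2.78, "P": 0.77, "AU": -0.49}
        n_data = 50
        for seed in range(n_data):
            cfg = synth.SynthConfig(
                n_genes=10, cluster_spec=(("flat", 0.0, 10),), seed=600 + seed
            )
            tbl = synth.gen_de_odds_table(cfg, n=1500)
            fit = integrate.fit_de_logistic(tbl)
            ci = fit.conf_int()
            for name in hits:
                if ci.loc[name, "lo"] <= true[name] <= ci.loc[name, "hi"]:
                    hits[name] += 1
        coverage = sum(hits.values()) / (3 * n_data)
        assert 0.90 <= coverage <= 0.99


class TestLogC0ClassTests:
    def test_identical_values_f_zero_p_one(self):
        logc0 = pd.Series([5.0] * 8)
        classes = pd.Series(["UB"] * 4 + ["AU"] * 4)
        res = integrate.logC0_class_tests(logc0, classes)
        assert res.anova_F == 0.0
        assert res.anova_p == 1.0

    def test_large_separation_tiny_one_sided_p(self, rng):
        logc0 = pd.Series(np.r_[rng.normal(3, 1, 100), rng.normal(0, 1, 100)])
        classes = pd.Series(["AU"] * 100 + ["UB"] * 100)
        res = integrate.logC0_class_tests(logc0, classes)
        row = res.pairwise.iloc[0]
        assert row["higher"] == "AU"
        assert row["p_one_sided"] < 1e-10

    def test_anova_f_matches_sum_of_squares_oracle(self):
        # 12-value toy table, 3 classes of 4
        vals = np.array([1.0, 2, 3, 4, 2, 3, 4, 5, 6, 7, 8, 9])
        classes = ["UB"] * 4 + ["P"] * 4 + ["AU"] * 4
        res = integrate.logC0_class_tests(pd.Series(vals), pd.Series(classes))
        groups = [vals[:4], vals[4:8], vals[8:]]
        grand = vals.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 2) / (ss_within / 9)
        assert res.anova_F == pytest.approx(f_oracle)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            integrate.logC0_class_tests(
                pd.Series([1.0, 2.0]), pd.Series(["UB", "UB"])
            )

    def test_class_activity_ordering_on_synthetic_data(self, rng):
        """logC0 tracks class activity: active classes > poised > unbound."""
        n = 80
        means = {"AU": 11.0, "AP": 10.5, "P": 9.0, "UB": 7.5}
        classes = pd.Series(rng.choice(list(means), size=n))
        logc0 = pd.Series([rng.normal(means[c], 0.5) for c in classes])
        res = integrate.logC0_class_tests(logc0, classes)
        assert res.anova_p < 1e-6
        active = logc0[classes.isin(["AU", "AP"])].mean()
        poised = logc0[classes == "P"].mean()
        unbound = logc0[classes == "UB"].mean()
        assert active > poised > unbound


class TestRegimeCompare:
    def test_identical_regimes(self):
        fc = pd.Series([1.0, -0.5, 2.0, 0.1], index=list("abcd"))
        res = integrate.regime_compare(fc, fc)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_flagged == 0

    def test_single_divergent_gene_flagged(self):
        fc_a = pd.Series([1.0, 1.0, 1.0, 2.0], index=list("abcd"))
        fc_b = fc_a.copy()
        fc_b["d"] = 4.0  # ratio 2**2 = 4 > 2
        res = integrate.regime_compare(fc_a, fc_b)
        assert list(res.flagged) == ["d"]

    def test_slope_r2_match_normal_equations_oracle(self, rng):
        x = rng.normal(0, 1, 100)
        y = 0.8 * x + rng.normal(0, 0.3, 100)
        fa, fb = pd.Series(x), pd.Series(y)
        res = integrate.regime_compare(fa, fb)
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert res.slope == pytest.approx(slope)
        assert res.r_squared == pytest.approx(r2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            integrate.regime_compare(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))


def test_master_table_schema_completeness(small_config):
    """Every tested transcript appears once with cluster, Pol II and Su(H) columns."""
    from notchpulse import cluster, expression

    tc, truth = synth.gen_expression(small_config)
    de = expression.timecourse_de(tc)
    profs = cluster.ProfileSet.from_timecourse(tc)
    samples = cluster.fit_dp(profs, n_sweeps=200, burn_in=100, seed=61)
    summ = cluster.summarize_clusters(samples, ids=profs.ids)
    polii_states = pd.DataFrame(
        {0.0: "UB", 10.0: "P"}, index=tc.transcripts
    )
    suh_counts = pd.DataFrame({0.0: 1, 10.0: 0}, index=tc.transcripts)
    master = integrate.build_master_table(
        de_table=de.table,
        transcript_gene=pd.Series({t: t for t in tc.transcripts}),
        median_m=tc.median_m(),
        cluster_assignments=summ.assignments,
        polii_states=polii_states,
        suh_counts=suh_counts,
        logc0=pd.Series(10.0, index=tc.transcripts),
    )
    assert len(master) == len(tc.transcripts)
    assert master.index.is_unique
    for col in ("cluster_primary", "polii_0min", "suh_0min", "logC0", "rank"):
        assert col in master.columns
    assert master["cluster_primary"].notna().all()
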