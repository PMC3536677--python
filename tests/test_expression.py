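"""M/A transform, within-array normalization, spline F-test DE, logC0."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from notchpulse import expression, synth


def _raw_row(transcript, time, rep, treated, reference, spot=None):
    return {
        "spot": spot or f"{transcript}_{time}_{rep}",
        "transcript": transcript,
        "time": time,
        "rep": rep,
        "ch_treated": treated,
        "ch_reference": reference,
    }


class TestComputeMA:
    def test_equal_channels_give_zero_m(self):
        raw = pd.DataFrame([_raw_row("t1", 0, 0, 1000, 1000)])
        tc = expression.compute_ma(raw)
        assert tc.m.iloc[0, 0] == pytest.approx(0.0)
        assert tc.a.iloc[0, 0] == pytest.approx(np.log2(1000))

    def test_fourfold_ratio_gives_m_two(self):
        raw = pd.DataFrame([_raw_row("t1", 0, 0, 4000, 1000)])
        assert expression.compute_ma(raw).m.iloc[0, 0] == pytest.approx(2.0)

    def test_elementwise_agreement_with_direct_recomputation(self, rng):
        rows = [
            _raw_row(f"t{i}", t, r, rng.uniform(10, 1e5), rng.uniform(10, 1e5))
            for i in range(20)
            for t in (0, 10)
            for r in (0, 1)
        ]
        raw = pd.DataFrame(rows)
        tc = expression.compute_ma(raw)
        for row in rows:
            m = np.log2(row["ch_treated"]) - np.log2(row["ch_reference"])
            a = 0.5 * (np.log2(row["ch_treated"]) + np.log2(row["ch_reference"]))
            assert tc.m.loc[row["transcript"], (row["time"], row["rep"])] == pytest.approx(m)
            assert tc.a.loc[row["transcript"], (row["time"], row["rep"])] == pytest.approx(a)

    def test_nonpositive_intensities_dropped(self):
        raw = pd.DataFrame(
            [_raw_row("t1", 0, 0, 1000, 1000), _raw_row("t2", 0, 0, -5, 1000)]
        )
        tc = expression.compute_ma(raw)
        assert "t2" not in tc.m.index


class TestNormalizeWithinArray:
    def _flat_tc(self, rng, n=200):
        a = rng.uniform(6, 14, size=n)
        m = rng.normal(0, 0.05, size=n)
        m -= np.median(m)
        cols = pd.MultiIndex.from_tuples([(0, 0)], names=["time", "rep"])
        return expression.TimecourseMatrix(
            m=pd.DataFrame(m, columns=cols),
            a=pd.DataFrame(a, columns=cols),
        )

    def test_idempotent_on_centered_flat_trend(self, rng):
        tc = self._flat_tc(rng)
        out = expression.normalize_within_array(tc)
        assert np.abs(out.m.to_numpy() - tc.m.to_numpy()).max() < 0.05

    def test_removes_planted_intensity_dependent_offset(self, rng):
        tc = self._flat_tc(rng)
        m_true = tc.m.to_numpy().ravel().copy()
        a = tc.a.to_numpy().ravel()
        tc.m.iloc[:, 0] = m_true + 0.5 * a
        out = expression.normalize_within_array(tc)
        recovered = out.m.to_numpy().ravel()
        assert np.abs(recovered - (m_true - np.median(m_true))).max() < 0.05

    def test_postcondition_median_zero(self, rng):
        tc = self._flat_tc(rng)
        tc.m.iloc[:, 0] = tc.m.to_numpy().ravel() + rng.normal(1.0, 0.4, size=len(tc.m))
        out = expression.normalize_within_array(tc)
        assert abs(np.median(out.m.to_numpy())) < 1e-6

    def test_constant_a_falls_back_to_median_centring(self, rng):
        tc = self._flat_tc(rng)
        tc.a.iloc[:, 0] = 10.0
        out = expression.normalize_within_array(tc)
        assert abs(np.median(out.m.to_numpy())) < 1e-6


class TestTimecourseDE:
    def test_constant_nonzero_profile_is_not_de(self):
        times = list(range(0, 180, 10))
        cols = pd.MultiIndex.from_product([times, [0, 1]], names=["time", "rep"])
        m = pd.DataFrame(np.ones((3, len(cols))), columns=cols)
        res = expression.timecourse_de(expression.TimecourseMatrix(m=m))
        assert np.allclose(res.table["F"], 0.0)
        assert (res.table["q"] > 0.5).all()

    def test_planted_signal_reaches_significance(self):
        cfg = synth.SynthConfig(
            n_genes=50,
            cluster_spec=(("early_up", 2.0, 10), ("flat", 0.0, 40)),
            sigma_c=0.0,
            sigma_t=0.0,
            sigma_r=0.2,
            seed=31,
        )
        tc, truth = synth.gen_expression(cfg)
        res = expression.timecourse_de(tc)
        planted = [g for g, k in zip(tc.transcripts, truth.cluster_labels) if k == 0]
        assert (res.table.loc[planted, "q"] < 0.05).all()

    def test_type_one_error_near_nominal_under_null(self):
        cfg = synth.SynthConfig(
            n_genes=300,
            cluster_spec=(("flat", 0.0, 300),),
            sigma_c=0.0,
            sigma_t=0.0,
            sigma_r=0.3,
            seed=32,
        )
        tc, _ = synth.gen_expression(cfg)
        res = expression.timecourse_de(tc)
        from scipy import stats

        rate = (res.table["p"] < 0.05).mean()
        lo, hi = stats.binom.interval(0.99, 300, 0.05)
        assert lo / 300 <= rate <= hi / 300

    def test_global_constant_shift_does_not_create_de(self):
        cfg = synth.SynthConfig(
            n_genes=50, cluster_spec=(("flat", 0.0, 50),), sigma_c=0.0,
            sigma_t=0.0, sigma_r=0.2, seed=33,
        )
        tc, _ = synth.gen_expression(cfg)
        base = expression.timecourse_de(tc)
        shifted = expression.TimecourseMatrix(m=tc.m + 5.0)
        res = expression.timecourse_de(shifted)
        assert np.allclose(res.table["F"], base.table["F"])

    def test_spline_df_must_be_less_than_timepoints(self):
        times = [0, 10, 20, 30]
        cols = pd.MultiIndex.from_product([times, [0]], names=["time", "rep"])
        m = pd.DataFrame(np.zeros((2, 4)), columns=cols)
        with pytest.raises(ValueError):
            expression.timecourse_de(expression.TimecourseMatrix(m=m), spline_df=4)

    def test_missing_cells_handled_per_transcript(self):
        cfg = synth.SynthConfig(
            n_genes=20, cluster_spec=(("early_up", 2.0, 20),), seed=34
        )
        tc, _ = synth.gen_expression(cfg)
        tc.m.iloc[0, 3] = np.nan
        res = expression.timecourse_de(tc)
        assert res.table["p"].notna().all()
        assert res.table.loc[tc.transcripts[0], "n_obs"] == tc.m.shape[1] - 1

    def test_ranks_are_a_permutation(self, small_config):
        tc, _ = synth.gen_expression(small_config)
        res = expression.timecourse_de(tc)
        assert sorted(res.table["rank"]) == list(range(1, len(res.table) + 1))


@given(
    p=st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=20)
)
def test_bh_qvalues_match_brute_force(p):
    """q_i = min over j>=i of p_(j) * n / j, clipped at 1."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p)
    q = multipletests(p, method="fdr_bh")[1]
    n = len(p)
    order = np.argsort(p, kind="stable")
    brute = np.empty(n)
    for rank_pos, idx in enumerate(order):
        candidates = [
            min(p[order[j]] * n / (j + 1), 1.0) for j in range(rank_pos, n)
        ]
        brute[idx] = min(candidates)
    assert np.allclose(q, brute, atol=1e-12)


class TestLogC0:
    def test_single_replicate(self):
        raw = pd.DataFrame([_raw_row("t1", 0, 0, 500, 1024)])
        assert expression.compute_logC0(raw)["t1"] == pytest.approx(10.0)

    def test_mean_of_two_replicates(self):
        raw = pd.DataFrame(
            [_raw_row("t1", 0, 0, 500, 512), _raw_row("t1", 0, 1, 500, 2048)]
        )
        assert expression.compute_logC0(raw)["t1"] == pytest.approx(10.0)

    def test_seeded_random_matches_direct_recomputation(self, rng):
        rows = [
            _raw_row(f"t{i}", 0, r, 100, rng.uniform(100, 1e5))
            for i in range(10)
            for r in range(4)
        ]
        raw = pd.DataFrame(rows)
        lc = expression.compute_logC0(raw)
        for i in range(10):
            vals = [np.log2(r["ch_reference"]) for r in rows if r["transcript"] == f"t{i}"]
            assert lc[f"t{i}"] == pytest.approx(np.mean(vals))

    def test_missing_at_t0_excluded(self):
        raw = pd.DataFrame([_raw_row("t1", 0, 0, 500, 1024), _raw_row("t2", 10, 0, 500, 1024)])
        lc = expression.compute_logC0(raw)
        assert "t2" not in lc.index
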