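"""DP mixture: prior closed form, planted-truth recovery, label alignment."""

import numpy as np
import pandas as pd
import pytest

from notchpulse import cluster, synth


class TestPriorExpectedK:
    def test_single_customer(self):
        assert cluster.prior_expected_K(1.0, 1) == pytest.approx(1.0)

    def test_closed_form_small_n(self):
        assert cluster.prior_expected_K(1.0, 3) == pytest.approx(1 + 0.5 + 1 / 3)

    def test_matches_monte_carlo_crp(self, rng):
        n, alpha, n_draws = 100, 1.0, 10_000
        ks = np.array(
            [len(np.unique(cluster.sample_crp_partition(alpha, n, rng))) for _ in range(n_draws)]
        )
        expected = cluster.prior_expected_K(alpha, n)
        se = ks.std(ddof=1) / np.sqrt(n_draws)
        assert abs(ks.mean() - expected) < 3 * se

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            cluster.prior_expected_K(0.0, 10)
        with pytest.raises(ValueError):
            cluster.prior_expected_K(1.0, 0)


class TestFitDP:
    def test_single_transcript_always_one_cluster(self):
        profs = cluster.ProfileSet(
            ids=["t1"], times=np.arange(5.0), y=np.zeros((1, 5, 2))
        )
        samples = cluster.fit_dp(profs, n_sweeps=120, burn_in=20, seed=1)
        assert all(s.n_clusters == 1 for s in samples)

    def test_planted_three_clusters_recovered(self, small_config):
        tc, truth = synth.gen_expression(small_config)
        profs = cluster.ProfileSet.from_timecourse(tc)
        samples = cluster.fit_dp(profs, n_sweeps=600, burn_in=200, seed=2)
        summ = cluster.summarize_clusters(samples, ids=profs.ids)
        assert summ.modal_K == 3
        assert cluster.adjusted_rand_index(summ.map_partition, truth.cluster_labels) == 1.0

    def test_chain_agreement_between_seeds(self, small_config):
        tc, _ = synth.gen_expression(small_config)
        profs = cluster.ProfileSet.from_timecourse(tc)
        cocl = []
        for seed in (3, 4):
            samples = cluster.fit_dp(profs, n_sweeps=400, burn_in=150, seed=seed)
            cocl.append(cluster.coclustering_matrix(samples))
        assert np.abs(cocl[0] - cocl[1]).max() <= 0.05

    def test_deterministic_given_seed(self, small_config):
        tc, _ = synth.gen_expression(small_config)
        profs = cluster.ProfileSet.from_timecourse(tc)
        s1 = cluster.fit_dp(profs, n_sweeps=150, burn_in=50, seed=5)
        s2 = cluster.fit_dp(profs, n_sweeps=150, burn_in=50, seed=5)
        assert all(np.array_equal(a.z, b.z) for a, b in zip(s1, s2))

    def test_prior_only_matches_crp_expectation(self):
        profs = cluster.ProfileSet(
            ids=[f"t{i}" for i in range(40)],
            times=np.arange(4.0),
            y=np.zeros((40, 4, 2)),
        )
        samples = cluster.fit_dp(
            profs, n_sweeps=1500, burn_in=300, seed=6, prior_only=True
        )
        ks = np.array([s.n_clusters for s in samples])
        expected = cluster.prior_expected_K(1.0, 40)
        # thinned SE to respect autocorrelation of the Gibbs chain
        se = ks[::10].std(ddof=1) / np.sqrt(len(ks[::10]))
        assert abs(ks.mean() - expected) < 3 * se

    def test_recovered_means_within_2se_of_planted(self, small_config):
        tc, truth = synth.gen_expression(small_config)
        profs = cluster.ProfileSet.from_timecourse(tc)
        samples = cluster.fit_dp(profs, n_sweeps=600, burn_in=200, seed=7)
        summ = cluster.summarize_clusters(samples, ids=profs.ids)
        # match recovered clusters to planted ones via member majority
        for k_true in range(3):
            members = np.flatnonzero(truth.cluster_labels == k_true)
            k_rec = pd.Series(summ.partition[members]).mode()[0]
            rec = summ.mean_profiles[k_rec]
            # SE of a cluster mean curve: sigma_c dominates at 20 members
            cfg = small_config
            se = np.sqrt(
                cfg.sigma_c**2 / 20 + cfg.sigma_t**2 / 20 + cfg.sigma_r**2 / (20 * 4)
            )
            assert np.abs(rec - truth.cluster_profiles[k_true]).max() < 2.5 * se

    def test_rejects_bad_sweep_counts(self, small_config):
        tc, _ = synth.gen_expression(small_config)
        profs = cluster.ProfileSet.from_timecourse(tc)
        with pytest.raises(ValueError):
            cluster.fit_dp(profs, n_sweeps=10, burn_in=10)


class TestSummarize:
    def _state(self, z, K=None):
        z = np.asarray(z)
        K = K or z.max() + 1
        return cluster.DPState(
            z=z, means=np.zeros((K, 3)), sigma_c=0.1, sigma_t=0.1,
            sigma_r=0.1, alpha=1.0, iteration=0, log_posterior=0.0,
        )

    def test_identical_samples_give_certain_primary(self):
        samples = [self._state([0, 0, 1]) for _ in range(10)]
        summ = cluster.summarize_clusters(samples)
        assert (summ.assignments["p_primary"] == 1.0).all()
        assert (summ.assignments["p_secondary"] == 0.0).all()

    def test_alternating_allocation_ties_break_low(self):
        # transcript 2 alternates between cluster 0 and cluster 1
        samples = [self._state([0, 1, i % 2], K=2) for i in range(10)]
        summ = cluster.summarize_clusters(samples)
        row = summ.assignments.iloc[2]
        assert row["p_primary"] == pytest.approx(0.5)
        assert row["p_secondary"] == pytest.approx(0.5)
        assert row["primary"] < row["secondary"]

    def test_coclustering_symmetric_unit_diagonal(self, small_config):
        tc, _ = synth.gen_expression(small_config)
        profs = cluster.ProfileSet.from_timecourse(tc)
        samples = cluster.fit_dp(profs, n_sweeps=200, burn_in=100, seed=8)
        C = cluster.coclustering_matrix(samples)
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)

    def test_primary_probability_dominates_secondary(self, small_config):
        tc, _ = synth.gen_expression(small_config)
        profs = cluster.ProfileSet.from_timecourse(tc)
        samples = cluster.fit_dp(profs, n_sweeps=200, burn_in=100, seed=9)
        summ = cluster.summarize_clusters(samples, ids=profs.ids)
        assert (summ.assignments["p_primary"] >= summ.assignments["p_secondary"]).all()


def test_adjusted_rand_index_against_sklearn(rng):
    from sklearn.metrics import adjusted_rand_score

    for _ in range(20):
        a = rng.integers(0, 4, size=30)
        b = rng.integers(0, 3, size=30)
        assert cluster.adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_score(a, b)
        )


def test_exchangeability_coclustering_invariant_under_permutation(small_config):
    """On well-separated data the co-clustering structure follows a
    permutation of the transcripts up to Monte-Carlo noise."""
    tc, _ = synth.gen_expression(small_config)
    profs = cluster.ProfileSet.from_timecourse(tc)
    perm = np.random.default_rng(0).permutation(len(profs.ids))
    profs_perm = cluster.ProfileSet(
        ids=[profs.ids[i] for i in perm], times=profs.times, y=profs.y[perm]
    )
    C1 = cluster.coclustering_matrix(
        cluster.fit_dp(profs, n_sweeps=400, burn_in=150, seed=10)
    )
    C2 = cluster.coclustering_matrix(
        cluster.fit_dp(profs_perm, n_sweeps=400, burn_in=150, seed=11)
    )
    assert np.abs(C1[np.ix_(perm, perm)] - C2).max() <= 0.05
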