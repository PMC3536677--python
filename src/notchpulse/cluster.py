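"""Dirichlet-process Gaussian-mixture clustering of timecourse profiles.

Replicated expression profiles are grouped with a Dirichlet-process mixture
so that the number of temporal response classes is estimated from the data
rather than fixed in advance.  The likelihood mirrors the generative model of
the synthetic data: for gene g in cluster k,

    M(g, t, r) = mu_k(t) + c_g + d_{g,t} + e_{g,t,r}

with c_g ~ N(0, sigma_c^2) a gene-level amplitude offset shared across the
whole profile, d_{g,t} ~ N(0, sigma_t^2) a time-specific deviation shared by
replicates, and e ~ N(0, sigma_r^2) replicate noise.  These three components
are the model's concrete reading of between-gene differences in response
amplitude, in temporal profile, and in expression noise.

Inference is MCMC: Chinese-restaurant-process Gibbs updates of allocations
with auxiliary-component proposals, conjugate normal updates of the cluster
mean curves, and random-walk Metropolis on the log variance components.
Posterior samples are summarised through the pairwise co-clustering matrix,
with label alignment against a least-squares reference partition so that
per-gene allocation probabilities survive label switching.

The exchangeable-partition structure implies a closed-form prior expectation
for the number of occupied clusters, E[K] = sum_{i=0}^{n-1} alpha/(alpha+i),
used as a prior sanity check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

logger = logging.getLogger(__name__)

LOG2PI = math.log(2 * math.pi)

_DEFAULT_PRIORS = {
    "tau": 2.0,          # prior sd of cluster mean per timepoint (log2 units)
    "alpha": 1.0,        # DP concentration
    "resample_alpha": False,
    "alpha_gamma": (1.0, 1.0),   # Gamma(shape, rate) when resampling alpha
    "log_sigma_bounds": (math.log(1e-3), math.log(10.0)),
    "proposal_sd": 0.15,  # random-walk sd on log sigma
}


@dataclass
class ProfileSet:
    """Replicate-resolved profiles on a shared timepoint grid.

    ``y`` has shape (n_transcripts, n_times, n_reps); rows with missing
    values are not allowed (filter upstream).  A median-collapsed set has
    n_reps == 1.
    """

    ids: list[str]
    times: np.ndarray
    y: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.y.ndim != 3:
            raise ValueError("y must be (n, T, R)")
        if np.isnan(self.y).any():
            raise ValueError("profiles contain missing values; drop incomplete rows first")
        if self.y.shape[1] != len(self.times):
            raise ValueError("time axis mismatch")

    @classmethod
    def from_timecourse(cls, tc, transcripts=None, collapse: str = "none") -> "ProfileSet":
        """Build from a TimecourseMatrix, keeping complete profiles only.

        ``collapse='median'`` reduces replicates to their per-timepoint
        median (then sigma_r and sigma_t are no longer separately
        identifiable, which is acceptable for summary-level input).
        """
        y = tc.profile_array()
        ids = list(tc.transcripts)
        if transcripts is not None:
            keep = [i for i, t in enumerate(ids) if t in set(transcripts)]
            y, ids = y[keep], [ids[i] for i in keep]
        if collapse == "median":
            y = np.nanmedian(y, axis=2, keepdims=True)
        ok = ~np.isnan(y).any(axis=(1, 2))
        return cls(ids=[t for t, k in zip(ids, ok) if k], times=tc.times, y=y[ok])


@dataclass
class DPState:
    """One posterior sample: allocations, mean curves, variance components."""

    z: np.ndarray
    means: np.ndarray = field(repr=False)  # (K_occ, T), row i is cluster i
    sigma_c: float
    sigma_t: float
    sigma_r: float
    alpha: float
    iteration: int
    log_posterior: float = np.nan

    @property
    def n_clusters(self) -> int:
        return self.means.shape[0]


def prior_expected_K(alpha: float, n: int) -> float:
    """Prior mean number of occupied clusters under the DP: sum alpha/(alpha+i)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    return float(np.sum(alpha / (alpha + i)))


def sample_crp_partition(alpha: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """One draw from the Chinese-restaurant-process partition prior."""
    z = np.zeros(n, dtype=int)
    counts = [1]
    for i in range(1, n):
        probs = np.array(counts + [alpha], dtype=float)
        probs /= probs.sum()
        k = rng.choice(len(probs), p=probs)
        if k == len(counts):
            counts.append(1)
        else:
            counts[k] += 1
        z[i] = k
    return z


class _Likelihood:
    """Sufficient-statistics evaluator for the three-component Gaussian model."""

    def __init__(self, y: np.ndarray):
        n, T, R = y.shape
        self.n, self.T, self.R = n, T, R
        self.ybar = y.mean(axis=2)                      # (n, T)
        self.ss_within = ((y - self.ybar[:, :, None]) ** 2).sum(axis=(1, 2))  # (n,)

    def lambdas(self, sc: float, st: float, sr: float) -> tuple[float, float, float]:
        l3 = sr ** 2
        l2 = sr ** 2 + self.R * st ** 2
        l1 = l2 + self.T * self.R * sc ** 2
        return l1, l2, l3

    def loglik_candidates(self, g: int, means: np.ndarray, l1: float, l2: float) -> np.ndarray:
        """Candidate-dependent part of the log-likelihood of gene g under each
        row of ``means`` (terms constant across candidates are omitted)."""
        r = self.ybar[g][None, :] - means          # (K, T)
        m = r.mean(axis=1)
        ssc = ((r - m[:, None]) ** 2).sum(axis=1)
        return -0.5 * (self.R * ssc / l2 + self.T * self.R * m ** 2 / l1)

    def log_marginal_new(self, g: int, l1: float, l2: float, tau: float) -> float:
        """Log-likelihood of gene g in a fresh cluster with the mean curve
        integrated out against its N(0, tau^2 I) prior, relative to the same
        constant terms omitted in :meth:`loglik_candidates`."""
        T, R = self.T, self.R
        v2 = l2 / R + tau ** 2      # contrast directions
        v1 = l1 / R + tau ** 2      # global-mean direction
        r = self.ybar[g]
        m = r.mean()
        ssc = ((r - m) ** 2).sum()
        ll = -0.5 * ((T - 1) * math.log(v2) + math.log(v1) + ssc / v2 + T * m ** 2 / v1)
        # remove the logdet terms that loglik_candidates leaves implicit
        ll -= -0.5 * ((T - 1) * math.log(l2 / R) + math.log(l1 / R))
        return ll

    def posterior_mean_draw(
        self,
        members: np.ndarray,
        nk: int,
        l1: float,
        l2: float,
        tau: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Conjugate draw of a cluster mean curve given its members."""
        T, R = self.T, self.R
        v = self.ybar[members].mean(axis=0) if members.ndim else self.ybar[members]
        a1 = nk * R / l1 + 1.0 / tau ** 2
        a2 = nk * R / l2 + 1.0 / tau ** 2
        vm = v.mean()
        post_mean = (nk * R / l1 / a1) * vm + (nk * R / l2 / a2) * (v - vm)
        eps = rng.normal(size=T)
        em = eps.mean()
        return post_mean + em / math.sqrt(a1) + (eps - em) / math.sqrt(a2)

    def total_loglik(self, mu_assigned: np.ndarray, sc: float, st: float, sr: float) -> float:
        """Full data log-likelihood given per-gene assigned mean curves."""
        l1, l2, l3 = self.lambdas(sc, st, sr)
        r = self.ybar - mu_assigned
        m = r.mean(axis=1)
        ssc = ((r - m[:, None]) ** 2).sum(axis=1)
        T, R, n = self.T, self.R, self.n
        const = -0.5 * n * (
            T * R * LOG2PI
            + T * (R - 1) * math.log(l3)
            + (T - 1) * math.log(l2)
            + math.log(l1)
        )
        quad = -0.5 * (
            self.ss_within.sum() / l3
            + R * ssc.sum() / l2
            + T * R * (m ** 2).sum() / l1
        )
        return const + quad


def _crp_log_prior(z: np.ndarray, alpha: float) -> float:
    _, counts = np.unique(z, return_counts=True)
    return (
        len(counts) * math.log(alpha)
        + float(np.sum(gammaln(counts)))
        + float(gammaln(alpha) - gammaln(alpha + len(z)))
    )


def fit_dp(
    profiles: ProfileSet,
    priors: dict | None = None,
    n_sweeps: int = 2000,
    burn_in: int = 500,
    seed: int = 0,
    prior_only: bool = False,
) -> list[DPState]:
    """Run the DP mixture sampler and return post-burn-in samples.

    Allocations are Gibbs-updated with the mean curve of a prospective new
    cluster integrated out against its conjugate normal prior, so opening a
    cluster does not depend on a lucky prior draw; a chosen new cluster's
    mean is then drawn from its single-member posterior.  ``prior_only=True``
    disables the likelihood so the chain targets the bare CRP partition
    prior (used for prior sanity checks).  Deterministic given the seed.
    """
    if n_sweeps <= burn_in:
        raise ValueError("n_sweeps must exceed burn_in")
    if profiles.y.shape[0] == 0:
        raise ValueError("empty profile set")
    pr = dict(_DEFAULT_PRIORS, **(priors or {}))
    rng = np.random.default_rng(seed)
    lik = _Likelihood(profiles.y)
    n, T, R = lik.n, lik.T, lik.R
    tau = float(pr["tau"])
    alpha = float(pr["alpha"])
    lo_ls, hi_ls = pr["log_sigma_bounds"]

    # init: one cluster; variance components from crude moment estimates
    z = np.zeros(n, dtype=int)
    means = lik.ybar.mean(axis=0, keepdims=True).copy()
    if R > 1:
        sr = math.sqrt(max(lik.ss_within.mean() / (T * (R - 1)), 1e-4))
    else:
        sr = 0.3
    sc, st = 0.3, 0.1
    n_divergent = 0
    n_var_proposals = 0

    samples: list[DPState] = []
    counts = np.array([n], dtype=int)

    for sweep in range(n_sweeps):
        l1, l2, _ = lik.lambdas(sc, st, sr)
        # --- allocation sweep (CRP Gibbs, new-cluster mean integrated out) ---
        for g in range(n):
            k_old = z[g]
            counts[k_old] -= 1
            if counts[k_old] == 0:
                keep = np.flatnonzero(counts)
                remap = -np.ones(len(counts), dtype=int)
                remap[keep] = np.arange(len(keep))
                z = remap[z]
                means = means[keep]
                counts = counts[keep]
            K = len(counts)
            logw = np.empty(K + 1)
            logw[:K] = np.log(counts)
            logw[K] = math.log(alpha)
            if not prior_only:
                logw[:K] += lik.loglik_candidates(g, means, l1, l2)
                logw[K] += lik.log_marginal_new(g, l1, l2, tau)
            logw -= logw.max()
            w = np.exp(logw)
            k_new = rng.choice(K + 1, p=w / w.sum())
            if k_new == K:
                mu_new = lik.posterior_mean_draw(np.array([g]), 1, l1, l2, tau, rng)
                means = np.vstack([means, mu_new[None, :]])
                counts = np.append(counts, 1)
                z[g] = K
            else:
                counts[k_new] += 1
                z[g] = k_new

        # --- cluster mean updates (conjugate, in the projection eigenbasis) ---
        if not prior_only:
            for k in range(len(counts)):
                members = np.flatnonzero(z == k)
                means[k] = lik.posterior_mean_draw(
                    members, int(counts[k]), l1, l2, tau, rng
                )

            # --- variance components: random-walk Metropolis on log scale ---
            mu_assigned = means[z]
            cur_ll = lik.total_loglik(mu_assigned, sc, st, sr)
            for which in range(3):
                n_var_proposals += 1
                cur = [sc, st, sr][which]
                prop = math.exp(math.log(cur) + rng.normal(0, pr["proposal_sd"]))
                if not (lo_ls <= math.log(prop) <= hi_ls) or not math.isfinite(prop):
                    n_divergent += 1
                    continue
                trial = [sc, st, sr]
                trial[which] = prop
                new_ll = lik.total_loglik(mu_assigned, *trial)
                if not math.isfinite(new_ll):
                    n_divergent += 1
                    continue
                # flat prior on log sigma within bounds; proposal symmetric on log scale
                if math.log(rng.uniform()) < new_ll - cur_ll:
                    sc, st, sr = trial
                    cur_ll = new_ll

        if pr["resample_alpha"]:
            alpha = _resample_alpha(alpha, n, len(counts), pr["alpha_gamma"], rng)

        if sweep >= burn_in:
            lp = _crp_log_prior(z, alpha)
            if not prior_only:
                lp += lik.total_loglik(means[z], sc, st, sr)
            samples.append(
                DPState(
                    z=z.copy(),
                    means=means.copy(),
                    sigma_c=sc,
                    sigma_t=st,
                    sigma_r=sr,
                    alpha=alpha,
                    iteration=sweep,
                    log_posterior=lp,
                )
            )

    if n_var_proposals and n_divergent / n_var_proposals > 0.5:
        logger.warning(
            "variance sampler rejected %.0f%% of proposals at the bounds",
            100 * n_divergent / n_var_proposals,
        )
    return samples


def _resample_alpha(alpha, n, k, gamma_prior, rng):
    """Escobar-West auxiliary-variable update for the DP concentration."""
    a, b = gamma_prior
    eta = rng.beta(alpha + 1, n)
    odds = (a + k - 1) / (n * (b - math.log(eta)))
    pi = odds / (1 + odds)
    shape = a + k if rng.uniform() < pi else a + k - 1
    return rng.gamma(shape, 1.0 / (b - math.log(eta)))


@dataclass
class ClusterSummary:
    """Posterior clustering summary with label-aligned allocation probabilities."""

    modal_K: int
    partition: np.ndarray            # least-squares point-estimate partition
    map_partition: np.ndarray        # partition of the max-posterior sample
    assignments: pd.DataFrame        # primary/secondary clusters + probabilities
    mean_profiles: dict[int, np.ndarray]
    coclustering: np.ndarray = field(repr=False)
    times: np.ndarray | None = None


def coclustering_matrix(samples: list[DPState]) -> np.ndarray:
    zs = np.stack([s.z for s in samples])
    n = zs.shape[1]
    C = np.zeros((n, n))
    for z in zs:
        C += z[:, None] == z[None, :]
    return C / len(samples)


def _align_labels(z: np.ndarray, ref: np.ndarray, n_ref: int) -> np.ndarray:
    """Relabel sample partition z to best match the reference labels."""
    ks = np.unique(z)
    cont = np.zeros((len(ks), n_ref))
    for i, k in enumerate(ks):
        members = z == k
        for r in range(n_ref):
            cont[i, r] = np.sum(members & (ref == r))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {}
    next_label = n_ref
    for i, k in enumerate(ks):
        j = np.flatnonzero(rows == i)
        if len(j) and cont[i, cols[j[0]]] > 0:
            mapping[k] = int(cols[j[0]])
        else:
            mapping[k] = next_label
            next_label += 1
    return np.array([mapping[k] for k in z])


def summarize_clusters(samples: list[DPState], ids: list[str] | None = None,
                       times: np.ndarray | None = None) -> ClusterSummary:
    """Relabel posterior samples and report allocation probabilities.

    The reference partition minimises the squared distance between its
    co-clustering indicator and the posterior co-clustering matrix (the
    least-squares criterion); each sample is then aligned to it by maximum
    label overlap, so per-gene allocation probabilities are immune to label
    switching.  Ties between equally probable clusters break toward the
    lower cluster index.
    """
    if len(samples) < 1:
        raise ValueError("no samples to summarise")
    C = coclustering_matrix(samples)
    n = C.shape[0]
    # Dahl's least-squares sample: argmin ||B_s - C||^2 = argmin sum B(1-2C)
    scores = []
    for s in samples:
        B = s.z[:, None] == s.z[None, :]
        scores.append(np.sum(B * (1 - 2 * C)))
    ref_state = samples[int(np.argmin(scores))]
    # canonicalise reference labels by order of first appearance
    ref = _canonical(ref_state.z)
    n_ref = ref.max() + 1

    K_counts = [len(np.unique(s.z)) for s in samples]
    modal_K = int(np.bincount(K_counts).argmax())

    max_label = n_ref
    aligned = []
    for s in samples:
        az = _align_labels(s.z, ref, n_ref)
        max_label = max(max_label, az.max() + 1)
        aligned.append(az)

    P = np.zeros((n, max_label))
    for az in aligned:
        P[np.arange(n), az] += 1
    P /= len(samples)

    order = np.argsort(-P, axis=1, kind="stable")  # stable: ties -> lower index
    primary = order[:, 0]
    secondary = order[:, 1] if max_label > 1 else np.full(n, -1)
    p_primary = P[np.arange(n), primary]
    p_secondary = P[np.arange(n), secondary] if max_label > 1 else np.zeros(n)

    profiles: dict[int, list[np.ndarray]] = {}
    for s, az in zip(samples, aligned):
        for k_orig in np.unique(s.z):
            k_new = az[np.flatnonzero(s.z == k_orig)[0]]
            profiles.setdefault(int(k_new), []).append(s.means[k_orig])
    mean_profiles = {k: np.mean(v, axis=0) for k, v in sorted(profiles.items())}

    idx = ids if ids is not None else list(range(n))
    assignments = pd.DataFrame(
        {
            "primary": primary,
            "p_primary": p_primary,
            "secondary": secondary,
            "p_secondary": p_secondary,
        },
        index=idx,
    )
    map_state = max(samples, key=lambda s: s.log_posterior)
    return ClusterSummary(
        modal_K=modal_K,
        partition=ref,
        map_partition=_canonical(map_state.z),
        assignments=assignments,
        mean_profiles=mean_profiles,
        coclustering=C,
        times=times,
    )


def _canonical(z: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (0, 1, 2, ...)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(z)
    for i, k in enumerate(z):
        if k not in mapping:
            mapping[k] = len(mapping)
        out[i] = mapping[k]
    return out


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two partitions."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    n = len(a)
    ka, kb = np.unique(a, return_inverse=True)[1], np.unique(b, return_inverse=True)[1]
    cont = np.zeros((ka.max() + 1, kb.max() + 1))
    np.add.at(cont, (ka, kb), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
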