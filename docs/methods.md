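# Methods

This note documents the models, algorithms and numerical choices behind
`notchpulse`, and what its synthetic-data tests do and do not demonstrate
about real data.

## The study design being emulated

The package analyses the transcriptional and chromatin response to a short
pulse of Notch pathway activation in *Drosophila* cells.  The design it
assumes throughout: a two-colour common-reference expression timecourse (18
timepoints spanning 0–150 min, 4 biological replicates), and tiling-array
ChIP tracks for Su(H) (the CSL DNA-binding partner of the Notch
intracellular domain) and total RNA Pol II at 7 timepoints (0, 10, 20, 30,
40, 60, 100 min; 3 replicates; 50 bp probe spacing).  None of the real
arrays ship with the package; the synthetic generator produces inputs with
the same structure and known ground truth, and every quantitative claim the
test suite makes is about recovery of that planted truth.

## Expression model and differential expression

Raw spots are transformed to M = log2(treated/reference) and
A = (log2 treated + log2 reference)/2.  Within each array, M is centred by a
local regression of M on A (lowess, default span 0.4) followed by median
subtraction, so the post-normalization median M per array is 0 to within
1e-6.  Arrays with constant A fall back to plain median centring.  Print-tip
effects and dye swaps are out of scope.

Timecourse DE is a natural-cubic-spline regression F-test: for each
transcript, all replicate M values are regressed on a spline basis in time
(default 4 df, knots at quantiles of the timepoint grid) against an
intercept-only null.  p-values come from the F reference distribution, with
an optional permutation null (time labels shuffled within replicate; off by
default for speed, seed mandatory when on).  q-values are
Benjamini–Hochberg.  This is an explicit, documented equivalent of
spline-based timecourse DE software; no attempt is made to clone any
specific tool's internals, and the tests are calibration-based (type-I error
inside the exact binomial band under the null; full power on planted
amplitude-2 responses).

logC0, the basal absolute-expression proxy, is the mean over replicates of
log2 reference-channel intensity at t = 0.

## Dirichlet-process clustering

Profiles of DE transcripts are clustered with a DP Gaussian mixture whose
likelihood matches the generator's three-component decomposition:

    M(g,t,r) = mu_k(t) + c_g + d_{g,t} + e_{g,t,r}

with c_g ~ N(0, sigma_c^2) (amplitude offsets within a cluster),
d_{g,t} ~ N(0, sigma_t^2) (temporal deviations shared across replicates) and
e ~ N(0, sigma_r^2) (replicate noise).  These are the package's concrete
reading of the three variability sources such clustering must tolerate —
amplitude, temporal profile, and noise.  Because the covariance is
exchangeable within gene and timepoint, the per-gene likelihood factorises
over three orthogonal projections (within-timepoint contrasts, timepoint
contrasts of the replicate means, and the global mean), with eigenvalues
sigma_r^2, sigma_r^2 + R sigma_t^2, and
sigma_r^2 + R sigma_t^2 + T R sigma_c^2.  All sampler algebra runs in this
basis; no T*R covariance matrix is ever formed.

Inference is MCMC: per-gene CRP Gibbs allocation updates; conjugate normal
updates of cluster mean curves (prior N(0, tau^2 I), tau = 2 log2 units, a
weak prior wide enough for any plausible response amplitude); and
random-walk Metropolis on log sigma (proposal sd 0.15, flat prior on log
sigma within [log 1e-3, log 10]; out-of-bounds proposals are rejected and
counted, with a warning above a 50% rejection rate).  The concentration
alpha is fixed at 1 by default, with optional Escobar–West Gamma(1,1)
resampling.

A design point worth recording: the new-cluster weight in the allocation
update uses the *marginal* likelihood of the gene with the prospective mean
curve integrated out against its conjugate prior; a newly opened cluster's
mean is then drawn from its single-member posterior.  The more common
auxiliary-component scheme (proposing new clusters from prior draws of the
mean) is ineffective here: a random draw of an 18-dimensional curve from
N(0, tau^2 I) essentially never resembles any actual profile, so the chain
cannot open clusters.  With conjugacy available, the partially collapsed
update is both valid and far better mixing; default 2000 sweeps with 500
burn-in are sized for n <= 1000 transcripts (the pipeline default uses
800/200 at its 500-gene demo scale).

Label switching is handled at summary time: the reference partition is the
posterior sample minimising the least-squares distance between its
co-clustering indicator and the posterior co-clustering matrix; every sample
is then aligned to the reference by maximum-overlap assignment (Hungarian
algorithm), and per-transcript allocation probabilities are computed from
the aligned samples.  Primary and secondary clusters are the top two
probabilities, ties breaking toward the lower cluster index.  The reported
cluster count K is the modal number of occupied clusters across samples.
The point-estimate partition reported alongside is the maximum-log-posterior
sample.  We report allocation probabilities as such rather than calling
them p-values.

The prior is sanity-checked by running the sampler with the likelihood
disabled, whose occupied-cluster count must match the closed form
E[K] = sum_{i=0}^{n-1} alpha/(alpha+i).

## Peak calling and peak areas

A peak is a maximal run of at least `min_run` consecutive probes (replicates
averaged per probe; a min-over-replicates mode exists for stringency) with
enrichment at or above a log2 `threshold`; runs separated by at most
`merge_gap` sub-threshold probes are merged, and a merged run qualifies if
it contains at least one qualifying consecutive stretch.  Defaults
(threshold 1.0, min_run 4, merge_gap 2) suit 50 bp probe spacing and are
config-exposed rather than hard-coded, since they are tuning parameters of
the method, not constants of nature.  Peak boundaries extend half a probe
spacing beyond the outermost enriched probes.  Area is the rectangle rule
over probes with negative values floored at zero.

One caveat discovered while property-testing: with any run-based caller,
raising the threshold can *split* one merged peak into several, so the peak
*count* is not monotone in threshold (covered bases are); the count is
monotone in min_run.

## Pol II state classification

Each transcript at each ChIP timepoint is classified as UB (unbound), P
(poised: 5' binding only), AP (active poised: 5' peak plus body binding) or
AU (active uniform).  Promoter and body binding are decided by the peak
caller's threshold/run rule restricted to each region.  The promoter window
is TSS +/- 500 bp (strand-aware; about 10 probes at default spacing); the
body runs from the promoter-window edge to the 3' end.  The AP/AU split
uses the pausing ratio

    max(log2 enrichment in promoter window) / max(median(log2 body), floor)

with cutoff 2.  Two choices are deliberate and prominent: the ratio is taken
on the log2 values as they appear on the tracks, not on linear fold changes;
and the body median is floored at 0.25 to keep the ratio finite on unbound
bodies.  The median is over the body only (excluding the promoter window) —
a flag switches to whole-transcript if wanted.  Gene-level state aggregates
transcript states by the precedence AU > AP > P > UB (most active wins).

## Peak–gene association and the DE-odds model

Distances between half-open intervals follow the end-gap convention: 0 on
overlap, otherwise the number of intervening bases (so [100,200) to
[210,260) is 10).  A gene's Su(H) count at a timepoint is the number of
peaks within 10 kb of any of its transcripts (boundary inclusive); a
nearest-2 mode assigns each peak to its two nearest genes irrespective of
distance, ties toward the leftmost gene start.

The logistic model regresses the per-gene DE indicator (any transcript DE)
on binary Su(H) occupancy within 10 kb, Pol II class indicators (P, AP, AU;
UB baseline) and logC0 entered linearly.  Fitting is maximum likelihood
(IRLS); constant columns are dropped with a warning; complete separation is
detected and the fit falls back to an L2-penalised estimate so coefficients
stay finite, with the condition flagged.  Wald p-values are Holm-adjusted
across the non-intercept coefficients and flagged at adjusted p < 0.005.
Coefficients are log-odds effects; exp(beta) to 2 decimals gives the odds
multiplier (e.g. 2.78 -> 16.12).

logC0-by-class comparisons use one-way ANOVA plus all pairwise one-sided
Welch t-tests in the direction higher-activity class > lower (activity
order AU/AP > P > UB).  Regime comparison (e.g. 5 min vs 30 min activation)
reports the OLS slope and r^2 of one log2 fold-change vector on the other
and flags genes whose linear-scale response ratio 2^|delta| exceeds 2.

## Motif and SPS scanning

Weight matrices are log-odds in bits against a stated background, built from
position frequencies with pseudocount 0.5.  The default score threshold is
60% of the maximal matrix score — "high affinity" is qualitative, so the
cut is config-exposed.  Both strands are scanned; windows containing N are
skipped; reverse-strand hits are reported at their forward-axis window
start.  The shipped Su(H) (consensus CGTGGGAA) and Hairy (CACGCG) matrices
are synthetic stand-ins encoding the canonical consensus of each factor with
mild degeneracy; they are not the published alignment matrices.

SPS (Su(H) paired site) detection takes all pairs of opposite-strand matches
whose inter-site gap — end of the left site to start of the right site —
lies in [10, 22] inclusive.  The measuring convention matters and is easy to
get wrong silently; gap (not centre-to-centre) was chosen and is asserted at
the boundaries (9 and 23 must not match).  Both head-to-head and
tail-to-tail arrangements qualify.  Per-gene motif fractions are reported as
percentages rounded to the nearest integer (10/13 -> 77%).

## Synthetic data: what it does and does not emulate

The generator plants: cluster-structured expression (canonical temporal
shapes early_up / late_up / down / transient / flat, amplitudes in log2
units); two-channel intensities back-transformed from M with a lognormal
basal intensity per gene (giving a well-defined logC0); Pol II class
templates (P: promoter block at height 4; AP: promoter 4 + body 1.5, so the
planted pausing ratio 2.7 clears the cutoff with margin; AU: uniform 1.5;
UB: background only); Su(H) enhancer peaks whose height follows a pulse
maximal at 20–30 min and declining after; and exact-consensus motif/SPS
instances in an i.i.d. uniform background scrubbed of accidental consensus
windows (verified by post-scan), with planted sites kept separated so
round-trips are exact.

Noise magnitudes (sigma_c = 0.3, sigma_t = 0.05, sigma_r = 0.25,
sigma_bg = 0.1; log2 units) are package choices sized so planted structure
is recoverable but not trivially so; they are not estimates of any real
array's noise.  sigma_t is kept small relative to sigma_r because d_{g,t} is
shared across replicates and therefore *is* temporal signal to any
timecourse DE test; large values would make even flat genes genuinely
differentially expressed.  ChIP background is N(0, sigma_bg) clipped at
zero — clipped, not shifted, to mirror the non-negative log2 enrichment
display convention of the tracks.

Passing tests on these inputs therefore demonstrate algorithmic
correctness — recovery of structure the model family describes — not
robustness to the pathologies of real arrays (spatial artifacts, dye bias
beyond a constant offset, cross-hybridization, outlier spots, non-Gaussian
tails), none of which are simulated.

## Pipeline and reproducibility

The pipeline runs simulate → normalize → DE → cluster (DE transcripts only)
→ peaks → Pol II → integrate → motifs.  One global seed is split per stage
through `numpy.random.SeedSequence`, so a single integer reproduces the
whole run byte-for-byte; a manifest records the config, per-stage seeds and
SHA-256 hashes of every output.  Stage toggles leave downstream columns
empty rather than failing.  Desk-scale sizes used throughout the tests and
the demo: 500 genes end-to-end, 60 transcripts for clustering benchmarks,
1000 null transcripts for error-rate calibration, 5000 observations for
logistic recovery — sizes at which every documented check runs comfortably
on one CPU.

## Known limitations

- The DP likelihood assumes a shared timepoint grid and complete profiles;
  transcripts with missing cells are excluded from clustering (they remain
  in the DE table).
- Variance components are updated conditionally on instantiated means;
  for very small n the chain can mix slowly between near-equivalent
  (sigma_c, cluster-mean) explanations of amplitude offsets.
- The peak caller has no FDR concept and does no background subtraction
  beyond the supplied log2 ratios.
- The logistic model treats genes as independent; spatial correlation along
  the chromosome is ignored.
- `min_distance` assigns distance 0 to intervals that merely touch
  ([100,200) and [200,300)), a boundary case where "0 iff overlap" is
  formally violated; callers who care should test overlap explicitly.
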