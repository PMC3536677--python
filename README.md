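# notchpulse

Integrative analysis of the transcriptional response to a **short pulse of
Notch activation**, built as a tested Python library with a fully synthetic,
ground-truthed test bed.

A brief pulse of Notch signalling — release of the Notch intracellular
domain, which partners the CSL transcription factor Su(H) in the nucleus —
triggers a wave of target-gene activity in *Drosophila* cells.  Dissecting
that wave takes several analyses working together, and this package
implements each of them behind one consistent API:

- **Timecourse differential expression** — two-colour common-reference
  arrays (M/A transform, loess M-vs-A normalization) and a
  natural-cubic-spline regression F-test of M on time with
  Benjamini–Hochberg q-values; the basal-expression proxy logC0 from t = 0
  intensities.
- **Dirichlet-process clustering** of temporal response profiles: a
  Gaussian mixture with the likelihood M(g,t,r) = μ_k(t) + c_g + d_{g,t} +
  e_{g,t,r} (amplitude, temporal and replicate variance components) and a
  Chinese-restaurant-process prior, so the number of response classes K is
  estimated from the data.  MCMC with conjugate mean updates, co-clustering
  summaries immune to label switching, and the closed-form prior check
  E[K] = Σᵢ α/(α+i).
- **ChIP tiling-array peak calling**: runs of ≥ `min_run` consecutive
  probes above a log2 enrichment threshold, gap merging, summit and
  area-under-peak quantification over the ChIP timecourse.
- **Pol II state classification** per transcript and timepoint — UB
  (unbound), P (poised, 5′ only), AP (active poised) and AU (active
  uniform), split by the pausing ratio
  log2(max promoter)/log2(median body) ≥ 2, aggregated to genes by the
  precedence AU > AP > P > UB.
- **Peak–gene association and odds modelling**: minimum-distance peak
  counting within 10 kb, a Table-style master summary, and logistic
  regression of the DE indicator on Su(H) occupancy, Pol II class and
  logC0 (log-odds effects; e.g. β = 2.78 ⇒ odds ×16.12), with Holm-adjusted
  Wald tests.
- **Motif and SPS scanning**: log-odds PWM scanning of both strands and
  detection of Su(H) paired sites — two opposite-strand matches spaced by
  10–22 nt — plus per-gene motif counts and fractions.
- **A synthetic-data generator** that emulates the whole study design (18
  expression timepoints × 4 replicates; 7 ChIP timepoints × 3 replicates at
  50 bp probe spacing; a genome with gene models and planted motifs) with
  every planted feature recorded, so each analysis step can be scored
  against exact ground truth.

## A worked example

```python
from notchpulse import cluster, synth

cfg = synth.SynthConfig(
    n_genes=60,
    cluster_spec=(("early_up", 2.5, 20), ("down", -3.0, 20), ("flat", 0.0, 20)),
    seed=4,
)
tc, truth = synth.gen_expression(cfg)
profs = cluster.ProfileSet.from_timecourse(tc)
samples = cluster.fit_dp(profs, n_sweeps=2000, burn_in=500, seed=5)
summ = cluster.summarize_clusters(samples, ids=profs.ids)
print(summ.modal_K, cluster.adjusted_rand_index(summ.map_partition, truth.cluster_labels))
```

prints

```
3 1.0
```

— the sampler finds exactly the three planted response classes (posterior
modal K = 3) and its point-estimate partition agrees perfectly with the
planted labels (adjusted Rand index 1.0).  The `examples/` directory holds
one short narrative script per capability (DE, clustering, peaks + Pol II,
the DE-odds model, motif/SPS scanning, and the full pipeline), each printing
the numbers it computes and what they mean.

The full pipeline runs from one seed and is reproducible byte for byte:

```bash
notchpulse run-all --seed 1 --outdir run1      # or: python examples/06_full_pipeline.py
```

writes `master_table.tsv` (one row per transcript: DE rank/p/q, primary and
secondary cluster with allocation probabilities, Pol II state and Su(H)
peak count within 10 kb at each ChIP timepoint, logC0, median M per
timepoint), per-timepoint peak BED files, the logistic model report and a
manifest with the per-stage seeds and output hashes.

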