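"""Detect transcripts responding to the activation pulse.

Generates a small synthetic timecourse (20 early-responding genes among 80),
normalizes it, runs the spline F-test, and prints the detection summary.
"""

from notchpulse import expression, synth

cfg = synth.SynthConfig(
    n_genes=80,
    cluster_spec=(("early_up", 2.0, 20), ("flat", 0.0, 60)),
    seed=1,
)
tc, truth = synth.gen_expression(cfg)
raw = synth.gen_raw_intensities(cfg, tc)

tc = expression.compute_ma(raw)
tc = expression.normalize_within_array(tc)
res = expression.timecourse_de(tc)

called = set(res.significant(0.05))
planted = {g for g, k in zip(tc.transcripts, truth.cluster_labels) if k == 0}
print(f"transcripts tested:        {len(res.table)}")
print(f"DE at q < 0.05:            {len(called)}")
print(f"planted responders found:  {len(called & planted)} / {len(planted)}")
print(f"flat genes also called:    {len(called - planted)}")
# The planted early-up profiles (amplitude 2 log2 units) are all recovered
# and dominate the top ranks.  Many flat genes also cross q < 0.05 here:
# the generator gives every gene a small temporal deviation shared across
# replicates (sigma_t), which is genuine - if weak - time structure, and
# with a quarter of the genes strongly responsive the BH threshold is
# liberal.  Rank order is the robust readout at this scale.
print(res.table.sort_values("rank").head(5).round(3))
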