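"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np


def peak_runs_oracle(values, threshold, min_run, merge_gap):
    """Enumerate merged enriched runs [lo, hi] (probe indices) by brute force."""
    above = [v >= threshold for v in values]
    runs = []
    i = 0
    while i < len(values):
        if above[i]:
            j = i
            while j + 1 < len(values) and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    out = []
    for lo, hi in merged:
        best = cur = 0
        for k in range(lo, hi + 1):
            cur = cur + 1 if above[k] else 0
            best = max(best, cur)
        if best >= min_run:
            out.append((lo, hi))
    return out


def pwm_scan_oracle(seq, wm):
    """Per-window rescoring of both strands, independent of the scanner."""
    from notchpulse.motifs import revcomp

    L = len(wm)
    idx = {b: i for i, b in enumerate("ACGT")}
    out = []
    for strand in ("+", "-"):
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            if strand == "-":
                window = revcomp(window)
            if any(b not in idx for b in window):
                continue
            score = sum(wm.weights[j, idx[b]] for j, b in enumerate(window))
            if score >= wm.threshold:
                out.append((i, strand, round(float(score), 9)))
    return sorted(out)


def precedence_oracle(subset):
    order = {"AU": 3, "AP": 2, "P": 1, "UB": 0}
    return max(subset, key=order.get)


def crp_expected_K_mc(alpha, n, n_draws, rng):
    """Monte-Carlo mean occupied-cluster count under the CRP."""
    from notchpulse.cluster import sample_crp_partition

    ks = np.array(
        [len(np.unique(sample_crp_partition(alpha, n, rng))) for _ in range(n_draws)]
    )
    return ks.mean(), ks.std(ddof=1) / np.sqrt(n_draws)
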