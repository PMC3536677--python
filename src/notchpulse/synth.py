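"""Synthetic data with planted ground truth for the whole analysis.

The generator emulates the statistical structure of a short Notch-activation
pulse experiment: a replicated two-colour expression timecourse (18
timepoints, 4 replicates by default) with genes drawn from temporal-profile
clusters; tiling-array ChIP enrichment tracks for Su(H) and Pol II (7
timepoints, 3 replicates, 50 bp probe spacing); a synthetic genome with gene
models and planted Su(H)/Hairy motif instances including SPS pairs; and a
gene table for the DE-odds logistic model generated at stated coefficients.
Every planted feature is recorded in a :class:`SynthTruth` so downstream
modules can be scored against exact ground truth.

Expression model: M(g, t, r) = mu_k(t) + c_g + d_{g,t} + e_{g,t,r}, where
mu_k is the cluster mean profile, c_g ~ N(0, sigma_c^2) is a per-gene
amplitude offset, d_{g,t} ~ N(0, sigma_t^2) a time-specific deviation shared
across replicates, and e ~ N(0, sigma_r^2) replicate noise — the three
variability sources the clustering model assumes (amplitude, temporal
profile, noise).

ChIP background is N(0, sigma_bg) clipped at zero, matching the non-negative
log2 enrichment convention of the tracks; the Su(H) peak-height profile over
the ChIP timecourse follows the observed pulse shape, maximal at 20-30 min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import TimecourseMatrix
from .motifs import SPS_GAP_RANGE, WeightMatrix, revcomp
from .peaks import ProbeTrack
from .polii import Transcript

#: Default expression timepoint grid in minutes (18 points spanning 0-150).
DEFAULT_EXPR_TIMES = (0, 5, 10, 15, 20, 25, 30, 35, 40, 50, 60, 70, 80, 90, 100, 110, 130, 150)

#: Default ChIP timepoint grid in minutes.
DEFAULT_CHIP_TIMES = (0, 10, 20, 30, 40, 60, 100)

#: Su(H) occupancy profile over the ChIP timepoints: a pulse peaking at
#: 20-30 min and declining thereafter (relative heights).
SUH_PULSE_PROFILE = (0.5, 0.85, 1.0, 1.0, 0.8, 0.5, 0.25)

PROFILE_SHAPES = ("early_up", "late_up", "down", "transient", "flat")
POLII_CLASSES = ("UB", "P", "AP", "AU")


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults follow the experimental design being emulated: 18 expression
    timepoints x 4 replicates, 7 ChIP timepoints x 3 replicates, 50 bp probe
    spacing.  Noise magnitudes (sigma_c, sigma_t, sigma_r, sigma_bg) are
    package choices on the log2 scale, sized so planted structure is
    recoverable but not trivial; they are not estimates of any real array's
    noise.
    """

    n_genes: int = 500
    expr_times: tuple = DEFAULT_EXPR_TIMES
    chip_times: tuple = DEFAULT_CHIP_TIMES
    n_expr_reps: int = 4
    n_chip_reps: int = 3
    # (shape, amplitude in log2 units, member count); counts must sum to n_genes
    cluster_spec: tuple = (
        ("early_up", 2.0, 60),
        ("late_up", 1.5, 50),
        ("down", -1.5, 40),
        ("transient", 2.5, 50),
        ("flat", 0.0, 300),
    )
    sigma_c: float = 0.3
    sigma_t: float = 0.05
    sigma_r: float = 0.25
    probe_spacing: int = 50
    peak_height: float = 3.0
    sigma_bg: float = 0.1
    polii_class_mix: dict = field(
        default_factory=lambda: {"UB": 0.4, "P": 0.2, "AP": 0.2, "AU": 0.2}
    )
    # generating coefficients of the DE-odds logistic model, log-odds units
    regression_betas: dict = field(
        default_factory=lambda: {
            "const": -2.0,
            "suh": 2.78,
            "P": 0.77,
            "AP": 0.5,
            "AU": -0.49,
            "logC0": 0.2,
        }
    )
    gene_length: int = 2000
    intergenic: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_expr_reps <= 0 or self.n_chip_reps <= 0:
            raise ValueError("counts must be positive")
        for times in (self.expr_times, self.chip_times):
            t = np.asarray(times, dtype=float)
            if t[0] != 0 or np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing and include 0")
        if min(self.sigma_c, self.sigma_t, self.sigma_r, self.sigma_bg) < 0:
            raise ValueError("variance components must be nonnegative")
        if not self.cluster_spec:
            raise ValueError("cluster_spec must not be empty")
        for shape, _, count in self.cluster_spec:
            if shape not in PROFILE_SHAPES:
                raise ValueError(f"unknown profile shape {shape!r}")
            if count <= 0:
                raise ValueError("cluster member counts must be positive")
        if sum(c for _, _, c in self.cluster_spec) != self.n_genes:
            raise ValueError("cluster_spec member counts must sum to n_genes")
        if not np.isclose(sum(self.polii_class_mix.values()), 1.0):
            raise ValueError("polii_class_mix proportions must sum to 1")
        if self.probe_spacing <= 0:
            raise ValueError("probe spacing must be positive")


@dataclass
class SynthTruth:
    """Record of everything the generator planted."""

    cluster_labels: np.ndarray | None = None          # gene index -> cluster index
    cluster_profiles: np.ndarray | None = None        # (K, T) mean curves
    gene_ids: list[str] | None = None
    transcripts: list[Transcript] | None = None
    genome_length: int | None = None
    polii_class: dict[str, str] | None = None         # transcript id -> class
    suh_peaks: dict[float, list[tuple[int, int]]] | None = None  # time -> intervals
    suh_heights: dict[float, float] | None = None     # time -> planted peak height
    suh_enhancers: list[tuple[int, int]] | None = None
    motif_positions: dict[str, list[tuple[int, str]]] | None = None  # matrix -> (pos, strand)
    sps_positions: list[tuple[int, int, int]] | None = None  # (left pos, right pos, gap)
    regression_betas: dict | None = None


def profile_shape(shape: str, times: np.ndarray, amplitude: float) -> np.ndarray:
    """Cluster mean curve mu_k(t) for one canonical temporal shape.

    ``early_up`` rises to its maximum near 20-30 min and decays; ``late_up``
    is a sigmoid engaging after ~1 h; ``down`` declines monotonically;
    ``transient`` is a sharp pulse around 25 min; ``flat`` is zero.
    """
    t = np.asarray(times, dtype=float)
    if shape == "early_up":
        return amplitude * (t / 25.0) * np.exp(1 - t / 25.0)
    if shape == "late_up":
        return amplitude / (1 + np.exp(-(t - 80.0) / 15.0))
    if shape == "down":
        # negative amplitude conventionally supplied; curve saturates
        return amplitude * t / (t + 40.0) if amplitude <= 0 else -amplitude * t / (t + 40.0)
    if shape == "transient":
        return amplitude * np.exp(-(((t - 25.0) / 12.0) ** 2))
    if shape == "flat":
        return np.zeros_like(t)
    raise ValueError(f"unknown shape {shape!r}")


def gen_expression(config: SynthConfig, rng: np.random.Generator | None = None
                   ) -> tuple[TimecourseMatrix, SynthTruth]:
    """Generate the replicated timecourse expression matrix.

    Gene order follows cluster_spec blocks; the truth records labels and the
    planted mean curves.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.asarray(config.expr_times, dtype=float)
    T, R = len(times), config.n_expr_reps
    n = config.n_genes
    profiles = np.stack(
        [profile_shape(s, times, a) for s, a, _ in config.cluster_spec]
    )
    labels = np.repeat(np.arange(len(config.cluster_spec)),
                       [c for _, _, c in config.cluster_spec])
    mu = profiles[labels]                                # (n, T)
    c = rng.normal(0, config.sigma_c, size=(n, 1, 1))
    d = rng.normal(0, config.sigma_t, size=(n, T, 1))
    e = rng.normal(0, config.sigma_r, size=(n, T, R))
    y = mu[:, :, None] + c + d + e

    gene_ids = [f"g{i:04d}" for i in range(n)]
    cols = pd.MultiIndex.from_product([times, range(R)], names=["time", "rep"])
    m = pd.DataFrame(y.reshape(n, T * R), index=gene_ids, columns=cols)
    truth = SynthTruth(
        cluster_labels=labels,
        cluster_profiles=profiles,
        gene_ids=gene_ids,
        regression_betas=dict(config.regression_betas),
    )
    return TimecourseMatrix(m=m), truth


def gen_raw_intensities(
    config: SynthConfig,
    tc: TimecourseMatrix,
    rng: np.random.Generator | None = None,
    base_log_intensity: float = 10.0,
    base_sd: float = 1.5,
) -> pd.DataFrame:
    """Back-transform M values into two-channel spot intensities.

    Each gene gets a basal reference-channel log2 intensity drawn once
    (base_log_intensity +/- base_sd); channels are reference = 2**A0 and
    treated = reference * 2**M.  This supplies raw input for the M/A
    transform and a well-defined basal-abundance proxy logC0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    base = rng.normal(base_log_intensity, base_sd, size=len(tc.m))
    rows = []
    for (t, r) in tc.m.columns:
        mcol = tc.m[(t, r)].to_numpy()
        ref = np.power(2.0, base)
        treated = ref * np.power(2.0, mcol)
        rows.append(
            pd.DataFrame(
                {
                    "spot": [f"{g}_{t:g}_{r}" for g in tc.m.index],
                    "transcript": tc.m.index,
                    "time": t,
                    "rep": r,
                    "ch_treated": treated,
                    "ch_reference": ref,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gen_gene_models(config: SynthConfig) -> tuple[list[Transcript], int]:
    """Lay out single-transcript gene models on one synthetic chromosome.

    Genes alternate strand, each ``gene_length`` bp, separated by
    ``intergenic`` bp; coordinates are 0-based half-open.
    """
    transcripts = []
    pos = config.intergenic
    for i in range(config.n_genes):
        gid = f"g{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        transcripts.append(
            Transcript(
                transcript_id=f"{gid}.t1",
                chrom="chrS",
                start=pos,
                end=pos + config.gene_length,
                strand=strand,
                gene_id=gid,
            )
        )
        pos += config.gene_length + config.intergenic
    return transcripts, pos


def _polii_template(
    cls: str,
    positions: np.ndarray,
    tx: Transcript,
    promoter_window: int,
    h_max: float,
    h_body: float,
) -> np.ndarray:
    """Noise-free Pol II enrichment template for one transcript."""
    vals = np.zeros(len(positions))
    p_lo, p_hi = tx.promoter_interval(promoter_window)
    b_lo, b_hi = tx.body_interval(promoter_window)
    prom = (positions >= p_lo) & (positions < p_hi)
    body = (positions >= b_lo) & (positions < b_hi)
    if cls == "P":
        vals[prom] = h_max
    elif cls == "AP":
        vals[prom] = h_max
        vals[body] = h_body
    elif cls == "AU":
        vals[prom] = h_body
        vals[body] = h_body
    return vals


def gen_chip(
    config: SynthConfig,
    transcripts: list[Transcript],
    genome_length: int,
    rng: np.random.Generator | None = None,
    promoter_window: int = 500,
    h_max: float = 4.0,
    h_body: float = 1.5,
    suh_fraction: float = 0.3,
) -> tuple[dict[str, ProbeTrack], SynthTruth]:
    """Generate Su(H) and Pol II probe tracks with planted truth.

    Pol II: each transcript is assigned a class from ``polii_class_mix``;
    the class template (promoter block / body block) is added to clipped
    Gaussian background and held constant over timepoints.  With the default
    h_max=4 and h_body=1.5 the AP template's pausing ratio is 4/1.5 ~ 2.7,
    safely above the >= 2 cutoff; the AU template's ratio is 1.

    Su(H): a fraction of genes get an enhancer interval upstream of the TSS
    whose peak height follows the pulse profile (maximal at 20-30 min).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    for tx in transcripts:
        if tx.start < 0 or tx.end > genome_length:
            raise ValueError(f"transcript {tx.transcript_id} outside the genome")
    spacing = config.probe_spacing
    positions = np.arange(spacing // 2, genome_length, spacing)
    times = np.asarray(config.chip_times, dtype=float)
    Tn, Rn = len(times), config.n_chip_reps

    classes = list(config.polii_class_mix)
    probs = np.array([config.polii_class_mix[c] for c in classes])
    assigned = rng.choice(classes, size=len(transcripts), p=probs)

    polii_signal = np.zeros(len(positions))
    polii_class = {}
    for tx, cls in zip(transcripts, assigned):
        polii_class[tx.transcript_id] = str(cls)
        polii_signal += _polii_template(str(cls), positions, tx, promoter_window, h_max, h_body)

    pulse = np.asarray(SUH_PULSE_PROFILE[: Tn], dtype=float)
    if len(pulse) < Tn:
        pulse = np.interp(times, np.linspace(times[0], times[-1], len(SUH_PULSE_PROFILE)),
                          SUH_PULSE_PROFILE)
    genes = {}
    for tx in transcripts:
        genes.setdefault(tx.gene_id, []).append(tx)
    gene_ids = sorted(genes)
    n_enh = max(1, int(round(suh_fraction * len(gene_ids))))
    enhancer_genes = list(rng.choice(gene_ids, size=n_enh, replace=False))
    enhancer_width = 8 * spacing
    enhancers = []
    # planted intervals are kept well separated (> merge distance at default
    # calling parameters) so each yields exactly one called peak
    min_sep = 6 * spacing
    for gid in enhancer_genes:
        tx = genes[gid][0]
        if tx.strand == "+":
            start = max(tx.start - 1500 - enhancer_width, 0)
        else:
            start = min(tx.end + 1500, genome_length - enhancer_width)
        iv = (int(start), int(start + enhancer_width))
        if all(iv[0] >= e + min_sep or iv[1] + min_sep <= s for s, e in enhancers):
            enhancers.append(iv)

    suh_signal = np.zeros((len(positions), Tn))
    suh_peaks: dict[float, list[tuple[int, int]]] = {float(t): [] for t in times}
    for (start, end) in enhancers:
        mask = (positions >= start) & (positions < end)
        for j, t in enumerate(times):
            h = config.peak_height * pulse[j]
            suh_signal[mask, j] += h
            if h > 0:
                suh_peaks[float(t)].append((start, end))

    def with_background(signal_tj: np.ndarray) -> np.ndarray:
        bg = rng.normal(0, config.sigma_bg, size=(len(positions), Tn, Rn))
        return np.clip(signal_tj[:, :, None] + bg, 0, None)

    polii_data = with_background(np.repeat(polii_signal[:, None], Tn, axis=1))
    suh_data = with_background(suh_signal)

    tracks = {
        "PolII": ProbeTrack("chrS", positions, polii_data, times, spacing),
        "SuH": ProbeTrack("chrS", positions, suh_data, times, spacing),
    }
    truth = SynthTruth(
        transcripts=transcripts,
        genome_length=genome_length,
        polii_class=polii_class,
        suh_peaks=suh_peaks,
        suh_heights={float(t): float(config.peak_height * pulse[j]) for j, t in enumerate(times)},
        suh_enhancers=enhancers,
    )
    return tracks, truth


def _safe_mutate(seq, j, patterns, max_len, is_planted) -> bool:
    """Change base j to an alternative that leaves no accidental pattern
    occurrence in its neighbourhood (a fixed swap can oscillate: destroying
    one consensus may create another that the next pass reverts).  Planted
    occurrences are exempt.  Returns False when no base at j is safe."""
    original = seq[j]
    lo = max(j - max_len + 1, 0)
    hi = min(j + max_len, len(seq))
    for alt in "ACGT":
        if alt == original:
            continue
        seq[j] = alt
        window = "".join(seq[lo:hi])
        clean = True
        for p in patterns:
            start = 0
            while clean:
                k = window.find(p, start)
                if k < 0:
                    break
                if not is_planted(lo + k, len(p)):
                    clean = False
                start = k + 1
        if clean:
            return True
    seq[j] = original
    return False


def gen_genome_with_motifs(
    config: SynthConfig,
    suh: WeightMatrix,
    hairy: WeightMatrix,
    genome_length: int | None = None,
    n_suh: int = 10,
    n_hairy: int = 10,
    n_sps: int = 3,
    sps_gaps: tuple[int, ...] = (10, 15, 22),
    rng: np.random.Generator | None = None,
) -> tuple[str, SynthTruth]:
    """Generate a uniform-background genome with planted consensus motifs.

    Single Su(H) and Hairy consensus instances are planted at random
    non-overlapping positions and strands; SPS pairs are head-to-head Su(H)
    consensus sites at the stated gaps.  Accidental background occurrences
    of either consensus (on either strand) are destroyed by point mutation
    before planting, so an exact-consensus scan recovers exactly the planted
    set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if genome_length is None:
        genome_length = gen_gene_models(config)[1]
    seq = list(rng.choice(list("ACGT"), size=genome_length))
    cons_suh, cons_hairy = suh.consensus(), hairy.consensus()
    patterns = [cons_suh, revcomp(cons_suh), cons_hairy, revcomp(cons_hairy)]

    blocks: list[tuple[int, int]] = []      # reserved placement regions
    footprints: list[tuple[int, int]] = []  # actual planted motif extents

    def in_plant(i: int) -> bool:
        return any(s <= i < e for s, e in footprints)

    def destroy_accidental() -> None:
        """Point-mutate background occurrences of any consensus (either strand)
        until none remain, never touching planted footprints.  Works in
        passes so the genome string is rebuilt only a handful of times."""
        for _ in range(50):
            text = "".join(seq)
            hits = []
            for pattern in patterns:
                start = 0
                while True:
                    i = text.find(pattern, start)
                    if i < 0:
                        break
                    # occurrences lying wholly inside planted sites are the
                    # plants themselves; everything else is accidental
                    if not (in_plant(i) and in_plant(i + len(pattern) - 1)):
                        hits.append((i, len(pattern)))
                    start = i + 1
            if not hits:
                return
            max_len = max(len(p) for p in patterns)

            def is_planted(start: int, length: int) -> bool:
                return in_plant(start) and in_plant(start + length - 1)

            for i, L in hits:
                for j in range(i, i + L):
                    if not in_plant(j) and _safe_mutate(seq, j, patterns, max_len, is_planted):
                        break
        raise RuntimeError("failed to clear accidental consensus occurrences")

    destroy_accidental()

    def reserve(length: int) -> int:
        for _ in range(10_000):
            pos = int(rng.integers(0, genome_length - length))
            # keep a one-motif-length margin so plants cannot merge into
            # accidental windows
            if not any(pos < e + length and s - length < pos + length for s, e in blocks):
                blocks.append((pos, pos + length))
                return pos
        raise RuntimeError("could not place motif without overlap")

    motif_positions: dict[str, list[tuple[int, str]]] = {suh.name: [], hairy.name: []}
    sps_positions: list[tuple[int, int, int]] = []

    lo, hi = SPS_GAP_RANGE
    for gap in (sps_gaps * ((n_sps // len(sps_gaps)) + 1))[:n_sps]:
        L = len(cons_suh)
        block = 2 * L + gap
        pos = reserve(block)
        left = cons_suh                     # + strand
        right = revcomp(cons_suh)           # - strand, head-to-head
        seq[pos : pos + L] = list(left)
        seq[pos + L + gap : pos + block] = list(right)
        footprints.append((pos, pos + L))
        footprints.append((pos + L + gap, pos + block))
        motif_positions[suh.name].append((pos, "+"))
        motif_positions[suh.name].append((pos + L + gap, "-"))
        if lo <= gap <= hi:
            sps_positions.append((pos, pos + L + gap, gap))

    for name, cons, count in ((suh.name, cons_suh, n_suh), (hairy.name, cons_hairy, n_hairy)):
        for _ in range(count):
            pos = reserve(len(cons))
            strand = "+" if rng.uniform() < 0.5 else "-"
            planted = cons if strand == "+" else revcomp(cons)
            seq[pos : pos + len(cons)] = list(planted)
            footprints.append((pos, pos + len(cons)))
            motif_positions[name].append((pos, strand))

    # junctions or SPS spacers may have produced new accidental consensus
    # windows; destroy them without touching the planted footprints
    destroy_accidental()

    truth = SynthTruth(
        genome_length=genome_length,
        motif_positions=motif_positions,
        sps_positions=sps_positions,
    )
    return "".join(seq), truth


def gen_de_odds_table(
    config: SynthConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the per-gene DE-odds table at the generating coefficients.

    Predictors: binary Su(H) occupancy, Pol II class indicators (UB
    baseline), and centred logC0; the DE indicator is Bernoulli with
    log-odds given by ``config.regression_betas``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    if n is None:
        n = config.n_genes
    b = config.regression_betas
    suh = rng.binomial(1, 0.3, size=n)
    classes = list(config.polii_class_mix)
    probs = np.array([config.polii_class_mix[c] for c in classes])
    cls = rng.choice(classes, size=n, p=probs)
    logc0 = rng.normal(0, 1.5, size=n)
    eta = b["const"] + b["suh"] * suh + b["logC0"] * logc0
    for name in ("P", "AP", "AU"):
        eta = eta + b.get(name, 0.0) * (cls == name)
    p = 1.0 / (1.0 + np.exp(-eta))
    de = rng.binomial(1, p)
    out = pd.DataFrame(
        {
            "suh": suh,
            "P": (cls == "P").astype(int),
            "AP": (cls == "AP").astype(int),
            "AU": (cls == "AU").astype(int),
            "logC0": logc0,
            "de": de,
        },
        index=[f"g{i:04d}" for i in range(n)],
    )
    return out


def zero_noise(config: SynthConfig) -> SynthConfig:
    """Copy of the config with all noise components set to zero."""
    return replace(config, sigma_c=0.0, sigma_t=0.0, sigma_r=0.0, sigma_bg=0.0)
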