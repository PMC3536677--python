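"""Peak-gene association, the master summary table, and statistical models
linking Su(H) binding, Pol II state and basal expression to differential
expression.

The central model is a logistic regression of the per-gene DE indicator on
binary Su(H) occupancy (>= 1 peak within 10 kb of the gene at a stated
timepoint), Pol II class indicators (P, AP, AU; UB is the baseline), and the
basal-expression proxy logC0.  Coefficients are log-odds effects; e.g. a
Su(H) coefficient of 2.78 means binding multiplies the odds of DE by
e^2.78 = 16.12.  Wald p-values are Holm-adjusted and flagged at p < 0.005.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 10_000  # bp window for Su(H)-gene association
SIGNIFICANCE_LEVEL = 0.005


def min_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Minimum distance in bp between two half-open intervals; 0 iff overlap."""
    a_start, a_end = a
    b_start, b_end = b
    if a_start < b_end and b_start < a_end:
        return 0
    if a_end <= b_start:
        return b_start - a_end
    return a_start - b_end


def count_peaks_within(
    gene_transcripts: list[tuple[int, int]],
    peaks: list[tuple[int, int]],
    radius: int = DEFAULT_RADIUS,
) -> int:
    """Number of peaks with minimum distance <= radius to any transcript of the gene."""
    count = 0
    for p in peaks:
        d = min(min_distance(t, p) for t in gene_transcripts) if gene_transcripts else None
        if d is not None and d <= radius:
            count += 1
    return count


def assign_peaks_nearest2(
    genes: dict[str, list[tuple[int, int]]],
    peaks: list[tuple[int, int]],
) -> dict[int, list[str]]:
    """Assign each peak to its 2 nearest genes irrespective of distance.

    Distance is the minimum over a gene's transcripts; ties break toward the
    gene whose leftmost transcript starts first, then by gene id.
    """
    out = {}
    for i, p in enumerate(peaks):
        scored = []
        for gid, txs in genes.items():
            d = min(min_distance(t, p) for t in txs)
            leftmost = min(t[0] for t in txs)
            scored.append((d, leftmost, gid))
        scored.sort()
        out[i] = [gid for _, _, gid in scored[:2]]
    return out


def effect_to_odds(beta: float) -> float:
    """Log-odds effect to an odds multiplier, reported to 2 decimals."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return round(float(np.exp(beta)), 2)


@dataclass
class LogisticFit:
    """Fitted DE-odds model: coefficients in log-odds units with Wald tests."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    adjusted_pvalues: pd.Series
    significant: pd.Series          # adjusted p < 0.005, intercept excluded
    dropped: list[str] = field(default_factory=list)
    separation: bool = False

    def odds(self) -> pd.Series:
        return self.params.map(effect_to_odds)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        zq = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"lo": self.params - zq * self.bse, "hi": self.params + zq * self.bse}
        )


def fit_de_logistic(
    table: pd.DataFrame,
    response: str = "de",
    predictors: list[str] | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of the DE indicator.

    Fits by IRLS; constant (all-equal) predictor columns are dropped with a
    warning.  Complete separation is detected and reported; the fit then
    falls back to an L2-penalised estimate so coefficients stay finite.
    Holm adjustment is applied across the non-intercept coefficients.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    X = table[predictors].astype(float)
    dropped = [c for c in predictors if X[c].nunique() <= 1]
    if dropped:
        logger.warning("dropping constant predictor columns: %s", dropped)
        X = X.drop(columns=dropped)
    y = table[response].astype(int)
    for c in X.columns:
        events = min((y[X[c] != X[c].min()] == 1).sum(), (y == 1).sum())
        if 0 < events < 10:
            logger.warning("predictor %s has only %d events", c, events)
    X = sm.add_constant(X)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if np.any(np.abs(res.params) > 15) or not np.all(np.isfinite(res.bse)):
                separation = True
        except (PerfectSeparationWarning, Exception) as exc:  # noqa: BLE001
            logger.warning("ML fit failed (%s); falling back to penalised fit", exc)
            separation = True
        if separation:
            logger.warning("possible complete separation: coefficients penalised (L2)")
            res = sm.Logit(y, X).fit_regularized(
                disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
            )
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(getattr(res, "bse", np.full(len(params), np.nan)), index=X.columns)
    pvals = pd.Series(getattr(res, "pvalues", np.full(len(params), np.nan)), index=X.columns)
    coef_names = [c for c in X.columns if c != "const"]
    adj = pd.Series(np.nan, index=params.index)
    if coef_names and np.isfinite(pvals[coef_names]).all():
        adj[coef_names] = multipletests(pvals[coef_names], method="holm")[1]
    sig = (adj < SIGNIFICANCE_LEVEL).reindex(params.index).fillna(False)
    sig["const"] = False
    return LogisticFit(
        params=params,
        bse=bse,
        pvalues=pvals,
        adjusted_pvalues=adj,
        significant=sig,
        dropped=dropped,
        separation=separation,
    )


@dataclass
class ClassTests:
    """One-way ANOVA plus directed pairwise Welch t-tests of logC0 by class."""

    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame  # higher, lower, t, p_one_sided


def logC0_class_tests(
    logc0: pd.Series,
    classes: pd.Series,
    order: tuple[str, ...] = ("AU", "AP", "P", "UB"),
) -> ClassTests:
    """Test whether Pol II classes differ in basal expression.

    One-way ANOVA across classes plus all pairwise one-sided Welch two-sample
    t-tests in the direction higher-activity class > lower-activity class
    (activity order AU/AP > P > UB).
    """
    df = pd.DataFrame({"logc0": logc0, "cls": classes}).dropna()
    groups = {c: g["logc0"].to_numpy() for c, g in df.groupby("cls")}
    usable = {c: v for c, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 classes with at least 2 members")
    F, p = stats.f_oneway(*usable.values())
    if np.isnan(F):  # identical values in all groups
        F, p = 0.0, 1.0
    present = [c for c in order if c in usable]
    rows = []
    for i, hi in enumerate(present):
        for lo in present[i + 1 :]:
            t, p1 = stats.ttest_ind(
                usable[hi], usable[lo], equal_var=False, alternative="greater"
            )
            rows.append({"higher": hi, "lower": lo, "t": t, "p_one_sided": p1})
    return ClassTests(anova_F=float(F), anova_p=float(p), pairwise=pd.DataFrame(rows))


@dataclass
class RegimeComparison:
    """Agreement between per-gene responses under two activation regimes."""

    slope: float
    r_squared: float
    ratios: pd.Series         # linear-scale fold-change ratio per gene
    flagged: pd.Index         # genes with ratio beyond the cutoff

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def regime_compare(
    fc_a: pd.Series, fc_b: pd.Series, ratio_cutoff: float = 2.0
) -> RegimeComparison:
    """Compare paired log2 fold changes between two activation regimes.

    OLS slope and r^2 of regime B on regime A, the per-gene linear-scale
    response ratio 2**|fc_b - fc_a|, and flags where it exceeds the cutoff.
    """
    joined = pd.DataFrame({"a": fc_a, "b": fc_b}).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired genes")
    res = stats.linregress(joined["a"], joined["b"])
    ratios = np.power(2.0, (joined["b"] - joined["a"]).abs())
    flagged = joined.index[ratios > ratio_cutoff]
    return RegimeComparison(
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        ratios=ratios,
        flagged=flagged,
    )


def build_master_table(
    de_table: pd.DataFrame,
    transcript_gene: pd.Series,
    median_m: pd.DataFrame | None = None,
    cluster_assignments: pd.DataFrame | None = None,
    polii_states: pd.DataFrame | None = None,
    suh_counts: pd.DataFrame | None = None,
    logc0: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-transcript integration table.

    One row per tested transcript: gene id; DE rank/p/q; primary/secondary
    cluster with allocation probabilities; Pol II state per ChIP timepoint;
    Su(H) peak count within 10 kb per ChIP timepoint; logC0; median M per
    expression timepoint.  Stages that did not run contribute empty columns.
    """
    out = de_table.copy()
    out.insert(0, "gene", transcript_gene.reindex(out.index))
    if cluster_assignments is not None:
        cl = cluster_assignments.reindex(out.index)
        cl.columns = [f"cluster_{c}" for c in cl.columns]
        out = out.join(cl)
    else:
        for c in ("cluster_primary", "cluster_p_primary", "cluster_secondary", "cluster_p_secondary"):
            out[c] = np.nan
    if polii_states is not None:
        ps = polii_states.reindex(out.index)
        ps.columns = [f"polii_{int(t)}min" for t in ps.columns]
        out = out.join(ps)
    if suh_counts is not None:
        gene_counts = suh_counts.reindex(out["gene"])
        gene_counts.index = out.index
        gene_counts.columns = [f"suh_{int(t)}min" for t in gene_counts.columns]
        out = out.join(gene_counts)
    if logc0 is not None:
        out["logC0"] = logc0.reindex(out.index)
    if median_m is not None:
        mm = median_m.reindex(out.index)
        mm.columns = [f"medianM_{t:g}min" for t in mm.columns]
        out = out.join(mm)
    return out
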