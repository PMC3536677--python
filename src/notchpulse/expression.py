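"""Two-colour timecourse expression: M/A values, normalization, and
differential expression over time.

The experimental design is a common-reference two-colour timecourse: at each
timepoint the treated sample is hybridised against a pooled reference, so the
log-ratio M = log2(treated/reference) is comparable between arrays and
replicates.  Differential expression over the timecourse is detected with a
natural-cubic-spline regression F-test of M on time against an intercept-only
null, with Benjamini-Hochberg q-values — an explicit, documented equivalent of
spline-based timecourse DE software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Column names expected in a raw spot-intensity table.
RAW_COLUMNS = ("spot", "transcript", "time", "rep", "ch_treated", "ch_reference")


@dataclass
class TimecourseMatrix:
    """Per-transcript log-ratio values over timepoints and replicates.

    Attributes
    ----------
    m : DataFrame
        Rows are transcripts; columns are a MultiIndex of (time, rep) holding
        M = log2(treated/reference).  Missing cells are NaN.
    a : DataFrame or None
        Same shape, holding A = (log2 treated + log2 reference) / 2.  None
        when the matrix was built from a precomputed M table.
    """

    m: pd.DataFrame
    a: pd.DataFrame | None = None

    @property
    def times(self) -> np.ndarray:
        return np.asarray(sorted({t for t, _ in self.m.columns}), dtype=float)

    @property
    def reps(self) -> list:
        return sorted({r for _, r in self.m.columns})

    @property
    def transcripts(self) -> pd.Index:
        return self.m.index

    def median_m(self) -> pd.DataFrame:
        """Median M across replicates, one column per timepoint."""
        return self.m.T.groupby(level="time").median().T

    def profile_array(self) -> np.ndarray:
        """M as a dense (n_transcripts, n_times, n_reps) array (NaN-filled)."""
        times, reps = self.times, self.reps
        out = np.full((len(self.m), len(times), len(reps)), np.nan)
        for j, t in enumerate(times):
            for k, r in enumerate(reps):
                if (t, r) in self.m.columns:
                    out[:, j, k] = self.m[(t, r)].to_numpy()
        return out


def compute_ma(raw: pd.DataFrame) -> TimecourseMatrix:
    """Transform raw two-channel spot intensities to M and A values.

    Spots with a nonpositive intensity in either channel are dropped (their
    count is logged); M = log2(treated) - log2(reference) and
    A = (log2 treated + log2 reference) / 2 for the rest.
    """
    missing = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"raw table lacks columns {missing}")
    ok = (raw["ch_treated"] > 0) & (raw["ch_reference"] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d spots with nonpositive intensity", n_dropped)
    raw = raw.loc[ok]
    lt = np.log2(raw["ch_treated"].to_numpy(dtype=float))
    lr = np.log2(raw["ch_reference"].to_numpy(dtype=float))
    vals = raw[["transcript", "time", "rep"]].copy()
    vals["M"] = lt - lr
    vals["A"] = 0.5 * (lt + lr)
    m = vals.pivot_table(index="transcript", columns=["time", "rep"], values="M")
    a = vals.pivot_table(index="transcript", columns=["time", "rep"], values="A")
    m.columns = m.columns.set_names(["time", "rep"])
    a.columns = a.columns.set_names(["time", "rep"])
    return TimecourseMatrix(m=m, a=a.reindex(index=m.index, columns=m.columns))


def normalize_within_array(tc: TimecourseMatrix, span: float = 0.4) -> TimecourseMatrix:
    """Remove intensity-dependent M trend within each array.

    Per array (one (time, rep) column), fit a local regression of M on A with
    the given span and subtract it, then centre the residual median at zero.
    Arrays whose A values are all identical fall back to global median
    centring (logged).
    """
    if tc.a is None:
        raise ValueError("normalization requires A values; build from raw intensities")
    m_norm = tc.m.copy()
    for col in tc.m.columns:
        m = tc.m[col].to_numpy(dtype=float)
        a = tc.a[col].to_numpy(dtype=float)
        ok = ~(np.isnan(m) | np.isnan(a))
        if ok.sum() < 50:
            raise ValueError(f"array {col}: fewer than 50 spots, cannot normalize")
        mv, av = m[ok], a[ok]
        if np.ptp(av) == 0.0:
            logger.warning("array %s: constant A, falling back to median centring", col)
            resid = mv - np.median(mv)
        else:
            fit = lowess(mv, av, frac=span, return_sorted=False)
            resid = mv - fit
        resid = resid - np.median(resid)
        out = np.full_like(m, np.nan)
        out[ok] = resid
        m_norm[col] = out
    return TimecourseMatrix(m=m_norm, a=tc.a)


def natural_spline_basis(x: np.ndarray, df: int, knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) with ``df`` columns.

    Truncated-power construction with linearity constraints beyond the
    boundary knots; interior knots at quantiles of the unique x values.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if knots is None:
        # df natural-spline columns need df+1 knots (boundary + interior)
        probs = np.linspace(0, 1, df + 1)
        knots = np.quantile(np.unique(x), probs)
    knots = np.asarray(knots, dtype=float)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("knots must be distinct; too few unique x values for df")
    k = len(knots)

    def d(j: int) -> np.ndarray:
        num = np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - knots[k - 1], 0, None) ** 3
        return num / (knots[k - 1] - knots[j])

    cols = [x]
    dlast = d(k - 2)
    for j in range(k - 2):
        cols.append(d(j) - dlast)
    return np.column_stack(cols)


@dataclass
class DEResult:
    """Timecourse differential-expression table.

    One row per transcript: F statistic, p, BH q, rank by p (1 = most
    significant), and the number of observations used.
    """

    table: pd.DataFrame = field(repr=False)

    def significant(self, q_cutoff: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < q_cutoff]


def timecourse_de(
    tc: TimecourseMatrix,
    spline_df: int = 4,
    n_null: int = 0,
    seed: int | None = None,
) -> DEResult:
    """Test each transcript for differential expression over the timecourse.

    Fits M ~ natural-cubic-spline(time) with ``spline_df`` degrees of freedom
    against an intercept-only null by F-test, pooling all replicates.  With
    ``n_null`` > 0, p-values come instead from a permutation null that
    shuffles time labels within each replicate (seed then mandatory).
    q-values are Benjamini-Hochberg; transcripts are ranked by p (ties broken
    by larger F).
    """
    times = tc.times
    if len(times) < 4:
        raise ValueError("need at least 4 distinct timepoints")
    if spline_df >= len(times):
        raise ValueError("spline_df must be smaller than the number of timepoints")
    if n_null > 0 and seed is None:
        raise ValueError("seed is mandatory when the permutation null is enabled")

    y = tc.profile_array()  # (n, T, R)
    n, T, R = y.shape
    tvec = np.repeat(times, R)
    yflat = y.reshape(n, T * R)

    complete = ~np.isnan(yflat).any(axis=1)
    f_stat = np.full(n, np.nan)
    p_val = np.full(n, np.nan)
    n_obs = np.full(n, 0, dtype=int)

    def f_test(tt: np.ndarray, yy: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
        """Vectorised spline-vs-intercept F over rows of yy (shared tt)."""
        X = np.column_stack([np.ones_like(tt), natural_spline_basis(tt, spline_df)])
        q, _ = np.linalg.qr(X)
        fitted = yy @ q @ q.T
        rss1 = np.sum((yy - fitted) ** 2, axis=-1)
        rss0 = np.sum((yy - yy.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
        df1 = X.shape[1] - 1
        df2 = yy.shape[-1] - X.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss0 - rss1) / df1) / np.where(rss1 > 0, rss1 / df2, np.nan)
        # guards: a constant profile (rss0 ~ 0) has no time structure; a
        # perfectly fitted non-constant one (rss1 ~ 0) is maximally DE
        scale = np.maximum((yy**2).sum(axis=-1), 1.0)
        f = np.where(rss1 <= 1e-12 * scale, np.inf, f)
        f = np.where(rss0 <= 1e-12 * scale, 0.0, f)
        f = np.clip(f, 0.0, None)
        return f, stats.f.sf(f, df1, df2), df1, df2

    if complete.any():
        yc = yflat[complete]
        f, p, df1, df2 = f_test(tvec, yc)
        f_stat[complete] = f
        p_val[complete] = p
        n_obs[complete] = T * R
        if n_null > 0:
            rng = np.random.default_rng(seed)
            exceed = np.ones(len(yc), dtype=int)  # +1 smoothing includes observed
            for _ in range(n_null):
                perm = np.empty(T * R)
                tgrid = tvec.reshape(T, R)
                for r in range(R):
                    perm.reshape(T, R)[:, r] = rng.permutation(tgrid[:, r])
                fp, _, _, _ = f_test(perm, yc)
                exceed += fp >= f
            p_val[complete] = exceed / (n_null + 1)

    # incomplete transcripts: per-transcript complete-case fit
    for i in np.flatnonzero(~complete):
        ok = ~np.isnan(yflat[i])
        tt, yy = tvec[ok], yflat[i, ok]
        if len(np.unique(tt)) <= spline_df or len(yy) < spline_df + 2:
            continue
        try:
            f, p, _, _ = f_test(tt, yy[None, :])
        except ValueError:
            continue
        f_stat[i], p_val[i], n_obs[i] = f[0], p[0], int(ok.sum())

    tab = pd.DataFrame(
        {"F": f_stat, "p": p_val, "n_obs": n_obs}, index=tc.transcripts
    )
    tested = tab["p"].notna()
    q = np.full(n, np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(tab.loc[tested, "p"], method="fdr_bh")[1]
    tab["q"] = q
    order = tab.sort_values(["p", "F"], ascending=[True, False]).index
    tab["rank"] = pd.Series(np.arange(1, n + 1), index=order)
    return DEResult(table=tab)


def compute_logC0(raw: pd.DataFrame) -> pd.Series:
    """Basal absolute-expression proxy from t=0 spot intensities.

    logC0 = mean over replicates of log2(reference-channel intensity) at the
    zero timepoint.  Transcripts without a valid t=0 spot get NaN and are
    excluded downstream.
    """
    at0 = raw[(raw["time"] == 0) & (raw["ch_reference"] > 0)]
    if at0.empty:
        raise ValueError("no t=0 arrays present")
    vals = at0.assign(l2=np.log2(at0["ch_reference"].astype(float)))
    return vals.groupby("transcript")["l2"].mean().rename("logC0")
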