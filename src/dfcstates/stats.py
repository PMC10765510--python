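"""Nonparametric pre/post comparison and time-series diagnostics.

Group comparisons use the two-sided Mann-Whitney U test: exact by exhaustive
enumeration of rank arrangements for small samples (n1 + n2 <= 12, ties
handled via midranks), otherwise the tie-corrected normal approximation with
continuity correction. The reported statistic is the standardised (z-scaled)
U of the pre-op sample, so positive values mean the metric was larger before
stimulation. Shapiro-Wilk and Levene (median-centred) precondition tests are
reported alongside, mirroring the usual justification for going nonparametric.

Dynamic indicator traces additionally get stationarity (ADF + KPSS) and FFT
periodicity reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erfc, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# precondition tests
# ---------------------------------------------------------------------------

@dataclass
class PreconditionResult:
    shapiro_p_pre: float | None
    shapiro_p_post: float | None
    levene_p: float | None
    skipped: dict[str, str] = field(default_factory=dict)


def precondition_tests(pre: np.ndarray, post: np.ndarray) -> PreconditionResult:
    """Shapiro-Wilk normality per group and two-group Levene (center='median')."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    out = PreconditionResult(None, None, None)
    for name, sample in (("shapiro_p_pre", pre), ("shapiro_p_post", post)):
        if len(sample) < 3:
            out.skipped[name] = f"n={len(sample)} < 3"
        elif np.ptp(sample) == 0:
            out.skipped[name] = "constant sample"
        else:
            setattr(out, name, float(sps.shapiro(sample).pvalue))
    if len(pre) < 3 or len(post) < 3:
        out.skipped["levene_p"] = "a group has n < 3"
    elif np.ptp(pre) == 0 and np.ptp(post) == 0:
        out.skipped["levene_p"] = "both samples constant (degenerate)"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.levene(pre, post, center="median").pvalue)
        if np.isnan(p):
            out.skipped["levene_p"] = "degenerate variance structure"
        else:
            out.levene_p = p
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    metric_name: str | None
    group_means: tuple[float, float]
    statistic: float
    p_value: float
    direction: str  # increased / decreased / no_change (post relative to pre)
    alpha: float = 0.05
    method: str = "exact"
    n_pre: int = 0
    n_post: int = 0
    precondition: PreconditionResult | None = None


def _u_and_sigma(pre: np.ndarray, post: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    n1, n2 = len(pre), len(post)
    pooled = np.concatenate([pre, post])
    ranks = sps.rankdata(pooled)
    u_pre = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return u_pre, n1 * n2 / 2.0, sqrt(max(sigma2, 0.0)), ranks


def mann_whitney(pre: np.ndarray, post: np.ndarray, alpha: float = 0.05,
                 metric_name: str | None = None, exact_limit: int = 12,
                 with_preconditions: bool = False) -> GroupTestResult:
    """Two-sided Mann-Whitney U comparing pre-op vs post-op samples.

    Small samples (n1 + n2 <= ``exact_limit``) use exhaustive enumeration over
    all C(n, n1) rank arrangements of the pooled (midranked) values; larger
    samples use the tie-corrected normal approximation with continuity
    correction. ``direction`` describes the post-op group relative to pre-op
    and is ``no_change`` whenever p >= alpha.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(pre), len(post)
    u_obs, mu, sigma, ranks = _u_and_sigma(pre, post)
    z = (u_obs - mu) / sigma if sigma > 0 else 0.0
    if sigma == 0.0:  # all values tied across both groups
        p = 1.0
        method = "degenerate"
    elif n1 + n2 <= exact_limit:
        method = "exact"
        n = n1 + n2
        crit = min(u_obs, n1 * n2 - u_obs) + 1e-9
        offset = n1 * (n1 + 1) / 2.0
        hits = 0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - offset
            if min(u, n1 * n2 - u) <= crit:
                hits += 1
        p = hits / comb(n, n1)
    else:
        method = "normal"
        cc = 0.5 if u_obs != mu else 0.0
        z_cc = (u_obs - mu - np.sign(u_obs - mu) * cc) / sigma
        p = min(1.0, erfc(abs(z_cc) / sqrt(2.0)))
    if p < alpha:
        direction = "decreased" if u_obs > mu else "increased"
    else:
        direction = "no_change"
    result = GroupTestResult(metric_name, (float(pre.mean()), float(post.mean())),
                             float(z), float(p), direction, alpha, method, n1, n2)
    if with_preconditions:
        result.precondition = precondition_tests(pre, post)
    return result


# ---------------------------------------------------------------------------
# group-level and per-participant comparisons
# ---------------------------------------------------------------------------

def group_compare(metrics_table: pd.DataFrame, metrics: list[str], alpha: float = 0.05,
                  correction: str = "none", paired: bool = False) -> pd.DataFrame:
    """One Mann-Whitney test per metric on per-participant session values.

    ``metrics_table`` needs columns participant_id, session and the metric
    columns; multiple rows per participant-session (runs, states already
    sliced out) are averaged first. Participants missing a session are
    excluded per metric. Optional Benjamini-Hochberg correction; optional
    paired Wilcoxon variant.
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    per = metrics_table.groupby(["participant_id", "session"], sort=True)[metrics].mean()
    rows = []
    for metric in metrics:
        wide = per[metric].unstack("session")
        for col in ("pre_op", "post_op"):
            if col not in wide:
                wide[col] = np.nan
        if paired:
            both = wide.dropna(subset=["pre_op", "post_op"])
            pre, post = both["pre_op"].to_numpy(), both["post_op"].to_numpy()
            if len(pre) == 0 or np.all(pre - post == 0):
                res = GroupTestResult(metric, (float(pre.mean()), float(post.mean())),
                                      0.0, 1.0, "no_change", alpha, "degenerate",
                                      len(pre), len(post))
            else:
                w = sps.wilcoxon(pre, post)
                p = float(w.pvalue)
                direction = ("no_change" if p >= alpha
                             else ("decreased" if pre.mean() > post.mean() else "increased"))
                res = GroupTestResult(metric, (float(pre.mean()), float(post.mean())),
                                      float(w.statistic), p, direction, alpha,
                                      "wilcoxon", len(pre), len(post))
        else:
            pre = wide["pre_op"].dropna().to_numpy()
            post = wide["post_op"].dropna().to_numpy()
            dropped = len(wide) - min(len(pre), len(post))
            if dropped:
                log.info("metric %s: %d participant(s) missing a session excluded",
                         metric, dropped)
            res = mann_whitney(pre, post, alpha, metric, with_preconditions=True)
        rows.append(res)
    frame = results_to_frame(rows)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        rej, p_adj, *_ = multipletests(frame["p_value"], alpha=alpha, method="fdr_bh")
        frame["p_value_adjusted"] = p_adj
        # BH-adjusted p >= raw p, so a rejected metric already carries its sign
        frame.loc[~rej, "direction"] = "no_change"
    return frame


def results_to_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        pc = r.precondition
        rows.append((r.metric_name, r.group_means[0], r.group_means[1], r.statistic,
                     r.p_value, r.direction, r.method, r.n_pre, r.n_post,
                     pc.shapiro_p_pre if pc else np.nan,
                     pc.shapiro_p_post if pc else np.nan,
                     pc.levene_p if pc else np.nan))
    return pd.DataFrame(rows, columns=["metric", "mean_pre", "mean_post", "statistic",
                                       "p_value", "direction", "method",
                                       "n_pre", "n_post", "shapiro_p_pre",
                                       "shapiro_p_post", "levene_p"])


def per_participant_change(window_table: pd.DataFrame, metrics: list[str],
                           alpha: float = 0.05, min_windows: int = 2) -> pd.DataFrame:
    """Per-participant window-level Mann-Whitney per metric, tallied across
    participants (how many increased / decreased / showed no change).

    ``window_table`` has one row per window with columns participant_id,
    session and the metric columns. Participants with fewer than
    ``min_windows`` windows in either session are counted as untested.
    """
    rows = []
    participants = sorted(window_table["participant_id"].unique())
    for metric in metrics:
        tally = {"no_change": 0, "increased": 0, "decreased": 0, "untested": 0}
        for pid in participants:
            sub = window_table[window_table["participant_id"] == pid]
            pre = sub.loc[sub["session"] == "pre_op", metric].dropna().to_numpy()
            post = sub.loc[sub["session"] == "post_op", metric].dropna().to_numpy()
            if len(pre) < min_windows or len(post) < min_windows:
                tally["untested"] += 1
                continue
            tally[mann_whitney(pre, post, alpha).direction] += 1
        rows.append((metric, tally["no_change"], tally["increased"],
                     tally["decreased"], tally["untested"]))
    return pd.DataFrame(rows, columns=["metric", "n_no_change", "n_increased",
                                       "n_decreased", "n_untested"])


# ---------------------------------------------------------------------------
# stationarity and periodicity
# ---------------------------------------------------------------------------

@dataclass
class StationarityReport:
    adf_statistic: float
    adf_p: float
    kpss_statistic: float
    kpss_p: float
    verdict: str  # stationary / nonstationary / conflicting
    alpha: float = 0.05
    degenerate: bool = False
    kpss_lags: int | None = None


def stationarity(series: np.ndarray, alpha: float = 0.05) -> StationarityReport:
    """ADF (constant regression, AIC lag selection) + KPSS (level
    stationarity, data-dependent Hobijn truncation lag, recorded in the
    report) with the combined verdict: stationary iff ADF rejects a unit
    root and KPSS fails to reject level stationarity; the reverse is
    nonstationary; anything else is conflicting. A constant series is
    stationary by convention, flagged degenerate.

    Note the verdict "nonstationary" requires ADF *not* to reject; since a
    unit-root process sits inside ADF's null, ADF still rejects at its
    nominal size, so even a pure random walk draws a conflicting verdict in
    roughly alpha of replicates."""
    x = np.asarray(series, dtype=float)
    if len(x) < 20:
        raise ValueError(f"need at least 20 points, got {len(x)}")
    if np.ptp(x) == 0:
        return StationarityReport(np.nan, 0.0, np.nan, 1.0, "stationary",
                                  alpha, degenerate=True)
    from statsmodels.tsa.stattools import adfuller, kpss
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adf_stat, adf_p, *_ = adfuller(x, regression="c", autolag="AIC")
        kpss_stat, kpss_p, lags, _ = kpss(x, regression="c", nlags="auto")
    if adf_p < alpha and kpss_p >= alpha:
        verdict = "stationary"
    elif adf_p >= alpha and kpss_p < alpha:
        verdict = "nonstationary"
    else:
        verdict = "conflicting"
    return StationarityReport(float(adf_stat), float(adf_p), float(kpss_stat),
                              float(kpss_p), verdict, alpha, kpss_lags=int(lags))


@dataclass
class PeriodicityReport:
    dominant_frequency: float | None  # cycles per window
    dominant_period_seconds: float | None
    peak_power_ratio: float | None
    significant: bool
    cutoff: float = 10.0


def periodicity(series: np.ndarray, tr_seconds: float, step_tr: int = 1,
                peak_ratio_cutoff: float = 10.0) -> PeriodicityReport:
    """Linear detrend + FFT; dominant frequency is the nonzero-frequency power
    argmax (in cycles per window), converted to seconds via the window stride.
    ``peak_power_ratio`` (peak / median nonzero-frequency power) above the
    cutoff flags the trace as periodic; a constant series has no dominant
    frequency."""
    x = np.asarray(series, dtype=float)
    if len(x) < 8:
        raise ValueError(f"need at least 8 points, got {len(x)}")
    if np.ptp(x) == 0:
        return PeriodicityReport(None, None, None, False, peak_ratio_cutoff)
    from scipy.signal import detrend
    xd = detrend(x, type="linear")
    power = np.abs(np.fft.rfft(xd)) ** 2
    freqs = np.fft.rfftfreq(len(xd), d=1.0)  # cycles per window
    power, freqs = power[1:], freqs[1:]  # drop DC
    peak = int(np.argmax(power))
    f = float(freqs[peak])
    med = float(np.median(power))
    ratio = float(power[peak] / med) if med > 0 else np.inf
    period_seconds = (1.0 / f) * step_tr * tr_seconds
    return PeriodicityReport(f, period_seconds, ratio,
                             bool(ratio >= peak_ratio_cutoff), peak_ratio_cutoff)
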