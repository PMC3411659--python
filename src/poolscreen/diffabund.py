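"""Differential abundance testing and hit calling for pooled screens.

Sequencing counts are tested with a negative-binomial exact test:
samples are normalized by median-of-ratios size factors, per-hairpin
dispersions are estimated by method-of-moments and shrunk toward a
local-regression mean-dispersion trend, and the p-value of an observed
T0/T1 split is the conditional probability, given the total count, of
all splits no more likely than the one observed (the Poisson/binomial
conditional test in the dispersion-zero limit).

Array intensities are tested with a two-sided two-sample (Welch)
t-test on the probe intensities of each clone in the two channels.

Both platforms share Benjamini-Hochberg correction and the hit rule:
absolute fold change of two or greater and adjusted p of 0.05 or
lower.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp, xlogy

# log-space tie band for "no more likely than observed"
_TIE_TOL = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    For each hairpin with nonzero counts in every sample, the ratio of
    each sample's count to the hairpin's geometric mean is formed; the
    per-sample median of these ratios is the size factor.  If no
    hairpin is positive everywhere, the geometric means are computed
    over the positive entries of each row instead (with a warning).
    """
    mat = counts.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("counts must be a hairpins-by-samples table")
    if np.any(mat < 0):
        raise ValueError("negative counts")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_positive = np.all(mat > 0, axis=1)
    if all_positive.any():
        log_gm = logs[all_positive].mean(axis=1)
        ratios = logs[all_positive] - log_gm[:, None]
    else:
        warnings.warn("no hairpin is positive in all samples; using positive entries per row")
        any_positive = mat > 0
        usable = any_positive.sum(axis=1) > 0
        masked = np.where(any_positive, logs, np.nan)
        log_gm = np.nanmean(masked[usable], axis=1)
        ratios = masked[usable] - log_gm[:, None]
    factors = np.exp(np.nanmedian(ratios, axis=0))
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("could not compute positive size factors")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors_: pd.Series | np.ndarray | None = None,
    mode: str = "blind",
    conditions: pd.Series | np.ndarray | None = None,
) -> pd.Series:
    """Per-hairpin NB dispersion from normalized counts.

    The raw method-of-moments estimate for hairpin *i* is
    ``max(0, (var_i - mean_i) / mean_i**2)`` over the pooling set of
    samples; ``mode="blind"`` pools every sample as a pseudo-replicate
    (required when each condition has a single sample),
    ``mode="per-condition"`` pools within the groups given by
    ``conditions`` and averages the group estimates.  Raw estimates
    are then shrunk toward a local mean-dispersion trend: hairpins are
    binned by mean abundance and each bin contributes the median raw
    estimate rescaled by a chi-square consistency factor, so the trend
    is robust to a minority of true-effect hairpins (whose
    between-condition change masquerades as variance under blind
    pooling) while staying consistent for genuine NB dispersion.  The
    weight on each hairpin's own raw estimate grows with the number of
    pooled samples (zero at two samples, where a single degree of
    freedom makes the raw value uninformative).
    """
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs at least two samples")
    if mode not in ("blind", "per-condition"):
        raise ValueError("mode must be 'blind' or 'per-condition'")
    sf = (
        np.asarray(size_factors_, dtype=float)
        if size_factors_ is not None
        else size_factors(counts).to_numpy()
    )
    norm = counts.to_numpy(dtype=float) / sf

    if mode == "blind":
        groups = [np.arange(counts.shape[1])]
    else:
        if conditions is None:
            raise ValueError("per-condition mode needs condition labels")
        conditions = np.asarray(conditions)
        groups = [np.flatnonzero(conditions == c) for c in pd.unique(conditions)]
        groups = [g for g in groups if len(g) >= 2]
        if not groups:
            raise ValueError("no condition has two or more samples")

    raw_sum = np.zeros(len(counts))
    weight_sum = 0.0
    m_pool = 0
    for g in groups:
        sub = norm[:, g]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (var - mean) / mean**2
        alpha = np.where(mean > 0, np.maximum(alpha, 0.0), 0.0)
        w = len(g) - 1
        raw_sum += w * alpha
        weight_sum += w
        m_pool = max(m_pool, len(g))
    raw = raw_sum / weight_sum

    grand_mean = norm.mean(axis=1)
    fit = _dispersion_trend(grand_mean, raw, df=max(m_pool - 1, 1))
    w_raw = max(0.0, 1.0 - 2.0 / m_pool)
    final = np.maximum((1.0 - w_raw) * fit + w_raw * raw, 0.0)
    return pd.Series(final, index=counts.index, name="dispersion")


def _dispersion_trend(mean: np.ndarray, alpha: np.ndarray, df: int) -> np.ndarray:
    """Local mean-dispersion trend: binned medians of the raw estimates
    along log mean, rescaled for median-induced bias.

    A raw moment estimate from ``df + 1`` samples scales like
    ``alpha * chi2_df / df``, so the bin median understates alpha by
    the factor ``chi2_df.median() / df``; dividing by that factor
    restores consistency while the median absorbs (up to half a bin
    of) hairpins whose raw estimate is inflated by real abundance
    change.  For Poisson data the median raw estimate is exactly zero,
    so the trend correctly vanishes.
    """
    ok = mean > 0
    if not ok.any():
        return np.zeros(len(mean))
    factor = stats.chi2.ppf(0.5, df) / df

    def located(values: np.ndarray) -> float:
        if len(values) == 0:
            return 0.0
        return float(np.median(values)) / factor

    x = np.log10(mean[ok])
    y = alpha[ok]
    n_ok = int(ok.sum())
    if n_ok < 50 or np.ptp(x) == 0.0:
        fitted = np.full(len(mean), located(y))
        return np.maximum(fitted, 0.0)
    order = np.argsort(x)
    bin_size = max(50, n_ok // 20)
    n_bins = max(1, n_ok // bin_size)
    centers, values = [], []
    for b in range(n_bins):
        lo = b * bin_size
        hi = n_ok if b == n_bins - 1 else (b + 1) * bin_size
        idx = order[lo:hi]
        centers.append(float(np.median(x[idx])))
        values.append(located(y[idx]))
    fitted = np.zeros(len(mean))
    if len(centers) == 1:
        fitted[ok] = values[0]
    else:
        fitted[ok] = np.interp(x, np.asarray(centers), np.asarray(values))
    fitted[~ok] = values[0]
    return np.maximum(fitted, 0.0)


def _nb_logpmf(k: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    """log pmf of NB with mean/dispersion parameterization (variance =
    mean + alpha*mean^2); Poisson in the alpha -> 0 limit."""
    k = np.asarray(k)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if alpha <= 0:
        return xlogy(k, mean) - mean - gammaln(k + 1)
    r = 1.0 / alpha
    logp = np.log(r) - np.log(r + mean)
    log1mp = np.log(mean) - np.log(r + mean)
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1) + r * logp + k * log1mp


def _conditional_p(ka: int, kb: int, sa: float, sb: float, alpha: float) -> float:
    """Conditional two-sided exact NB test for one hairpin."""
    k = ka + kb
    if k == 0:
        return 1.0
    q = (ka + kb) / (sa + sb)
    mu_a, mu_b = q * sa, q * sb
    a = np.arange(k + 1)
    lp = _nb_logpmf(a, mu_a, alpha) + _nb_logpmf(k - a, mu_b, alpha)
    total = logsumexp(lp)
    obs = lp[ka]
    keep = lp <= obs + _TIE_TOL
    p = float(np.exp(logsumexp(lp[keep]) - total))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def nb_test(
    t0_counts,
    t1_counts,
    size_factors_=(1.0, 1.0),
    dispersion: float | np.ndarray | pd.Series = 0.0,
) -> pd.Series:
    """Negative-binomial conditional exact test per hairpin.

    ``t0_counts``/``t1_counts`` are per-hairpin counts for the two
    conditions; replicate columns (2-D input) are summed and their size
    factors added, matching the pooled form of the test.
    ``size_factors_`` is a pair of per-condition totals or a pair of
    per-sample vectors.  ``dispersion`` is a scalar or per-hairpin
    vector; zero gives the Poisson (conditional binomial) limit.

    Returns two-sided p-values in (0, 1]: the summed conditional
    probability, given each hairpin's total count, of every T0/T1
    split no more likely than the observed one.
    """
    ka, sa = _collapse(t0_counts, size_factors_[0])
    kb, sb = _collapse(t1_counts, size_factors_[1])
    if len(ka) != len(kb):
        raise ValueError("condition count vectors differ in length")
    if np.any(ka < 0) or np.any(kb < 0):
        raise ValueError("negative counts")
    alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), ka.shape)
    if np.any(alpha < 0):
        raise ValueError("dispersion must be nonnegative")
    index = t0_counts.index if isinstance(t0_counts, (pd.Series, pd.DataFrame)) else None
    p = np.empty(len(ka))
    for i in range(len(ka)):
        p[i] = _conditional_p(int(ka[i]), int(kb[i]), sa, sb, float(alpha[i]))
    return pd.Series(p, index=index, name="pvalue")


def _collapse(counts, sf) -> tuple[np.ndarray, float]:
    """Sum replicate columns and their size factors."""
    arr = counts.to_numpy() if isinstance(counts, (pd.Series, pd.DataFrame)) else np.asarray(counts)
    sf = np.atleast_1d(np.asarray(sf, dtype=float))
    if arr.ndim == 2:
        if len(sf) == 1:
            sf = np.repeat(sf, arr.shape[1])
        if len(sf) != arr.shape[1]:
            raise ValueError("one size factor per replicate column is required")
        return arr.sum(axis=1).astype(np.int64), float(sf.sum())
    return arr.astype(np.int64), float(sf.sum())


def array_ratio_test(probe_intensities_t0, probe_intensities_t1) -> tuple[float, float]:
    """Fold change and p-value for one clone's probe intensities.

    FC is the ratio of the mean probe intensity in the T1 channel to
    that in the T0 channel; the p-value is a two-sided two-sample
    Welch t-test of the probe intensities (null: no fold change).
    """
    x0 = np.asarray(probe_intensities_t0, dtype=float)
    x1 = np.asarray(probe_intensities_t1, dtype=float)
    if x0.size < 2 or x1.size < 2:
        raise ValueError("need at least two probes per channel")
    if x0.mean() == 0:
        raise ValueError("zero mean T0 intensity; fold change undefined")
    fc = x1.mean() / x0.mean()
    if np.ptp(x0) == 0.0 and np.ptp(x1) == 0.0:
        p = 1.0 if x0.mean() == x1.mean() else 0.0
    else:
        _, p = stats.ttest_ind(x1, x0, equal_var=False)
    return float(fc), float(p)


def bh_adjust(p_values) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``padj_(i) = min_{j>=i} (p_(j) * m / j)`` over the sorted p-values,
    capped at 1 and mapped back to the input order.
    """
    is_series = isinstance(p_values, pd.Series)
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    if is_series:
        return pd.Series(out, index=p_values.index, name="padj")
    return out


def call_hits(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Flag hits: absolute fold change of ``fc_threshold`` or greater
    (in either direction) and adjusted p of ``fdr`` or lower.

    Adds/overwrites boolean ``hit`` and categorical ``direction``
    (enriched/depleted/none) columns; bounds are inclusive.
    """
    out = table.copy()
    fc = out["fc"].to_numpy(dtype=float)
    padj = out["padj"].to_numpy(dtype=float)
    changed = (fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)
    out["hit"] = changed & (padj <= fdr)
    direction = np.where(fc >= fc_threshold, "enriched", np.where(fc <= 1.0 / fc_threshold, "depleted", "none"))
    out["direction"] = np.where(out["hit"], direction, "none")
    return out


def ngs_hit_table(
    t0_counts,
    t1_counts,
    size_factors_: pd.Series | None = None,
    dispersion: float | np.ndarray | None = None,
    pseudocount: float = 0.5,
    fc_threshold: float = 2.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full sequencing analysis: normalize, test, adjust, call hits.

    ``t0_counts``/``t1_counts`` are Series (one sample) or DataFrames
    (replicate columns).  Size factors default to median-of-ratios on
    the combined matrix; dispersion defaults to a blind estimate
    across all samples (the only option when each condition has a
    single sample).  Fold changes are ratios of normalized mean counts
    with ``pseudocount`` added to both conditions.

    Returns a table with columns ``fc, log2_ratio, log2_mean, pvalue,
    padj, hit, direction``.
    """
    t0 = pd.DataFrame(t0_counts)
    t1 = pd.DataFrame(t1_counts)
    combined = pd.concat([t0, t1], axis=1)
    if combined.columns.duplicated().any():
        combined.columns = [f"s{i}" for i in range(combined.shape[1])]
    sf = size_factors(combined) if size_factors_ is None else pd.Series(size_factors_)
    sf0, sf1 = sf.iloc[: t0.shape[1]].to_numpy(), sf.iloc[t0.shape[1] :].to_numpy()
    if dispersion is None:
        dispersion = estimate_dispersion(combined, sf.to_numpy(), mode="blind").to_numpy()

    pvals = nb_test(t0, t1, (sf0, sf1), dispersion)
    q0 = t0.to_numpy().sum(axis=1) / sf0.sum()
    q1 = t1.to_numpy().sum(axis=1) / sf1.sum()
    fc = (q1 + pseudocount) / (q0 + pseudocount)
    log2_ratio = np.log2(fc)
    log2_mean = 0.5 * (np.log2(q1 + pseudocount) + np.log2(q0 + pseudocount))
    table = pd.DataFrame(
        {
            "fc": fc,
            "log2_ratio": log2_ratio,
            "log2_mean": log2_mean,
            "pvalue": pvals.to_numpy(),
            "padj": bh_adjust(pvals.to_numpy()),
        },
        index=t0.index,
    )
    return call_hits(table, fc_threshold, fdr)


def array_hit_table(
    probes_t0: pd.DataFrame | list[pd.DataFrame],
    probes_t1: pd.DataFrame | list[pd.DataFrame],
    pseudocount: float = 0.5,
    fc_threshold: float = 2.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full array analysis: per-clone Welch test on probe intensities.

    ``probes_t0``/``probes_t1`` are clones-by-probes DataFrames of
    linear (background-subtracted) intensities; lists of frames
    (technical replicates) are pooled column-wise.  Returns the same
    hit-table layout as :func:`ngs_hit_table`.
    """
    x0 = _stack_probes(probes_t0)
    x1 = _stack_probes(probes_t1)
    index = (probes_t0[0] if isinstance(probes_t0, list) else probes_t0).index
    if x0.shape[1] < 2 or x1.shape[1] < 2:
        raise ValueError("need at least two probes per channel")
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(x1, x0, axis=1, equal_var=False)
    degenerate = (np.ptp(x0, axis=1) == 0) & (np.ptp(x1, axis=1) == 0)
    p = np.where(degenerate, np.where(m0 == m1, 1.0, 0.0), p)
    p = np.nan_to_num(p, nan=1.0)
    fc = (m1 + pseudocount) / (m0 + pseudocount)
    table = pd.DataFrame(
        {
            "fc": fc,
            "log2_ratio": np.log2(fc),
            "log2_mean": 0.5 * (np.log2(m1 + pseudocount) + np.log2(m0 + pseudocount)),
            "pvalue": p,
            "padj": bh_adjust(p),
        },
        index=index,
    )
    return call_hits(table, fc_threshold, fdr)


def _stack_probes(probes) -> np.ndarray:
    if isinstance(probes, list):
        return np.hstack([f.to_numpy(dtype=float) for f in probes])
    return probes.to_numpy(dtype=float)
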