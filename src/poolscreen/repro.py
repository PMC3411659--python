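"""Replicate-reproducibility metrics for pooled screens.

A screen's quality is read off three statistics computed between
replicates: the Pearson correlation of per-hairpin log10(T1/T0)
ratios, the overlap of the hit lists (percent of the smaller list),
and the minimum fold range spanned by 70% of the library's abundance
distribution (a skew statistic — small means the protocol preserved
library representation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats


def log_ratio(
    t1_norm,
    t0_norm,
    pseudocount: float = 0.5,
    keep: np.ndarray | pd.Series | None = None,
) -> pd.Series | np.ndarray:
    """Per-hairpin log10((t1 + pc) / (t0 + pc)) of normalized abundances.

    ``keep`` is an optional boolean signal filter (e.g. the array
    platform's "T0 signal above two-fold median background" rule);
    excluded hairpins get NaN so they drop out of correlations.
    """
    t1 = np.asarray(t1_norm, dtype=float)
    t0 = np.asarray(t0_norm, dtype=float)
    if t1.shape != t0.shape:
        raise ValueError("t1 and t0 must have equal length")
    if np.any(t1 < 0) or np.any(t0 < 0):
        raise ValueError("abundances must be nonnegative")
    lr = np.log10((t1 + pseudocount) / (t0 + pseudocount))
    if keep is not None:
        lr = np.where(np.asarray(keep, dtype=bool), lr, np.nan)
    if isinstance(t1_norm, pd.Series):
        return pd.Series(lr, index=t1_norm.index, name="log10_ratio")
    return lr


def pearson_log_ratio(lr_a, lr_b) -> float:
    """Pearson R of two replicates' log-ratio vectors.

    Computed on the intersection of finite entries; requires at least
    three paired values and nonzero variance in both.
    """
    a = np.asarray(lr_a, dtype=float)
    b = np.asarray(lr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least three paired finite values")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("zero variance in a replicate; correlation undefined")
    r, _ = stats.pearsonr(a, b)
    return float(r)


def overlap_stats(hits_a, hits_b) -> tuple[int, int, int, float | None]:
    """Hit-list overlap between two replicates.

    Returns ``(n_a, n_b, n_overlap, percent_overlap)`` where the
    percentage uses the smaller list as denominator —
    ``100 * |A ∩ B| / min(|A|, |B|)`` — the convention under which two
    nested lists overlap 100%.  The percentage is None when either
    list is empty; raw counts are always reported.
    """
    a, b = set(hits_a), set(hits_b)
    n_overlap = len(a & b)
    if not a or not b:
        return len(a), len(b), n_overlap, None
    return len(a), len(b), n_overlap, 100.0 * n_overlap / min(len(a), len(b))


def unique_fraction(hits_a, hits_b) -> float:
    """Percent of A's hits absent from B: ``100 * |A \\ B| / |A|``."""
    a, b = set(hits_a), set(hits_b)
    if not a:
        raise ValueError("A is empty; unique fraction undefined")
    return 100.0 * len(a - b) / len(a)


def min_fold_range(abundances, fraction: float = 0.7) -> float:
    """Minimum fold range covering ``fraction`` of the population.

    Selects the ``ceil(fraction * n)`` hairpins whose abundances span
    the smallest max/min ratio and returns that ratio.  On sorted
    values the optimum is a contiguous window, so the search is a
    single sliding-window pass.  Zeros are excluded with a warning
    (the ratio is undefined for them).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be nonnegative")
    if np.any(x == 0):
        warnings.warn("excluding zero abundances from fold-range computation")
        x = x[x > 0]
    if x.size < 2:
        raise ValueError("need at least two positive abundances")
    x = np.sort(x)
    k = math.ceil(fraction * x.size)
    if k < 2:
        return 1.0
    ratios = x[k - 1 :] / x[: x.size - k + 1]
    return float(ratios.min())


@dataclass
class ReproReport:
    """Pairwise replicate comparison summary."""

    pair: str
    pearson_r: float
    n_hits_1: int
    n_hits_2: int
    n_overlap: int
    percent_overlap: float | None
    percent_unique_1: float | None
    range_fold_1: float | None = None
    range_fold_2: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def repro_report(
    lr_a,
    lr_b,
    hits_a,
    hits_b,
    abundances_a=None,
    abundances_b=None,
    pair: str = "A_vs_B",
    range_fraction: float = 0.7,
) -> ReproReport:
    """Bundle the standard replicate comparison into one report:
    Pearson R of log ratios, hit overlap, and per-sample abundance
    ranges (when abundances are supplied)."""
    n_a, n_b, n_ov, pct = overlap_stats(hits_a, hits_b)
    uniq = unique_fraction(hits_a, hits_b) if n_a else None
    return ReproReport(
        pair=pair,
        pearson_r=pearson_log_ratio(lr_a, lr_b),
        n_hits_1=n_a,
        n_hits_2=n_b,
        n_overlap=n_ov,
        percent_overlap=pct,
        percent_unique_1=uniq,
        range_fold_1=(
            min_fold_range(abundances_a, range_fraction) if abundances_a is not None else None
        ),
        range_fold_2=(
            min_fold_range(abundances_b, range_fraction) if abundances_b is not None else None
        ),
    )
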