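"""Locating the exponential-to-linear transition of the deconvolution PCR.

Replicate high-fidelity PCR reactions are stopped at successive cycle
numbers, and each stopped product is diluted and re-measured by SYBR
qPCR.  While the high-fidelity reaction is still doubling, the SYBR Cq
drops by one doubling per stop-cycle; once amplification leaves the
exponential phase the per-cycle Cq drop shrinks below that.  Because
real SYBR primers are not 100% efficient, one observed Cq unit does not
equal one doubling: the efficiency correction factor

    E_c = log base (1 + efficiency) of 2

converts observed ΔCq into doubling units (E_c = 1.38 for 65% efficient
primers).  The last cycle whose corrected ΔCq still reaches 1 is the
recommended amplification cycle count.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("stop_cycle", "dilution", "replicate", "cq")


def efficiency_correction_factor(efficiency_pct: float) -> float:
    """ΔCq observed per true doubling: log base (1+eff) of 2.

    Strictly decreasing in efficiency; equals 1 at 100%.
    """
    if not 0.0 < efficiency_pct <= 100.0:
        raise ValueError("efficiency must lie in (0, 100] percent")
    return math.log(2.0) / math.log(1.0 + efficiency_pct / 100.0)


def corrected_delta_cq(
    panel: pd.DataFrame,
    efficiency_pct: float = 100.0,
    step: int = 1,
) -> pd.DataFrame:
    """Per-cycle, efficiency-corrected mean ΔCq series from a stop-cycle panel.

    Within each dilution, replicate Cq values are averaged per
    stop-cycle and the absolute difference between stop-cycles ``N``
    and ``N+step`` is taken; these differences are averaged across
    dilutions (the dilution factors cancel in the subtraction), divided
    by the efficiency correction factor, and divided by ``step`` so the
    series reads in doublings per cycle regardless of the panel's
    spacing.

    Returns a DataFrame indexed by the pair's starting cycle ``N`` with
    columns ``delta_cq`` (corrected, per cycle), ``raw_delta_cq``
    (uncorrected mean |ΔCq| for the pair), ``signed_delta_cq``
    (diagnostic: without the absolute value) and ``n_dilutions``.
    Cycle pairs missing in some dilution use the dilutions that have
    them; pairs missing everywhere are skipped with a warning.
    """
    if step < 1:
        raise ValueError("step must be a positive integer")
    missing = set(REQUIRED_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    ec = efficiency_correction_factor(efficiency_pct)

    mean_cq = panel.groupby(["dilution", "stop_cycle"])["cq"].mean()
    cycles = sorted(panel["stop_cycle"].unique())
    if len(cycles) < 2:
        raise ValueError("panel must cover at least two stop-cycles")

    rows = []
    for n in cycles:
        if n + step not in cycles:
            continue
        diffs, signed = [], []
        for d in panel["dilution"].unique():
            try:
                a, b = mean_cq[(d, n)], mean_cq[(d, n + step)]
            except KeyError:
                continue
            signed.append(a - b)  # Cq drops as product grows
            diffs.append(abs(a - b))
        if not diffs:
            warnings.warn(f"no dilution covers the cycle pair {n}->{n + step}; skipped")
            continue
        raw = float(np.mean(diffs))
        rows.append((n, raw / ec / step, raw, float(np.mean(signed)) / ec / step, len(diffs)))
    if not rows:
        raise ValueError("no evaluable cycle pairs in panel")
    out = pd.DataFrame(
        rows, columns=["cycle", "delta_cq", "raw_delta_cq", "signed_delta_cq", "n_dilutions"]
    ).set_index("cycle")
    out.attrs["step"] = step
    return out


def call_transition_cycle(
    series: pd.DataFrame | pd.Series,
    threshold: float = 1.0,
    tolerance: float = 0.05,
) -> int:
    """Last exponential cycle from a corrected ΔCq series.

    Walks the cycle pairs in order; while every pair's corrected ΔCq
    stays at or above ``threshold - tolerance`` the reaction is still
    doubling.  Returns the starting cycle of the first sub-threshold
    pair (the last cycle with full doubling behind it); if no pair
    falls below, returns the final cycle the panel measured.  A series
    that starts below threshold raises, as no exponential window was
    observed.

    ``tolerance`` is the noise allowance on the ΔCq = 1 doubling rule;
    scale it to the replicate scatter of the panel (a few standard
    errors of the averaged series).
    """
    if isinstance(series, pd.DataFrame):
        step = series.attrs.get("step", 1)
        values = series["delta_cq"]
    else:
        step = series.attrs.get("step", 1) if hasattr(series, "attrs") else 1
        values = series
    if len(values) == 0:
        raise ValueError("empty ΔCq series")
    cutoff = threshold - tolerance
    start_cycles = list(values.index)
    if values.iloc[0] < cutoff:
        raise ValueError("no exponential window detected: series starts below threshold")
    for n, v in values.items():
        if v < cutoff:
            return int(n)
    return int(start_cycles[-1] + step)
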