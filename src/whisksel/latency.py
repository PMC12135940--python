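"""Reaction-time extraction and baseline-rate-to-latency correlation.

Lick latency is the time from first touch to the first subsequent lick.
Per unit, the per-trial pre-touch baseline rate (1.5 s window) on Hit
trials is correlated with latency; a population one-sample t-test over the
per-unit coefficients asks whether spontaneous rate predicts reaction time
(negative r: higher baseline, faster lick).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .core import Trial

__all__ = ["lick_latency", "UnitLatencyCorrelation", "baseline_latency_correlation",
           "population_latency_test"]


def lick_latency(trial: Trial) -> float | None:
    """First lick strictly after first touch, minus first touch; None when
    no qualifying lick exists (including lick-before-touch-only trials)."""
    after = trial.lick_times[trial.lick_times > trial.first_touch]
    if after.size == 0:
        return None
    return float(after[0] - trial.first_touch)


@dataclass
class UnitLatencyCorrelation:
    unit_id: str
    r: float
    p: float
    n_trials: int
    method: str
    flagged: bool = False  # zero-variance rate or latency


def baseline_latency_correlation(baseline_rates: np.ndarray, latencies: np.ndarray,
                                 method: str = "pearson",
                                 unit_id: str = "") -> UnitLatencyCorrelation:
    """Correlate one unit's per-Hit-trial baseline rates with lick latencies.

    Trials with undefined latency must be excluded by the caller (pairwise
    deletion, no imputation). Requires >= 10 trials; zero-variance input
    flags the unit with r = NaN.
    """
    rates = np.asarray(baseline_rates, float)
    lat = np.asarray(latencies, float)
    if rates.size != lat.size:
        raise ValueError("rates and latencies must be paired")
    if rates.size < 10:
        raise ValueError("need >= 10 Hit trials with defined latency")
    if np.ptp(rates) == 0 or np.ptp(lat) == 0:
        return UnitLatencyCorrelation(unit_id, np.nan, np.nan, rates.size,
                                      method, flagged=True)
    if method == "pearson":
        r, p = sstats.pearsonr(rates, lat)
    elif method == "spearman":
        r, p = sstats.spearmanr(rates, lat)
    else:
        raise ValueError(f"unknown method {method!r}")
    return UnitLatencyCorrelation(unit_id, float(r), float(p), rates.size, method)


def population_latency_test(correlations: list[UnitLatencyCorrelation]) -> tuple[float, float]:
    """One-sample t-test of per-unit r values against 0: (mean r, p)."""
    rs = np.array([c.r for c in correlations if not c.flagged and np.isfinite(c.r)])
    if rs.size < 2:
        raise ValueError("need >= 2 unflagged units")
    t, p = sstats.ttest_1samp(rs, 0.0)
    return float(rs.mean()), float(p)
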