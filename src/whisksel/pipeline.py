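"""Session-level orchestration of the analysis stages.

These helpers wire the primitive operations together the way the full
analysis runs: bin and z-score against the engaged-trial baseline, classify
units (responsive / preference / touch effect), build trial-averaged
z-scored traces, run the facilitation-suppression lag analysis, the
context-modulation contrasts, and the baseline-rate-to-latency correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnalysisWindows, Session
from .dynamics import LagResult, xcorr_min_lag
from .latency import (UnitLatencyCorrelation, baseline_latency_correlation,
                      lick_latency, population_latency_test)
from .rates import RateTensor, build_rate_tensor, window_rate, zscore
from .selectivity import (BiasSeries, UnitClass, bias_series_from_tensor,
                          classify_preference, classify_responsive,
                          classify_touch_effect, filter_disengaged_cr)

__all__ = ["SessionAnalysis", "analyze_session", "cr_response_traces",
           "lag_analysis", "cr_baseline_bias", "latency_analysis",
           "bias_table", "class_table"]


@dataclass
class SessionAnalysis:
    """Per-session tensors, trial selections, and unit classifications."""

    session: Session
    windows: AnalysisWindows
    tensor: RateTensor  # raw, 10 ms bins over [baseline_start, response_end)
    ztensor: RateTensor  # z-scored on the engaged-trial baseline
    hit_ids: list[int]
    cr_ids: list[int]  # CR trials retained by the disengagement filter
    engaged_ids: list[int]
    classes: list[UnitClass]
    bias: list[BiasSeries]  # Hit-vs-CR stimulus bias (raw rates)


def engaged_trial_ids(session: Session) -> tuple[list[int], list[int], list[int]]:
    """(hit_ids, retained_cr_ids, engaged_ids) for one session.

    "Engaged" trials are Hits plus the CR trials surviving the
    consecutive-miss disengagement filter; detection sessions use Hits of
    both stimuli and have no CRs.
    """
    hits = [tr.trial_id for tr in session.trials if tr.outcome == "Hit"]
    # The disengagement filter runs over Home trials only: Away trials deny
    # the response by design (the mouse stays engaged), so they neither count
    # toward consecutive misses nor enter the engaged pool.
    home = [tr for tr in session.trials if tr.context == "Home"]
    retained = filter_disengaged_cr(home)
    crs = [tr.trial_id for tr in retained if tr.outcome == "CR"]
    return hits, crs, hits + crs


def analyze_session(session: Session,
                    windows: AnalysisWindows | None = None) -> SessionAnalysis:
    """Bin, z-score, and classify every unit of one session."""
    windows = windows or AnalysisWindows()
    hit_ids, cr_ids, engaged_ids = engaged_trial_ids(session)
    span = (windows.baseline[0], windows.response[1])
    tensor = build_rate_tensor(session, span, windows.bias_bin)
    ztensor = zscore(tensor, windows, reference_trials=engaged_ids)

    if session.task == "detection":
        # condition A = whisker 1 (positive alias), B = whisker 2
        a_ids = [tr.trial_id for tr in session.trials
                 if tr.stimulus == "positive" and tr.outcome == "Hit"]
        b_ids = [tr.trial_id for tr in session.trials
                 if tr.stimulus == "negative" and tr.outcome == "Hit"]
    else:
        a_ids, b_ids = hit_ids, cr_ids

    resp_rates = window_rate(tensor, windows.response)
    base_rates = window_rate(tensor, windows.baseline)
    idx_a = tensor.trial_index(a_ids)
    idx_b = tensor.trial_index(b_ids)
    idx_eng = tensor.trial_index(engaged_ids if session.task == "discrimination"
                                 else a_ids + b_ids)

    bias = bias_series_from_tensor(tensor, a_ids, b_ids, windows=windows)
    classes: list[UnitClass] = []
    for i, uid in enumerate(tensor.unit_ids):
        try:
            responsive = classify_responsive(
                base_rates[i, idx_eng], resp_rates[i, idx_a], resp_rates[i, idx_b]
            )
        except ValueError:
            responsive = False
        pref = classify_preference(bias[i], windows) if responsive else "none"
        try:
            effect = classify_touch_effect(resp_rates[i, idx_b], base_rates[i, idx_b])
        except ValueError:
            effect = "neither"
        classes.append(
            UnitClass(
                unit_id=uid,
                responsive=responsive,
                preference=pref,
                touch_effect=effect,
                baseline_rate=float(base_rates[i, idx_eng].mean()),
                mouse_id=session.mouse_id,
            )
        )
    return SessionAnalysis(session=session, windows=windows, tensor=tensor,
                           ztensor=ztensor, hit_ids=hit_ids, cr_ids=cr_ids,
                           engaged_ids=engaged_ids, classes=classes, bias=bias)


def cr_response_traces(analysis: SessionAnalysis) -> tuple[dict, dict]:
    """Trial-averaged z-scored CR-response traces (0-300 ms) of the
    touch-facilitated and touch-suppressed populations."""
    win = analysis.windows.response
    centers = analysis.ztensor.bin_centers
    bins = (centers >= win[0]) & (centers < win[1])
    idx_cr = analysis.ztensor.trial_index(analysis.cr_ids)
    facilitated, suppressed = {}, {}
    for i, (uid, cls) in enumerate(zip(analysis.ztensor.unit_ids, analysis.classes)):
        trace = analysis.ztensor.values[i][np.ix_(idx_cr, np.where(bins)[0])].mean(axis=0)
        if cls.touch_effect == "facilitated":
            facilitated[uid] = trace
        elif cls.touch_effect == "suppressed":
            suppressed[uid] = trace
    return facilitated, suppressed


def lag_analysis(analysis: SessionAnalysis, max_lag: float = 0.3) -> LagResult:
    """Facilitation-to-suppression lag from all facilitated x suppressed pairs."""
    facilitated, suppressed = cr_response_traces(analysis)
    return xcorr_min_lag(facilitated, suppressed, bin=analysis.windows.bias_bin,
                         max_lag=max_lag, mouse_id=analysis.session.mouse_id)


def cr_baseline_bias(analysis: SessionAnalysis,
                     preference: str = "positive") -> list[BiasSeries]:
    """Per-unit bias of the CR response relative to the pre-touch baseline,
    restricted to units of the given preference."""
    keep = [i for i, c in enumerate(analysis.classes) if c.preference == preference]
    series = bias_series_from_tensor(analysis.tensor, analysis.cr_ids, "baseline",
                                     windows=analysis.windows)
    return [series[i] for i in keep]


def latency_analysis(analysis: SessionAnalysis,
                     method: str = "pearson") -> list[UnitLatencyCorrelation]:
    """Per-unit correlation of Hit-trial baseline rate with lick latency."""
    session = analysis.session
    lat_by_id = {}
    for tr in session.trials:
        if tr.outcome == "Hit":
            lat = lick_latency(tr)
            if lat is not None:
                lat_by_id[tr.trial_id] = lat
    ids = [t for t in analysis.tensor.trial_ids if t in lat_by_id]
    idx = analysis.tensor.trial_index(ids)
    lats = np.array([lat_by_id[t] for t in ids])
    base = window_rate(analysis.tensor, analysis.windows.baseline)
    out = []
    for i, uid in enumerate(analysis.tensor.unit_ids):
        out.append(baseline_latency_correlation(base[i, idx], lats,
                                                method=method, unit_id=uid))
    return out


def bias_table(analysis: SessionAnalysis) -> pd.DataFrame:
    """Long-format per-unit bias series for writing with write_results."""
    rows = []
    for series in analysis.bias:
        for t, d in zip(series.bin_centers, series.dprime):
            rows.append({"unit_id": series.unit_id,
                         "mouse_id": analysis.session.mouse_id,
                         "time_s": t, "dprime": d})
    return pd.DataFrame(rows)


def class_table(analysis: SessionAnalysis) -> pd.DataFrame:
    rows = [
        {
            "unit_id": c.unit_id,
            "mouse_id": c.mouse_id,
            "responsive": c.responsive,
            "preference": c.preference,
            "touch_effect": c.touch_effect,
            "baseline_rate": c.baseline_rate,
        }
        for c in analysis.classes
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multi-session experiments (parameter recovery on synthetic fleets)
# ---------------------------------------------------------------------------

def pooled_min_lag(profile: str, seeds, n_units: int = 64,
                   n_trials: int = 512) -> tuple[float, int]:
    """Pooled facilitation-to-suppression lag over seeded sessions.

    Generates one discrimination session per seed with the given region
    profile, classifies units facilitated/suppressed against baseline on CR
    trials, cross-correlates every pair's trial-averaged z-scored response
    in 10 ms bins over +-300 ms, and returns (mean pair lag in seconds,
    number of pairs pooled over seeds).
    """
    from .synth import GeneratorConfig, generate_session

    lags: list[float] = []
    for seed in seeds:
        cfg = GeneratorConfig(region_profile=profile, n_units=n_units,
                              n_trials=n_trials, seed=int(seed))
        session, _ = generate_session(cfg)
        analysis = analyze_session(session)
        res = lag_analysis(analysis)
        lags.extend(l for _, _, l in res.pair_lags)
    return float(np.mean(lags)), len(lags)


def cr_crossing_time(seeds, n_units: int = 64, n_trials: int = 512) -> tuple[float | None, int]:
    """First 10 ms bin at which the population-mean CR-vs-baseline bias of
    positive-preferring SC-like units becomes and stays negative.

    Returns (bin center in seconds, number of units pooled); None when the
    mean never settles below zero.
    """
    from .synth import GeneratorConfig, generate_session

    series: list[np.ndarray] = []
    centers = None
    for seed in seeds:
        cfg = GeneratorConfig(region_profile="SC_like", n_units=n_units,
                              n_trials=n_trials, seed=int(seed))
        session, _ = generate_session(cfg)
        analysis = analyze_session(session)
        for b in cr_baseline_bias(analysis):
            series.append(b.dprime)
            centers = b.bin_centers
    mean = np.mean(series, axis=0)
    for i in range(mean.size):
        if (mean[i:] < 0).all():
            return float(centers[i]), len(series)
    return None, len(series)


def hit_latency_tail(seeds, threshold: float = 0.3, n_units: int = 4,
                     n_trials: int = 512) -> tuple[float, int]:
    """Fraction of pooled Hit-trial lick latencies exceeding ``threshold``.

    Latencies are extracted from generated sessions exactly as from real
    ones: first lick after first touch. Unit count does not enter the
    latency model; a small population keeps the fleet cheap.
    """
    from .synth import GeneratorConfig, generate_session

    lats: list[float] = []
    for seed in seeds:
        cfg = GeneratorConfig(n_units=n_units, n_trials=n_trials, seed=int(seed))
        session, _ = generate_session(cfg)
        for tr in session.trials:
            if tr.outcome == "Hit":
                lat = lick_latency(tr)
                if lat is not None:
                    lats.append(lat)
    lats_arr = np.array(lats)
    return float(np.mean(lats_arr > threshold)), lats_arr.size
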