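"""Stimulus-bias (neurometric d-prime), neuron classification, trial filters,
and population preference statistics.

The stimulus bias of a unit at one time bin is

    bias = (mu_A - mu_B) / sqrt((var_A + var_B) / 2)

where mu and var are the mean and across-trial variance of the binned firing
rate under conditions A and B. Positive values indicate preference for
condition A (the positive/rewarded stimulus, by convention). The series is
evaluated in non-overlapping 10 ms bins through the 300 ms response window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .core import AnalysisWindows, Trial
from .rates import ConditionRateSample, RateTensor, window_rate

__all__ = [
    "DPRIME_CAP",
    "BiasSeries",
    "UnitClass",
    "stimulus_bias",
    "bias_from_baseline",
    "bias_series_from_tensor",
    "classify_responsive",
    "classify_preference",
    "classify_touch_effect",
    "filter_disengaged_cr",
    "population_preference_stats",
    "PreferenceStats",
    "group_by_baseline_rate",
    "behavioral_dprime",
]

#: cap applied when both variances are zero but the means differ; such bins
#: are flagged as degenerate rather than left infinite.
DPRIME_CAP = 10.0


@dataclass
class BiasSeries:
    """Per-unit time-resolved d-prime with analysis-window summaries."""

    unit_id: str
    bin_centers: np.ndarray  # seconds relative to first touch
    dprime: np.ndarray
    window_means: dict[str, float] = field(default_factory=dict)
    degenerate_bins: np.ndarray | None = None  # bool mask of capped bins

    def mean_in(self, window: tuple[float, float]) -> float:
        m = (self.bin_centers >= window[0]) & (self.bin_centers < window[1])
        return float(self.dprime[m].mean())


@dataclass
class UnitClass:
    """Classification labels for one unit."""

    unit_id: str
    responsive: bool
    preference: str  # positive | negative | none
    touch_effect: str = "neither"  # facilitated | suppressed | neither
    baseline_rate: float = np.nan  # bfr, sp/s
    baseline_group: int | None = None
    mouse_id: str = ""

    def __post_init__(self) -> None:
        if (self.preference == "none") != (not self.responsive) and self.responsive \
                and self.preference not in ("positive", "negative", "none"):
            raise ValueError("invalid preference label")
        if not self.responsive and self.preference != "none":
            raise ValueError("non-responsive units must have preference 'none'")


def _dprime_core(mu_a, var_a, mu_b, var_b):
    mu_a = np.asarray(mu_a, dtype=float)
    mu_b = np.asarray(mu_b, dtype=float)
    var_a = np.asarray(var_a, dtype=float)
    var_b = np.asarray(var_b, dtype=float)
    denom = np.sqrt((var_a + var_b) / 2.0)
    diff = mu_a - mu_b
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, denom))
    d = np.where(degenerate & (diff != 0), np.sign(diff) * DPRIME_CAP, d)
    return d, degenerate & (diff != 0)


def stimulus_bias(a: list[ConditionRateSample], b: list[ConditionRateSample],
                  bin_centers: np.ndarray | None = None,
                  unit_id: str = "", windows: AnalysisWindows | None = None) -> BiasSeries:
    """Per-bin d-prime between condition A and condition B samples.

    Both conditions need >= 2 trials in every bin. Bins where both variances
    vanish give 0 when the means agree, else sign(diff) * DPRIME_CAP
    (flagged in ``degenerate_bins``).
    """
    if len(a) != len(b):
        raise ValueError("condition series must have equal length")
    for name, cond in (("A", a), ("B", b)):
        if any(s.n_trials < 2 for s in cond):
            raise ValueError(f"condition {name} has a bin with fewer than 2 trials")
    d, degen = _dprime_core(
        [s.mu for s in a], [s.var for s in a], [s.mu for s in b], [s.var for s in b]
    )
    if bin_centers is None:
        bin_centers = np.arange(len(a), dtype=float)
    windows = windows or AnalysisWindows()
    series = BiasSeries(unit_id=unit_id, bin_centers=np.asarray(bin_centers, float),
                        dprime=np.atleast_1d(d), degenerate_bins=np.atleast_1d(degen))
    for name in ("response", "early", "late"):
        win = getattr(windows, name)
        mask = (series.bin_centers >= win[0]) & (series.bin_centers < win[1])
        if mask.any():
            series.window_means[name] = float(series.dprime[mask].mean())
    return series


def bias_from_baseline(cond: list[ConditionRateSample], base: ConditionRateSample,
                       bin_centers: np.ndarray | None = None, unit_id: str = "",
                       windows: AnalysisWindows | None = None) -> BiasSeries:
    """d-prime of a condition against the (single) pre-touch baseline sample."""
    return stimulus_bias(cond, [base] * len(cond), bin_centers=bin_centers,
                         unit_id=unit_id, windows=windows)


def _condition_samples(tensor: RateTensor, unit_index: int,
                       trial_idx: np.ndarray, bins: np.ndarray) -> list[ConditionRateSample]:
    sub = tensor.values[unit_index][np.ix_(trial_idx, bins)]
    return [
        ConditionRateSample(mu=float(sub[:, j].mean()), var=float(sub[:, j].var(ddof=1)),
                            n_trials=sub.shape[0])
        for j in range(sub.shape[1])
    ]


def baseline_sample(tensor: RateTensor, unit_index: int, trial_idx: np.ndarray,
                    windows: AnalysisWindows | None = None) -> ConditionRateSample:
    """Baseline-window bin rates pooled over trials, as one condition sample.

    Pooling individual bins (rather than per-trial window means) keeps the
    variance on the same per-bin scale as the condition series it is
    compared against, so bias-from-baseline is dimensionally comparable to
    stimulus bias."""
    windows = windows or AnalysisWindows()
    centers = tensor.bin_centers
    bins = np.where((centers >= windows.baseline[0]) & (centers < windows.baseline[1]))[0]
    pooled = tensor.values[unit_index][np.ix_(trial_idx, bins)].ravel()
    return ConditionRateSample(mu=float(pooled.mean()),
                               var=float(pooled.var(ddof=1)),
                               n_trials=trial_idx.size)


def bias_series_from_tensor(tensor: RateTensor, trials_a: list[int], trials_b,
                            windows: AnalysisWindows | None = None,
                            window: tuple[float, float] | None = None) -> list[BiasSeries]:
    """Convenience: per-unit bias series from a tensor and two trial-id sets.

    ``trials_b`` may be a list of trial ids (condition-vs-condition) or the
    string ``"baseline"`` (condition-vs-pre-touch-baseline, using the A
    trials' own baseline sample).
    """
    windows = windows or AnalysisWindows()
    window = window or windows.response
    centers = tensor.bin_centers
    bins = np.where((centers >= window[0]) & (centers < window[1]))[0]
    idx_a = tensor.trial_index(trials_a)
    against_baseline = isinstance(trials_b, str) and trials_b == "baseline"
    idx_b = None if against_baseline else tensor.trial_index(trials_b)
    out = []
    for i, uid in enumerate(tensor.unit_ids):
        a = _condition_samples(tensor, i, idx_a, bins)
        if against_baseline:
            series = bias_from_baseline(a, baseline_sample(tensor, i, idx_a, windows),
                                        bin_centers=centers[bins], unit_id=uid,
                                        windows=windows)
        else:
            b = _condition_samples(tensor, i, idx_b, bins)
            series = stimulus_bias(a, b, bin_centers=centers[bins], unit_id=uid,
                                   windows=windows)
        out.append(series)
    return out


def classify_responsive(baseline: np.ndarray, stim_a: np.ndarray,
                        stim_b: np.ndarray, alpha: float = 0.05) -> bool:
    """Touch responsiveness: one-way ANOVA over {baseline, stim A, stim B}
    per-trial window rates, then Tukey HSD; responsive iff a baseline-vs-
    stimulus contrast (not A-vs-B) is significant at ``alpha``.

    Requires >= 5 trials per group. Degenerate (zero overall variance)
    groups yield not-responsive.
    """
    groups = [np.asarray(g, float) for g in (baseline, stim_a, stim_b)]
    if any(g.size < 5 for g in groups):
        raise ValueError("classify_responsive requires >= 5 trials per group")
    if np.ptp(np.concatenate(groups)) == 0:
        return False
    try:
        res = sstats.tukey_hsd(*groups)
    except Exception:
        return False
    # groups: 0=baseline, 1=stimA, 2=stimB; test the two baseline contrasts
    p_a = res.pvalue[0, 1]
    p_b = res.pvalue[0, 2]
    return bool(min(p_a, p_b) < alpha)


def classify_preference(bias: BiasSeries, windows: AnalysisWindows | None = None) -> str:
    """Preference from the sign of the mean response-window bias.

    Exact zero means yield ``none`` (tie, flagged by the caller).
    """
    windows = windows or AnalysisWindows()
    mean_bias = bias.window_means.get("response")
    if mean_bias is None:
        mean_bias = bias.mean_in(windows.response)
    if mean_bias > 0:
        return "positive"
    if mean_bias < 0:
        return "negative"
    return "none"


def classify_touch_effect(response: np.ndarray, baseline: np.ndarray,
                          alpha: float = 0.05) -> str:
    """Touch facilitation/suppression: paired two-sided t-test on per-trial
    response-minus-baseline rates; the sign of the mean difference sets the
    label. Zero-variance differences give ``neither``."""
    response = np.asarray(response, float)
    baseline = np.asarray(baseline, float)
    if response.size != baseline.size:
        raise ValueError("paired samples must be equal length")
    if response.size < 5:
        raise ValueError("classify_touch_effect requires >= 5 trials")
    diff = response - baseline
    if np.ptp(diff) == 0:
        return "neither"
    t, p = sstats.ttest_rel(response, baseline)
    if p < alpha:
        return "facilitated" if diff.mean() > 0 else "suppressed"
    return "neither"


def filter_disengaged_cr(trials: list[Trial], min_misses: int = 5) -> list[Trial]:
    """Remove CR trials that fall in disengagement windows.

    A disengagement window is a maximal run of consecutive no-lick trials
    (Miss or CR) containing at least ``min_misses`` Miss trials; CR trials
    inside such a run are dropped, everything else is kept in order. CRs
    inside a run count as members of the run but not toward the Miss count.
    """
    keep = [True] * len(trials)
    run: list[int] = []

    def _close_run() -> None:
        n_miss = sum(1 for j in run if trials[j].outcome == "Miss")
        if n_miss >= min_misses:
            for j in run:
                if trials[j].outcome == "CR":
                    keep[j] = False

    for i, tr in enumerate(trials):
        if tr.outcome in ("Miss", "CR"):
            run.append(i)
        else:
            _close_run()
            run = []
    _close_run()
    return [tr for tr, k in zip(trials, keep) if k]


@dataclass
class PreferenceStats:
    n_positive: int
    n_negative: int
    fraction_positive: float
    gof_chi2: float
    gof_p: float
    homogeneity_chi2: float | None = None
    homogeneity_p: float | None = None
    single_mouse: bool = False


def population_preference_stats(classes: list[UnitClass],
                                by_mouse: bool = True) -> PreferenceStats:
    """Preference skew of a unit population.

    Reports the positive-preferring fraction, a goodness-of-fit chi-squared
    against a 50/50 split, and (given >= 2 mice) a homogeneity chi-squared
    over the mouse x preference contingency table.
    """
    labeled = [c for c in classes if c.preference in ("positive", "negative")]
    if len(labeled) < 2:
        raise ValueError("need >= 2 preference-labeled units")
    n_pos = sum(1 for c in labeled if c.preference == "positive")
    n_neg = len(labeled) - n_pos
    chi2, p = sstats.chisquare([n_pos, n_neg])
    out = PreferenceStats(
        n_positive=n_pos, n_negative=n_neg,
        fraction_positive=n_pos / len(labeled),
        gof_chi2=float(chi2), gof_p=float(p),
    )
    mice = sorted({c.mouse_id for c in labeled})
    if by_mouse and len(mice) >= 2:
        table = np.array(
            [[sum(1 for c in labeled if c.mouse_id == m and c.preference == pref)
              for pref in ("positive", "negative")] for m in mice]
        )
        table = table[table.sum(axis=1) > 0]
        hchi2, hp, _, _ = sstats.chi2_contingency(table)
        out.homogeneity_chi2 = float(hchi2)
        out.homogeneity_p = float(hp)
    else:
        out.single_mouse = True
    return out


def group_by_baseline_rate(classes: list[UnitClass],
                           edges: tuple[float, ...] = (10.0, 5.0, 1.0)) -> list[list[UnitClass]]:
    """Partition units by baseline firing rate (bfr) into half-open groups.

    ``edges`` must be strictly decreasing; group k holds
    ``edges[k-1] > bfr >= edges[k]`` with the first group ``bfr >= edges[0]``
    and the last ``bfr < edges[-1]``. A bfr exactly at an edge joins the
    >=-side group. Empty groups are reported, not dropped.
    """
    edges = tuple(float(e) for e in edges)
    if any(b >= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly decreasing")
    groups: list[list[UnitClass]] = [[] for _ in range(len(edges) + 1)]
    for c in classes:
        for k, e in enumerate(edges):
            if c.baseline_rate >= e:
                groups[k].append(c)
                break
        else:
            groups[-1].append(c)
    return groups


def group_summary(values_by_group: list[np.ndarray]) -> list[dict]:
    """Mean +- SEM per baseline-rate group; empty groups report n=0."""
    out = []
    for vals in values_by_group:
        vals = np.asarray(vals, float)
        n = vals.size
        out.append(
            {
                "n": int(n),
                "mean": float(vals.mean()) if n else np.nan,
                "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            }
        )
    return out


def behavioral_dprime(hit_rate: float, fa_rate: float,
                      n_go: int | None = None, n_nogo: int | None = None) -> float:
    """Signal-detection d' from hit and false-alarm rates.

    With trial counts given, applies the log-linear correction
    H' = (hits + 0.5) / (n + 1); otherwise extreme rates are clipped to
    [1/(2n), 1 - 1/(2n)] with a nominal n of 100 when no count is known.
    """
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    if n_go is not None and n_nogo is not None:
        h = (hit_rate * n_go + 0.5) / (n_go + 1)
        f = (fa_rate * n_nogo + 0.5) / (n_nogo + 1)
    else:
        n = 100
        h = np.clip(hit_rate, 1 / (2 * n), 1 - 1 / (2 * n))
        f = np.clip(fa_rate, 1 / (2 * n), 1 - 1 / (2 * n))
    return float(sstats.norm.ppf(h) - sstats.norm.ppf(f))
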