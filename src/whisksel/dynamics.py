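"""Timing of touch facilitation vs suppression via pairwise cross-correlograms.

Every touch-facilitated unit's trial-averaged z-scored response is cross-
correlated against every touch-suppressed unit's response (within a mouse).
The lag of the minimum cross-correlation gives the temporal offset between
facilitation and suppression; by convention a NEGATIVE lag means suppression
follows facilitation (a suppressed trace equal to a negated, delayed copy of
a facilitated trace recovers minus that delay).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LagResult", "pair_min_lag", "xcorr_min_lag"]


@dataclass
class LagResult:
    mouse_id: str
    #: (facilitated_id, suppressed_id, lag_s) per analyzed pair
    pair_lags: list[tuple[str, str, float]]
    #: lag grid (s) and mean correlogram over pairs
    lags: np.ndarray
    correlogram: np.ndarray
    summary_lag: float  # mean of per-pair minimum-correlation lags, seconds
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


def _normalized_xcorr(f: np.ndarray, s: np.ndarray, max_lag_bins: int) -> np.ndarray:
    """Coefficient-normalized cross-correlation c(l) = sum_t f[t+l] s[t] /
    sqrt(sum f^2 sum s^2) over l in [-L, L], traces mean-removed."""
    f = f - f.mean()
    s = s - s.mean()
    norm = np.sqrt((f ** 2).sum() * (s ** 2).sum())
    n = f.size
    out = np.empty(2 * max_lag_bins + 1)
    for k, lag in enumerate(range(-max_lag_bins, max_lag_bins + 1)):
        if lag >= 0:
            seg = f[lag:] if lag else f
            out[k] = np.dot(seg[: n - lag], s[: n - lag])
        else:
            out[k] = np.dot(f[: n + lag], s[-lag:])
    return out / norm


def pair_min_lag(facilitated: np.ndarray, suppressed: np.ndarray,
                 bin: float, max_lag: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum-correlation lag for one (facilitated, suppressed) trace pair.

    Ties in the minimum resolve toward the lag of smallest magnitude
    (negative before positive at equal magnitude). Returns
    (lag_s, lag_grid_s, correlogram).
    """
    f = np.asarray(facilitated, float)
    s = np.asarray(suppressed, float)
    if f.shape != s.shape:
        raise ValueError("traces must share the time grid")
    if np.ptp(f) == 0 or np.ptp(s) == 0:
        raise ValueError("constant trace")
    max_lag_bins = min(int(round(max_lag / bin)), f.size - 1)
    c = _normalized_xcorr(f, s, max_lag_bins)
    lags = bin * np.arange(-max_lag_bins, max_lag_bins + 1)
    cmin = c.min()
    candidates = np.where(c == cmin)[0]
    best = min(candidates, key=lambda i: (abs(lags[i]), lags[i]))
    return float(lags[best]), lags, c


def xcorr_min_lag(facilitated: dict[str, np.ndarray], suppressed: dict[str, np.ndarray],
                  bin: float = 0.010, max_lag: float = 0.3,
                  mouse_id: str = "") -> LagResult:
    """All-pairs minimum-correlation lags between two unit populations.

    ``facilitated`` and ``suppressed`` map unit ids to trial-averaged
    z-scored response traces on a shared time grid of width ``bin``.
    Constant traces cause the pair to be skipped (flagged). The summary lag
    is the unrounded mean of the per-pair minimum lags.
    """
    if not facilitated or not suppressed:
        raise ValueError("both populations must be nonempty")
    pair_lags: list[tuple[str, str, float]] = []
    skipped: list[tuple[str, str]] = []
    acc = None
    lag_grid = None
    for fid, f in facilitated.items():
        for sid, s in suppressed.items():
            try:
                lag, lags, c = pair_min_lag(f, s, bin=bin, max_lag=max_lag)
            except ValueError:
                skipped.append((fid, sid))
                continue
            pair_lags.append((fid, sid, lag))
            lag_grid = lags
            acc = c if acc is None else acc + c
    if not pair_lags:
        raise ValueError("no analyzable pairs (all traces constant)")
    mean_c = acc / len(pair_lags)
    summary = float(np.mean([p[2] for p in pair_lags]))
    return LagResult(mouse_id=mouse_id, pair_lags=pair_lags, lags=lag_grid,
                     correlogram=mean_c, summary_lag=summary, skipped_pairs=skipped)
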