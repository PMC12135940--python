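"""Event-aligned spike binning, z-scoring, and windowed rate estimation.

The central container is :class:`RateTensor`, a unit x trial x bin array of
firing rates (sp/s, or z-units after :func:`zscore`). The bin grid is
anchored at the alignment event (an edge at 0), so "post first touch"
windows start exactly at a bin edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace  # noqa: F401

import numpy as np

from .core import AnalysisWindows, Session, Trial, Unit

__all__ = ["RateTensor", "ConditionRateSample", "bin_spikes", "build_rate_tensor",
           "zscore", "window_rate", "SD_FLOOR"]

#: z-scoring SD floor, sp/s: near-silent units are floored and flagged
#: rather than excluded, keeping population histograms complete.
SD_FLOOR = 0.1


@dataclass
class RateTensor:
    """unit x trial x bin firing rates with alignment provenance."""

    values: np.ndarray  # (n_units, n_trials, n_bins)
    bin_edges: np.ndarray  # (n_bins + 1,), seconds relative to the alignment event
    alignment: str = "first_touch"
    zscored: bool = False
    #: per-unit (mean, sd) in sp/s used for z-scoring; None before zscore()
    baseline_stats: np.ndarray | None = None
    unit_ids: list[str] = field(default_factory=list)
    trial_ids: list[int] = field(default_factory=list)
    #: unit indices whose baseline SD was floored (near-silent units)
    floored_units: list[int] = field(default_factory=list)
    #: unit indices excluded from z-scored outputs (absent from reference trials)
    flagged_units: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if widths.size and not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bins must be contiguous and of equal width")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def trial_index(self, trial_ids) -> np.ndarray:
        lookup = {tid: i for i, tid in enumerate(self.trial_ids)}
        return np.array([lookup[t] for t in trial_ids], dtype=int)


@dataclass
class ConditionRateSample:
    """Across-trial moments of the rate of one unit in one window/bin."""

    mu: float
    var: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.var < 0:
            raise ValueError("var must be nonnegative")


def _bin_grid(window: tuple[float, float], bin: float) -> np.ndarray:
    span = window[1] - window[0]
    n_bins = span / bin
    if abs(n_bins - round(n_bins)) > 1e-6 * max(1.0, abs(n_bins)):
        raise ValueError(f"bin {bin} does not divide window length {span}")
    n_bins = int(round(n_bins))
    return window[0] + bin * np.arange(n_bins + 1)


def bin_spikes(unit: Unit, events: np.ndarray, window: tuple[float, float],
               bin: float) -> np.ndarray:
    """Event-aligned binned firing rates for one unit.

    Returns an (n_events, n_bins) array where entry ``[t, b]`` is the spike
    count of ``unit`` in ``[event_t + edge_b, event_t + edge_{b+1})`` divided
    by the bin width, in sp/s. Empty ``events`` yields an empty array with a
    warning.
    """
    edges = _bin_grid(window, bin)
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        warnings.warn("bin_spikes: empty event list", stacklevel=2)
        return np.zeros((0, edges.size - 1))
    # searchsorted('left') implements half-open [edge, next_edge) bins
    abs_edges = events[:, None] + edges[None, :]
    idx = np.searchsorted(unit.spike_times, abs_edges, side="left")
    counts = np.diff(idx, axis=1)
    return counts / bin


def build_rate_tensor(session: Session, window: tuple[float, float], bin: float,
                      alignment: str = "first_touch",
                      trials: list[Trial] | None = None) -> RateTensor:
    """Bin every unit against the per-trial alignment event.

    ``alignment`` is ``first_touch`` or ``first_lick``; trials without the
    alignment event are dropped.
    """
    trials = session.trials if trials is None else trials
    if alignment == "first_touch":
        kept = [tr for tr in trials if np.isfinite(tr.first_touch)]
        events = np.array([tr.first_touch for tr in kept])
    elif alignment == "first_lick":
        kept = [tr for tr in trials if tr.lick_times.size]
        events = np.array([tr.lick_times[0] for tr in kept])
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    edges = _bin_grid(window, bin)
    vals = np.zeros((len(session.units), len(kept), edges.size - 1))
    for i, unit in enumerate(session.units):
        if events.size:
            vals[i] = bin_spikes(unit, events, window, bin)
    return RateTensor(
        values=vals,
        bin_edges=edges,
        alignment=alignment,
        unit_ids=[u.unit_id for u in session.units],
        trial_ids=[tr.trial_id for tr in kept],
    )


def zscore(tensor: RateTensor, windows: AnalysisWindows | None = None,
           reference_trials: list[int] | None = None) -> RateTensor:
    """Z-score each unit against its pooled baseline-window bin rates.

    The reference distribution is the unit's baseline-window bins pooled
    over ``reference_trials`` (trial ids; default all trials in the tensor
    — pass the engaged Hit+CR trials to express context effects on the
    engaged scale). SDs are floored at ``SD_FLOOR`` sp/s, with floored
    units flagged. Units with no reference trials are flagged and their
    z-values set to NaN.
    """
    if tensor.zscored:
        raise ValueError("tensor is already z-scored")
    windows = windows or AnalysisWindows()
    if reference_trials is None:
        ref_idx = np.arange(len(tensor.trial_ids))
    else:
        have = set(tensor.trial_ids)
        ref_idx = tensor.trial_index([t for t in reference_trials if t in have])
    centers = tensor.bin_centers
    in_base = (centers >= windows.baseline[0]) & (centers < windows.baseline[1])
    if not in_base.any():
        raise ValueError("tensor does not cover the baseline window")
    stats = np.zeros((tensor.values.shape[0], 2))
    floored: list[int] = []
    flagged: list[int] = []
    out = np.full_like(tensor.values, np.nan, dtype=float)
    for i in range(tensor.values.shape[0]):
        if ref_idx.size == 0:
            flagged.append(i)
            stats[i] = (np.nan, np.nan)
            continue
        pool = tensor.values[i][np.ix_(ref_idx, np.where(in_base)[0])].ravel()
        mu = float(pool.mean())
        sd = float(pool.std(ddof=0))
        if sd < SD_FLOOR:
            sd = SD_FLOOR
            floored.append(i)
        stats[i] = (mu, sd)
        out[i] = (tensor.values[i] - mu) / sd
    return replace(
        tensor,
        values=out,
        zscored=True,
        baseline_stats=stats,
        floored_units=floored,
        flagged_units=flagged,
    )


def window_rate(tensor: RateTensor, window: tuple[float, float]) -> np.ndarray:
    """Mean rate over the bins fully inside the half-open ``window``.

    Returns an (n_units, n_trials) array. Raises if the window overlaps no
    complete bin.
    """
    lo = tensor.bin_edges[:-1]
    hi = tensor.bin_edges[1:]
    eps = 1e-9
    inside = (lo >= window[0] - eps) & (hi <= window[1] + eps)
    if not inside.any():
        raise ValueError(f"window {window} overlaps no complete bin")
    return tensor.values[:, :, inside].mean(axis=2)
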