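"""Behavioral-context (Miss/Away) modulation with feature-occupancy matching.

Sensory (0-300 ms) and baseline (-1.5-0 s) rates are compared between a
reference condition (engaged Hit trials) and a test condition (Miss trials,
or Away trials where the water port was displaced). Because conditions can
differ in whisking and locomotion, comparisons may be run on occupancy-
matched trial subsets: trials are binned jointly over behavioral features
(run speed, curvature, touch rate) and each condition is subsampled per bin
to the common minimum count; statistics are averaged over resampling
permutations (default 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .core import Trial
from .rates import RateTensor, window_rate

__all__ = ["OccupancyPlan", "ModulationResult", "occupancy_match",
           "condition_modulation", "modulation_fraction_report",
           "trial_features"]

FEATURES = ("run_speed", "curvature", "touch_rate")


@dataclass
class OccupancyPlan:
    """Matched-trial resampling plan: per permutation, the retained trial
    indices (into the given trial lists) for each condition."""

    features: tuple[str, ...]
    n_bins: int
    #: per permutation: (indices_a, indices_b)
    permutations: list[tuple[np.ndarray, np.ndarray]]

    @property
    def n_permutations(self) -> int:
        return len(self.permutations)


@dataclass
class ModulationResult:
    unit_id: str
    window: str  # evoked | baseline
    contrast: str  # Hit_vs_Miss | Home_vs_Away
    delta_z: float  # condition minus reference, z-units
    p_unit: float  # per-neuron Mann-Whitney p (two-sided)
    significant: bool
    n_reference: int = 0
    n_condition: int = 0


def trial_features(trial: Trial, features=FEATURES) -> np.ndarray:
    vals = []
    for f in features:
        if f == "touch_rate":
            vals.append(trial.touch_times.size / trial.response_window)
        else:
            vals.append(getattr(trial, f))
    return np.array(vals, dtype=float)


def occupancy_match(trials_a: list[Trial], trials_b: list[Trial],
                    features=("run_speed", "curvature"), n_bins: int = 8,
                    n_perm: int = 20, rng=None) -> OccupancyPlan:
    """Joint-histogram occupancy matching of two trial sets.

    Features are binned over the pooled range; within each jointly
    occupied cell both conditions are subsampled without replacement to the
    smaller count. Raises when no cell is occupied by both conditions
    ("disjoint feature supports").
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    rng = np.random.default_rng(rng)
    fa = np.array([trial_features(t, features) for t in trials_a])
    fb = np.array([trial_features(t, features) for t in trials_b])
    if not (np.isfinite(fa).all() and np.isfinite(fb).all()):
        raise ValueError("feature values must be finite")
    pooled = np.vstack([fa, fb])
    cells_a = np.zeros(len(trials_a), dtype=int)
    cells_b = np.zeros(len(trials_b), dtype=int)
    for j in range(pooled.shape[1]):
        lo, hi = pooled[:, j].min(), pooled[:, j].max()
        edges = np.linspace(lo, hi, n_bins + 1)
        ia = np.clip(np.searchsorted(edges, fa[:, j], side="right") - 1, 0, n_bins - 1)
        ib = np.clip(np.searchsorted(edges, fb[:, j], side="right") - 1, 0, n_bins - 1)
        cells_a = cells_a * n_bins + ia
        cells_b = cells_b * n_bins + ib
    shared = np.intersect1d(np.unique(cells_a), np.unique(cells_b))
    if shared.size == 0:
        raise ValueError("disjoint feature supports")
    perms = []
    for _ in range(n_perm):
        keep_a: list[int] = []
        keep_b: list[int] = []
        for cell in shared:
            ia = np.where(cells_a == cell)[0]
            ib = np.where(cells_b == cell)[0]
            k = min(ia.size, ib.size)
            keep_a.extend(rng.choice(ia, size=k, replace=False))
            keep_b.extend(rng.choice(ib, size=k, replace=False))
        perms.append((np.sort(np.array(keep_a, int)), np.sort(np.array(keep_b, int))))
    return OccupancyPlan(features=tuple(features), n_bins=n_bins, permutations=perms)


def _window_values(tensor: RateTensor, trial_ids: list[int],
                   window: tuple[float, float]) -> np.ndarray:
    """(n_units, n_trials) per-trial window rates for the given trial ids."""
    idx = tensor.trial_index(trial_ids)
    return window_rate(tensor, window)[:, idx]


def condition_modulation(tensor: RateTensor, reference_trials: list[int],
                         condition_trials: list[int], contrast: str,
                         window: str = "evoked",
                         plan: OccupancyPlan | None = None,
                         alpha: float = 0.05,
                         min_trials: int = 5) -> tuple[list[ModulationResult], float]:
    """Per-unit Miss/Away modulation plus the population test.

    ``tensor`` must be z-scored on the shared engaged-trial baseline so the
    per-unit ``delta_z`` (condition minus reference mean z-rate in the
    window) is comparable across contexts. Per unit: two-sided Mann-Whitney
    U on per-trial window rates. Population: one-sample t-test of delta_z
    over units. With an :class:`OccupancyPlan`, statistics are computed per
    permutation (indices select into the given trial lists) and averaged.

    Returns (per-unit results, population p). Units cannot be excluded
    individually here; trial-count checks apply to the selections.
    """
    if not tensor.zscored:
        raise ValueError("condition_modulation expects a z-scored tensor")
    win = (0.0, 0.3) if window == "evoked" else (-1.5, 0.0)
    if plan is None:
        plans = [(np.arange(len(reference_trials)), np.arange(len(condition_trials)))]
    else:
        plans = plan.permutations
    ref_ids = list(reference_trials)
    cond_ids = list(condition_trials)
    n_units = len(tensor.unit_ids)
    deltas = np.zeros((len(plans), n_units))
    pvals = np.zeros((len(plans), n_units))
    n_ref = n_cond = 0
    for k, (ia, ib) in enumerate(plans):
        sel_ref = [ref_ids[i] for i in ia]
        sel_cond = [cond_ids[i] for i in ib]
        if len(sel_ref) < min_trials or len(sel_cond) < min_trials:
            raise ValueError(
                f"fewer than {min_trials} trials per side after matching"
            )
        n_ref, n_cond = len(sel_ref), len(sel_cond)
        ref_vals = _window_values(tensor, sel_ref, win)
        cond_vals = _window_values(tensor, sel_cond, win)
        deltas[k] = cond_vals.mean(axis=1) - ref_vals.mean(axis=1)
        for i in range(n_units):
            if np.ptp(np.concatenate([ref_vals[i], cond_vals[i]])) == 0:
                pvals[k, i] = 1.0
            else:
                pvals[k, i] = sstats.mannwhitneyu(
                    cond_vals[i], ref_vals[i], alternative="two-sided"
                ).pvalue
    delta_z = deltas.mean(axis=0)
    p_unit = pvals.mean(axis=0)
    results = [
        ModulationResult(
            unit_id=uid, window=window, contrast=contrast,
            delta_z=float(delta_z[i]), p_unit=float(p_unit[i]),
            significant=bool(p_unit[i] < alpha),
            n_reference=n_ref, n_condition=n_cond,
        )
        for i, uid in enumerate(tensor.unit_ids)
    ]
    finite = delta_z[np.isfinite(delta_z)]
    pop_p = float(sstats.ttest_1samp(finite, 0.0).pvalue) if finite.size > 1 else np.nan
    return results, pop_p


def modulation_fraction_report(results: list[ModulationResult]) -> dict:
    """Counts and fractions of significantly modulated units, split by sign."""
    if not results:
        raise ValueError("no modulation results")
    n = len(results)
    sig = [r for r in results if r.significant]
    dec = sum(1 for r in sig if r.delta_z < 0)
    inc = len(sig) - dec
    return {
        "n_units": n,
        "n_significant": len(sig),
        "fraction_significant": len(sig) / n,
        "n_decreased": dec,
        "n_increased": inc,
        "fraction_decreased": dec / n,
        "fraction_increased": inc / n,
    }
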