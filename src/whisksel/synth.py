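"""Synthetic Go/No-Go sessions with the statistical structure the analyses assume.

The generator emulates one recording session: a log-normal population of
baseline firing rates; touch-locked facilitation (an alpha-like rise/decay
kernel per touch, adapting after the first touch of a trial); delayed
touch suppression of positive-preferring units on negative-stimulus trials
(depth proportional to baseline rate, onset ``supp_delay`` after
facilitation onset — 60 ms for SC-like, 10 ms for S1-like profiles);
Miss/Away gain reductions; Away blocks of seven positive-stimulus trials;
and a per-trial "readiness" latent that couples pre-touch baseline rate to
lick latency. Spike trains are drawn from an inhomogeneous Poisson process
by thinning on a 1 ms grid. A single RNG stream per session, seeded
explicitly, drives every draw in documented order, so identical
(config, seed) give bit-identical sessions.

Draw order: unit baselines -> preferences -> depths -> trial stimuli ->
readiness -> FA coin flips -> touch times -> lick latencies -> covariates
-> spike thinning, unit by unit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sstats

from .core import Session, Trial, Unit

__all__ = ["GeneratorConfig", "GroundTruth", "generate_session", "poisson_thinning"]

THIN_DT = 1e-3  # thinning grid, s


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Generator parameters. ``None`` fields resolve to region-profile
    defaults in :meth:`resolved`."""

    n_units: int = 64
    region_profile: str = "SC_like"  # SC_like | S1_like
    task: str = "discrimination"
    n_trials: int = 512
    #: fraction of units preferring the positive stimulus; profile default
    #: 0.70 (SC-like) / 0.42 (S1-like) in discrimination, 0.5 in detection
    frac_positive_preferring: float | None = None
    # log-normal baseline-rate law: b = median * exp(dispersion * N(0,1))
    baseline_median: float = 4.0
    baseline_dispersion: float = 1.1
    # facilitation kernel: onset latency, rise tau, decay tau (s); peak
    # amplitude = gain * baseline + floor (sp/s)
    facil_onset: float = 0.005
    facil_rise: float = 0.008
    facil_decay: float = 0.040
    facil_gain: float = 2.0
    facil_floor: float = 3.0
    #: response amplitude to the non-preferred stimulus, fraction of preferred
    cross_gain: float = 0.10
    #: amplitude factor for touches after the first in a trial
    adaptation: float = 0.1
    #: adaptation factor for the suppression kernel (sustained inhibition
    #: adapts less than feed-forward facilitation); None shares `adaptation`
    supp_adaptation: float | None = 0.3
    #: facilitation-to-suppression offset (s); profile default 0.060 / 0.010
    supp_delay: float | None = None
    #: suppression trough depth as a fraction of baseline rate
    supp_depth: float = 1.0
    #: suppression kernel decay tau (s); rise is shared with facilitation
    supp_decay: float = 0.040
    #: baseline rate (sp/s) below which positive-preferring units carry no
    #: suppression kernel (suppression concentrates in high-rate neurons)
    supp_bfr_min: float = 4.0
    miss_gain: float = 0.5
    away_evoked_gain: float = 0.6
    away_baseline_gain: float = 0.7
    away_block: int = 7
    touch_rate_hz: float = 5.0
    p_miss: float = 0.25
    p_fa: float = 0.08
    # latency model: latency = intercept + slope * readiness + N(0, noise_sd),
    # floored; defaults keep > 92% of Hit latencies above 0.3 s
    latency_intercept: float = 0.55
    latency_slope: float = -0.07
    latency_noise_sd: float = 0.12
    latency_floor: float = 0.10
    #: baseline-rate log-gain per readiness z-unit for positive-preferring units
    readiness_coupling: float = 0.25
    covariate_rho: float = 0.7
    trial_spacing: float = 6.0
    stim_duration: float = 1.5
    pre_touch: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1 or self.n_trials < 1:
            raise GeneratorError("n_units and n_trials must be >= 1")
        if self.region_profile not in ("SC_like", "S1_like"):
            raise GeneratorError(f"unknown region_profile {self.region_profile!r}")
        if self.task not in ("discrimination", "detection"):
            raise GeneratorError(f"unknown task {self.task!r}")
        frac = self.frac_positive_preferring
        if frac is not None and not 0.0 <= frac <= 1.0:
            raise GeneratorError("frac_positive_preferring must be in [0, 1]")
        for name in ("baseline_median", "facil_gain", "facil_floor", "touch_rate_hz",
                     "supp_depth", "cross_gain", "adaptation"):
            if getattr(self, name) < 0:
                raise GeneratorError(f"{name} must be >= 0")
        if self.supp_delay is not None and self.supp_delay < 0:
            raise GeneratorError("supp_delay must be >= 0")
        for name in ("miss_gain", "away_evoked_gain", "away_baseline_gain"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise GeneratorError(f"{name} must be in (0, 1]")
        if self.away_block < 1:
            raise GeneratorError("away_block must be >= 1")
        for name in ("p_miss", "p_fa"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise GeneratorError(f"{name} must be in [0, 1]")

    def resolved(self) -> "GeneratorConfig":
        cfg = GeneratorConfig(**asdict(self))
        if cfg.supp_adaptation is None:
            cfg.supp_adaptation = cfg.adaptation
        if cfg.supp_delay is None:
            cfg.supp_delay = 0.060 if cfg.region_profile == "SC_like" else 0.010
        if cfg.frac_positive_preferring is None:
            if cfg.task == "detection":
                cfg.frac_positive_preferring = 0.5
            else:
                cfg.frac_positive_preferring = (
                    0.70 if cfg.region_profile == "SC_like" else 0.42
                )
        cfg.validate()
        return cfg

    @property
    def region(self) -> str:
        return "SC" if self.region_profile == "SC_like" else "S1"


@dataclass
class GroundTruth:
    """Generator-side labels retained for parameter-recovery tests."""

    units: list[dict]  # unit_id, preference, suppressed, baseline_rate, amplitude, coupling
    trials: list[dict]  # trial_id, stimulus, outcome, context, readiness, latency
    config: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def poisson_thinning(rate_fn, t_span: tuple[float, float], dt: float = THIN_DT,
                     rng=None) -> np.ndarray:
    """Sample an inhomogeneous Poisson process by thinning.

    ``rate_fn`` is either a callable (time -> sp/s) or an array of rates on
    the uniform grid ``t_span[0] + dt * arange(n)``. Homogeneous candidates
    at the peak rate are kept with probability rate(t)/peak, which leaves
    exactly the target process (exponential ISIs for constant rates).
    """
    if dt > 1e-3 + 1e-12:
        raise GeneratorError("thinning resolution dt must be <= 1 ms")
    rng = np.random.default_rng(rng)
    t0, t1 = t_span
    n = int(np.ceil((t1 - t0) / dt))
    if callable(rate_fn):
        rates = np.asarray(rate_fn(t0 + dt * np.arange(n)), dtype=float)
    else:
        rates = np.asarray(rate_fn, dtype=float)
        if rates.size != n:
            raise GeneratorError("rate array does not match the time grid")
    if np.any(rates < 0):
        raise GeneratorError("negative rate encountered")
    lam_max = float(rates.max()) if rates.size else 0.0
    if lam_max == 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    idx = np.minimum(((cand - t0) / dt).astype(int), n - 1)
    keep = rng.uniform(size=n_cand) < rates[idx] / lam_max
    return cand[keep]


def _kernel(rise: float, decay: float, dt: float) -> np.ndarray:
    """Peak-normalized alpha-like bump exp(-t/decay) - exp(-t/rise)."""
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    t = dt * np.arange(int(round(6 * decay / dt)))
    return (np.exp(-t / decay) - np.exp(-t / rise)) / peak


def _add_at(grid: np.ndarray, t: float, kernel: np.ndarray, scale: float,
            dt: float) -> None:
    i0 = int(round(t / dt))
    if i0 >= grid.size:
        return
    i1 = min(i0 + kernel.size, grid.size)
    grid[i0:i1] += scale * kernel[: i1 - i0]


def generate_session(config: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """Generate one synthetic session plus its ground-truth record."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    mouse_id = f"m{cfg.seed % 100000}"
    duration = cfg.n_trials * cfg.trial_spacing
    n_grid = int(round(duration / THIN_DT))

    # --- units -------------------------------------------------------------
    baselines = cfg.baseline_median * np.exp(
        cfg.baseline_dispersion * rng.standard_normal(cfg.n_units)
    )
    positive_pref = rng.uniform(size=cfg.n_units) < cfg.frac_positive_preferring
    depths = rng.uniform(0, 1200, size=cfg.n_units)
    amplitudes = cfg.facil_gain * baselines + cfg.facil_floor
    suppress = (positive_pref & (baselines >= cfg.supp_bfr_min)
                & (cfg.task == "discrimination"))
    coupling = np.where(positive_pref, cfg.readiness_coupling, 0.0)

    # --- trials ------------------------------------------------------------
    stimuli = np.where(rng.uniform(size=cfg.n_trials) < 0.5, "positive", "negative")
    readiness = rng.standard_normal(cfg.n_trials)
    fa_draw = rng.uniform(size=cfg.n_trials)
    z_miss = sstats.norm.ppf(cfg.p_miss) if cfg.p_miss > 0 else -np.inf

    contexts: list[str] = []
    ctx, n_pos_in_ctx = "Home", 0
    for stim in stimuli:
        if n_pos_in_ctx == cfg.away_block:
            ctx = "Away" if ctx == "Home" else "Home"
            n_pos_in_ctx = 0
        contexts.append(ctx)
        if stim == "positive" or cfg.task == "detection":
            n_pos_in_ctx += 1

    outcomes: list[str] = []
    for i in range(cfg.n_trials):
        go_stim = stimuli[i] == "positive" or cfg.task == "detection"
        if go_stim:
            if contexts[i] == "Away" or readiness[i] < z_miss:
                outcomes.append("Miss")
            else:
                outcomes.append("Hit")
        else:
            if contexts[i] == "Home" and fa_draw[i] < cfg.p_fa:
                outcomes.append("FA")
            else:
                outcomes.append("CR")

    # touch times (first touch fixed at pre_touch into the trial, then a
    # homogeneous contact train at touch_rate_hz through the stimulus)
    touch_lists: list[np.ndarray] = []
    for i in range(cfg.n_trials):
        start = i * cfg.trial_spacing
        first = start + cfg.pre_touch
        touches = [first]
        t = first
        while True:
            t = t + rng.exponential(1.0 / cfg.touch_rate_hz)
            if t >= first + cfg.stim_duration:
                break
            touches.append(t)
        touch_lists.append(np.array(touches))

    latencies: list[float | None] = []
    lick_lists: list[np.ndarray] = []
    for i in range(cfg.n_trials):
        noise = rng.normal(0.0, cfg.latency_noise_sd)
        if outcomes[i] in ("Hit", "FA"):
            lat = cfg.latency_intercept + cfg.latency_slope * readiness[i] + noise
            lat = float(np.clip(lat, cfg.latency_floor, cfg.stim_duration - 0.05))
            first = touch_lists[i][0]
            lick_lists.append(first + lat + 0.15 * np.arange(3))
            latencies.append(lat)
        else:
            lick_lists.append(np.empty(0))
            latencies.append(None)

    # covariates: AR(1) across trials
    eps_r = rng.standard_normal(cfg.n_trials)
    eps_c = rng.standard_normal(cfg.n_trials)
    rho = cfg.covariate_rho
    ar_r = np.empty(cfg.n_trials)
    ar_c = np.empty(cfg.n_trials)
    for i in range(cfg.n_trials):
        prev_r = ar_r[i - 1] if i else 0.0
        prev_c = ar_c[i - 1] if i else 0.0
        ar_r[i] = rho * prev_r + np.sqrt(1 - rho ** 2) * eps_r[i]
        ar_c[i] = rho * prev_c + np.sqrt(1 - rho ** 2) * eps_c[i]
    run_speeds = 20.0 + 5.0 * ar_r
    curvatures = 0.010 + 0.002 * ar_c

    # --- shared rate components on the thinning grid -----------------------
    kern = _kernel(cfg.facil_rise, cfg.facil_decay, THIN_DT)
    kern_s = _kernel(cfg.facil_rise, cfg.supp_decay, THIN_DT)
    f_pos = np.zeros(n_grid)  # facilitation train, positive-stimulus trials
    f_neg = np.zeros(n_grid)  # facilitation train, negative-stimulus trials
    s_neg = np.zeros(n_grid)  # delayed suppression train, negative trials
    for i in range(cfg.n_trials):
        go_stim = stimuli[i] == "positive" or cfg.task == "detection"
        if go_stim:
            if contexts[i] == "Away":
                scale = cfg.away_evoked_gain
            else:
                scale = cfg.miss_gain if outcomes[i] == "Miss" else 1.0
        else:
            scale = 1.0
        target = f_pos if stimuli[i] == "positive" else f_neg
        for k, tt in enumerate(touch_lists[i]):
            a = 1.0 if k == 0 else cfg.adaptation
            _add_at(target, tt + cfg.facil_onset, kern, a * scale, THIN_DT)
            if stimuli[i] == "negative" and cfg.task == "discrimination":
                a_s = 1.0 if k == 0 else cfg.supp_adaptation
                _add_at(s_neg, tt + cfg.facil_onset + cfg.supp_delay, kern_s,
                        a_s, THIN_DT)

    # per-trial baseline multiplier for readiness-coupled units
    mult_coupled = np.ones(n_grid)
    for i in range(cfg.n_trials):
        lo = int(round(i * cfg.trial_spacing / THIN_DT))
        hi = int(round((i + 1) * cfg.trial_spacing / THIN_DT))
        m = np.exp(cfg.readiness_coupling * readiness[i])
        if contexts[i] == "Away":
            m *= cfg.away_baseline_gain
        mult_coupled[lo:hi] = m

    # --- units: rates and spikes -------------------------------------------
    units: list[Unit] = []
    for u in range(cfg.n_units):
        b, amp = baselines[u], amplitudes[u]
        if positive_pref[u]:
            rate = b * mult_coupled + amp * (f_pos + cfg.cross_gain * f_neg)
            if suppress[u]:
                rate = rate - cfg.supp_depth * b * s_neg
        else:
            rate = b + amp * (f_neg + cfg.cross_gain * f_pos)
        np.clip(rate, 0.0, None, out=rate)
        spikes = poisson_thinning(rate, (0.0, duration), THIN_DT, rng)
        units.append(
            Unit(unit_id=f"u{u:03d}", region=cfg.region, mouse_id=mouse_id,
                 spike_times=spikes, depth_um=float(depths[u]), shank=u % 3 + 1)
        )

    trials = [
        Trial(
            trial_id=i,
            stimulus=str(stimuli[i]),
            outcome=outcomes[i],
            context=contexts[i],
            first_touch=float(touch_lists[i][0]),
            touch_times=touch_lists[i],
            lick_times=lick_lists[i],
            run_speed=float(run_speeds[i]),
            curvature=float(curvatures[i]),
            response_window=cfg.stim_duration,
        )
        for i in range(cfg.n_trials)
    ]
    session = Session(units=units, trials=trials, task=cfg.task)
    truth = GroundTruth(
        units=[
            {
                "unit_id": f"u{u:03d}",
                "preference": "positive" if positive_pref[u] else "negative",
                "suppressed": bool(suppress[u]),
                "baseline_rate": float(baselines[u]),
                "amplitude": float(amplitudes[u]),
                "coupling": float(coupling[u]),
            }
            for u in range(cfg.n_units)
        ],
        trials=[
            {
                "trial_id": i,
                "stimulus": str(stimuli[i]),
                "outcome": outcomes[i],
                "context": contexts[i],
                "readiness": float(readiness[i]),
                "latency": latencies[i],
            }
            for i in range(cfg.n_trials)
        ],
        config=asdict(cfg),
    )
    return session, truth
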