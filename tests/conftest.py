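import numpy as np
import pytest

from whisksel.core import Session, Trial, Unit


def make_trial(trial_id=0, stimulus="positive", outcome="Hit", context="Home",
               first_touch=2.0, extra_touches=(), lick_delay=0.5,
               run_speed=20.0, curvature=0.01):
    touches = np.sort(np.r_[first_touch, np.asarray(extra_touches, float)])
    if outcome in ("Hit", "FA"):
        licks = np.array([first_touch + lick_delay])
    else:
        licks = np.empty(0)
    return Trial(trial_id=trial_id, stimulus=stimulus, outcome=outcome,
                 context=context, first_touch=float(touches[0]),
                 touch_times=touches, lick_times=licks,
                 run_speed=run_speed, curvature=curvature)


def make_session(spikes_by_unit, trials, task="discrimination", region="SC",
                 mouse_id="m0"):
    units = [Unit(unit_id=f"u{i}", region=region, mouse_id=mouse_id,
                  spike_times=np.asarray(st, float))
             for i, st in enumerate(spikes_by_unit)]
    return Session(units=units, trials=trials, task=task)


@pytest.fixture
def tiny_session():
    """2 units, 3 trials, hand-placed spikes."""
    trials = [
        make_trial(0, "positive", "Hit", first_touch=2.0),
        make_trial(1, "negative", "CR", first_touch=8.0),
        make_trial(2, "positive", "Miss", first_touch=14.0),
    ]
    spikes = [
        [0.5, 2.005, 2.015, 8.1, 13.0],
        [1.0, 1.2, 2.2, 8.05, 8.06, 14.25],
    ]
    return make_session(spikes, trials)


@pytest.fixture(scope="session")
def small_generated():
    """One small SC-like generated session shared across fast tests."""
    from whisksel.synth import GeneratorConfig, generate_session

    cfg = GeneratorConfig(n_units=12, n_trials=96, seed=7)
    return generate_session(cfg)


def _fleet(profile, seeds=(1, 2, 3, 4, 5)):
    from whisksel.pipeline import analyze_session
    from whisksel.synth import GeneratorConfig, generate_session

    out = []
    for seed in seeds:
        cfg = GeneratorConfig(region_profile=profile, seed=seed)
        session, truth = generate_session(cfg)
        out.append((session, truth, analyze_session(session)))
    return out


@pytest.fixture(scope="session")
def sc_fleet():
    """Five seeded SC-like discrimination sessions at the default scale."""
    return _fleet("SC_like")


@pytest.fixture(scope="session")
def s1_fleet():
    """Five seeded S1-like discrimination sessions at the default scale."""
    return _fleet("S1_like")
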