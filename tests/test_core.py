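import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from whisksel.core import (AnalysisWindows, SchemaError, Session,
                           SessionValidationError, Trial, Unit, read_session,
                           write_results, write_session)

from conftest import make_session, make_trial


class TestValidation:
    def test_unsorted_spikes_rejected(self):
        with pytest.raises(SessionValidationError, match="u7"):
            Unit("u7", "SC", "m0", np.array([1.0, 0.5]))

    def test_negative_spike_time_rejected(self):
        with pytest.raises(SessionValidationError):
            Unit("u0", "SC", "m0", np.array([-0.1, 0.5]))

    def test_bad_region_rejected(self):
        with pytest.raises(SessionValidationError):
            Unit("u0", "V1", "m0", np.array([0.5]))

    def test_hit_without_lick_rejected(self):
        with pytest.raises(SessionValidationError, match="Hit"):
            Trial(trial_id=3, stimulus="positive", outcome="Hit", context="Home",
                  first_touch=1.0, touch_times=np.array([1.0]),
                  lick_times=np.empty(0))

    def test_cr_with_lick_rejected(self):
        with pytest.raises(SessionValidationError, match="CR"):
            Trial(trial_id=0, stimulus="negative", outcome="CR", context="Home",
                  first_touch=1.0, touch_times=np.array([1.0]),
                  lick_times=np.array([1.5]))

    def test_first_touch_mismatch_rejected(self):
        with pytest.raises(SessionValidationError, match="first_touch"):
            Trial(trial_id=0, stimulus="negative", outcome="CR", context="Home",
                  first_touch=0.5, touch_times=np.array([1.0]),
                  lick_times=np.empty(0))

    def test_outcome_stimulus_mismatch_rejected(self):
        # a Hit on the negative stimulus is invalid in discrimination
        tr = Trial(trial_id=9, stimulus="negative", outcome="Hit", context="Home",
                   first_touch=1.0, touch_times=np.array([1.0]),
                   lick_times=np.array([1.4]))
        with pytest.raises(SessionValidationError, match="trial 9"):
            make_session([[0.5]], [tr])

    def test_mixed_mice_rejected(self):
        units = [Unit("a", "SC", "m0", np.array([0.1])),
                 Unit("b", "SC", "m1", np.array([0.1]))]
        with pytest.raises(SessionValidationError, match="mice"):
            Session(units=units, trials=[], task="discrimination")

    def test_detection_allows_hit_on_either_whisker(self):
        tr = Trial(trial_id=0, stimulus="whisker2", outcome="Hit", context="Home",
                   first_touch=1.0, touch_times=np.array([1.0]),
                   lick_times=np.array([1.4]))
        s = make_session([[0.5]], [tr], task="detection")
        assert s.trials[0].stimulus == "negative"  # alias resolution


class TestWindows:
    def test_defaults_valid(self):
        w = AnalysisWindows()
        assert w.early[1] <= w.response[1] and w.late[0] >= w.response[0]

    @pytest.mark.parametrize("kwargs", [
        {"baseline": (-1.5, 0.1)},
        {"early": (-0.1, 0.05)},
        {"late": (0.07, 0.4)},
        {"bias_bin": 0.0},
    ])
    def test_bad_windows_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnalysisWindows(**kwargs)


class TestRoundTrip:
    def test_tiny_session_round_trip_bitwise(self, tiny_session, tmp_path):
        sp, tr = tmp_path / "spikes.csv", tmp_path / "trials.csv"
        write_session(tiny_session, sp, tr)
        back = read_session(str(sp), str(tr))
        assert len(back.units) == len(tiny_session.units)
        for u0, u1 in zip(tiny_session.units, back.units):
            assert u0.unit_id == u1.unit_id
            assert np.array_equal(u0.spike_times, u1.spike_times)
        for t0, t1 in zip(tiny_session.trials, back.trials):
            assert np.array_equal(t0.touch_times, t1.touch_times)
            assert np.array_equal(t0.lick_times, t1.lick_times)
            assert (t0.stimulus, t0.outcome, t0.context) == \
                   (t1.stimulus, t1.outcome, t1.context)
            assert t0.first_touch == t1.first_touch

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_random_sessions_round_trip(self, tmp_path_factory, data):
        """read(write(S)) reproduces S exactly for random valid sessions."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10 ** 6)))
        n_units = data.draw(st.integers(1, 4))
        n_trials = data.draw(st.integers(1, 5))
        trials = []
        for i in range(n_trials):
            stim = rng.choice(["positive", "negative"])
            if stim == "positive":
                outcome = rng.choice(["Hit", "Miss"])
            else:
                outcome = rng.choice(["CR", "FA"])
            t0 = 2.0 + 6.0 * i
            extra = np.sort(rng.uniform(t0, t0 + 1.4, size=rng.integers(0, 4)))
            trials.append(make_trial(i, stim, outcome,
                                     context=rng.choice(["Home", "Away"]),
                                     first_touch=t0, extra_touches=extra,
                                     lick_delay=float(rng.uniform(0.2, 1.4)),
                                     run_speed=float(rng.normal(20, 5)),
                                     curvature=float(rng.normal(0.01, 0.002))))
        spikes = [np.sort(rng.uniform(0, 6.0 * n_trials, size=rng.integers(0, 30)))
                  for _ in range(n_units)]
        session = make_session(spikes, trials)
        d = tmp_path_factory.mktemp("rt")
        write_session(session, d / "s.csv", d / "t.csv")
        back = read_session(str(d / "s.csv"), str(d / "t.csv"))
        # note: units with zero spikes vanish from the spike table; compare the rest
        kept = [u for u in session.units if u.n_spikes]
        assert len(back.units) == len(kept)
        for u0, u1 in zip(sorted(kept, key=lambda u: u.unit_id), back.units):
            assert np.array_equal(u0.spike_times, u1.spike_times)
        for t0, t1 in zip(session.trials, back.trials):
            assert np.array_equal(t0.touch_times, t1.touch_times)
            assert t0.run_speed == t1.run_speed


class TestPhyReader:
    def test_sample_rate_conversion(self, tmp_path):
        """Spike sample 20000 at a 20 kHz rate reads as 1.0 s."""
        d = tmp_path / "phy"
        d.mkdir()
        np.save(d / "spike_times.npy", np.array([20000, 30000], dtype=np.int64))
        np.save(d / "spike_clusters.npy", np.array([0, 0], dtype=np.int32))
        (d / "params.py").write_text("sample_rate = 20000.\nn_channels_dat = 128\n")
        trials = tmp_path / "trials.csv"
        write_session(make_session([[0.5]], [make_trial()]),
                      tmp_path / "unused.csv", trials)
        session = read_session(str(d), str(trials))
        assert np.allclose(session.units[0].spike_times, [1.0, 1.5])

    def test_missing_params_raises_schema_error(self, tmp_path):
        d = tmp_path / "phy"
        d.mkdir()
        np.save(d / "spike_times.npy", np.array([1], dtype=np.int64))
        np.save(d / "spike_clusters.npy", np.array([0], dtype=np.int32))
        with pytest.raises(SchemaError, match="params.py"):
            read_session(str(d), "unused")

    def test_missing_column_raises_schema_error(self, tmp_path):
        p = tmp_path / "spikes.csv"
        pd.DataFrame({"unit_id": ["a"], "spike_time_s": [0.1]}).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="region"):
            read_session(str(p), "unused")


class TestWriteResults:
    def test_empty_table_header_only(self, tmp_path):
        p = tmp_path / "r.csv"
        write_results(pd.DataFrame(columns=["unit_id", "value"]), p)
        assert p.read_text().strip() == "unit_id,value"

    def test_round_trip_preserves_values(self, tmp_path):
        p = tmp_path / "r.csv"
        df = pd.DataFrame({"unit_id": ["a", "b", "c"],
                           "mouse_id": ["m0"] * 3,
                           "bias": [0.1234567890123, -2.5, 1e-9]})
        write_results(df, p)
        back = pd.read_csv(p)
        assert np.array_equal(back["bias"].to_numpy(), df["bias"].to_numpy())
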