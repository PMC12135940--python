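"""Domain types for touch-aligned SC/S1 analyses, plus on-disk readers/writers.

Conventions
-----------
* All times are in seconds, floating point, referenced to session start.
* Intervals are half-open ``[start, end)`` so that bins partition time.
* Event-time lists inside tabular trial files are semicolon-delimited
  within a single CSV cell (one row per trial).

The tabular schemas here are this package's own (the study deposited no
public data format); they are documented in the README.
"""

from __future__ import annotations

import ast
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "STIMULI",
    "OUTCOMES",
    "CONTEXTS",
    "TASKS",
    "SchemaError",
    "SessionValidationError",
    "Unit",
    "Trial",
    "Session",
    "AnalysisWindows",
    "read_session",
    "write_session",
    "write_results",
    "read_results",
]

REGIONS = ("SC", "S1")
STIMULI = ("positive", "negative")
#: detection-task alias: whisker1 -> positive, whisker2 -> negative
STIMULUS_ALIASES = {"whisker1": "positive", "whisker2": "negative"}
OUTCOMES = ("Hit", "Miss", "CR", "FA")
CONTEXTS = ("Home", "Away")
TASKS = ("discrimination", "detection")

#: outcomes consistent with each stimulus in the discrimination task
_DISCRIM_OUTCOMES = {"positive": {"Hit", "Miss"}, "negative": {"CR", "FA"}}


class SchemaError(ValueError):
    """A required column or key is missing from an input file."""


class SessionValidationError(ValueError):
    """A domain-type invariant is violated; inputs are rejected, not repaired."""


def _as_time_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    return arr


@dataclass
class Unit:
    """One sorted single unit: spike times plus recording metadata."""

    unit_id: str
    region: str
    mouse_id: str
    spike_times: np.ndarray
    depth_um: float | None = None
    shank: int | None = None

    def __post_init__(self) -> None:
        self.spike_times = _as_time_array(self.spike_times)
        if self.region not in REGIONS:
            raise SessionValidationError(
                f"unit {self.unit_id}: region {self.region!r} not in {REGIONS}"
            )
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) < 0):
                raise SessionValidationError(
                    f"unit {self.unit_id}: spike times are not nondecreasing"
                )
            if self.spike_times[0] < 0:
                raise SessionValidationError(
                    f"unit {self.unit_id}: negative spike time"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class Trial:
    """One behavioral trial with stimulus/outcome/context labels and event times."""

    trial_id: int
    stimulus: str
    outcome: str
    context: str
    first_touch: float
    touch_times: np.ndarray
    lick_times: np.ndarray
    run_speed: float = np.nan
    curvature: float = np.nan
    response_window: float = 1.5

    def __post_init__(self) -> None:
        self.stimulus = STIMULUS_ALIASES.get(self.stimulus, self.stimulus)
        if self.stimulus not in STIMULI:
            raise SessionValidationError(
                f"trial {self.trial_id}: unknown stimulus {self.stimulus!r}"
            )
        if self.outcome not in OUTCOMES:
            raise SessionValidationError(
                f"trial {self.trial_id}: unknown outcome {self.outcome!r}"
            )
        if self.context not in CONTEXTS:
            raise SessionValidationError(
                f"trial {self.trial_id}: unknown context {self.context!r}"
            )
        self.touch_times = _as_time_array(self.touch_times)
        self.lick_times = _as_time_array(self.lick_times)
        for name, arr in (("touch_times", self.touch_times), ("lick_times", self.lick_times)):
            if arr.size and (np.any(np.diff(arr) < 0) or arr[0] < 0):
                raise SessionValidationError(
                    f"trial {self.trial_id}: {name} must be nonnegative and ordered"
                )
        if self.first_touch < 0:
            raise SessionValidationError(f"trial {self.trial_id}: negative first_touch")
        if self.touch_times.size and not np.isclose(
            self.first_touch, self.touch_times[0], rtol=0, atol=1e-9
        ):
            raise SessionValidationError(
                f"trial {self.trial_id}: first_touch != min(touch_times)"
            )
        licked = self.licked_in_window
        if self.outcome in ("Hit", "FA") and not licked:
            raise SessionValidationError(
                f"trial {self.trial_id}: outcome {self.outcome} requires a lick "
                "in the response window"
            )
        if self.outcome in ("Miss", "CR") and licked:
            raise SessionValidationError(
                f"trial {self.trial_id}: outcome {self.outcome} is inconsistent "
                "with a lick in the response window"
            )

    @property
    def licked_in_window(self) -> bool:
        """True if any lick falls in [first_touch, first_touch + response_window)."""
        t0, t1 = self.first_touch, self.first_touch + self.response_window
        return bool(np.any((self.lick_times >= t0) & (self.lick_times < t1)))


@dataclass
class Session:
    """One recording: a unit population plus an ordered trial table."""

    units: list[Unit]
    trials: list[Trial]
    task: str = "discrimination"
    sampling_dt: float = 5e-5  # 20 kHz acquisition

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise SessionValidationError(f"unknown task {self.task!r}")
        mice = {u.mouse_id for u in self.units}
        if len(mice) > 1:
            raise SessionValidationError(
                f"units from multiple mice in one session: {sorted(mice)}"
            )
        if self.task == "discrimination":
            for tr in self.trials:
                if tr.outcome not in _DISCRIM_OUTCOMES[tr.stimulus]:
                    raise SessionValidationError(
                        f"trial {tr.trial_id}: outcome {tr.outcome} inconsistent "
                        f"with {tr.stimulus} stimulus in the discrimination task"
                    )
        span = self.time_span
        for tr in self.trials:
            for arr in (tr.touch_times, tr.lick_times):
                if arr.size and (arr[0] < span[0] - 1e-9 or arr[-1] > span[1] + 1e-9):
                    raise SessionValidationError(
                        f"trial {tr.trial_id}: event times outside session span"
                    )

    @property
    def mouse_id(self) -> str:
        return self.units[0].mouse_id if self.units else ""

    @property
    def time_span(self) -> tuple[float, float]:
        """[0, end] covering every spike and trial event."""
        hi = 0.0
        for u in self.units:
            if u.spike_times.size:
                hi = max(hi, float(u.spike_times[-1]))
        for tr in self.trials:
            hi = max(hi, tr.first_touch + tr.response_window)
            for arr in (tr.touch_times, tr.lick_times):
                if arr.size:
                    hi = max(hi, float(arr[-1]))
        return (0.0, hi)

    def trials_where(self, **criteria) -> list[Trial]:
        """Trials matching all given field==value criteria (value may be a set)."""
        out = []
        for tr in self.trials:
            ok = True
            for key, want in criteria.items():
                have = getattr(tr, key)
                if isinstance(want, (set, frozenset, list, tuple)):
                    ok = have in want
                else:
                    ok = have == want
                if not ok:
                    break
            if ok:
                out.append(tr)
        return out


@dataclass(frozen=True)
class AnalysisWindows:
    """Analysis windows relative to first touch (seconds, half-open).

    Defaults follow the study design: a 1.5 s pre-touch baseline, a 300 ms
    stimulus period, an early 0-50 ms feed-forward window, a late 70-300 ms
    window where suppression dominates, and 10 ms bias bins.
    """

    baseline: tuple[float, float] = (-1.5, 0.0)
    response: tuple[float, float] = (0.0, 0.3)
    early: tuple[float, float] = (0.0, 0.05)
    late: tuple[float, float] = (0.07, 0.3)
    bias_bin: float = 0.010

    def __post_init__(self) -> None:
        def _contains(outer, inner):
            return outer[0] <= inner[0] and inner[1] <= outer[1]

        if not self.baseline[1] <= self.response[0]:
            raise ValueError("baseline must strictly precede the response window")
        if not _contains(self.response, self.early):
            raise ValueError("early window must lie within the response window")
        if not _contains(self.response, self.late):
            raise ValueError("late window must lie within the response window")
        if not self.bias_bin > 0:
            raise ValueError("bias_bin must be positive")


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

_SPIKE_COLUMNS = ["unit_id", "spike_time_s", "region", "mouse_id"]
_TRIAL_COLUMNS = [
    "trial_id", "stimulus", "outcome", "context", "first_touch",
    "touch_times", "lick_times", "run_speed", "curvature", "response_window",
]


def _encode_times(arr: np.ndarray) -> str:
    return ";".join(repr(float(t)) for t in np.asarray(arr, dtype=float))


def _decode_times(cell) -> np.ndarray:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return np.empty(0)
    return np.array([float(tok) for tok in str(cell).split(";")], dtype=float)


def _read_phy_dir(path: str) -> pd.DataFrame:
    """Read a Kilosort/Phy-style sorted-output directory.

    Expects ``spike_times.npy`` (samples), ``spike_clusters.npy`` and a
    plain-text ``params.py`` sidecar assigning ``sample_rate``. Optional
    ``cluster_info.tsv`` supplies region/mouse/depth/shank per cluster;
    otherwise region defaults to SC and mouse_id to the directory name.
    """
    st_path = os.path.join(path, "spike_times.npy")
    sc_path = os.path.join(path, "spike_clusters.npy")
    params_path = os.path.join(path, "params.py")
    for p, what in ((st_path, "spike_times.npy"), (sc_path, "spike_clusters.npy"),
                    (params_path, "params.py")):
        if not os.path.exists(p):
            raise SchemaError(f"Phy directory {path}: missing {what}")
    sample_rate = None
    with open(params_path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line.startswith("sample_rate"):
                sample_rate = float(ast.literal_eval(line.split("=", 1)[1].strip()))
    if not sample_rate or sample_rate <= 0:
        raise SchemaError(f"Phy directory {path}: params.py does not define sample_rate")
    samples = np.load(st_path).ravel().astype(np.int64)
    clusters = np.load(sc_path).ravel()
    if samples.shape != clusters.shape:
        raise SchemaError(f"Phy directory {path}: spike_times/spike_clusters length mismatch")
    info = {}
    info_path = os.path.join(path, "cluster_info.tsv")
    if os.path.exists(info_path):
        tab = pd.read_csv(info_path, sep="\t")
        info = {str(r["cluster_id"]): r for _, r in tab.iterrows()}
    rows = []
    default_mouse = os.path.basename(os.path.normpath(path)) or "unknown"
    for samp, clu in zip(samples, clusters):
        meta = info.get(str(clu), {})
        rows.append(
            {
                "unit_id": str(clu),
                "spike_time_s": samp / sample_rate,
                "region": meta.get("region", "SC") if len(meta) else "SC",
                "mouse_id": meta.get("mouse_id", default_mouse) if len(meta) else default_mouse,
                "depth_um": meta.get("depth_um", np.nan) if len(meta) else np.nan,
                "shank": meta.get("shank", np.nan) if len(meta) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def read_session(spike_path: str, trial_path: str) -> Session:
    """Read a Session from a spike table (CSV or Phy directory) and a trial CSV.

    Invariant violations raise :class:`SessionValidationError` naming the
    offending unit or trial; missing columns raise :class:`SchemaError`.
    """
    if os.path.isdir(spike_path):
        spikes = _read_phy_dir(spike_path)
    else:
        spikes = pd.read_csv(spike_path, float_precision="round_trip")
        for col in _SPIKE_COLUMNS:
            if col not in spikes.columns:
                raise SchemaError(f"spike table missing required column {col!r}")
    trials_df = pd.read_csv(trial_path, float_precision="round_trip")
    for col in _TRIAL_COLUMNS:
        if col not in trials_df.columns:
            raise SchemaError(f"trial table missing required column {col!r}")

    units: list[Unit] = []
    for uid, grp in spikes.groupby("unit_id", sort=True):
        depth = grp["depth_um"].iloc[0] if "depth_um" in grp else None
        shank = grp["shank"].iloc[0] if "shank" in grp else None
        units.append(
            Unit(
                unit_id=str(uid),
                region=str(grp["region"].iloc[0]),
                mouse_id=str(grp["mouse_id"].iloc[0]),
                spike_times=grp["spike_time_s"].to_numpy(dtype=float),
                depth_um=None if depth is None or pd.isna(depth) else float(depth),
                shank=None if shank is None or pd.isna(shank) else int(shank),
            )
        )
    trials = [
        Trial(
            trial_id=int(row["trial_id"]),
            stimulus=str(row["stimulus"]),
            outcome=str(row["outcome"]),
            context=str(row["context"]),
            first_touch=float(row["first_touch"]),
            touch_times=_decode_times(row["touch_times"]),
            lick_times=_decode_times(row["lick_times"]),
            run_speed=float(row["run_speed"]),
            curvature=float(row["curvature"]),
            response_window=float(row["response_window"]),
        )
        for _, row in trials_df.iterrows()
    ]
    task = str(trials_df["task"].iloc[0]) if "task" in trials_df and len(trials_df) else "discrimination"
    return Session(units=units, trials=trials, task=task)


def write_session(session: Session, spike_path: str, trial_path: str) -> None:
    """Write a Session as a spike CSV and a trial CSV (read_session inverse)."""
    spike_rows = []
    for u in session.units:
        for t in u.spike_times:
            spike_rows.append(
                {
                    "unit_id": u.unit_id,
                    "spike_time_s": repr(float(t)),
                    "region": u.region,
                    "mouse_id": u.mouse_id,
                    "depth_um": "" if u.depth_um is None else repr(float(u.depth_um)),
                    "shank": "" if u.shank is None else u.shank,
                }
            )
    pd.DataFrame(spike_rows, columns=_SPIKE_COLUMNS + ["depth_um", "shank"]).to_csv(
        spike_path, index=False
    )
    trial_rows = [
        {
            "trial_id": tr.trial_id,
            "stimulus": tr.stimulus,
            "outcome": tr.outcome,
            "context": tr.context,
            "first_touch": repr(float(tr.first_touch)),
            "touch_times": _encode_times(tr.touch_times),
            "lick_times": _encode_times(tr.lick_times),
            "run_speed": repr(float(tr.run_speed)),
            "curvature": repr(float(tr.curvature)),
            "response_window": repr(float(tr.response_window)),
            "task": session.task,
        }
        for tr in session.trials
    ]
    pd.DataFrame(trial_rows, columns=_TRIAL_COLUMNS + ["task"]).to_csv(
        trial_path, index=False
    )


def write_results(table: pd.DataFrame, path: str) -> None:
    """Write a result table as delimited text: header, deterministic column
    order (as given), floats at full precision."""
    table.to_csv(path, index=False)


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
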