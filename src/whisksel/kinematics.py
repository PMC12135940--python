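"""Whisker kinematics from tracked label coordinates at 500 fps.

Coordinates are image coordinates (x right-positive, y down-positive,
pixels). The whisker angle of a label is the signed angle between the
face-point-to-label vector and the image vertical axis (the -y direction),
in degrees, with the sign configurable so that protraction is positive.
Whisker bending is summarized by the Menger curvature (reciprocal
circumradius) averaged over all label triples. Touch onsets are the first
entry of the tip label into the surface ROI within each whisk cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = ["WhiskerTrack", "read_dlc_csv", "whisker_angle", "menger_curvature",
           "frame_curvature", "detect_touches"]

FRAME_DT = 0.002  # 500 fps


@dataclass
class WhiskerTrack:
    """Tracked label coordinates for one whisker."""

    frame_times: np.ndarray  # seconds, uniform 2 ms spacing
    labels: np.ndarray  # (n_frames, n_labels, 2) pixel coordinates
    face_point: tuple[float, float]
    roi: tuple[float, float, float, float] | None = None  # (x0, y0, x1, y1)
    likelihood: np.ndarray | None = None  # (n_frames, n_labels)
    likelihood_threshold: float = 0.9

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, float)
        self.labels = np.asarray(self.labels, float)
        if self.labels.ndim != 3 or self.labels.shape[2] != 2:
            raise ValueError("labels must be (n_frames, n_labels, 2)")
        dt = np.diff(self.frame_times)
        if dt.size and not np.allclose(dt, FRAME_DT, rtol=1e-3):
            raise ValueError("frame_times must be uniform at 2 ms (500 fps)")

    @property
    def n_labels(self) -> int:
        return self.labels.shape[1]

    def valid_frames(self) -> np.ndarray:
        """Frames where every label passes the likelihood threshold."""
        if self.likelihood is None:
            return np.ones(self.labels.shape[0], dtype=bool)
        return (self.likelihood >= self.likelihood_threshold).all(axis=1)


def read_dlc_csv(path: str, face_point: tuple[float, float],
                 roi=None, fps: float = 500.0) -> WhiskerTrack:
    """Read a DeepLabCut-style wide CSV (scorer/bodyparts/coords header rows)."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    n = len(df)
    labels = np.stack(
        [df.xs((bp, c), axis=1, level=(1, 2)).to_numpy(float).ravel()
         for bp in bodyparts for c in ("x", "y")], axis=1
    ).reshape(n, len(bodyparts), 2)
    try:
        lik = np.stack(
            [df.xs((bp, "likelihood"), axis=1, level=(1, 2)).to_numpy(float).ravel()
             for bp in bodyparts], axis=1)
    except KeyError:
        lik = None
    times = np.arange(n) / fps
    return WhiskerTrack(frame_times=times, labels=labels, face_point=face_point,
                        roi=roi, likelihood=lik)


def whisker_angle(track: WhiskerTrack, label_index: int, sign: float = 1.0) -> np.ndarray:
    """Per-frame signed angle (degrees) of one label about the face point.

    0 deg is the image vertical (-y, "up"); +90 deg is +x. Frames where the
    label coincides with the face point are NaN (flagged undefined).
    """
    v = track.labels[:, label_index, :] - np.asarray(track.face_point, float)
    degenerate = (v == 0).all(axis=1)
    ang = np.degrees(np.arctan2(v[:, 0], -v[:, 1])) * sign
    ang[degenerate] = np.nan
    return ang


def menger_curvature(p1, p2, p3) -> float:
    """Menger curvature of three points: 4*area / product of side lengths,
    in 1/pixels. Collinear points give 0; duplicate points are an error."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    d12 = np.linalg.norm(p2 - p1)
    d23 = np.linalg.norm(p3 - p2)
    d31 = np.linalg.norm(p1 - p3)
    if d12 == 0 or d23 == 0 or d31 == 0:
        raise ValueError("duplicate points")
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    return float(2.0 * abs(cross) / (d12 * d23 * d31))


def frame_curvature(track: WhiskerTrack) -> np.ndarray:
    """Mean Menger curvature over all C(n_labels, 3) label triples, per frame.

    Frames with a missing (low-likelihood) label are NaN."""
    from itertools import combinations

    n_frames = track.labels.shape[0]
    valid = track.valid_frames()
    out = np.full(n_frames, np.nan)
    triples = list(combinations(range(track.n_labels), 3))
    for f in range(n_frames):
        if not valid[f]:
            continue
        pts = track.labels[f]
        out[f] = float(np.mean([menger_curvature(pts[i], pts[j], pts[k])
                                for i, j, k in triples]))
    return out


def detect_touches(track: WhiskerTrack, angle: np.ndarray,
                   tip_index: int = -1, prominence: float = 5.0,
                   min_period: float = 0.040) -> tuple[np.ndarray, np.ndarray]:
    """ROI-based touch onsets, one at most per whisk cycle.

    Whisk cycles are delimited by successive protraction peaks of the angle
    trace (minimum ``prominence`` degrees, minimum period 40 ms covering the
    10-25 Hz whisking envelope). Within each cycle the first frame where the
    tip label transitions from outside to inside the ROI is a touch onset.
    Returns (onset_times, retraction_flags): an onset is flagged when the
    angle is falling at contact (retraction-phase touch; exclusion is left
    to the caller). Raises when the tip never leaves the ROI.
    """
    if track.roi is None:
        raise ValueError("track has no ROI")
    x0, y0, x1, y1 = track.roi
    tip = track.labels[:, tip_index, :]
    inside = ((tip[:, 0] >= x0) & (tip[:, 0] <= x1)
              & (tip[:, 1] >= y0) & (tip[:, 1] <= y1))
    if inside.all():
        raise ValueError("ROI misconfigured: tip never leaves the ROI")
    if not inside.any():
        return np.empty(0), np.empty(0, dtype=bool)
    dt = FRAME_DT
    peaks, _ = find_peaks(angle, prominence=prominence,
                          distance=max(1, int(round(min_period / dt))))
    bounds = np.concatenate([[0], peaks, [angle.size]])
    entries = np.where(inside & ~np.concatenate([[False], inside[:-1]]))[0]
    onsets: list[int] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        in_cycle = entries[(entries >= lo) & (entries < hi)]
        if in_cycle.size:
            onsets.append(int(in_cycle[0]))
    onsets_arr = np.array(onsets, dtype=int)
    slope = np.gradient(angle)
    retraction = slope[onsets_arr] < 0 if onsets_arr.size else np.empty(0, bool)
    return track.frame_times[onsets_arr], retraction
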