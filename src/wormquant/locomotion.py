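"""Trajectory metrics: centroid linking, crawling speed, turns, thrashes.

Replaces the wrMTrck/ImageJ step of a plate-tracking workflow with an
explicit, testable implementation.  A trajectory is a time-ordered series of
centroid positions (mm) at a known frame rate, optionally carrying a
body-bend-angle channel (degrees) for thrashing assays in liquid.

Definitions used throughout:

* speed -- mean frame-to-frame centroid displacement times fps, after
  moving-average smoothing of the positions;
* turn -- a local maximum of the heading-change series that strictly
  exceeds the angle threshold (the assay convention is "turns exceeding
  90 degrees"); headings are measured over displacement vectors spanning
  ``step`` frames (0.5 s by default) for noise robustness, and contiguous
  supra-threshold frames merge into a single event;
* thrash -- one full oscillation cycle of the bend-angle series, counted
  as positive-going zero crossings of the mean-subtracted series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "WormTrack",
    "TurnEvent",
    "link_detections",
    "compute_speed",
    "count_turns",
    "count_thrashes",
]


@dataclass
class WormTrack:
    """Time-ordered centroid track for one worm.

    ``positions`` holds n_frames+1 samples (t = 0 .. duration inclusive) in
    mm; ``bend_angle`` (degrees), when present, is sampled at the same
    instants.  ``ground_truth`` carries planted labels on synthetic tracks.
    """

    worm_id: str
    fps: float
    positions: np.ndarray
    bend_angle: Optional[np.ndarray] = None
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.positions) < 2:
            raise ValueError("a track needs at least 2 samples")
        if self.bend_angle is not None:
            self.bend_angle = np.asarray(self.bend_angle, dtype=float)
            if len(self.bend_angle) != len(self.positions):
                raise ValueError("bend_angle must match positions in length")

    @property
    def n_frames(self) -> int:
        """Number of inter-sample intervals (video frames spanned)."""
        return len(self.positions) - 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) / self.fps

    def path_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.positions, axis=0), axis=1)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "worm_id": self.worm_id,
                "frame": np.arange(len(self.positions)),
                "t_s": self.times,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
            }
        )
        if self.bend_angle is not None:
            df["bend_deg"] = self.bend_angle
        return df


class TurnEvent(NamedTuple):
    frame: int
    angle: float  # degrees, in (0, 180]


def link_detections(
    frames: Sequence[np.ndarray], max_step: float, fps: float = 8.0
) -> list[WormTrack]:
    """Greedy nearest-neighbour linking of per-frame centroid detections.

    Candidate links are taken in order of increasing distance; links longer
    than ``max_step`` are rejected and start new tracks.  There is no gap
    bridging: a track not matched in a frame is closed, and a one-frame
    dropout therefore splits a worm into two tracks.  Tracks with a single
    sample are discarded (a track needs two samples to carry any kinematics).
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    frames = [np.asarray(f, dtype=float).reshape(-1, 2) for f in frames]
    if len(frames) == 0:
        raise ValueError("no frames to link")

    finished: list[list[np.ndarray]] = []
    open_tracks: list[list[np.ndarray]] = [[p] for p in frames[0]]
    for dets in frames[1:]:
        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        if open_tracks and len(dets):
            last = np.array([t[-1] for t in open_tracks])
            dist = np.linalg.norm(last[:, None, :] - dets[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
            for ti, di in order:
                if dist[ti, di] > max_step:
                    break
                if ti in matched_tracks or di in matched_dets:
                    continue
                open_tracks[ti].append(dets[di])
                matched_tracks.add(ti)
                matched_dets.add(di)
        still_open = []
        for ti, tr in enumerate(open_tracks):
            if ti in matched_tracks:
                still_open.append(tr)
            else:
                finished.append(tr)
        for di, p in enumerate(dets):
            if di not in matched_dets:
                still_open.append([p])
        open_tracks = still_open
    finished.extend(open_tracks)

    tracks = []
    for i, pts in enumerate(finished):
        if len(pts) >= 2:
            tracks.append(WormTrack(worm_id=f"t{i}", fps=fps, positions=np.array(pts)))
    return tracks


def compute_speed(track: WormTrack, smooth_window: int = 5) -> float:
    """Mean centroid speed (mm/s) after moving-average position smoothing.

    ``smooth_window`` must be odd; the window is applied per axis in
    'valid' mode, so a track must be longer than the window.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 1")
    if len(track.positions) < smooth_window + 1:
        raise ValueError("track shorter than the smoothing window")
    if smooth_window == 1:
        pos = track.positions
    else:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        pos = np.column_stack(
            [np.convolve(track.positions[:, k], kernel, mode="valid") for k in (0, 1)]
        )
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(steps.mean() * track.fps)


def _wrap_degrees(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to (-180, 180]."""
    return (angle + 180.0) % 360.0 - 180.0


def count_turns(
    track: WormTrack,
    angle_threshold: float = 90.0,
    step: Optional[int] = None,
) -> list[TurnEvent]:
    """Turn events whose heading change strictly exceeds ``angle_threshold``.

    Heading is measured over ``step``-frame displacement vectors (default
    0.5 s worth of frames); the turn angle at frame i compares the heading
    of the window after i+step with the window before.  Events are local
    maxima of that series above the threshold -- a plateau of contiguous
    supra-threshold frames yields one event.  Zero-length displacement
    windows (stationary worm) are skipped.
    """
    if not 0.0 < angle_threshold < 180.0:
        raise ValueError("angle_threshold must lie in (0, 180) degrees")
    if step is None:
        step = max(1, int(round(0.5 * track.fps)))
    if step < 1:
        raise ValueError("step must be >= 1")
    pos = track.positions
    n = len(pos)
    if n < 2 * step + 1:
        return []
    disp = pos[step:] - pos[:-step]
    lengths = np.linalg.norm(disp, axis=1)
    valid = lengths > 1e-12
    heading = np.degrees(np.arctan2(disp[:, 1], disp[:, 0]))

    m = len(disp) - step
    dtheta = np.abs(_wrap_degrees(heading[step:] - heading[:m]))
    ok = valid[step:] & valid[:m]
    series = np.where(ok, dtheta, -np.inf)

    padded = np.concatenate([[-np.inf], series, [-np.inf]])
    peaks, _ = find_peaks(padded)
    events = [
        TurnEvent(frame=int(p - 1 + step), angle=float(series[p - 1]))
        for p in peaks
        if series[p - 1] > angle_threshold
    ]
    return events


def count_thrashes(track: WormTrack) -> int:
    """Full bend cycles: positive-going zero crossings of the bend series."""
    if track.bend_angle is None:
        raise ValueError("track has no bend-angle channel")
    s = track.bend_angle - track.bend_angle.mean()
    span = float(np.ptp(s))
    if span == 0:
        return 0
    # clamp numerically-zero samples so a crossing landing exactly on a
    # sample (e.g. a sinusoid ending on a cycle boundary) is not lost
    s = np.where(np.abs(s) < 1e-9 * span, 0.0, s)
    return int(np.sum((s[:-1] < 0) & (s[1:] >= 0)))
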