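"""Forward/backward segmentation of worm tracks and plate-level speed
statistics for exploratory locomotion.

A step between consecutive samples is labeled by the sign of the
centroid velocity projected on the body axis: forward if the projection
exceeds ``v_min``, backward if below ``-v_min``, otherwise unclassified
(stationary periods and compound turns both land there).  Brief label
islands shorter than ``min_bout_s`` are absorbed into their neighbors to
suppress jitter-induced flicker.

Plate summaries follow the weighted-mean convention of the exploratory
assay: each animal's direction speed is weighted by the proportion of
its tracked time spent moving in that direction, tracks shorter than 10
seconds are discarded, and the analysis window defaults to the final
minute of the recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import PlateRecording, WormhabError, WormTrack

__all__ = [
    "FORWARD",
    "BACKWARD",
    "UNCLASSIFIED",
    "SegmentedTrack",
    "PlateMotionSummary",
    "segment_track",
    "track_speed",
    "plate_motion_summary",
]

FORWARD = 1
BACKWARD = -1
UNCLASSIFIED = 0
_LABEL_NAMES = {FORWARD: "forward", BACKWARD: "backward", UNCLASSIFIED: "unclassified"}

V_MIN_DEFAULT = 0.005      # mm/s; projection threshold
MIN_BOUT_S_DEFAULT = 0.3   # s; ~4 frames at 13.5 Hz
MIN_TRACK_S_DEFAULT = 10.0 # s; objects tracked less than this are ignored


@dataclass
class SegmentedTrack:
    """A track partitioned into maximal same-label motion intervals.

    ``intervals`` are (i0, i1, label) index ranges into the track's
    sample arrays: the interval spans samples i0..i1 and therefore steps
    i0..i1-1.  Intervals are non-overlapping and contiguous over the
    tracked time, so the per-label time totals sum to the track
    duration.
    """

    worm_id: str
    track: WormTrack
    step_labels: np.ndarray
    intervals: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.track.t
        self._step_dt = np.diff(t)
        self._step_disp = np.hypot(np.diff(self.track.x), np.diff(self.track.y))

    def label_time(self, label: int) -> float:
        """Total seconds spent in ``label``."""
        return float(self._step_dt[self.step_labels == label].sum())

    def label_path(self, label: int) -> float:
        """Total path length (mm) accumulated while in ``label``."""
        return float(self._step_disp[self.step_labels == label].sum())

    @property
    def time_totals(self) -> dict[str, float]:
        return {_LABEL_NAMES[l]: self.label_time(l) for l in (FORWARD, BACKWARD, UNCLASSIFIED)}

    @property
    def path_totals(self) -> dict[str, float]:
        return {_LABEL_NAMES[l]: self.label_path(l) for l in (FORWARD, BACKWARD, UNCLASSIFIED)}

    def interval_times(self) -> list[tuple[float, float, str]]:
        """Intervals as (t_start, t_end, label-name) tuples."""
        t = self.track.t
        return [(float(t[i0]), float(t[i1]), _LABEL_NAMES[lab]) for i0, i1, lab in self.intervals]


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal same-label runs of step labels as (i0, i1, label) sample ranges."""
    out = []
    n = labels.size
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            out.append((start, i, int(labels[start])))
            start = i
    return out


def _absorb_short_runs(labels: np.ndarray, dt: np.ndarray, min_bout_s: float) -> np.ndarray:
    """Relabel runs shorter than min_bout_s into a neighboring run.

    The shortest offending run is merged first (ties: leftmost); a run
    flanked by two neighbors takes the longer neighbor's label, an edge
    run takes its only neighbor's.  Repeats until stable.
    """
    labels = labels.copy()
    while True:
        runs = _runs(labels)
        if len(runs) < 2:
            return labels
        durs = [float(dt[i0:i1].sum()) for i0, i1, _ in runs]
        short = [j for j, d in enumerate(durs) if d < min_bout_s]
        if not short:
            return labels
        j = min(short, key=lambda j: (durs[j], j))
        i0, i1, _ = runs[j]
        if j == 0:
            new = runs[1][2]
        elif j == len(runs) - 1:
            new = runs[j - 1][2]
        else:
            left, right = runs[j - 1], runs[j + 1]
            if left[2] == right[2]:
                new = left[2]
            else:
                new = left[2] if durs[j - 1] >= durs[j + 1] else right[2]
        labels[i0:i1] = new


def segment_track(
    track: WormTrack,
    v_min: float = V_MIN_DEFAULT,
    min_bout_s: float = MIN_BOUT_S_DEFAULT,
) -> SegmentedTrack:
    """Label each inter-frame step forward/backward/unclassified.

    The step velocity is the centroid displacement over the step divided
    by its duration, projected on the body-axis heading at the step's
    first sample.  Steps spanning tracking gaps are classified the same
    way (the mean velocity over the gap).
    """
    if track.n_samples < 2:
        raise WormhabError(f"track {track.worm_id!r}: need >= 2 samples to segment")
    dt = np.diff(track.t)
    vx = np.diff(track.x) / dt
    vy = np.diff(track.y) / dt
    proj = vx * np.cos(track.theta[:-1]) + vy * np.sin(track.theta[:-1])
    labels = np.where(proj > v_min, FORWARD, np.where(proj < -v_min, BACKWARD, UNCLASSIFIED))
    labels = labels.astype(np.int8)
    if min_bout_s > 0:
        labels = _absorb_short_runs(labels, dt, min_bout_s)
    seg = SegmentedTrack(
        worm_id=track.worm_id,
        track=track,
        step_labels=labels,
        intervals=_runs(labels),
    )
    return seg


def track_speed(track: WormTrack, seg: SegmentedTrack, label: int | str) -> float:
    """Average speed within a label: summed step displacements / summed time.

    Returns NaN when the track spent no time in the label (an undefined
    value, deliberately not zero).
    """
    if isinstance(label, str):
        inv = {v: k for k, v in _LABEL_NAMES.items()}
        label = inv[label]
    t = seg.label_time(label)
    if t <= 0:
        return math.nan
    return seg.label_path(label) / t


@dataclass
class PlateMotionSummary:
    """Direction fractions and weighted mean speeds for one plate."""

    plate_id: str
    fwd_fraction: float
    bwd_fraction: float
    uncl_fraction: float
    fwd_speed_mm_s: float
    bwd_speed_mm_s: float
    n_tracks_used: int
    n_tracks_filtered: int
    tracked_time_s: float = 0.0  # pooled tracked seconds behind the fractions


def plate_motion_summary(
    plate: PlateRecording,
    window: tuple[float, float] | None = None,
    min_track_s: float = MIN_TRACK_S_DEFAULT,
    v_min: float = V_MIN_DEFAULT,
    min_bout_s: float = MIN_BOUT_S_DEFAULT,
) -> PlateMotionSummary:
    """Exploratory-locomotion summary over an analysis window.

    Tracks are clipped to the window; tracks with less than
    ``min_track_s`` of within-window duration are discarded.  Direction
    fractions are pooled over all surviving tracked time.  The per-
    direction speed is the weighted mean sum(w_i * s_i) / sum(w_i),
    where w_i is worm i's proportion of its tracked window time spent in
    that direction and s_i its :func:`track_speed` for that direction.

    The default window is the final 60 seconds of the recording.
    """
    total = plate.protocol.total_s
    if window is None:
        window = (max(0.0, total - 60.0), total)
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= total):
        raise WormhabError(f"window {window} not within recording [0, {total}]")
    if min_track_s < 0:
        raise WormhabError("min_track_s must be >= 0")

    used: list[SegmentedTrack] = []
    n_filtered = 0
    for tr in plate.tracks:
        clip = tr.clipped(t0, t1)
        if clip is None or clip.n_samples < 2 or clip.duration_s < min_track_s:
            n_filtered += 1
            continue
        used.append(segment_track(clip, v_min=v_min, min_bout_s=min_bout_s))
    if not used:
        raise WormhabError(
            f"plate {plate.plate_id!r}: no tracks survive the window/min-track filter "
            f"(window={window}, min_track_s={min_track_s}; {n_filtered} filtered)"
        )

    time_tot = {FORWARD: 0.0, BACKWARD: 0.0, UNCLASSIFIED: 0.0}
    wsum = {FORWARD: 0.0, BACKWARD: 0.0}
    wssum = {FORWARD: 0.0, BACKWARD: 0.0}
    for seg in used:
        times = {l: seg.label_time(l) for l in time_tot}
        dur = sum(times.values())
        for l in time_tot:
            time_tot[l] += times[l]
        for l in (FORWARD, BACKWARD):
            if times[l] > 0 and dur > 0:
                w = times[l] / dur
                wsum[l] += w
                wssum[l] += w * track_speed(seg.track, seg, l)

    pooled = sum(time_tot.values())
    return PlateMotionSummary(
        plate_id=plate.plate_id,
        fwd_fraction=time_tot[FORWARD] / pooled,
        bwd_fraction=time_tot[BACKWARD] / pooled,
        uncl_fraction=time_tot[UNCLASSIFIED] / pooled,
        fwd_speed_mm_s=wssum[FORWARD] / wsum[FORWARD] if wsum[FORWARD] > 0 else math.nan,
        bwd_speed_mm_s=wssum[BACKWARD] / wsum[BACKWARD] if wsum[BACKWARD] > 0 else math.nan,
        n_tracks_used=len(used),
        n_tracks_filtered=n_filtered,
        tracked_time_s=pooled,
    )
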