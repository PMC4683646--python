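"""Stochastic simulator of multi-worm plate recordings.

Stands in for tracker output: each simulated worm crawls forward along
its body axis with a meandering heading, reverses (moves against the
body axis) in response to plate taps with a probability that decays
exponentially in stimulus number, reverses spontaneously as a Poisson
process, pauses intermittently, and is occasionally lost by the tracker
and re-acquired under a new object id.

Kinematics are piecewise-constant between frames: the motion state is
evaluated at each inter-frame midpoint and integrated over the frame
interval, so recorded displacements are exactly consistent with the
generative speeds (before optional pixel quantization).  All randomness
flows through one seeded generator per call; identical arguments give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import PlateRecording, Protocol, WormhabError, WormTrack
from .presets import GenotypeParams

__all__ = ["simulate_plate", "simulate_harsh_touch", "HarshTouchDataset"]

# Fixed micro-parameters of the motion model (not genotype-dependent).
_PAUSE_MEAN_S = 1.0        # mean pause duration (exponential)
_GAP_MEAN_S = 3.0          # mean tracker-loss gap (exponential)
_HEADING_DIFFUSION = 0.4   # heading random walk, rad / sqrt(s)
_SPEED_FLOOR = 0.02        # truncation floor for sampled speeds, mm/s
_DURATION_FLOOR = 0.4      # truncation floor for reversal durations, s
_ARENA_RADIUS_MM = 20.0    # initial placement radius on the plate


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Normal draw truncated below at ``lo`` (by redraw; clips after 100 tries)."""
    if sd == 0:
        return max(mean, lo)
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return lo


@dataclass
class HarshTouchDataset:
    """Reverse-body-bend counts from a harsh-touch assay.

    ``day_counts`` holds one integer array per experimental day, one
    count per animal (the standard design tests 20 animals per day).
    """

    genotype: str
    day_counts: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.day_counts = [np.asarray(d, dtype=int) for d in self.day_counts]
        for i, d in enumerate(self.day_counts):
            if d.size == 0:
                raise WormhabError(f"day {i + 1}: empty day")
            if (d < 0).any():
                raise WormhabError(f"day {i + 1}: negative bend count")


def _simulate_worm(
    rng: np.random.Generator,
    params: GenotypeParams,
    protocol: Protocol,
    t_frames: np.ndarray,
):
    """One worm's full-session kinematics on the frame grid.

    Returns (x, y, theta, visible) arrays over all frames.
    """
    nf = t_frames.size
    dt = 1.0 / protocol.frame_rate_hz
    mid = t_frames[:-1] + 0.5 * dt  # state-evaluation times, one per step
    total = protocol.total_s

    fwd_speed = _trunc_normal(
        rng, params.fwd_speed_mean_mm_s, params.fwd_speed_sd_mm_s, _SPEED_FLOOR
    )

    # --- reversal schedule: evoked then spontaneous -------------------
    intervals: list[tuple[float, float, float]] = []  # (t0, t1, speed)

    tap_times = protocol.tap_times
    for k, tap in enumerate(tap_times, start=1):
        if rng.random() < params.response_probability(k):
            lat = rng.uniform(0.0, params.rev_latency_max_s) if params.rev_latency_max_s > 0 else 0.0
            dur = _trunc_normal(
                rng, params.rev_duration_mean_s, params.rev_duration_sd_s, _DURATION_FLOOR
            )
            spd = _trunc_normal(
                rng, params.rev_speed_mean_mm_s, params.rev_speed_sd_mm_s, _SPEED_FLOOR
            )
            intervals.append((tap + lat, tap + lat + dur, spd))

    evoked = list(intervals)
    n_spont = rng.poisson(params.spont_reversal_rate_hz * total)
    for t0 in np.sort(rng.uniform(0.0, total, size=n_spont)):
        dur = _trunc_normal(
            rng, params.rev_duration_mean_s, params.rev_duration_sd_s, _DURATION_FLOOR
        )
        spd = _trunc_normal(
            rng, params.rev_speed_mean_mm_s, params.rev_speed_sd_mm_s, _SPEED_FLOOR
        )
        t1 = float(t0) + dur
        # a worm cannot initiate a spontaneous reversal while an evoked one
        # is in progress (and an abutting pair would be indistinguishable
        # from one long bout), so overlapping spontaneous events are dropped
        if any(t0 < e1 and t1 > e0 for e0, e1, _ in evoked):
            continue
        intervals.append((float(t0), t1, spd))

    speed = np.full(nf - 1, fwd_speed)
    rev_mask = np.zeros(nf - 1, dtype=bool)
    rev_ends: list[float] = []
    for t0, t1, spd in intervals:
        i0, i1 = np.searchsorted(mid, [t0, t1])
        if i1 > i0:
            speed[i0:i1] = -spd
            rev_mask[i0:i1] = True
            rev_ends.append(t1)

    # --- pauses (suppressed during reversals) -------------------------
    if params.pause_fraction > 0:
        rate = params.pause_fraction / (1.0 - params.pause_fraction) / _PAUSE_MEAN_S
        n_pause = rng.poisson(rate * total)
        for t0 in rng.uniform(0.0, total, size=n_pause):
            t1 = t0 + rng.exponential(_PAUSE_MEAN_S)
            i0, i1 = np.searchsorted(mid, [t0, t1])
            if i1 > i0:
                sl = slice(i0, i1)
                keep = ~rev_mask[sl]
                speed[sl] = np.where(keep, 0.0, speed[sl])

    # --- heading: random walk plus post-reversal reorientation --------
    dtheta = rng.normal(0.0, _HEADING_DIFFUSION * math.sqrt(dt), size=nf - 1)
    for t1 in rev_ends:
        j = int(np.searchsorted(mid, t1))
        if j < nf - 1:
            dtheta[j] += rng.uniform(-math.pi, math.pi)
    theta = np.empty(nf)
    theta[0] = rng.uniform(-math.pi, math.pi)
    theta[1:] = theta[0] + np.cumsum(dtheta)

    # --- integrate position -------------------------------------------
    r = _ARENA_RADIUS_MM * math.sqrt(rng.random())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    vx = speed * np.cos(theta[:-1]) * dt
    vy = speed * np.sin(theta[:-1]) * dt
    x = np.empty(nf)
    y = np.empty(nf)
    x[0] = r * math.cos(phi)
    y[0] = r * math.sin(phi)
    x[1:] = x[0] + np.cumsum(vx)
    y[1:] = y[0] + np.cumsum(vy)

    if protocol.pixel_mm > 0:
        q = protocol.pixel_mm
        x = np.round(x / q) * q
        y = np.round(y / q) * q

    # --- tracker dropouts ---------------------------------------------
    visible = np.ones(nf, dtype=bool)
    n_drop = rng.poisson(params.dropout_rate_hz * total)
    for td in rng.uniform(0.0, total, size=n_drop):
        tg = td + rng.exponential(_GAP_MEAN_S)
        i0, i1 = np.searchsorted(t_frames, [td, tg])
        visible[i0:i1] = False

    return x, y, theta, visible


def simulate_plate(
    params: GenotypeParams,
    protocol: Protocol,
    n_worms: int,
    seed: int,
    plate_id: str = "plate",
    genotype: str | None = None,
) -> PlateRecording:
    """Simulate one assay plate of ``n_worms`` animals.

    Tracker losses split a worm's session into several tracks with
    distinct ids (as real multi-worm trackers do), so downstream code
    must cope with short tracks and with animals untracked at some
    stimuli.

    Parameters
    ----------
    params
        Genotype preset (see :func:`wormhab.presets.make_preset`).
    protocol
        Recording/stimulus protocol; taps are delivered at its
        ``tap_times``.
    n_worms
        Animals on the plate (>= 1).
    seed
        Seed for the single random generator used by this call.
    """
    if n_worms < 1:
        raise WormhabError("n_worms must be >= 1")
    rng = np.random.default_rng(seed)
    t_frames = protocol.frame_times
    tracks: list[WormTrack] = []
    counter = 0
    for _ in range(n_worms):
        x, y, theta, visible = _simulate_worm(rng, params, protocol, t_frames)
        # contiguous visible runs -> separate tracks
        idx = np.flatnonzero(visible)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            if run.size < 2:
                continue
            counter += 1
            tracks.append(
                WormTrack(
                    worm_id=f"t{counter:04d}",
                    t=t_frames[run],
                    x=x[run],
                    y=y[run],
                    theta=theta[run],
                )
            )
    return PlateRecording(
        plate_id=plate_id,
        genotype=genotype if genotype is not None else params.name,
        protocol=protocol,
        stimuli=protocol.tap_times,
        tracks=tracks,
    )


def simulate_harsh_touch(
    params: GenotypeParams,
    n_days: int,
    n_per_day: int,
    seed: int,
) -> HarshTouchDataset:
    """Simulate a harsh-touch assay: integer bend counts per animal per day.

    Counts are normal draws at the preset's mean/sd, rounded to the
    nearest whole number (as scored by eye) and floored at zero.
    """
    if n_days < 1 or n_per_day < 1:
        raise WormhabError("n_days and n_per_day must be >= 1")
    rng = np.random.default_rng(seed)
    raw = rng.normal(params.harsh_bends_mean, params.harsh_bends_sd, size=(n_days, n_per_day))
    counts = np.maximum(np.rint(raw), 0.0).astype(int)
    return HarshTouchDataset(genotype=params.name, day_counts=list(counts))
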