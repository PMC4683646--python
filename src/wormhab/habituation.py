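"""Tap-habituation scoring: stimulus-locked reversal detection, per-
stimulus response-probability profiles, exponential-decay fitting, and
the derived habituation phenotypes.

The habituation level is the fitted curve p(k) = a + b*exp(-(k-1)/lam)
evaluated at the final stimulus (the operationalized asymptote); the
habituation rate is the half-life lam*ln(2), in stimulus-number units.
Both are computed per plate: one plate's fit is one statistical datum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import PlateRecording, WormhabError, WormTrack
from .locomotion import (
    BACKWARD,
    MIN_BOUT_S_DEFAULT,
    V_MIN_DEFAULT,
    SegmentedTrack,
    segment_track,
)

__all__ = [
    "ReversalEvent",
    "WormResponse",
    "HabituationProfile",
    "ExponentialFit",
    "detect_reversals",
    "score_stimulus",
    "response_profile",
    "fit_exponential",
    "initial_response",
    "response_magnitude",
    "mean_profile",
]

WINDOW_S_DEFAULT = 2.0      # scoring window after each tap, s
MIN_DISP_MM_DEFAULT = 0.1   # net backward displacement to count as a reversal
                            # (~10% of adult body length)
_FLAT_B = 0.01              # |b| below this: decay unidentifiable


@dataclass
class ReversalEvent:
    """One bout of backward locomotion."""

    worm_id: str
    t_start: float
    t_end: float
    duration_s: float
    mean_speed_mm_s: float
    peak_speed_mm_s: float
    net_displacement_mm: float
    evoked_by: int | None = None  # 1-based stimulus index, set by scoring


def detect_reversals(
    track: WormTrack,
    seg: SegmentedTrack | None = None,
    min_disp_mm: float = MIN_DISP_MM_DEFAULT,
    v_min: float = V_MIN_DEFAULT,
    min_bout_s: float = MIN_BOUT_S_DEFAULT,
) -> list[ReversalEvent]:
    """Reversal events: maximal backward intervals with net displacement
    of at least ``min_disp_mm``.

    Duration, mean speed (path length / duration) and peak step speed
    are measured over the whole backward interval.  An empty list is a
    valid result.
    """
    if seg is None:
        seg = segment_track(track, v_min=v_min, min_bout_s=min_bout_s)
    events: list[ReversalEvent] = []
    t, x, y = track.t, track.x, track.y
    dt = np.diff(t)
    disp = np.hypot(np.diff(x), np.diff(y))
    for i0, i1, lab in seg.intervals:
        if lab != BACKWARD:
            continue
        net = math.hypot(x[i1] - x[i0], y[i1] - y[i0])
        if net < min_disp_mm:
            continue
        dur = float(t[i1] - t[i0])
        path = float(disp[i0:i1].sum())
        peak = float((disp[i0:i1] / dt[i0:i1]).max())
        events.append(
            ReversalEvent(
                worm_id=track.worm_id,
                t_start=float(t[i0]),
                t_end=float(t[i1]),
                duration_s=dur,
                mean_speed_mm_s=path / dur,
                peak_speed_mm_s=peak,
                net_displacement_mm=net,
            )
        )
    return events


@dataclass
class WormResponse:
    """One worm's scored outcome at one stimulus."""

    worm_id: str
    stimulus: int
    responded: bool
    duration_s: float = math.nan
    mean_speed_mm_s: float = math.nan
    peak_speed_mm_s: float = math.nan


def score_stimulus(
    plate: PlateRecording,
    events_by_worm: dict[str, list[ReversalEvent]],
    k: int,
    window_s: float = WINDOW_S_DEFAULT,
    count_ongoing: bool = False,
) -> list[WormResponse]:
    """Score every eligible worm at stimulus ``k`` (1-based).

    A worm is a responder iff one of its reversal events starts within
    ``window_s`` of the tap, i.e. onset in [t_k, t_k + window_s]; the
    response magnitude is that event's, even if the event outlasts the
    window.  Onsets resolve to the frame grid, so a response beginning
    within the first frame after the tap carries the tap's own
    timestamp (hence the closed left edge).  A worm already reversing
    when the tap arrives is not a responder unless ``count_ongoing``.
    Worms not tracked throughout the window are excluded entirely.
    """
    if not 1 <= k <= plate.stimuli.size:
        raise WormhabError(f"stimulus {k} out of range 1..{plate.stimuli.size}")
    t_k = float(plate.stimuli[k - 1])
    t_hi = t_k + window_s
    out: list[WormResponse] = []
    for tr in plate.tracks:
        if tr.first_t > t_k or tr.last_t < t_hi:
            continue  # not tracked throughout the window
        resp = None
        for ev in events_by_worm.get(tr.worm_id, ()):
            if t_k <= ev.t_start <= t_hi:
                resp = ev
                break
            if count_ongoing and ev.t_start < t_k < ev.t_end:
                resp = ev
                break
        if resp is not None:
            resp.evoked_by = k
            out.append(
                WormResponse(
                    worm_id=tr.worm_id,
                    stimulus=k,
                    responded=True,
                    duration_s=resp.duration_s,
                    mean_speed_mm_s=resp.mean_speed_mm_s,
                    peak_speed_mm_s=resp.peak_speed_mm_s,
                )
            )
        else:
            out.append(WormResponse(worm_id=tr.worm_id, stimulus=k, responded=False))
    return out


@dataclass
class HabituationProfile:
    """Per-stimulus response probabilities (with denominators) for one plate.

    ``data`` has one row per stimulus: stimulus (1-based), n_tracked,
    n_responded, p, mean_duration_s, mean_speed_mm_s.  Stimuli with no
    tracked animals have p = NaN and are excluded from fitting.
    """

    plate_id: str
    n_stimuli: int
    data: pd.DataFrame = field(repr=False, default=None)

    @property
    def p(self) -> np.ndarray:
        return self.data["p"].to_numpy()

    @property
    def defined(self) -> pd.DataFrame:
        return self.data[self.data["n_tracked"] > 0]


def response_profile(
    plate: PlateRecording,
    window_s: float = WINDOW_S_DEFAULT,
    min_disp_mm: float = MIN_DISP_MM_DEFAULT,
    v_min: float = V_MIN_DEFAULT,
    min_bout_s: float = MIN_BOUT_S_DEFAULT,
    count_ongoing: bool = False,
    speed_stat: str = "mean",
) -> HabituationProfile:
    """Full scoring pipeline for one plate: segment every track, detect
    reversals, and score every stimulus.

    ``speed_stat`` selects the per-response speed statistic aggregated
    into the profile: the mean reversal speed (default) or the peak.
    """
    if plate.stimuli.size < 1:
        raise WormhabError(f"plate {plate.plate_id!r}: no stimuli to score")
    if speed_stat not in ("mean", "peak"):
        raise WormhabError("speed_stat must be 'mean' or 'peak'")
    events_by_worm: dict[str, list[ReversalEvent]] = {}
    for tr in plate.tracks:
        if tr.n_samples < 2:
            continue
        events_by_worm[tr.worm_id] = detect_reversals(
            tr, min_disp_mm=min_disp_mm, v_min=v_min, min_bout_s=min_bout_s
        )
    rows = []
    any_defined = False
    for k in range(1, plate.stimuli.size + 1):
        recs = score_stimulus(
            plate, events_by_worm, k, window_s=window_s, count_ongoing=count_ongoing
        )
        n_tracked = len(recs)
        responders = [r for r in recs if r.responded]
        n_resp = len(responders)
        if n_tracked > 0:
            any_defined = True
            p = n_resp / n_tracked
        else:
            p = math.nan
        if responders:
            dur = float(np.mean([r.duration_s for r in responders]))
            if speed_stat == "mean":
                spd = float(np.mean([r.mean_speed_mm_s for r in responders]))
            else:
                spd = float(np.mean([r.peak_speed_mm_s for r in responders]))
        else:
            dur = spd = math.nan
        rows.append((k, n_tracked, n_resp, p, dur, spd))
    if not any_defined:
        raise WormhabError(f"plate {plate.plate_id!r}: no stimulus has any tracked animal")
    df = pd.DataFrame(
        rows,
        columns=["stimulus", "n_tracked", "n_responded", "p", "mean_duration_s", "mean_speed_mm_s"],
    )
    return HabituationProfile(plate_id=plate.plate_id, n_stimuli=plate.stimuli.size, data=df)


@dataclass
class ExponentialFit:
    """Bounded least-squares fit of p(k) = a + b*exp(-(k-1)/lam).

    ``habituation_level`` is the curve at the final stimulus;
    ``half_life`` is lam*ln(2) (NaN for flat profiles, where the decay
    constant is unidentifiable).
    """

    a: float
    b: float
    lam: float
    habituation_level: float
    half_life: float
    rss: float
    converged: bool

    def predict(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        return self.a + self.b * np.exp(-(k - 1.0) / self.lam)


def _grid_fit(k: np.ndarray, p: np.ndarray, n: int) -> tuple[float, float, float, float]:
    """Fallback: grid over lam with linear solve for (a, b), bounds enforced."""
    best = None
    for lam in np.geomspace(0.05, 10.0 * n, 400):
        basis = np.column_stack([np.ones_like(k), np.exp(-(k - 1.0) / lam)])
        coef, *_ = np.linalg.lstsq(basis, p, rcond=None)
        a = float(np.clip(coef[0], 0.0, 1.0))
        b = float(np.clip(coef[1], -1.0, 1.0))
        rss = float(np.sum((p - (a + b * np.exp(-(k - 1.0) / lam))) ** 2))
        if best is None or rss < best[3]:
            best = (a, b, float(lam), rss)
    return best


def fit_exponential(profile: HabituationProfile) -> ExponentialFit:
    """Fit the decay curve to one plate's defined response probabilities.

    Requires at least 4 defined stimuli.  Bounds: a in [0, 1], b in
    [-1, 1], lam in (0, 10n].  Initialization is deterministic (a0 =
    min p, b0 = p1 - a0, lam0 = n/4); if the optimizer fails, a grid
    search over lam with a closed-form linear solve for (a, b) is used
    and ``converged`` is set False.  Flat profiles (|b| < 0.01) report
    the profile mean as the level and an undefined half-life.
    """
    d = profile.defined
    if len(d) < 4:
        raise WormhabError(
            f"plate {profile.plate_id!r}: need >= 4 defined stimuli to fit, have {len(d)}"
        )
    k = d["stimulus"].to_numpy(dtype=float)
    p = d["p"].to_numpy(dtype=float)
    n = profile.n_stimuli

    def resid(theta):
        a, b, lam = theta
        return a + b * np.exp(-(k - 1.0) / lam) - p

    a0 = float(np.clip(p.min(), 0.0, 1.0))
    b0 = float(np.clip(p[0] - a0, -1.0, 1.0))
    lam0 = max(n / 4.0, 1e-3)
    converged = True
    try:
        sol = least_squares(
            resid,
            x0=[a0, b0, lam0],
            bounds=([0.0, -1.0, 1e-9], [1.0, 1.0, 10.0 * n]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
        ok = sol.success
    except Exception:
        ok = False
    if ok:
        a, b, lam = map(float, sol.x)
        rss = float(np.sum(sol.fun**2))
    else:
        converged = False
        a, b, lam, rss = _grid_fit(k, p, n)

    if abs(b) < _FLAT_B:
        level = float(np.clip(p.mean(), 0.0, 1.0))
        half = math.nan
    else:
        level = float(np.clip(a + b * math.exp(-(n - 1.0) / lam), 0.0, 1.0))
        half = lam * math.log(2.0)
    return ExponentialFit(
        a=a, b=b, lam=lam, habituation_level=level, half_life=half, rss=rss, converged=converged
    )


def initial_response(profile: HabituationProfile) -> float:
    """Response probability at stimulus 1 (the naive response)."""
    row = profile.data.iloc[0]
    if row["n_tracked"] == 0:
        raise WormhabError(f"plate {profile.plate_id!r}: stimulus 1 has no tracked animals")
    return float(row["p"])


def response_magnitude(
    profile: HabituationProfile, variant: str = "initial"
) -> tuple[float, float]:
    """Tap-response magnitude as (duration_s, speed_mm_s).

    ``variant='initial'`` (default) returns the stimulus-1 responders'
    means, matching naive-response comparisons; ``variant='all'``
    averages the defined per-stimulus means over all stimuli.  Values
    are NaN when no responders exist in scope.
    """
    if variant == "initial":
        row = profile.data.iloc[0]
        if row["n_tracked"] == 0:
            raise WormhabError(f"plate {profile.plate_id!r}: stimulus 1 has no tracked animals")
        return float(row["mean_duration_s"]), float(row["mean_speed_mm_s"])
    if variant == "all":
        d = profile.defined
        return (
            float(d["mean_duration_s"].mean()),
            float(d["mean_speed_mm_s"].mean()),
        )
    raise WormhabError("variant must be 'initial' or 'all'")


def mean_profile(profiles: list[HabituationProfile]) -> HabituationProfile:
    """Cross-plate mean profile (for display-curve fits and figures).

    The mean at each stimulus averages the plates' defined p values; the
    returned denominators pool tracked animals across plates.  Group
    inference should use per-plate fits, not a fit to this mean curve.
    """
    if not profiles:
        raise WormhabError("no profiles to average")
    n = profiles[0].n_stimuli
    if any(pr.n_stimuli != n for pr in profiles):
        raise WormhabError("profiles have differing stimulus counts")
    rows = []
    for k in range(1, n + 1):
        ps, durs, spds, tracked, resp = [], [], [], 0, 0
        for pr in profiles:
            row = pr.data.iloc[k - 1]
            if row["n_tracked"] > 0:
                ps.append(row["p"])
                tracked += int(row["n_tracked"])
                resp += int(row["n_responded"])
                if row["n_responded"] > 0:
                    durs.append(row["mean_duration_s"])
                    spds.append(row["mean_speed_mm_s"])
        rows.append(
            (
                k,
                tracked,
                resp,
                float(np.mean(ps)) if ps else math.nan,
                float(np.mean(durs)) if durs else math.nan,
                float(np.mean(spds)) if spds else math.nan,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["stimulus", "n_tracked", "n_responded", "p", "mean_duration_s", "mean_speed_mm_s"],
    )
    return HabituationProfile(plate_id="<group-mean>", n_stimuli=n, data=df)
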