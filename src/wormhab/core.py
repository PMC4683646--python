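"""Core domain types shared across the package.

Units are fixed throughout: seconds, millimetres, radians.  A worm's
``theta`` is its body-axis orientation, measured counter-clockwise from
the +x axis and pointing toward the head; backward (reversal) movement
is displacement opposite this axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Protocol", "WormTrack", "PlateRecording", "WormhabError"]


class WormhabError(ValueError):
    """Base class for domain validation errors."""


@dataclass(frozen=True)
class Protocol:
    """Stimulus/recording protocol for one assay plate.

    The standard tap-habituation protocol records for 400 s at ~13.5 Hz
    with 30 taps starting at 100 s and a 10-s interstimulus interval
    (the 45-tap variant records for 550 s).  Exploratory-locomotion
    sessions carry no taps (``n_stimuli = 0``).

    Parameters
    ----------
    baseline_s
        Seconds of recording before the first stimulus.
    n_stimuli
        Number of taps (0 for stimulus-free recordings).
    isi_s
        Interstimulus interval, seconds.
    total_s
        Total recording length, seconds.
    frame_rate_hz
        Sampling rate of the tracker.
    pixel_mm
        Spatial quantization of reported centroids in mm; 0 disables
        quantization.  The study camera's pixel size was 23.3 µm
        (0.0233 mm); conversion from pixel units is the caller's
        responsibility at the I/O boundary.
    """

    baseline_s: float = 100.0
    n_stimuli: int = 30
    isi_s: float = 10.0
    total_s: float = 400.0
    frame_rate_hz: float = 13.5
    pixel_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise WormhabError("frame_rate_hz must be > 0")
        if self.total_s <= 0:
            raise WormhabError("total_s must be > 0")
        if self.n_stimuli < 0:
            raise WormhabError("n_stimuli must be >= 0")
        if self.baseline_s < 0:
            raise WormhabError("baseline_s must be >= 0")
        if self.n_stimuli >= 1:
            if self.isi_s <= 0:
                raise WormhabError("isi_s must be > 0 when stimuli are present")
            last = self.baseline_s + (self.n_stimuli - 1) * self.isi_s
            if last >= self.total_s:
                raise WormhabError(
                    f"stimulus train ends at {last} s, at or beyond total_s={self.total_s}"
                )
        if self.pixel_mm < 0:
            raise WormhabError("pixel_mm must be >= 0")

    @property
    def tap_times(self) -> np.ndarray:
        """Tap times in seconds: baseline_s + k*isi_s for k = 0..n-1."""
        return self.baseline_s + self.isi_s * np.arange(self.n_stimuli, dtype=float)

    @property
    def frame_times(self) -> np.ndarray:
        n = int(round(self.total_s * self.frame_rate_hz)) + 1
        return np.arange(n) / self.frame_rate_hz

    @classmethod
    def tap_habituation(cls, n_stimuli: int = 30, **kw) -> "Protocol":
        """Standard tap protocol: 30 taps/400 s, or 45 taps/550 s."""
        total = kw.pop("total_s", 400.0 if n_stimuli <= 30 else 550.0)
        return cls(baseline_s=100.0, n_stimuli=n_stimuli, isi_s=10.0, total_s=total, **kw)

    @classmethod
    def exploration(cls, total_s: float = 300.0, **kw) -> "Protocol":
        """Stimulus-free 5-min exploratory recording."""
        return cls(baseline_s=0.0, n_stimuli=0, isi_s=10.0, total_s=total_s, **kw)


@dataclass
class WormTrack:
    """One tracked object's time series of centroid position and body axis.

    Times must be strictly increasing; gaps are permitted (trackers drop
    and re-acquire objects).
    """

    worm_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.theta.size == n):
            raise WormhabError(f"track {self.worm_id!r}: field lengths differ")
        if n == 0:
            raise WormhabError(f"track {self.worm_id!r}: empty track")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise WormhabError(f"track {self.worm_id!r}: time not strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def first_t(self) -> float:
        return float(self.t[0])

    @property
    def last_t(self) -> float:
        return float(self.t[-1])

    @property
    def duration_s(self) -> float:
        return self.last_t - self.first_t

    def clipped(self, t0: float, t1: float) -> "WormTrack | None":
        """Samples with t0 <= t <= t1, or None if fewer than one remains."""
        m = (self.t >= t0) & (self.t <= t1)
        if not m.any():
            return None
        return WormTrack(self.worm_id, self.t[m], self.x[m], self.y[m], self.theta[m])


@dataclass
class PlateRecording:
    """All tracks, stimulus events, and metadata for one assay plate."""

    plate_id: str
    genotype: str
    protocol: Protocol
    stimuli: np.ndarray
    tracks: list[WormTrack] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        if self.stimuli.size and (
            self.stimuli.min() < 0 or self.stimuli.max() > self.protocol.total_s
        ):
            raise WormhabError(
                f"plate {self.plate_id!r}: stimulus times outside [0, {self.protocol.total_s}]"
            )

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def track_by_id(self, worm_id: str) -> WormTrack:
        for tr in self.tracks:
            if tr.worm_id == worm_id:
                return tr
        raise KeyError(worm_id)
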