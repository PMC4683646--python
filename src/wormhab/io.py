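"""Plain-text file formats for plates and results, with exact
round-tripping.

Trajectory files are tab-separated, one sample per row
(``plate_id  worm_id  t_s  x_mm  y_mm  theta_rad``), preceded by
``#``-prefixed header lines carrying the protocol metadata as
``key = value`` pairs.  Floats are written with Python's shortest
round-trip representation, so ``read(write(x)) == x`` bit-exactly.

Events files hold one tap time per line, in seconds at millisecond
(3-decimal) resolution.  Results tables are CSV with a fixed header and
a closed metric-name registry.

All values are in seconds / millimetres / radians at this boundary;
conversion from tracker pixel units (x 0.0233 mm per pixel for the
reference camera) is the caller's responsibility.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PlateRecording, Protocol, WormhabError, WormTrack

__all__ = [
    "METRICS",
    "ResultsTable",
    "TrajectoryFormatError",
    "read_plate",
    "write_plate",
    "read_results",
    "write_results",
    "apply_roi",
]

METRICS = (
    "habituation_level",
    "half_life",
    "initial_probability",
    "fwd_fraction",
    "bwd_fraction",
    "fwd_speed",
    "bwd_speed",
    "response_duration",
    "response_speed",
    "harsh_day_mean",
)

_TRAJ_COLUMNS = ("plate_id", "worm_id", "t_s", "x_mm", "y_mm", "theta_rad")
_PROTOCOL_KEYS = ("baseline_s", "n_stimuli", "isi_s", "total_s", "frame_rate_hz", "pixel_mm")


class TrajectoryFormatError(WormhabError):
    """Malformed trajectory/events file; message names file and line."""


def write_plate(plate: PlateRecording, trajectory_file, events_file) -> None:
    """Write a plate to a trajectory TSV and a tap-events file.

    An empty plate yields a valid header-only trajectory file.  Tap
    times are written one per line at 3-decimal (ms) resolution, so
    stimuli must lie on the millisecond grid to round-trip exactly.
    """
    proto = plate.protocol
    lines = ["# wormhab trajectory v1"]
    lines.append(f"# plate_id = {plate.plate_id}")
    lines.append(f"# genotype = {plate.genotype}")
    for key in _PROTOCOL_KEYS:
        lines.append(f"# {key} = {getattr(proto, key)!r}")
    lines.append("\t".join(_TRAJ_COLUMNS))
    buf = _io.StringIO()
    buf.write("\n".join(lines) + "\n")
    for tr in plate.tracks:
        for t, x, y, th in zip(tr.t, tr.x, tr.y, tr.theta):
            buf.write(
                f"{plate.plate_id}\t{tr.worm_id}\t"
                f"{float(t)!r}\t{float(x)!r}\t{float(y)!r}\t{float(th)!r}\n"
            )
    Path(trajectory_file).write_text(buf.getvalue())
    Path(events_file).write_text(
        "".join(f"{t:.3f}\n" for t in plate.stimuli)
    )


def _parse_header(path: Path, lines: list[str]) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if "=" in body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
    else:
        i += 1
    return meta, i


def read_plate(
    trajectory_file,
    events_file,
    protocol: Protocol | None = None,
) -> PlateRecording:
    """Read a plate written by :func:`write_plate`.

    When ``protocol`` is None it is reconstructed from the header.
    Rows are grouped by worm id and must be time-sorted within each
    worm; a duplicated (worm_id, t) or non-monotone time raises a
    :class:`TrajectoryFormatError` naming file and line — rows are
    never silently dropped.
    """
    tpath = Path(trajectory_file)
    lines = tpath.read_text().splitlines()
    meta, start = _parse_header(tpath, lines)

    if protocol is None:
        try:
            protocol = Protocol(
                baseline_s=float(meta["baseline_s"]),
                n_stimuli=int(meta["n_stimuli"]),
                isi_s=float(meta["isi_s"]),
                total_s=float(meta["total_s"]),
                frame_rate_hz=float(meta["frame_rate_hz"]),
                pixel_mm=float(meta["pixel_mm"]),
            )
        except KeyError as e:
            raise TrajectoryFormatError(
                f"{tpath}: header missing protocol key {e.args[0]!r}"
            ) from None
    plate_id = meta.get("plate_id", tpath.stem)
    genotype = meta.get("genotype", "unknown")

    if start >= len(lines):
        raise TrajectoryFormatError(f"{tpath}: missing column header row")
    header = tuple(lines[start].rstrip("\n").split("\t"))
    if header != _TRAJ_COLUMNS:
        raise TrajectoryFormatError(
            f"{tpath}, line {start + 1}: expected columns {_TRAJ_COLUMNS}, got {header}"
        )

    data: dict[str, list[tuple[float, float, float, float]]] = {}
    last_t: dict[str, tuple[float, int]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(lines[start + 1 :], start=start + 2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 6:
            raise TrajectoryFormatError(
                f"{tpath}, line {lineno}: expected 6 tab-separated fields, got {len(parts)}"
            )
        _, worm_id, t_s, x_mm, y_mm, theta_rad = parts
        try:
            t, x, y, th = float(t_s), float(x_mm), float(y_mm), float(theta_rad)
        except ValueError:
            raise TrajectoryFormatError(
                f"{tpath}, line {lineno}: non-numeric sample field"
            ) from None
        if worm_id in last_t:
            prev, prev_line = last_t[worm_id]
            if t == prev:
                raise TrajectoryFormatError(
                    f"{tpath}, line {lineno}: duplicate (worm_id={worm_id!r}, t={t}) "
                    f"(first at line {prev_line})"
                )
            if t < prev:
                raise TrajectoryFormatError(
                    f"{tpath}, line {lineno}: time not increasing within worm "
                    f"{worm_id!r} ({t} after {prev})"
                )
        else:
            data[worm_id] = []
            order.append(worm_id)
        last_t[worm_id] = (t, lineno)
        data[worm_id].append((t, x, y, th))

    tracks = []
    for worm_id in order:
        arr = np.asarray(data[worm_id])
        tracks.append(WormTrack(worm_id, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]))

    epath = Path(events_file)
    stimuli = []
    for lineno, raw in enumerate(epath.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            stimuli.append(float(line))
        except ValueError:
            raise TrajectoryFormatError(
                f"{epath}, line {lineno}: non-numeric tap time {line!r}"
            ) from None
    if len(stimuli) != protocol.n_stimuli:
        raise TrajectoryFormatError(
            f"{epath}: {len(stimuli)} tap times but protocol specifies {protocol.n_stimuli}"
        )
    return PlateRecording(
        plate_id=plate_id,
        genotype=genotype,
        protocol=protocol,
        stimuli=np.asarray(stimuli),
        tracks=tracks,
    )


@dataclass
class ResultsTable:
    """Long-format results: one row per (plate_id, metric).

    Columns: plate_id, genotype, metric, value, n.  Metric names come
    from the fixed :data:`METRICS` registry.
    """

    data: pd.DataFrame = field(default_factory=lambda: ResultsTable.empty_frame())

    @staticmethod
    def empty_frame() -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plate_id": pd.Series(dtype=str),
                "genotype": pd.Series(dtype=str),
                "metric": pd.Series(dtype=str),
                "value": pd.Series(dtype=float),
                "n": pd.Series(dtype=int),
            }
        )

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        bad = set(self.data["metric"]) - set(METRICS)
        if bad:
            raise WormhabError(f"unregistered metric name(s): {sorted(bad)}")
        dup = self.data.duplicated(subset=["plate_id", "metric"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise WormhabError(
                f"duplicate row for (plate_id={row['plate_id']!r}, metric={row['metric']!r})"
            )

    def add(self, plate_id: str, genotype: str, metric: str, value: float, n: int) -> None:
        if metric not in METRICS:
            raise WormhabError(
                f"unregistered metric {metric!r}; valid metrics: {', '.join(METRICS)}"
            )
        row = pd.DataFrame(
            [{"plate_id": plate_id, "genotype": genotype, "metric": metric,
              "value": float(value), "n": int(n)}]
        )
        self.data = pd.concat([self.data, row], ignore_index=True)
        self._validate()

    def group_values(self, metric: str, genotype: str) -> np.ndarray:
        m = (self.data["metric"] == metric) & (self.data["genotype"] == genotype)
        return self.data.loc[m, "value"].to_numpy()

    def sorted(self) -> "ResultsTable":
        df = self.data.sort_values(["genotype", "plate_id", "metric"], kind="mergesort")
        return ResultsTable(df.reset_index(drop=True))


def write_results(table: ResultsTable, path) -> None:
    """Write a results table as CSV (float values at full precision)."""
    df = table.data.copy()
    df["value"] = df["value"].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)


def read_results(path) -> ResultsTable:
    """Read a results CSV; unknown metric names are an error."""
    df = pd.read_csv(
        path,
        dtype={"plate_id": str, "genotype": str, "metric": str, "value": float, "n": int},
    )
    expected = ["plate_id", "genotype", "metric", "value", "n"]
    if list(df.columns) != expected:
        raise WormhabError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return ResultsTable(df)


def apply_roi(
    plate: PlateRecording, roi: tuple[float, float, float, float]
) -> PlateRecording:
    """Optional rectangular region-of-interest crop (xmin, xmax, ymin, ymax).

    Samples outside the ROI are removed (edge regions of real plates
    track poorly); a track whose remaining samples are discontinuous
    keeps its id with internal gaps, and tracks left with fewer than
    one sample are dropped.  No default geometry is claimed.
    """
    xmin, xmax, ymin, ymax = roi
    if not (xmin < xmax and ymin < ymax):
        raise WormhabError("roi must satisfy xmin < xmax and ymin < ymax")
    tracks = []
    for tr in plate.tracks:
        m = (tr.x >= xmin) & (tr.x <= xmax) & (tr.y >= ymin) & (tr.y <= ymax)
        if not m.any():
            continue
        tracks.append(WormTrack(tr.worm_id, tr.t[m], tr.x[m], tr.y[m], tr.theta[m]))
    return dataclasses.replace(plate, tracks=tracks)
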