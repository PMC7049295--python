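"""Tracked-trajectory tables and the two population statistics built on them.

A :class:`Track` holds the time-lapse positions of one tracked (or synthetic)
agent at a fixed frame interval, together with the kinematic sequence derived
from it: the frame-to-frame speed and the signed rate of orientation change.
These sequences are what the in-sequence motility sampler replays, so the
conventions fixed here (turn-rate sign and alignment) are load-bearing for
exact trajectory reintegration.

Two population statistics are provided:

* ``persistence`` -- net displacement over path length, a dimensionless
  measure in [0, 1] of how straight an agent's path is over a time horizon;
* ``cpc`` -- the chemotaxis partition coefficient (B_R - B_L)/(B_R + B_L),
  the normalized left/right imbalance of a population about a midline,
  the standard readout for migration bias in a linear gradient.

Conventions
-----------
Coordinates are continuous 2D micrometres; positive turn rate is
counter-clockwise in the image plane; turn angles are the smallest signed
angle in (-180, 180] degrees.  ``turn_rates[0]`` is defined as 0 (there is
no orientation change leading into the first velocity vector), so that
``len(speeds) == len(turn_rates) == len(positions) - 1`` and a
rotate-then-translate replay starting from the first velocity's heading
reproduces the positions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrajectoryLibrary",
    "read_tracks",
    "write_tracks",
    "extract_kinematics",
    "write_kinematics",
    "persistence",
    "persistence_curve",
    "cpc",
]


@dataclass
class Track:
    """One agent path: positions at a fixed frame interval plus kinematics.

    Parameters
    ----------
    track_id
        Identifier carried through from the tracking table.
    frame_interval
        Seconds between successive positions (e.g. 1/14.1 for NanoBEADS
        imaged at 14.1 FPS, 1/1.3 for BacteriaBots); must be positive.
    positions
        ``(n, 2)`` array of (x, y) in micrometres, ordered by frame.
    speeds, turn_rates
        Kinematic sequence of length ``n - 1``; empty until
        :func:`extract_kinematics` fills them.  Speeds are um/s; turn rates
        are signed deg/s, ``turn_rates[0] == 0`` by convention.
    """

    track_id: str
    frame_interval: float
    positions: np.ndarray
    speeds: np.ndarray = field(default_factory=lambda: np.empty(0))
    turn_rates: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.speeds = np.asarray(self.speeds, dtype=float)
        self.turn_rates = np.asarray(self.turn_rates, dtype=float)
        if self.frame_interval <= 0:
            raise ValueError(f"track {self.track_id!r}: frame_interval must be > 0")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError(f"track {self.track_id!r}: positions must be (n, 2)")
        if self.speeds.size and np.any(self.speeds < 0):
            raise ValueError(f"track {self.track_id!r}: speeds must be >= 0")

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1

    @property
    def duration(self) -> float:
        """Total tracked time in seconds."""
        return self.n_steps * self.frame_interval


@dataclass
class TrajectoryLibrary:
    """A set of tracks plus the two orientation-sampling groups.

    ``group_pos``/``group_neg`` are disjoint index sets over ``tracks`` used
    by the motility sampler: agents oriented toward increasing gradient draw
    replacement tracks from ``group_pos``, agents oriented away draw from
    ``group_neg``.  The groups are an equal (+-1) random split of the whole
    library; which split is used is what the chemotactic-bias calibration
    optimizes.
    """

    tracks: list[Track]
    agent_kind: str = "nanobeads"
    group_pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    group_neg: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __post_init__(self) -> None:
        self.group_pos = np.asarray(self.group_pos, dtype=np.intp)
        self.group_neg = np.asarray(self.group_neg, dtype=np.intp)
        if self.group_pos.size or self.group_neg.size:
            combined = np.sort(np.concatenate([self.group_pos, self.group_neg]))
            if not np.array_equal(combined, np.arange(len(self.tracks))):
                raise ValueError("group_pos and group_neg must partition the tracks")
            if abs(self.group_pos.size - self.group_neg.size) > 1:
                raise ValueError("groups must be an equal split (+-1)")

    def __len__(self) -> int:
        return len(self.tracks)


def read_tracks(path, frame_interval: float) -> list[Track]:
    """Read a tracked-position CSV into per-track position arrays.

    The file must have columns ``track_id,frame,x_um,y_um`` (header
    required).  Frames within a track must be consecutive once sorted;
    kinematics are left empty until :func:`extract_kinematics`.
    """
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            raise ValueError(f"track {tid!r}: duplicated (track_id, frame) rows")
        if not np.array_equal(np.diff(frames), np.ones(len(frames) - 1)):
            raise ValueError(f"track {tid!r}: frames are not consecutive")
        if len(frames) < 3:
            raise ValueError(f"track {tid!r}: fewer than 3 positions")
        tracks.append(
            Track(
                track_id=str(tid),
                frame_interval=frame_interval,
                positions=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    """Write tracks in the same CSV dialect ``read_tracks`` accepts."""
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": np.arange(len(t.positions)),
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _signed_angle_deg(v0: np.ndarray, v1: np.ndarray) -> np.ndarray:
    """Smallest signed angle (deg, CCW positive, in (-180, 180]) from v0 to v1."""
    ang = np.degrees(
        np.arctan2(
            v0[..., 0] * v1[..., 1] - v0[..., 1] * v1[..., 0],
            v0[..., 0] * v1[..., 0] + v0[..., 1] * v1[..., 1],
        )
    )
    # arctan2 returns [-180, 180]; fold -180 onto +180 for the half-open range
    return np.where(ang == -180.0, 180.0, ang)


def extract_kinematics(track: Track) -> Track:
    """Fill ``speeds`` and ``turn_rates`` from the position sequence.

    The velocity vector between every two successive positions gives the
    speed; the signed angle between successive velocity vectors, divided by
    the frame interval, gives the turn rate.  Intervals with zero
    displacement record speed 0 and propagate a turn rate of 0 (the
    orientation is carried over), preserving sequence length.  Stored in
    sequence; order is everything for the replay sampler.
    """
    if len(track.positions) < 2:
        raise ValueError(f"track {track.track_id!r}: need at least 2 positions")
    dt = track.frame_interval
    disp = np.diff(track.positions, axis=0)  # (n-1, 2)
    seg = np.hypot(disp[:, 0], disp[:, 1])
    track.speeds = seg / dt
    turn = np.zeros(len(disp))
    if len(disp) > 1:
        v0, v1 = disp[:-1], disp[1:]
        ang = _signed_angle_deg(v0, v1)
        # zero-length velocity on either side: turn undefined -> carried as 0
        ok = (seg[:-1] > 0) & (seg[1:] > 0)
        turn[1:] = np.where(ok, ang, 0.0) / dt
    track.turn_rates = turn
    return track


def write_kinematics(tracks: list[Track], path) -> None:
    """Write per-track kinematics as ``track_id,step,speed_um_s,turn_rate_deg_s``."""
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "step": np.arange(len(t.speeds)),
                    "speed_um_s": t.speeds,
                    "turn_rate_deg_s": t.turn_rates,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def persistence(track: Track, n_steps: int) -> float:
    """Displacement-over-distance persistence after ``n_steps`` frames.

    Returns the straight-line displacement from the start position to the
    position ``n_steps`` frames later, divided by the summed step lengths,
    a ratio in [0, 1]: 1 for straight monotone motion, approaching 0 for
    confined wandering.  An agent that never moved (zero path length) is
    trivially persistent and scores 1.
    """
    if not 1 <= n_steps <= track.n_steps:
        raise ValueError(
            f"n_steps must be in [1, {track.n_steps}] for track {track.track_id!r}"
        )
    p = track.positions
    displacement = float(np.hypot(*(p[n_steps] - p[0])))
    steps = np.diff(p[: n_steps + 1], axis=0)
    distance = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    if distance == 0.0:
        return 1.0
    return min(displacement / distance, 1.0)


def persistence_curve(track: Track) -> np.ndarray:
    """Persistence at every horizon 1..n_steps (the per-agent persistence-vs-time trace)."""
    p = track.positions
    steps = np.diff(p, axis=0)
    dist = np.cumsum(np.hypot(steps[:, 0], steps[:, 1]))
    disp = np.hypot(p[1:, 0] - p[0, 0], p[1:, 1] - p[0, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(dist > 0, disp / dist, 1.0)
    return np.minimum(out, 1.0)


def cpc(x_positions, midline: float) -> float:
    """Chemotaxis partition coefficient (B_R - B_L)/(B_R + B_L).

    ``B_R`` counts agents with x >= midline and ``B_L`` those with
    x < midline (ties go right; measure-zero under continuous motion).
    Returns a ratio in [-1, 1]: +1 means the whole population sits right of
    the midline, 0 means no bias.
    """
    x = np.asarray(x_positions, dtype=float)
    if x.size == 0:
        raise ValueError("cpc requires at least one agent")
    br = int(np.count_nonzero(x >= midline))
    bl = x.size - br
    return (br - bl) / (br + bl)
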