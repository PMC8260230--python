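"""Track containers and the shared embryo coordinate convention.

Coordinates are micrometres in a fixed embryo frame: ``x`` is mediolateral
with the midline at x = 0 (motion toward x = 0 is convergence), ``y`` is
anteroposterior and increases posteriorly.  Time is minutes.

A :class:`Track` is one cell's time-ordered position samples plus a final
status: ``live`` (still present when the movie ends), ``ingressed`` (left
the epiblast; the track is censored), ``divided`` (the track ends at a
division and two daughter tracks begin), or ``lost`` (tracking failure).
"""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Track", "TrackSet", "Region", "STATUSES"]

STATUSES = ("live", "ingressed", "divided", "lost")


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangular region of interest in embryo coordinates (µm)."""

    label: str
    x_min: float = -np.inf
    x_max: float = np.inf
    y_min: float = -np.inf
    y_max: float = np.inf

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )


@dataclass
class Track:
    track_id: int
    parent_id: int | None
    t: np.ndarray  # minutes, strictly increasing
    x: np.ndarray  # µm, mediolateral
    y: np.ndarray  # µm, anteroposterior (posterior positive)
    status: str = "live"
    frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.frame is None:
            self.frame = np.arange(len(self.t))
        else:
            self.frame = np.asarray(self.frame, dtype=int)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def t_start(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def position_at(self, t: float) -> tuple[float, float] | None:
        """Linearly interpolated position at time t, or None outside the span."""
        if t < self.t[0] or t > self.t[-1]:
            return None
        return (
            float(np.interp(t, self.t, self.x)),
            float(np.interp(t, self.t, self.y)),
        )


@dataclass
class TrackSet:
    """An ordered collection of tracks sharing one coordinate frame."""

    tracks: list[Track] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, track_id: int) -> Track:
        return self._index()[track_id]

    def _index(self) -> dict[int, Track]:
        return {tr.track_id: tr for tr in self.tracks}

    def children(self) -> dict[int, list[int]]:
        """Map of track_id -> daughter track ids."""
        out: dict[int, list[int]] = {}
        for tr in self.tracks:
            if tr.parent_id is not None:
                out.setdefault(tr.parent_id, []).append(tr.track_id)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: track_id, parent_id, frame, t_min, x_um, y_um, status."""
        parts = []
        for tr in self.tracks:
            parts.append(
                pd.DataFrame(
                    {
                        "track_id": tr.track_id,
                        "parent_id": -1 if tr.parent_id is None else tr.parent_id,
                        "frame": tr.frame,
                        "t_min": tr.t,
                        "x_um": tr.x,
                        "y_um": tr.y,
                        "status": tr.status,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(
                columns=["track_id", "parent_id", "frame", "t_min", "x_um", "y_um", "status"]
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackSet":
        tracks = []
        for tid, grp in df.groupby("track_id", sort=True):
            grp = grp.sort_values("t_min")
            pid = int(grp["parent_id"].iloc[0])
            tracks.append(
                Track(
                    track_id=int(tid),
                    parent_id=None if pid < 0 else pid,
                    t=grp["t_min"].to_numpy(),
                    x=grp["x_um"].to_numpy(),
                    y=grp["y_um"].to_numpy(),
                    status=str(grp["status"].iloc[0]),
                    frame=grp["frame"].to_numpy(),
                )
            )
        return cls(tracks)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrackSet":
        return cls.from_dataframe(pd.read_csv(path))
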