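"""Time-ordered 2D single-molecule trajectories and their CSV form."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_trajectory_csv", "write_trajectory_csv"]


@dataclass
class Trajectory:
    """A tracked molecule: frame indices and positions in micrometres.

    Frames are strictly increasing but need not be contiguous (gap-closed
    links leave missing frames). ``frame_interval`` is the acquisition lag
    in seconds (0.020 for the fast modality, 0.500 for the slow one);
    ``pixel_size`` the camera pixel in micrometres.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float
    pixel_size: float = 0.1
    intensity: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) >= 2 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Span in seconds, counting both end frames."""
        return (int(self.frames[-1]) - int(self.frames[0]) + 1) * self.frame_interval

    def jumps(self, lag: int = 1, contiguous: bool = True) -> np.ndarray:
        """Jump distances (um) between localizations ``lag`` frames apart.

        With ``contiguous`` (default) only windows free of gap-closed missing
        frames contribute, avoiding displacement/time ambiguity.
        """
        if len(self) < lag + 1:
            return np.empty(0)
        dx = self.x[lag:] - self.x[:-lag]
        dy = self.y[lag:] - self.y[:-lag]
        r = np.hypot(dx, dy)
        if contiguous:
            # frames i..i+lag must be consecutive integers
            ok = (self.frames[lag:] - self.frames[:-lag]) == lag
            step_ok = np.diff(self.frames) == 1
            if lag > 1:
                window_ok = np.ones(len(r), dtype=bool)
                for s in range(lag):
                    window_ok &= step_ok[s: s + len(r)]
                ok &= window_ok
            else:
                ok &= step_ok
            r = r[ok]
        return r

    def displacements(self) -> np.ndarray:
        """(n-1, 2) array of consecutive displacement vectors (contiguous frames only)."""
        d = np.column_stack([np.diff(self.x), np.diff(self.y)])
        return d[np.diff(self.frames) == 1]


def write_trajectory_csv(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    rows = []
    for t in trajectories:
        for f, xi, yi in zip(t.frames, t.x, t.y):
            rows.append((t.track_id, int(f), float(xi), float(yi)))
    pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_trajectory_csv(
    path: str | Path, frame_interval: float, pixel_size: float = 0.1
) -> list[Trajectory]:
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory table needs columns {sorted(required)}")
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                int(tid),
                grp["frame"].to_numpy(),
                grp["x_um"].to_numpy(),
                grp["y_um"].to_numpy(),
                frame_interval=frame_interval,
                pixel_size=pixel_size,
            )
        )
    return out
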