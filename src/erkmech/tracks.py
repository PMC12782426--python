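"""Tracked-cell containers and trajectory-level quality filters.

A :class:`CellTrack` holds one cell's time series of position and ERK
activity (FRET/CFP ratio at the centroid), as produced by a tracking tool
such as TrackMate. Positions are in pixels; the x axis is orthogonal to the
wound edge and the y axis parallel to it. Frames are sampled at a fixed
interval (2 min by default elsewhere in the package).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["cell_id", "frame", "x_px", "y_px", "erk"]


@dataclass
class CellTrack:
    """One cell's trajectory: positions and ERK activity per frame.

    Parameters
    ----------
    cell_id:
        Opaque identifier (kept as given; compared/sorted as string).
    frames:
        Strictly increasing integer frame indices with unit step.
    pos:
        ``(n, 2)`` array of (x, y) positions in pixels.
    erk:
        ``(n,)`` array of ERK activity (ratio units). May contain NaN
        before filtering; filtered tracks are NaN-free.
    """

    cell_id: str
    frames: np.ndarray
    pos: np.ndarray
    erk: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.pos = np.asarray(self.pos, dtype=float)
        self.erk = np.asarray(self.erk, dtype=float)
        n = len(self.frames)
        if self.pos.shape != (n, 2):
            raise ValueError(
                f"track {self.cell_id!r}: pos shape {self.pos.shape} != ({n}, 2)"
            )
        if self.erk.shape != (n,):
            raise ValueError(
                f"track {self.cell_id!r}: erk length {self.erk.shape} != {n}"
            )
        if n > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError(
                f"track {self.cell_id!r}: frame indices must increase with unit step"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    def has_missing(self) -> bool:
        """True if any position or ERK value is NaN."""
        return bool(np.isnan(self.pos).any() or np.isnan(self.erk).any())


def tracks_to_table(tracks: Iterable[CellTrack]) -> pd.DataFrame:
    """Flatten tracks into the delimited track-table layout (one row per
    cell-frame, columns cell_id, frame, x_px, y_px, erk)."""
    parts = []
    for t in tracks:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "frame": t.frames,
                    "x_px": t.pos[:, 0],
                    "y_px": t.pos[:, 1],
                    "erk": t.erk,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def table_to_tracks(table: pd.DataFrame) -> list[CellTrack]:
    """Group a track table into :class:`CellTrack` objects.

    Frame gaps within a cell are re-indexed to a contiguous range with NaN
    rows inserted, so that downstream missing-value filtering removes
    tracks whose cells dropped out of detection for some frames.
    """
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    tracks = []
    for cell_id, sub in table.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy(dtype=int)
        full = np.arange(frames[0], frames[-1] + 1)
        sub = sub.set_index("frame").reindex(full)
        tracks.append(
            CellTrack(
                cell_id=str(cell_id),
                frames=full,
                pos=sub[["x_px", "y_px"]].to_numpy(dtype=float),
                erk=sub["erk"].to_numpy(dtype=float),
            )
        )
    return tracks


def read_track_table(path: str | Path, sep: str = ",") -> list[CellTrack]:
    """Read a delimited track table (header cell_id, frame, x_px, y_px, erk;
    empty fields are missing values)."""
    table = pd.read_csv(path, sep=sep)
    return table_to_tracks(table)


def write_track_table(tracks: Iterable[CellTrack], path: str | Path, sep: str = ",") -> None:
    tracks_to_table(tracks).to_csv(path, sep=sep, index=False, float_format="%.9g")


@dataclass
class FilterReport:
    """Bookkeeping of why tracks were discarded by :func:`filter_trajectories`."""

    n_input: int = 0
    n_kept: int = 0
    too_short: list[str] = field(default_factory=list)
    has_missing: list[str] = field(default_factory=list)
    late_start: list[str] = field(default_factory=list)


def filter_trajectories(
    tracks: Sequence[CellTrack],
    min_frames: int = 400,
    require_first_frame: bool = False,
    first_frame: int | None = None,
    report: FilterReport | None = None,
) -> list[CellTrack]:
    """Keep tracks lasting at least ``min_frames`` frames with no missing
    values, optionally requiring the track to start at the dataset's first
    frame.

    Short tracks and tracks containing missing values are discarded rather
    than imputed, removing unstable trajectories that would add noise to
    the regression. ``first_frame`` defaults to the earliest start frame
    across the input. An empty result is returned as an empty list.
    """
    if report is None:
        report = FilterReport()
    report.n_input = len(tracks)
    if require_first_frame and first_frame is None and tracks:
        first_frame = min(t.start_frame for t in tracks)
    kept = []
    for t in tracks:
        if t.has_missing():
            report.has_missing.append(t.cell_id)
            continue
        if len(t) < min_frames:
            report.too_short.append(t.cell_id)
            continue
        if require_first_frame and t.start_frame != first_frame:
            report.late_start.append(t.cell_id)
            continue
        kept.append(t)
    report.n_kept = len(kept)
    logger.info(
        "filter_trajectories: kept %d/%d (short=%d, missing=%d, late-start=%d)",
        report.n_kept,
        report.n_input,
        len(report.too_short),
        len(report.has_missing),
        len(report.late_start),
    )
    return kept
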