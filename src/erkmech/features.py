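"""Per-cell, per-frame regression features from tracked trajectories.

For each cell and frame this module extracts the quantities entering the
convolutional acceleration model: the velocity component along a chosen
axis (x1), the spatial gradients of ERK activity (x2) and of the local
cell density (x3), and the second spatial derivatives of the velocity
component along x and y (x4, x5), together with the target acceleration.

Temporal derivatives come from a second-order Savitzky-Golay filter;
spatial derivatives from least-squares quadratic surface fits to
neighboring cells; the density field from a 2D Gaussian kernel density
estimate at cell positions. All internal units are pixels and frames; the
frame interval is applied only when converting to physical units for
reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.spatial.distance import cdist

from .tracks import CellTrack

logger = logging.getLogger(__name__)

#: feature-table column layout (one file per axis)
FEATURE_COLUMNS = [
    "cell_id",
    "frame",
    "axis",
    "accel",
    "x1_vel",
    "x2_erk_grad",
    "x3_rho_grad",
    "x4_d2v_dx2",
    "x5_d2v_dy2",
    "rho",
]

FEATURE_NAMES = ["x1_vel", "x2_erk_grad", "x3_rho_grad", "x4_d2v_dx2", "x5_d2v_dy2"]

AXES = ("orthogonal", "parallel")


@dataclass
class SmoothingConfig:
    """Smoothing and differentiation settings for feature extraction.

    sg_window / sg_order: Savitzky-Golay window (frames, odd) and
    polynomial order for temporal derivatives. fit_radius_erk /
    fit_radius_vel: neighborhood radii (px) for the quadratic surface fits
    of ERK and of velocity; the density fit reuses ``fit_radius_vel``.
    kde_sigma: Gaussian kernel width (px) of the density estimate.
    image_sigma: Gaussian blur (px) applied to FRET/CFP frames before
    ratioing. frame_interval: imaging cadence in minutes.
    """

    sg_window: int = 11
    sg_order: int = 2
    fit_radius_erk: float = 10.0
    fit_radius_vel: float = 10.0
    kde_sigma: float = 25.0
    image_sigma: float = 1.0
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        for name in ("fit_radius_erk", "fit_radius_vel", "kde_sigma", "image_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


class SavgolResult(NamedTuple):
    """Interior-frame temporal derivatives of one track (px/frame units)."""

    frames: np.ndarray  # frames retaining a full centered window
    vel: np.ndarray  # (m, 2) first derivative
    acc: np.ndarray  # (m, 2) second derivative


def savgol_derivatives(track: CellTrack, cfg: SmoothingConfig) -> SavgolResult:
    """Velocity and acceleration of a track by Savitzky-Golay filtering.

    At each frame with a full centered window, the returned velocity and
    acceleration are the first and second derivatives of the local
    least-squares polynomial of order ``cfg.sg_order`` over the window —
    exact for trajectories that are polynomials of that order. Frames
    within half a window of either end are dropped (no mirroring), so a
    track of length n yields n - (sg_window - 1) interior frames.
    """
    n = len(track)
    if n < cfg.sg_window:
        raise ValueError(
            f"track {track.cell_id!r} has {n} frames, "
            f"shorter than the Savitzky-Golay window ({cfg.sg_window})"
        )
    half = cfg.sg_window // 2
    vel = savgol_filter(track.pos, cfg.sg_window, cfg.sg_order, deriv=1, delta=1.0, axis=0)
    acc = savgol_filter(track.pos, cfg.sg_window, cfg.sg_order, deriv=2, delta=1.0, axis=0)
    sl = slice(half, n - half)
    return SavgolResult(track.frames[sl].copy(), vel[sl], acc[sl])


class QuadFit(NamedTuple):
    """Quadratic surface fit at a point: value, gradient, and the pure
    second derivatives (d2/dx2, d2/dy2); ``usable`` is False when fewer
    than six in-radius points (or a rank-deficient design) were available."""

    value: float
    grad: np.ndarray  # (2,)
    second: np.ndarray  # (2,)
    n_points: int
    usable: bool


_UNUSABLE = QuadFit(np.nan, np.full(2, np.nan), np.full(2, np.nan), 0, False)


def local_quadratic_fit(
    center: np.ndarray,
    points: np.ndarray,
    values: np.ndarray,
    radius: float,
) -> QuadFit:
    """Least-squares fit of a full 2D quadratic surface to scattered values
    within ``radius`` of ``center``; derivatives are evaluated analytically
    at the center.

    The design is built in center-relative coordinates
    (1, dx, dy, dx^2, dx*dy, dy^2), which makes the fit invariant to
    translation of the coordinate origin. At least six in-radius points of
    full rank are required; otherwise the result is flagged unusable
    rather than silently zeroed.
    """
    center = np.asarray(center, dtype=float)
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float).ravel()
    d = points - center
    mask = np.einsum("ij,ij->i", d, d) <= radius * radius
    m = int(mask.sum())
    if m < 6:
        return _UNUSABLE
    dx, dy = d[mask, 0], d[mask, 1]
    design = np.column_stack([np.ones(m), dx, dy, dx * dx, dx * dy, dy * dy])
    coef, _, rank, _ = np.linalg.lstsq(design, values[mask], rcond=None)
    if rank < 6:
        return _UNUSABLE
    grad = np.array([coef[1], coef[2]])
    second = np.array([2.0 * coef[3], 2.0 * coef[5]])
    return QuadFit(float(coef[0]), grad, second, m, True)


def kde_density(
    positions: np.ndarray, queries: np.ndarray, kde_sigma: float
) -> np.ndarray:
    """Cell-density field by Gaussian kernel density estimation.

    rho(q) = sum_cells (2 pi sigma^2)^-1 exp(-|q - p|^2 / (2 sigma^2)),
    including the focal cell's own kernel, so the field integrates to the
    number of cells. An empty frame yields zeros.
    """
    if kde_sigma <= 0:
        raise ValueError("kde_sigma must be positive")
    queries = np.asarray(queries, dtype=float).reshape(-1, 2)
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(positions) == 0:
        return np.zeros(len(queries))
    d2 = cdist(queries, positions, "sqeuclidean")
    norm = 1.0 / (2.0 * np.pi * kde_sigma**2)
    return norm * np.exp(-d2 / (2.0 * kde_sigma**2)).sum(axis=1)


def _axis_indices(axis: str) -> tuple[int, int]:
    """(velocity component index, differentiation direction index)."""
    if axis == "orthogonal":
        return 0, 0
    if axis == "parallel":
        return 1, 1
    raise ValueError(f"axis must be one of {AXES}, got {axis!r}")


def assemble_feature_table(
    tracks: Sequence[CellTrack],
    cfg: SmoothingConfig,
    axis: str = "orthogonal",
) -> pd.DataFrame:
    """Build the per-cell, per-frame feature table for one axis.

    For ``axis='orthogonal'``: x1 = v_x, x2 = dERK/dx, x3 = drho/dx,
    x4 = d2 v_x/dx2, x5 = d2 v_x/dy2, target = a_x. For
    ``axis='parallel'`` the matching component v_y is used and ERK/rho are
    differentiated along y. Records whose spatial fits are unusable (too
    few in-radius neighbors) or whose temporal window is incomplete are
    dropped and counted; drop reasons are stored in ``df.attrs['drops']``.
    """
    if not tracks:
        raise ValueError("assemble_feature_table requires at least one track")
    comp, direction = _axis_indices(axis)

    # temporal derivatives per track
    sg: dict[str, SavgolResult] = {}
    drops = {"short_track": 0, "erk_fit": 0, "rho_fit": 0, "vel_fit": 0}
    for t in tracks:
        try:
            sg[t.cell_id] = savgol_derivatives(t, cfg)
        except ValueError:
            drops["short_track"] += len(t)

    # frame-indexed views: all present cells, and the subset with valid velocity
    frame_cells: dict[int, list[tuple[str, int]]] = {}
    for t in tracks:
        if t.cell_id not in sg:
            continue
        for j, f in enumerate(t.frames):
            frame_cells.setdefault(int(f), []).append((t.cell_id, j))
    by_id = {t.cell_id: t for t in tracks}

    records = []
    for f, members in sorted(frame_cells.items()):
        pos = np.array([by_id[cid].pos[j] for cid, j in members])
        erk = np.array([by_id[cid].erk[j] for cid, j in members])
        rho_all = kde_density(pos, pos, cfg.kde_sigma)

        # cells with a valid SG window at this frame
        vel_rows = []
        for idx, (cid, _) in enumerate(members):
            r = sg[cid]
            k = f - int(r.frames[0])
            if 0 <= k < len(r.frames):
                vel_rows.append((idx, cid, r.vel[k], r.acc[k]))
        if not vel_rows:
            continue
        vel_idx = np.array([row[0] for row in vel_rows])
        vel_pos = pos[vel_idx]
        vel_comp = np.array([row[2][comp] for row in vel_rows])

        for idx, cid, vel, acc in vel_rows:
            center = pos[idx]
            erk_fit = local_quadratic_fit(center, pos, erk, cfg.fit_radius_erk)
            if not erk_fit.usable:
                drops["erk_fit"] += 1
                continue
            rho_fit = local_quadratic_fit(center, pos, rho_all, cfg.fit_radius_vel)
            if not rho_fit.usable:
                drops["rho_fit"] += 1
                continue
            v_fit = local_quadratic_fit(center, vel_pos, vel_comp, cfg.fit_radius_vel)
            if not v_fit.usable:
                drops["vel_fit"] += 1
                continue
            records.append(
                (
                    cid,
                    f,
                    axis,
                    acc[comp],
                    vel[comp],
                    erk_fit.grad[direction],
                    rho_fit.grad[direction],
                    v_fit.second[0],
                    v_fit.second[1],
                    rho_all[idx],
                )
            )

    df = pd.DataFrame(records, columns=FEATURE_COLUMNS)
    df = df.sort_values(["cell_id", "frame"], kind="mergesort").reset_index(drop=True)
    df.attrs["drops"] = drops
    logger.info(
        "assemble_feature_table(axis=%s): %d records, drops=%s", axis, len(df), drops
    )
    return df


def read_feature_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns and c != "rho"]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, float_format="%.9g")


def feature_crosscorrelation(
    table: pd.DataFrame,
    max_lag_minutes: float = 100.0,
    frame_interval: float = 2.0,
) -> pd.DataFrame:
    """Mean pairwise Pearson cross-correlations of the input features.

    For each ordered feature pair (a, b) and lag ell in frames, computes
    corr(a(t), b(t + ell)) per cell over the overlapping segment and
    averages across cells, for lags spanning +/- ``max_lag_minutes``.
    Cells whose series are not longer than twice the maximum lag are
    skipped (count in ``df.attrs['skipped_cells']``). Lags are reported in
    minutes (negative lag: b leads a).
    """
    max_lag = int(round(max_lag_minutes / frame_interval))
    lags = np.arange(-max_lag, max_lag + 1)
    pair_sums: dict[tuple[str, str], np.ndarray] = {}
    pair_counts: dict[tuple[str, str], np.ndarray] = {}
    pairs = list(combinations_with_replacement(FEATURE_NAMES, 2))
    for p in pairs:
        pair_sums[p] = np.zeros(len(lags))
        pair_counts[p] = np.zeros(len(lags), dtype=int)
    skipped = 0
    for _, sub in table.groupby("cell_id"):
        sub = sub.sort_values("frame")
        n = len(sub)
        if n <= 2 * max_lag:
            skipped += 1
            continue
        series = {name: sub[name].to_numpy(dtype=float) for name in FEATURE_NAMES}
        for a, b in pairs:
            xa, xb = series[a], series[b]
            for i, ell in enumerate(lags):
                if ell >= 0:
                    u, v = xa[: n - ell], xb[ell:]
                else:
                    u, v = xa[-ell:], xb[: n + ell]
                su, sv = u.std(), v.std()
                if su == 0 or sv == 0:
                    continue
                c = np.corrcoef(u, v)[0, 1]
                pair_sums[(a, b)][i] += c
                pair_counts[(a, b)][i] += 1
    rows = []
    for (a, b), sums in pair_sums.items():
        counts = pair_counts[(a, b)]
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for ell, m in zip(lags, mean):
            rows.append((a, b, ell * frame_interval, m))
    out = pd.DataFrame(rows, columns=["feature_a", "feature_b", "lag_min", "corr"])
    out.attrs["skipped_cells"] = skipped
    return out
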