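"""Convolutional response-function regression for single-cell acceleration.

The model expresses a cell's acceleration along one axis as

    a(t) = w0 - w1 * x1(t) + sum_{i=2..5} sum_{tau=0}^{L-1} w_i(tau) * x_i(t - tau)

where x1 is the instantaneous velocity component (history excluded so the
model cannot trivially differentiate its own target), and x2..x5 are the
ERK-activity gradient, the cell-density gradient, and the two second
spatial derivatives of the velocity component, each entering through a
lag kernel w_i of length L ("response function"). Discretized, this is a
linear regression on a lagged design matrix, fitted by ridge regression
with the penalty strength selected by k-fold cross-validation. With L = 1
the model reduces to a plain multivariate linear regression on the five
instantaneous features.

Sign convention: the regression fits an unconstrained coefficient on x1
and reports w1 as its negative, so positive w1 means friction-like
damping. The per-frame time step is absorbed into the kernels, so kernel
units are per-input-unit per frame^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import GroupKFold, KFold

from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: names of the history-bearing features, in design-matrix order (x2..x5)
KERNEL_FEATURES = ("erk_grad", "rho_grad", "visc_x", "visc_y")

MODEL_FORMAT_VERSION = 1


@dataclass
class LagSpec:
    """Length of the input history window, in frames."""

    L: int = 20
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_params(self) -> int:
        return 2 + 4 * self.L


@dataclass
class ResponseFunction:
    """Fitted model: bias, instantaneous velocity coefficient, and four
    lag kernels of length L (order: erk_grad, rho_grad, visc_x, visc_y).

    ``kernels[i, tau]`` weights feature i at lag tau frames.
    """

    axis: str
    lag_spec: LagSpec
    w0: float
    w1: float
    kernels: np.ndarray  # (4, L)

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        if self.kernels.shape != (4, self.lag_spec.L):
            raise ValueError(
                f"kernels shape {self.kernels.shape} != (4, {self.lag_spec.L})"
            )

    # -- parameter-vector layout used by the solver -----------------------
    def to_theta(self) -> np.ndarray:
        """Flatten to the regression coefficient vector
        [w0, -w1, w2(0..L-1), w3(...), w4(...), w5(...)] of length 2+4L."""
        return np.concatenate([[self.w0, -self.w1], self.kernels.ravel()])

    @classmethod
    def from_theta(cls, theta: np.ndarray, axis: str, lag_spec: LagSpec) -> "ResponseFunction":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (lag_spec.n_params,):
            raise ValueError(f"theta length {theta.shape} != {lag_spec.n_params}")
        return cls(
            axis=axis,
            lag_spec=lag_spec,
            w0=float(theta[0]),
            w1=float(-theta[1]),
            kernels=theta[2:].reshape(4, lag_spec.L),
        )

    def flatten(self, include_bias: bool = False, include_velocity: bool = True) -> np.ndarray:
        """Kernel-space vector for similarity/PCA analyses, in the fixed
        order [w0?, w1?, w2(0..L-1), w3, w4, w5]."""
        head = []
        if include_bias:
            head.append(self.w0)
        if include_velocity:
            head.append(self.w1)
        return np.concatenate([head, self.kernels.ravel()])

    def kernel(self, name: str) -> np.ndarray:
        return self.kernels[KERNEL_FEATURES.index(name)]

    @property
    def lags_minutes(self) -> np.ndarray:
        return np.arange(self.lag_spec.L) * self.lag_spec.frame_interval

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "axis": self.axis,
            "lag": int(self.lag_spec.L),
            "frame_interval": float(self.lag_spec.frame_interval),
            "w0": float(self.w0),
            "w1": float(self.w1),
            "kernels": {
                name: [float(v) for v in self.kernels[i]]
                for i, name in enumerate(KERNEL_FEATURES)
            },
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "ResponseFunction":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version: {d.get('format_version')}")
        lag_spec = LagSpec(L=int(d["lag"]), frame_interval=float(d["frame_interval"]))
        kernels = np.array([d["kernels"][name] for name in KERNEL_FEATURES])
        return cls(axis=d["axis"], lag_spec=lag_spec, w0=float(d["w0"]), w1=float(d["w1"]), kernels=kernels)


@dataclass
class RidgeConfig:
    """Ridge-regression settings.

    ``lambda_`` is the L2 penalty strength (bias unpenalized); ``grid``
    overrides the broad cross-validation grid; ``grouping`` selects
    sample-wise or cell-wise (grouped) folds; ``standardize`` z-scores the
    penalized columns before fitting and rescales the reported kernels
    back to raw units.
    """

    lambda_: float = 1.0
    grid: np.ndarray | None = None
    folds: int = 5
    grouping: str = "sample-wise"
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.grouping not in ("sample-wise", "cell-wise"):
            raise ValueError("grouping must be 'sample-wise' or 'cell-wise'")


def build_design(
    table: pd.DataFrame, lag_spec: LagSpec, axis: str | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Lagged design matrix, target vector, and (cell, frame) row index.

    Each row corresponds to a (cell, frame) with at least L lags of
    history available within that cell's contiguous record:
    [1, x1(t), x2(t), x2(t-1), ..., x2(t-L+1), x3(t), ..., x5(t-L+1)],
    length 2 + 4L; the target is accel(t). Rows never span cell
    boundaries. Non-contiguous frames inside a cell raise an error naming
    the cell.
    """
    if axis is not None and "axis" in table.columns and len(table):
        found = set(table["axis"].unique())
        if found != {axis}:
            raise ValueError(f"feature table axis {found} does not match requested {axis!r}")
    L = lag_spec.L
    X_parts, y_parts, idx_parts = [], [], []
    for cell_id, sub in table.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy(dtype=int)
        if len(frames) > 1 and not np.all(np.diff(frames) == 1):
            raise ValueError(f"cell {cell_id!r}: frames are not contiguous")
        n = len(frames)
        if n < L:
            continue
        m = n - (L - 1)
        feats = {name: sub[name].to_numpy(dtype=float) for name in FEATURE_NAMES}
        cols = [np.ones((m, 1)), feats["x1_vel"][L - 1 :, None]]
        for name in FEATURE_NAMES[1:]:
            x = feats[name]
            # windows [t-L+1 .. t] reversed to lag order x(t), x(t-1), ...
            win = np.lib.stride_tricks.sliding_window_view(x, L)[:, ::-1]
            cols.append(win)
        X_parts.append(np.hstack(cols))
        y_parts.append(sub["accel"].to_numpy(dtype=float)[L - 1 :])
        idx_parts.append(
            pd.DataFrame({"cell_id": cell_id, "frame": frames[L - 1 :]})
        )
    if not X_parts:
        return (
            np.empty((0, lag_spec.n_params)),
            np.empty(0),
            pd.DataFrame(columns=["cell_id", "frame"]),
        )
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    index = pd.concat(idx_parts, ignore_index=True)
    return X, y, index


def _ridge_solve(X: np.ndarray, y: np.ndarray, lam: float, standardize: bool) -> np.ndarray:
    """Solve min ||y - X theta||^2 + lam ||theta_pen||^2 with the first
    (bias) coefficient unpenalized, via the normal equations."""
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("design matrix or target contains non-finite entries")
    p = X.shape[1]
    if standardize:
        mu = X[:, 1:].mean(axis=0)
        sd = X[:, 1:].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xs = X.copy()
        Xs[:, 1:] = (X[:, 1:] - mu) / sd
        theta_s = _ridge_solve(Xs, y, lam, standardize=False)
        theta = np.empty(p)
        theta[1:] = theta_s[1:] / sd
        theta[0] = theta_s[0] - mu @ theta[1:]
        return theta
    G = X.T @ X
    b = X.T @ y
    pen = np.ones(p)
    pen[0] = 0.0
    A = G + lam * np.diag(pen)
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def ridge_fit(
    X: np.ndarray,
    y: np.ndarray,
    cfg: RidgeConfig,
    axis: str = "orthogonal",
    lag_spec: LagSpec | None = None,
) -> ResponseFunction:
    """Fit the response function by ridge regression at ``cfg.lambda_``.

    Minimizes ||y - X theta||^2 + lambda ||theta||^2 over all coefficients
    except the bias, and unfolds the solution into a
    :class:`ResponseFunction` (w1 reported with the damping sign
    convention).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if (p - 2) % 4 != 0:
        raise ValueError(f"design width {p} is not of the form 2 + 4L")
    if lag_spec is None:
        lag_spec = LagSpec(L=(p - 2) // 4)
    theta = _ridge_solve(X, y, cfg.lambda_, cfg.standardize)
    return ResponseFunction.from_theta(theta, axis=axis, lag_spec=lag_spec)


def _fold_splits(n: int, cfg: RidgeConfig, groups: np.ndarray | None):
    if cfg.grouping == "cell-wise":
        if groups is None:
            raise ValueError("cell-wise grouping requires a groups array")
        n_groups = len(np.unique(groups))
        if n_groups < cfg.folds:
            raise ValueError(f"{n_groups} cells < {cfg.folds} folds")
        return list(GroupKFold(n_splits=cfg.folds).split(np.empty(n), groups=groups))
    if n < cfg.folds:
        raise ValueError(f"{n} rows < {cfg.folds} folds")
    kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    return list(kf.split(np.empty(n)))


def _cv_errors(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, splits, standardize: bool
) -> np.ndarray:
    """Mean held-out squared error per lambda across folds.

    The training-fold Gram matrices are formed once; each lambda then
    costs only a p x p solve per fold.
    """
    errs = np.zeros(len(lambdas))
    for train, val in splits:
        Xt, yt = X[train], y[train]
        Xv, yv = X[val], y[val]
        if standardize:
            mu = Xt[:, 1:].mean(axis=0)
            sd = Xt[:, 1:].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xt = Xt.copy()
            Xt[:, 1:] = (Xt[:, 1:] - mu) / sd
            Xv = Xv.copy()
            Xv[:, 1:] = (Xv[:, 1:] - mu) / sd
        G = Xt.T @ Xt
        b = Xt.T @ yt
        pen = np.ones(X.shape[1])
        pen[0] = 0.0
        for i, lam in enumerate(lambdas):
            theta = np.linalg.solve(G + lam * np.diag(pen), b)
            r = yv - Xv @ theta
            errs[i] += (r @ r) / len(yv)
    return errs / len(splits)


def cv_lambda(
    X: np.ndarray,
    y: np.ndarray,
    cfg: RidgeConfig,
    groups: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Select the ridge penalty by two-stage k-fold cross-validation.

    Stage one scans a broad geometric grid (10^-4 .. 10^4 by default);
    stage two refines within one decade either side of the broad argmin at
    20 points per decade. Returns the lambda minimizing the mean held-out
    squared error (ties broken toward larger lambda, i.e. more
    regularization) and the full error curve. Deterministic given
    ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    splits = _fold_splits(len(y), cfg, groups)
    broad = cfg.grid if cfg.grid is not None else np.logspace(-4, 4, 17)
    broad = np.asarray(broad, dtype=float)
    errs_broad = _cv_errors(X, y, broad, splits, cfg.standardize)
    center = broad[_argmin_prefer_larger(broad, errs_broad)]
    fine = np.logspace(np.log10(center) - 1.0, np.log10(center) + 1.0, 41)
    errs_fine = _cv_errors(X, y, fine, splits, cfg.standardize)
    lams = np.concatenate([broad, fine])
    errs = np.concatenate([errs_broad, errs_fine])
    order = np.argsort(lams, kind="mergesort")
    curve = pd.DataFrame({"lambda": lams[order], "cv_mse": errs[order]})
    best = lams[_argmin_prefer_larger(lams, errs)]
    logger.info("cv_lambda: selected lambda=%.6g", best)
    return float(best), curve


def _argmin_prefer_larger(lams: np.ndarray, errs: np.ndarray) -> int:
    """Index of the minimum error; exact ties go to the largest lambda."""
    best = np.min(errs)
    tied = np.flatnonzero(errs == best)
    return int(tied[np.argmax(lams[tied])])


def grouped_cv_stability(
    table: pd.DataFrame,
    lag_spec: LagSpec,
    cfg: RidgeConfig,
    axis: str | None = None,
) -> tuple[list[ResponseFunction], np.ndarray]:
    """Stability of the fitted response function under leave-cells-out.

    Splits cells into ``cfg.folds`` groups, refits the response function
    on each training set at ``cfg.lambda_``, and reports the fold models
    together with the pairwise cosine-similarity matrix of their kernel
    vectors. Nearly identical fold kernels indicate a stable fit.
    """
    X, y, index = build_design(table, lag_spec, axis=axis)
    groups = index["cell_id"].to_numpy()
    n_cells = len(np.unique(groups))
    if n_cells < cfg.folds:
        raise ValueError(f"{n_cells} cells < {cfg.folds} folds")
    splits = list(GroupKFold(n_splits=cfg.folds).split(X, groups=groups))
    ax = axis if axis is not None else (table["axis"].iloc[0] if len(table) else "orthogonal")
    rfs = [
        ridge_fit(X[train], y[train], cfg, axis=ax, lag_spec=lag_spec)
        for train, _ in splits
    ]
    vecs = [rf.flatten() for rf in rfs]
    k = len(vecs)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            sim[i, j] = sim[j, i] = cosine_similarity(vecs[i], vecs[j])
    return rfs, sim


def predict_acceleration(
    rf: ResponseFunction, table: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Model-predicted accelerations for every (cell, frame) of the table
    with full lag history, with the alignment index.

    The table must have been assembled for the same axis as ``rf``.
    """
    if "axis" in table.columns and len(table):
        found = set(table["axis"].unique())
        if found != {rf.axis}:
            raise ValueError(
                f"axis mismatch: model is {rf.axis!r}, table contains {found}"
            )
    X, _, index = build_design(table, rf.lag_spec)
    return X @ rf.to_theta(), index


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (|a| |b|); NaN (with a warning) for zero vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        logger.warning("cosine_similarity: zero vector, similarity undefined")
        return float("nan")
    return float(a @ b / (na * nb))


@dataclass
class ContinuumParams:
    """Mechanistic parameters of the continuum tissue model: basal
    friction mu0 (min^-1), ERK-friction gain beta, ERK-size gain alpha,
    spring constant k (min^-2), basal radius R0, viscosity eta."""

    mu0: float
    beta: float
    alpha: float
    k: float
    R0: float
    eta: float = 0.0


def coefficient_map(
    params: ContinuumParams, rho_ref: float, erk_ref: float = 0.0
) -> dict[str, float]:
    """Map mechanistic parameters to the regression coefficients of the
    instantaneous (L=1) linear model, evaluated at a reference density
    rho_ref and reference ERK level erk_ref.

    The continuum limit of the spring-particle tissue gives
    c_vel = -mu0 (1 - beta ERK), c_erk = -2 alpha k R0 / rho,
    c_rho = -k / rho^3, c_visc_x = c_visc_y = eta / rho^2; the mapping is
    valid only in the high-density regime and requires rho_ref > 0.
    """
    if rho_ref <= 0:
        raise ValueError("coefficient map requires rho_ref > 0")
    return {
        "c_vel": -params.mu0 * (1.0 - params.beta * erk_ref),
        "c_erk": -2.0 * params.alpha * params.k * params.R0 / rho_ref,
        "c_rho": -params.k / rho_ref**3,
        "c_visc_x": params.eta / rho_ref**2,
        "c_visc_y": params.eta / rho_ref**2,
    }
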