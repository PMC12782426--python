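"""Cell-cell heterogeneity of migratory response rules.

Fits a distinct response function to every cell, scores each cell by how
well the population-level model predicts its acceleration (Pearson
correlation), and characterizes the population structure: the pairwise
cosine-similarity matrix of per-cell response functions ordered by
prediction rank, a PCA of the flattened kernels, and mean response
functions of the best- and worst-predicted subgroups. Cohort-wise refits
(e.g. wound-front vs interior cells) use this same machinery on a
different input table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .inference import (
    LagSpec,
    ResponseFunction,
    RidgeConfig,
    build_design,
    cosine_similarity,
    predict_acceleration,
    ridge_fit,
)

logger = logging.getLogger(__name__)


@dataclass
class CellRFSet:
    """Per-cell response functions with population-model prediction scores.

    ``cell_ids`` is in rank order: descending prediction score, NaN
    scores last, ties broken by cell id.
    """

    cell_ids: list[str]
    rfs: dict[str, ResponseFunction]
    scores: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cell_ids)

    def vectors(self, include_bias: bool = False, include_velocity: bool = True) -> np.ndarray:
        """Stack of flattened rf vectors, rows in rank order."""
        return np.array(
            [self.rfs[c].flatten(include_bias, include_velocity) for c in self.cell_ids]
        )


def fit_per_cell(
    table: pd.DataFrame,
    lag_spec: LagSpec,
    lambda_: float,
    axis: str | None = None,
) -> tuple[dict[str, ResponseFunction], dict[str, str]]:
    """One ridge fit per cell at a fixed penalty (the population-level
    cross-validated lambda by default). Cells with fewer than L usable
    frames yield no design rows and are excluded with a reason."""
    rfs: dict[str, ResponseFunction] = {}
    excluded: dict[str, str] = {}
    cfg = RidgeConfig(lambda_=lambda_)
    for cell_id, sub in table.groupby("cell_id", sort=True):
        cell_id = str(cell_id)
        X, y, _ = build_design(sub, lag_spec, axis=axis)
        if len(y) == 0:
            excluded[cell_id] = "fewer than L usable frames"
            continue
        ax = axis if axis is not None else sub["axis"].iloc[0]
        rfs[cell_id] = ridge_fit(X, y, cfg, axis=ax, lag_spec=lag_spec)
    if excluded:
        logger.info("fit_per_cell: excluded %d cells", len(excluded))
    return rfs, excluded


def rank_cells(population_rf: ResponseFunction, table: pd.DataFrame) -> pd.DataFrame:
    """Score every cell by the Pearson correlation between its observed
    acceleration and the population model's prediction, sorted descending.

    Cells with undefined correlation (constant observed or predicted
    series, or too few rows) are scored NaN and ranked last; ties are
    broken by cell id.
    """
    pred, index = predict_acceleration(population_rf, table)
    obs = (
        table.set_index(["cell_id", "frame"])["accel"]
        .loc[pd.MultiIndex.from_frame(index)]
        .to_numpy()
    )
    rows = []
    for cell_id in index["cell_id"].unique():
        m = (index["cell_id"] == cell_id).to_numpy()
        o, p = obs[m], pred[m]
        if len(o) < 2 or o.std() == 0 or p.std() == 0:
            score = np.nan
        else:
            score = float(np.corrcoef(o, p)[0, 1])
        rows.append((str(cell_id), score))
    df = pd.DataFrame(rows, columns=["cell_id", "score"])
    df["_nan"] = df["score"].isna()
    df = (
        df.sort_values(["_nan", "score", "cell_id"], ascending=[True, False, True])
        .drop(columns="_nan")
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(len(df))
    return df


def per_cell_analysis(
    table: pd.DataFrame,
    population_rf: ResponseFunction,
    lambda_: float,
    axis: str | None = None,
) -> CellRFSet:
    """Per-cell fits plus population-model ranking, bundled in rank order."""
    lag_spec = population_rf.lag_spec
    rfs, excluded = fit_per_cell(table, lag_spec, lambda_, axis=axis)
    ranks = rank_cells(population_rf, table)
    ordered = [c for c in ranks["cell_id"] if c in rfs]
    scores = dict(zip(ranks["cell_id"], ranks["score"]))
    return CellRFSet(
        cell_ids=ordered,
        rfs=rfs,
        scores={c: scores.get(c, np.nan) for c in ordered},
        excluded=excluded,
    )


def similarity_matrix(
    rf_set: CellRFSet,
    include_bias: bool = False,
    include_velocity: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Pairwise cosine similarity of per-cell response functions.

    Vectors are the flattened concatenated kernels (bias excluded by
    default, velocity coefficient included); rows/columns follow the
    prediction-rank order so well-predicted cells sit toward the top
    left. Symmetric with unit diagonal.
    """
    if len(rf_set) < 2:
        raise ValueError("similarity matrix requires at least 2 cells")
    V = rf_set.vectors(include_bias, include_velocity)
    n = len(V)
    sim = np.eye(n)
    norms = np.linalg.norm(V, axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] == 0 or norms[j] == 0:
                sim[i, j] = sim[j, i] = np.nan
            else:
                sim[i, j] = sim[j, i] = V[i] @ V[j] / (norms[i] * norms[j])
    return sim, list(rf_set.cell_ids)


def pca_response_functions(
    rf_set: CellRFSet,
    n_components: int | None = None,
    include_bias: bool = False,
    include_velocity: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the per-cell response functions (mean-centered flattened
    kernels, no per-feature scaling).

    Returns the component scores (cells in rank order) and the
    explained-variance fractions, which sum to 1 over all components.
    """
    if len(rf_set) < 3:
        raise ValueError("PCA requires at least 3 cells")
    V = rf_set.vectors(include_bias, include_velocity)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(V)
    return scores, pca.explained_variance_ratio_


def subgroup_mean_rf(
    rf_set: CellRFSet, n_best: int = 20, n_worst: int = 20
) -> tuple[ResponseFunction, ResponseFunction]:
    """Mean response functions of the best- and worst-predicted subgroups.

    Cells are taken from the top and bottom of the prediction-rank order;
    kernels, bias and velocity coefficient are averaged arithmetically.
    """
    if n_best + n_worst > len(rf_set):
        raise ValueError(
            f"n_best + n_worst = {n_best + n_worst} exceeds {len(rf_set)} cells"
        )

    def mean_rf(ids: list[str]) -> ResponseFunction:
        rfs = [rf_set.rfs[c] for c in ids]
        ref = rfs[0]
        return ResponseFunction(
            axis=ref.axis,
            lag_spec=ref.lag_spec,
            w0=float(np.mean([r.w0 for r in rfs])),
            w1=float(np.mean([r.w1 for r in rfs])),
            kernels=np.mean([r.kernels for r in rfs], axis=0),
        )

    return mean_rf(rf_set.cell_ids[:n_best]), mean_rf(rf_set.cell_ids[-n_worst:])
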