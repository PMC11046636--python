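"""Recovering conceptual geometry from absolute gaze positions.

Rather than trial-to-trial displacements, these analyses ask where on the
screen the gaze sits before a given concept is named: per-concept mean
fixation positions, the regression of horizontal position on numerical
value (the mental-number-line slope), representational similarity analysis
between the matrix of pairwise fixation distances and the matrix of
conceptual distances, and a group-level reconstruction of the color wheel
by classical MDS of averaged, normalized per-subject fixation-distance
matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _procrustes
from scipy.spatial.distance import pdist, squareform

from .conceptspace import DissimilarityMatrix, Embedding2D, classical_mds
from .errors import AlignmentError, DataError, DegenerateDataError
from .trialstats import spearman_rho

__all__ = [
    "RegressionResult",
    "concept_mean_positions",
    "position_regression",
    "group_position_regression",
    "distance_matrix_from_points",
    "rsa_lower_triangle",
    "group_gaze_mds",
    "procrustes_disparity",
    "plot_concept_positions",
]


@dataclass
class RegressionResult:
    """Mental-number-line regression: px of gaze per unit concept value."""

    slope: float
    intercept: float
    per_subject_slopes: np.ndarray
    per_subject_intercepts: np.ndarray


def concept_mean_positions(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean of the per-trial median gaze positions, per concept.

    Only valid trials contribute; concepts with no valid trials are absent.
    Returns columns word, mean_x_px, mean_y_px, n_trials.
    """
    v = trials[trials["valid"]]
    if len(v) == 0:
        return pd.DataFrame(columns=["word", "mean_x_px", "mean_y_px", "n_trials"])
    g = v.groupby("word", sort=False).agg(
        mean_x_px=("median_x_px", "mean"),
        mean_y_px=("median_y_px", "mean"),
        n_trials=("word", "size")).reset_index()
    return g


def position_regression(table: pd.DataFrame, concept_values: dict,
                        axis: str = "x") -> tuple:
    """OLS of one subject's mean gaze position on the concept value.

    Returns (slope, intercept) in px per concept unit / px.
    """
    if axis not in ("x", "y"):
        raise DataError(f"axis must be 'x' or 'y', got {axis!r}")
    vals = np.asarray([float(concept_values[w]) for w in table["word"]])
    if len(np.unique(vals)) < 2:
        raise DegenerateDataError("need >= 2 distinct concept values")
    pos = table[f"mean_{axis}_px"].to_numpy(float)
    design = np.column_stack([vals, np.ones_like(vals)])
    (slope, intercept), *_ = np.linalg.lstsq(design, pos, rcond=None)
    return float(slope), float(intercept)


def group_position_regression(tables: Sequence[pd.DataFrame],
                              concept_values: dict,
                              axis: str = "x") -> RegressionResult:
    """Per-subject regressions summarized by their average coefficients.

    Group significance of the mean slope against zero is obtained by passing
    ``per_subject_slopes`` to :func:`gazegeom.trialstats.group_t`.
    """
    fits = [position_regression(t, concept_values, axis) for t in tables]
    slopes = np.asarray([f[0] for f in fits])
    intercepts = np.asarray([f[1] for f in fits])
    return RegressionResult(slope=float(slopes.mean()),
                            intercept=float(intercepts.mean()),
                            per_subject_slopes=slopes,
                            per_subject_intercepts=intercepts)


def distance_matrix_from_points(table: pd.DataFrame) -> DissimilarityMatrix:
    """Pairwise Euclidean distances between per-concept mean positions."""
    if len(table) < 2:
        raise DataError("need at least 2 concepts")
    pts = table[["mean_x_px", "mean_y_px"]].to_numpy(float)
    return DissimilarityMatrix(tuple(table["word"].astype(str)),
                               squareform(pdist(pts)))


def rsa_lower_triangle(dm_a: DissimilarityMatrix,
                       dm_b: DissimilarityMatrix) -> tuple:
    """Representational similarity: Spearman rho of the two lower triangles.

    Returns (rho, p) where p is the subject-less permutation-free p value of
    the rank correlation over pairs; group inference should instead pass the
    per-subject rho values (Fisher-z) to :func:`gazegeom.trialstats.group_t`.
    """
    if dm_a.labels != dm_b.labels:
        raise AlignmentError("matrices must share labels in the same order")
    if len(dm_a.labels) < 4:
        raise DataError("need at least 4 labels for RSA")
    from scipy import stats
    a, b = dm_a.lower_triangle(), dm_b.lower_triangle()
    rho = spearman_rho(a, b)   # raises UndefinedCorrelationError on constants
    p = float(stats.spearmanr(a, b).pvalue)
    return rho, p


def group_gaze_mds(matrices: Sequence[DissimilarityMatrix],
                   dims: int = 2) -> Embedding2D:
    """Group-level conceptual space from per-subject fixation distances.

    Each subject matrix is scaled to unit mean off-diagonal entry (removing
    the arbitrary spatial extent of each subject's gaze), matrices are
    averaged entrywise, and the average is embedded by classical MDS.
    Zero matrices are skipped with a warning.
    """
    labels = matrices[0].labels
    acc, used = None, 0
    for dm in matrices:
        if dm.labels != labels:
            raise AlignmentError("all matrices must share labels")
        mean_off = dm.lower_triangle().mean()
        if mean_off == 0:
            warnings.warn("skipping zero dissimilarity matrix")
            continue
        norm = dm.matrix / mean_off
        acc = norm if acc is None else acc + norm
        used += 1
    if used == 0:
        raise DataError("no usable (nonzero) matrices")
    return classical_mds(DissimilarityMatrix(labels, acc / used), dims=dims)


def procrustes_disparity(a: Embedding2D, b: Embedding2D) -> float:
    """Normalized residual misfit of b onto a after optimal translation,
    uniform scaling, and rotation/reflection; 0 means identical shapes."""
    if a.labels != b.labels:
        raise AlignmentError("embeddings must share labels in the same order")
    if a.coords.shape != b.coords.shape:
        raise DataError("embeddings must share dimensionality")
    for emb in (a, b):
        if np.allclose(emb.coords - emb.coords.mean(axis=0), 0):
            raise DegenerateDataError("all-coincident configuration")
    _, _, disparity = _procrustes(a.coords, b.coords)
    return float(disparity)


def plot_concept_positions(table: pd.DataFrame, path=None, ax=None,
                           invert_y: bool = True):
    """Scatter of per-concept mean gaze positions in screen coordinates.

    y is inverted by default because the tracker origin is the top-left
    corner of the screen.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["mean_x_px"], table["mean_y_px"])
    for _, row in table.iterrows():
        ax.annotate(str(row["word"]), (row["mean_x_px"], row["mean_y_px"]),
                    fontsize=8, xytext=(3, 3), textcoords="offset points")
    if invert_y:
        ax.invert_yaxis()
    ax.set_xlabel("gaze x (px)")
    ax.set_ylabel("gaze y (px)")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
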