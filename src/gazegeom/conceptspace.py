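"""Conceptual change/distance series and reconstruction of conceptual spaces.

Given the sequence of words a subject produced, these functions compute the
per-transition conceptual change under the distance model appropriate for
each domain:

* numbers: the signed numerical difference (next minus current);
* colors: the Euclidean distance in the subject-specific 2D embedding
  obtained by classical (Torgerson) multidimensional scaling of averaged
  1-9 similarity judgments (dissimilarity = 10 - mean similarity);
* animals: one of five models — cosine distance between word-embedding
  vectors, binary cluster jumps from a semantic labeling, externally rated
  similarity (10 - rating), Euclidean distance along the first principal
  component of the embedding vectors, or the unsigned difference in word
  frequency.

A transition-count series (how often each ordered word pair occurs in a
subject's blocks) is provided as a control covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateDataError

__all__ = [
    "ConceptChangeSeries",
    "DissimilarityMatrix",
    "Embedding2D",
    "signed_number_change",
    "dissimilarity_from_judgments",
    "classical_mds",
    "mds_distance_series",
    "animal_distance_series",
    "pc1_projection",
    "transition_count_series",
    "load_word2vec_text",
    "load_cluster_labels",
    "load_frequency_table",
    "load_similarity_matrix",
]

ANIMAL_MODELS = ("cosine", "cluster", "external_similarity", "pc1", "frequency")


@dataclass
class ConceptChangeSeries:
    """Per-transition conceptual change values aligned to trial transitions.

    ``index`` holds, for each value, the positional index of the first trial
    of the transition in the subject's full trial order; gaze displacement
    series carry the same indices, so the two can be intersected.
    """

    model: str
    values: np.ndarray
    index: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.index = np.asarray(self.index, dtype=int)
        if len(self.values) != len(self.index):
            raise DataError("values and index have unequal lengths")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DissimilarityMatrix:
    """Labeled symmetric non-negative dissimilarities with zero diagonal."""

    labels: tuple
    matrix: np.ndarray

    def __post_init__(self):
        self.labels = tuple(str(w) for w in self.labels)
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise DataError("matrix shape does not match labels")
        if not np.all(np.isfinite(m)):
            raise DataError("dissimilarities must be finite")
        if not np.allclose(m, m.T):
            raise DataError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise DataError("dissimilarity diagonal must be zero")
        self.matrix = m

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.labels), k=-1)
        return self.matrix[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))


@dataclass
class Embedding2D:
    """Centered low-dimensional coordinates, defined up to isometry."""

    labels: tuple
    coords: np.ndarray

    def __post_init__(self):
        self.labels = tuple(str(w) for w in self.labels)
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[0] != len(self.labels):
            raise DataError("coords shape does not match labels")
        self.coords = c

    def coord_of(self, word: str) -> np.ndarray:
        try:
            return self.coords[self.labels.index(str(word))]
        except ValueError:
            raise DataError(f"word {word!r} not in embedding") from None


# ---------------------------------------------------------------------------
# number line

def signed_number_change(seq: Sequence, start_index: int = 0) -> ConceptChangeSeries:
    """Signed numerical difference between consecutive words (next - current)."""
    vals = []
    for w in seq:
        try:
            vals.append(int(str(w)))
        except ValueError:
            raise DataError(f"word {w!r} does not parse as a number") from None
    v = np.asarray(vals, dtype=float)
    return ConceptChangeSeries("number_signed", np.diff(v),
                               start_index + np.arange(len(v) - 1))


# ---------------------------------------------------------------------------
# similarity judgments -> dissimilarity -> MDS

def dissimilarity_from_judgments(table: pd.DataFrame,
                                 labels: Sequence[str] | None = None) -> DissimilarityMatrix:
    """Average 1-9 similarity ratings per unordered pair; dissimilarity = 10 - mean.

    Ratings for (a, b) and (b, a), and across repetitions/days, are pooled.
    Every unordered pair of the label set must be rated at least once.
    """
    df = table.copy()
    df["word_a"] = df["word_a"].astype(str)
    df["word_b"] = df["word_b"].astype(str)
    if labels is None:
        labels = sorted(set(df["word_a"]) | set(df["word_b"]))
    labels = [str(w) for w in labels]
    idx = {w: i for i, w in enumerate(labels)}
    n = len(labels)
    s = np.zeros((n, n))
    cnt = np.zeros((n, n), dtype=int)
    for a, b, r in zip(df["word_a"], df["word_b"], df["rating"]):
        i, j = idx[a], idx[b]
        if i == j:
            continue
        s[i, j] += float(r)
        s[j, i] += float(r)
        cnt[i, j] += 1
        cnt[j, i] += 1
    iu = np.triu_indices(n, k=1)
    missing = [f"({labels[i]}, {labels[j]})"
               for i, j in zip(*iu) if cnt[i, j] == 0]
    if missing:
        raise DataError("unrated pairs: " + ", ".join(missing))
    d = np.zeros((n, n))
    d[cnt > 0] = 10.0 - s[cnt > 0] / cnt[cnt > 0]
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(tuple(labels), d)


def classical_mds(dm: DissimilarityMatrix, dims: int = 2) -> Embedding2D:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared dissimilarities, eigendecomposes, and builds
    coordinates from the top `dims` non-negative eigenvalues.  Negative
    eigenvalues (non-Euclidean noise) are clipped to zero; if fewer than
    `dims` positive eigenvalues exist the missing columns are zero-padded
    with a warning.  The output is centered by construction.
    """
    if dims < 1:
        raise DataError("dims must be >= 1")
    d = dm.matrix
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int(np.sum(evals > 1e-12))
    if n_pos < dims:
        warnings.warn(f"only {n_pos} positive eigenvalues; padding "
                      f"{dims - n_pos} zero dimension(s)")
    lam = np.clip(evals[:dims], 0.0, None)
    coords = evecs[:, :dims] * np.sqrt(lam)
    coords = coords - coords.mean(axis=0)
    return Embedding2D(dm.labels, coords)


def mds_distance_series(seq: Sequence[str], emb: Embedding2D,
                        start_index: int = 0) -> ConceptChangeSeries:
    """Euclidean distance between consecutive words in the 2D embedding."""
    pts = np.vstack([emb.coord_of(w) for w in seq])
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return ConceptChangeSeries("mds_distance", d,
                               start_index + np.arange(len(seq) - 1))


# ---------------------------------------------------------------------------
# animal distance models

def pc1_projection(vectors: dict) -> dict:
    """Project embedding vectors onto their first principal axis.

    Columns are centered (not scaled); the sign of the axis is arbitrary,
    which leaves all pairwise distances invariant.
    """
    labels = list(vectors)
    if len(labels) < 2:
        raise DataError("pc1 requires at least 2 labels")
    x = np.vstack([np.asarray(vectors[w], dtype=float) for w in labels])
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise DegenerateDataError("constant data has no principal axis")
    # leading right singular vector of the centered data = PC1
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    proj = xc @ vt[0]
    return {w: float(p) for w, p in zip(labels, proj)}


def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DataError("zero-norm vector under cosine distance")
    return float(1.0 - (u @ v) / (nu * nv))


def animal_distance_series(seq: Sequence[str], model: str, resources: dict,
                           start_index: int = 0,
                           graded_cluster: bool = False) -> ConceptChangeSeries:
    """Per-transition distance between consecutive animal words.

    model selects the distance rule and the resource it needs:

    * ``cosine`` — resources["vectors"]: word -> embedding vector;
    * ``cluster`` — resources["clusters"]: word -> set of semantic labels;
      emits 1 iff the two words share no label (a cluster jump), else 0
      (or, with graded_cluster, the negated count of shared labels);
    * ``external_similarity`` — resources["similarity"]: DissimilarityMatrix
      or labeled similarity DataFrame, transformed as 10 - rating;
    * ``pc1`` — resources["vectors"], absolute difference of PC1 scores;
    * ``frequency`` — resources["frequency"]: word -> frequency value,
      unsigned difference, used exactly as supplied (no log transform).
    """
    if model not in ANIMAL_MODELS:
        raise DataError(f"unknown distance model {model!r}")
    seq = [str(w) for w in seq]

    def _require(res_key: str) -> dict:
        res = resources.get(res_key)
        if res is None:
            raise DataError(f"model {model!r} requires resources[{res_key!r}]")
        missing = sorted(set(seq) - set(res))
        if missing:
            raise DataError(f"words missing from {res_key}: {', '.join(missing)}")
        return res

    if model == "cosine":
        vec = _require("vectors")
        vals = [_cosine_distance(np.asarray(vec[a], float), np.asarray(vec[b], float))
                for a, b in zip(seq, seq[1:])]
    elif model == "cluster":
        clus = _require("clusters")
        shared = [len(set(clus[a]) & set(clus[b])) for a, b in zip(seq, seq[1:])]
        vals = [-s for s in shared] if graded_cluster else \
               [0.0 if s > 0 else 1.0 for s in shared]
    elif model == "external_similarity":
        sim = resources.get("similarity")
        if sim is None:
            raise DataError("model 'external_similarity' requires resources['similarity']")
        if isinstance(sim, DissimilarityMatrix):
            lut = sim.to_frame()
            vals = [float(lut.loc[a, b]) for a, b in zip(seq, seq[1:])]
        else:
            lut = sim
            missing = sorted(set(seq) - set(map(str, lut.index)))
            if missing:
                raise DataError("words missing from similarity matrix: "
                                + ", ".join(missing))
            vals = [10.0 - float(lut.loc[a, b]) for a, b in zip(seq, seq[1:])]
    elif model == "pc1":
        vec = _require("vectors")
        p = pc1_projection({w: vec[w] for w in vec})
        vals = [abs(p[b] - p[a]) for a, b in zip(seq, seq[1:])]
    else:  # frequency
        freq = _require("frequency")
        vals = [abs(float(freq[b]) - float(freq[a])) for a, b in zip(seq, seq[1:])]
    return ConceptChangeSeries(model, np.asarray(vals, float),
                               start_index + np.arange(len(seq) - 1))


def transition_count_series(seqs: Sequence[Sequence[str]]) -> list[ConceptChangeSeries]:
    """Count of each ordered word pair across a subject's blocks.

    Every transition in every block is annotated with how often that exact
    ordered pair occurs over all blocks; returns one series per block with
    indices continuing across blocks (matching the concatenated trial order).
    """
    seqs = [[str(w) for w in s] for s in seqs]
    counts: dict = {}
    for s in seqs:
        for a, b in zip(s, s[1:]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    out, offset = [], 0
    for s in seqs:
        vals = [counts[(a, b)] for a, b in zip(s, s[1:])]
        out.append(ConceptChangeSeries("transition_count",
                                       np.asarray(vals, float),
                                       offset + np.arange(len(s) - 1)))
        offset += len(s)
    return out


# ---------------------------------------------------------------------------
# resource file readers

def load_word2vec_text(path: str | Path) -> dict:
    """Read embedding vectors in word2vec text format.

    First line is ``n dim``; each following line is ``word v1 ... vdim``.
    """
    vectors: dict = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise DataError("word2vec text file must start with 'n dim' header")
        n, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                raise DataError(f"malformed vector line: {line[:50]!r}")
            vectors[parts[0]] = np.asarray(parts[1:dim + 1], dtype=float)
    if len(vectors) != n:
        raise DataError(f"header declares {n} vectors, found {len(vectors)}")
    return vectors


def load_cluster_labels(path: str | Path) -> dict:
    """CSV (word, label); multi-label words use repeated rows."""
    df = pd.read_csv(path)
    out: dict = {}
    for w, lab in zip(df["word"].astype(str), df["label"].astype(str)):
        out.setdefault(w, set()).add(lab)
    return out


def load_frequency_table(path: str | Path) -> dict:
    """CSV (word, frequency)."""
    df = pd.read_csv(path)
    return {str(w): float(f) for w, f in zip(df["word"], df["frequency"])}


def load_similarity_matrix(path: str | Path) -> pd.DataFrame:
    """Labeled square similarity matrix as CSV (first column = labels)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
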