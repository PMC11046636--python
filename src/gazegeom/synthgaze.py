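"""Synthetic verbal-fluency eye-tracking sessions with known conceptual geometry.

The generator emulates the structure of a metronome-paced word-generation
block recorded with a desk-mounted eye tracker: words are produced at a
fixed pace (default 0.75 words/s) from a 12-item vocabulary, gaze is sampled
at 1000 Hz in screen pixels (origin top-left, y increasing downward), and in
the 500 ms window before each word onset the gaze sits near a screen
position that is an affine image of the word's latent conceptual coordinate
scaled by a coupling constant.  Between windows the gaze follows a random
walk.  Blinks/track losses are contiguous invalid runs.

Three conceptual domains are supported:

``number``
    latent coordinate = the integer value 1..12 (a 1D mental number line,
    embedded along the horizontal screen axis);
``color``
    latent coordinate = a point on the unit circle, 12 equally spaced hues
    (the color wheel, defined only up to rotation/reflection);
``animal``
    each label carries a (Zipf-like) word-frequency value; the embedded
    gaze effect couples the horizontal target to the *unsigned frequency
    difference* between consecutive words, i.e. small transitions sit left
    and large transitions sit right.  The per-label frequency values are
    still reported in the truth table.

Everything is reproducible from (config, seed): the same configuration and
seed produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gazeprep import GazeRecording

__all__ = [
    "Affine",
    "LatentGeometry",
    "SessionConfig",
    "Session",
    "generate_session",
    "simulate_subject",
    "generate_similarity_judgments",
    "inject_dropouts",
    "random_isometry_affine",
    "write_session_bundle",
]

# fraction of noise_sd used as iid within-window sample jitter; the per-trial
# fixation offset (sd = noise_sd) dominates the window median by construction
_WITHIN_WINDOW_JITTER = 0.2


@dataclass(frozen=True)
class Affine:
    """2D affine map ``p -> matrix @ p + offset`` (latent -> screen px)."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        b = np.asarray(self.offset, dtype=float).reshape(2)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", b)

    @property
    def singular(self) -> bool:
        return abs(np.linalg.det(self.matrix)) < 1e-12

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.offset

    @classmethod
    def identity(cls) -> "Affine":
        return cls(np.eye(2), np.zeros(2))


def random_isometry_affine(rng: np.random.Generator,
                           scale: float = 1.0,
                           center: Sequence[float] = (0.0, 0.0)) -> Affine:
    """Random rotation (and reflection with prob. 1/2) scaled by `scale`.

    Used to give every synthetic subject an idiosyncratic screen frame for
    the color ring: the wheel is only defined up to isometry, so subjects
    should not share an orientation.
    """
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    if rng.random() < 0.5:
        rot = rot @ np.array([[1.0, 0.0], [0.0, -1.0]])
    return Affine(scale * rot, np.asarray(center, dtype=float))


@dataclass(frozen=True)
class LatentGeometry:
    """12 concept labels with their latent conceptual coordinates.

    ``coords`` maps each label to a 1-vector (number value or animal word
    frequency) or a 2-vector (position on the color ring).
    """

    domain: str
    labels: tuple
    coords: dict

    def __post_init__(self):
        labels = tuple(str(w) for w in self.labels)
        if len(set(labels)) != len(labels):
            raise ConfigurationError("geometry labels must be unique")
        coords = {str(k): np.atleast_1d(np.asarray(v, dtype=float))
                  for k, v in self.coords.items()}
        if set(coords) != set(labels):
            raise ConfigurationError("coords must cover exactly the labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "coords", coords)

    @property
    def ndim(self) -> int:
        return len(next(iter(self.coords.values())))

    def coord_array(self, words: Sequence[str]) -> np.ndarray:
        return np.vstack([self.coords[w] for w in words])

    # -- canonical constructors -------------------------------------------

    @classmethod
    def number_line(cls) -> "LatentGeometry":
        """Integers 1..12 on a 1D line."""
        labels = [str(i) for i in range(1, 13)]
        return cls("number", tuple(labels), {w: [float(w)] for w in labels})

    @classmethod
    def color_ring(cls, labels: Sequence[str] | None = None) -> "LatentGeometry":
        """12 equally spaced points on the unit circle."""
        if labels is None:
            labels = ["red", "orange", "yellow", "lime", "green", "turquoise",
                      "cyan", "blue", "violet", "lilac", "pink", "magenta"]
        labels = list(labels)
        if len(labels) != 12:
            raise ConfigurationError("color ring requires 12 labels")
        ang = 2 * np.pi * np.arange(12) / 12
        return cls("color", tuple(labels),
                   {w: [np.cos(a), np.sin(a)] for w, a in zip(labels, ang)})

    @classmethod
    def animal_frequencies(cls, seed: int = 0,
                           labels: Sequence[str] | None = None,
                           log10_range: tuple = (0.0, 3.0)) -> "LatentGeometry":
        """12 animal words with log-uniform (Zipf-like) frequency values."""
        if labels is None:
            labels = ["dog", "cat", "horse", "cow", "sheep", "wolf",
                      "eagle", "sparrow", "shark", "dolphin", "ant", "bee"]
        labels = list(labels)
        if len(labels) != 12:
            raise ConfigurationError("animal geometry requires 12 labels")
        rng = np.random.default_rng(seed)
        freqs = 10 ** rng.uniform(*log10_range, size=12)
        return cls("animal", tuple(labels),
                   {w: [f] for w, f in zip(labels, freqs)})


@dataclass(frozen=True)
class SessionConfig:
    """All knobs of one synthetic block.

    coupling is in screen px per unit latent coordinate; noise_sd (px) is the
    per-trial scatter of the pre-onset fixation around its target; drift_sd
    (px per sample) is the step of the between-window random walk.
    """

    domain: str
    n_trials: int = 90
    pace_hz: float = 0.75
    sample_rate_hz: float = 1000.0
    coupling: float = 0.0
    noise_sd: float = 0.0
    drift_sd: float = 0.0
    dropout_rate: float = 0.0
    dropout_mean_len_ms: float = 100.0
    affine: Affine | None = None
    screen: tuple = (1920, 1080)
    window_ms: float = 500.0
    no_repeat: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.domain not in ("number", "color", "animal"):
            raise ConfigurationError(f"unknown domain {self.domain!r}")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be positive")
        if self.pace_hz <= 0 or self.sample_rate_hz <= 0:
            raise ConfigurationError("pace_hz and sample_rate_hz must be > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1]")
        if self.coupling < 0 or self.noise_sd < 0 or self.drift_sd < 0:
            raise ConfigurationError("coupling/noise_sd/drift_sd must be >= 0")
        if self.affine is not None and self.coupling > 0 and self.affine.singular:
            raise ConfigurationError("affine map is singular with coupling > 0")


@dataclass
class Session:
    """One generated block: gaze, word events, and the embedded ground truth."""

    recording: GazeRecording
    events: pd.DataFrame     # subject, block, word, onset_ms, offset_ms
    truth: pd.DataFrame      # trial, word, latent coords, target_x/y px


def _latent_points(config: SessionConfig, geometry: LatentGeometry,
                   words: list) -> np.ndarray:
    """Per-trial latent 2-vectors fed to the affine map (before coupling)."""
    if geometry.domain in ("number", "color"):
        c = geometry.coord_array(words)
        if c.shape[1] == 1:
            c = np.hstack([c, np.zeros_like(c)])
        return c
    # animal: horizontal target = unsigned frequency difference vs previous
    f = geometry.coord_array(words)[:, 0]
    dx = np.abs(np.diff(f, prepend=f[0]))
    return np.column_stack([dx, np.zeros_like(dx)])


def generate_session(config: SessionConfig, geometry: LatentGeometry,
                     subject: str = "s00", block: int = 0) -> Session:
    """Simulate one block of a verbal-fluency session.

    Word onsets are spaced 1/pace_hz apart, starting one pace period into
    the recording so the first pre-onset window exists.  Samples inside each
    pre-onset window sit at ``affine(coupling * latent) + trial offset``;
    samples outside follow a random walk anchored at the previous window.
    """
    if geometry.domain != config.domain:
        raise ConfigurationError(
            f"geometry domain {geometry.domain!r} != config domain {config.domain!r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    labels = list(geometry.labels)

    if config.no_repeat:
        words = [labels[rng.integers(len(labels))]]
        for _ in range(n - 1):
            prev = words[-1]
            choices = [w for w in labels if w != prev]
            words.append(choices[rng.integers(len(choices))])
    else:
        words = [labels[i] for i in rng.integers(len(labels), size=n)]

    latent = _latent_points(config, geometry, words)
    affine = config.affine
    if affine is None:
        # identity orientation, centered on the screen at the mean latent point
        center = np.array([config.screen[0] / 2, config.screen[1] / 2], float)
        affine = Affine(np.eye(2), center - config.coupling * latent.mean(axis=0))
    targets = affine.apply(config.coupling * latent)

    period_ms = 1000.0 / config.pace_hz
    onsets = period_ms * (np.arange(n) + 1)
    offsets = onsets + min(400.0, 0.5 * period_ms)
    dt = 1000.0 / config.sample_rate_hz
    t_end = onsets[-1] + period_ms
    time_ms = np.arange(0.0, t_end, dt)
    m = len(time_ms)

    xy = np.empty((m, 2))
    trial_offsets = rng.normal(0.0, config.noise_sd, size=(n, 2))
    jitter_sd = _WITHIN_WINDOW_JITTER * config.noise_sd
    pos = np.array([config.screen[0] / 2, config.screen[1] / 2], float)
    cursor = 0
    for i in range(n):
        w_start = np.searchsorted(time_ms, onsets[i] - config.window_ms, "left")
        w_end = np.searchsorted(time_ms, onsets[i], "left")
        # random walk from the end of the previous window to this window
        gap = w_start - cursor
        if gap > 0:
            steps = rng.normal(0.0, config.drift_sd, size=(gap, 2))
            xy[cursor:w_start] = pos + np.cumsum(steps, axis=0)
            pos = xy[w_start - 1]
        fix = targets[i] + trial_offsets[i]
        k = w_end - w_start
        if jitter_sd > 0:
            xy[w_start:w_end] = fix + rng.normal(0.0, jitter_sd, size=(k, 2))
        else:
            xy[w_start:w_end] = fix
        pos = fix
        cursor = w_end
    if cursor < m:
        steps = rng.normal(0.0, config.drift_sd, size=(m - cursor, 2))
        xy[cursor:] = pos + np.cumsum(steps, axis=0)

    np.clip(xy[:, 0], 0, config.screen[0], out=xy[:, 0])
    np.clip(xy[:, 1], 0, config.screen[1], out=xy[:, 1])

    rec = GazeRecording(time_ms=time_ms, x_px=xy[:, 0], y_px=xy[:, 1],
                        valid=np.ones(m, dtype=bool))
    if config.dropout_rate > 0:
        rec = inject_dropouts(rec, config.dropout_rate,
                              config.dropout_mean_len_ms,
                              seed=int(rng.integers(2**31)),
                              sample_rate_hz=config.sample_rate_hz)

    events = pd.DataFrame({
        "subject": subject, "block": block, "word": words,
        "onset_ms": onsets, "offset_ms": offsets,
    })
    truth = pd.DataFrame({
        "trial": np.arange(n), "word": words,
        "target_x_px": targets[:, 0], "target_y_px": targets[:, 1],
    })
    coords = geometry.coord_array(words)
    for d in range(coords.shape[1]):
        truth[f"latent_{'xy'[d] if coords.shape[1] > 1 else 'value'}"] = coords[:, d]
    return Session(recording=rec, events=events, truth=truth)


def simulate_subject(config: SessionConfig, geometry: LatentGeometry,
                     n_blocks: int = 3, subject: str = "s00") -> list[Session]:
    """Generate `n_blocks` independent blocks for one subject.

    Block b uses seed ``config.seed + b`` so blocks differ but the whole
    subject is reproducible from the base seed.
    """
    return [generate_session(replace(config, seed=config.seed + b), geometry,
                             subject=subject, block=b)
            for b in range(n_blocks)]


def generate_similarity_judgments(geometry: LatentGeometry, noise_sd: float,
                                  n_reps: int = 2, seed: int = 0,
                                  subject: str = "s00") -> pd.DataFrame:
    """Noisy 1-9 similarity ratings over all unordered label pairs.

    rating = clip(round(9 - 8*d/d_max + eps), 1, 9) with d the latent
    Euclidean distance and eps ~ N(0, noise_sd); each repetition emits both
    orderings of every pair, mirroring a two-day rating protocol.
    """
    if geometry.ndim < 2:
        raise ConfigurationError(
            "similarity judgments require a 2D geometry (color ring)")
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = geometry.labels
    pts = geometry.coord_array(labels)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    d_max = d.max()
    rows = []
    for rep in range(n_reps):
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                base = 9.0 - 8.0 * d[i, j] / d_max
                for a, b in ((i, j), (j, i)):
                    r = int(np.clip(np.round(base + rng.normal(0, noise_sd)), 1, 9))
                    rows.append((subject, rep, labels[a], labels[b], r))
    return pd.DataFrame(rows, columns=["subject", "day", "word_a", "word_b", "rating"])


def inject_dropouts(rec: GazeRecording, rate: float, mean_len_ms: float = 100.0,
                    seed: int = 0, sample_rate_hz: float = 1000.0) -> GazeRecording:
    """Mark contiguous runs invalid so the expected invalid fraction is `rate`.

    Runs emulate blinks / track losses: geometric lengths with the given
    mean, uniformly placed starts.  Timestamps and coordinates are untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("rate must be in [0, 1]")
    if mean_len_ms <= 0:
        raise ConfigurationError("mean_len_ms must be positive")
    n = len(rec.time_ms)
    if rate == 0.0 or n == 0:
        return rec
    valid = rec.valid.copy()
    if rate == 1.0:
        valid[:] = False
    else:
        rng = np.random.default_rng(seed)
        mean_len = max(1, int(round(mean_len_ms * sample_rate_hz / 1000.0)))
        target_invalid = rate * n
        invalid = np.zeros(n, dtype=bool)
        # draw runs until the expected budget is spent; overlaps are harmless
        while invalid.sum() < target_invalid:
            start = int(rng.integers(n))
            length = 1 + rng.geometric(1.0 / mean_len)
            invalid[start:start + length] = True
        valid &= ~invalid
    return GazeRecording(time_ms=rec.time_ms.copy(), x_px=rec.x_px.copy(),
                         y_px=rec.y_px.copy(), valid=valid)


def write_session_bundle(out_dir: str | Path, sessions: dict,
                         similarity: pd.DataFrame | None = None,
                         seeds: dict | None = None) -> Path:
    """Write sessions to the on-disk contract.

    sessions maps subject id -> list of Session.  Layout::

        out_dir/
          events.csv                     all subjects/blocks
          truth.csv
          similarity.csv                 (optional)
          gaze/<subject>_b<block>.tsv    one TSV per block
          seeds.json
    """
    out = Path(out_dir)
    (out / "gaze").mkdir(parents=True, exist_ok=True)
    events, truths = [], []
    for subject, sess_list in sessions.items():
        for sess in sess_list:
            block = int(sess.events["block"].iloc[0])
            sess.recording.to_tsv(out / "gaze" / f"{subject}_b{block}.tsv")
            events.append(sess.events)
            t = sess.truth.copy()
            t.insert(0, "subject", subject)
            t.insert(1, "block", block)
            truths.append(t)
    pd.concat(events, ignore_index=True).to_csv(out / "events.csv", index=False)
    pd.concat(truths, ignore_index=True).to_csv(out / "truth.csv", index=False)
    if similarity is not None:
        similarity.to_csv(out / "similarity.csv", index=False)
    with open(out / "seeds.json", "w") as fh:
        json.dump(seeds or {}, fh, indent=2)
    return out
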