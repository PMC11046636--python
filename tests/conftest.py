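import numpy as np
import pandas as pd
import pytest

from gazegeom import gazeprep, synthgaze


@pytest.fixture(scope="session")
def number_geometry():
    return synthgaze.LatentGeometry.number_line()


@pytest.fixture(scope="session")
def color_geometry():
    return synthgaze.LatentGeometry.color_ring()


@pytest.fixture
def make_recording():
    """Build a GazeRecording from short per-sample arrays."""

    def _make(x, y=None, t0=0.0, dt=1.0, valid=None):
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
        t = t0 + dt * np.arange(len(x))
        v = np.ones(len(x), bool) if valid is None else np.asarray(valid, bool)
        return gazeprep.GazeRecording(t, x, y, v)

    return _make


@pytest.fixture
def make_trials():
    """Build a trial table from (block, word, x, y, valid) tuples."""

    def _make(rows, subject="s00"):
        return pd.DataFrame(
            [(subject, b, str(w), float(x), float(y), 500, bool(v))
             for b, w, x, y, v in rows],
            columns=["subject", "block", "word", "median_x_px",
                     "median_y_px", "n_valid_samples", "valid"])

    return _make


def number_session(seed=0, n_trials=60, coupling=6.5, noise_sd=85.0,
                   drift_sd=2.0, **kw):
    geom = synthgaze.LatentGeometry.number_line()
    cfg = synthgaze.SessionConfig(domain="number", n_trials=n_trials,
                                  coupling=coupling, noise_sd=noise_sd,
                                  drift_sd=drift_sd, seed=seed, **kw)
    return synthgaze.generate_session(cfg, geom)
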