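"""Subject-level correlations and group-level frequentist + Bayesian inference.

The central quantity is the Spearman rank correlation between a subject's
trial-to-trial gaze displacement and the conceptual change between the
corresponding words.  Per-subject correlations are Fisher z-transformed and
taken to a one-sample (or paired) t test at the group level, accompanied by
a default two-sided JZS Bayes factor (Cauchy prior on the standardized
effect, scale sqrt(2)/2 — the default of common Bayesian t-test software).

The number effect can be decomposed: ``combined`` correlates signed change
with signed displacement, ``magnitude_only`` correlates the unsigned
magnitudes, ``sign_only`` correlates only the directions (signs), and
``control_transition`` correlates unsigned displacement with how often the
specific word transition occurs (a transition-probability control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .conceptspace import ConceptChangeSeries
from .errors import (AlignmentError, ConfigurationError, DataError,
                     DegenerateDataError, IntegrationError,
                     UndefinedCorrelationError)

__all__ = [
    "SubjectCorrelationResult",
    "GroupStats",
    "spearman_rho",
    "fisher_z",
    "condition_correlation",
    "partial_spearman",
    "group_t",
    "jzs_bf10",
    "bonferroni_alpha",
    "AXES",
    "MODES",
]

AXES = ("x_signed", "y_signed", "euclid_2d")
MODES = ("combined", "sign_only", "magnitude_only", "control_transition")

DEFAULT_CAUCHY_SCALE = math.sqrt(2) / 2


@dataclass
class SubjectCorrelationResult:
    subject: str
    condition: str
    axis: str
    mode: str
    rho: float
    z: float
    n_pairs: int


@dataclass
class GroupStats:
    mean_z: float
    sd_z: float
    t: float
    df: int
    p: float
    bf10: float


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("inputs must be 1D vectors of equal length")
    if len(x) < min_n:
        raise DataError(f"need at least {min_n} observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a constant vector")
    return x, y


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x, y = _check_pair(x, y)
    return float(stats.spearmanr(x, y).statistic)


def pearson_r(x, y) -> float:
    """Pearson correlation (sensitivity-check alternative)."""
    x, y = _check_pair(x, y)
    return float(stats.pearsonr(x, y).statistic)


def fisher_z(rho: float, clip: bool = False) -> float:
    """Fisher transform atanh(rho); |rho| = 1 raises unless clip is set."""
    if abs(rho) >= 1.0:
        if not clip:
            raise DataError("Fisher transform infinite at |rho| = 1 "
                            "(pass clip=True to clip at 1 - 1e-7)")
        rho = math.copysign(1.0 - 1e-7, rho)
    return float(math.atanh(rho))


def condition_correlation(disp: pd.DataFrame, change: ConceptChangeSeries,
                          axis: str = "x_signed", mode: str = "combined",
                          subject: str = "s00", condition: str = "",
                          method: str = "spearman") -> SubjectCorrelationResult:
    """Correlate a gaze displacement series with a conceptual change series.

    The two series are aligned on their transition indices (transitions with
    an invalid gaze trial are absent from `disp` and are skipped).  For the
    ``euclid_2d`` axis the displacement is the non-negative 2D distance, so
    the conceptual change enters unsigned regardless of mode.
    """
    if axis not in AXES:
        raise ConfigurationError(f"unknown axis {axis!r}")
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}")
    d = disp.set_index("transition")
    common = d.index.intersection(pd.Index(change.index))
    if len(common) < 3:
        raise AlignmentError(
            f"only {len(common)} aligned transitions between series")
    gaze = d.loc[common, {"x_signed": "dx", "y_signed": "dy",
                          "euclid_2d": "d2"}[axis]].to_numpy(float)
    lut = pd.Series(change.values, index=change.index)
    conc = lut.loc[common].to_numpy(float)

    if mode == "combined":
        if axis == "euclid_2d":
            conc = np.abs(conc)
    elif mode == "magnitude_only":
        gaze, conc = np.abs(gaze), np.abs(conc)
    elif mode == "sign_only":
        gaze, conc = np.sign(gaze), np.sign(conc)
    else:  # control_transition: unsigned movement vs transition count
        gaze = np.abs(gaze)

    corr = {"spearman": spearman_rho, "pearson": pearson_r}[method]
    rho = corr(gaze, conc)
    return SubjectCorrelationResult(subject=subject, condition=condition,
                                    axis=axis, mode=mode, rho=rho,
                                    z=fisher_z(rho, clip=True),
                                    n_pairs=int(len(common)))


def partial_spearman(x, y, control) -> tuple:
    """First-order partial Spearman correlation of x and y given control.

    All three vectors are rank-transformed; the standard first-order
    partial-correlation formula is applied to the pairwise rank
    correlations.  The p value uses the t approximation with n - 3 degrees
    of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(control, float)
    if not (len(x) == len(y) == len(c)) or len(x) < 4:
        raise DataError("need three equal-length vectors of length >= 4")
    rx, ry, rc = (stats.rankdata(v) for v in (x, y, c))
    r_xy = stats.pearsonr(rx, ry).statistic
    r_xc = stats.pearsonr(rx, rc).statistic
    r_yc = stats.pearsonr(ry, rc).statistic
    denom = math.sqrt((1 - r_xc ** 2) * (1 - r_yc ** 2))
    if denom < 1e-12:
        raise DegenerateDataError(
            "control is perfectly collinear with x or y")
    rp = (r_xy - r_xc * r_yc) / denom
    n = len(x)
    df = n - 3
    rp_c = max(min(rp, 1 - 1e-15), -1 + 1e-15)
    t = rp_c * math.sqrt(df / (1 - rp_c ** 2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(rp), float(p)


def jzs_bf10(t: float, n: int, scale: float = DEFAULT_CAUCHY_SCALE) -> float:
    """Two-sided JZS one-sample Bayes factor BF10 from (t, n).

    Marginal likelihood of t under a Cauchy(0, scale) prior on the
    standardized effect size — evaluated through the inverse-gamma mixture
    representation, g ~ InvGamma(1/2, scale^2/2), by numerical quadrature —
    divided by the likelihood under the point null.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if scale <= 0:
        raise ConfigurationError("scale must be positive")
    nu = n - 1
    t2 = float(t) * float(t)
    log_null = -(nu + 1) / 2 * math.log1p(t2 / nu)

    def integrand(g: float) -> float:
        log_f = (-0.5 * math.log1p(n * g)
                 - (nu + 1) / 2 * math.log1p(t2 / ((1 + n * g) * nu))
                 - log_null
                 + math.log(scale) - 0.5 * math.log(2 * math.pi)
                 - 1.5 * math.log(g) - scale * scale / (2 * g))
        return math.exp(log_f)

    val, err = integrate.quad(integrand, 0, np.inf, limit=200)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-4):
        raise IntegrationError(
            f"quadrature did not converge (value={val}, abserr={err})")
    return float(val)


def group_t(values, mode: str = "one_sample_vs_zero", values2=None,
            scale: float = DEFAULT_CAUCHY_SCALE) -> GroupStats:
    """Group-level t test on per-subject Fisher-z values, with JZS BF10.

    ``one_sample_vs_zero`` tests the mean of `values` against 0; ``paired``
    tests the mean difference values - values2 against 0.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DataError("need at least 2 subjects")
    if mode == "paired":
        if values2 is None or len(values2) != len(v):
            raise ConfigurationError("paired mode requires equal-length values2")
        v = v - np.asarray(values2, dtype=float)
    elif mode != "one_sample_vs_zero":
        raise ConfigurationError(f"unknown mode {mode!r}")
    sd = float(np.std(v, ddof=1))
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(v)))):
        raise DegenerateDataError("zero variance across subjects")
    n = len(v)
    t = float(np.mean(v) / (sd / math.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return GroupStats(mean_z=float(np.mean(v)), sd_z=sd, t=t, df=n - 1,
                      p=p, bf10=jzs_bf10(t, n, scale=scale))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return alpha / m
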