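"""Receptive-field estimation, filter plausibility and population statistics.

Receptive fields are estimated as the gradient of a model neuron's
pre-exponential (log-rate) output with respect to the stimulus, evaluated
at a blank (all-zero) input — the first-order approximation of the
stimulus that maximally drives the neuron.  The spatio-temporal gradient
is factorized by SVD into a unit-norm temporal kernel and a spatial map
that carries the polarity and magnitude.

Filter plausibility follows the convention that retinal receptive fields
are well approximated by smooth 2D Gaussians: the coefficient of
determination of an elliptical Gaussian fit, forced to 0 when the fitted
sigma exceeds the filter size.

Direction selectivity uses the vector-sum index of the SVD-derived tuning
curve with a trial-label permutation test; model comparisons use paired
two-sided permutation tests and percentile bootstrap intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._autodiff import Tensor
from .synthetic import DirectionTrials, GroundTruthNeuron

__all__ = [
    "RFEstimate", "GaussianFit", "DSResult",
    "estimate_rf", "gaussian_fit_r2", "dominant_channel", "predictive_cc",
    "ds_test", "compare_models", "bootstrap_ci",
    "ground_truth_spatiotemporal", "rf_recovery_correlation",
    "filter_plausibility",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# receptive fields
# ----------------------------------------------------------------------
@dataclass
class RFEstimate:
    spatiotemporal: np.ndarray      # [channel, lag, H, W], lag oldest->newest
    spatial_component: np.ndarray   # [channel, H, W], carries magnitude
    temporal_component: np.ndarray  # [lag], unit L2 norm
    singular_value_ratio: float


def _svd_factorize(rf: np.ndarray) -> RFEstimate:
    c, lags, h, w = rf.shape
    mat = rf.transpose(1, 0, 2, 3).reshape(lags, c * h * w)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    temporal = u[:, 0]
    spatial = (s[0] * vt[0]).reshape(c, h, w)
    if temporal[np.argmax(np.abs(temporal))] < 0:
        temporal, spatial = -temporal, -spatial
    ratio = float(s[0] / s.sum()) if s.sum() > 0 else 1.0
    return RFEstimate(spatiotemporal=rf, spatial_component=spatial,
                      temporal_component=temporal, singular_value_ratio=ratio)


def estimate_rf(model, neuron: int) -> RFEstimate:
    """Gradient receptive field of one model neuron at the blank stimulus.

    `model` is an SIModel (or anything with `.preactivation` over clips
    [B, C, lags, H, W]).  The gradient of the log-rate with respect to the
    input is taken at zeros and SVD-factorized into spatial and temporal
    components.
    """
    si = getattr(model, "si_model", model)
    if not 0 <= neuron < si.n_neurons:
        raise IndexError(f"neuron index {neuron} out of range")
    x = Tensor(
        np.zeros((1, si.n_channels, si.config.n_lags, si.height, si.width),
                 dtype=np.float64),
        requires_grad=True,
    )
    out = si.preactivation(x)
    out[0, neuron].backward()
    rf = x.grad[0]
    return _svd_factorize(rf.astype(np.float64))


def ground_truth_spatiotemporal(neuron: GroundTruthNeuron, n_lags: int) -> np.ndarray:
    """Ground-truth LN filter as [channel, lag, H, W], lag oldest->newest."""
    kernel = np.zeros(n_lags)
    k = neuron.temporal_kernel[:n_lags]
    kernel[-len(k):] = k[::-1]  # kernel[0] weights the most recent frame
    return neuron.spatial_rf[:, None] * kernel[None, :, None, None]


def rf_recovery_correlation(est: RFEstimate, neuron: GroundTruthNeuron,
                            component: str = "spatial") -> float:
    """|Pearson r| between an estimated and a ground-truth receptive field.

    `component` = "spatial" compares the SVD spatial maps (the standard
    parameter-recovery readout; sign-agnostic), "spatiotemporal" the full
    gradient tensor against the separable ground-truth filter.
    """
    if component == "spatial":
        return abs(predictive_cc(est.spatial_component.ravel(),
                                 neuron.spatial_rf.ravel()))
    truth = ground_truth_spatiotemporal(neuron, est.spatiotemporal.shape[1])
    return abs(predictive_cc(est.spatiotemporal.ravel(), truth.ravel()))


# ----------------------------------------------------------------------
# Gaussian plausibility
# ----------------------------------------------------------------------
@dataclass
class GaussianFit:
    center: tuple[float, float]   # (x, y) pixels
    sigmas: tuple[float, float]   # (sigma_x, sigma_y) pixels
    amplitude: float
    offset: float
    rotation: float               # radians
    r_squared: float


def _gauss2d(coords, amp, x0, y0, sx, sy, theta, off):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    xr = (x - x0) * ct + (y - y0) * st
    yr = -(x - x0) * st + (y - y0) * ct
    return amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2)) + off


def gaussian_fit_r2(spatial_filter: np.ndarray, n_restarts: int = 5,
                    seed: int = 0) -> GaussianFit:
    """Least-squares elliptical Gaussian fit of a 2-D filter.

    r_squared = 1 - SS_res / SS_tot, clipped to [0, 1], and forced to 0
    when the larger fitted sigma exceeds the filter size (a fit escaping
    the filter window is not a plausible receptive field).  Invariant to
    sign flips and rescaling of the filter.  A constant filter has
    r_squared = 0 by convention.
    """
    z = np.asarray(spatial_filter, dtype=float)
    if z.ndim != 2:
        raise ValueError("spatial filter must be 2-D")
    if not np.isfinite(z).all():
        raise ValueError("non-finite filter values")
    h, w = z.shape
    size = max(h, w)
    ss_tot = ((z - z.mean()) ** 2).sum()
    if np.ptp(z) == 0 or ss_tot == 0:  # constant filter: statistic undefined
        return GaussianFit((np.nan, np.nan), (np.nan, np.nan), 0.0, float(z.mean()),
                           0.0, 0.0)
    yy, xx = np.mgrid[0:h, 0:w]
    coords = (xx.ravel(), yy.ravel())
    target = z.ravel()
    peak = np.unravel_index(np.argmax(np.abs(z - z.mean())), z.shape)
    amp0 = z[peak] - z.mean()
    rng = np.random.default_rng(seed)

    best = None
    for trial in range(n_restarts):
        jit = rng.normal(0, 0.5, size=2) if trial else np.zeros(2)
        p0 = [amp0, peak[1] + jit[0], peak[0] + jit[1], 2.0, 2.0, 0.0, z.mean()]
        try:
            popt, _ = optimize.curve_fit(
                _gauss2d, coords, target, p0=p0, maxfev=5000,
                bounds=([-np.inf, -size, -size, 1e-3, 1e-3, -np.pi, -np.inf],
                        [np.inf, 2 * size, 2 * size, 10 * size, 10 * size,
                         np.pi, np.inf]),
            )
        except RuntimeError:
            continue
        ss_res = ((target - _gauss2d(coords, *popt)) ** 2).sum()
        if best is None or ss_res < best[0]:
            best = (ss_res, popt)
    if best is None:
        return GaussianFit((np.nan, np.nan), (np.nan, np.nan), 0.0, 0.0, 0.0, 0.0)
    ss_res, p = best
    amp, x0, y0, sx, sy, theta, off = p
    r2 = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    if max(sx, sy) > size:
        r2 = 0.0
    return GaussianFit((x0, y0), (sx, sy), amp, off, theta, r2)


def dominant_channel(rf: RFEstimate) -> int:
    """Chromatic channel with the largest peak absolute spatial response."""
    peaks = np.abs(rf.spatial_component).max(axis=(1, 2))
    if peaks.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    best = int(np.argmax(peaks))
    if np.sum(peaks == peaks[best]) > 1:
        logger.info("dominant_channel tie; returning lowest index")
        best = int(np.flatnonzero(peaks == peaks[best])[0])
    return best


def filter_plausibility(model, channel: int | None = None,
                        seed: int = 0) -> np.ndarray:
    """Gaussian-fit R^2 of each shared spatial filter.

    For 2D models the spatial filter tensor is used directly; for 3D
    models each joint filter is first SVD-factorized into its spatial
    component.  `channel` selects the chromatic channel; None uses each
    filter's dominant channel (largest peak absolute value).
    """
    si = getattr(model, "si_model", model)
    if si.config.mode == "factorized2d":
        filters = si.spatial_filters().data  # [F, C, k, k]
    else:
        joint = si.joint.data  # [F, C, L, k, k]
        filters = np.stack([_svd_factorize(f.astype(float)).spatial_component
                            for f in joint])
    out = np.empty(filters.shape[0])
    for i, filt in enumerate(filters):
        ch = channel
        if ch is None:
            ch = int(np.argmax(np.abs(filt).max(axis=(1, 2))))
        out[i] = gaussian_fit_r2(filt[ch], seed=seed).r_squared
    return out


# ----------------------------------------------------------------------
# performance and population statistics
# ----------------------------------------------------------------------
def predictive_cc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pearson correlation between a predicted and an observed trace."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("traces must share a length >= 2")
    if pred.std() == 0 or truth.std() == 0:
        raise ZeroDivisionError("zero-variance trace: correlation undefined")
    return float(stats.pearsonr(pred, truth).statistic)


@dataclass
class DSResult:
    ds_index: float
    p_value: float
    temporal_component: np.ndarray
    directional_component: np.ndarray  # tuning curve over the 8 directions


def _tuning_curve(mean_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SVD of a [time, direction] matrix into temporal and tuning parts."""
    u, s, vt = np.linalg.svd(mean_matrix, full_matrices=False)
    temporal, tuning = u[:, 0], vt[0]
    if tuning.sum() < 0:
        temporal, tuning = -temporal, -tuning
    return temporal, tuning


def _vector_sum_dsi(tuning: np.ndarray, directions_deg: np.ndarray) -> float:
    """Normalized vector-sum index: |sum_d w_d e^{i theta_d}| / sum_d w_d.

    Weights are the tuning curve clipped at zero; the normalization makes
    the index 1 exactly when all tuning mass sits in one direction and 0
    for direction-symmetric tuning.
    """
    weights = np.clip(tuning, 0.0, None)
    mass = weights.sum()
    if mass == 0:
        return 0.0
    angles = np.deg2rad(directions_deg)
    return float(abs(np.sum(weights * np.exp(1j * angles))) / mass)


def ds_test(trials: DirectionTrials, n_perm: int = 1000, seed: int = 0) -> DSResult:
    """Direction-selectivity index with a trial-label permutation test.

    The trial-mean [time, direction] response matrix is SVD-factorized;
    the leading right-singular vector (sign-fixed to nonnegative sum,
    clipped at 0) is the tuning curve, and the DS index is the length of
    the vector sum of tuning-weighted unit vectors at the 8 directions.
    The null distribution shuffles direction labels across trials; the
    p-value uses the add-one estimator (b + 1) / (n + 1).
    """
    resp = trials.responses  # [time, direction, trial]
    n_time, n_dir, n_trial = resp.shape
    if n_dir < 2:
        raise ValueError("need at least 2 directions")
    temporal, tuning = _tuning_curve(resp.mean(axis=2))
    dsi = _vector_sum_dsi(tuning, trials.directions)

    rng = np.random.default_rng(seed)
    flat = resp.reshape(n_time, n_dir * n_trial)
    perms = np.stack([rng.permutation(n_dir * n_trial) for _ in range(n_perm)])
    shuffled = flat[:, perms]                          # [time, n_perm, dir*trial]
    means = shuffled.reshape(n_time, n_perm, n_dir, n_trial).mean(axis=3)
    mats = means.transpose(1, 0, 2)                    # [n_perm, time, dir]
    _, _, vt = np.linalg.svd(mats, full_matrices=False)  # batched
    tunings = vt[:, 0, :]
    tunings *= np.where(tunings.sum(axis=1) < 0, -1.0, 1.0)[:, None]
    weights = np.clip(tunings, 0.0, None)
    mass = weights.sum(axis=1)
    phases = np.exp(1j * np.deg2rad(trials.directions))
    null = np.abs(weights @ phases) / np.where(mass == 0, 1.0, mass)
    exceed = int(np.sum(null >= dsi))
    p = (exceed + 1) / (n_perm + 1)
    return DSResult(ds_index=dsi, p_value=p, temporal_component=temporal,
                    directional_component=tuning)


def compare_models(scores_a, scores_b, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided paired permutation test on the mean score difference.

    Randomly sign-flips the per-unit differences to build the null of the
    mean difference; p uses the add-one estimator.
    """
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("score vectors must share a length >= 2")
    d = a - b
    obs = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.size))
    null = np.abs((signs * d).mean(axis=1))
    return float((np.sum(null >= obs) + 1) / (n_perm + 1))


def bootstrap_ci(values, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap (2.5 / 97.5) of the mean."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    return float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))
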