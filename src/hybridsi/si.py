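"""System-identification encoding models (Poisson-output CNNs).

Two architectures predict a population's responses from short stimulus
clips:

* ``factorized2d`` — one spatial convolutional layer (16 filters, 9x9,
  applied to every lag), one temporal convolutional layer collapsing the
  lags, then a fully connected readout and an exponential output
  nonlinearity.  No padding anywhere, so a 28x28 input yields 20x20
  feature maps and a 6,400-dimensional readout input.
* ``spatiotemporal3d`` — one joint space-time convolutional layer followed
  by the same readout and exponential.

The spatial (2D) or joint (3D) filters are the tensor optionally shared
with the efficient-coding branch in the hybrid model.  Spatial filters may
instead be composed from a fixed DCT or PCA basis, in which case only the
basis weights are learned.

Training minimizes a Poisson loss with L2 penalties on convolutional
filters and an L1 penalty on the readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from ._conv import correlate2d, sliding_clips
from .basis import BasisSet

__all__ = ["SIConfig", "SIModel", "make_clips", "poisson_loss"]


@dataclass
class SIConfig:
    """Architecture and penalty weights of an SI model.

    `alpha1` is the L2 weight on the spatial (2D) or joint (3D)
    convolutional filters, `alpha2` the L2 weight on the temporal filters
    (2D only), `beta` the L1 weight on the readout.  Defaults follow the
    grid-search optima for the dense-noise protocol (2D: alpha1 = alpha2 =
    10, beta = 1/16; for 3D use alpha1 = 100, beta = 1/4).
    """

    n_filters: int = 16
    kernel_size: int = 9
    n_lags: int = 8
    mode: str = "factorized2d"  # or "spatiotemporal3d"
    alpha1: float = 10.0
    alpha2: float = 10.0
    beta: float = 1.0 / 16.0

    def __post_init__(self):
        if self.mode not in ("factorized2d", "spatiotemporal3d"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.alpha1, self.alpha2, self.beta) < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")


def make_clips(frames: np.ndarray, times: np.ndarray, n_lags: int) -> np.ndarray:
    """Stimulus clips ending at each time index, [B, C, lags, H, W].

    `frames` is [T, C, H, W]; clip lag axis runs oldest to newest, so the
    last lag is the frame at the clip's time index.  Times below
    n_lags - 1 have incomplete history and are rejected.
    """
    times = np.asarray(times)
    if times.min() < n_lags - 1:
        raise ValueError("clip time with incomplete stimulus history")
    idx = times[:, None] + np.arange(-(n_lags - 1), 1)[None, :]
    return frames[idx].transpose(0, 2, 1, 3, 4)


def poisson_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Sum_i (r_hat_i - r_i log r_hat_i) for nonnegative targets."""
    if np.any(np.asarray(target) < 0):
        raise ValueError("Poisson targets must be nonnegative")
    return (pred - Tensor(np.asarray(target)) * pred.log()).sum()


class SIModel:
    """Poisson-output CNN encoding model for a neural population."""

    def __init__(
        self,
        config: SIConfig,
        input_shape: tuple[int, int, int],
        n_neurons: int,
        basis: BasisSet | None = None,
        seed: int = 0,
        dtype=np.float32,
        init_scale: float = 0.05,
    ):
        self.config = config
        self.n_channels, self.height, self.width = input_shape
        self.n_neurons = n_neurons
        self.basis = basis
        self.dtype = dtype
        c, k, f, lags = self.n_channels, config.kernel_size, config.n_filters, config.n_lags
        self.out_h = self.height - k + 1
        self.out_w = self.width - k + 1
        if self.out_h < 1 or self.out_w < 1:
            raise ValueError("input smaller than kernel")
        rng = np.random.default_rng(seed)

        def init(*shape):
            return Tensor(rng.normal(0, init_scale, size=shape).astype(dtype),
                          requires_grad=True)

        if config.mode == "factorized2d":
            if basis is None:
                self.spatial = init(f, c, k, k)
                self.basis_weights = None
            elif basis.kind == "pca":
                self.spatial = None
                self.basis_weights = init(f, basis.k)
            else:  # dct: per-channel weights
                self.spatial = None
                self.basis_weights = init(f, basis.k, c)
            self.temporal = init(f, f, lags)
            self.joint = None
        else:
            if basis is not None:
                raise NotImplementedError("basis constraint is a 2D-model control")
            self.joint = init(f, c, lags, k, k)
            self.spatial = None
            self.temporal = None
            self.basis_weights = None
        d = f * self.out_h * self.out_w
        self.readout_dim = d
        self.readout = init(n_neurons, d)
        self.bias = Tensor(np.zeros(n_neurons, dtype=dtype), requires_grad=True)

    # ------------------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = []
        for p in (self.spatial, self.basis_weights, self.temporal, self.joint,
                  self.readout, self.bias):
            if p is not None:
                params.append(p)
        return params

    def spatial_filters(self) -> Tensor:
        """Spatial filter tensor [filters, channels, k, k] (2D mode).

        For basis-constrained models the filters are composed from the
        basis on the fly; gradients flow only to the basis weights.
        """
        if self.spatial is not None:
            return self.spatial
        f = self.config.n_filters
        c, k = self.n_channels, self.config.kernel_size
        flat = Tensor(self.basis.flat().astype(self.dtype))
        if self.basis.kind == "pca":  # weights [f, k_b] x basis [k_b, c*k*k]
            return (self.basis_weights @ flat).reshape(f, c, k, k)
        # dct: weights [f, k_b, c] -> per-channel composition
        w = self.basis_weights.transpose(0, 2, 1).reshape(f * c, self.basis.k)
        return (w @ flat).reshape(f, c, k, k)

    # ------------------------------------------------------------------
    def _as_tensor(self, x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        return Tensor(np.ascontiguousarray(x, dtype=self.dtype))

    def preactivation(self, clips) -> Tensor:
        """Pre-exponential (log-rate) output for clips [B, C, lags, H, W]."""
        x = self._as_tensor(clips)
        b, c, lags, h, w = x.shape
        if lags != self.config.n_lags:
            raise ValueError("clip lag count does not match the model")
        if (h, w) != (self.height, self.width):
            raise ValueError("clip spatial size does not match the model")
        f = self.config.n_filters
        k = self.config.kernel_size
        p = self.out_h * self.out_w
        if self.config.mode == "factorized2d":
            ws = self.spatial_filters().reshape(f, c * k * k)
            frames = x.transpose(0, 2, 1, 3, 4).reshape(b * lags, c, h, w)
            a = correlate2d(frames, ws, k).reshape(b, lags, p, f)
            return self._head(a)
        wc = self.joint.reshape(f, c * lags * k * k)
        maps = correlate2d(x.reshape(b, c * lags, h, w), wc, k)  # [B, P, F]
        flat = maps.transpose(0, 2, 1).reshape(b, f * p)
        return flat @ self.readout.transpose(1, 0) + self.bias

    def _head(self, a: Tensor) -> Tensor:
        """Temporal collapse + readout for lag-stacked maps [B, L, P, F]."""
        b, lags, p, f = a.shape
        wt = self.temporal.transpose(0, 2, 1).reshape(f, lags * f)
        a = a.transpose(0, 2, 1, 3).reshape(b, p, lags * f)
        maps = a @ wt.transpose(1, 0)                           # [B, P, F]
        flat = maps.transpose(0, 2, 1).reshape(b, f * p)
        return flat @ self.readout.transpose(1, 0) + self.bias

    def preactivation_window(self, frames: np.ndarray, times: np.ndarray) -> Tensor:
        """Log-rate outputs for a contiguous block of clip times.

        Equivalent to `preactivation(make_clips(frames, times, n_lags))`
        but convolves each stimulus frame once instead of once per lag,
        which is the fast path used by the trainer and `predict_trace`.
        Falls back to the generic path for non-contiguous times or 3D
        models.
        """
        times = np.asarray(times)
        lags = self.config.n_lags
        if (self.config.mode != "factorized2d" or times.size < 2
                or np.any(np.diff(times) != 1)):
            return self.preactivation(make_clips(frames, times, lags))
        if times[0] < lags - 1:
            raise ValueError("clip time with incomplete stimulus history")
        c, k, f = self.n_channels, self.config.kernel_size, self.config.n_filters
        uf = Tensor(np.ascontiguousarray(
            frames[times[0] - lags + 1 : times[-1] + 1], dtype=self.dtype))
        ws = self.spatial_filters().reshape(f, c * k * k)
        maps_u = correlate2d(uf, ws, k)                 # [U, P, F]
        a = sliding_clips(maps_u, times.size, lags)     # [B, L, P, F]
        return self._head(a)

    def forward(self, clips) -> Tensor:
        """Predicted firing rates (strictly positive), [B, n_neurons]."""
        return self.preactivation(clips).exp()

    __call__ = forward

    # ------------------------------------------------------------------
    def penalties(self) -> dict[str, Tensor]:
        """Regularization terms of the loss, unweighted."""
        out = {"readout_l1": self.readout.abs().sum()}
        if self.config.mode == "factorized2d":
            ws = self.spatial_filters()
            out["spatial_l2"] = (ws * ws).sum()
            out["temporal_l2"] = (self.temporal * self.temporal).sum()
        else:
            out["conv_l2"] = (self.joint * self.joint).sum()
        return out

    def loss(self, clips, target: np.ndarray) -> Tensor:
        """Poisson loss plus L2/L1 penalties (the stand-alone SI objective)."""
        cfg = self.config
        pen = self.penalties()
        total = poisson_loss(self.forward(clips), target)
        if cfg.mode == "factorized2d":
            total = (total + cfg.alpha1 * pen["spatial_l2"]
                     + cfg.alpha2 * pen["temporal_l2"])
        else:
            total = total + cfg.alpha1 * pen["conv_l2"]
        return total + cfg.beta * pen["readout_l1"]

    # ------------------------------------------------------------------
    def predict_trace(self, frames: np.ndarray, t_slice: slice,
                      batch: int = 256) -> np.ndarray:
        """Predicted rates for every frame of a segment with full history.

        Clips may reach back before the segment start (the stimulus is
        continuous), so only times with fewer than n_lags - 1 preceding
        frames overall are skipped.  Returns [n_valid_times, n_neurons].
        """
        lags = self.config.n_lags
        start = max(t_slice.start or 0, lags - 1)
        stop = t_slice.stop if t_slice.stop is not None else frames.shape[0]
        times = np.arange(start, stop)
        preds = []
        for i in range(0, len(times), batch):
            out = self.preactivation_window(frames, times[i : i + batch])
            preds.append(np.exp(out.data))
        return np.concatenate(preds, axis=0)
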