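"""Efficient-coding branch: noisy, sparse convolutional autoencoders.

The autoencoder learns to reconstruct images (or movie frames) through a
single convolutional layer whose filters can be shared with the SI branch.
There is no hard bottleneck; instead, bandwidth is limited by Gaussian
noise added to the encoder output during training and an L1 penalty on the
latent activation.  L2 penalties on the convolutional and deconvolutional
weights encourage smooth filters.  Trained on natural-like input this
architecture develops center-surround spatial filters, which is what makes
it useful as a normative regularizer.

Three modes:

* ``image2d`` — encode and reconstruct a single chromatic image.
* ``past3d``  — input an 8-frame clip, reconstruct its 7th frame.
* ``future3d`` — input the first 7 frames (8th slot filled with their
  mean), predict the 8th frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from ._conv import correlate2d, maps_to_images
from .synthetic import StimulusMovie

__all__ = ["ECConfig", "ECModel", "make_clip_targets"]


@dataclass
class ECConfig:
    """Autoencoder architecture and penalties.

    `alpha` is the L2 weight on conv and deconv filters, `beta` the L1
    weight on the latent activation, `noise_sd` the SD of the Gaussian
    noise injected after the encoder during training (in units of
    post-ReLU activation).  Defaults follow the stand-alone 2D optima
    (alpha = 1e3, beta = 1/16).
    """

    n_filters: int = 16
    kernel_size: int = 9
    latent_dim: int = 512
    noise_sd: float = 0.1
    alpha: float = 1e3
    beta: float = 1.0 / 16.0
    mode: str = "image2d"  # past3d | future3d
    n_clip_frames: int = 8

    def __post_init__(self):
        if self.mode not in ("image2d", "past3d", "future3d"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.alpha, self.beta, self.noise_sd) < 0:
            raise ValueError("alpha, beta and noise_sd must be >= 0")


def make_clip_targets(movie: StimulusMovie, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Sliding 8-frame clips and their reconstruction/prediction targets.

    Returns (inputs [n, C, 8, H, W], targets [n, C, H, W]).  In ``past3d``
    the target is the clip's 7th frame; in ``future3d`` the 8th input slot
    is replaced by the per-channel mean of the first 7 frames and the
    target is the true 8th frame.
    """
    n_clip = 8
    frames = movie.frames
    if frames.shape[0] < n_clip:
        raise ValueError("movie shorter than one clip")
    n = frames.shape[0] - n_clip + 1
    idx = np.arange(n)[:, None] + np.arange(n_clip)[None, :]
    clips = frames[idx].transpose(0, 2, 1, 3, 4).copy()  # [n, C, 8, H, W]
    if mode == "past3d":
        targets = clips[:, :, 6].copy()
    elif mode == "future3d":
        targets = clips[:, :, 7].copy()
        clips[:, :, 7] = clips[:, :, :7].mean(axis=2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return clips, targets


class ECModel:
    """Convolutional autoencoder, optionally sharing its conv filters."""

    def __init__(
        self,
        config: ECConfig,
        input_shape: tuple[int, int, int],
        conv: Tensor | None = None,
        seed: int = 0,
        dtype=np.float32,
        init_scale: float = 0.05,
    ):
        self.config = config
        self.n_channels, self.height, self.width = input_shape
        self.dtype = dtype
        c, k, f = self.n_channels, config.kernel_size, config.n_filters
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        self.pad = (k - 1) // 2
        self.flat_dim = f * self.height * self.width
        rng = np.random.default_rng(seed)

        def init(*shape):
            return Tensor(rng.normal(0, init_scale, size=shape).astype(dtype),
                          requires_grad=True)

        if config.mode == "image2d":
            conv_shape = (f, c, k, k)
        else:
            conv_shape = (f, c, config.n_clip_frames, k, k)
        if conv is None:
            self.conv = init(*conv_shape)
        else:
            if tuple(conv.shape) != conv_shape:
                raise ValueError(
                    f"shared filter shape {tuple(conv.shape)} != required {conv_shape}"
                )
            self.conv = conv  # the shared tensor: same object, not a copy
        self.enc_w = init(config.latent_dim, self.flat_dim)
        # small positive biases keep the ReLUs alive at initialization
        # (a unit at exactly 0 would receive no gradient)
        self.enc_b = Tensor(np.full(config.latent_dim, 0.1, dtype=dtype),
                            requires_grad=True)
        self.dec_w = init(self.flat_dim, config.latent_dim)
        self.dec_b = Tensor(np.full(self.flat_dim, 0.1, dtype=dtype),
                            requires_grad=True)
        self.deconv = init(f, c, k, k)  # decoder always emits a single frame

    # ------------------------------------------------------------------
    def parameters(self, include_shared: bool = True) -> list[Tensor]:
        params = [self.enc_w, self.enc_b, self.dec_w, self.dec_b, self.deconv]
        if include_shared:
            params.insert(0, self.conv)
        return params

    def private_parameters(self) -> list[Tensor]:
        """Parameters not shared with the SI branch."""
        return self.parameters(include_shared=False)

    def _as_tensor(self, x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        x = np.asarray(x)
        if np.abs(x).max() > 1 + 1e-6:
            raise ValueError("autoencoder inputs must lie in [-1, 1]")
        return Tensor(np.ascontiguousarray(x, dtype=self.dtype))

    # ------------------------------------------------------------------
    def encode(self, x) -> Tensor:
        """Latent activation h (post-ReLU, noise-free), [B, latent_dim]."""
        x = self._as_tensor(x)
        cfg = self.config
        c, k, f = self.n_channels, cfg.kernel_size, cfg.n_filters
        b = x.shape[0]
        if cfg.mode == "image2d":
            w_flat = self.conv.reshape(f, c * k * k)
            maps = correlate2d(x, w_flat, k, pad=self.pad)           # [B, P, F]
        else:
            lags = cfg.n_clip_frames
            w_flat = self.conv.reshape(f, c * lags * k * k)
            maps = correlate2d(x.reshape(b, c * lags, self.height, self.width),
                               w_flat, k, pad=self.pad)
        act = maps.relu().transpose(0, 2, 1).reshape(b, self.flat_dim)
        return (act @ self.enc_w.transpose(1, 0) + self.enc_b).relu()

    def decode(self, h: Tensor) -> Tensor:
        """Reconstruction x_hat in (-1, 1), [B, C, H, W]."""
        cfg = self.config
        c, k, f = self.n_channels, cfg.kernel_size, cfg.n_filters
        b = h.shape[0]
        act = (h @ self.dec_w.transpose(1, 0) + self.dec_b).relu()
        act = act.reshape(b, f, self.height, self.width)
        # transposed convolution == convolution with the flipped, channel-
        # swapped kernel; same padding keeps the input size exactly
        w_t = self.deconv.transpose(1, 0, 2, 3).flip((-1, -2)).reshape(c, f * k * k)
        maps = correlate2d(act, w_t, k, pad=self.pad)                # [B, P, C]
        return maps_to_images(maps, self.height, self.width).tanh()

    def forward(self, x, rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Full pass; pass an `rng` to inject training noise after the encoder.

        Returns (reconstruction, latent h).  The L1 penalty applies to the
        clean latent; the decoder sees the noisy one when rng is given.
        """
        h = self.encode(x)
        z = h
        if rng is not None and self.config.noise_sd > 0:
            noise = rng.normal(0, self.config.noise_sd, size=h.shape).astype(self.dtype)
            z = h + Tensor(noise)
        return self.decode(z), h

    __call__ = forward

    # ------------------------------------------------------------------
    def penalties(self) -> dict[str, Tensor]:
        return {
            "conv_l2": (self.conv * self.conv).sum(),
            "deconv_l2": (self.deconv * self.deconv).sum(),
        }

    def loss(self, x, x_hat: Tensor, h: Tensor) -> Tensor:
        """Reconstruction MSE plus L2/L1 penalties (stand-alone objective)."""
        cfg = self.config
        target = Tensor(np.ascontiguousarray(np.asarray(x), dtype=x_hat.dtype))
        err = target - x_hat
        pen = self.penalties()
        return ((err * err).sum()
                + cfg.alpha * (pen["conv_l2"] + pen["deconv_l2"])
                + cfg.beta * h.abs().sum())
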