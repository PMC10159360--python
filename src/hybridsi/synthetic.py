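"""Synthetic stimuli, image corpora and model neurons with known ground truth.

This module emulates the experimental material that the modeling stack is
designed for: chromatic (UV/green) binary dense-noise movies shown to the
retina, corpora of natural-like images for the efficient-coding branch
(1/f amplitude spectra with higher-order phase structure), phase-scrambled
and white-noise control corpora, linear-nonlinear (LN) model neurons with
difference-of-Gaussians receptive fields and biphasic temporal kernels,
and moving-bar direction-tuning trials.

All generators are deterministic given a seed and emit values in [-1, 1]
so every stimulus lies in the representable range of the autoencoder's
tanh output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import ResponseSet, quality_index

__all__ = [
    "StimulusMovie",
    "ImageCorpus",
    "GroundTruthNeuron",
    "DirectionTrials",
    "LNTemplate",
    "generate_binary_noise",
    "generate_structured_images",
    "generate_white_noise_images",
    "phase_scramble",
    "radial_amplitude_slope",
    "simulate_ln_population",
    "simulate_direction_trials",
]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class StimulusMovie:
    """A chromatic frame sequence, shape [time, channel, height, width]."""

    frames: np.ndarray
    frame_rate: float
    channel_names: tuple[str, ...] = ("UV", "green")

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise ValueError("frames must be [time, channel, height, width]")
        if not np.isfinite(self.frames).all():
            raise ValueError("non-finite stimulus values")
        if np.abs(self.frames).max() > 1 + 1e-9:
            raise ValueError("stimulus values must lie in [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class ImageCorpus:
    """A set of images, shape [n, channel, height, width], values in [-1, 1]."""

    images: np.ndarray
    provenance: str  # structured | phase_scrambled | white_noise

    def __post_init__(self):
        self.images = np.asarray(self.images)
        if self.images.ndim != 4:
            raise ValueError("images must be [n, channel, height, width]")
        if np.abs(self.images).max() > 1 + 1e-9:
            raise ValueError("image values must lie in [-1, 1]")
        if self.provenance not in ("structured", "phase_scrambled", "white_noise"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class GroundTruthNeuron:
    """LN model cell: rate = f(<stimulus, spatial_rf * temporal_kernel>)."""

    spatial_rf: np.ndarray          # [channel, height, width]
    temporal_kernel: np.ndarray     # [lags], unit L2 norm, lag 0 = most recent
    output_nonlinearity: str = "softplus"   # or "exponential"
    gain: float = 1.0
    threshold: float = 0.0
    trial_noise_sd: float = 0.0
    direction_tuning: tuple[float, float] | None = None  # (preferred deg, strength)

    def rate(self, projection: np.ndarray) -> np.ndarray:
        z = self.gain * (projection - self.threshold)
        if self.output_nonlinearity == "exponential":
            return np.exp(z)
        if self.output_nonlinearity == "softplus":
            return np.logaddexp(0.0, z)
        raise ValueError(f"unknown nonlinearity {self.output_nonlinearity!r}")


@dataclass
class DirectionTrials:
    """Moving-bar responses, shape [time, direction, trial]; 8 directions."""

    responses: np.ndarray
    directions: np.ndarray = field(
        default_factory=lambda: np.arange(8, dtype=float) * 45.0
    )

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        if self.responses.shape[1] != len(self.directions):
            raise ValueError("direction axis does not match direction labels")
        if self.responses.shape[2] < 2:
            raise ValueError("need at least 2 trials per direction")


# ----------------------------------------------------------------------
# stimuli and image corpora
# ----------------------------------------------------------------------
def generate_binary_noise(
    height: int,
    width: int,
    n_frames: int,
    n_channels: int = 2,
    frame_rate: float = 5.0,
    seed: int = 0,
) -> StimulusMovie:
    """Independent binary dense noise: each pixel is +/-1 with p = 0.5.

    Pixels are independent across space, time and chromatic channel, the
    standard reverse-correlation stimulus for retinal recordings.
    """
    if min(height, width, n_frames, n_channels) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    frames = rng.integers(0, 2, size=(n_frames, n_channels, height, width))
    frames = frames.astype(np.float64) * 2.0 - 1.0
    names = ("UV", "green") if n_channels == 2 else tuple(f"ch{i}" for i in range(n_channels))
    return StimulusMovie(frames=frames, frame_rate=frame_rate, channel_names=names)


def _radial_frequency(height: int, width: int) -> np.ndarray:
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    return np.hypot(fy * height, fx * width)  # cycles per image


def generate_structured_images(
    n: int,
    height: int,
    width: int,
    spectral_exponent: float = 1.0,
    chromatic_corr: float = 0.8,
    seed: int = 0,
    nonlinearity: bool = True,
    rms_contrast: float = 0.45,
) -> ImageCorpus:
    """Natural-like images: 1/f^gamma amplitude spectra plus phase structure.

    A Gaussian random field is spectrally shaped to a radially averaged
    amplitude spectrum proportional to 1/f^spectral_exponent, then passed
    through a signed-square pointwise nonlinearity (x -> x|x|) that creates
    sparse, edge-like higher-order structure beyond second-order statistics.
    Channels share a common component so their correlation approximates
    `chromatic_corr`.  Each image is normalized to a fixed RMS contrast
    (pixel values clipped to [-1, 1]); heavy-tailed signed-square pixels
    would otherwise leave most of the dynamic range unused.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spectral_exponent < 0:
        raise ValueError("spectral_exponent must be >= 0")
    if abs(chromatic_corr) > 1:
        raise ValueError("|chromatic_corr| must be <= 1")
    rng = np.random.default_rng(seed)

    f = _radial_frequency(height, width)
    amp = np.zeros_like(f)
    amp[f > 0] = f[f > 0] ** (-spectral_exponent)

    shared = rng.normal(size=(n, height, width))
    rho = chromatic_corr
    images = np.empty((n, 2, height, width))
    for c in range(2):
        indep = rng.normal(size=(n, height, width))
        white = (
            np.sign(rho) ** c * np.sqrt(abs(rho)) * shared
            + np.sqrt(1.0 - abs(rho)) * indep
        )
        spec = np.fft.fft2(white) * amp
        images[:, c] = np.fft.ifft2(spec).real

    if nonlinearity:
        images = images * np.abs(images)

    rms = np.sqrt((images**2).mean(axis=(1, 2, 3), keepdims=True))
    rms[rms == 0] = 1.0
    images = np.clip(images * (rms_contrast / rms), -1.0, 1.0)
    return ImageCorpus(images=images, provenance="structured")


def generate_structured_movie(
    n_frames: int,
    height: int,
    width: int,
    spectral_exponent: float = 1.0,
    chromatic_corr: float = 0.8,
    temporal_corr: float = 0.9,
    drift: tuple[float, float] = (0.3, 0.15),
    frame_rate: float = 5.0,
    seed: int = 0,
) -> StimulusMovie:
    """Natural-like movie: 1/f frames with AR(1) dynamics and global drift.

    The Fourier coefficients of a latent Gaussian field evolve as an AR(1)
    process (coefficient `temporal_corr`) while a per-frame phase ramp
    shifts the whole image by `drift` pixels per frame, emulating footage
    dominated by global motion.  Frames pass through the same signed-square
    nonlinearity as the image corpus and are rescaled to [-1, 1].
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    f = _radial_frequency(height, width)
    amp = np.zeros_like(f)
    amp[f > 0] = f[f > 0] ** (-spectral_exponent)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    ramp = np.exp(-2j * np.pi * (fy * drift[0] + fx * drift[1]))

    rho = chromatic_corr
    a = temporal_corr

    def noise_pair():
        shared = np.fft.fft2(rng.normal(size=(height, width)))
        out = []
        for c in range(2):
            indep = np.fft.fft2(rng.normal(size=(height, width)))
            out.append(np.sign(rho) ** c * np.sqrt(abs(rho)) * shared
                       + np.sqrt(1.0 - abs(rho)) * indep)
        return out

    state = noise_pair()
    frames = np.empty((n_frames, 2, height, width))
    for t in range(n_frames):
        fresh = noise_pair()
        for c in range(2):
            state[c] = a * state[c] * ramp + np.sqrt(1.0 - a**2) * fresh[c]
            frames[t, c] = np.fft.ifft2(state[c] * amp).real
    frames = frames * np.abs(frames)
    rms = np.sqrt((frames**2).mean())
    if rms > 0:
        frames = np.clip(frames * (0.45 / rms), -1.0, 1.0)
    return StimulusMovie(frames=frames, frame_rate=frame_rate)


def generate_white_noise_images(
    n: int, height: int, width: int, seed: int = 0, binary: bool = True
) -> ImageCorpus:
    """Control corpus without any spatial or chromatic structure."""
    rng = np.random.default_rng(seed)
    if binary:
        images = rng.integers(0, 2, size=(n, 2, height, width)) * 2.0 - 1.0
    else:
        images = rng.normal(size=(n, 2, height, width))
        images /= np.abs(images).max(axis=(1, 2, 3), keepdims=True)
    return ImageCorpus(images=images, provenance="white_noise")


def phase_scramble(corpus: ImageCorpus, seed: int = 0) -> ImageCorpus:
    """Randomize Fourier phases, preserving each channel's amplitude spectrum.

    Random phases are taken from the Fourier transform of a white Gaussian
    field, which guarantees Hermitian symmetry (a real-valued result).  The
    DC component is kept, so a constant image maps to itself.  Destroys
    higher-order (phase) statistics while keeping second-order structure.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(seed)
    n, c, h, w = corpus.images.shape
    out = np.empty_like(corpus.images)
    for i in range(n):
        for j in range(c):
            spec = np.fft.fft2(corpus.images[i, j])
            phase = np.angle(np.fft.fft2(rng.normal(size=(h, w))))
            new = np.abs(spec) * np.exp(1j * phase)
            new[0, 0] = spec[0, 0]  # keep the mean
            out[i, j] = np.fft.ifft2(new).real
    # Parseval: scrambling preserves each image's RMS and amplitude
    # spectrum; realigned phases can push single pixels past 1, and only
    # those images are scaled down (a per-image scalar, spectrum shape kept)
    peak = np.abs(out).max(axis=(1, 2, 3), keepdims=True)
    out = out / np.maximum(peak, 1.0)
    return ImageCorpus(images=out, provenance="phase_scrambled")


def radial_amplitude_slope(
    images: np.ndarray, f_min: float = 1.5, f_max: float | None = None
) -> float:
    """Log-log slope of the radially averaged amplitude spectrum.

    Averages amplitude spectra over all images and channels, bins them by
    radial frequency, and fits a line to log(amplitude) vs log(frequency).
    A 1/f^gamma corpus yields a slope of about -gamma.
    """
    images = np.asarray(images)
    flat = images.reshape(-1, images.shape[-2], images.shape[-1])
    amp = np.abs(np.fft.fft2(flat)).mean(axis=0)
    f = _radial_frequency(images.shape[-2], images.shape[-1])
    if f_max is None:
        f_max = min(images.shape[-2], images.shape[-1]) / 2.0 - 1.0
    bins = np.arange(int(np.floor(f_min)), int(np.ceil(f_max)) + 1)
    centers, means = [], []
    for lo in bins[:-1]:
        m = (f >= lo) & (f < lo + 1)
        if m.any():
            centers.append(lo + 0.5)
            means.append(amp[m].mean())
    x = np.log10(np.asarray(centers))
    y = np.log10(np.asarray(means))
    return float(np.polyfit(x, y, 1)[0])


# ----------------------------------------------------------------------
# LN population
# ----------------------------------------------------------------------
@dataclass
class LNTemplate:
    """Parameter ranges for sampling ground-truth LN neurons.

    The spatial receptive field is an antagonistic difference of Gaussians
    (center-surround); the temporal kernel is biphasic.  `population`
    controls chromatic dominance: ventral cells weight the UV channel,
    dorsal cells the green channel, mirroring the opsin gradient of the
    mouse retina.
    """

    center_sigma: tuple[float, float] = (1.0, 1.6)   # pixels
    surround_scale: float = 2.0                       # sigma_s / sigma_c
    surround_weight: tuple[float, float] = (0.4, 0.7)
    off_fraction: float = 0.5                        # probability of OFF polarity
    n_lags: int = 8
    nonlinearity: str = "softplus"
    gain: float = 2.0
    threshold: float = 0.0
    trial_noise_sd: float = 1.0
    population: str = "ventral"                      # ventral (UV) | dorsal (green)
    nondominant_weight: tuple[float, float] = (0.1, 0.4)
    margin: int = 3                                  # RF center distance from border


def _dog_rf(h, w, cy, cx, sigma_c, sigma_s, w_surround):
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    d2 = (y - cy) ** 2 + (x - cx) ** 2
    center = np.exp(-d2 / (2 * sigma_c**2))
    surround = np.exp(-d2 / (2 * sigma_s**2))
    surround *= sigma_c**2 / sigma_s**2  # equal-volume scaling
    return center - w_surround * surround


def _biphasic_kernel(n_lags: int, peak1: float, peak2: float, w2: float) -> np.ndarray:
    lags = np.arange(n_lags, dtype=float)
    k = np.exp(-0.5 * ((lags - peak1) / 0.9) ** 2) - w2 * np.exp(
        -0.5 * ((lags - peak2) / 1.4) ** 2
    )
    return k / np.linalg.norm(k)


def sample_neuron(rng: np.random.Generator, h: int, w: int, tpl: LNTemplate) -> GroundTruthNeuron:
    cy = rng.uniform(tpl.margin, h - 1 - tpl.margin)
    cx = rng.uniform(tpl.margin, w - 1 - tpl.margin)
    sigma_c = rng.uniform(*tpl.center_sigma)
    dog = _dog_rf(h, w, cy, cx, sigma_c, tpl.surround_scale * sigma_c,
                  rng.uniform(*tpl.surround_weight))
    if rng.uniform() < tpl.off_fraction:
        dog = -dog
    dominant = 0 if tpl.population == "ventral" else 1  # UV first
    weights = np.empty(2)
    weights[dominant] = 1.0
    weights[1 - dominant] = rng.uniform(*tpl.nondominant_weight)
    spatial = weights[:, None, None] * dog[None]
    spatial /= np.linalg.norm(spatial)
    kernel = _biphasic_kernel(
        tpl.n_lags,
        peak1=rng.uniform(0.8, 1.6),
        peak2=rng.uniform(3.2, 4.5),
        w2=rng.uniform(0.4, 0.7),
    )
    return GroundTruthNeuron(
        spatial_rf=spatial,
        temporal_kernel=kernel,
        output_nonlinearity=tpl.nonlinearity,
        gain=tpl.gain,
        threshold=tpl.threshold,
        trial_noise_sd=tpl.trial_noise_sd,
    )


def _ln_rates(neuron: GroundTruthNeuron, frames: np.ndarray) -> np.ndarray:
    """Deterministic firing rate of an LN neuron for a frame sequence."""
    proj = np.tensordot(frames, neuron.spatial_rf, axes=([1, 2, 3], [0, 1, 2]))
    lags = len(neuron.temporal_kernel)
    # kernel[0] weights the most recent frame
    filt = np.convolve(proj, neuron.temporal_kernel, mode="full")[: len(proj)]
    rates = neuron.rate(filt)
    rates[: lags - 1] = neuron.rate(0.0)  # incomplete history: baseline
    return rates


def simulate_ln_population(
    n_neurons: int,
    stimulus: StimulusMovie,
    template: LNTemplate | None = None,
    n_test_repeats: int = 6,
    n_test_frames: int = 50,
    train_fraction: float = 440.0 / 480.0,
    seed: int = 0,
) -> tuple[ResponseSet, list[GroundTruthNeuron]]:
    """Simulate an LN population responding to a stimulus movie.

    The last `n_test_frames` of the stimulus form the repeated test
    sequence (simulated `n_test_repeats` times with fresh trial noise); the
    remaining frames are split into contiguous training and validation
    segments.  Observed traces are rate + Gaussian trial noise, clipped at
    zero, emulating nonnegative event rates derived from Ca2+ imaging.
    """
    template = template or LNTemplate()
    T = stimulus.n_frames
    lags = template.n_lags
    if T < n_test_frames + 4 * lags:
        raise ValueError("stimulus too short for train + validation + test segments")
    rng = np.random.default_rng(seed)
    h, w = stimulus.spatial_shape

    neurons = [sample_neuron(rng, h, w, template) for _ in range(n_neurons)]

    n_nontest = T - n_test_frames
    n_train = int(round(n_nontest * train_fraction))
    train_sl = slice(0, n_train)
    val_sl = slice(n_train, n_nontest)
    test_sl = slice(n_nontest, T)

    def observe(rates: np.ndarray) -> np.ndarray:
        if template.trial_noise_sd == 0:
            return rates.copy()
        noisy = rates + rng.normal(0.0, template.trial_noise_sd, size=rates.shape)
        return np.clip(noisy, 0.0, None)

    rates = np.stack([_ln_rates(nrn, stimulus.frames) for nrn in neurons])
    train = observe(rates[:, train_sl])
    val = observe(rates[:, val_sl])
    test_rates = rates[:, test_sl]
    test_block = np.stack([observe(test_rates) for _ in range(n_test_repeats)], axis=1)

    qi = np.array(
        [quality_index(test_block[i].T) for i in range(n_neurons)]
    ) if n_test_repeats >= 2 else np.full(n_neurons, np.nan)

    responses = ResponseSet(
        train_traces=train,
        val_traces=val,
        test_block=test_block,
        sampling_rate=stimulus.frame_rate,
        qi_noise=qi,
        train_slice=train_sl,
        val_slice=val_sl,
        test_slice=test_sl,
    )
    return responses, neurons


# ----------------------------------------------------------------------
# direction-tuning trials
# ----------------------------------------------------------------------
def simulate_direction_trials(
    n_cells: int,
    tuning_strengths,
    n_trials: int = 4,
    n_time: int = 32,
    noise_sd: float = 0.15,
    kappa: float = 3.0,
    seed: int = 0,
) -> list[DirectionTrials]:
    """Moving-bar trials at 8 directions for a set of cells.

    Each cell responds with a shared temporal profile whose amplitude is
    modulated across directions by a von Mises tuning curve of strength
    `tuning_strengths[i]` (0 = untuned, 1 = fully tuned); trial-to-trial
    variability is additive Gaussian noise.
    """
    tuning_strengths = np.broadcast_to(np.asarray(tuning_strengths, float), (n_cells,))
    if np.any((tuning_strengths < 0) | (tuning_strengths > 1)):
        raise ValueError("tuning strengths must lie in [0, 1]")
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    directions = np.arange(8) * 45.0
    t = np.arange(n_time)
    profile = np.exp(-0.5 * ((t - n_time / 2) / (n_time / 8)) ** 2)

    cells = []
    for s in tuning_strengths:
        pref = rng.uniform(0, 360)
        delta = np.deg2rad(directions - pref)
        vm = np.exp(kappa * (np.cos(delta) - 1.0))
        amps = (1.0 - s) + s * vm
        mean = profile[:, None] * amps[None, :]
        noise = rng.normal(0.0, noise_sd, size=(n_time, 8, n_trials))
        cells.append(DirectionTrials(responses=mean[:, :, None] + noise,
                                     directions=directions))
    return cells
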