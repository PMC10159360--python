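"""Response reliability, trace conditioning and train/validation/test splits.

The quality index QI measures repeat-to-repeat reliability of a response:

    QI = Var_t[ E_r[C] ] / E_r[ Var_t[C] ]

for a time-by-repeat response matrix C.  QI is 1 for perfectly repeatable
responses and approaches 1/r for r repeats of pure noise.

Raw fluorescence traces are conditioned for model fitting by z-scoring,
resampling to the stimulus frame rate, detrending with a 0.1-Hz high-pass
filter, differentiating, and clipping negative values — producing the
nonnegative event-rate-like traces the Poisson encoding models are fit to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ResponseSet",
    "quality_index",
    "preprocess_trace",
    "highpass_detrend",
    "split_sequences",
    "SplitScheme",
    "NOISE_SCHEME",
    "MOVIE_SCHEME",
]


@dataclass
class ResponseSet:
    """Per-neuron response traces aligned to a stimulus movie.

    `train_traces` / `val_traces` are [neuron, time] single-trial traces;
    `test_block` is [neuron, repeat, test_time] — responses to a repeated
    test sequence whose repeat average serves as ground truth for model
    evaluation.  The slices locate each segment in the stimulus frames.
    """

    train_traces: np.ndarray
    val_traces: np.ndarray
    test_block: np.ndarray
    sampling_rate: float
    qi_noise: np.ndarray | None = None
    train_slice: slice | None = None
    val_slice: slice | None = None
    test_slice: slice | None = None

    def __post_init__(self):
        for arr in (self.train_traces, self.val_traces, self.test_block):
            if np.isnan(np.asarray(arr)).any():
                raise ValueError("NaNs in response traces")
        if self.test_block.ndim != 3:
            raise ValueError("test_block must be [neuron, repeat, test_time]")

    @property
    def n_neurons(self) -> int:
        return self.train_traces.shape[0]

    @property
    def test_mean(self) -> np.ndarray:
        """Repeat-averaged test response, [neuron, test_time]."""
        return self.test_block.mean(axis=1)

    def select(self, mask: np.ndarray) -> "ResponseSet":
        """Restrict to a boolean subset of neurons (e.g. a QI filter)."""
        return ResponseSet(
            train_traces=self.train_traces[mask],
            val_traces=self.val_traces[mask],
            test_block=self.test_block[mask],
            sampling_rate=self.sampling_rate,
            qi_noise=None if self.qi_noise is None else self.qi_noise[mask],
            train_slice=self.train_slice,
            val_slice=self.val_slice,
            test_slice=self.test_slice,
        )


def quality_index(C: np.ndarray) -> float:
    """Response reliability of a time-by-repeat matrix, in [0, 1].

    Ratio of the temporal variance of the repeat-averaged response to the
    mean over repeats of each repeat's temporal variance.  Raises if every
    repeat is constant in time (the statistic is then 0/0).
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[1] < 2:
        raise ValueError("C must be [time, repeat] with >= 2 repeats")
    denom = C.var(axis=0).mean()
    if denom == 0:
        raise ZeroDivisionError("all repeats are constant in time: QI undefined")
    return float(C.mean(axis=1).var() / denom)


def highpass_detrend(trace: np.ndarray, fs: float, cutoff: float = 0.1) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth high-pass (detrending) filter."""
    if fs <= 2 * cutoff:
        raise ValueError("sampling rate too low for the high-pass cutoff")
    sos = signal.butter(2, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trace)


def preprocess_trace(raw: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Condition a raw fluorescence trace into a nonnegative event-rate trace.

    Pipeline: z-normalize; linearly interpolate from the recording rate to
    the stimulus rate; high-pass filter at 0.1 Hz; first-order difference;
    clip negative values to zero.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("raw trace must be 1-D with length >= 2")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    sd = raw.std()
    if sd == 0:
        raise ZeroDivisionError("constant trace: z-normalization undefined")
    z = (raw - raw.mean()) / sd

    duration = (raw.size - 1) / fs_in
    t_in = np.arange(raw.size) / fs_in
    t_out = np.arange(int(np.floor(duration * fs_out)) + 1) / fs_out
    resampled = np.interp(t_out, t_in, z)

    detrended = highpass_detrend(resampled, fs_out)
    rate = np.diff(detrended, prepend=detrended[0])
    return np.clip(rate, 0.0, None)


@dataclass(frozen=True)
class SplitScheme:
    """Contiguous train/validation split of the non-test recording."""

    total_s: float
    train_s: float

    @property
    def val_s(self) -> float:
        return self.total_s - self.train_s


NOISE_SCHEME = SplitScheme(total_s=480.0, train_s=440.0)
MOVIE_SCHEME = SplitScheme(total_s=540.0, train_s=433.0)


def split_sequences(
    n_frames: int,
    frame_rate: float,
    scheme: SplitScheme = NOISE_SCHEME,
    fraction: float = 1.0,
) -> tuple[slice, slice]:
    """Split `n_frames` of non-test data into (train, validation) slices.

    The train/validation proportion follows the recording scheme (e.g.
    440 s / 40 s for the dense-noise protocol).  `fraction` < 1 truncates
    the training segment to its leading part — the data-efficiency
    protocol; validation is untouched.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    needed = scheme.total_s * frame_rate
    if n_frames + 1e-9 < needed:
        raise ValueError(
            f"{n_frames} frames < {needed:.0f} required by the scheme"
        )
    n_train_full = int(round(n_frames * scheme.train_s / scheme.total_s))
    n_train = int(round(n_train_full * fraction))
    if n_train < 1:
        raise ValueError("fraction leaves no training data")
    return slice(0, n_train), slice(n_train_full, n_frames)
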