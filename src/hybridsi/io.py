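"""HDF5 persistence for synthetic datasets and experiment reports."""

from __future__ import annotations

import numpy as np
import h5py

from .preprocessing import ResponseSet
from .synthetic import GroundTruthNeuron, StimulusMovie

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(path, stimulus: StimulusMovie, responses: ResponseSet,
                 neurons: list[GroundTruthNeuron] | None = None) -> None:
    """Write one dataset to HDF5 (groups /stimulus, /responses, /ground_truth)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("stimulus")
        g.create_dataset("frames", data=stimulus.frames, compression="gzip")
        g.attrs["frame_rate"] = stimulus.frame_rate
        g.attrs["channel_names"] = list(stimulus.channel_names)

        r = f.create_group("responses")
        r.create_dataset("train_traces", data=responses.train_traces)
        r.create_dataset("val_traces", data=responses.val_traces)
        r.create_dataset("test_block", data=responses.test_block)
        r.attrs["sampling_rate"] = responses.sampling_rate
        if responses.qi_noise is not None:
            r.create_dataset("qi_noise", data=responses.qi_noise)
        for name in ("train", "val", "test"):
            sl = getattr(responses, f"{name}_slice")
            if sl is not None:
                r.attrs[f"{name}_slice"] = (sl.start or 0, sl.stop)

        if neurons:
            gt = f.create_group("ground_truth")
            gt.create_dataset("spatial_rf", data=np.stack([n.spatial_rf for n in neurons]))
            gt.create_dataset("temporal_kernel",
                              data=np.stack([n.temporal_kernel for n in neurons]))
            gt.attrs["nonlinearity"] = neurons[0].output_nonlinearity
            gt.create_dataset("gain", data=[n.gain for n in neurons])
            gt.create_dataset("threshold", data=[n.threshold for n in neurons])
            gt.create_dataset("trial_noise_sd", data=[n.trial_noise_sd for n in neurons])


def load_dataset(path) -> tuple[StimulusMovie, ResponseSet, list[GroundTruthNeuron]]:
    with h5py.File(path, "r") as f:
        g = f["stimulus"]
        stimulus = StimulusMovie(
            frames=g["frames"][...],
            frame_rate=float(g.attrs["frame_rate"]),
            channel_names=tuple(str(c) for c in g.attrs["channel_names"]),
        )
        r = f["responses"]
        slices = {}
        for name in ("train", "val", "test"):
            key = f"{name}_slice"
            slices[key] = (slice(*map(int, r.attrs[key]))
                           if key in r.attrs else None)
        responses = ResponseSet(
            train_traces=r["train_traces"][...],
            val_traces=r["val_traces"][...],
            test_block=r["test_block"][...],
            sampling_rate=float(r.attrs["sampling_rate"]),
            qi_noise=r["qi_noise"][...] if "qi_noise" in r else None,
            **slices,
        )
        neurons = []
        if "ground_truth" in f:
            gt = f["ground_truth"]
            for i in range(gt["spatial_rf"].shape[0]):
                neurons.append(GroundTruthNeuron(
                    spatial_rf=gt["spatial_rf"][i],
                    temporal_kernel=gt["temporal_kernel"][i],
                    output_nonlinearity=str(gt.attrs["nonlinearity"]),
                    gain=float(gt["gain"][i]),
                    threshold=float(gt["threshold"][i]),
                    trial_noise_sd=float(gt["trial_noise_sd"][i]),
                ))
    return stimulus, responses, neurons
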