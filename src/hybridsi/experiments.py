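"""End-to-end experiment protocols: model zoos, sweeps, data-efficiency curves.

These runners mirror the comparison protocols the modeling framework is
built for: train a set of models (stand-alone SI, basis-constrained SI
controls, hybrids with different efficient-coding inputs) across random
seeds on one synthetic dataset, evaluate predictive performance on the
repeat-averaged test responses and filter plausibility on the shared
filters, and attach permutation-test / bootstrap statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import bootstrap_ci, compare_models, filter_plausibility
from .basis import BasisSet, make_dct_basis, make_pca_basis
from .ec import ECConfig, ECModel, make_clip_targets
from .preprocessing import ResponseSet
from .si import SIConfig
from .synthetic import (
    ImageCorpus,
    LNTemplate,
    StimulusMovie,
    generate_binary_noise,
    generate_structured_images,
    generate_structured_movie,
    generate_white_noise_images,
    phase_scramble,
    simulate_ln_population,
)
from .training import HybridConfig, TrainedModel, evaluate_test_cc, train_model

__all__ = ["ExperimentSpec", "EvalReport", "make_dataset", "make_ec_corpora",
           "run_experiment", "data_efficiency_curve", "train_ec",
           "ds_subgroup_delta"]

logger = logging.getLogger(__name__)

KNOWN_MODELS = ("si", "si_pca", "si_dct", "hybrid_structured",
                "hybrid_phase_scrambled", "hybrid_white_noise")


@dataclass
class ExperimentSpec:
    """A reproducible model-comparison protocol on one synthetic dataset.

    Defaults are the scaled-down study conditions: a 28x28 two-channel
    binary noise movie at 5 Hz with 2400 non-test frames and a 50-frame
    repeated test sequence, 50 LN neurons with 6 test repeats.
    """

    models: tuple = ("si", "hybrid_structured")
    seeds: tuple = (0, 1, 2, 3, 4)
    data_seed: int = 1234
    n_neurons: int = 50
    height: int = 28
    width: int = 28
    n_nontest_frames: int = 2400
    n_test_frames: int = 50
    n_test_repeats: int = 6
    frame_rate: float = 5.0
    template: LNTemplate = field(default_factory=LNTemplate)
    data_fraction: float = 1.0
    w: float = 0.5
    n_ec_images: int = 320
    ec_image_size: int = 20
    n_pca_bases: int = 16
    n_dct_bases: int = 4
    dim: str = "2d"            # "2d" | "3d"
    ec_strategy: str = "past"  # 3D only: "past" | "future"
    config: HybridConfig = field(default_factory=lambda: HybridConfig(
        learning_rate=1e-3, max_epochs=40, patience=4,
        ec=ECConfig(latent_dim=256)))

    def __post_init__(self):
        unknown = set(self.models) - set(KNOWN_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")


@dataclass
class EvalReport:
    spec: ExperimentSpec
    cc: pd.DataFrame          # columns: model, seed, neuron, test_cc
    filter_r2: pd.DataFrame   # columns: model, seed, mean_r2
    comparisons: dict         # (model_a, model_b) -> p-value
    cc_ci: dict               # model -> (lo, hi) bootstrap CI of mean CC
    errors: dict              # (model, seed) -> error message

    def mean_cc(self, model: str) -> float:
        return float(self.cc.loc[self.cc.model == model, "test_cc"].mean())

    def median_seed_cc(self, model: str) -> float:
        per_seed = self.cc[self.cc.model == model].groupby("seed")["test_cc"].mean()
        return float(per_seed.median())

    def median_seed_r2(self, model: str) -> float:
        per_seed = self.filter_r2[self.filter_r2.model == model]
        return float(per_seed.groupby("seed")["mean_r2"].mean().median())

    def per_neuron_cc(self, model: str) -> np.ndarray:
        """Per-neuron CC averaged over seeds."""
        sub = self.cc[self.cc.model == model]
        return sub.groupby("neuron")["test_cc"].mean().to_numpy()

    def save(self, out_dir) -> None:
        """Persist per-seed results and aggregates as CSV."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cc.to_csv(out / "test_cc.csv", index=False)
        self.filter_r2.to_csv(out / "filter_r2.csv", index=False)
        rows = [{"model_a": a, "model_b": b, "p_value": p}
                for (a, b), p in self.comparisons.items()]
        pd.DataFrame(rows).to_csv(out / "comparisons.csv", index=False)


def make_dataset(spec: ExperimentSpec):
    """The study stimulus and simulated population for a spec."""
    n_total = spec.n_nontest_frames + spec.n_test_frames
    stimulus = generate_binary_noise(spec.height, spec.width, n_total,
                                     n_channels=2, frame_rate=spec.frame_rate,
                                     seed=spec.data_seed)
    responses, neurons = simulate_ln_population(
        spec.n_neurons, stimulus, template=spec.template,
        n_test_repeats=spec.n_test_repeats, n_test_frames=spec.n_test_frames,
        seed=spec.data_seed + 1,
    )
    return stimulus, responses, neurons


def make_ec_corpora(spec: ExperimentSpec) -> dict[str, np.ndarray]:
    """Structured / phase-scrambled / white-noise EC inputs for a spec.

    For 2D experiments these are image arrays [n, C, H, W]; for 3D they
    are (clips, targets) tuples built from synthetic movies.
    """
    if spec.dim == "2d":
        side = spec.ec_image_size
        structured = generate_structured_images(
            spec.n_ec_images, side, side, seed=spec.data_seed + 2)
        scrambled = phase_scramble(structured, seed=spec.data_seed + 3)
        white = generate_white_noise_images(
            spec.n_ec_images, side, side, seed=spec.data_seed + 4)
        return {"structured": structured.images,
                "phase_scrambled": scrambled.images,
                "white_noise": white.images}
    mode = f"{spec.ec_strategy}3d"
    n_frames = spec.n_ec_images + 7
    movie = generate_structured_movie(n_frames, spec.height, spec.width,
                                      seed=spec.data_seed + 2,
                                      frame_rate=spec.frame_rate)
    corpora = {"structured": make_clip_targets(movie, mode)}
    scr = phase_scramble(ImageCorpus(images=movie.frames, provenance="structured"),
                         seed=spec.data_seed + 3)
    corpora["phase_scrambled"] = make_clip_targets(
        StimulusMovie(frames=scr.images, frame_rate=spec.frame_rate), mode)
    white = generate_binary_noise(spec.height, spec.width, n_frames,
                                  seed=spec.data_seed + 4,
                                  frame_rate=spec.frame_rate)
    corpora["white_noise"] = make_clip_targets(white, mode)
    return corpora


def _train_one(name: str, spec: ExperimentSpec, stimulus, responses,
               corpora, structured_for_pca, seed: int) -> TrainedModel:
    cfg = spec.config
    if spec.dim == "3d":
        si_cfg = replace(cfg.si, mode="spatiotemporal3d")
        ec_cfg = replace(cfg.ec, mode=f"{spec.ec_strategy}3d")
        cfg = replace(cfg, si=si_cfg, ec=ec_cfg)
    basis: BasisSet | None = None
    ec_inputs = ec_targets = None
    if name == "si":
        cfg = replace(cfg, w=1.0)
    elif name == "si_pca":
        cfg = replace(cfg, w=1.0)
        basis = make_pca_basis(structured_for_pca, spec.n_pca_bases,
                               patch=cfg.si.kernel_size)
    elif name == "si_dct":
        cfg = replace(cfg, w=1.0)
        basis = make_dct_basis(cfg.si.kernel_size, spec.n_dct_bases)
    else:
        key = name.removeprefix("hybrid_")
        cfg = replace(cfg, w=spec.w)
        data = corpora[key]
        if spec.dim == "2d":
            ec_inputs = data
        else:
            ec_inputs, ec_targets = data
    return train_model(stimulus, responses, cfg, ec_inputs=ec_inputs,
                       ec_targets=ec_targets, basis=basis,
                       data_fraction=spec.data_fraction, seed=seed)


def run_experiment(spec: ExperimentSpec, out_dir=None) -> EvalReport:
    """Train all requested models across seeds and evaluate them.

    A failure in one (model, seed) cell is recorded and does not abort the
    rest of the grid.
    """
    stimulus, responses, _ = make_dataset(spec)
    needs_corpora = any(m.startswith("hybrid") for m in spec.models)
    corpora = make_ec_corpora(spec) if needs_corpora else {}
    structured_for_pca = None
    if "si_pca" in spec.models:
        structured_for_pca = generate_structured_images(
            max(spec.n_ec_images, 64), spec.ec_image_size, spec.ec_image_size,
            seed=spec.data_seed + 2)

    cc_rows, r2_rows, errors = [], [], {}
    for name in spec.models:
        for seed in spec.seeds:
            try:
                tm = _train_one(name, spec, stimulus, responses, corpora,
                                structured_for_pca, seed)
                cc = evaluate_test_cc(tm.si_model, stimulus, responses)
                for i, v in enumerate(cc):
                    cc_rows.append({"model": name, "seed": seed, "neuron": i,
                                    "test_cc": v})
                r2 = filter_plausibility(tm)
                r2_rows.append({"model": name, "seed": seed,
                                "mean_r2": float(np.mean(r2))})
            except Exception as exc:  # crash isolation per grid cell
                logger.exception("model %s seed %d failed", name, seed)
                errors[(name, seed)] = str(exc)

    cc_df = pd.DataFrame(cc_rows)
    r2_df = pd.DataFrame(r2_rows)
    comparisons, cis = {}, {}
    done = [m for m in spec.models
            if not cc_df.empty and (cc_df.model == m).any()]
    for i, a in enumerate(done):
        va = cc_df[cc_df.model == a].groupby("neuron")["test_cc"].mean()
        cis[a] = bootstrap_ci(va.to_numpy(), seed=spec.data_seed)
        for b in done[i + 1:]:
            vb = cc_df[cc_df.model == b].groupby("neuron")["test_cc"].mean()
            comparisons[(a, b)] = compare_models(va.to_numpy(), vb.to_numpy(),
                                                 seed=spec.data_seed)
    report = EvalReport(spec=spec, cc=cc_df, filter_r2=r2_df,
                        comparisons=comparisons, cc_ci=cis, errors=errors)
    if out_dir is not None:
        report.save(out_dir)
    return report


def data_efficiency_curve(spec: ExperimentSpec, fractions) -> pd.DataFrame:
    """Test CC and filter R^2 as a function of training-data fraction.

    Each fraction truncates the training segment to its leading part (the
    learning rate is doubled below 1.0, matching the training protocol)
    and re-runs the experiment; returns one row per (fraction, model) with
    seed-median summaries and the hybrid-SI delta where both are present.
    """
    rows = []
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        rep = run_experiment(replace(spec, data_fraction=float(f)))
        for m in spec.models:
            rows.append({
                "fraction": f, "model": m,
                "median_cc": rep.median_seed_cc(m),
                "median_r2": rep.median_seed_r2(m),
            })
    table = pd.DataFrame(rows)
    if {"si", "hybrid_structured"} <= set(spec.models):
        wide = table.pivot(index="fraction", columns="model", values="median_cc")
        delta = (wide["hybrid_structured"] - wide["si"]).rename("hybrid_si_delta")
        table = table.merge(delta.reset_index(), on="fraction")
    return table


def train_ec(images: np.ndarray, config: ECConfig, n_epochs: int = 20,
             batch_size: int = 32, lr: float = 1e-4, val_fraction: float = 0.1,
             seed: int = 0, targets: np.ndarray | None = None) -> ECModel:
    """Train a stand-alone EC autoencoder on an image corpus."""
    from .training import Adam  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    n = images.shape[0]
    n_val = max(1, int(n * val_fraction))
    order = rng.permutation(n)
    train_idx, _val_idx = order[n_val:], order[:n_val]
    if targets is None:
        targets = images
    shape = (images.shape[1], images.shape[-2], images.shape[-1])
    model = ECModel(config, shape, seed=int(rng.integers(2**31)))
    opt = Adam(model.parameters(), lr=lr)
    for _epoch in range(n_epochs):
        for start in range(0, len(train_idx), batch_size):
            sel = train_idx[start : start + batch_size]
            x_hat, h = model.forward(images[sel], rng=rng)
            loss = model.loss(targets[sel], x_hat, h)
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model


def ds_subgroup_delta(cc_a: np.ndarray, cc_b: np.ndarray,
                      ds_mask: np.ndarray, seed: int = 0) -> dict:
    """Performance delta (model a - model b) split by DS membership.

    Returns the mean delta for direction-selective and non-DS cells and a
    two-sided permutation p-value for each group's delta against zero.
    """
    ds_mask = np.asarray(ds_mask, bool)
    delta = np.asarray(cc_a) - np.asarray(cc_b)
    return {
        "ds_delta": float(delta[ds_mask].mean()),
        "non_ds_delta": float(delta[~ds_mask].mean()),
        "ds_p": compare_models(np.asarray(cc_a)[ds_mask],
                               np.asarray(cc_b)[ds_mask], seed=seed),
        "non_ds_p": compare_models(np.asarray(cc_a)[~ds_mask],
                                   np.asarray(cc_b)[~ds_mask], seed=seed),
    }
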