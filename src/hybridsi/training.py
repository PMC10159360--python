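"""Joint training of the SI and EC branches on shared convolutional filters.

The hybrid objective is a convex combination of the two branch losses,

    L_hybrid = w * L_SI + (1 - w) * L_EC,

where the branch weight w in [0, 1] controls how strongly the shared
filters are pulled toward the efficient-coding solution.  Branch-private
penalty terms are divided by w (SI: temporal filters, readout) or 1 - w
(EC: deconv filters, latent L1) inside the branch losses, so that after
multiplication by the branch weight their effective strength is constant
across w — varying w trades off only the data terms and the shared-filter
penalties.  At w = 0 or w = 1 the weight is substituted by 1e-8 /
1 - 1e-8 to avoid division by zero; the hybrid model then behaves as the
stand-alone EC or SI model.

Both branches take one gradient step per mini-batch pair (Adam, learning
rate 1e-4); training runs for at most 100 epochs with early stopping on
the validation correlation and keeps the best-validation snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._autodiff import Tensor
from .analysis import predictive_cc
from .basis import BasisSet
from .ec import ECConfig, ECModel
from .preprocessing import ResponseSet
from .si import SIConfig, SIModel, poisson_loss
from .synthetic import StimulusMovie

__all__ = ["HybridConfig", "TrainedModel", "Adam", "hybrid_loss",
           "train_model", "sweep", "evaluate_test_cc"]

logger = logging.getLogger(__name__)

_W_EPS = 1e-8


@dataclass
class HybridConfig:
    """Everything needed to train one (possibly degenerate) hybrid model.

    `w` = 1 with no EC data trains a stand-alone SI model; `w` = 0 a
    stand-alone EC model.  SI penalties (alpha1, alpha2, beta) live in
    `si`, EC penalties (alpha, beta) in `ec`.
    """

    w: float = 0.5
    si: SIConfig = field(default_factory=SIConfig)
    ec: ECConfig = field(default_factory=ECConfig)
    learning_rate: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 32
    patience: int = 3
    init_scale: float = 0.05

    def __post_init__(self):
        if not 0 <= self.w <= 1:
            raise ValueError("w must lie in [0, 1]")


@dataclass
class TrainedModel:
    si_model: SIModel
    ec_model: ECModel | None
    config: HybridConfig
    history: dict
    stopped_epoch: int
    best_epoch: int
    best_val_cc: float
    seed: int


class Adam:
    """Adaptive-moment gradient descent (deduplicates shared parameters)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        unique, seen = [], set()
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                unique.append(p)
        self.params = unique
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in unique]
        self.v = [np.zeros_like(p.data) for p in unique]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def effective_w(w: float) -> float:
    """Branch weight with the endpoint substitution (1e-8 at w = 0 or 1)."""
    if not 0 <= w <= 1:
        raise ValueError("w must lie in [0, 1]")
    if w == 0:
        return _W_EPS
    if w == 1:
        return 1.0 - _W_EPS
    return w


def hybrid_loss(si_terms: dict | None, ec_terms: dict | None,
                config: HybridConfig, n_neurons: int, n_images: int):
    """Assemble the weighted total loss from raw branch terms.

    `si_terms` carries Tensors/scalars {poisson, spatial_l2 (or conv_l2),
    temporal_l2, readout_l1}; `ec_terms` carries {mse, conv_l2, deconv_l2,
    h_l1}.  Either branch may be None (pure-EC / pure-SI training); its
    normalized loss is then 0.
    """
    w = effective_w(config.w)
    sic, ecc = config.si, config.ec
    total = 0.0
    if si_terms is not None:
        if sic.mode == "factorized2d":
            l_si = (si_terms["poisson"]
                    + sic.alpha1 * si_terms["spatial_l2"]
                    + sic.alpha2 * si_terms["temporal_l2"] / w
                    + sic.beta * si_terms["readout_l1"] / w) / n_neurons
        else:
            l_si = (si_terms["poisson"]
                    + sic.alpha1 * si_terms["conv_l2"]
                    + sic.beta * si_terms["readout_l1"] / w) / n_neurons
        total = total + w * l_si
    if ec_terms is not None:
        l_ec = (ec_terms["mse"]
                + ecc.alpha * ec_terms["conv_l2"]
                + ecc.alpha * ec_terms["deconv_l2"] / (1.0 - w)
                + ecc.beta * ec_terms["h_l1"] / (1.0 - w)) / n_images
        total = total + (1.0 - w) * l_ec
    return total


def _si_terms(model: SIModel, frames, times, target) -> dict:
    terms = model.penalties()
    pred = model.preactivation_window(frames, times).exp()
    terms["poisson"] = poisson_loss(pred, target)
    return terms


def _ec_terms(model: ECModel, x, target, rng) -> dict:
    x_hat, h = model.forward(x, rng=rng)
    t = Tensor(np.ascontiguousarray(np.asarray(target), dtype=model.dtype))
    err = t - x_hat
    terms = model.penalties()
    terms["mse"] = (err * err).sum()
    terms["h_l1"] = h.abs().sum()
    return terms


def _val_cc(model: SIModel, frames: np.ndarray, responses: ResponseSet) -> float:
    """Mean single-trial correlation on the validation segment."""
    sl = responses.val_slice
    # float64: the zero-variance guard must agree with predictive_cc's
    pred = model.predict_trace(frames, sl).astype(np.float64)
    offset = max(0, model.config.n_lags - 1 - (sl.start or 0))
    target = responses.val_traces[:, offset:].astype(np.float64)
    p = pred - pred.mean(axis=0)
    t = target.T - target.T.mean(axis=0)
    ps, ts = p.std(axis=0), t.std(axis=0)
    ok = (ps > 0) & (ts > 0)
    if not ok.any():
        return 0.0
    cc = (p[:, ok] * t[:, ok]).mean(axis=0) / (ps[ok] * ts[ok])
    return float(cc.mean())


def evaluate_test_cc(model: SIModel, stimulus: StimulusMovie,
                     responses: ResponseSet) -> np.ndarray:
    """Per-neuron correlation with the repeat-averaged test response."""
    pred = model.predict_trace(stimulus.frames, responses.test_slice).astype(
        np.float64)
    truth = responses.test_mean
    out = np.full(responses.n_neurons, np.nan)
    for i in range(responses.n_neurons):
        if truth[i].std() > 0 and pred[:, i].std() > 0:
            out[i] = predictive_cc(pred[:, i], truth[i])
    return out


def train_model(
    stimulus: StimulusMovie,
    responses: ResponseSet,
    config: HybridConfig,
    ec_inputs: np.ndarray | None = None,
    ec_targets: np.ndarray | None = None,
    basis: BasisSet | None = None,
    data_fraction: float = 1.0,
    seed: int = 0,
) -> TrainedModel:
    """Train a hybrid (or stand-alone) model and return the best snapshot.

    `ec_inputs` is an image corpus array [n, C, H, W] (2D) or clip array
    [n, C, 8, H, W] (3D, with `ec_targets` the frames to reconstruct).
    With `ec_inputs` None (or w = 1) only the SI branch is trained.  With
    `data_fraction` < 1 the leading fraction of the training segment is
    used and the learning rate is doubled.
    """
    if not 0 < data_fraction <= 1:
        raise ValueError("data_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    frames = stimulus.frames
    n_neurons = responses.n_neurons
    c = stimulus.n_channels
    h, w_px = stimulus.spatial_shape

    si_model = SIModel(config.si, (c, h, w_px), n_neurons, basis=basis,
                       seed=int(rng.integers(2**31)), init_scale=config.init_scale)

    use_ec = ec_inputs is not None and config.w < 1
    ec_model = None
    if use_ec:
        if config.ec.mode == "image2d":
            shared = si_model.spatial
            ec_targets = ec_inputs
            ec_shape = tuple(ec_inputs.shape[1:])       # [C, H_ec, W_ec]
        else:
            shared = si_model.joint
            if ec_targets is None:
                raise ValueError("3D EC training needs explicit targets")
            n, cc_, _lags, he, we = ec_inputs.shape
            ec_shape = (cc_, he, we)
        if shared is None:
            raise ValueError("basis-constrained SI models cannot share filters")
        # the shared filters fix channel count and kernel size, not the
        # image size: the EC branch may train on smaller crops
        ec_model = ECModel(config.ec, ec_shape, conv=shared,
                           seed=int(rng.integers(2**31)), init_scale=config.init_scale)

    # training clip times: inside the training segment, with full history
    tr = responses.train_slice
    t0 = (tr.start or 0) + config.si.n_lags - 1
    t1 = tr.stop
    n_train_full = t1 - t0
    times = np.arange(t0, t0 + max(1, int(round(n_train_full * data_fraction))))
    target_all = responses.train_traces  # aligned to stimulus frames via tr

    lr = config.learning_rate * (2.0 if data_fraction < 1 else 1.0)
    params = si_model.parameters() + (ec_model.parameters() if ec_model else [])
    opt = Adam(params, lr=lr)

    n_images = 0 if ec_inputs is None else ec_inputs.shape[0]
    ec_order = rng.permutation(n_images) if use_ec else None
    ec_pos = 0
    bs = config.batch_size
    # contiguous mini-batch blocks (shuffled each epoch): overlapping clips
    # within a block share frames, which the windowed forward pass exploits
    blocks = [times[i : i + bs] for i in range(0, len(times), bs)]

    history = {"train_loss": [], "val_cc": []}
    best = (-np.inf, 0, None)  # (val_cc, epoch, snapshot)
    bad_epochs = 0
    stopped = config.max_epochs

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(blocks))
        epoch_loss = 0.0
        for bi in order:
            sel = blocks[bi]
            target = target_all[:, sel - (tr.start or 0)].T  # [B, neurons]
            si_terms = _si_terms(si_model, frames, sel, target)
            ec_terms = None
            if use_ec:
                take = []
                for _ in range(len(sel)):
                    if ec_pos == n_images:
                        ec_order = rng.permutation(n_images)
                        ec_pos = 0
                    take.append(ec_order[ec_pos])
                    ec_pos += 1
                take = np.asarray(take)
                ec_terms = _ec_terms(ec_model, ec_inputs[take], ec_targets[take], rng)
            loss = hybrid_loss(si_terms, ec_terms, config, n_neurons,
                               len(take) if use_ec else 1)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
        val_cc = _val_cc(si_model, frames, responses)
        history["train_loss"].append(epoch_loss / len(blocks))
        history["val_cc"].append(val_cc)
        logger.info("epoch %d: train loss %.4f, val CC %.4f", epoch,
                    history["train_loss"][-1], val_cc)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"divergent loss at epoch {epoch}")
        if val_cc > best[0]:
            best = (val_cc, epoch, [p.data.copy() for p in opt.params])
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                stopped = epoch
                break

    if best[2] is not None:
        for p, snap in zip(opt.params, best[2]):
            p.data[...] = snap
    return TrainedModel(si_model=si_model, ec_model=ec_model, config=config,
                        history=history, stopped_epoch=stopped,
                        best_epoch=best[1], best_val_cc=best[0], seed=seed)


def sweep(
    parameter: str,
    values,
    base_config: HybridConfig,
    stimulus: StimulusMovie,
    responses: ResponseSet,
    ec_inputs=None,
    ec_targets=None,
    basis_builder=None,
    seeds=(0,),
    **train_kwargs,
):
    """Train one model per (value, seed) and tabulate mean validation CC.

    `parameter` is "w" or "n_bases" (the latter needs `basis_builder`, a
    callable k -> BasisSet).  Returns (DataFrame, best value), where best
    maximizes the mean validation CC — the selection rule used for all
    model-comparison hyperparameters.
    """
    import pandas as pd

    values = list(values)
    if not values:
        raise ValueError("empty sweep")
    rows = []
    for v in values:
        for s in seeds:
            if parameter == "w":
                cfg = replace(base_config, w=float(v))
                basis = None
            elif parameter == "n_bases":
                cfg = base_config
                basis = basis_builder(int(v))
            else:
                raise ValueError(f"unknown sweep parameter {parameter!r}")
            tm = train_model(stimulus, responses, cfg, ec_inputs=ec_inputs,
                             ec_targets=ec_targets, basis=basis, seed=s,
                             **train_kwargs)
            rows.append({"value": v, "seed": s, "val_cc": tm.best_val_cc,
                         "stopped_epoch": tm.stopped_epoch})
    table = pd.DataFrame(rows)
    means = table.groupby("value")["val_cc"].mean()
    return table, means.idxmax()
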