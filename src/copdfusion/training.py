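"""Seeded mini-batch SGD training and the iteration / batch-size sweep
experiments.

"Iterations" counts parameter updates. The batch sweep fixes an epoch budget,
so larger batches mean fewer updates and shorter training time. Every run is
bit-reproducible from (model seed, data, TrainConfig).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import lenet
from .evaluation import MetricsTriple, evaluate
from .fusion import FusionModel, FusionSpec, build_fusion_model, randomized_fuse
from .lenet import NetworkParams, build_layers, feature_layers
from .nn_core import Dense, SigmoidLayer, softmax_xent_batch
from .synthetic_data import LabeledImagePair

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "SweepResult",
    "sample_batch",
    "train",
    "sweep_iterations",
    "sweep_batches",
]


@dataclass
class TrainConfig:
    iterations: int = 100
    batch_size: int = 16
    learning_rate: float = 0.5
    seed: int = 0
    freeze_backbones: bool = True  # fusion only

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")


@dataclass
class TrainHistory:
    records: list[tuple[int, float, float]] = field(default_factory=list)
    """(update index, mean batch loss, elapsed wall seconds) per update."""

    def append(self, update: int, loss: float, elapsed: float) -> None:
        if self.records and update <= self.records[-1][0]:
            raise ValueError("update indices must be strictly increasing")
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at update {update}")
        self.records.append((update, float(loss), float(elapsed)))

    @property
    def losses(self) -> list[float]:
        return [r[1] for r in self.records]


@dataclass
class SweepResult:
    model_tag: str  # CT-CNN | XRAY-CNN | FUSION
    grid_name: str  # "iterations" | "batch_size"
    grid_value: int
    metrics: MetricsTriple
    train_seconds: float
    seed: int


def sample_batch(
    train_set: Sequence[LabeledImagePair], batch_size: int, rng: np.random.Generator
) -> list[LabeledImagePair]:
    """Uniform sample without replacement; deterministic under the rng state."""
    if batch_size > len(train_set):
        raise ValueError(
            f"batch_size {batch_size} exceeds training-set size {len(train_set)}"
        )
    idx = rng.choice(len(train_set), size=batch_size, replace=False)
    return [train_set[i] for i in idx]


# ---------------------------------------------------------------------------
# training loops


def _train_single(net: NetworkParams, train_set, config: TrainConfig) -> TrainHistory:
    rng = np.random.default_rng(config.seed)
    layers = build_layers(net)
    use_ct = net.modality_tag == "CT"
    history = TrainHistory()
    t0 = time.perf_counter()
    for step in range(1, config.iterations + 1):
        batch = sample_batch(train_set, config.batch_size, rng)
        x = np.stack([(p.ct_image if use_ct else p.xray_image) for p in batch])[:, None]
        y = np.array([p.label for p in batch])
        for layer in layers:
            x = layer.forward(x)
        _, loss, g = softmax_xent_batch(x, y)
        for layer in reversed(layers):
            g = layer.backward(g)
        for layer in layers:
            layer.step(config.learning_rate)
        history.append(step, loss, time.perf_counter() - t0)
    return history


def _train_fusion(model: FusionModel, train_set, config: TrainConfig) -> TrainHistory:
    rng = np.random.default_rng(config.seed)
    ct_layers = feature_layers(model.ct_backbone)
    xr_layers = feature_layers(model.xray_backbone)
    head_fc = Dense(model.head_fc)
    head_sig = SigmoidLayer()
    head_out = Dense(model.head_out)
    freeze_backbones = config.freeze_backbones and model.freeze_backbones
    history = TrainHistory()
    t0 = time.perf_counter()
    for step in range(1, config.iterations + 1):
        batch = sample_batch(train_set, config.batch_size, rng)
        y = np.array([p.label for p in batch])
        f_ct = np.stack([p.ct_image for p in batch])[:, None]
        f_xr = np.stack([p.xray_image for p in batch])[:, None]
        for layer in ct_layers:
            f_ct = layer.forward(f_ct)
        for layer in xr_layers:
            f_xr = layer.forward(f_xr)
        fused = randomized_fuse(f_ct, f_xr, model)
        h = head_out.forward(head_sig.forward(head_fc.forward(fused)))
        _, loss, g = softmax_xent_batch(h, y)

        g = head_fc.backward(head_sig.backward(head_out.backward(g)))
        if model.train_projections:
            d_proj_ct = g.T @ f_ct
            d_proj_xray = g.T @ f_xr
        if not freeze_backbones:
            g_ct = g @ model.proj_ct
            g_xr = g @ model.proj_xray
            for layer in reversed(ct_layers):
                g_ct = layer.backward(g_ct)
            for layer in reversed(xr_layers):
                g_xr = layer.backward(g_xr)
            for layer in ct_layers + xr_layers:
                layer.step(config.learning_rate)
        head_fc.step(config.learning_rate)
        head_out.step(config.learning_rate)
        if model.train_projections:
            model.proj_ct -= config.learning_rate * d_proj_ct
            model.proj_xray -= config.learning_rate * d_proj_xray
        history.append(step, loss, time.perf_counter() - t0)
    return history


def train(model, train_set: Sequence[LabeledImagePair], config: TrainConfig):
    """Run ``config.iterations`` SGD updates in place; returns (model, history)."""
    if not train_set:
        raise ValueError("training set must be nonempty")
    if config.batch_size > len(train_set):
        raise ValueError(
            f"batch_size {config.batch_size} exceeds training-set size {len(train_set)}"
        )
    if isinstance(model, NetworkParams):
        history = _train_single(model, train_set, config)
    elif isinstance(model, FusionModel):
        history = _train_fusion(model, train_set, config)
    else:
        raise TypeError(f"cannot train model of type {type(model)!r}")
    return model, history


# ---------------------------------------------------------------------------
# sweeps


def _train_all_models(
    train_set, iterations: int, batch_size: int, config: TrainConfig, fusion_seed_offset: int = 1000
):
    """Train CT-CNN and XRAY-CNN fresh, then a fusion model on the transferred
    backbones. Returns dict tag -> (model, train_seconds)."""
    out = {}
    cfg = TrainConfig(
        iterations=iterations,
        batch_size=batch_size,
        learning_rate=config.learning_rate,
        seed=config.seed,
        freeze_backbones=config.freeze_backbones,
    )
    nets = {}
    for tag, modality in (("CT-CNN", "CT"), ("XRAY-CNN", "XRAY")):
        net = lenet.build_network(n_classes=2, seed=config.seed, modality_tag=modality)
        t0 = time.perf_counter()
        train(net, train_set, cfg)
        out[tag] = (net, time.perf_counter() - t0)
        nets[modality] = net
    fmodel = build_fusion_model(
        nets["CT"], nets["XRAY"], FusionSpec(seed=config.seed + fusion_seed_offset)
    )
    t0 = time.perf_counter()
    train(fmodel, train_set, cfg)
    # fusion wall time includes backbone training: the fused model cannot
    # exist without its transferred single-modal networks
    out["FUSION"] = (fmodel, out["CT-CNN"][1] + out["XRAY-CNN"][1] + time.perf_counter() - t0)
    return out


def sweep_iterations(
    train_set: Sequence[LabeledImagePair],
    test_set: Sequence[LabeledImagePair],
    iteration_grid: Sequence[int],
    config: TrainConfig,
) -> list[SweepResult]:
    """Train all three models fresh at each iteration count and evaluate held-out."""
    if not iteration_grid:
        raise ValueError("iteration grid must be nonempty")
    if list(iteration_grid) != sorted(iteration_grid):
        raise ValueError("iteration grid must be ascending")
    results: list[SweepResult] = []
    for iters in iteration_grid:
        trained = _train_all_models(train_set, iters, config.batch_size, config)
        for tag, (model, seconds) in trained.items():
            _, triple = evaluate(model, test_set)
            results.append(SweepResult(tag, "iterations", int(iters), triple, seconds, config.seed))
    return results


def sweep_batches(
    train_set: Sequence[LabeledImagePair],
    test_set: Sequence[LabeledImagePair],
    batch_grid: Sequence[int],
    config: TrainConfig,
    epochs: int = 10,
) -> list[SweepResult]:
    """Vary batch size under a fixed epoch budget (updates = epochs*n/batch)."""
    if not batch_grid:
        raise ValueError("batch grid must be nonempty")
    n = len(train_set)
    if any(b > n for b in batch_grid):
        raise ValueError("batch sizes must not exceed the training-set size")
    results: list[SweepResult] = []
    for batch in batch_grid:
        updates = max(1, int(round(epochs * n / batch)))
        trained = _train_all_models(train_set, updates, int(batch), config)
        for tag, (model, seconds) in trained.items():
            _, triple = evaluate(model, test_set)
            results.append(SweepResult(tag, "batch_size", int(batch), triple, seconds, config.seed))
    return results
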