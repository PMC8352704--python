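"""Randomized fusion of the two modality feature vectors.

The two backbones' 192-d fully-connected features are mapped into a common
target dimension by seeded random linear projections (drawn once at build
time and frozen by default), combined, and classified by a freshly
initialized fully-connected + softmax head. Backbone parameters are copied
from the trained single-modal networks (parameter transfer) and frozen by
default during fusion training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import lenet
from .lenet import FEATURE_DIM, NetworkParams
from .nn_core import Dense, DenseLayerParams, SigmoidLayer, glorot_uniform, sigmoid, softmax
from .synthetic_data import LabeledImagePair

__all__ = ["FusionSpec", "FusionModel", "build_fusion_model", "randomized_fuse", "fusion_forward", "fusion_forward_batch", "fusion_predict"]

COMBINE_MODES = ("sum", "concat_project")


@dataclass
class FusionSpec:
    target_dim: int = FEATURE_DIM
    seed: int = 0
    scale: float = float(np.sqrt(3.0 / FEATURE_DIM))  # unit output variance for unit inputs
    combine_mode: str = "sum"

    def __post_init__(self) -> None:
        if self.target_dim < 1:
            raise ValueError("target_dim must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.combine_mode not in COMBINE_MODES:
            raise ValueError(f"combine_mode must be one of {COMBINE_MODES}")


@dataclass
class FusionModel:
    ct_backbone: NetworkParams
    xray_backbone: NetworkParams
    proj_ct: np.ndarray  # (target_dim, 192)
    proj_xray: np.ndarray  # (target_dim, 192)
    head_fc: DenseLayerParams  # target_dim -> target_dim, sigmoid
    head_out: DenseLayerParams  # target_dim -> n_classes
    spec: FusionSpec
    n_classes: int
    freeze_backbones: bool = True
    train_projections: bool = False


def build_fusion_model(
    ct_net: NetworkParams,
    xray_net: NetworkParams,
    spec: FusionSpec | None = None,
    n_classes: int = 2,
    freeze_backbones: bool = True,
    train_projections: bool = False,
) -> FusionModel:
    """Transfer the trained backbones, draw frozen random projections, and
    initialize a fresh classifier head."""
    spec = spec or FusionSpec()
    for net in (ct_net, xray_net):
        if net.fc1.weights.shape[0] != FEATURE_DIM:
            raise ValueError("backbone feature dimension must be 192")
    rng = np.random.default_rng(spec.seed)
    t = spec.target_dim
    if spec.combine_mode == "concat_project":
        proj = rng.uniform(-spec.scale, spec.scale, size=(t, 2 * FEATURE_DIM))
        proj_ct, proj_xray = proj[:, :FEATURE_DIM].copy(), proj[:, FEATURE_DIM:].copy()
    else:
        proj_ct = rng.uniform(-spec.scale, spec.scale, size=(t, FEATURE_DIM))
        proj_xray = rng.uniform(-spec.scale, spec.scale, size=(t, FEATURE_DIM))
    head_fc = DenseLayerParams(
        weights=glorot_uniform(rng, (t, t), t, t), biases=np.zeros(t)
    )
    head_out = DenseLayerParams(
        weights=glorot_uniform(rng, (n_classes, t), t, n_classes), biases=np.zeros(n_classes)
    )
    return FusionModel(
        ct_backbone=ct_net.copy(),
        xray_backbone=xray_net.copy(),
        proj_ct=proj_ct,
        proj_xray=proj_xray,
        head_fc=head_fc,
        head_out=head_out,
        spec=spec,
        n_classes=n_classes,
        freeze_backbones=freeze_backbones,
        train_projections=train_projections,
    )


def randomized_fuse(f_ct: np.ndarray, f_xray: np.ndarray, model: FusionModel) -> np.ndarray:
    """Project both 192-d features into the target dimension and combine.

    Both combine modes reduce to ``proj_ct @ f_ct + proj_xray @ f_xray``
    (for concat_project the two blocks are the halves of the single
    concatenation matrix). Purely linear: no bias, deterministic given the
    built model.
    """
    f_ct = np.asarray(f_ct, dtype=np.float64)
    f_xray = np.asarray(f_xray, dtype=np.float64)
    if f_ct.shape[-1] != FEATURE_DIM or f_xray.shape[-1] != FEATURE_DIM:
        raise ValueError(f"feature vectors must have length {FEATURE_DIM}")
    return f_ct @ model.proj_ct.T + f_xray @ model.proj_xray.T


def fusion_forward_batch(model: FusionModel, ct_images: np.ndarray, xray_images: np.ndarray) -> np.ndarray:
    """Class probabilities (N, n_classes) for batched paired images."""
    _, f_ct = lenet.forward_batch(model.ct_backbone, ct_images)
    _, f_xray = lenet.forward_batch(model.xray_backbone, xray_images)
    fused = randomized_fuse(f_ct, f_xray, model)
    h = sigmoid(fused @ model.head_fc.weights.T + model.head_fc.biases)
    logits = h @ model.head_out.weights.T + model.head_out.biases
    return softmax(logits)


def fusion_forward(model: FusionModel, pair: LabeledImagePair) -> np.ndarray:
    """Class probabilities for one paired sample."""
    return fusion_forward_batch(model, pair.ct_image[None], pair.xray_image[None])[0]


def fusion_predict(model: FusionModel, pair: LabeledImagePair) -> int:
    """Argmax class; ties break toward the lower index."""
    return int(np.argmax(fusion_forward(model, pair)))
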