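"""Single-modality convolutional network: two conv+pool stages, two dense layers.

Layer-shape schedule on a 28x28 input (the build contract, checked by a
dry-run forward pass at construction time):

    28x28 -> 6x24x24 -> 6x12x12 -> 12x8x8 -> 12x4x4 -> 192 -> n_classes

The printed configuration this schedule comes from lists a 3x3 kernel, but
28->24 and 12->8 under valid convolution force 5x5 kernels; 5x5 is the
default here and the kernel size stays configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn_core import (
    AvgPool,
    Conv2D,
    ConvLayerParams,
    Dense,
    DenseLayerParams,
    Flatten,
    InputScale,
    SigmoidLayer,
    glorot_uniform,
    softmax,
)

__all__ = ["NetworkParams", "build_network", "forward", "forward_batch", "predict", "shape_trace", "parameter_count"]

INPUT_SIZE = 28
FEATURE_DIM = 192
MODALITY_TAGS = ("CT", "XRAY")


@dataclass
class NetworkParams:
    conv1: ConvLayerParams  # 6 output channels
    conv2: ConvLayerParams  # 12 output channels
    fc1: DenseLayerParams  # 192 -> 192, sigmoid-activated feature layer
    fc2: DenseLayerParams  # 192 -> n_classes
    n_classes: int
    modality_tag: str

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            conv1=ConvLayerParams(self.conv1.kernels.copy(), self.conv1.biases.copy(), self.conv1.stride),
            conv2=ConvLayerParams(self.conv2.kernels.copy(), self.conv2.biases.copy(), self.conv2.stride),
            fc1=DenseLayerParams(self.fc1.weights.copy(), self.fc1.biases.copy()),
            fc2=DenseLayerParams(self.fc2.weights.copy(), self.fc2.biases.copy()),
            n_classes=self.n_classes,
            modality_tag=self.modality_tag,
        )

    def parameter_arrays(self) -> list[np.ndarray]:
        return [
            self.conv1.kernels, self.conv1.biases,
            self.conv2.kernels, self.conv2.biases,
            self.fc1.weights, self.fc1.biases,
            self.fc2.weights, self.fc2.biases,
        ]


def build_layers(net: NetworkParams):
    """Layer stack sharing the parameter arrays of ``net`` (updates are in place)."""
    return [
        InputScale(),  # [0,1] -> [-1,1], keeps the first sigmoid stage unsaturated
        Conv2D(net.conv1),
        SigmoidLayer(),
        AvgPool(2, 2),
        Conv2D(net.conv2),
        SigmoidLayer(),
        AvgPool(2, 2),
        Flatten(),
        Dense(net.fc1),
        SigmoidLayer(),  # output of this layer is the 192-d fusion feature
        Dense(net.fc2),
    ]


def feature_layers(net: NetworkParams):
    """The sub-stack producing the 192-d sigmoid feature (everything before fc2)."""
    return build_layers(net)[:-1]


def build_network(
    n_classes: int = 2,
    seed: int = 0,
    modality_tag: str = "CT",
    kernel_size: int = 5,
) -> NetworkParams:
    """Seeded construction; the shape schedule is verified by a dry run."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if modality_tag not in MODALITY_TAGS:
        raise ValueError(f"modality_tag must be one of {MODALITY_TAGS}")
    rng = np.random.default_rng(seed)
    k = kernel_size

    def conv(out_c: int, in_c: int) -> ConvLayerParams:
        fan_in, fan_out = in_c * k * k, out_c * k * k
        return ConvLayerParams(
            kernels=glorot_uniform(rng, (out_c, in_c, k, k), fan_in, fan_out),
            biases=np.zeros(out_c),
            stride=1,
        )

    def dense(out_d: int, in_d: int) -> DenseLayerParams:
        return DenseLayerParams(
            weights=glorot_uniform(rng, (out_d, in_d), in_d, out_d),
            biases=np.zeros(out_d),
        )

    net = NetworkParams(
        conv1=conv(6, 1),
        conv2=conv(12, 6),
        fc1=dense(FEATURE_DIM, FEATURE_DIM),
        fc2=dense(n_classes, FEATURE_DIM),
        n_classes=n_classes,
        modality_tag=modality_tag,
    )
    trace = shape_trace(net)
    expected = [
        (INPUT_SIZE, INPUT_SIZE),
        (6, 24, 24), (6, 12, 12), (12, 8, 8), (12, 4, 4),
        (FEATURE_DIM,), (n_classes,),
    ]
    if kernel_size == 5 and trace != expected:
        raise RuntimeError(f"shape schedule violated: {trace}")
    return net


def shape_trace(net: NetworkParams) -> list[tuple[int, ...]]:
    """Dry-run forward on a zero image, recording the shape after each stage."""
    x = np.zeros((1, 1, INPUT_SIZE, INPUT_SIZE))
    layers = build_layers(net)
    trace: list[tuple[int, ...]] = [(INPUT_SIZE, INPUT_SIZE)]
    record_after = {1, 3, 4, 6, 8, 10}  # conv1, pool1, conv2, pool2, fc1, fc2
    for i, layer in enumerate(layers):
        x = layer.forward(x)
        if i in record_after:
            trace.append(tuple(x.shape[1:]))
    return trace


def parameter_count(net: NetworkParams) -> int:
    return sum(a.size for a in net.parameter_arrays())


def forward_batch(net: NetworkParams, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched forward; returns (probabilities (N, C), fc features (N, 192))."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:] != (INPUT_SIZE, INPUT_SIZE):
        raise ValueError(f"images must be (N, {INPUT_SIZE}, {INPUT_SIZE}), got {images.shape}")
    x = images[:, None, :, :]
    layers = build_layers(net)
    feat = None
    for i, layer in enumerate(layers):
        x = layer.forward(x)
        if i == 9:  # sigmoid after fc1
            feat = x
    return softmax(x), feat


def forward(net: NetworkParams, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and the sigmoid-activated 192-d feature for one image."""
    probs, feat = forward_batch(net, np.asarray(image)[None, :, :])
    return probs[0], feat[0]


def predict(net: NetworkParams, image: np.ndarray) -> int:
    """Argmax class; ties break toward the lower class index."""
    probs, _ = forward(net, image)
    return int(np.argmax(probs))
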