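"""Branch networks, feature fusion and the softmax head.

Each input representation gets its own lightweight CNN branch of five
convolution stages (every stage is convolution -> batch norm -> ReLU), with a
stride-2 max pool after each of the first four stages and global average
pooling at the end, so every branch emits a 32-dimensional feature vector.
The first stage is a standard convolution with a large receptive field
(31x1 for 1-D inputs, 15x7 for the spectrogram); the remaining four stages
are depthwise-separable convolutions with 3-tap kernels.  Channel counts
widen 16, 16, 32, 32, 32.

The four branch features are fused by concatenation in the fixed order
(raw, dft, stft, dwt) into a 128-dimensional vector, classified by a dense
layer with two outputs and a softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError, InvalidInputError
from .nn import (
    BatchNorm,
    Conv1d,
    Conv2d,
    Dense,
    DepthwiseSeparableConv,
    GlobalAvgPool,
    MaxPool,
    Param,
    ReLU,
    Sequential,
    softmax,
)
from .transforms import HybridInput

__all__ = [
    "ArchConfig",
    "LayerSpec",
    "BranchSpec",
    "FusionHead",
    "BRANCH_ORDER",
    "METHOD_BRANCHES",
    "branch_spec",
    "build_branch",
    "build_head",
    "fuse",
    "classify",
    "predict_labels",
    "count_parameters",
    "HybridNetwork",
    "stack_hybrids",
]

#: Canonical branch (and fusion) order.
BRANCH_ORDER = ("raw", "dft", "stft", "dwt")

#: Experiment method name -> branches used.
METHOD_BRANCHES = {
    "EEG": ("raw",),
    "FFT": ("dft",),
    "STFT": ("stft",),
    "DWT": ("dwt",),
    "Hybrid": BRANCH_ORDER,
}

_INPUT_KINDS = {"raw": "raw_1d", "dft": "dft_1d", "dwt": "dwt_1d", "stft": "stft_2d"}


@dataclass(frozen=True)
class ArchConfig:
    """Tunable architecture defaults.

    ``rest_kernel_2d`` applies the 3x1 receptive field literally to the
    spectrogram branch as well; set ``(3, 3)`` for square kernels.
    ``use_separable=False`` swaps every depthwise-separable stage for a
    standard convolution of the same kernel shape (useful for parameter-count
    comparisons).
    """

    channels: tuple[int, ...] = (16, 16, 32, 32, 32)
    first_kernel_1d: tuple[int, ...] = (31,)
    rest_kernel_1d: tuple[int, ...] = (3,)
    first_kernel_2d: tuple[int, int] = (15, 7)
    rest_kernel_2d: tuple[int, ...] = (3, 1)
    bn_momentum: float = 0.9
    use_separable: bool = True
    n_pools: int = 4  # stride-2 max pool after each of the first n_pools stages


@dataclass(frozen=True)
class LayerSpec:
    """One entry of a branch's layer list."""

    kind: str  # standard_conv | depthwise_separable_conv | max_pool | global_avg_pool
    kernels: int = 0
    kernel_shape: tuple[int, ...] = ()
    stride: int = 1


@dataclass(frozen=True)
class BranchSpec:
    """Declarative description of one CNN branch."""

    input_kind: str  # raw_1d | dft_1d | dwt_1d | stft_2d
    layers: tuple[LayerSpec, ...]
    bn_momentum: float = 0.9

    def __post_init__(self) -> None:
        convs = [l for l in self.layers if l.kind.endswith("conv")]
        if len(convs) != 5:
            raise ConfigurationError(
                f"a branch requires exactly 5 convolution layers, got {len(convs)}"
            )
        if convs[0].kind != "standard_conv" or convs[0].kernels != 16:
            raise ConfigurationError(
                "first layer must be a standard convolution with 16 kernels"
            )
        if any(l.kernels not in (16, 32) for l in convs):
            raise ConfigurationError("kernel counts must be 16 or 32")
        if self.layers[-1].kind != "global_avg_pool":
            raise ConfigurationError("final layer must be global average pooling")
        if not 0.0 < self.bn_momentum < 1.0:
            raise ConfigurationError("bn_momentum must lie in (0, 1)")

    @property
    def feature_dim(self) -> int:
        convs = [l for l in self.layers if l.kind.endswith("conv")]
        return convs[-1].kernels


@dataclass(frozen=True)
class FusionHead:
    """Dimensions and regularization of the classification head."""

    input_dims: tuple[int, ...] = (32, 32, 32, 32)
    output_classes: int = 2
    l2_lambda: float = 1e-4

    def __post_init__(self) -> None:
        if self.output_classes != 2:
            raise ConfigurationError("binary classification head requires 2 classes")
        if self.l2_lambda < 0:
            raise ConfigurationError("l2_lambda must be non-negative")

    @property
    def fused_dim(self) -> int:
        return sum(self.input_dims)


def branch_spec(branch: str, arch: ArchConfig | None = None) -> BranchSpec:
    """Default 5-stage layer list for one branch (``raw``/``dft``/``dwt``/``stft``)."""
    arch = arch or ArchConfig()
    if branch not in _INPUT_KINDS:
        raise ConfigurationError(f"unknown branch {branch!r}")
    two_d = branch == "stft"
    first_k = arch.first_kernel_2d if two_d else arch.first_kernel_1d
    rest_k = arch.rest_kernel_2d if two_d else arch.rest_kernel_1d
    rest_kind = "depthwise_separable_conv" if arch.use_separable else "standard_conv"
    layers: list[LayerSpec] = []
    for i, ch in enumerate(arch.channels):
        if i == 0:
            layers.append(LayerSpec("standard_conv", ch, tuple(first_k)))
        else:
            layers.append(LayerSpec(rest_kind, ch, tuple(rest_k)))
        if i < arch.n_pools:
            layers.append(LayerSpec("max_pool", stride=2))
    layers.append(LayerSpec("global_avg_pool"))
    return BranchSpec(
        input_kind=_INPUT_KINDS[branch], layers=tuple(layers), bn_momentum=arch.bn_momentum
    )


def build_branch(spec: BranchSpec, rng: np.random.Generator | int) -> Sequential:
    """Instantiate a branch network from its spec.

    Every convolution stage expands to convolution -> batch normalization ->
    ReLU; the very first convolution skips its input gradient during backprop
    (its input is the data).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    two_d = spec.input_kind == "stft_2d"
    layers: list = []
    in_ch = 1
    conv_idx = 0
    for lspec in spec.layers:
        if lspec.kind in ("standard_conv", "depthwise_separable_conv"):
            name = f"{spec.input_kind}.conv{conv_idx}"
            shape = lspec.kernel_shape
            if lspec.kind == "standard_conv":
                if two_d:
                    if len(shape) == 1:
                        shape = (shape[0], 1)
                    conv = Conv2d(in_ch, lspec.kernels, shape, rng,
                                  first_layer=conv_idx == 0, name=name)
                else:
                    conv = Conv1d(in_ch, lspec.kernels, shape[0], rng,
                                  first_layer=conv_idx == 0, name=name)
            else:
                if two_d and len(shape) == 1:
                    shape = (shape[0], 1)
                if not two_d and len(shape) > 1:
                    shape = (shape[0],)
                conv = DepthwiseSeparableConv(in_ch, lspec.kernels, shape, rng, name=name)
            layers += [conv, BatchNorm(lspec.kernels, spec.bn_momentum, name=name + ".bn"),
                       ReLU()]
            in_ch = lspec.kernels
            conv_idx += 1
        elif lspec.kind == "max_pool":
            if lspec.stride != 2:
                raise ConfigurationError("max pooling uses stride 2")
            layers.append(MaxPool())
        elif lspec.kind == "global_avg_pool":
            layers.append(GlobalAvgPool())
        else:
            raise ConfigurationError(f"unknown layer kind {lspec.kind!r}")
    return Sequential(layers)


def build_head(head: FusionHead, rng: np.random.Generator | int,
               n_branches: int | None = None) -> Dense:
    """Dense softmax head over the fused feature vector."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    dims = head.input_dims if n_branches is None else head.input_dims[:n_branches]
    return Dense(sum(dims), head.output_classes, rng, name="head")


def fuse(*features: np.ndarray) -> np.ndarray:
    """Concatenate branch feature vectors in the given order.

    Accepts 1-D vectors or (B, F) matrices; every input must be
    32-dimensional along its feature axis.
    """
    if not features:
        raise InvalidInputError("fuse requires at least one feature vector")
    prepped = []
    for f in features:
        f = np.asarray(f)
        if f.ndim == 1:
            f = f[None, :]
        if f.ndim != 2 or f.shape[1] != 32:
            raise InvalidInputError(
                f"branch features must be 32-dimensional, got shape {f.shape}"
            )
        prepped.append(f)
    fused = np.concatenate(prepped, axis=1)
    return fused[0] if np.asarray(features[0]).ndim == 1 else fused


def classify(fused: np.ndarray, head: Dense) -> np.ndarray:
    """Class probabilities for fused features; rows sum to one."""
    fused = np.atleast_2d(np.asarray(fused, dtype=np.float64))
    if fused.shape[1] != head.w.value.shape[0]:
        raise InvalidInputError(
            f"fused dimension {fused.shape[1]} does not match head "
            f"input {head.w.value.shape[0]}"
        )
    logits = head.forward(fused.astype(np.float32), training=False)
    if not np.all(np.isfinite(logits)):
        from ._errors import NumericalError

        raise NumericalError("non-finite logits in classification head")
    return softmax(logits.astype(np.float64))


def predict_labels(probabilities: np.ndarray) -> np.ndarray:
    """Class indices from probabilities: normal (0) iff p0 > p1, else epileptic (1).

    Ties resolve to epileptic — the clinically conservative call.
    """
    p = np.atleast_2d(probabilities)
    return (p[:, 0] <= p[:, 1]).astype(np.int64)


def count_parameters(obj) -> dict:
    """Trainable parameter counts, total plus per-component breakdown."""
    if isinstance(obj, HybridNetwork):
        parts = {name: sum(p.size for p in br.params()) for name, br in obj.branches.items()}
        parts["head"] = sum(p.size for p in obj.head.params())
        return {"total": sum(parts.values()), "breakdown": parts}
    params = obj.params() if hasattr(obj, "params") else list(obj)
    total = sum(p.size for p in params)
    return {"total": total, "breakdown": {p.name: p.size for p in params}}


def stack_hybrids(hybrids: list[HybridInput], branches: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Stack per-segment model arrays into (1, B, *spatial) batch tensors."""
    out = {}
    for name in branches:
        arrs = [h.model_arrays()[name] for h in hybrids]
        out[name] = np.stack(arrs)[None, ...].astype(np.float32)
    return out


class HybridNetwork:
    """The multi-branch classifier: branch CNNs + fusion + softmax head.

    ``branches`` may be any subset of (raw, dft, stft, dwt); single-branch
    instances implement the single-input baselines, the full set is the
    hybrid model.
    """

    def __init__(
        self,
        branches: tuple[str, ...] = BRANCH_ORDER,
        arch: ArchConfig | None = None,
        head: FusionHead | None = None,
        seed: int = 0,
    ) -> None:
        unknown = set(branches) - set(BRANCH_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown branches: {sorted(unknown)}")
        self.branch_names = tuple(b for b in BRANCH_ORDER if b in branches)
        self.arch = arch or ArchConfig()
        self.head_spec = head or FusionHead(
            input_dims=(32,) * len(self.branch_names)
        )
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(self.branch_names) + 1)
        self.branches = {
            name: build_branch(branch_spec(name, self.arch), np.random.default_rng(child))
            for name, child in zip(self.branch_names, children[:-1])
        }
        self.head = build_head(self.head_spec, np.random.default_rng(children[-1]),
                               n_branches=len(self.branch_names))
        self._split_dims = [32] * len(self.branch_names)

    # -- parameters --------------------------------------------------------
    def params(self) -> list[Param]:
        ps = [p for br in self.branches.values() for p in br.params()]
        return ps + self.head.params()

    @property
    def fused_dim(self) -> int:
        return sum(self._split_dims)

    # -- forward / backward ------------------------------------------------
    def features(self, inputs: dict[str, np.ndarray], training: bool = False) -> np.ndarray:
        feats = [self.branches[name].forward(inputs[name], training)
                 for name in self.branch_names]
        return np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]

    def forward(self, inputs: dict[str, np.ndarray], training: bool = False) -> np.ndarray:
        return self.head.forward(self.features(inputs, training), training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        start = 0
        for name, dim in zip(self.branch_names, self._split_dims):
            self.branches[name].backward(np.ascontiguousarray(dfused[:, start : start + dim]))
            start += dim

    # -- inference ---------------------------------------------------------
    def predict_proba(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        logits = self.forward(inputs, training=False)
        return softmax(logits.astype(np.float64))

    def predict(self, inputs: dict[str, np.ndarray]) -> np.ndarray:
        return predict_labels(self.predict_proba(inputs))
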