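"""The multi-branch GCN with separable multi-head attention.

Architecture, per 3-s segment of 22-channel EEG:

1. **Intrachannel extractor** — ``k`` depthwise convolutions (kernel
   ``(1, 2)``, stride 2, no cross-channel mixing) halve the temporal
   resolution per layer, turning the ``(n, C)`` window into graph signals
   ``N`` of shape ``(n, C / 2^k)``.
2. **Three GCN branches** — identical structure, unshared parameters, each
   propagating ``N`` over a different adjacency: a fixed spatial-distance
   graph, a per-segment Pearson functional-connectivity graph (computed on
   ``N`` itself), and a trainable adaptive graph constrained by
   standardization + ReLU. Each layer is
   ``BN(ReLU(D^-1/2 (A+I) D^-1/2 H theta))``.
3. **Separable multi-head attention** — per head, a softmax over the
   flattened node x feature positions of a query projection yields context
   scores; their weighted sum of the key projection gives a context vector,
   broadcast-multiplied with ``ReLU(V)``. Heads are concatenated, fused by a
   3x3 convolution + BN + ReLU, and added residually to the branch stack
   (cost linear in ``n * D`` rather than quadratic).
4. **Classifier** — two 3x3 convolutions with ReLU, global average pooling,
   dropout, a linear layer to 2 units and an element-wise sigmoid; the
   predicted class is the argmax (ties resolve to interictal).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, softmax, stack
from .graphs import Adjacency, build_distance_adjacency, normalize_adjacency
from .montage import ElectrodeLayout, canonical_layout
from .nn import BatchNorm, Conv2d, Dropout, Linear, Module, Parameter, _fan_in_uniform


@dataclass
class ModelConfig:
    """All architectural hyperparameters, including every choice the
    architecture leaves open (GCN depth/width, head geometry, classifier
    channels), recorded explicitly so a run is fully specified by its config."""

    n_channels: int = 22
    window_samples: int = 768
    k_depthwise: int = 2
    gcn_layers: int = 2
    gcn_dim: int = 64
    n_heads: int = 3
    head_dim: int = 1
    dropout: float = 0.5
    classifier_channels: tuple[int, int] = (16, 32)
    n_classes: int = 2
    branch_distance: bool = True
    branch_connectivity: bool = True
    branch_adaptive: bool = True
    attention: bool = True
    r1: float = 0.4
    r2: float = 0.25
    corr_mode: str = "shifted"
    two_delta_sq: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_samples % (2**self.k_depthwise) != 0:
            raise ValueError(
                f"window_samples={self.window_samples} not divisible by "
                f"2^{self.k_depthwise}"
            )
        if not (self.branch_distance or self.branch_connectivity or self.branch_adaptive):
            raise ValueError("at least one branch must be enabled")
        if min(self.n_heads, self.head_dim, self.gcn_layers, self.gcn_dim) < 1:
            raise ValueError("n_heads, head_dim, gcn_layers, gcn_dim must be >= 1")
        self.classifier_channels = tuple(self.classifier_channels)

    @property
    def feature_dim(self) -> int:
        """Temporal length of the graph signals N: ``C / 2^k``."""
        return self.window_samples // (2**self.k_depthwise)

    @property
    def n_branches(self) -> int:
        return sum(
            (self.branch_distance, self.branch_connectivity, self.branch_adaptive)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["classifier_channels"] = list(self.classifier_channels)
        return d

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        if "classifier_channels" in d:
            d["classifier_channels"] = tuple(d["classifier_channels"])
        return ModelConfig(**d)


class IntrachannelExtractor(Module):
    """k depthwise conv layers, kernel (1, 2), stride 2, no channel mixing."""

    def __init__(self, n_channels: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.weights = [
            Parameter(_fan_in_uniform(rng, (n_channels, 2), 2)) for _ in range(k)
        ]
        self.biases = [
            Parameter(_fan_in_uniform(rng, (n_channels,), 2)) for _ in range(k)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, n, C); each layer halves C
        for w, b in zip(self.weights, self.biases):
            n = x.shape[1]
            w0 = w[:, 0].reshape(1, n, 1)
            w1 = w[:, 1].reshape(1, n, 1)
            x = x[:, :, 0::2] * w0 + x[:, :, 1::2] * w1 + b.reshape(1, n, 1)
        return x


class GCNBranch(Module):
    """m graph-convolution layers with per-layer BN; parameters unshared
    across branches (each branch owns one instance)."""

    def __init__(self, in_dim: int, hidden: int, n_layers: int,
                 rng: np.random.Generator):
        super().__init__()
        dims = [in_dim] + [hidden] * n_layers
        self.thetas = [
            Parameter(_fan_in_uniform(rng, (dims[i], dims[i + 1]), dims[i]))
            for i in range(n_layers)
        ]
        self.bns = [BatchNorm(dims[i + 1], channel_axis=-1) for i in range(n_layers)]

    def __call__(self, h: Tensor, s: Tensor, use_bn: bool = True) -> Tensor:
        # h: (B, n, F); s: (n, n) or (B, n, n) normalized propagation operator
        for theta, bn in zip(self.thetas, self.bns):
            h = (s @ (h @ theta)).relu()
            if use_bn:
                h = bn(h)
        return h


class AdaptiveGraph(Module):
    """Trainable raw adjacency with the standardize+ReLU constraint.

    ``raw`` is a free n x n parameter (i.i.d. uniform(0, 1/n) at init, no
    symmetry imposed) updated by backpropagation; the constrained adjacency
    is ``ReLU(affine(standardize(raw)))`` with a scalar learnable affine
    initialized to identity, and the propagation operator adds the self-loop
    and applies the symmetric degree normalization differentiably.
    """

    def __init__(self, n: int, rng: np.random.Generator, eps: float = 1e-5):
        super().__init__()
        self.n = n
        self.eps = eps
        self.raw = Parameter(rng.uniform(0.0, 1.0 / n, (n, n)))
        self.gamma = Parameter(np.ones(1))
        self.beta = Parameter(np.zeros(1))

    def adjacency(self) -> Tensor:
        z = self.raw - self.raw.mean()
        std = ((z**2).mean()) ** 0.5
        return ((z / (std + self.eps)) * self.gamma + self.beta).relu()

    def propagation(self) -> Tensor:
        a = self.adjacency()
        at = a + Tensor(np.eye(self.n))
        dinv = at.sum(axis=-1) ** -0.5
        return at * dinv.reshape(self.n, 1) * dinv.reshape(1, self.n)


class SeparableAttention(Module):
    """Separable multi-head self-attention with residual fusion.

    Q/K/V come from three unshared 1x1 convolutions over the branch axis;
    per head the softmax-normalized query scores (over the flattened
    ``n * D`` positions) contract K into a single context vector, which
    gates ``ReLU(V)`` element-wise. Heads are concatenated, fused by a 3x3
    convolution + BN + ReLU and added to the input, followed by BN.
    """

    def __init__(self, n_branches: int, n_heads: int, head_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.h, self.d = n_heads, head_dim
        self.proj_q = Conv2d(n_branches, n_heads, 1, rng)
        self.proj_k = Conv2d(n_branches, n_heads * head_dim, 1, rng)
        self.proj_v = Conv2d(n_branches, n_heads * head_dim, 1, rng)
        self.fuse = Conv2d(n_heads * head_dim, n_branches, 3, rng, padding=1)
        self.bn_fuse = BatchNorm(n_branches, channel_axis=1)
        self.bn_out = BatchNorm(n_branches, channel_axis=1)
        #: softmax scores of the last forward pass, (B, h, 1, n*D); for audits
        self.last_scores: np.ndarray | None = None

    def __call__(self, z: Tensor) -> Tensor:
        B, nb, n, D = z.shape
        L = n * D
        scores = softmax(self.proj_q(z).reshape(B, self.h, 1, L), axis=-1)
        self.last_scores = scores.data
        k = self.proj_k(z).reshape(B, self.h, self.d, L)
        ctx = (scores * k).sum(axis=-1, keepdims=True)  # (B, h, d, 1)
        v = self.proj_v(z).relu().reshape(B, self.h, self.d, L)
        att = (v * ctx).reshape(B, self.h * self.d, n, D)
        ma = self.bn_fuse(self.fuse(att)).relu()
        return self.bn_out(z + ma)


class Classifier(Module):
    """Two 3x3 conv+ReLU layers, GAP, dropout, linear to 2, sigmoid."""

    def __init__(self, in_channels: int, conv_channels: tuple[int, int],
                 n_classes: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        c1, c2 = conv_channels
        self.conv1 = Conv2d(in_channels, c1, 3, rng, padding=1)
        self.conv2 = Conv2d(c1, c2, 3, rng, padding=1)
        self.drop = Dropout(dropout, rng)
        self.fc = Linear(c2, n_classes, rng)

    def __call__(self, z: Tensor) -> Tensor:
        f = self.conv2(self.conv1(z).relu()).relu()
        g = f.mean(axis=(2, 3))  # global average pooling -> (B, c2)
        return self.fc(self.drop(g)).sigmoid()


class MultiBranchGCN(Module):
    """The full seizure-detection network.

    Parameters
    ----------
    config
        Architectural hyperparameters.
    layout
        Electrode layout used to build the fixed spatial-distance graph
        (defaults to the canonical 22-channel montage). Ignored if
        ``distance_adjacency`` is given.
    distance_adjacency
        A pre-built (e.g. checkpointed) distance adjacency.
    """

    def __init__(
        self,
        config: ModelConfig,
        layout: ElectrodeLayout | None = None,
        distance_adjacency: Adjacency | None = None,
    ):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        n = config.n_channels

        self.distance_adjacency: Adjacency | None = None
        self._s1: np.ndarray | None = None
        if config.branch_distance:
            if distance_adjacency is None:
                if layout is None:
                    layout = canonical_layout()
                if len(layout) != n:
                    raise ValueError("layout size does not match n_channels")
                distance_adjacency = build_distance_adjacency(
                    layout, r1=config.r1, two_delta_sq=config.two_delta_sq
                )
            self.distance_adjacency = distance_adjacency
            self._s1 = normalize_adjacency(distance_adjacency.matrix)

        self.extractor = IntrachannelExtractor(n, config.k_depthwise, rng)
        D = config.feature_dim
        self.branch_names = [
            name
            for name, on in (
                ("distance", config.branch_distance),
                ("connectivity", config.branch_connectivity),
                ("adaptive", config.branch_adaptive),
            )
            if on
        ]
        self.branches = [
            GCNBranch(D, config.gcn_dim, config.gcn_layers, rng)
            for _ in self.branch_names
        ]
        self.adaptive = (
            AdaptiveGraph(n, rng) if config.branch_adaptive else None
        )
        self.attention = (
            SeparableAttention(config.n_branches, config.n_heads, config.head_dim, rng)
            if config.attention
            else None
        )
        self.classifier = Classifier(
            config.n_branches,
            config.classifier_channels,
            config.n_classes,
            config.dropout,
            rng,
        )

    # -- adjacency plumbing --------------------------------------------------

    def connectivity_propagation(self, features: np.ndarray) -> np.ndarray:
        """Per-segment functional-connectivity propagation operators.

        ``features`` is the (detached) extractor output ``(B, n, D)``;
        Pearson correlation across the feature axis is mapped to [0, 1],
        thresholded at ``r2``, zero-diagonal'd, and degree-normalized.
        The graph is data-dependent but carries no gradient.
        """
        x = features - features.mean(axis=-1, keepdims=True)
        norm = np.sqrt((x**2).sum(axis=-1))
        denom = norm[:, :, None] * norm[:, None, :]
        rho = np.divide(
            x @ x.transpose(0, 2, 1),
            denom,
            out=np.zeros_like(denom),
            where=denom > 0,
        )
        rho = np.clip(rho, -1.0, 1.0)
        if self.config.corr_mode == "shifted":
            rho01 = (rho + 1.0) / 2.0
        else:
            rho01 = np.abs(rho)
        a = np.where(rho01 >= self.config.r2, rho01, 0.0)
        idx = np.arange(a.shape[-1])
        a[:, idx, idx] = 0.0
        return normalize_adjacency(a)

    # -- forward -------------------------------------------------------------

    def branch_outputs(
        self,
        x: np.ndarray | Tensor,
        fixed_connectivity: np.ndarray | None = None,
        use_bn: bool = True,
    ) -> tuple[Tensor, list[Tensor]]:
        """Graph signals and per-branch outputs ``z_i`` (each ``(B, n, P)``)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim != 3:
            raise ValueError("input must be (batch, channels, samples)")
        n_feat = self.extractor(x)
        outs = []
        for name, branch in zip(self.branch_names, self.branches):
            if name == "distance":
                s = Tensor(self._s1)
            elif name == "connectivity":
                if fixed_connectivity is not None:
                    s = Tensor(normalize_adjacency(fixed_connectivity))
                else:
                    s = Tensor(self.connectivity_propagation(n_feat.data))
            else:
                s = self.adaptive.propagation()
            outs.append(branch(n_feat, s, use_bn=use_bn))
        return n_feat, outs

    def __call__(
        self,
        x: np.ndarray | Tensor,
        fixed_connectivity: np.ndarray | None = None,
    ) -> Tensor:
        """Class probabilities ``(B, n_classes)`` (element-wise sigmoid)."""
        _, outs = self.branch_outputs(x, fixed_connectivity)
        z = stack(outs, axis=1)  # (B, n_branches, n, P)
        if self.attention is not None:
            z = self.attention(z)
        return self.classifier(z)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Eval-mode probabilities; deterministic (dropout off, running BN)."""
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self(x[i : i + batch_size]).data)
        if was_training:
            self.train()
        return np.concatenate(out) if out else np.empty((0, self.config.n_classes))

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Predicted class per segment; a probability tie resolves to 0."""
        return np.argmax(self.predict_proba(x, batch_size), axis=1)


# -- introspection -----------------------------------------------------------


def describe(model: MultiBranchGCN) -> pd.DataFrame:
    """Parameter audit: one row per parameter tensor plus a total row."""
    rows = [
        {"name": name, "shape": str(tuple(p.shape)), "n_params": p.size}
        for name, p in model.named_parameters()
    ]
    rows.append(
        {"name": "TOTAL", "shape": "", "n_params": sum(r["n_params"] for r in rows)}
    )
    return pd.DataFrame(rows)


def attention_flops(config: ModelConfig) -> int:
    """Multiply-accumulate count of one separable-attention forward pass
    (batch of one). Every term is linear in ``L = n * D``."""
    b, h, d = config.n_branches, config.n_heads, config.head_dim
    L = config.n_channels * config.gcn_dim  # attention runs on the branch stack
    projections = L * b * (h + 2 * h * d)  # three 1x1 convs
    scores = 2 * h * L  # softmax exp + normalize
    context = h * d * L  # score * K contraction
    gate = h * d * L  # ReLU(V) * context
    fusion = 9 * h * d * b * L  # 3x3 conv
    residual = b * L
    return projections + scores + context + gate + fusion + residual


# -- checkpointing -----------------------------------------------------------


def save_checkpoint(model: MultiBranchGCN, path) -> None:
    """Single-file archive: weights + config JSON + frozen distance graph."""
    payload = {f"state::{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.array(json.dumps(model.config.to_dict()))
    if model.distance_adjacency is not None:
        payload["distance_adjacency"] = model.distance_adjacency.matrix
    np.savez_compressed(path, **payload)


def load_checkpoint(path) -> MultiBranchGCN:
    with np.load(path, allow_pickle=False) as z:
        config = ModelConfig.from_dict(json.loads(str(z["config_json"])))
        adj = (
            Adjacency(z["distance_adjacency"], "distance")
            if "distance_adjacency" in z
            else None
        )
        state = {
            k.removeprefix("state::"): z[k] for k in z.files if k.startswith("state::")
        }
    model = MultiBranchGCN(config, distance_adjacency=adj)
    model.load_state_dict(state)
    return model
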