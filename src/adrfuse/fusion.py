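"""Coarse- and fine-grained fusion of drug and side-effect representations,
and the two prediction heads.

Each drug carries three modality vectors (text t, molecular structure v,
attribute similarity o) and each side effect two (t, o), all in the shared
``dim`` space, giving 6 drug-modality x side-effect-modality pairs.

Coarse fusion summarizes each pair by aggregating the element-wise product
and mixing with a linear map.  Two defensible readings of the printed
formula are both implemented: "scalar" (the default) takes the inner
product per pair, yielding 6 scalars mixed by W in R^{6 x c}; "vector" sums
the 6 element-wise product vectors and mixes with W in R^{dim x c}.

Fine fusion forms the 6 outer-product maps (dim x dim), stacks them as
channels, and runs a small CNN: two blocks of 2x2 kernels with stride 2
(kernel = stride, so each block is a non-overlapping patch transform),
channels 6 -> 16 -> 32 with ReLU, then flatten and a linear map.

The heads are two separate two-layer MLPs on [c1 ; c2]: a frequency score
FS (unbounded at train time) and an association score AS squashed by a
sigmoid into (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, glorot, parameter

__all__ = [
    "RepresentationBundle",
    "FusionParams",
    "HeadParams",
    "PairPrediction",
    "modality_pairs",
    "coarse_pair_scores",
    "coarse_fuse",
    "outer_product_channels",
    "fine_fuse",
    "predict_pair",
]

DRUG_MODALITIES = ("t", "v", "o")
SIDE_MODALITIES = ("t", "o")
N_PAIRS = len(DRUG_MODALITIES) * len(SIDE_MODALITIES)  # 6


@dataclass
class RepresentationBundle:
    """Batched per-pair representations; every tensor is (batch, dim)."""

    drug_t: Tensor
    drug_v: Tensor
    drug_o: Tensor
    side_t: Tensor
    side_o: Tensor

    def __post_init__(self) -> None:
        tensors = [as_tensor(t) for t in (self.drug_t, self.drug_v, self.drug_o, self.side_t, self.side_o)]
        self.drug_t, self.drug_v, self.drug_o, self.side_t, self.side_o = tensors
        dims = {t.shape[-1] for t in tensors}
        if len(dims) != 1:
            raise ValueError(f"all representations must share dim, got {sorted(dims)}")
        if any(not np.isfinite(t.data).all() for t in tensors):
            raise ValueError("non-finite representation")

    @property
    def dim(self) -> int:
        return self.drug_t.shape[-1]

    def drug(self, m: str) -> Tensor:
        return {"t": self.drug_t, "v": self.drug_v, "o": self.drug_o}[m]

    def side(self, m: str) -> Tensor:
        return {"t": self.side_t, "o": self.side_o}[m]


def modality_pairs() -> list[tuple[str, str]]:
    return [(a, b) for a in DRUG_MODALITIES for b in SIDE_MODALITIES]


@dataclass
class FusionParams:
    coarse_W: Tensor  # (6, c) for 'scalar' reading, (dim, c) for 'vector'
    conv1_W: Tensor  # (6*4, 16)  2x2 stride-2 patches as a matmul
    conv1_b: Tensor
    conv2_W: Tensor  # (16*4, 32)
    conv2_b: Tensor
    fine_W: Tensor  # (32*(dim/4)^2, c)
    reading: str = "scalar"
    activation: str = "relu"

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        dim: int,
        out_dim: int = 32,
        reading: str = "scalar",
        channels: tuple[int, int] = (16, 32),
    ) -> "FusionParams":
        if dim % 4 != 0:
            raise ValueError("fine fusion needs dim divisible by 4 (two 2x2/stride-2 blocks)")
        if reading not in ("scalar", "vector"):
            raise ValueError(f"unknown coarse reading {reading!r}")
        c1, c2 = channels
        fan = N_PAIRS if reading == "scalar" else dim
        flat = c2 * (dim // 4) ** 2
        return cls(
            coarse_W=parameter(glorot(rng, fan, out_dim)),
            conv1_W=parameter(glorot(rng, N_PAIRS * 4, c1)),
            conv1_b=parameter(np.zeros(c1)),
            conv2_W=parameter(glorot(rng, c1 * 4, c2)),
            conv2_b=parameter(np.zeros(c2)),
            fine_W=parameter(glorot(rng, flat, out_dim)),
            reading=reading,
        )

    def named(self, prefix: str = "fusion") -> dict[str, Tensor]:
        return {
            f"{prefix}.coarse_W": self.coarse_W,
            f"{prefix}.conv1_W": self.conv1_W,
            f"{prefix}.conv1_b": self.conv1_b,
            f"{prefix}.conv2_W": self.conv2_W,
            f"{prefix}.conv2_b": self.conv2_b,
            f"{prefix}.fine_W": self.fine_W,
        }


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "linear":
        return x
    raise ValueError(f"unknown activation {name!r}")


def _stacked(bundle: RepresentationBundle) -> tuple[Tensor, Tensor]:
    """Drug reps stacked (batch, 3, dim) and side reps (batch, 2, dim),
    in modality_pairs() order."""
    dim = bundle.dim
    a = concat([bundle.drug(m).reshape(-1, 1, dim) for m in DRUG_MODALITIES], axis=1)
    b = concat([bundle.side(m).reshape(-1, 1, dim) for m in SIDE_MODALITIES], axis=1)
    return a, b


# ---------------------------------------------------------------- coarse
def coarse_pair_scores(bundle: RepresentationBundle) -> Tensor:
    """Inner product of every drug/side modality pair: (batch, 6)."""
    a, b = _stacked(bundle)
    dim = bundle.dim
    prod = a.reshape(-1, 3, 1, dim) * b.reshape(-1, 1, 2, dim)  # (B,3,2,dim)
    return prod.sum(axis=-1).reshape(-1, N_PAIRS)


def coarse_fuse(bundle: RepresentationBundle, params: FusionParams) -> Tensor:
    """Coarse-grained fusion representation c1 of each pair in the batch."""
    if params.reading == "scalar":
        x = coarse_pair_scores(bundle)
    else:  # sum of the 6 element-wise product vectors
        x = None
        for a, b in modality_pairs():
            prod = bundle.drug(a) * bundle.side(b)
            x = prod if x is None else x + prod
    if x.shape[-1] != params.coarse_W.shape[0]:
        raise ValueError("coarse fusion weight shape incompatible with reading")
    return _activate(x @ params.coarse_W, params.activation)


# ------------------------------------------------------------------ fine
def outer_product_channels(bundle: RepresentationBundle) -> Tensor:
    """Stack the 6 outer-product maps a b^T as channels: (batch, 6, dim, dim)."""
    dim = bundle.dim
    a, b = _stacked(bundle)
    maps = a.reshape(-1, 3, 1, dim).outer(b.reshape(-1, 1, 2, dim))  # (B,3,2,dim,dim)
    return maps.reshape(-1, N_PAIRS, dim, dim)


def _patch_conv(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 convolution: because kernel equals stride, it is a
    linear map on non-overlapping 2x2 patches."""
    B, C, H, Wd = x.shape
    x = x.reshape(B, C, H // 2, 2, Wd // 2, 2)
    x = x.transpose(0, 2, 4, 1, 3, 5)  # (B, H/2, W/2, C, 2, 2)
    x = x.reshape(B, H // 2, Wd // 2, C * 4)
    out = x @ W + b  # (B, H/2, W/2, C')
    return out.transpose(0, 3, 1, 2)


def fine_fuse(bundle: RepresentationBundle, params: FusionParams) -> Tensor:
    """Fine-grained fusion representation c2 via the outer-product CNN."""
    x = outer_product_channels(bundle)
    x = _patch_conv(x, params.conv1_W, params.conv1_b).relu()
    x = _patch_conv(x, params.conv2_W, params.conv2_b).relu()
    B = x.shape[0]
    x = x.reshape(B, -1)
    return _activate(x @ params.fine_W, params.activation)


# ----------------------------------------------------------------- heads
@dataclass
class HeadParams:
    """Two separate two-layer MLPs over [c1 ; c2]."""

    freq_W1: Tensor
    freq_b1: Tensor
    freq_W2: Tensor
    freq_b2: Tensor
    assoc_W1: Tensor
    assoc_b1: Tensor
    assoc_W2: Tensor
    assoc_b2: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, hidden: int = 32) -> "HeadParams":
        def mlp():
            return (
                parameter(glorot(rng, in_dim, hidden)),
                parameter(np.zeros(hidden)),
                parameter(glorot(rng, hidden, 1)),
                parameter(np.zeros(1)),
            )

        fw1, fb1, fw2, fb2 = mlp()
        aw1, ab1, aw2, ab2 = mlp()
        # start the frequency head at the middle class so early training is
        # no worse than the constant predictor
        fb2.data = np.array([3.0])
        return cls(fw1, fb1, fw2, fb2, aw1, ab1, aw2, ab2)

    def named(self, prefix: str = "heads") -> dict[str, Tensor]:
        return {
            f"{prefix}.freq_W1": self.freq_W1,
            f"{prefix}.freq_b1": self.freq_b1,
            f"{prefix}.freq_W2": self.freq_W2,
            f"{prefix}.freq_b2": self.freq_b2,
            f"{prefix}.assoc_W1": self.assoc_W1,
            f"{prefix}.assoc_b1": self.assoc_b1,
            f"{prefix}.assoc_W2": self.assoc_W2,
            f"{prefix}.assoc_b2": self.assoc_b2,
        }


@dataclass
class PairPrediction:
    """Association score AS in (0,1) and frequency score FS (batched tensors)."""

    AS: Tensor
    FS: Tensor


def predict_pair(
    c1: Tensor,
    c2: Tensor,
    params: HeadParams,
    dropout: tuple[np.ndarray, np.ndarray] | None = None,
) -> PairPrediction:
    """Run both heads on the concatenated fusion representations.

    ``dropout`` optionally carries pre-drawn inverted-dropout multipliers
    for the hidden layer of each head (frequency, association); training
    only.
    """
    x = concat([as_tensor(c1), as_tensor(c2)], axis=-1)
    hf = (x @ params.freq_W1 + params.freq_b1).relu()
    ha = (x @ params.assoc_W1 + params.assoc_b1).relu()
    if dropout is not None:
        hf = hf * as_tensor(dropout[0])
        ha = ha * as_tensor(dropout[1])
    fs = (hf @ params.freq_W2 + params.freq_b2).reshape(-1)
    as_ = (ha @ params.assoc_W2 + params.assoc_b2).reshape(-1).sigmoid()
    return PairPrediction(AS=as_, FS=fs)
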