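"""Molecular structure representation: SMILES -> heavy-atom graph -> graph
attention network (GAT) -> max-pooled drug structure vector.

The graph is the RDKit heavy-atom skeleton: implicit hydrogens, bond types
collapsed to plain adjacency.  Atom features default to a one-hot element
encoding over the corpus element vocabulary, optionally extended with
degree, formal charge and an aromaticity flag.

The encoder is a standard multi-head GAT: per-head linear transform,
additive attention scores passed through LeakyReLU, softmax over the
neighborhood (self-loops included so every atom attends at least to
itself), head outputs concatenated; ELU between layers; a final linear
projection to the shared embedding dimension followed by coordinate-wise
max pooling over atoms, which makes the drug vector invariant to atom
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .autodiff import Tensor, as_tensor, glorot, parameter

RDLogger.DisableLog("rdApp.*")  # rdkit warnings are noise for invalid-SMILES tests

__all__ = [
    "MoleculeGraph",
    "GATConfig",
    "GATParams",
    "InvalidMoleculeError",
    "smiles_to_graph",
    "element_vocabulary",
    "featurize",
    "attention_coefficients",
    "gat_attention",
    "encode_molecules",
    "pad_graphs",
]


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass
class MoleculeGraph:
    atom_elements: list[str]
    adjacency: np.ndarray  # binary, symmetric, zero diagonal
    atom_features: np.ndarray | None = None  # filled by featurize()

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.atom_elements)
        if n < 1:
            raise InvalidMoleculeError("molecule must have at least one atom")
        if self.adjacency.shape != (n, n):
            raise InvalidMoleculeError("adjacency shape mismatch")
        if not np.allclose(self.adjacency, self.adjacency.T) or np.diag(self.adjacency).any():
            raise InvalidMoleculeError("adjacency must be symmetric with zero diagonal")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_elements)

    @property
    def n_bonds(self) -> int:
        return int(self.adjacency.sum()) // 2


def smiles_to_graph(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a heavy-atom molecular graph."""
    if not smiles or not smiles.strip():
        raise InvalidMoleculeError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"unparseable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    adj = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    graph = MoleculeGraph(elements, adj)
    graph._mol = mol  # kept for extended featurization
    return graph


def element_vocabulary(graphs: list[MoleculeGraph]) -> list[str]:
    """Sorted element vocabulary over a corpus of molecules."""
    return sorted({e for g in graphs for e in g.atom_elements})


def featurize(graph: MoleculeGraph, vocab: list[str], extended: bool = False) -> np.ndarray:
    """One-hot element features, with an optional extended block
    (degree, formal charge, aromatic flag)."""
    index = {e: k for k, e in enumerate(vocab)}
    n = graph.n_atoms
    extra = 3 if extended else 0
    x = np.zeros((n, len(vocab) + extra))
    for i, e in enumerate(graph.atom_elements):
        if e not in index:
            raise InvalidMoleculeError(f"element {e!r} outside vocabulary")
        x[i, index[e]] = 1.0
    if extended:
        mol = getattr(graph, "_mol", None)
        for i in range(n):
            x[i, len(vocab)] = graph.adjacency[i].sum()
            if mol is not None:
                atom = mol.GetAtomWithIdx(i)
                x[i, len(vocab) + 1] = atom.GetFormalCharge()
                x[i, len(vocab) + 2] = float(atom.GetIsAromatic())
    graph.atom_features = x
    return x


# ------------------------------------------------------------------- config
@dataclass
class GATConfig:
    hidden_dim: int = 32  # per-head hidden width d
    heads: int = 4
    layers: int = 2
    leaky_relu_slope: float = 0.2
    out_dim: int = 32  # shared embedding dimension

    def __post_init__(self) -> None:
        if self.heads < 1 or self.hidden_dim < 1 or self.layers < 1 or self.out_dim < 1:
            raise ValueError("GAT dimensions must be positive")


@dataclass
class GATParams:
    """Per-layer head-stacked transforms W (heads, in, d) and attention
    vectors split into source/target halves (a = [a_src ; a_dst], each
    (heads, d, 1)), plus the final linear projection to the shared space."""

    W: list[Tensor]
    a_src: list[Tensor]
    a_dst: list[Tensor]
    proj_W: Tensor  # (heads*d, out_dim)
    proj_b: Tensor
    config: GATConfig = field(default_factory=GATConfig)

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, config: GATConfig) -> "GATParams":
        W, a_src, a_dst = [], [], []
        fan = in_dim
        h, d = config.heads, config.hidden_dim
        for _ in range(config.layers):
            W.append(parameter(glorot(rng, fan, d, shape=(h, fan, d))))
            a_src.append(parameter(glorot(rng, d, 1, shape=(h, d, 1))))
            a_dst.append(parameter(glorot(rng, d, 1, shape=(h, d, 1))))
            fan = h * d
        proj_W = parameter(glorot(rng, fan, config.out_dim))
        proj_b = parameter(np.zeros(config.out_dim))
        return cls(W, a_src, a_dst, proj_W, proj_b, config)

    def named(self, prefix: str = "gat") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {f"{prefix}.proj_W": self.proj_W, f"{prefix}.proj_b": self.proj_b}
        for li in range(len(self.W)):
            out[f"{prefix}.W{li}"] = self.W[li]
            out[f"{prefix}.a_src{li}"] = self.a_src[li]
            out[f"{prefix}.a_dst{li}"] = self.a_dst[li]
        return out


# ---------------------------------------------------------------- attention
def attention_coefficients(e: np.ndarray, slope: float = 0.2) -> np.ndarray:
    """Normalize raw attention logits over a neighborhood:
    softmax of LeakyReLU(e)."""
    z = np.where(e > 0, e, slope * e)
    z = z - z.max()
    w = np.exp(z)
    return w / w.sum()


def gat_attention(
    x_p: np.ndarray, x_neighbors: np.ndarray, W: np.ndarray, a: np.ndarray, slope: float = 0.2
) -> np.ndarray:
    """Attention coefficients of node p over its neighbors for one head.

    e_pq = a . [W x_p ; W x_q]; coefficients are the softmax over the
    neighborhood of LeakyReLU(e) and always sum to 1.
    """
    x_neighbors = np.atleast_2d(x_neighbors)
    hp = W.T @ x_p
    hn = x_neighbors @ W
    d = hp.size
    e = np.array([a[:d] @ hp + a[d:] @ hq for hq in hn])
    return attention_coefficients(e, slope)


# ----------------------------------------------------------------- encoding
def pad_graphs(graphs: list[MoleculeGraph]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack graphs into padded feature/adjacency tensors plus an atom mask.

    Self-loops are added to the adjacency so every atom (isolated ones
    included) participates in its own attention neighborhood.
    """
    if any(g.atom_features is None for g in graphs):
        raise ValueError("featurize() must run before padding")
    n_max = max(g.n_atoms for g in graphs)
    feat_dim = graphs[0].atom_features.shape[1]
    X = np.zeros((len(graphs), n_max, feat_dim))
    A = np.zeros((len(graphs), n_max, n_max))
    mask = np.zeros((len(graphs), n_max), dtype=bool)
    for k, g in enumerate(graphs):
        n = g.n_atoms
        X[k, :n] = g.atom_features
        A[k, :n, :n] = g.adjacency + np.eye(n)
        mask[k, :n] = True
    return X, A, mask


def encode_molecules(X, A, mask, params: GATParams, attention_out: list | None = None) -> Tensor:
    """Run the GAT over a padded batch; returns (n_mols, out_dim) drug vectors.

    Heads are evaluated together via batched matmul: hidden states carry a
    leading head axis (heads, B, n, d) and the concatenation of head
    outputs becomes a transpose + reshape.  If ``attention_out`` is a list,
    the normalized attention arrays (heads, B, n, n) of each layer are
    appended to it.
    """
    cfg = params.config
    B, n = np.asarray(X).shape[:2]
    h = as_tensor(X).reshape(1, B, n, -1)
    blocked = (np.asarray(A) == 0)[None]  # (1, B, n, n) disallowed pairs
    for li in range(cfg.layers):
        Wl = params.W[li].reshape(cfg.heads, 1, -1, cfg.hidden_dim)
        z = h @ Wl  # (heads, B, n, d)
        s_src = z @ params.a_src[li].reshape(cfg.heads, 1, cfg.hidden_dim, 1)
        s_dst = z @ params.a_dst[li].reshape(cfg.heads, 1, cfg.hidden_dim, 1)
        e = s_src + s_dst.transpose(0, 1, 3, 2)  # e[p, q] = a_src.z_p + a_dst.z_q
        e = e.leaky_relu(cfg.leaky_relu_slope)
        e = e.masked_fill(np.broadcast_to(blocked, e.shape), -1e30)
        alpha = e.softmax(axis=-1)
        if attention_out is not None:
            attention_out.append(alpha.data.copy())
        out = alpha @ z  # (heads, B, n, d)
        h = out.transpose(1, 2, 0, 3).reshape(1, B, n, cfg.heads * cfg.hidden_dim)
        if li + 1 < cfg.layers:
            h = h.elu()
    out = h.reshape(B, n, -1) @ params.proj_W + params.proj_b  # (B, n, out_dim)
    pad = ~np.asarray(mask)
    out = out.masked_fill(pad[:, :, None], -1e30)
    return out.max(axis=1)  # coordinate-wise max over atoms
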