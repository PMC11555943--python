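"""Attribute-similarity learning: the five similarity matrices and the
fused attribute representations of drugs and side effects.

Drug side: Jaccard over binary drug-disease profiles plus an externally
supplied drug-chemical similarity; the two matrix rows are concatenated and
projected into the shared embedding space.

Side-effect side: three views -- hyponymy similarity over a four-level
ontology DAG (semantic contributions decaying by a factor mu per 'is-a'
edge), cosine similarity of word vectors, and cosine similarity of known
drug-association profiles -- combined by a learned softmax attention over
views.  In cold-start mode the association-derived view is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .autodiff import Tensor, as_tensor, concat, glorot, parameter

__all__ = [
    "SimilarityMatrix",
    "OntologyDAG",
    "jaccard_similarity_matrix",
    "build_ontology_dag",
    "semantic_contributions",
    "semantic_value",
    "hyponymy_similarity",
    "hyponymy_similarity_matrix",
    "cosine_similarity_matrix",
    "side_drug_profile_matrix",
    "DrugProjectionParams",
    "project_drug_attributes",
    "ViewAttentionParams",
    "attention_combine_views",
]

KINDS = ("drug-chem", "drug-disease", "side-hypo", "side-word", "side-drug")


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError("similarity matrix must be square over its ids")
        if self.kind not in KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        lo = 0.0 if self.kind in ("drug-disease", "side-hypo") else -1.0
        if self.values.min() < lo - 1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError(f"{self.kind} similarity values out of range")

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.ids.index(entity_id)]


# ------------------------------------------------------------------ Jaccard
def jaccard_similarity_matrix(assoc: np.ndarray, ids: list[str], kind: str = "drug-disease") -> SimilarityMatrix:
    """Pairwise Jaccard similarity between the rows of a binary matrix.

    Two empty profiles get similarity 0 (no evidence of similarity); an
    entity with a nonzero profile has self-similarity 1.
    """
    assoc = np.asarray(assoc)
    if not np.isin(assoc, (0, 1)).all():
        raise ValueError("Jaccard input must be binary")
    assoc = assoc.astype(float)
    inter = assoc @ assoc.T
    sizes = assoc.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return SimilarityMatrix(sim, ids, kind)


# ------------------------------------------------------------- ontology DAG
@dataclass
class OntologyDAG:
    """'is-a' DAG over dotted ids; the parent of a k-segment id is its
    (k-1)-segment prefix.  ``term_map`` sends each side-effect id to the set
    of ontology nodes it annotates (possibly several, possibly none)."""

    graph: nx.DiGraph  # edges child -> parent
    term_map: dict[str, set[str]] = field(default_factory=dict)

    def ancestors_of_node(self, node: str) -> set[str]:
        """Node plus everything reachable along child->parent edges."""
        return {node} | nx.descendants(self.graph, node)

    def term_nodes(self, term: str) -> set[str]:
        return self.term_map.get(term, set())


def build_ontology_dag(term_map: dict[str, list[str]]) -> OntologyDAG:
    """Construct the prefix DAG: each dotted id links to its prefix parent;
    missing intermediate prefixes are created implicitly."""
    g = nx.DiGraph()
    for dotted_ids in term_map.values():
        for dotted in dotted_ids:
            segments = dotted.split(".")
            if len(segments) > 4:
                raise ValueError(f"dotted id {dotted!r} exceeds 4 levels")
            g.add_node(dotted)
            for k in range(len(segments), 1, -1):
                child = ".".join(segments[:k])
                par = ".".join(segments[: k - 1])
                g.add_edge(child, par)
    if not nx.is_directed_acyclic_graph(g):  # pragma: no cover - impossible by prefix construction
        raise ValueError("ontology graph has a cycle")
    return OntologyDAG(g, {t: set(ids) for t, ids in term_map.items()})


def _term_ancestor_set(dag: OntologyDAG, nodes: set[str]) -> set[str]:
    anc: set[str] = set()
    for n in nodes:
        if n not in dag.graph:
            raise KeyError(f"node {n!r} not in ontology DAG")
        anc |= dag.ancestors_of_node(n)
    return anc


def semantic_contributions(dag: OntologyDAG, a: str | set[str], mu: float) -> dict[str, float]:
    """Semantic contribution D_A(s) of every ancestor s to target A.

    D_A(A) = 1; for any other node s in A's ancestor closure,
    D_A(s) = max over children s' of s inside the closure of mu * D_A(s'),
    i.e. mu raised to the shortest-in-decay (best) path length from A up to
    s.  ``a`` may be one node or a term's node set (multi-id terms take the
    union closure, with D = 1 on each of the term's own nodes).
    """
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must lie in (0, 1)")
    base = {a} if isinstance(a, str) else set(a)
    if not base:
        raise KeyError("empty target node set")
    closure = _term_ancestor_set(dag, base)
    d: dict[str, float] = {}

    def value(node: str) -> float:
        if node in d:
            return d[node]
        if node in base:
            d[node] = 1.0
            return 1.0
        # children of `node` inside the closure: predecessors along child->parent edges
        kids = [c for c in dag.graph.predecessors(node) if c in closure]
        d[node] = mu * max(value(c) for c in kids)
        return d[node]

    for node in closure:
        value(node)
    return d


def semantic_value(dag: OntologyDAG, a: str | set[str], mu: float) -> float:
    """Total semantic value DV(A): sum of contributions over A's ancestor set."""
    return float(sum(semantic_contributions(dag, a, mu).values()))


def hyponymy_similarity(dag: OntologyDAG, term_i: str, term_j: str, mu: float = 0.5) -> float:
    """Ontology similarity of two terms from their shared ancestors'
    contributions relative to the terms' total semantic values.

    Terms absent from the ontology are similar only to themselves
    (similarity 1 to self, 0 to everything else).
    """
    nodes_i = dag.term_nodes(term_i)
    nodes_j = dag.term_nodes(term_j)
    if not nodes_i or not nodes_j:
        return 1.0 if term_i == term_j else 0.0
    di = semantic_contributions(dag, nodes_i, mu)
    dj = semantic_contributions(dag, nodes_j, mu)
    shared = set(di) & set(dj)
    if not shared:
        return 0.0
    num = sum(di[x] + dj[x] for x in shared)
    return float(num / (sum(di.values()) + sum(dj.values())))


def hyponymy_similarity_matrix(
    dag: OntologyDAG, se_ids: list[str], terms: list[str], mu: float = 0.5
) -> SimilarityMatrix:
    contribs = []
    for t in terms:
        nodes = dag.term_nodes(t)
        contribs.append(semantic_contributions(dag, nodes, mu) if nodes else None)
    k = len(se_ids)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if contribs[i] is None or contribs[j] is None:
                s = 0.0
            else:
                shared = set(contribs[i]) & set(contribs[j])
                if shared:
                    num = sum(contribs[i][x] + contribs[j][x] for x in shared)
                    s = num / (sum(contribs[i].values()) + sum(contribs[j].values()))
                else:
                    s = 0.0
            sim[i, j] = sim[j, i] = s
    return SimilarityMatrix(sim, list(se_ids), "side-hypo")


# -------------------------------------------------------------------- cosine
def cosine_similarity_matrix(features: np.ndarray, ids: list[str], kind: str) -> SimilarityMatrix:
    """Row-wise cosine similarity; zero-norm rows are 0 off-diagonal, 1 on it."""
    features = np.asarray(features, dtype=float)
    if np.isnan(features).any():
        raise ValueError("features contain NaN")
    norms = np.linalg.norm(features, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = features / safe[:, None]
    sim = unit @ unit.T
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, np.where(zero, 1.0, np.clip(np.diag(sim), -1.0, 1.0)))
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(sim, ids, kind)


def side_drug_profile_matrix(train_matrix) -> SimilarityMatrix:
    """Cosine similarity of side effects' binarized drug-association columns.

    Must be built from the training fold's matrix only; test-fold cells do
    not exist here, which is what keeps the view leakage-free.
    """
    binary = (np.asarray(train_matrix.values) > 0).astype(float)
    return cosine_similarity_matrix(binary.T, list(train_matrix.col_ids), "side-drug")


# ----------------------------------------------- learned attribute fusions
@dataclass
class DrugProjectionParams:
    """Affine map from the concatenated chem+disease similarity rows to the
    shared embedding space, with a configurable nonlinearity."""

    W: Tensor
    b: Tensor
    activation: str = "relu"

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, dim: int, activation: str = "relu"):
        return cls(parameter(glorot(rng, in_dim, dim)), parameter(np.zeros(dim)), activation)


def _activate(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    if name == "elu":
        return x.elu()
    if name == "linear":
        return x
    raise ValueError(f"unknown activation {name!r}")


def project_drug_attributes(chem_row, disease_row, params: DrugProjectionParams) -> Tensor:
    """o^d = activation(W [chem_row ; disease_row] + b); accepts batched rows."""
    x = concat([as_tensor(chem_row), as_tensor(disease_row)], axis=-1)
    if x.shape[-1] != params.W.shape[0]:
        raise ValueError(f"input length {x.shape[-1]} != projection fan-in {params.W.shape[0]}")
    return _activate(x @ params.W + params.b, params.activation)


@dataclass
class ViewAttentionParams:
    """One scorer shared across side-effect views: a single-output affine
    map on the view vector, squashed by tanh, softmaxed across views."""

    W: Tensor  # (dim, 1)
    b: Tensor  # (1,)

    @classmethod
    def init(cls, rng: np.random.Generator, dim: int):
        return cls(parameter(glorot(rng, dim, 1)), parameter(np.zeros(1)))


def attention_combine_views(views: dict[str, Tensor], params: ViewAttentionParams) -> Tensor:
    """Softmax-attention combination of the available side-effect views.

    ``views`` maps view name -> (batch, dim) tensor; cold-start passes two
    views instead of three.  Weights sum to 1 across whatever views are
    present.
    """
    if not views:
        raise ValueError("at least one view required")
    names = sorted(views)
    scores = concat([(as_tensor(views[n]) @ params.W + params.b).tanh() for n in names], axis=-1)
    alpha = scores.softmax(axis=-1)  # (batch, n_views)
    out = None
    for k, n in enumerate(names):
        col = alpha @ _unit_col(len(names), k)  # (batch, 1) attention weight of view n
        term = as_tensor(views[n]) * col
        out = term if out is None else out + term
    return out


def _unit_col(n: int, k: int) -> Tensor:
    e = np.zeros((n, 1))
    e[k, 0] = 1.0
    return Tensor(e)
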