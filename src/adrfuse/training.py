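"""Model assembly and optimization.

The end-to-end model wires the three modality encoders into the fusion
heads: hashed/pretrained text embeddings with a learned linear projection,
the molecular GAT, the drug attribute projection, and the side-effect view
attention.  Training minimizes the joint multiplicative objective

    L = L1 * L2 + gamma * R(Theta)

where L1 is the mean squared association error over all samples, L2 the
mean squared frequency error over positive samples only (frequency is
undefined for non-associated pairs), and R the sum of squared parameters.
The multiplicative coupling means each task's gradient is scaled by the
other task's current error.

Optimization is Adam with the configured weight decay, batch size 128 by
default, initial learning rate 5e-4 decayed by 80% after epoch 250, at most
400 epochs.  Dropout and gamma are tuned on a 3x3 grid by inner
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Adam, Tensor, as_tensor, dropout_mask, get_dtype, glorot, parameter
from .corpus import FrequencyCorpus, FrequencyMatrix, PairSample
from .fusion import (
    FusionParams,
    HeadParams,
    PairPrediction,
    RepresentationBundle,
    coarse_fuse,
    fine_fuse,
    predict_pair,
)
from .molecule import GATConfig, GATParams, encode_molecules, element_vocabulary, featurize, pad_graphs, smiles_to_graph
from .similarity import (
    DrugProjectionParams,
    SimilarityMatrix,
    ViewAttentionParams,
    attention_combine_views,
    hyponymy_similarity_matrix,
    build_ontology_dag,
    cosine_similarity_matrix,
    jaccard_similarity_matrix,
    project_drug_attributes,
    side_drug_profile_matrix,
)
from .text import SemanticTable, TextEmbeddingProvider, embed_corpus_texts

__all__ = [
    "TrainingConfig",
    "LossBreakdown",
    "FeatureSet",
    "JointModel",
    "TrainedModel",
    "TrainingDivergence",
    "prepare_features",
    "matrix_from_samples",
    "joint_loss",
    "train_model",
    "train_with_validation",
    "inner_grid_search",
    "learning_rate_at",
    "DEFAULT_DROPOUT_GRID",
    "DEFAULT_GAMMA_GRID",
]

DEFAULT_DROPOUT_GRID = (0.4, 0.5, 0.6)
DEFAULT_GAMMA_GRID = (1e-3, 1e-4, 1e-5)


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class TrainingConfig:
    lr: float = 5e-4
    lr_decay_factor: float = 0.2  # 80% reduction
    lr_decay_epoch: int = 250
    max_epochs: int = 400
    batch_size: int = 128
    dim: int = 128
    dropout: float = 0.5
    gamma: float = 1e-3
    weight_decay: float = 1e-3
    seed: int = 0
    fusion_reading: str = "scalar"
    fusion_out: int = 32
    head_hidden: int = 32
    gat_heads: int = 4
    gat_layers: int = 2
    label_smoothing: float = 0.0
    semantic_mu: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.dropout < 1.0:
            raise ValueError("dropout must lie in (0,1)")
        if min(self.lr, self.max_epochs, self.batch_size, self.dim) <= 0:
            raise ValueError("learning rate, epochs, batch size and dim must be positive")


def learning_rate_at(epoch: int, config: TrainingConfig) -> float:
    """Learning rate for a 1-based epoch under the step decay schedule."""
    return config.lr * config.lr_decay_factor if epoch > config.lr_decay_epoch else config.lr


@dataclass
class LossBreakdown:
    L1: float
    L2: float
    R: float
    total: float
    lr: float = 0.0
    epoch: int = 0


# ----------------------------------------------------------------- features
@dataclass
class FeatureSet:
    """All per-entity model inputs, aligned to the corpus id order."""

    drug_ids: list[str]
    se_ids: list[str]
    graph_X: np.ndarray
    graph_A: np.ndarray
    graph_mask: np.ndarray
    drug_text: SemanticTable
    se_text: SemanticTable
    chem: SimilarityMatrix
    disease: SimilarityMatrix
    side_hypo: SimilarityMatrix
    side_word: SimilarityMatrix
    side_drug: SimilarityMatrix | None  # None in cold-start mode
    text_dim: int = 64

    def side_views(self) -> dict[str, np.ndarray]:
        views = {"hypo": self.side_hypo.values, "word": self.side_word.values}
        if self.side_drug is not None:
            views["drug"] = self.side_drug.values
        return views

    def with_side_drug(self, matrix: SimilarityMatrix | None) -> "FeatureSet":
        return replace(self, side_drug=matrix)


def matrix_from_samples(
    samples: list[PairSample], drug_ids: list[str], se_ids: list[str]
) -> FrequencyMatrix:
    """Frequency matrix containing only the positive samples given."""
    values = np.zeros((len(drug_ids), len(se_ids)), dtype=int)
    ridx = {d: i for i, d in enumerate(drug_ids)}
    cidx = {s: j for j, s in enumerate(se_ids)}
    for p in samples:
        if p.k_hat == 1:
            values[ridx[p.drug_id], cidx[p.se_id]] = p.y_hat
    return FrequencyMatrix(values, list(drug_ids), list(se_ids))


def prepare_features(
    corpus: FrequencyCorpus,
    drug_chem: SimilarityMatrix,
    drug_disease_assoc: np.ndarray,
    provider: TextEmbeddingProvider,
    train_matrix: FrequencyMatrix | None = None,
    coldstart: bool = False,
    mu: float = 0.5,
    extended_atom_features: bool = False,
) -> FeatureSet:
    """Build every model input from corpus files.

    ``drug_chem`` rows must be ordered like the corpus drugs;
    ``drug_disease_assoc`` is the binary drug-by-disease matrix (same row
    order).  ``train_matrix`` supplies the association profiles for the
    side-drug view and must contain training-fold pairs only; it is ignored
    when ``coldstart`` is set (that view is disabled then).
    """
    drug_ids, se_ids = corpus.drug_ids, corpus.se_ids
    if list(drug_chem.ids) != drug_ids:
        raise ValueError("drug-chem similarity ids do not match corpus drugs")

    graphs = [smiles_to_graph(d.smiles) for d in corpus.drugs]
    vocab = element_vocabulary(graphs)
    for g in graphs:
        featurize(g, vocab, extended=extended_atom_features)
    X, A, mask = pad_graphs(graphs)

    drug_text = embed_corpus_texts(drug_ids, [d.description for d in corpus.drugs], provider)
    se_text = embed_corpus_texts(se_ids, [s.description or s.term for s in corpus.side_effects], provider)

    disease = jaccard_similarity_matrix(drug_disease_assoc, drug_ids, "drug-disease")

    term_map = {s.term: list(s.dotted_ids) for s in corpus.side_effects if s.dotted_ids}
    dag = build_ontology_dag(term_map)
    side_hypo = hyponymy_similarity_matrix(dag, se_ids, [s.term for s in corpus.side_effects], mu)

    wv = np.array(
        [
            s.word_vector if s.word_vector is not None else np.zeros(1)
            for s in corpus.side_effects
        ],
        dtype=object,
    )
    dims = {v.size for v in wv}
    if len(dims) > 1:  # pad missing vectors to the common dimension
        f = max(dims)
        wv = np.array([np.resize(v, f) if v.size != f else v for v in wv])
    wv = np.vstack(wv).astype(float)
    side_word = cosine_similarity_matrix(wv, se_ids, "side-word")

    side_drug = None
    if not coldstart and train_matrix is not None:
        side_drug = side_drug_profile_matrix(train_matrix)

    return FeatureSet(
        drug_ids=drug_ids,
        se_ids=se_ids,
        graph_X=X,
        graph_A=A,
        graph_mask=mask,
        drug_text=drug_text,
        se_text=se_text,
        chem=drug_chem,
        disease=disease,
        side_hypo=side_hypo,
        side_word=side_word,
        side_drug=side_drug,
        text_dim=provider.output_dim,
    )


# -------------------------------------------------------------------- model
class JointModel:
    """All trainable parameters plus the forward pass over pair batches."""

    def __init__(self, features: FeatureSet, config: TrainingConfig, rng: np.random.Generator):
        self.features = features
        self.config = config
        dim = config.dim
        in_dim = features.graph_X.shape[2]
        n_drug, n_se = len(features.drug_ids), len(features.se_ids)

        self.gat = GATParams.init(
            rng,
            in_dim,
            GATConfig(hidden_dim=max(dim // config.gat_heads, 4), heads=config.gat_heads,
                      layers=config.gat_layers, out_dim=dim),
        )
        f = features.text_dim
        self.drug_text_W = parameter(glorot(rng, f, dim))
        self.drug_text_b = parameter(np.zeros(dim))
        self.se_text_W = parameter(glorot(rng, f, dim))
        self.se_text_b = parameter(np.zeros(dim))
        self.drug_attr = DrugProjectionParams.init(rng, 2 * n_drug, dim)
        self.view_proj = {
            name: (parameter(glorot(rng, n_se, dim)), parameter(np.zeros(dim)))
            for name in sorted(features.side_views())
        }
        self.view_attn = ViewAttentionParams.init(rng, dim)
        self.fusion = FusionParams.init(rng, dim, out_dim=config.fusion_out, reading=config.fusion_reading)
        self.heads = HeadParams.init(rng, 2 * config.fusion_out, hidden=config.head_hidden)

        self._drug_index = {d: i for i, d in enumerate(features.drug_ids)}
        self._se_index = {s: j for j, s in enumerate(features.se_ids)}

    def parameters(self) -> dict[str, Tensor]:
        out = self.gat.named("gat")
        out.update(
            {
                "text.drug_W": self.drug_text_W,
                "text.drug_b": self.drug_text_b,
                "text.se_W": self.se_text_W,
                "text.se_b": self.se_text_b,
                "attr.drug_W": self.drug_attr.W,
                "attr.drug_b": self.drug_attr.b,
                "attn.W": self.view_attn.W,
                "attn.b": self.view_attn.b,
            }
        )
        for name, (W, b) in self.view_proj.items():
            out[f"view.{name}_W"] = W
            out[f"view.{name}_b"] = b
        out.update(self.fusion.named("fusion"))
        out.update(self.heads.named("heads"))
        return out

    # -- entity encoders (all entities at once) --
    def drug_representations(self) -> tuple[Tensor, Tensor, Tensor]:
        feats = self.features
        t = as_tensor(feats.drug_text.vectors) @ self.drug_text_W + self.drug_text_b
        v = encode_molecules(feats.graph_X, feats.graph_A, feats.graph_mask, self.gat)
        o = project_drug_attributes(feats.chem.values, feats.disease.values, self.drug_attr)
        return t, v, o

    def side_representations(self) -> tuple[Tensor, Tensor]:
        feats = self.features
        t = as_tensor(feats.se_text.vectors) @ self.se_text_W + self.se_text_b
        views = {}
        for name, sim in feats.side_views().items():
            W, b = self.view_proj[name]
            views[name] = as_tensor(sim) @ W + b
        o = attention_combine_views(views, self.view_attn)
        return t, o

    def forward(
        self,
        drug_idx: np.ndarray,
        se_idx: np.ndarray,
        dropout_rng: np.random.Generator | None = None,
    ) -> PairPrediction:
        dt, dv, do = self.drug_representations()
        st, so = self.side_representations()
        bundle = RepresentationBundle(
            drug_t=dt.gather(drug_idx),
            drug_v=dv.gather(drug_idx),
            drug_o=do.gather(drug_idx),
            side_t=st.gather(se_idx),
            side_o=so.gather(se_idx),
        )
        c1 = coarse_fuse(bundle, self.fusion)
        c2 = fine_fuse(bundle, self.fusion)
        drop = None
        if dropout_rng is not None and self.config.dropout > 0:
            shape = (len(drug_idx), self.config.head_hidden)
            drop = (
                dropout_mask(dropout_rng, shape, self.config.dropout),
                dropout_mask(dropout_rng, shape, self.config.dropout),
            )
        return predict_pair(c1, c2, self.heads, dropout=drop)

    def forward_pairs(self, pairs: list[tuple[str, str]]) -> PairPrediction:
        di = np.array([self._drug_index[d] for d, _ in pairs])
        si = np.array([self._se_index[s] for _, s in pairs])
        return self.forward(di, si)


# --------------------------------------------------------------------- loss
def joint_loss(
    pred: PairPrediction,
    k_hat: np.ndarray,
    y_hat: np.ndarray,
    pos_mask: np.ndarray,
    params: dict[str, Tensor],
    gamma: float,
) -> tuple[Tensor, LossBreakdown]:
    """Multiplicative joint objective.

    ``y_hat`` holds frequency labels at positions where ``pos_mask`` is
    True; L2 averages over those positions only.  A batch without positives
    falls back to total = L1 + gamma R (L2 is undefined there; multiplying
    by a placeholder would distort the gradient scale).
    """
    l1 = ((pred.AS - as_tensor(k_hat)) ** 2).mean()
    r = as_tensor(0.0)
    for p in params.values():
        r = r + (p**2).sum()
    pos_idx = np.nonzero(pos_mask)[0]
    if pos_idx.size > 0:
        fs_pos = pred.FS.gather(pos_idx)
        l2 = ((fs_pos - as_tensor(y_hat[pos_idx])) ** 2).mean()
        total = l1 * l2 + gamma * r
        l2_val = float(l2.data)
    else:
        total = l1 + gamma * r
        l2_val = 0.0
    return total, LossBreakdown(L1=float(l1.data), L2=l2_val, R=float(r.data), total=float(total.data))


# ----------------------------------------------------------------- training
def _stratified_batches(
    samples: list[PairSample], batch_size: int, rng: np.random.Generator
) -> list[list[int]]:
    """Shuffle positives and negatives separately and deal them out so every
    batch holds at least one positive whenever arithmetic allows it."""
    pos = [i for i, s in enumerate(samples) if s.k_hat == 1]
    neg = [i for i, s in enumerate(samples) if s.k_hat == 0]
    rng.shuffle(pos)
    rng.shuffle(neg)
    n_batches = max(1, int(np.ceil(len(samples) / batch_size)))
    batches: list[list[int]] = [[] for _ in range(n_batches)]
    for k, i in enumerate(pos):
        batches[k % n_batches].append(i)
    # fill remaining capacity with negatives
    cap = [batch_size - len(b) for b in batches]
    cursor = 0
    for b, c in zip(batches, cap):
        b.extend(neg[cursor : cursor + max(c, 0)])
        cursor += max(c, 0)
    # any leftover negatives (rounding) go to the last batch
    if cursor < len(neg):
        batches[-1].extend(neg[cursor:])
    return [b for b in batches if b]


@dataclass
class TrainedModel:
    model: JointModel
    history: list[LossBreakdown]  # per-epoch means
    config: TrainingConfig
    batch_log: list[LossBreakdown] = field(default_factory=list)  # per-batch; identity holds here
    snapshots: list[dict] = field(default_factory=list)  # best validation checkpoints

    def predict_ensemble(self, pairs: list[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
        """Average the predictions of the stored validation checkpoints
        (falls back to the current parameters when none are stored)."""
        if not self.snapshots:
            return self.predict(pairs)
        params = self.model.parameters()
        backup = {k: p.data for k, p in params.items()}
        as_sum = fs_sum = None
        for snap in self.snapshots:
            for k, p in params.items():
                p.data = snap[k]
            pred = self.model.forward_pairs(pairs)
            a, f = pred.AS.data.copy(), np.clip(pred.FS.data, 1.0, 5.0)
            as_sum = a if as_sum is None else as_sum + a
            fs_sum = f if fs_sum is None else fs_sum + f
        for k, p in params.items():
            p.data = backup[k]
        n = len(self.snapshots)
        return as_sum / n, fs_sum / n

    def predict(self, pairs: list[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
        """Association and frequency scores for (drug_id, se_id) pairs;
        frequency is clamped to the valid class range [1, 5] for reporting."""
        pred = self.model.forward_pairs(pairs)
        return pred.AS.data.copy(), np.clip(pred.FS.data, 1.0, 5.0)

    def predict_raw(self, pairs: list[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray]:
        pred = self.model.forward_pairs(pairs)
        return pred.AS.data.copy(), pred.FS.data.copy()


def train_model(
    features: FeatureSet,
    samples: list[PairSample],
    config: TrainingConfig,
    on_epoch=None,
) -> TrainedModel:
    """Train the joint model on pair samples; deterministic per config.seed.

    ``on_epoch(model, epoch)`` is called after each epoch when given
    (monitoring only; it must not mutate the model).
    """
    rng = np.random.default_rng(config.seed)
    model = JointModel(features, config, rng)
    params = model.parameters()
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay)

    drug_idx = np.array([model._drug_index[s.drug_id] for s in samples])
    se_idx = np.array([model._se_index[s.se_id] for s in samples])
    k_hat = np.array([float(s.k_hat) for s in samples])
    if config.label_smoothing > 0:
        eps = config.label_smoothing
        k_hat = k_hat * (1 - 2 * eps) + eps
    y_hat = np.array([float(s.y_hat) if s.y_hat is not None else 0.0 for s in samples])
    pos_mask_all = np.array([s.k_hat == 1 for s in samples])

    history: list[LossBreakdown] = []
    batch_log: list[LossBreakdown] = []
    for epoch in range(1, config.max_epochs + 1):
        opt.lr = learning_rate_at(epoch, config)
        sums = np.zeros(4)
        batches = _stratified_batches(samples, config.batch_size, rng)
        for batch in batches:
            idx = np.asarray(batch)
            pred = model.forward(drug_idx[idx], se_idx[idx], dropout_rng=rng)
            total, breakdown = joint_loss(
                pred, k_hat[idx], y_hat[idx], pos_mask_all[idx], params, config.gamma
            )
            if not np.isfinite(breakdown.total):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch}: L1={breakdown.L1}, L2={breakdown.L2}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            breakdown.lr, breakdown.epoch = opt.lr, epoch
            batch_log.append(breakdown)
            sums += (breakdown.L1, breakdown.L2, breakdown.R, breakdown.total)
        n = len(batches)
        history.append(
            LossBreakdown(
                L1=sums[0] / n, L2=sums[1] / n, R=sums[2] / n, total=sums[3] / n,
                lr=opt.lr, epoch=epoch,
            )
        )
        if on_epoch is not None:
            on_epoch(model, epoch)
    return TrainedModel(model, history, config, batch_log)


def train_with_validation(
    features: FeatureSet,
    train_samples: list[PairSample],
    val_samples: list[PairSample],
    config: TrainingConfig,
    eval_every: int = 5,
    keep_best: int = 3,
) -> TrainedModel:
    """Train with epoch selection on a held-out validation set.

    Every ``eval_every`` epochs the validation frequency RMSE (clamped
    predictions, positives only) is measured.  Under the multiplicative
    objective the frequency error fluctuates once the association task
    saturates, so the epoch count behaves like a hyperparameter: the
    parameters of the best epoch are restored at the end, and the
    ``keep_best`` best checkpoints are stored on the returned model so
    :meth:`TrainedModel.predict_ensemble` can average their predictions (a
    snapshot ensemble over one run, which damps the late-training
    fluctuations).
    """
    val_pairs = [(s.drug_id, s.se_id) for s in val_samples]
    pos = np.array([s.k_hat == 1 for s in val_samples])
    if not pos.any():
        raise ValueError("validation set needs at least one positive pair")
    truth = np.array([s.y_hat for s, p in zip(val_samples, pos) if p], dtype=float)
    ranked: list[tuple[float, int, dict]] = []

    def hook(model: JointModel, epoch: int) -> None:
        if epoch % eval_every:
            return
        pred = model.forward_pairs(val_pairs)
        fs = np.clip(pred.FS.data, 1.0, 5.0)
        rmse = float(np.sqrt(np.mean((fs[pos] - truth) ** 2)))
        if len(ranked) < keep_best or rmse < ranked[-1][0]:
            ranked.append((rmse, epoch, {k: p.data.copy() for k, p in model.parameters().items()}))
            ranked.sort(key=lambda t: t[0])
            del ranked[keep_best:]

    trained = train_model(features, train_samples, config, on_epoch=hook)
    if ranked:
        for k, p in trained.model.parameters().items():
            p.data = ranked[0][2][k]
        trained.snapshots = [snap for _, _, snap in ranked]
        trained.best_epoch = ranked[0][1]
        trained.best_val_rmse = ranked[0][0]
    return trained


# ------------------------------------------------------------- persistence
def save_params(trained: TrainedModel, path) -> None:
    """Save all parameter arrays (npz) for later prediction/resumption."""
    np.savez(path, **{k: p.data for k, p in trained.model.parameters().items()})


def load_params(model: JointModel, path) -> None:
    """Load parameter arrays saved by :func:`save_params` into a model built
    with the same configuration and feature shapes."""
    stored = np.load(path)
    for k, p in model.parameters().items():
        if k not in stored:
            raise KeyError(f"parameter {k!r} missing from checkpoint")
        if stored[k].shape != p.data.shape:
            raise ValueError(f"parameter {k!r} shape {stored[k].shape} != {p.data.shape}")
        p.data = stored[k].astype(get_dtype())


# -------------------------------------------------------------- grid search
@dataclass
class GridSearchResult:
    best_dropout: float
    best_gamma: float
    evaluated: list[tuple[float, float]] = field(default_factory=list)
    scores: dict[tuple[float, float], float] = field(default_factory=dict)


def inner_grid_search(
    features: FeatureSet,
    samples: list[PairSample],
    config: TrainingConfig,
    dropout_grid: tuple[float, ...] = DEFAULT_DROPOUT_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    n_folds: int = 5,
) -> GridSearchResult:
    """Pick (dropout, gamma) by inner cross-validated frequency RMSE.

    Every grid point is trained on each inner fold; the side-drug view is
    rebuilt from that fold's training positives so validation pairs never
    leak into it.  Ties break toward lower gamma, then lower dropout.
    """
    if not dropout_grid or not gamma_grid:
        raise ValueError("grid must be nonempty")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(samples))
    folds = np.array_split(order, n_folds)
    result = GridSearchResult(best_dropout=dropout_grid[0], best_gamma=gamma_grid[0])
    for dropout in dropout_grid:
        for gamma in gamma_grid:
            result.evaluated.append((dropout, gamma))
            errors = []
            for f in range(n_folds):
                val_idx = set(folds[f].tolist())
                train = [samples[i] for i in range(len(samples)) if i not in val_idx]
                val_pos = [samples[i] for i in val_idx if samples[i].k_hat == 1]
                if not val_pos:
                    continue
                fold_feats = features
                if features.side_drug is not None:
                    fold_matrix = matrix_from_samples(train, features.drug_ids, features.se_ids)
                    fold_feats = features.with_side_drug(side_drug_profile_matrix(fold_matrix))
                cfg = replace(config, dropout=dropout, gamma=gamma)
                trained = train_model(fold_feats, train, cfg)
                _, fs = trained.predict([(p.drug_id, p.se_id) for p in val_pos])
                truth = np.array([p.y_hat for p in val_pos], dtype=float)
                errors.append(float(np.sqrt(np.mean((fs - truth) ** 2))))
            result.scores[(dropout, gamma)] = float(np.mean(errors)) if errors else np.inf
    best = min(result.scores, key=lambda k: (result.scores[k], k[1], k[0]))
    result.best_dropout, result.best_gamma = best
    return result
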