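"""Metrics, cross-validation planners, and comparison utilities.

Association quality is measured by AUROC (Mann-Whitney concordance with 0.5
credit for ties) and AUPR (step-wise average precision); frequency quality
by RMSE and MAE over positive pairs only, since a frequency class is
undefined for non-associated pairs.

Two split protocols are provided: pairwise nested 5-fold cross-validation
(positives and sampled negatives pooled, shuffled, split; each outer
training set re-split 5-fold for hyperparameter selection), and a drug-wise
cold-start protocol (a held-out fraction of drugs for final testing, the
rest partitioned into drug folds; the association-derived side-effect view
is disabled in this mode because a new drug has no known associations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve

from .corpus import FrequencyCorpus, FrequencyMatrix, PairSample

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "rmse_mae",
    "ranking_metrics",
    "make_split_plan",
    "per_drug_metrics",
    "topk_accuracy",
    "write_curve_points",
    "wilcoxon_rank_sum",
]


def rmse_mae(pred, truth) -> tuple[float, float]:
    """Root-mean-square and mean absolute error of frequency predictions."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("pred and truth must be nonempty and aligned")
    resid = pred - truth
    return float(np.sqrt(np.mean(resid**2))), float(np.mean(np.abs(resid)))


def ranking_metrics(scores, labels) -> tuple[float, float]:
    """(AUROC, AUPR) of association scores against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present for ranking metrics")
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


# ------------------------------------------------------------------- splits
@dataclass
class SplitPlan:
    """Fold assignments for either protocol.

    pairwise mode: ``outer_folds[k]`` are sample indices of outer fold k and
    ``inner_folds[k][j]`` re-splits outer-train k into 5 inner folds.
    cold-start mode: ``test_drugs`` are held out entirely; ``drug_folds``
    partition the remaining drugs; ``side_drug_enabled`` is False.
    """

    mode: str
    seed: int
    outer_folds: list[np.ndarray] = field(default_factory=list)
    inner_folds: list[list[np.ndarray]] = field(default_factory=list)
    test_drugs: list[str] = field(default_factory=list)
    drug_folds: list[list[str]] = field(default_factory=list)
    side_drug_enabled: bool = True


def make_split_plan(
    n_samples_or_corpus,
    mode: str,
    seed: int,
    n_outer: int = 5,
    n_inner: int = 5,
    n_drug_folds: int = 10,
    test_fraction: float = 0.1,
) -> SplitPlan:
    """Build a seeded split plan.

    ``pairwise-nested-5fold`` takes the pooled sample count (or a corpus,
    whose positives are counted); ``drugwise-coldstart`` takes the corpus
    and partitions drugs so no test drug contributes any training pair.
    """
    rng = np.random.default_rng(seed)
    if mode == "pairwise-nested-5fold":
        n = (
            n_samples_or_corpus
            if isinstance(n_samples_or_corpus, (int, np.integer))
            else len(n_samples_or_corpus.triplets) * 2
        )
        order = rng.permutation(n)
        outer = [f.copy() for f in np.array_split(order, n_outer)]
        inner: list[list[np.ndarray]] = []
        for k in range(n_outer):
            train = np.concatenate([outer[j] for j in range(n_outer) if j != k])
            train = rng.permutation(train)
            inner.append([f.copy() for f in np.array_split(train, n_inner)])
        return SplitPlan(mode=mode, seed=seed, outer_folds=outer, inner_folds=inner)
    if mode == "drugwise-coldstart":
        corpus: FrequencyCorpus = n_samples_or_corpus
        drugs = list(corpus.drug_ids)
        order = rng.permutation(len(drugs))
        n_test = max(1, int(round(test_fraction * len(drugs))))
        test = [drugs[i] for i in order[:n_test]]
        cv = [drugs[i] for i in order[n_test:]]
        if len(cv) < 2:
            raise ValueError("too few drugs for a drug-wise cold-start split")
        k = min(n_drug_folds, len(cv))
        folds = [list(f) for f in np.array_split(np.array(cv, dtype=object), k)]
        return SplitPlan(
            mode=mode, seed=seed, test_drugs=test,
            drug_folds=[[str(d) for d in f] for f in folds],
            side_drug_enabled=False,
        )
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------- reporting
@dataclass
class MetricsReport:
    AUROC: float
    AUPR: float
    RMSE: float
    MAE: float
    per_drug: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "AUROC": self.AUROC,
            "AUPR": self.AUPR,
            "RMSE": self.RMSE,
            "MAE": self.MAE,
            "per_drug": self.per_drug,
        }


def evaluate_predictions(
    samples: list[PairSample],
    assoc_scores: np.ndarray,
    freq_scores: np.ndarray,
) -> MetricsReport:
    """Full report on a held-out sample set: ranking metrics on all samples,
    error metrics on positives only."""
    labels = np.array([s.k_hat for s in samples])
    auroc, aupr = ranking_metrics(assoc_scores, labels)
    pos = labels == 1
    truth = np.array([s.y_hat for s, p in zip(samples, pos) if p], dtype=float)
    rmse, mae = rmse_mae(np.asarray(freq_scores)[pos], truth)
    report = MetricsReport(auroc, aupr, rmse, mae)
    report.per_drug = per_drug_metrics(samples, assoc_scores, freq_scores)
    return report


def per_drug_metrics(
    samples: list[PairSample],
    assoc_scores: np.ndarray,
    freq_scores: np.ndarray,
) -> dict[str, dict[str, float]]:
    """Metrics restricted to each drug's pairs.  AUROC/AUPR appear only for
    drugs whose pairs include both classes; RMSE/MAE only for drugs with at
    least one positive."""
    assoc_scores = np.asarray(assoc_scores)
    freq_scores = np.asarray(freq_scores)
    by_drug: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_drug.setdefault(s.drug_id, []).append(i)
    table: dict[str, dict[str, float]] = {}
    for drug, idx in by_drug.items():
        idx = np.asarray(idx)
        entry: dict[str, float] = {}
        labels = np.array([samples[i].k_hat for i in idx])
        if labels.min() != labels.max():
            auroc, aupr = ranking_metrics(assoc_scores[idx], labels)
            entry["AUROC"], entry["AUPR"] = auroc, aupr
        pos = idx[labels == 1]
        if pos.size:
            truth = np.array([samples[i].y_hat for i in pos], dtype=float)
            entry["RMSE"], entry["MAE"] = rmse_mae(freq_scores[pos], truth)
        table[drug] = entry
    return table


def topk_accuracy(
    pairs: list[tuple[str, str]],
    scores: np.ndarray,
    truth_matrix: FrequencyMatrix,
    k: int,
) -> float:
    """Fraction of the k highest-scored pairs that are true associations.

    Ties in score are broken by stable (drug_id, se_id) order so the result
    does not depend on input ordering.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError(f"k={k} exceeds the {scores.size} scored pairs")
    order = sorted(range(len(pairs)), key=lambda i: (-scores[i], pairs[i]))
    hits = 0
    for i in order[:k]:
        d, s = pairs[i]
        if truth_matrix.values[truth_matrix.row_index[d], truth_matrix.col_index[s]] > 0:
            hits += 1
    return hits / k


def write_curve_points(path_roc, path_pr, scores, labels) -> None:
    """Write ROC (fpr, tpr, threshold) and precision-recall (recall,
    precision, threshold) curve points as CSV."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    with open(path_roc, "w") as fh:
        fh.write("fpr,tpr,threshold\n")
        for f, t, th in zip(fpr, tpr, roc_thr):
            fh.write(f"{f:.6g},{t:.6g},{th:.6g}\n")
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    with open(path_pr, "w") as fh:
        fh.write("recall,precision,threshold\n")
        for r, p, th in zip(recall, precision, np.append(pr_thr, np.nan)):
            fh.write(f"{r:.6g},{p:.6g},{th:.6g}\n")


def wilcoxon_rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic W of the first sample and the two-sided
    p-value: exact for small tie-free samples, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank-sum W
    return w, float(res.pvalue)
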