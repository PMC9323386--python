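"""End-to-end study protocol: split, MSC, OLDA, chained clustering, scoring.

The protocol mirrors a storage-day classification study: a stratified 2:1
train/test split; MSC fitted on the training spectra only (the reference is
reused to correct the test spectra, so there is no leakage); OLDA fitted on
the corrected training spectra and used to project the test spectra to
k - 1 = 5 scores; fuzzy clustering of the test scores with chained
initialization (FCM starts from the first sample of each class in class
order, runs to convergence, and its centers seed KHM and GK); finally
clusters are matched to classes and the report carries, per algorithm, the
iteration count, the misclassification number and the accuracy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import confusion_matrix

from .synthetic import SpectraSet
from .msc import fit_msc_reference, apply_msc
from .olda import fit_olda, project
from .fuzzy import (ClusterParams, FuzzyPartition, fcm_fit, khm_fit, gk_fit,
                    assign_labels)

__all__ = ["PipelineConfig", "AlgorithmResult", "EvalReport",
           "split_train_test", "initial_centers_by_class",
           "chain_initialize", "match_clusters_to_classes", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    split_ratio: tuple[int, int] = (2, 1)
    split_seed: int = 0
    preprocessing: str = "msc"            # "msc" or "none"
    msc_reference_scope: str = "train"    # "train" or "all"
    n_components: int = 5
    algorithms: tuple[str, ...] = ("fcm", "khm", "gk")
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    matching: str = "fixed-order"         # or "optimal"
    cluster_scope: str = "test"           # or "all": cluster train+test jointly

    def __post_init__(self) -> None:
        if self.preprocessing not in ("msc", "none"):
            raise ValueError("preprocessing must be 'msc' or 'none'")
        if self.matching not in ("fixed-order", "optimal"):
            raise ValueError("matching must be 'fixed-order' or 'optimal'")
        if self.cluster_scope not in ("test", "all"):
            raise ValueError("cluster_scope must be 'test' or 'all'")
        if self.msc_reference_scope not in ("train", "all"):
            raise ValueError("msc_reference_scope must be 'train' or 'all'")
        a, b = self.split_ratio
        if a < 1 or b < 1:
            raise ValueError("both split ratio parts must be >= 1")


@dataclass
class AlgorithmResult:
    algorithm: str
    n_iter: int
    converged: bool
    misclassification_count: int
    accuracy: float                      # percent
    confusion: np.ndarray                # [k, k], rows true, cols predicted
    cluster_to_class: dict[int, int]
    partition: FuzzyPartition


@dataclass
class EvalReport:
    results: dict[str, AlgorithmResult]
    n_evaluated: int
    classes: np.ndarray
    config_hash: str

    def to_table(self) -> pd.DataFrame:
        """Human-readable summary (Methods / Iterations / Misclassified / Accuracy)."""
        rows = [{"Methods": r.algorithm.upper(),
                 "Number of Iterations": r.n_iter,
                 "Misclassification Number": r.misclassification_count,
                 "Accuracy": f"{r.accuracy:.2f}%"}
                for r in self.results.values()]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "n_evaluated": self.n_evaluated,
            "algorithms": {
                name: {
                    "n_iter": r.n_iter,
                    "converged": r.converged,
                    "misclassification_count": r.misclassification_count,
                    "accuracy_percent": r.accuracy,
                    "confusion": r.confusion.tolist(),
                    "cluster_to_class": r.cluster_to_class,
                } for name, r in self.results.items()
            },
        }


def split_train_test(dataset: SpectraSet, ratio: tuple[int, int] = (2, 1),
                     seed: int = 0) -> tuple[SpectraSet, SpectraSet]:
    """Stratified random split at ``ratio`` (train : test), seeded.

    Per class, round(n_c * train_share) samples go to training; every class
    must keep at least one sample on each side.  With 67 samples per class
    at 2:1 this yields the canonical 45 / 22.
    """
    if dataset.labels is None:
        raise ValueError("split requires labels")
    a, b = ratio
    share = a / (a + b)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == c)
        n_train = int(round(idx.size * share))
        if n_train < 1 or idx.size - n_train < 1:
            raise ValueError(
                f"ratio {a}:{b} infeasible for class {c} with {idx.size} samples")
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def initial_centers_by_class(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """First sample of each class, in class order — the FCM seeding rule."""
    classes = np.unique(labels)
    first = [np.flatnonzero(labels == c)[0] for c in classes]
    return scores[first].copy()


def chain_initialize(scores: np.ndarray, labels: np.ndarray,
                     params: ClusterParams
                     ) -> tuple[dict[str, np.ndarray], FuzzyPartition]:
    """Chained initialization protocol.

    FCM starts from one seed sample per class (class order) and runs to
    convergence; its converged centers become the initial centers of KHM
    and GK.  Returns the per-algorithm initial centers and the FCM run.
    """
    classes = np.unique(labels)
    if classes.size != params.n_clusters:
        raise ValueError(
            f"{classes.size} classes present but {params.n_clusters} clusters "
            "requested")
    v0 = initial_centers_by_class(scores, labels)
    fcm_part = fcm_fit(scores, v0, params)
    inits = {"fcm": v0, "khm": fcm_part.V.copy(), "gk": fcm_part.V.copy()}
    return inits, fcm_part


def match_clusters_to_classes(pred_clusters: np.ndarray,
                              true_labels: np.ndarray,
                              mode: str = "fixed-order"
                              ) -> tuple[dict[int, int], int]:
    """Map cluster indices to class labels and count misclassifications.

    ``fixed-order`` maps cluster i to the i-th class (valid when clusters
    were seeded one-per-class in class order); ``optimal`` solves the
    minimum-misclassification one-to-one assignment (Hungarian method).
    """
    pred_clusters = np.asarray(pred_clusters)
    true_labels = np.asarray(true_labels)
    if pred_clusters.shape != true_labels.shape:
        raise ValueError("prediction and truth lengths differ")
    classes = np.unique(true_labels)
    k = classes.size
    # counts[c, j]: samples of class index c placed in cluster j
    counts = np.zeros((k, k), dtype=int)
    for ci, c in enumerate(classes):
        in_c = pred_clusters[true_labels == c]
        for j in range(k):
            counts[ci, j] = int(np.sum(in_c == j))
    if mode == "fixed-order":
        mapping = {j: int(classes[j]) for j in range(k)}
        correct = sum(counts[j, j] for j in range(k))
    elif mode == "optimal":
        row, col = linear_sum_assignment(-counts)   # maximize matched counts
        mapping = {int(j): int(classes[c]) for c, j in zip(row, col)}
        correct = int(counts[row, col].sum())
    else:
        raise ValueError("mode must be 'fixed-order' or 'optimal'")
    return mapping, int(true_labels.size - correct)


_FITTERS = {"fcm": fcm_fit, "khm": khm_fit, "gk": gk_fit}


def run_pipeline(dataset: SpectraSet, config: PipelineConfig) -> EvalReport:
    """Execute the full protocol on a labeled spectra set."""
    train, test = split_train_test(dataset, config.split_ratio,
                                   config.split_seed)
    if config.preprocessing == "msc":
        scope = dataset if config.msc_reference_scope == "all" else train
        ref = fit_msc_reference(scope)
        train, _ = apply_msc(train, ref)
        test, _ = apply_msc(test, ref)

    model = fit_olda(train.absorbance, train.labels, config.n_components)

    if config.cluster_scope == "all":
        eval_X = np.vstack([train.absorbance, test.absorbance])
        eval_labels = np.concatenate([train.labels, test.labels])
    else:
        eval_X, eval_labels = test.absorbance, test.labels
    scores = project(model, eval_X)

    inits, fcm_part = chain_initialize(scores, eval_labels,
                                       config.cluster_params)
    classes = np.unique(eval_labels)
    results: dict[str, AlgorithmResult] = {}
    for algo in config.algorithms:
        if algo == "fcm":
            part = fcm_part
        else:
            part = _FITTERS[algo](scores, inits[algo], config.cluster_params)
        clusters = assign_labels(part.U)
        mapping, miscls = match_clusters_to_classes(clusters, eval_labels,
                                                    config.matching)
        pred_class = np.array([mapping[j] for j in clusters])
        cm = confusion_matrix(eval_labels, pred_class, labels=classes)
        acc = 100.0 * (eval_labels.size - miscls) / eval_labels.size
        results[algo] = AlgorithmResult(
            algorithm=algo, n_iter=part.n_iter, converged=part.converged,
            misclassification_count=miscls, accuracy=acc, confusion=cm,
            cluster_to_class=mapping, partition=part)

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return EvalReport(results=results, n_evaluated=int(eval_labels.size),
                      classes=classes, config_hash=cfg_hash)
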