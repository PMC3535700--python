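"""Two-state linear-chain CRF: inference, training, prediction.

The model assigns a label sequence ``y`` over the bins of a chromosome the
conditional probability

    p(y | x; lambda) = exp( sum_j sum_k lambda_k f_k(y_j, y_{j-1}, j, x) ) / Z(x)

with ``Z(x)`` the partition function over all 2^L label sequences.  Training
maximises the L2-regularised conditional log-likelihood

    sum_chains [ score(y | x) - ln Z(x) ] - ||lambda||^2 / (2 sigma^2)

(one shared penalty, chains = chromosomes) with an analytic gradient
(empirical minus expected feature counts, minus ``lambda_k / sigma^2``) under
bounded-memory quasi-Newton (L-BFGS-B).  The objective is concave, so a zero
initialisation is deterministic and sufficient.

Prediction is by the posterior marginal ``s_j = p(y_j = 1 | x; lambda)``
from forward-backward; a bin is called a binding site when ``s_j`` strictly
exceeds the chosen threshold.

Inference is exact, linear-time and log-space; the inner recursions are
numba-jitted so whole-chromosome chains stay cheap.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from typing import Sequence

import numba
import numpy as np
import scipy.optimize

from .feature_templates import (
    CompiledFeatures,
    FeatureSet,
    compile_features,
)
from .genome_prep import FeatureMatrix, LabelSequence

DEFAULT_SIGMA2 = 10.0

Chain = tuple[FeatureMatrix, LabelSequence]


class TrainingWarning(UserWarning):
    pass


@numba.njit(cache=False)
def _ladd(a: float, b: float) -> float:
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    m = a if a > b else b
    return m + math.log(math.exp(a - m) + math.exp(b - m))


@numba.njit(cache=False)
def _forward_backward(clique):
    """Exact log-space forward-backward over an (L, 2, 2) clique array.

    Bin 0 uses only the u = 0 slice (virtual background label before the
    chain).  Returns log alpha, log beta, log Z (forward), log Z (backward),
    node marginals and edge marginals.
    """
    L = clique.shape[0]
    la = np.empty((L, 2))
    lb = np.empty((L, 2))
    la[0, 0] = clique[0, 0, 0]
    la[0, 1] = clique[0, 0, 1]
    for j in range(1, L):
        for v in range(2):
            la[j, v] = _ladd(
                la[j - 1, 0] + clique[j, 0, v], la[j - 1, 1] + clique[j, 1, v]
            )
    log_z = _ladd(la[L - 1, 0], la[L - 1, 1])
    lb[L - 1, 0] = 0.0
    lb[L - 1, 1] = 0.0
    for j in range(L - 2, -1, -1):
        for u in range(2):
            lb[j, u] = _ladd(
                clique[j + 1, u, 0] + lb[j + 1, 0],
                clique[j + 1, u, 1] + lb[j + 1, 1],
            )
    log_z_back = _ladd(clique[0, 0, 0] + lb[0, 0], clique[0, 0, 1] + lb[0, 1])
    node = np.empty((L, 2))
    for j in range(L):
        for v in range(2):
            node[j, v] = math.exp(la[j, v] + lb[j, v] - log_z)
    edge = np.zeros((L - 1, 2, 2))
    for j in range(L - 1):
        for u in range(2):
            for v in range(2):
                edge[j, u, v] = math.exp(
                    la[j, u] + clique[j + 1, u, v] + lb[j + 1, v] - log_z
                )
    return la, lb, log_z, log_z_back, node, edge


@dataclasses.dataclass
class ChainPosteriors:
    """Forward-backward quantities for one chain."""

    log_alpha: np.ndarray
    log_beta: np.ndarray
    log_Z: float
    log_Z_backward: float
    node_marginals: np.ndarray  # (L, 2)
    edge_marginals: np.ndarray  # (L-1, 2, 2)

    def pair_marginals(self) -> np.ndarray:
        """(L, 2, 2) clique marginals aligned with feature positions.

        Position 0 holds ``I{u = 0} p(y_0 = v)`` (boundary), position j >= 1
        the edge marginal of ``(y_{j-1}, y_j)``.
        """
        L = self.node_marginals.shape[0]
        out = np.zeros((L, 2, 2))
        out[0, 0, :] = self.node_marginals[0]
        if L > 1:
            out[1:] = self.edge_marginals
        return out


@dataclasses.dataclass
class CRFModel:
    """Trained (or assembled) CRF: template set, weights, regularisation."""

    feature_set: FeatureSet
    weights: np.ndarray
    sigma2: float = DEFAULT_SIGMA2
    training_meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (self.feature_set.k,):
            raise ValueError(
                f"expected {self.feature_set.k} weights, got {self.weights.shape}"
            )
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite model weights")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclasses.dataclass
class ScoredBins:
    """Per-bin posterior binding-site probabilities for one chromosome."""

    chrom_name: str
    scores: np.ndarray
    threshold: float | None = None
    calls: np.ndarray | None = None  # 1 where score strictly exceeds threshold

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("marginal scores must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Inference


def _posteriors_from_clique(clique: np.ndarray) -> ChainPosteriors:
    if not np.isfinite(clique).all():
        j = int(np.argwhere(~np.isfinite(clique))[0][0])
        raise FloatingPointError(f"non-finite clique score at bin {j}")
    la, lb, log_z, log_z_back, node, edge = _forward_backward(clique)
    return ChainPosteriors(la, lb, float(log_z), float(log_z_back), node, edge)


def log_partition_and_posteriors(
    X: FeatureMatrix, model: CRFModel
) -> ChainPosteriors:
    """Exact forward-backward posteriors of one chain under ``model``."""
    compiled = compile_features(X, model.feature_set)
    return _posteriors_from_clique(compiled.clique_scores(model.weights))


def sequence_score(X: FeatureMatrix, y: LabelSequence, model: CRFModel) -> float:
    """Unnormalised log-score ``sum_j sum_k lambda_k f_k`` of one labelling."""
    if len(y) != X.n_bins:
        raise ValueError("label sequence length does not match the matrix")
    compiled = compile_features(X, model.feature_set)
    return float(compiled.empirical_counts(y.labels) @ model.weights)


def predict(
    X: FeatureMatrix, model: CRFModel, threshold: float | None = None
) -> ScoredBins:
    """Per-bin marginal probability of the binding-site state."""
    post = log_partition_and_posteriors(X, model)
    scores = np.clip(post.node_marginals[:, 1], 0.0, 1.0)
    calls = (scores > threshold).astype(np.int8) if threshold is not None else None
    return ScoredBins(X.chrom_name, scores, threshold, calls)


def sample_labels(
    X: FeatureMatrix, model: CRFModel, rng: np.random.Generator
) -> LabelSequence:
    """Draw one label sequence from ``p(y | x; lambda)`` (backward-sampling)."""
    compiled = compile_features(X, model.feature_set)
    clique = compiled.clique_scores(model.weights)
    post = _posteriors_from_clique(clique)
    lb = post.log_beta
    L = X.n_bins
    y = np.empty(L, dtype=np.int8)
    u = rng.random(L)
    # p(y_0 = v) from the boundary slice and the backward messages
    logits = clique[0, 0, :] + lb[0]
    p1 = math.exp(logits[1] - np.logaddexp(logits[0], logits[1]))
    y[0] = 1 if u[0] < p1 else 0
    for j in range(1, L):
        logits = clique[j, y[j - 1], :] + lb[j]
        p1 = math.exp(logits[1] - np.logaddexp(logits[0], logits[1]))
        y[j] = 1 if u[j] < p1 else 0
    return LabelSequence(X.chrom_name, y)


# ---------------------------------------------------------------------------
# Objective, gradient, training


def _compile_dataset(
    dataset: Sequence[Chain], feature_set: FeatureSet
) -> list[tuple[CompiledFeatures, np.ndarray, np.ndarray]]:
    if not dataset:
        raise ValueError("empty training dataset")
    out = []
    for X, y in dataset:
        if len(y) != X.n_bins:
            raise ValueError(
                f"chain {X.chrom_name}: labels ({len(y)}) != bins ({X.n_bins})"
            )
        compiled = compile_features(X, feature_set)
        out.append((compiled, compiled.empirical_counts(y.labels), y.labels))
    return out


def _objective_and_gradient(
    compiled_chains, weights: np.ndarray, sigma2: float
) -> tuple[float, np.ndarray]:
    obj = -float(weights @ weights) / (2.0 * sigma2)
    grad = -weights / sigma2
    for compiled, emp, _ in compiled_chains:
        clique = compiled.clique_scores(weights)
        post = _posteriors_from_clique(clique)
        obj += float(emp @ weights) - post.log_Z
        grad += emp - compiled.expected_counts(post.pair_marginals())
    return obj, grad


def regularized_cll(
    dataset: Sequence[Chain],
    feature_set: FeatureSet,
    weights: np.ndarray,
    sigma2: float = DEFAULT_SIGMA2,
) -> float:
    """Regularised conditional log-likelihood of a dataset (penalty once)."""
    weights = np.asarray(weights, dtype=np.float64)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    obj, _ = _objective_and_gradient(
        _compile_dataset(dataset, feature_set), weights, sigma2
    )
    return obj


def cll_gradient(
    dataset: Sequence[Chain],
    feature_set: FeatureSet,
    weights: np.ndarray,
    sigma2: float = DEFAULT_SIGMA2,
) -> np.ndarray:
    """Analytic gradient: empirical minus expected counts minus lambda/sigma^2."""
    weights = np.asarray(weights, dtype=np.float64)
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    _, grad = _objective_and_gradient(
        _compile_dataset(dataset, feature_set), weights, sigma2
    )
    return grad


def train(
    dataset: Sequence[Chain],
    feature_set: FeatureSet,
    sigma2: float = DEFAULT_SIGMA2,
    max_iter: int = 200,
    tol: float = 1e-5,
    init: np.ndarray | None = None,
) -> CRFModel:
    """Fit weights by regularised maximum conditional likelihood (L-BFGS-B).

    Deterministic given ``dataset`` and ``init`` (zeros by default; the
    objective is concave so no restarts are needed).  Emits a
    :class:`TrainingWarning` and returns the best-so-far weights if the
    optimizer hits ``max_iter`` without meeting the gradient tolerance.
    """
    compiled_chains = _compile_dataset(dataset, feature_set)
    all_labels = np.concatenate([labels for _, _, labels in compiled_chains])
    if all_labels.min() == all_labels.max():
        raise ValueError("training data contains a single label class")

    k = feature_set.k
    x0 = np.zeros(k) if init is None else np.asarray(init, dtype=np.float64).copy()
    log: list[float] = []

    def negated(w: np.ndarray) -> tuple[float, np.ndarray]:
        obj, grad = _objective_and_gradient(compiled_chains, w, sigma2)
        return -obj, -grad

    def record(w: np.ndarray) -> None:
        obj, _ = _objective_and_gradient(compiled_chains, w, sigma2)
        log.append(obj)

    res = scipy.optimize.minimize(
        negated,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12, "maxls": 50},
    )
    if not res.success and "ITERATIONS" in str(res.message).upper():
        warnings.warn(
            f"optimizer stopped after {res.nit} iterations without meeting "
            f"tol={tol}; returning best-so-far weights",
            TrainingWarning,
        )
    meta = {
        "converged": bool(res.success),
        "n_iter": int(res.nit),
        "final_objective": -float(res.fun),
        "grad_max_norm": float(np.abs(res.jac).max()),
        "tol": tol,
        "max_iter": max_iter,
        "objective_log": log,
    }
    return CRFModel(feature_set, res.x, sigma2, meta)


# ---------------------------------------------------------------------------
# Model and prediction I/O


def save_model(model: CRFModel, path) -> None:
    doc = {
        "feature_set": model.feature_set.to_config(),
        "weights": model.weights.tolist(),
        "sigma2": model.sigma2,
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_model(path) -> CRFModel:
    with open(path) as fh:
        doc = json.load(fh)
    return CRFModel(
        FeatureSet.from_config(doc["feature_set"]),
        np.asarray(doc["weights"]),
        doc["sigma2"],
        doc.get("training_meta", {}),
    )


def write_predictions(
    scored: ScoredBins, bins, bed_path=None, bedgraph_path=None
) -> None:
    """Write per-bin scores: BED (score = s_j x 1000) and/or bedGraph (raw)."""
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for j, s in enumerate(scored.scores):
                start, end = bins.bin_span(j)
                fh.write(
                    f"{scored.chrom_name}\t{start}\t{end}\tbin_{j}\t"
                    f"{int(round(1000 * s))}\n"
                )
    if bedgraph_path is not None:
        with open(bedgraph_path, "w") as fh:
            for j, s in enumerate(scored.scores):
                start, end = bins.bin_span(j)
                fh.write(f"{scored.chrom_name}\t{start}\t{end}\t{s:.6g}\n")
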