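"""ROC/AUC metrics, chromosome-grouped cross-validation, and binning of
external predictions for like-for-like comparison.

TPR is the fraction of positive bins called, FPR the fraction of negative
bins called; the ROC sweeps the score threshold with tied scores entering
together.  AUC is the trapezoidal area; AUC10% is the area restricted to
FPR <= 0.1 (right endpoint interpolated), so its maximum is 0.1 and a random
ranker expects 0.005.

Cross-validation groups by chromosome: chromosomes are shuffled with a seed
and dealt round-robin into k folds; each fold is scored by a model trained
on the other folds, and both per-fold and pooled ROC results are reported.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np

from . import crf_core
from .crf_core import Chain, CRFModel
from .feature_templates import FeatureSet
from .genome_prep import BinnedChromosome, Interval

SENTINEL = -np.inf


@dataclasses.dataclass
class RocResult:
    """An ROC curve with its full and partial (FPR <= 10%) areas."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # leading +inf for the (0, 0) point
    auc: float
    auc10: float

    def tpr_at_fpr(self, level: float) -> float:
        """Highest TPR attained at FPR <= ``level`` (step convention)."""
        ok = self.fpr <= level
        return float(self.tpr[ok].max()) if ok.any() else 0.0


def _partial_auc_counts(
    tp: np.ndarray, fp: np.ndarray, pos: int, neg: int, fmax=None
) -> float:
    """Trapezoidal area restricted to FPR <= ``fmax`` (default 1/10).

    Computed in integer count space with rational arithmetic so that e.g. a
    perfect classifier yields exactly ``float(fmax)``; the right endpoint is
    interpolated at the cutoff.
    """
    from fractions import Fraction

    fmax = Fraction(1, 10) if fmax is None else Fraction(fmax)
    cut = fmax * neg
    area = Fraction(0)
    pts = [(0, 0)] + list(zip(fp.tolist(), tp.tolist()))
    for (f1, t1), (f2, t2) in zip(pts, pts[1:]):
        if f2 <= cut:
            area += Fraction((f2 - f1) * (t1 + t2), 2)
            continue
        if f1 >= cut:
            break
        t_cut = Fraction(t1) + Fraction(t2 - t1) * (cut - f1) / (f2 - f1)
        area += (cut - f1) * (Fraction(t1) + t_cut) / 2
        break
    return float(area / (pos * neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve over per-bin scores vs 0/1 labels (ties grouped)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pos = int(labels.sum())
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("ROC needs at least one positive and one negative bin")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # last index of each tie group (s is non-increasing)
    group_end = np.flatnonzero(np.append(s[1:] != s[:-1], True))
    tp = np.cumsum(y)[group_end].astype(np.int64)
    fp = np.cumsum(1 - y)[group_end].astype(np.int64)
    fpr = np.concatenate(([0.0], fp / neg))
    tpr = np.concatenate(([0.0], tp / pos))
    thresholds = np.concatenate(([np.inf], s[group_end]))
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr, tpr, thresholds, auc, _partial_auc_counts(tp, fp, pos, neg))


@dataclasses.dataclass
class CvPlan:
    """Partition of chromosome names into k folds."""

    groups: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        names = [c for g in self.groups for c in g]
        if len(names) != len(set(names)):
            raise ValueError("chromosome appears in more than one fold")
        sizes = [len(g) for g in self.groups]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than one")


def make_cv_plan(chroms: Sequence[str], k: int = 10, seed: int = 0) -> CvPlan:
    """Seeded shuffle followed by round-robin assignment into ``k`` folds."""
    chroms = list(chroms)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(chroms):
        raise ValueError(f"cannot make {k} folds from {len(chroms)} chromosomes")
    if k == 1:
        warnings.warn("k = 1 leaves no held-out data", UserWarning)
    rng = np.random.default_rng(seed)
    order = [chroms[i] for i in rng.permutation(len(chroms))]
    groups: list[list[str]] = [[] for _ in range(k)]
    for idx, name in enumerate(order):
        groups[idx % k].append(name)
    return CvPlan(groups, seed)


@dataclasses.dataclass
class CvResult:
    """Per-fold and pooled cross-validation metrics."""

    fold_rocs: list[RocResult]
    fold_chroms: list[list[str]]
    pooled: RocResult
    skipped_folds: list[int]

    @property
    def fold_aucs(self) -> np.ndarray:
        return np.array([r.auc for r in self.fold_rocs])

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.fold_aucs.std(ddof=1)) if len(self.fold_rocs) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "pooled_auc": self.pooled.auc,
            "pooled_auc10": self.pooled.auc10,
            "tpr_at_1pct_fpr": self.pooled.tpr_at_fpr(0.01),
            "fold_aucs": self.fold_aucs.tolist(),
            "n_folds": len(self.fold_rocs),
            "skipped_folds": self.skipped_folds,
        }


def cross_validate(
    dataset: Sequence[Chain],
    feature_set: FeatureSet,
    plan: CvPlan,
    sigma2: float = crf_core.DEFAULT_SIGMA2,
    **train_kwargs,
) -> CvResult:
    """Chromosome-holdout CV: train out-of-fold, score in-fold bins.

    Folds whose held-out bins carry a single class are skipped with a
    warning and recorded in the result.
    """
    by_chrom = {X.chrom_name: (X, y) for X, y in dataset}
    planned = [c for g in plan.groups for c in g]
    missing = set(planned) - set(by_chrom)
    if missing:
        raise ValueError(f"CV plan names chromosomes absent from data: {missing}")

    fold_rocs: list[RocResult] = []
    fold_chroms: list[list[str]] = []
    skipped: list[int] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    for fold_idx, test_chroms in enumerate(plan.groups):
        train_chains = [
            by_chrom[c] for c in by_chrom if c not in set(test_chroms)
        ]
        test_chains = [by_chrom[c] for c in test_chroms]
        test_labels = np.concatenate([y.labels for _, y in test_chains])
        if test_labels.min() == test_labels.max():
            warnings.warn(
                f"fold {fold_idx} held-out bins are single-class; skipped",
                UserWarning,
            )
            skipped.append(fold_idx)
            continue
        model = crf_core.train(
            train_chains, feature_set, sigma2=sigma2, **train_kwargs
        )
        scores = np.concatenate(
            [crf_core.predict(X, model).scores for X, _ in test_chains]
        )
        fold_rocs.append(roc_points(scores, test_labels))
        fold_chroms.append(list(test_chroms))
        pooled_scores.append(scores)
        pooled_labels.append(test_labels)

    if not fold_rocs:
        raise ValueError("no usable folds")
    pooled = roc_points(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return CvResult(fold_rocs, fold_chroms, pooled, skipped)


def bin_external_predictions(
    predictions: Sequence[tuple[Interval, float]], bins: BinnedChromosome
) -> np.ndarray:
    """Assign interval predictions to bins for like-for-like ROC comparison.

    Each prediction goes to the bin containing its interval center; a bin's
    score is the maximum over its predictions, and bins with none carry a
    ``-inf`` sentinel so they rank last (tied).
    """
    out = np.full(bins.n_bins, SENTINEL)
    for iv, score in predictions:
        if iv.chrom != bins.chrom_name:
            raise ValueError(
                f"prediction on {iv.chrom!r} does not match {bins.chrom_name!r}"
            )
        c = iv.center
        if c >= bins.chrom_length:
            raise ValueError(
                f"prediction center {c} beyond end of {bins.chrom_name}"
            )
        j = bins.bin_of(c)
        if score > out[j]:
            out[j] = score
    return out


# ---------------------------------------------------------------------------
# Reporting


def write_roc_table(roc: RocResult, path) -> None:
    """TSV of (threshold, fpr, tpr) per swept threshold."""
    with open(path, "w") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        for thr, f, t in zip(roc.thresholds, roc.fpr, roc.tpr):
            fh.write(f"{thr:.6g}\t{f:.6g}\t{t:.6g}\n")


def write_metrics_json(roc: RocResult, path, extra: dict | None = None) -> None:
    doc = {
        "auc": roc.auc,
        "auc10": roc.auc10,
        "tpr_at_fpr": {
            "0.01": roc.tpr_at_fpr(0.01),
            "0.05": roc.tpr_at_fpr(0.05),
            "0.10": roc.tpr_at_fpr(0.10),
        },
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def plot_roc(rocs: dict[str, RocResult], path) -> None:
    """Optional ROC figure (one curve per named result)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in rocs.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC = {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
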