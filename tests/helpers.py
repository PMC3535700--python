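"""Shared oracle implementations and generators for the test suite.

These deliberately avoid the code paths they check: the enumeration oracle
sums over all label sequences instead of running forward-backward, and the
pairwise AUC oracle is the rank statistic rather than a trapezoid.
"""

import itertools

import numpy as np

import chromcrf as cc
from chromcrf.feature_templates import compile_features


def random_chain(rng, n_bins, n_binary=2, row_names=None):
    """A random small feature matrix + label sequence for oracle tests."""
    if row_names is None:
        row_names = ["PWM"] + [f"M{i}" for i in range(1, n_binary + 1)]
    bins = cc.make_bins({"chrT": n_bins * 10}, 10)[0]
    pwm = rng.normal(size=n_bins)
    binary = {name: rng.integers(0, 2, size=n_bins) for name in row_names[1:]}
    X = cc.assemble_feature_matrix(bins, pwm, binary)
    y = cc.LabelSequence("chrT", rng.integers(0, 2, size=n_bins))
    return X, y


def enumerate_posteriors(X, fs, weights):
    """Brute-force log Z and node marginals by summing over all 2^L label
    sequences of their clique-score totals (independent of forward-backward)."""
    from scipy.special import logsumexp

    clique = compile_features(X, fs).clique_scores(weights)
    L = X.n_bins
    seqs = np.array(list(itertools.product((0, 1), repeat=L)), dtype=np.int64)
    prev = np.hstack([np.zeros((len(seqs), 1), dtype=np.int64), seqs[:, :-1]])
    scores = clique[np.arange(L), prev, seqs].sum(axis=1)
    log_z = logsumexp(scores)
    p = np.exp(scores - log_z)
    node1 = np.array([p[seqs[:, j] == 1].sum() for j in range(L)])
    return log_z, node1


def pairwise_auc(scores, labels):
    """O(P*N) probability that a random positive outranks a random negative
    (ties count one half) — the rank-statistic AUC oracle."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    with np.errstate(invalid="ignore"):
        diff = pos[:, None] - neg[None, :]
    # nan arises from (-inf) - (-inf): both unscored, i.e. tied
    ties = (diff == 0) | np.isnan(diff)
    wins = (diff > 0).sum() + 0.5 * ties.sum()
    return wins / (pos.size * neg.size)
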