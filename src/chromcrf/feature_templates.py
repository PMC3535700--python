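"""Feature functions of the two-state linear-chain CRF.

Five template families map ``(y_prev, y_cur, j, x)`` to a value, where ``x``
is the feature matrix (row 1 = real-valued PWM score, other rows binary) and
``y`` are the 0/1 bin labels:

``PWM_STATE``      ``x[1, j] * I{y_j = u}`` — the only real-valued family.
``OCCURRENCE``     ``I{y_{j-1} = u, y_j = v, x[i, j] = 1}`` — a marker (or
                   promoter membership) is present in the current bin.
``COOCCURRENCE``   additionally requires ``x[i', j] = 1`` — two markers in
                   the same bin (e.g. a bivalent domain).
``ADJ_PAIR``       ``I{y_{j-1} = u, y_j = v, x[i', j-1] = 1, x[i, j] = 1}`` —
                   a marker pattern across adjacent bins.
``ADJ_TRIPLE``     additionally requires ``x[i'', j+1] = 1``.

A sixth family, ``TRANSITION`` (``I{y_{j-1} = u, y_j = v}`` with no
``x``-condition), is an extension toggle (default on): without it the chain
cannot encode baseline binding-site sparsity in bins where every binary
feature is 0.

Boundary convention: a virtual background label precedes bin 0 (``y_{-1}``
matches ``u = 0`` only), and ``x`` references outside ``[0, n_bins)`` read 0.

Row indices are 1-based with row 1 = the PWM row.  Each binary condition may
be negated via a polarity flag (tests ``x = 0`` instead of ``x = 1``),
which realises features such as "not in a promoter region"; the default is
positive polarity everywhere.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np

from .genome_prep import FeatureMatrix

PWM_STATE = "PWM_STATE"
OCCURRENCE = "OCCURRENCE"
COOCCURRENCE = "COOCCURRENCE"
ADJ_PAIR = "ADJ_PAIR"
ADJ_TRIPLE = "ADJ_TRIPLE"
TRANSITION = "TRANSITION"
FAMILIES = (PWM_STATE, OCCURRENCE, COOCCURRENCE, ADJ_PAIR, ADJ_TRIPLE, TRANSITION)

#: Sentinel for the virtual label before the first bin; matches ``u = 0``.
BOUNDARY = "BOUNDARY"

PWM_ROW = 1  # 1-based index of the real-valued PWM row


@dataclasses.dataclass(frozen=True)
class FeatureTemplate:
    """One instantiated feature function ``f_k``.

    ``u`` is the previous-bin label (or, for ``PWM_STATE``, the sole label);
    ``v`` the current-bin label.  ``i`` is the row tested at bin ``j``,
    ``i_prev`` the second co-occurring row (``COOCCURRENCE``) or the row
    tested at bin ``j - 1`` (``ADJ_*``), ``i_next`` the row tested at bin
    ``j + 1`` (``ADJ_TRIPLE``).  ``negate`` lists row polarities in the same
    order ``(i, i_prev, i_next)``.
    """

    family: str
    u: int
    v: int | None = None
    i: int | None = None
    i_prev: int | None = None
    i_next: int | None = None
    negate: tuple[bool, ...] = (False, False, False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.u not in (0, 1):
            raise ValueError("u must be 0 or 1")
        need_v = self.family != PWM_STATE
        if need_v and self.v not in (0, 1):
            raise ValueError(f"{self.family} requires v in {{0, 1}}")
        if self.family == PWM_STATE:
            if self.i != PWM_ROW:
                raise ValueError("PWM_STATE must use the PWM row (i = 1)")
            if self.v is not None or self.i_prev is not None or self.i_next is not None:
                raise ValueError("PWM_STATE takes only the label u and row i = 1")
        elif self.family == TRANSITION:
            if self.i is not None or self.i_prev is not None or self.i_next is not None:
                raise ValueError("TRANSITION has no feature-row condition")
        else:
            if self.i is None or self.i == PWM_ROW:
                raise ValueError(f"{self.family} needs a binary row index i > 1")
            if self.family == OCCURRENCE:
                if self.i_prev is not None or self.i_next is not None:
                    raise ValueError("OCCURRENCE uses a single row")
            elif self.family == COOCCURRENCE:
                if self.i_prev is None or self.i_prev == self.i:
                    raise ValueError("COOCCURRENCE needs a distinct second row")
                if self.i_next is not None:
                    raise ValueError("COOCCURRENCE uses two rows")
            elif self.family == ADJ_PAIR:
                if self.i_prev is None:
                    raise ValueError("ADJ_PAIR needs i_prev (row at bin j-1)")
                if self.i_next is not None:
                    raise ValueError("ADJ_PAIR uses two rows")
            elif self.family == ADJ_TRIPLE:
                if self.i_prev is None or self.i_next is None:
                    raise ValueError("ADJ_TRIPLE needs i_prev and i_next")
        for row in (self.i, self.i_prev, self.i_next):
            if row is not None and row != PWM_ROW and row < 2:
                raise ValueError("binary row indices start at 2")

    def to_dict(self) -> dict:
        d = {"family": self.family, "u": self.u}
        for key in ("v", "i", "i_prev", "i_next"):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        if any(self.negate):
            d["negate"] = list(self.negate)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureTemplate":
        return cls(
            d["family"],
            d["u"],
            d.get("v"),
            d.get("i"),
            d.get("i_prev"),
            d.get("i_next"),
            tuple(d.get("negate", (False, False, False))),
        )


@dataclasses.dataclass
class FeatureSet:
    """Ordered collection of templates; index k pairs with weight lambda_k."""

    templates: list[FeatureTemplate]
    row_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.templates = list(self.templates)
        self.row_names = tuple(self.row_names)
        if len(set(self.templates)) != len(self.templates):
            raise ValueError("duplicate feature templates")
        n_rows = len(self.row_names)
        for t in self.templates:
            for row in (t.i, t.i_prev, t.i_next):
                if row is not None and row > n_rows:
                    raise ValueError(
                        f"template references row {row} but registry has "
                        f"{n_rows} rows"
                    )

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def k(self) -> int:
        return len(self.templates)

    def to_config(self) -> dict:
        return {
            "row_names": list(self.row_names),
            "templates": [t.to_dict() for t in self.templates],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "FeatureSet":
        return cls(
            [FeatureTemplate.from_dict(d) for d in cfg["templates"]],
            tuple(cfg["row_names"]),
        )


def build_default_feature_set(
    row_names: Sequence[str],
    marker_pairs: str | Iterable[tuple[int, int]] = "all",
    include_transitions: bool = True,
) -> FeatureSet:
    """Instantiate the full default template set over a row registry.

    ``row_names[0]`` must be the PWM row.  ``marker_pairs`` gives the
    unordered binary-row pairs (1-based indices) used for co-occurrence and
    adjacent-pair features, or ``"all"`` for every pair.  Adjacent pairs use
    both orders of each requested pair plus the diagonal ``(r, r)`` of every
    binary row; adjacent triples default to ``(r, r, r)`` per binary row.
    """
    n_rows = len(row_names)
    binary = list(range(2, n_rows + 1))
    if marker_pairs == "all":
        pairs = list(itertools.combinations(binary, 2))
    else:
        pairs = [tuple(sorted(p)) for p in marker_pairs]
        for a, b in pairs:
            if a == b:
                raise ValueError(f"co-occurrence pair ({a}, {b}) is degenerate")
            if PWM_ROW in (a, b):
                raise ValueError("indicator families cannot reference the PWM row")
            if not (2 <= a <= n_rows and 2 <= b <= n_rows):
                raise ValueError(f"pair ({a}, {b}) outside the row registry")
    labels = (0, 1)
    uv = list(itertools.product(labels, labels))

    templates: list[FeatureTemplate] = []
    for u in labels:
        templates.append(FeatureTemplate(PWM_STATE, u, i=PWM_ROW))
    for i in binary:
        for u, v in uv:
            templates.append(FeatureTemplate(OCCURRENCE, u, v, i=i))
    for a, b in pairs:
        for u, v in uv:
            templates.append(FeatureTemplate(COOCCURRENCE, u, v, i=b, i_prev=a))
    ordered = [(r, r) for r in binary]
    ordered += [p for a, b in pairs for p in ((a, b), (b, a))]
    for i_prev, i in ordered:
        for u, v in uv:
            templates.append(FeatureTemplate(ADJ_PAIR, u, v, i=i, i_prev=i_prev))
    for r in binary:
        for u, v in uv:
            templates.append(FeatureTemplate(ADJ_TRIPLE, u, v, i=r, i_prev=r, i_next=r))
    if include_transitions:
        for u, v in uv:
            templates.append(FeatureTemplate(TRANSITION, u, v))
    return FeatureSet(templates, tuple(row_names))


# ---------------------------------------------------------------------------
# Evaluation


def _x_at(X: FeatureMatrix, row: int, j: int) -> float:
    """Matrix lookup with the out-of-range-reads-0 boundary convention."""
    if j < 0 or j >= X.n_bins:
        return 0.0
    return float(X.values[row - 1, j])


def _cond(X: FeatureMatrix, row: int, j: int, negated: bool) -> bool:
    val = _x_at(X, row, j)
    return (val == 0.0) if negated else (val == 1.0)


def evaluate_feature(
    t: FeatureTemplate,
    y_prev,
    y_cur: int,
    j: int,
    X: FeatureMatrix,
) -> float:
    """Reference (scalar) evaluation of one template at one position.

    ``y_prev`` may be :data:`BOUNDARY` at ``j = 0``, which matches ``u = 0``.
    """
    prev = 0 if y_prev == BOUNDARY else y_prev
    neg = t.negate + (False,) * (3 - len(t.negate))
    if t.family == PWM_STATE:
        return _x_at(X, PWM_ROW, j) if y_cur == t.u else 0.0
    if prev != t.u or y_cur != t.v:
        return 0.0
    if t.family == TRANSITION:
        return 1.0
    if t.family == OCCURRENCE:
        return float(_cond(X, t.i, j, neg[0]))
    if t.family == COOCCURRENCE:
        return float(_cond(X, t.i, j, neg[0]) and _cond(X, t.i_prev, j, neg[1]))
    if t.family == ADJ_PAIR:
        return float(_cond(X, t.i, j, neg[0]) and _cond(X, t.i_prev, j - 1, neg[1]))
    # ADJ_TRIPLE
    return float(
        _cond(X, t.i, j, neg[0])
        and _cond(X, t.i_prev, j - 1, neg[1])
        and _cond(X, t.i_next, j + 1, neg[2])
    )


def _activation(t: FeatureTemplate, X: FeatureMatrix) -> np.ndarray:
    """Per-bin x-part of a template (label-independent factor), vectorised."""
    L = X.n_bins
    neg = t.negate + (False,) * (3 - len(t.negate))

    def cond(row: int, shift: int, negated: bool) -> np.ndarray:
        vals = X.values[row - 1]
        if shift == -1:
            vals = np.concatenate(([0.0], vals[:-1]))
        elif shift == 1:
            vals = np.concatenate((vals[1:], [0.0]))
        return (vals == 0.0) if negated else (vals == 1.0)

    if t.family == PWM_STATE:
        return X.values[0].astype(np.float64)
    if t.family == TRANSITION:
        return np.ones(L)
    if t.family == OCCURRENCE:
        act = cond(t.i, 0, neg[0])
    elif t.family == COOCCURRENCE:
        act = cond(t.i, 0, neg[0]) & cond(t.i_prev, 0, neg[1])
    elif t.family == ADJ_PAIR:
        act = cond(t.i, 0, neg[0]) & cond(t.i_prev, -1, neg[1])
    else:  # ADJ_TRIPLE
        act = (
            cond(t.i, 0, neg[0])
            & cond(t.i_prev, -1, neg[1])
            & cond(t.i_next, 1, neg[2])
        )
    return act.astype(np.float64)


def _label_mask(t: FeatureTemplate) -> np.ndarray:
    """2x2 mask over ``(y_prev, y_cur)`` under which the template fires."""
    m = np.zeros((2, 2))
    if t.family == PWM_STATE:
        m[:, t.u] = 1.0  # fires for either previous label
    else:
        m[t.u, t.v] = 1.0
    return m


@dataclasses.dataclass
class CompiledFeatures:
    """Template set pre-evaluated against one feature matrix.

    ``activations`` is K x L (the x-part per template per bin) and ``masks``
    K x 2 x 2 (the label part), so the clique score array is a single matrix
    product and feature expectations are linear maps of the chain marginals.
    """

    activations: np.ndarray  # (K, L)
    masks: np.ndarray  # (K, 2, 2)

    @property
    def k(self) -> int:
        return self.activations.shape[0]

    @property
    def n_bins(self) -> int:
        return self.activations.shape[1]

    def clique_scores(self, weights: np.ndarray) -> np.ndarray:
        """(L, 2, 2) array of summed weighted feature values per clique."""
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (self.k,):
            raise ValueError(
                f"expected {self.k} weights, got {weights.shape}"
            )
        m4 = self.masks.reshape(self.k, 4)
        return (self.activations.T @ (weights[:, None] * m4)).reshape(-1, 2, 2)

    def empirical_counts(self, labels: np.ndarray) -> np.ndarray:
        """Per-template feature totals along an observed label sequence."""
        y = np.asarray(labels, dtype=np.int64)
        y_prev = np.concatenate(([0], y[:-1]))  # virtual background at j = -1
        pair = 2 * y_prev + y
        m4 = self.masks.reshape(self.k, 4)
        return (self.activations * m4[:, pair]).sum(axis=1)

    def expected_counts(self, pair_marginals: np.ndarray) -> np.ndarray:
        """Per-template expectations given (L, 2, 2) clique marginals.

        Entry ``[0, u, v]`` must hold ``I{u = 0} * p(y_0 = v)`` and entry
        ``[j, u, v]`` (j >= 1) the edge marginal ``p(y_{j-1} = u, y_j = v)``.
        """
        m4 = self.masks.reshape(self.k, 4)
        p4 = pair_marginals.reshape(-1, 4)
        return ((m4 @ p4.T) * self.activations).sum(axis=1)


def compile_features(X: FeatureMatrix, fs: FeatureSet) -> CompiledFeatures:
    """Pre-evaluate every template of ``fs`` against ``X``."""
    if tuple(fs.row_names) != tuple(X.row_names):
        raise ValueError(
            f"feature set registry {fs.row_names} does not match matrix rows "
            f"{X.row_names}"
        )
    acts = np.vstack([_activation(t, X) for t in fs.templates])
    masks = np.stack([_label_mask(t) for t in fs.templates])
    return CompiledFeatures(acts, masks)


def clique_scores(
    X: FeatureMatrix, fs: FeatureSet, weights: np.ndarray
) -> np.ndarray:
    """(n_bins, 2, 2) array: entry (j, u, v) = sum_k lambda_k f_k(u, v, j, x).

    At j = 0 only the u = 0 slice is meaningful (virtual background label).
    """
    return compile_features(X, fs).clique_scores(weights)
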