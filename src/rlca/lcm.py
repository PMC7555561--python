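"""Core latent class model: parameterization, likelihood, simulation.

A latent class model (LCM) represents the joint distribution of I categorical
items by C latent classes: items are conditionally independent given class
membership, so

    P(X = x) = sum_c p_c * prod_i P(X_i = x_i | U = c).

Item response probabilities are parameterized on the logit scale.  For an
item with categories 0..K_i, class-specific logits gamma_{ikc} (k = 1..K_i)
define a multinomial logit with the reference category 0 fixed at
gamma_{i0c} = 0; class probabilities p_c come from class logits delta_c with
delta_1 = 0.  Dichotomous items are the K_i = 1 special case, where category
1 is the "correct" response and gamma_{i1c} is its log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np

from . import datasets

__all__ = [
    "ResponseMatrix",
    "ModelParams",
    "TrueDesign",
    "logits_to_probs",
    "probs_to_logits",
    "class_probs",
    "delta_from_probs",
    "log_likelihood",
    "simulate",
    "fixture_design",
    "match_labels",
]

PROB_FLOOR = 1e-12  # probabilities are clamped to [floor, 1-floor] before logs


@dataclass
class ResponseMatrix:
    """Wide-format item responses: persons in rows, items in columns.

    ``data[n, i]`` is the observed category of person ``n`` on item ``i``,
    an integer in ``0..K_i``.  Missing values are rejected.
    """

    data: np.ndarray
    n_categories: list[int]  # K_i + 1 per item
    item_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("response data must be a nonempty 2-D matrix")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.asarray(self.data, dtype=np.int64)):
                raise ValueError("responses must be integer categories")
            self.data = self.data.astype(np.int64)
        if len(self.n_categories) != self.data.shape[1]:
            raise ValueError("n_categories length must equal number of items")
        for i, ncat in enumerate(self.n_categories):
            if ncat < 2:
                raise ValueError(f"item {i} must have at least 2 categories")
            col = self.data[:, i]
            if col.min() < 0 or col.max() >= ncat:
                bad = int(np.argmax((col < 0) | (col >= ncat)))
                raise ValueError(
                    f"item {i}: category {col[bad]} of person {bad} outside 0..{ncat - 1}"
                )
        if not self.item_labels:
            self.item_labels = [f"I{i + 1}" for i in range(self.data.shape[1])]

    @classmethod
    def from_array(cls, data, n_categories=None, item_labels=None):
        """Build from a raw array, inferring K_i from observed maxima if needed."""
        data = np.asarray(data)
        if n_categories is None:
            n_categories = [int(data[:, i].max()) + 1 for i in range(data.shape[1])]
        return cls(data, list(n_categories), list(item_labels or []))

    @property
    def N(self) -> int:
        return self.data.shape[0]

    @property
    def I(self) -> int:
        return self.data.shape[1]

    def compress(self):
        """Unique response patterns with multiplicities.

        Returns ``(patterns, weights, inverse)`` where ``patterns`` is
        ``(P, I)``, ``weights`` the pattern counts and ``inverse`` maps
        persons to pattern rows.  The likelihood and all EM sufficient
        statistics depend on the data only through these.
        """
        patterns, inverse, weights = np.unique(
            self.data, axis=0, return_inverse=True, return_counts=True
        )
        return patterns, weights.astype(float), inverse


@dataclass
class ModelParams:
    """LCM parameters on the logit scale.

    ``gamma[i]`` is the ``(K_i, C)`` matrix of item logits (reference
    category 0 implicit at zero); ``delta`` the length-C class logits with
    ``delta[0] == 0``.
    """

    gamma: list[np.ndarray]
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = [np.atleast_2d(np.asarray(g, dtype=float)) for g in self.gamma]
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 1:
            raise ValueError("delta must be a vector")
        if abs(self.delta[0]) > 0:
            raise ValueError("delta[0] must be fixed at 0 (reference class)")
        C = self.delta.shape[0]
        for i, g in enumerate(self.gamma):
            if g.shape[1] != C:
                raise ValueError(f"gamma[{i}] has {g.shape[1]} columns, expected {C}")

    @property
    def C(self) -> int:
        return int(self.delta.shape[0])

    @property
    def I(self) -> int:
        return len(self.gamma)

    @property
    def n_categories(self) -> list[int]:
        return [g.shape[0] + 1 for g in self.gamma]

    def item_probs(self, i: int) -> np.ndarray:
        """(K_i + 1, C) response probability table of item ``i``."""
        return logits_to_probs(self.gamma[i])

    def all_item_probs(self) -> list[np.ndarray]:
        return [logits_to_probs(g) for g in self.gamma]

    def class_probs(self) -> np.ndarray:
        return class_probs(self.delta)

    def permute_classes(self, perm: Sequence[int]) -> "ModelParams":
        """Relabel classes by ``perm`` (new class c = old class perm[c])."""
        perm = list(perm)
        p = self.class_probs()[perm]
        delta = np.log(p / p[0])
        delta[0] = 0.0
        return ModelParams([g[:, perm].copy() for g in self.gamma], delta)

    def copy(self) -> "ModelParams":
        return ModelParams([g.copy() for g in self.gamma], self.delta.copy())

    @classmethod
    def from_probs(cls, item_tables: Sequence[np.ndarray], class_p: np.ndarray,
                   clamp: bool = True) -> "ModelParams":
        gamma = [probs_to_logits(t, clamp=clamp) for t in item_tables]
        p = np.asarray(class_p, dtype=float)
        delta = np.log(p / p[0])
        delta[0] = 0.0
        return cls(gamma, delta)


@dataclass
class TrueDesign:
    """A data-generating design: class probabilities plus per-item
    ``(K_i + 1, C)`` response-probability tables (category 0 first)."""

    class_probs: np.ndarray
    item_probs: list[np.ndarray]
    name: str = ""

    def __post_init__(self) -> None:
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        self.item_probs = [np.asarray(t, dtype=float) for t in self.item_probs]
        if not np.isclose(self.class_probs.sum(), 1.0):
            raise ValueError("class probabilities must sum to 1")
        if np.any(self.class_probs <= 0):
            raise ValueError("class probabilities must be positive")
        C = self.class_probs.shape[0]
        for i, t in enumerate(self.item_probs):
            if t.ndim != 2 or t.shape[1] != C:
                raise ValueError(f"item {i}: table must be (K_i+1) x {C}")
            if np.any(t < 0) or np.any(t > 1):
                raise ValueError(f"item {i}: probabilities outside [0, 1]")
            if not np.allclose(t.sum(axis=0), 1.0):
                raise ValueError(f"item {i}: columns must sum to 1")

    @property
    def C(self) -> int:
        return int(self.class_probs.shape[0])

    @property
    def I(self) -> int:
        return len(self.item_probs)

    def to_params(self) -> ModelParams:
        return ModelParams.from_probs(self.item_probs, self.class_probs)

    def to_frame(self):
        """Long-format table (item, category, one column per class)."""
        import pandas as pd

        rows = []
        for i, t in enumerate(self.item_probs):
            for k in range(t.shape[0]):
                rows.append([i + 1, k, *t[k]])
        cols = ["item", "category"] + [f"class{c + 1}" for c in range(self.C)]
        return pd.DataFrame(rows, columns=cols)


def logits_to_probs(gamma_item: np.ndarray) -> np.ndarray:
    """Multinomial-logit transform of one item's ``(K_i, C)`` logits.

    Returns the ``(K_i + 1, C)`` probability table with category 0 as the
    reference: ``p_k = exp(gamma_k) / (1 + sum_j exp(gamma_j))``.  Computed
    stably via a column-wise max shift.
    """
    g = np.atleast_2d(np.asarray(gamma_item, dtype=float))
    full = np.vstack([np.zeros((1, g.shape[1])), g])
    full = full - full.max(axis=0, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=0, keepdims=True)


def probs_to_logits(prob_table: np.ndarray, clamp: bool = False) -> np.ndarray:
    """Inverse transform: ``gamma_k = log(p_k / p_0)`` per class column."""
    t = np.atleast_2d(np.asarray(prob_table, dtype=float))
    if clamp:
        t = np.clip(t, PROB_FLOOR, 1.0 - PROB_FLOOR)
    elif np.any(t <= 0) or np.any(t >= 1):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    return np.log(t[1:] / t[0])


def class_probs(delta: np.ndarray) -> np.ndarray:
    """Class probabilities from class logits (``delta[0]`` fixed at 0)."""
    d = np.asarray(delta, dtype=float)
    if abs(d[0]) > 0:
        raise ValueError("delta[0] must be 0")
    d = d - d.max()
    e = np.exp(d)
    return e / e.sum()


def delta_from_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    delta = np.log(p / p[0])
    delta[0] = 0.0
    return delta


def _log_item_tables(params: ModelParams) -> list[np.ndarray]:
    return [
        np.log(np.clip(params.item_probs(i), PROB_FLOOR, 1.0))
        for i in range(params.I)
    ]


def pattern_class_loglik(patterns: np.ndarray, params: ModelParams) -> np.ndarray:
    """(P, C) matrix of log P(pattern | class)."""
    P, I = patterns.shape
    out = np.zeros((P, params.C))
    for i, logt in enumerate(_log_item_tables(params)):
        out += logt[patterns[:, i], :]
    return out


def log_likelihood(data: ResponseMatrix, params: ModelParams) -> float:
    """Observed-data log-likelihood of the mixture model."""
    if data.I != params.I:
        raise ValueError("data and params disagree on the number of items")
    for i, (ncat, k1) in enumerate(zip(data.n_categories, params.n_categories)):
        if ncat > k1:
            raise ValueError(f"item {i}: data has more categories than the model")
    patterns, weights, _ = data.compress()
    lpc = pattern_class_loglik(patterns, params)
    lp = lpc + np.log(params.class_probs())[None, :]
    m = lp.max(axis=1)
    ll = m + np.log(np.exp(lp - m[:, None]).sum(axis=1))
    return float(weights @ ll)


def simulate(design: TrueDesign, N: int, seed: int,
             return_membership: bool = True):
    """Draw ``N`` persons from a :class:`TrueDesign`.

    One integer ``seed`` governs both the class-membership draw and the
    per-item response draws, so results are exactly reproducible.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    membership = rng.choice(design.C, size=N, p=design.class_probs)
    data = np.zeros((N, design.I), dtype=np.int64)
    u = rng.random((N, design.I))
    for i, table in enumerate(design.item_probs):
        cum = np.cumsum(table, axis=0)  # (K+1, C)
        cum[-1] = 1.0
        thresholds = cum[:, membership]  # (K+1, N)
        data[:, i] = (u[:, i][None, :] > thresholds).sum(axis=0)
    rm = ResponseMatrix(data, [t.shape[0] for t in design.item_probs])
    if return_membership:
        return rm, membership
    return rm


def fixture_design(name: str) -> TrueDesign:
    """Bundled simulation designs.

    ``"dichotomous_4class"``: 12 binary items, 4 classes, class probabilities
    (0.30, 0.20, 0.10, 0.40), many response probabilities equal across
    classes within each item.  ``"polytomous_4class"``: 12 four-category
    items with equality structure across both classes and categories.
    """
    if name == "dichotomous_4class":
        tables = [
            np.vstack([1.0 - row, row])
            for row in datasets.DICHOTOMOUS_ITEM_PROBS
        ]
        return TrueDesign(datasets.DICHOTOMOUS_CLASS_PROBS, tables, name=name)
    if name == "polytomous_4class":
        return TrueDesign(
            datasets.POLYTOMOUS_CLASS_PROBS,
            [t.copy() for t in datasets.POLYTOMOUS_ITEM_TABLES],
            name=name,
        )
    raise ValueError(f"unknown fixture design {name!r}")


def match_labels(fitted: ModelParams, truth: TrueDesign) -> ModelParams:
    """Resolve label switching against a generating design.

    Finite-mixture likelihoods are invariant under permutation of class
    labels; comparison with the truth requires choosing the permutation
    minimizing the total absolute difference between fitted and true
    response-probability tables (exhaustive search, C <= 8).
    """
    C = fitted.C
    if C != truth.C:
        raise ValueError("class counts differ")
    if C > 8:
        raise ValueError("exhaustive label matching supported for C <= 8 only")
    fitted_tables = fitted.all_item_probs()
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(C)):
        cost = sum(
            np.abs(ft[:, perm] - tt).sum()
            for ft, tt in zip(fitted_tables, truth.item_probs)
        )
        if cost < best_cost:
            best_cost, best_perm = cost, perm
    return fitted.permute_classes(best_perm)
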