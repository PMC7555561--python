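"""Model selection: unique-parameter counting, AIC/BIC, lambda-grid search.

The effective dimension of a regularized fit counts fused parameters once:
per item, parameters whose penalized pairwise logit differences vanish (up to
``fuse_tol``) are grouped by transitive closure, and each group contributes a
single free parameter.  AIC/BIC computed with this count make fits along a
regularization path comparable with unpenalized models of any class number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .em import FitResult, fit
from .lcm import ModelParams, ResponseMatrix
from .penalties import PenaltySpec

__all__ = [
    "SelectionResult",
    "count_unique_params",
    "information_criteria",
    "grid_search",
    "regularization_path",
]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def n_groups(self) -> int:
        return len({self.find(i) for i in range(len(self.parent))})


def _item_groups(g: np.ndarray, spec: PenaltySpec, tol: float) -> int:
    """Number of unique parameter groups in one item's (K, C) logits."""
    K, C = g.shape
    uf = _UnionFind(K * C)
    idx = lambda k, c: k * C + c  # noqa: E731

    fuse_classes = spec.strategy in ("fused_classes", "fused_both")
    fuse_cats = spec.strategy in ("fused_categories", "fused_both")
    if fuse_classes and spec.lambda1 > 0:
        for k in range(K):
            for c in range(C):
                for d in range(c + 1, C):
                    if abs(g[k, c] - g[k, d]) < tol:
                        uf.union(idx(k, c), idx(k, d))
    if fuse_cats and spec.lambda2 > 0:
        for c in range(C):
            for k in range(K):
                for h in range(k + 1, K):
                    if abs(g[k, c] - g[h, c]) < tol:
                        uf.union(idx(k, c), idx(h, c))
    if spec.strategy == "group_categories" and spec.lambda2 > 0:
        for k in range(K):
            for h in range(k + 1, K):
                if np.abs(g[k] - g[h]).max() < tol:
                    for c in range(C):
                        uf.union(idx(k, c), idx(h, c))
    if spec.strategy == "group_classes" and spec.lambda1 > 0:
        for c in range(C):
            for d in range(c + 1, C):
                if np.abs(g[:, c] - g[:, d]).max() < tol:
                    for k in range(K):
                        uf.union(idx(k, c), idx(k, d))
    return uf.n_groups()


def count_unique_params(params: ModelParams, spec: Optional[PenaltySpec],
                        fuse_tol: float = 0.01) -> tuple[int, int]:
    """Count unique free parameters and regularized (fused) item parameters.

    Per item, parameters are grouped by the transitive closure of
    "penalized difference below ``fuse_tol``" along the pairs the fusion
    strategy penalizes, so a chain a ~ b ~ c counts as a single
    parameter.  Returns ``(n_params, n_regularized)`` with
    ``n_params = sum_i #groups_i + (C - 1)`` and
    ``n_regularized = sum_i K_i * C - sum_i #groups_i``.

    Without an active penalty the raw counts are returned: equality of
    unpenalized estimates is a measure-zero event, and the exploratory
    model's dimension is its raw parameter count.
    """
    C = params.C
    raw_items = sum(g.size for g in params.gamma)
    active = spec is not None and (
        (spec.lambda1 > 0 and spec.uses_classes)
        or (spec.lambda2 > 0 and spec.uses_categories)
    )
    if not active:
        return raw_items + C - 1, 0
    groups = sum(_item_groups(g, spec, fuse_tol) for g in params.gamma)
    return groups + C - 1, raw_items - groups


def information_criteria(loglik: float, n_params: int, N: int) -> tuple[float, float]:
    """AIC = -2 loglik + 2 k and BIC = -2 loglik + k log N."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    aic = -2.0 * loglik + 2.0 * n_params
    bic = -2.0 * loglik + n_params * np.log(N)
    return float(aic), float(bic)


@dataclass
class SelectionResult:
    """Fits along a regularization-parameter grid plus selection bookkeeping."""

    grid: list[tuple[float, float]]  # (lambda1, lambda2) per point
    fits: list[FitResult]
    best_bic_index: int
    best_aic_index: int
    criterion: str = "bic"
    C: int = 0

    @property
    def best_fit(self) -> FitResult:
        idx = self.best_bic_index if self.criterion == "bic" else self.best_aic_index
        return self.fits[idx]

    @property
    def best_lambda(self) -> tuple[float, float]:
        idx = self.best_bic_index if self.criterion == "bic" else self.best_aic_index
        return self.grid[idx]

    def summary(self) -> pd.DataFrame:
        rows = []
        for (l1, l2), f in zip(self.grid, self.fits):
            rows.append(
                [self.C, l1, l2, f.loglik, f.n_params, f.n_regularized,
                 f.aic, f.bic, f.converged]
            )
        return pd.DataFrame(
            rows,
            columns=["C", "lambda1", "lambda2", "loglik", "n_params",
                     "n_regularized", "aic", "bic", "converged"],
        )

    def is_1d(self) -> bool:
        l1 = {p[0] for p in self.grid}
        l2 = {p[1] for p in self.grid}
        return len(l1) == 1 or len(l2) == 1


def grid_search(
    data: ResponseMatrix,
    C: int,
    spec_template: PenaltySpec,
    grid1: Optional[Sequence[float]] = None,
    grid2: Optional[Sequence[float]] = None,
    criterion: str = "bic",
    seed: int = 0,
    n_starts: int = 10,
    starts_per_point: int = 1,
    fuse_tol: float = 0.01,
    max_iter: int = 500,
    tol: float = 1e-6,
    base_params: Optional[ModelParams] = None,
) -> SelectionResult:
    """Fit the penalized model over a grid of regularization parameters.

    The path is traversed from small to large lambda with each point
    warm-started from the previous solution; the path root is an
    unpenalized multi-start fit (``n_starts`` starts).  ``grid1`` holds
    class-fusion strengths (lambda1), ``grid2`` category-fusion strengths
    (lambda2); strategies using only one of the two may omit the other.
    Points that fail to converge are flagged and excluded from
    best-by-criterion selection.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    g1 = sorted(grid1) if grid1 else [0.0]
    g2 = sorted(grid2) if grid2 else [0.0]
    if not g1 or not g2:
        raise ValueError("grids must be nonempty")
    points = [(l1, l2) for l1 in g1 for l2 in g2]

    if base_params is None:
        base = fit(data, C, spec=None, n_starts=n_starts, seed=seed,
                   max_iter=max_iter, tol=tol)
        base_params = base.params

    fits: list[FitResult] = []
    prev = base_params
    row_start = base_params  # warm start of each lambda1 row (2-D grids)
    for j, (l1, l2) in enumerate(points):
        spec = spec_template.replace(lambda1=l1, lambda2=l2)
        init = row_start if (j % len(g2) == 0) else prev
        f = fit(
            data, C, spec=spec, n_starts=starts_per_point, seed=seed + 1 + j,
            max_iter=max_iter, tol=tol, init_params=init, fuse_tol=fuse_tol,
        )
        fits.append(f)
        prev = f.params
        if j % len(g2) == 0:
            row_start = f.params

    def _best(attr: str) -> int:
        vals = [getattr(f, attr) if f.converged else np.inf for f in fits]
        if not np.isfinite(min(vals)):
            vals = [getattr(f, attr) for f in fits]
        return int(np.argmin(vals))

    return SelectionResult(
        grid=points,
        fits=fits,
        best_bic_index=_best("bic"),
        best_aic_index=_best("aic"),
        criterion=criterion,
        C=C,
    )


def regularization_path(
    selection: SelectionResult,
    item: int,
    classes: Optional[Sequence[int]] = None,
    category: Optional[int] = None,
) -> pd.DataFrame:
    """Fitted response probabilities of one item as a function of lambda.

    Only defined for 1-D grids.  ``category`` defaults to the
    correct-response category (1 for dichotomous items, 0 otherwise);
    ``classes`` are 0-based indices, defaulting to all classes.  Merge
    events show up as columns becoming (and staying) equal.
    """
    if not selection.is_1d():
        raise ValueError("regularization paths require a 1-D grid")
    C = selection.fits[0].params.C
    if not 0 <= item < selection.fits[0].params.I:
        raise IndexError(f"item {item} out of range")
    classes = list(classes) if classes is not None else list(range(C))
    if any(not 0 <= c < C for c in classes):
        raise IndexError("class index out of range")
    lam = [max(l1, l2) for (l1, l2) in selection.grid]
    rows = []
    for lv, f in zip(lam, selection.fits):
        t = f.params.item_probs(item)
        cat = category if category is not None else (1 if t.shape[0] == 2 else 0)
        rows.append([lv] + [t[cat, c] for c in classes])
    return pd.DataFrame(rows, columns=["lambda"] + [f"class{c + 1}" for c in classes])
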