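"""Fused regularization penalties for latent class models.

Penalty families (LASSO, SCAD, MCP) are applied to pairwise differences of
item logits so that class-specific (and, for polytomous items,
category-specific) parameters are shrunk towards — and eventually merged at —
common values.  SCAD and MCP are concave with an upper plateau, which removes
the shrinkage bias that a plain LASSO difference penalty would leave on
parameters that are genuinely distinct.

All functions accept scalars or arrays and broadcast in the usual numpy way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PenaltySpec",
    "penalty_value",
    "smooth_penalty_value",
    "fused_penalty",
    "fused_penalty_grad",
    "FAMILIES",
    "STRATEGIES",
]

FAMILIES = ("lasso", "scad", "mcp")
STRATEGIES = (
    "fused_classes",
    "fused_categories",
    "fused_both",
    "group_categories",
    "group_classes",
)

#: conventional default shape constants
DEFAULT_CONCAVITY = {"mcp": 3.0, "scad": 3.7, "lasso": None}

_CLASS_STRATEGIES = frozenset({"fused_classes", "fused_both", "group_classes"})
_CATEGORY_STRATEGIES = frozenset(
    {"fused_categories", "fused_both", "group_categories"}
)


@dataclass(frozen=True)
class PenaltySpec:
    """Specification of a fused penalty.

    Parameters
    ----------
    family:
        Penalty family applied to each pairwise difference:
        ``"lasso"``, ``"scad"`` or ``"mcp"``.
    strategy:
        Which pairwise differences are penalized.  ``fused_classes``
        penalizes, per category, differences between classes;
        ``fused_categories`` penalizes, per class, differences between
        item categories; ``fused_both`` adds the two; the ``group_*``
        strategies penalize the Euclidean norm of a whole difference
        vector so an entire block merges (or not) as one decision.
    lambda1:
        Class-fusion strength (λ1).  For dichotomous items this is the
        single regularization parameter.
    lambda2:
        Category-fusion strength (λ2), used by the category strategies.
    concavity:
        Shape constant ``a`` of SCAD/MCP.  Defaults to 3.0 for MCP and
        3.7 for SCAD; ignored for LASSO.
    smooth_eps:
        ε of the differentiable approximation ``|x| ≈ sqrt(x² + ε)``
        used during numerical optimization.
    """

    family: str = "mcp"
    strategy: str = "fused_classes"
    lambda1: float = 0.0
    lambda2: float = 0.0
    concavity: float | None = None
    smooth_eps: float = 1e-4

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization parameters must be nonnegative")
        if self.smooth_eps <= 0:
            raise ValueError("smooth_eps must be positive")
        if self.concavity is None:
            object.__setattr__(
                self, "concavity", DEFAULT_CONCAVITY[self.family]
            )
        else:
            _check_concavity(self.family, self.concavity)

    @property
    def uses_classes(self) -> bool:
        return self.strategy in _CLASS_STRATEGIES

    @property
    def uses_categories(self) -> bool:
        return self.strategy in _CATEGORY_STRATEGIES

    def replace(self, **kwargs) -> "PenaltySpec":
        from dataclasses import replace

        return replace(self, **kwargs)


def _check_concavity(family: str, a: float | None) -> None:
    if family == "lasso":
        return
    if a is None:
        raise ValueError(f"{family} requires a concavity constant")
    if family == "scad" and not a > 2:
        raise ValueError("scad requires concavity > 2")
    if family == "mcp" and not a > 1:
        raise ValueError("mcp requires concavity > 1")


def _h_of_t(t, lam: float, family: str, a: float | None):
    """Penalty as a function of the magnitude t = |x| >= 0 (vectorized)."""
    t = np.asarray(t, dtype=float)
    if lam == 0.0:
        return np.zeros_like(t)
    if family == "lasso":
        return lam * t
    if family == "mcp":
        # Zhang (2010): λt − t²/(2a) below the plateau aλ, constant aλ²/2 above
        inner = lam * t - t * t / (2.0 * a)
        return np.where(t <= a * lam, inner, a * lam * lam / 2.0)
    # scad (Fan & Li 2001)
    lin = lam * t
    mid = (2.0 * a * lam * t - t * t - lam * lam) / (2.0 * (a - 1.0))
    out = np.full_like(t, (a + 1.0) * lam * lam / 2.0)
    res = np.where(t <= lam, lin, np.where(t <= a * lam, mid, out))
    return res


def _h_prime_of_t(t, lam: float, family: str, a: float | None):
    """Derivative dH/dt of the magnitude form (vectorized, t >= 0)."""
    t = np.asarray(t, dtype=float)
    if lam == 0.0:
        return np.zeros_like(t)
    if family == "lasso":
        return np.full_like(t, lam)
    if family == "mcp":
        return np.where(t <= a * lam, lam - t / a, 0.0)
    mid = (a * lam - t) / (a - 1.0)
    return np.where(t <= lam, lam, np.where(t <= a * lam, mid, 0.0))


def penalty_value(x, lam: float, family: str = "mcp", concavity: float | None = None):
    """Exact (non-smoothed) penalty H(x; λ) of a single difference.

    Symmetric in ``x``; zero iff ``x == 0`` or ``lam == 0``; for SCAD and
    MCP constant beyond the family's plateau threshold (``aλ`` for MCP,
    ``aλ`` for SCAD).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown penalty family {family!r}")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if concavity is None:
        concavity = DEFAULT_CONCAVITY[family]
    _check_concavity(family, concavity)
    return _h_of_t(np.abs(x), lam, family, concavity)


def smooth_penalty_value(
    x,
    lam: float,
    family: str = "mcp",
    concavity: float | None = None,
    eps: float = 1e-4,
):
    """Differentiable approximation of :func:`penalty_value`.

    ``|x|`` is replaced by ``sqrt(x² + ε)``; since H(t) is continuously
    differentiable in the magnitude t for all three families, the
    composite is everywhere differentiable and converges to the exact
    penalty as ε → 0, with error bounded by ``H(sqrt(ε)) ≤ λ·sqrt(ε)``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if family not in FAMILIES:
        raise ValueError(f"unknown penalty family {family!r}")
    if concavity is None:
        concavity = DEFAULT_CONCAVITY[family]
    _check_concavity(family, concavity)
    x = np.asarray(x, dtype=float)
    t = np.sqrt(x * x + eps)
    return _h_of_t(t, lam, family, concavity)


def _smooth_h_and_dx(x, lam, family, a, eps):
    """Smoothed penalty value and its derivative w.r.t. x (vectorized)."""
    t = np.sqrt(x * x + eps)
    val = _h_of_t(t, lam, family, a)
    dval = _h_prime_of_t(t, lam, family, a) * (x / t)
    return val, dval


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def fused_penalty(gamma_i: np.ndarray, spec: PenaltySpec, smooth: bool = False) -> float:
    """Total fused penalty of one item's logit matrix.

    Parameters
    ----------
    gamma_i:
        ``(K_i, C)`` matrix of item logits (reference category excluded).
    spec:
        Penalty specification; ``spec.strategy`` selects which pairwise
        differences enter, ``spec.lambda1``/``spec.lambda2`` their weights.
    smooth:
        If true, use the ε-smoothed magnitude (the objective actually
        optimized); otherwise the exact penalty.

    Returns
    -------
    float
        Nonnegative penalty; zero when all entries relevant to the
        strategy coincide (exact form only).
    """
    g = np.asarray(gamma_i, dtype=float)
    if g.ndim != 2:
        raise ValueError("gamma_i must be a (K_i, C) matrix")
    val, _ = _fused_value_grad(g, spec, smooth=smooth, want_grad=False)
    return float(val)


def fused_penalty_grad(gamma_i: np.ndarray, spec: PenaltySpec) -> np.ndarray:
    """Gradient of the ε-smoothed fused penalty w.r.t. ``gamma_i``."""
    g = np.asarray(gamma_i, dtype=float)
    _, grad = _fused_value_grad(g, spec, smooth=True, want_grad=True)
    return grad


def _fused_value_grad(g, spec, smooth, want_grad):
    K, C = g.shape
    a = spec.concavity
    fam = spec.family
    eps = spec.smooth_eps
    total = 0.0
    grad = np.zeros_like(g) if want_grad else None

    def _accum_pairwise(diff, idx_hi, idx_lo, axis_is_classes, lam):
        # diff: (..., n_pairs) array of γ differences along the penalized axis
        nonlocal total
        if smooth:
            val, dval = _smooth_h_and_dx(diff, lam, fam, a, eps)
        else:
            val = _h_of_t(np.abs(diff), lam, fam, a)
            dval = None
        total += val.sum()
        if want_grad:
            if axis_is_classes:
                # diff[k, p] = g[k, c_p] - g[k, d_p]
                np.add.at(grad, (slice(None), idx_hi), dval)
                np.add.at(grad, (slice(None), idx_lo), -dval)
            else:
                np.add.at(grad, (idx_hi, slice(None)), dval)
                np.add.at(grad, (idx_lo, slice(None)), -dval)

    strat = spec.strategy
    if strat in ("fused_classes", "fused_both") and C > 1:
        c_idx, d_idx = _pair_index(C)
        diff = g[:, c_idx] - g[:, d_idx]
        _accum_pairwise(diff, c_idx, d_idx, True, spec.lambda1)
    if strat in ("fused_categories", "fused_both") and K > 1:
        k_idx, h_idx = _pair_index(K)
        diff = g[k_idx, :] - g[h_idx, :]
        _accum_pairwise(diff, k_idx, h_idx, False, spec.lambda2)
    if strat == "group_categories" and K > 1:
        k_idx, h_idx = _pair_index(K)
        diff = g[k_idx, :] - g[h_idx, :]  # (n_pairs, C)
        total, grad = _accum_group(
            diff, k_idx, h_idx, False, spec.lambda2, g, fam, a, eps,
            smooth, want_grad, total, grad,
        )
    if strat == "group_classes" and C > 1:
        c_idx, d_idx = _pair_index(C)
        diff = (g[:, c_idx] - g[:, d_idx]).T  # (n_pairs, K)
        total, grad = _accum_group(
            diff, c_idx, d_idx, True, spec.lambda1, g, fam, a, eps,
            smooth, want_grad, total, grad,
        )
    return total, grad


def _accum_group(diff, idx_hi, idx_lo, axis_is_classes, lam, g, fam, a, eps,
                 smooth, want_grad, total, grad):
    # Euclidean group norm per pair; smoothing enters through the norm itself
    sq = (diff * diff).sum(axis=1)
    if smooth:
        t = np.sqrt(sq + eps)
    else:
        t = np.sqrt(sq)
    total += _h_of_t(t, lam, fam, a).sum()
    if want_grad:
        hp = _h_prime_of_t(t, lam, fam, a)
        scale = hp / t  # t > 0 under smoothing
        contrib = diff * scale[:, None]  # d(total)/d(diff)
        if axis_is_classes:
            np.add.at(grad, (slice(None), idx_hi), contrib.T)
            np.add.at(grad, (slice(None), idx_lo), -contrib.T)
        else:
            np.add.at(grad, (idx_hi, slice(None)), contrib)
            np.add.at(grad, (idx_lo, slice(None)), -contrib)
    return total, grad
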