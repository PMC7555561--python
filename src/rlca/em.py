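"""Penalized EM estimation of (regularized) latent class models.

The E-step computes posterior class-membership probabilities; the M-step
updates class probabilities in closed form and, per item, maximizes the
posterior-weighted multinomial log-likelihood minus N times the fused
penalty.  Because the penalty is defined item-wise, the M-step separates over
items.  The penalty's absolute values are replaced by the differentiable
approximation sqrt(x^2 + eps) so a quasi-Newton optimizer applies; the fit
runs a main phase at the spec's ``smooth_eps`` and a refinement phase at a
tighter eps so that fused parameters collapse numerically.

The likelihood, and every EM sufficient statistic, depends on the data only
through the unique response patterns and their counts, so all heavy lifting
is done on the compressed pattern table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .lcm import (
    ModelParams,
    ResponseMatrix,
    class_probs,
    delta_from_probs,
    logits_to_probs,
    pattern_class_loglik,
    probs_to_logits,
    PROB_FLOOR,
)
from .penalties import PenaltySpec, fused_penalty, fused_penalty_grad

__all__ = ["FitResult", "e_step", "m_step_class_probs", "m_step_item", "fit"]

REFINE_EPS = 1e-6  # smoothing eps of the final refinement phase
CLASS_PROB_FLOOR = 1e-6


@dataclass
class FitResult:
    """Converged penalized-EM fit.

    ``n_params`` counts unique free parameters (fused parameters count
    once); ``n_regularized`` the item parameters merged away, so
    ``n_params + n_regularized`` equals the raw parameter total
    ``sum_i K_i * C + C - 1``.  ``penalized_objective`` is the
    log-likelihood minus N times the exact (non-smoothed) penalty.
    """

    params: ModelParams
    loglik: float
    penalized_objective: float
    posterior: np.ndarray
    n_iter: int
    converged: bool
    n_params: int
    n_regularized: int
    aic: float
    bic: float
    spec: PenaltySpec
    n_obs: int
    seed: Optional[int] = None
    start_index: int = 0
    objective_history: list = field(default_factory=list, repr=False)

    def class_probs(self) -> np.ndarray:
        return self.params.class_probs()

    def prob_table(self, labels: Optional[list[str]] = None):
        """Long-format item/category probability table, one column per class."""
        import pandas as pd

        rows = []
        labels = labels or [f"I{i + 1}" for i in range(self.params.I)]
        for i in range(self.params.I):
            t = self.params.item_probs(i)
            for k in range(t.shape[0]):
                rows.append([labels[i], k, *t[k]])
        cols = ["item", "category"] + [
            f"class{c + 1}" for c in range(self.params.C)
        ]
        return pd.DataFrame(rows, columns=cols)

    def to_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "penalized_objective": self.penalized_objective,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_params": self.n_params,
            "n_regularized": self.n_regularized,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "seed": self.seed,
            "start_index": self.start_index,
            "class_probs": self.class_probs().tolist(),
            "delta": self.params.delta.tolist(),
            "gamma": [g.tolist() for g in self.params.gamma],
            "penalty": {
                "family": self.spec.family,
                "strategy": self.spec.strategy,
                "lambda1": self.spec.lambda1,
                "lambda2": self.spec.lambda2,
                "concavity": self.spec.concavity,
                "smooth_eps": self.spec.smooth_eps,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _posterior_from_patterns(patterns: np.ndarray, params: ModelParams):
    """Posterior per unique pattern and the total weighted log-likelihood
    pieces: returns (post (P, C), log-mixture per pattern (P,))."""
    lpc = pattern_class_loglik(patterns, params)
    lp = lpc + np.log(np.clip(params.class_probs(), PROB_FLOOR, 1.0))[None, :]
    m = lp.max(axis=1)
    lse = m + np.log(np.exp(lp - m[:, None]).sum(axis=1))
    post = np.exp(lp - lse[:, None])
    return post, lse


def e_step(data: ResponseMatrix, params: ModelParams) -> np.ndarray:
    """Posterior class-membership probabilities, one row per person.

    Row ``n`` equals ``p_c prod_i p_{i, x_ni, c}`` renormalized over
    classes (Bayes' rule under conditional independence).
    """
    patterns, _, inverse = data.compress()
    post, _ = _posterior_from_patterns(patterns, params)
    return post[inverse]


def m_step_class_probs(posterior: np.ndarray,
                       weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Closed-form class-logit update: p_c = weighted mean posterior."""
    post = np.asarray(posterior, dtype=float)
    if weights is None:
        p = post.mean(axis=0)
    else:
        p = (weights[:, None] * post).sum(axis=0) / weights.sum()
    if np.any(p < CLASS_PROB_FLOOR):
        warnings.warn(
            "a latent class collapsed; probability floored", RuntimeWarning
        )
        p = np.clip(p, CLASS_PROB_FLOOR, None)
        p = p / p.sum()
    return delta_from_probs(p)


def _item_counts(item_col: np.ndarray, post: np.ndarray,
                 weights: Optional[np.ndarray], ncat: int) -> np.ndarray:
    """Posterior-weighted category-by-class counts n_kc for one item."""
    w = post if weights is None else post * weights[:, None]
    n_kc = np.zeros((ncat, post.shape[1]))
    np.add.at(n_kc, item_col, w)
    return n_kc


def _item_objective(flat, n_kc, N, spec, K, C, eps):
    """Negative smoothed M-step objective for one item, with gradient."""
    g = flat.reshape(K, C)
    p = logits_to_probs(g)  # (K+1, C)
    logp = np.log(np.clip(p, PROB_FLOOR, 1.0))
    ll = float((n_kc * logp).sum())
    spec_eps = spec if spec.smooth_eps == eps else spec.replace(smooth_eps=eps)
    pen = fused_penalty(g, spec_eps, smooth=True)
    # d ll / d gamma_kc = n_kc - N_c * p_kc   (k >= 1)
    Nc = n_kc.sum(axis=0)
    grad_ll = n_kc[1:] - Nc[None, :] * p[1:]
    grad_pen = fused_penalty_grad(g, spec_eps)
    val = ll - N * pen
    grad = grad_ll - N * grad_pen
    return -val, -grad.ravel()


def _m_step_item_counts(n_kc: np.ndarray, N: float, spec: PenaltySpec,
                        gamma_init: np.ndarray, eps: float) -> np.ndarray:
    K1, C = n_kc.shape
    K = K1 - 1
    penalized = (spec.lambda1 > 0 and spec.uses_classes and C > 1) or (
        spec.lambda2 > 0 and spec.uses_categories and K > 1
    )
    if not penalized:
        # weighted multinomial ML: fitted probabilities are the
        # posterior-weighted category frequencies per class
        Nc = np.clip(n_kc.sum(axis=0), PROB_FLOOR, None)
        p = np.clip(n_kc / Nc[None, :], PROB_FLOOR, 1.0)
        p = p / p.sum(axis=0, keepdims=True)
        return probs_to_logits(p, clamp=True)
    x0 = np.asarray(gamma_init, dtype=float).ravel()
    res = minimize(
        _item_objective,
        x0,
        args=(n_kc, N, spec, K, C, eps),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
    )
    # ascent contract: never return something worse than the initial point
    f0, _ = _item_objective(x0, n_kc, N, spec, K, C, eps)
    if res.fun > f0:
        return gamma_init.copy()
    return res.x.reshape(K, C)


def m_step_item(item_data: np.ndarray, posterior: np.ndarray,
                spec: PenaltySpec, gamma_init: np.ndarray,
                n_categories: Optional[int] = None,
                eps: Optional[float] = None) -> np.ndarray:
    """Penalized M-step for a single item.

    Maximizes the posterior-weighted multinomial log-likelihood of this
    item minus ``N`` times the smoothed fused penalty, starting from
    ``gamma_init``.  With all relevant lambdas zero this is the
    closed-form weighted-frequency solution.
    """
    item_data = np.asarray(item_data)
    gamma_init = np.atleast_2d(np.asarray(gamma_init, dtype=float))
    ncat = n_categories or gamma_init.shape[0] + 1
    n_kc = _item_counts(item_data, np.asarray(posterior, dtype=float), None, ncat)
    N = float(posterior.shape[0])
    return _m_step_item_counts(
        n_kc, N, spec, gamma_init, eps if eps is not None else spec.smooth_eps
    )


def _total_penalty(params: ModelParams, spec: PenaltySpec,
                   smooth: bool = False, eps: Optional[float] = None) -> float:
    s = spec if (eps is None or spec.smooth_eps == eps) else spec.replace(smooth_eps=eps)
    return sum(fused_penalty(g, s, smooth=smooth) for g in params.gamma)


def _random_start(rng: np.random.Generator, n_categories: list[int],
                  C: int) -> ModelParams:
    lo, hi = np.log(0.2 / 0.8), np.log(0.8 / 0.2)
    gamma = [rng.uniform(lo, hi, size=(ncat - 1, C)) for ncat in n_categories]
    return ModelParams(gamma, np.zeros(C))


def _em_run(patterns, weights, n_categories, C, spec, init: ModelParams,
            max_iter, tol_obj, tol_gamma, refine: bool):
    N = float(weights.sum())
    params = init.copy()
    history: list[tuple[float, float]] = []  # (eps, smoothed objective)
    n_iter = 0
    converged = False
    phases = [spec.smooth_eps]
    if refine and REFINE_EPS < spec.smooth_eps:
        phases.append(REFINE_EPS)
    item_cols = [patterns[:, i] for i in range(patterns.shape[1])]
    for eps in phases:
        prev_obj = -np.inf
        converged = False
        for _ in range(max_iter):
            n_iter += 1
            post, lse = _posterior_from_patterns(patterns, params)
            loglik = float(weights @ lse)
            obj = loglik - N * _total_penalty(params, spec, smooth=True, eps=eps)
            history.append((eps, obj))
            wpost = post * weights[:, None]
            delta = m_step_class_probs(post, weights)
            max_dgamma = 0.0
            new_gamma = []
            for i, col in enumerate(item_cols):
                n_kc = np.zeros((n_categories[i], C))
                np.add.at(n_kc, col, wpost)
                g_new = _m_step_item_counts(n_kc, N, spec, params.gamma[i], eps)
                max_dgamma = max(max_dgamma, float(np.abs(g_new - params.gamma[i]).max()))
                new_gamma.append(g_new)
            params = ModelParams(new_gamma, delta)
            if abs(obj - prev_obj) < tol_obj and max_dgamma < tol_gamma:
                converged = True
                break
            prev_obj = obj
    return params, history, n_iter, converged


def fit(
    data: ResponseMatrix,
    C: int,
    spec: Optional[PenaltySpec] = None,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    tol_gamma: float = 1e-4,
    init_params: Optional[ModelParams] = None,
    fuse_tol: float = 0.01,
    refine: bool = True,
) -> FitResult:
    """Fit a (regularized) latent class model by penalized EM.

    Runs ``n_starts`` random starts (plus ``init_params`` as a warm start
    when given) and returns the solution with the best exact penalized
    objective.  Deterministic given ``seed``.

    Parameters
    ----------
    data, C:
        Responses and the number of latent classes.
    spec:
        Penalty specification; ``None`` or all-zero lambdas give the
        unpenalized exploratory LCM (closed-form M-steps).
    tol, tol_gamma:
        Convergence: successive smoothed penalized objectives within
        ``tol`` and max absolute logit change below ``tol_gamma``.
    fuse_tol:
        Threshold on logit differences for counting unique parameters.
    refine:
        Run the final phase at the tighter smoothing eps so fused
        parameters coincide numerically.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    if spec is None:
        spec = PenaltySpec(family="mcp", strategy="fused_classes",
                           lambda1=0.0, lambda2=0.0)
    patterns, weights, inverse = data.compress()
    if C > patterns.shape[0]:
        warnings.warn(
            f"C={C} exceeds the {patterns.shape[0]} distinct response patterns",
            RuntimeWarning,
        )
    ncats = list(data.n_categories)
    rng = np.random.default_rng(seed)
    inits: list[ModelParams] = []
    if init_params is not None:
        inits.append(init_params)
    n_random = max(n_starts - len(inits), 0) if init_params is not None else n_starts
    for _ in range(n_random):
        inits.append(_random_start(rng, ncats, C))

    best = None
    for s_idx, init in enumerate(inits):
        params, history, n_iter, converged = _em_run(
            patterns, weights, ncats, C, spec, init,
            max_iter, tol, tol_gamma, refine,
        )
        post, lse = _posterior_from_patterns(patterns, params)
        loglik = float(weights @ lse)
        pen_obj = loglik - float(weights.sum()) * _total_penalty(params, spec)
        if best is None or pen_obj > best[0]:
            best = (pen_obj, loglik, params, post, history, n_iter, converged, s_idx)

    pen_obj, loglik, params, post, history, n_iter, converged, s_idx = best
    from .selection import count_unique_params, information_criteria

    n_params, n_reg = count_unique_params(params, spec, fuse_tol=fuse_tol)
    aic, bic = information_criteria(loglik, n_params, data.N)
    return FitResult(
        params=params,
        loglik=loglik,
        penalized_objective=pen_obj,
        posterior=post[inverse],
        n_iter=n_iter,
        converged=converged,
        n_params=n_params,
        n_regularized=n_reg,
        aic=aic,
        bic=bic,
        spec=spec,
        n_obs=data.N,
        seed=seed,
        start_index=s_idx,
        objective_history=history,
    )
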