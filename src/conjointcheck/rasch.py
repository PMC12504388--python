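"""Conditional maximum likelihood (CML) Rasch estimation.

Item difficulties are estimated by maximizing the likelihood of the
response patterns conditional on person sum scores, which removes the
person parameters entirely (sum scores are sufficient for theta under the
Rasch model). The conditional likelihood's normalizing constants are the
elementary symmetric functions (ESFs) of the item easiness parameters
eps_j = exp(-b_j); both the gradient and the Hessian of the conditional
log-likelihood are ratios of ESFs, so Newton-Raphson converges in a
handful of iterations.

Person abilities are then estimated by maximum likelihood given the fixed
item difficulties. The ML ability estimate depends on the data only
through the sum score, so the score-to-ability map is computed once per
fit; abilities for zero and perfect scores (where the ML estimate is
infinite) are assigned by monotone cubic extrapolation of the interior
score-to-ability curve.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

from conjointcheck.datagen import PersonParams, ResponseMatrix

__all__ = ["RaschFit", "FitStats", "esf", "fit_difficulties_cml", "estimate_abilities_ml", "infit_outfit"]

logger = logging.getLogger(__name__)

GRAD_TOL = 1e-8
MAX_ITER = 100


@dataclass(frozen=True)
class RaschFit:
    """Result of a conditional ML Rasch calibration.

    difficulty_hat is sum-zero normalized (the conditional likelihood only
    identifies difficulty differences). theta_by_score maps every raw sum
    score 0..J to an ability estimate and is strictly increasing.
    """

    difficulty_hat: np.ndarray
    theta_by_score: dict[int, float]
    converged: bool
    loglik: float
    n_iter: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "difficulty_hat": self.difficulty_hat.tolist(),
                "theta_by_score": {str(s): t for s, t in self.theta_by_score.items()},
                "converged": self.converged,
                "loglik": self.loglik,
                "n_iter": self.n_iter,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "RaschFit":
        d = json.loads(text)
        return cls(
            difficulty_hat=np.asarray(d["difficulty_hat"], dtype=float),
            theta_by_score={int(s): float(t) for s, t in d["theta_by_score"].items()},
            converged=bool(d["converged"]),
            loglik=float(d["loglik"]),
            n_iter=int(d.get("n_iter", 0)),
        )


@dataclass(frozen=True)
class FitStats:
    """Infit/outfit mean-square item fit statistics (expectation 1 under the model)."""

    infit: np.ndarray
    outfit: np.ndarray


def esf(epsilon: np.ndarray) -> np.ndarray:
    """Elementary symmetric functions gamma_0..gamma_J of a positive vector.

    gamma_r sums the products of every r-subset of ``epsilon`` — equivalently
    the coefficients of prod_j (1 + eps_j t). Computed by the standard
    summation recursion, which is numerically stable for positive inputs.
    """
    eps = np.asarray(epsilon, dtype=float)
    if eps.ndim != 1:
        raise ValueError("epsilon must be a vector")
    if np.any(eps <= 0) or not np.all(np.isfinite(eps)):
        raise ValueError("epsilon entries must be positive and finite")
    g = np.zeros(eps.size + 1)
    g[0] = 1.0
    for k, e in enumerate(eps):
        g[1 : k + 2] = g[1 : k + 2] + e * g[: k + 1]
    return g


def _esf_leave_one_out(eps: np.ndarray) -> np.ndarray:
    """gamma^{(j)}: ESFs of eps with item j removed, for every j. Shape (J, J)."""
    J = eps.size
    out = np.empty((J, J))
    for j in range(J):
        out[j] = esf(np.delete(eps, j))
    return out


def _score_expectations(eps: np.ndarray, g: np.ndarray, g_loo: np.ndarray) -> np.ndarray:
    """pi[s, j] = P(item j correct | sum score s) for interior s = 1..J-1."""
    J = eps.size
    s = np.arange(1, J)
    # eps_j * gamma_{s-1}^{(j)} / gamma_s
    return eps[None, :] * g_loo[:, s - 1].T / g[s][:, None]


def _pairwise_expectations(eps: np.ndarray, g: np.ndarray) -> np.ndarray:
    """pi2[s, j, k] = P(items j and k both correct | score s), interior s; j != k."""
    J = eps.size
    s = np.arange(1, J)
    pi2 = np.zeros((J - 1, J, J))
    for j in range(J):
        rest = np.delete(eps, j)
        for k_idx, k in enumerate(range(j + 1, J)):
            g_jk = esf(np.delete(rest, j + k_idx))  # eps without items j and k
            kk = j + 1 + k_idx
            with np.errstate(invalid="ignore"):
                vals = eps[j] * eps[kk] * np.concatenate(([0.0], g_jk))[s - 1] / g[s]
            pi2[:, j, kk] = vals
            pi2[:, kk, j] = vals
    return pi2


def fit_difficulties_cml(data: ResponseMatrix, tol: float = GRAD_TOL, max_iter: int = MAX_ITER) -> RaschFit:
    """Estimate Rasch item difficulties by conditional maximum likelihood.

    Persons with zero or perfect sum scores carry no conditional information
    and contribute nothing. Raises if any item lacks both a correct and an
    incorrect response among interior-score persons (its difficulty would
    diverge), or if N < J.
    """
    X = data.X
    N, J = X.shape
    if N < J:
        raise ValueError(f"need at least as many persons ({N}) as items ({J})")
    scores = X.sum(axis=1)
    interior = (scores > 0) & (scores < J)
    Xi = X[interior]
    if Xi.shape[0] == 0:
        raise ValueError("no persons with interior sum scores")
    t = Xi.sum(axis=0).astype(float)  # item totals among interior persons
    n_int = Xi.shape[0]
    degenerate = np.flatnonzero((t == 0) | (t == n_int))
    if degenerate.size:
        labels = ", ".join(str(data.item_labels[j]) for j in degenerate)
        raise ValueError(
            f"item(s) {labels} have all-0 or all-1 responses among interior-score "
            "persons; difficulties are not estimable"
        )
    # counts of persons per interior score s = 1..J-1
    n_s = np.bincount(scores[interior], minlength=J + 1)[1:J].astype(float)

    b = np.log((n_int - t) / t)
    b -= b.mean()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eps = np.exp(-b)
        g = esf(eps)
        g_loo = _esf_leave_one_out(eps)
        pi = _score_expectations(eps, g, g_loo)  # (J-1, J)
        grad = -t + n_s @ pi
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        pi2 = _pairwise_expectations(eps, g)
        # observed (= expected given score counts) information matrix
        info = np.einsum("s,sjk->jk", n_s, pi2) - (pi.T * n_s) @ pi
        np.fill_diagonal(info, n_s @ (pi * (1.0 - pi)))
        # info is singular along the all-ones direction (translation invariance);
        # regularize there and project the step back to the sum-zero subspace
        info_reg = info + np.ones((J, J)) / J
        step = np.linalg.solve(info_reg, grad)
        step -= step.mean()
        max_step = np.max(np.abs(step))
        if max_step > 3.0:  # damp early wild steps
            step *= 3.0 / max_step
        b = b + step
        b -= b.mean()
    else:
        it = max_iter
    if not converged:
        # final gradient check in case the loop exited at max_iter
        eps = np.exp(-b)
        g = esf(eps)
        g_loo = _esf_leave_one_out(eps)
        grad = -t + n_s @ _score_expectations(eps, g, g_loo)
        converged = bool(np.linalg.norm(grad) < tol)
        if not converged:
            warnings.warn("CML Newton-Raphson did not converge", RuntimeWarning)
            logger.warning("CML did not converge: |grad| = %.3e after %d iterations", np.linalg.norm(grad), it)
    eps = np.exp(-b)
    loglik = float(-(t @ b) - n_s @ np.log(esf(eps)[1:J]))
    theta_by_score = _score_to_theta(b)
    return RaschFit(
        difficulty_hat=b,
        theta_by_score=theta_by_score,
        converged=converged,
        loglik=loglik,
        n_iter=it,
    )


def _score_to_theta(b: np.ndarray) -> dict[int, float]:
    """ML ability for each interior score; monotone cubic extrapolation at 0 and J."""
    J = b.size
    s = np.arange(1, J, dtype=float)
    theta = np.zeros(J - 1)
    # Newton on the score equation sum_j logistic(theta - b_j) = s (vectorized over s)
    for _ in range(100):
        p = expit(theta[:, None] - b[None, :])
        f = p.sum(axis=1) - s
        fp = (p * (1.0 - p)).sum(axis=1)
        delta = f / np.maximum(fp, 1e-12)
        theta -= np.clip(delta, -2.0, 2.0)
        if np.max(np.abs(f)) < 1e-10:
            break
    mapping = {int(si): float(ti) for si, ti in zip(s, theta)}
    if J - 1 >= 2:
        spline = PchipInterpolator(s, theta, extrapolate=True)
        t0, tJ = float(spline(0.0)), float(spline(float(J)))
    else:
        t0 = tJ = float("nan")
    # guard: extrapolation must preserve strict monotonicity of the score map
    if not np.isfinite(t0) or t0 >= theta[0]:
        t0 = theta[0] - (theta[1] - theta[0])
    if not np.isfinite(tJ) or tJ <= theta[-1]:
        tJ = theta[-1] + (theta[-1] - theta[-2])
    mapping[0] = t0
    mapping[J] = tJ
    return dict(sorted(mapping.items()))


def estimate_abilities_ml(fit: RaschFit, data: ResponseMatrix) -> PersonParams:
    """Map each person's sum score through the fit's score-to-ability table."""
    if not fit.converged:
        raise ValueError("Rasch fit did not converge; abilities would be unreliable")
    if data.j != fit.difficulty_hat.size:
        raise ValueError("response matrix and fit have different item counts")
    table = np.array([fit.theta_by_score[s] for s in range(data.j + 1)])
    return PersonParams(table[data.sum_scores])


def infit_outfit(data: ResponseMatrix, persons: PersonParams, fit: RaschFit) -> FitStats:
    """Mean-square residual fit statistics per item.

    With P_ij the Rasch probability at the estimates, W_ij = P_ij(1-P_ij)
    and R_ij = X_ij - P_ij:

        outfit_j = mean_i(R_ij^2 / W_ij)       (unweighted)
        infit_j  = sum_i R_ij^2 / sum_i W_ij   (information-weighted)

    Persons with extreme (zero/perfect) scores are excluded.
    """
    if persons.n != data.n:
        raise ValueError("persons and data have different lengths")
    scores = data.sum_scores
    keep = (scores > 0) & (scores < data.j)
    X = data.X[keep].astype(float)
    theta = persons.theta[keep]
    P = expit(theta[:, None] - fit.difficulty_hat[None, :])
    W = P * (1.0 - P)
    if np.any(W.sum(axis=0) <= 0):
        raise ValueError("zero total response variance for an item")
    R2 = (X - P) ** 2
    outfit = (R2 / W).mean(axis=0)
    infit = R2.sum(axis=0) / W.sum(axis=0)
    return FitStats(infit=infit, outfit=outfit)
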