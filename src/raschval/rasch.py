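"""Dichotomous Rasch measurement by conditional maximum likelihood (CML).

Item difficulties are estimated by maximising the likelihood of the responses
conditional on each person's raw score. Conditioning eliminates the person
parameters, so the estimates are consistent for a fixed number of items as the
sample grows. The normalising constants of the conditional likelihood are the
elementary symmetric functions (ESF) of the item easiness terms
``eps_i = exp(-beta_i)``; they are computed by the summation recursion in log
space for numerical stability.

Person abilities are Warm's weighted likelihood estimates (WLE), which remain
finite for perfect and zero raw scores — a requirement for person-separation
reliability, which needs an ability and a standard error for every respondent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import brentq

from .data_io import ResponseMatrix
from .errors import EstimationError, ValidationError

__all__ = [
    "ItemParameters",
    "PersonAbility",
    "elementary_symmetric",
    "log_esf",
    "fit_cml",
    "estimate_abilities",
    "expected_prob",
]


@dataclass
class ItemParameters:
    """Item difficulties in logits under a sum-to-zero constraint."""

    labels: list[str]
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_iterations: int
    constraint: str = "sum_to_zero"

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.beta))) > 1e-8:
            raise EstimationError(f"sum-to-zero constraint violated: sum(beta)={np.sum(self.beta)}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"label": self.labels, "beta": self.beta, "se": self.se})


@dataclass
class PersonAbility:
    """Per-person latent-trait estimates (logits) with standard errors."""

    theta: np.ndarray
    se: np.ndarray
    raw_score: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "person_id": np.arange(len(self.theta)),
                "raw_score": self.raw_score,
                "theta": self.theta,
                "se": self.se,
            }
        )


def expected_prob(theta, beta):
    """Rasch response function P(X=1) = 1 / (1 + exp(-(theta - beta)))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(theta, float) - np.asarray(beta, float))))


def log_esf(log_eps: np.ndarray) -> np.ndarray:
    """Log elementary symmetric functions of terms given on the log scale.

    Returns ``log gamma_0 .. log gamma_k`` where ``gamma_r`` is the sum over
    all r-subsets of the products of the terms. Uses the summation recursion
    gamma^{(m)}(x) = gamma^{(m-1)}(x) * (1 + eps_m x) entirely in log space.
    """
    log_eps = np.asarray(log_eps, float)
    k = log_eps.size
    lg = np.full(k + 1, -np.inf)
    lg[0] = 0.0
    for m in range(k):
        lg[1 : m + 2] = np.logaddexp(lg[1 : m + 2], lg[0 : m + 1] + log_eps[m])
    return lg


def elementary_symmetric(eps: np.ndarray) -> np.ndarray:
    """Elementary symmetric polynomials gamma_0..gamma_k of positive terms."""
    eps = np.asarray(eps, float)
    if np.any(eps <= 0) or not np.all(np.isfinite(eps)):
        raise ValidationError("all easiness terms must be positive and finite")
    return np.exp(log_esf(np.log(eps)))


def _esf_brute_force(eps: np.ndarray) -> np.ndarray:
    """Enumerate all item subsets; oracle for small k (tests only)."""
    eps = np.asarray(eps, float)
    k = eps.size
    out = np.zeros(k + 1)
    out[0] = 1.0
    for r in range(1, k + 1):
        out[r] = sum(np.prod(eps[list(c)]) for c in combinations(range(k), r))
    return out


def _conditional_item_probs(log_eps: np.ndarray) -> np.ndarray:
    """P(X_i = 1 | raw score r) for each item i and r = 0..k.

    pi[i, r] = eps_i * gamma_{r-1}^{(i)} / gamma_r, where gamma^{(i)} are the
    ESF of the items without item i.
    """
    k = log_eps.size
    lg = log_esf(log_eps)
    pi = np.zeros((k, k + 1))
    for i in range(k):
        lg_i = log_esf(np.delete(log_eps, i))
        with np.errstate(invalid="ignore"):
            pi[i, 1:] = np.exp(log_eps[i] + lg_i[: k] - lg[1:])
    pi[:, k] = 1.0
    return pi


def _conditional_pair_probs(log_eps: np.ndarray) -> np.ndarray:
    """P(X_i = 1, X_j = 1 | raw score r) for i != j; shape (k, k, k+1)."""
    k = log_eps.size
    lg = log_esf(log_eps)
    pp = np.zeros((k, k, k + 1))
    for i in range(k):
        for j in range(i + 1, k):
            lg_ij = log_esf(np.delete(log_eps, (i, j)))
            vals = np.zeros(k + 1)
            vals[2:] = np.exp(log_eps[i] + log_eps[j] + lg_ij[: k - 1] - lg[2:])
            pp[i, j] = pp[j, i] = vals
    return pp


def fit_cml(
    data: ResponseMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ItemParameters:
    """Calibrate item difficulties by conditional maximum likelihood.

    Persons with extreme raw scores (0 or all items) carry no information
    about the item parameters and are excluded. Identification is by
    sum-to-zero on the difficulties; Newton-Raphson iterates on a basis of the
    sum-to-zero subspace until the projected gradient norm falls below `tol`.
    Standard errors come from the observed conditional information matrix.
    """
    x = data.responses
    k = data.n_items
    if k < 2:
        raise ValidationError("need at least 2 items for calibration")
    r = x.sum(axis=1)
    nonextreme = (r > 0) & (r < k)
    xs = x[nonextreme]
    if xs.shape[0] == 0:
        raise EstimationError("no non-extreme persons: item parameters inestimable")
    s = xs.sum(axis=0).astype(float)  # item scores
    n_r = np.bincount(xs.sum(axis=1), minlength=k + 1).astype(float)  # score counts
    for i, si in enumerate(s):
        if si == 0 or si == xs.shape[0]:
            raise EstimationError(
                f"item {data.item_labels[i]!r} has no variation among non-extreme "
                "persons; difficulty inestimable"
            )

    p = s / xs.shape[0]
    beta = np.log((1 - p) / p)
    beta -= beta.mean()
    Z = null_space(np.ones((1, k)))  # k x (k-1) orthonormal basis of sum-zero subspace

    def neg_condloglik(b):
        lg = log_esf(-b)
        return float(np.dot(s, b) + np.dot(n_r[1:k], lg[1:k]))

    nll = neg_condloglik(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_eps = -beta
        pi = _conditional_item_probs(log_eps)  # (k, k+1)
        # gradient of the conditional log-likelihood wrt beta
        grad = -s + pi[:, 1:k] @ n_r[1:k]
        pg = Z.T @ grad
        if np.linalg.norm(pg) < tol:
            converged = True
            break
        pp = _conditional_pair_probs(log_eps)
        # observed conditional information: score-conditional covariance of the item vector
        info = np.einsum("ijr,r->ij", pp[:, :, 1:k], n_r[1:k])
        info -= np.einsum("ir,jr,r->ij", pi[:, 1:k], pi[:, 1:k], n_r[1:k])
        np.fill_diagonal(info, (pi[:, 1:k] * (1 - pi[:, 1:k])) @ n_r[1:k])
        step = Z @ np.linalg.solve(Z.T @ info @ Z, pg)
        # damped Newton: halve until the conditional likelihood improves
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            cand -= cand.mean()
            new_nll = neg_condloglik(cand)
            if new_nll <= nll + 1e-12:
                beta, nll = cand, new_nll
                break
            lam /= 2.0
        else:
            raise EstimationError(f"line search failed at iteration {it}")
    if not converged:
        raise EstimationError(
            f"CML did not converge in {max_iter} iterations; gradient norm "
            f"{np.linalg.norm(Z.T @ grad):.3e}"
        )

    pi = _conditional_item_probs(-beta)
    pp = _conditional_pair_probs(-beta)
    info = np.einsum("ijr,r->ij", pp[:, :, 1:k], n_r[1:k])
    info -= np.einsum("ir,jr,r->ij", pi[:, 1:k], pi[:, 1:k], n_r[1:k])
    np.fill_diagonal(info, (pi[:, 1:k] * (1 - pi[:, 1:k])) @ n_r[1:k])
    cov = Z @ np.linalg.inv(Z.T @ info @ Z) @ Z.T
    se = np.sqrt(np.diag(cov))
    return ItemParameters(
        labels=list(data.item_labels),
        beta=beta - beta.mean(),
        se=se,
        converged=True,
        n_iterations=it,
    )


def _wle_for_score(r: int, beta: np.ndarray) -> tuple[float, float]:
    """Solve Warm's weighted likelihood equation for one raw score."""

    def score_fn(theta):
        p = expected_prob(theta, beta)
        w = p * (1 - p)
        info = w.sum()
        j = (w * (1 - 2 * p)).sum()
        return r - p.sum() + j / (2 * info)

    theta = brentq(score_fn, -30.0, 30.0, xtol=1e-10)
    p = expected_prob(theta, beta)
    info = (p * (1 - p)).sum()
    return theta, 1.0 / np.sqrt(info)


def estimate_abilities(data: ResponseMatrix, items: ItemParameters) -> PersonAbility:
    """Warm weighted-likelihood person estimates with asymptotic SEs.

    In the Rasch model the raw score is sufficient for ability, so the
    equation is solved once per observed score and mapped back to persons.
    The WLE bias-correction term keeps estimates finite at scores 0 and k.
    """
    if not items.converged:
        raise EstimationError("item parameters not converged")
    r = data.raw_scores()
    table = {int(s): _wle_for_score(int(s), items.beta) for s in np.unique(r)}
    theta = np.array([table[int(s)][0] for s in r])
    se = np.array([table[int(s)][1] for s in r])
    return PersonAbility(theta=theta, se=se, raw_score=r.astype(int))
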