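"""Marginal likelihood, BIC model selection and analytic error bars.

The number of processes ``n`` is chosen by fitting each candidate,
integrating the latent activities out of the likelihood with a Laplace
(saddle-point) approximation, and maximizing the Bayesian information
criterion

    BIC = 2 log P(X | mu_hat) - n (Nc - 1) log M,

where ``n (Nc - 1)`` counts the free signature parameters (each row
lives on the 95-simplex) and M is the number of tumors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .em_core import FitResult, estep, fit, poisson_loglik

__all__ = [
    "ModelScore",
    "saddlepoint_loglik",
    "bic",
    "select_n",
    "signature_uncertainty",
]

_LOG2PI = np.log(2.0 * np.pi)


def _sample_saddle(
    X_m: np.ndarray,
    omega_m: np.ndarray,
    mu: np.ndarray,
    *,
    include_constant: bool,
    active_rel: float = 1e-8,
    jitter_rel: float = 1e-10,
) -> float:
    """Laplace approximation of log of the marginal over one tumor's activities."""
    x_hat = estep(X_m, omega_m, mu)
    L_hat = -poisson_loglik(X_m, x_hat, omega_m, mu, include_constant=include_constant)
    active = x_hat > active_rel * x_hat.sum()
    d = int(active.sum())
    if d == 0:
        return -L_hat
    G = (mu * omega_m[None, :])[active]
    lam = x_hat @ (mu * omega_m[None, :])
    lam_floor = np.maximum(lam, 1e-130 * max(float(lam.max()), 1e-130))
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(lam > 0, X_m / lam_floor**2, 0.0)
    H = (G * w[None, :]) @ G.T
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(logdet):
        jitter = jitter_rel * max(np.trace(H), 1e-300)
        warnings.warn(
            f"singular activity Hessian; adding jitter {jitter:.2e}", RuntimeWarning
        )
        sign, logdet = np.linalg.slogdet(H + jitter * np.eye(d))
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError(
                "activity Hessian is singular after active-set reduction"
            )
    return 0.5 * d * _LOG2PI - L_hat - 0.5 * logdet


def saddlepoint_loglik(
    X: np.ndarray,
    omega: np.ndarray,
    mu_hat: np.ndarray,
    *,
    include_constant: bool = True,
) -> float:
    """Total data log-likelihood with activities integrated out.

    For each tumor the integral of the conditional likelihood over the
    non-negative activity orthant is approximated at its interior
    maximum ``x_hat`` by

        (d/2) log 2pi - L(x_hat) - 1/2 log det H(L)(x_hat),

    where ``L`` is the negative conditional log-likelihood, ``H`` its
    Hessian, and ``d`` the number of strictly positive activity
    components (zero components lie on the boundary and are dropped
    from the integration dimension).
    """
    X = np.asarray(X, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
        omega = omega[None, :]
    return float(
        sum(
            _sample_saddle(X[m], omega[m], mu_hat, include_constant=include_constant)
            for m in range(X.shape[0])
        )
    )


def bic(loglik: float, n: int, Nc: int, M: int) -> float:
    """Bayesian information criterion: ``2 loglik - n (Nc-1) log M``."""
    if M < 1 or n < 1 or Nc < 1:
        raise ValueError("need M >= 1, n >= 1, Nc >= 1")
    return 2.0 * loglik - n * (Nc - 1) * np.log(M)


@dataclass
class ModelScore:
    """Score of one candidate number of processes."""

    n: int
    loglik_saddle: float
    bic: float
    fit: FitResult


@dataclass
class SelectionResult:
    scores: list[ModelScore]
    chosen: ModelScore

    @property
    def chosen_n(self) -> int:
        return self.chosen.n


def select_n(
    X: np.ndarray,
    omega: np.ndarray,
    n_range,
    *,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = 0,
    include_constant: bool = True,
) -> SelectionResult:
    """Scan candidate process numbers and pick the BIC maximiser.

    Each candidate ``n`` is fitted by multi-restart EM and scored with
    the saddle-point BIC. Ties are broken toward the smaller ``n``
    (parsimony). Candidates whose fit or scoring fails are dropped with
    a warning; if all fail, an error is raised.
    """
    X = np.asarray(X, dtype=float)
    omega = np.asarray(omega, dtype=float)
    n_range = list(n_range)
    if not n_range:
        raise ValueError("n_range is empty")
    M, Nc = X.shape
    scores: list[ModelScore] = []
    for n in n_range:
        try:
            res = fit(
                X, omega, n, restarts=restarts, tol=tol, max_iter=max_iter,
                seed=seed, include_constant=include_constant,
            )
            ll = saddlepoint_loglik(
                X, omega, res.mu, include_constant=include_constant
            )
            scores.append(ModelScore(n, ll, bic(ll, n, Nc, M), res))
        except Exception as exc:  # noqa: BLE001 - candidate dropped, scan continues
            warnings.warn(f"candidate n={n} failed and was dropped: {exc}", RuntimeWarning)
    if not scores:
        raise RuntimeError("model selection failed for every candidate n")
    chosen = min(scores, key=lambda s: (-s.bic, s.n))
    return SelectionResult(scores, chosen)


def signature_uncertainty(
    X: np.ndarray,
    omega: np.ndarray,
    fit_result: FitResult,
) -> np.ndarray:
    """Analytic standard errors for the fitted signature entries.

    Uses the observed information of the conditional log-likelihood in
    ``mu`` with activities held at their estimates. Within one process
    the information matrix over channels is diagonal,

        I_aj = sum_m X_j^m (x_a^m omega_j^m)^2 / (lambda_j^m)^2,

    and is projected onto the tangent space of the row simplex before
    (pseudo-)inversion, which accounts for the sum-to-one constraint.
    Channels that carry no information (zero expected counts under all
    tumors) get NaN errors and trigger a warning.
    """
    X = np.asarray(X, dtype=float)
    omega = np.asarray(omega, dtype=float)
    mu, x = fit_result.mu, fit_result.x
    n, Nc = mu.shape
    lam = (x @ mu) * omega
    lam_floor = np.maximum(lam, 1e-130 * max(float(lam.max()), 1e-130))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(lam > 0, X / lam_floor**2, 0.0)
    se = np.full((n, Nc), np.nan)
    warned = False
    for a in range(n):
        info = ((x[:, a][:, None] * omega) ** 2 * r).sum(axis=0)  # (Nc,)
        ok = info > 0
        k = int(ok.sum())
        if k < 2:
            warned = True
            continue
        P = np.eye(k) - np.full((k, k), 1.0 / k)
        cov = np.linalg.pinv(P @ np.diag(info[ok]) @ P, hermitian=True)
        se[a, ok] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if k < Nc:
            warned = True
    if warned:
        warnings.warn(
            "some channels carry no information; their errors are NaN", RuntimeWarning
        )
    return se
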