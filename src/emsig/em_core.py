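"""Poisson generative model of mutation counts and its EM inference.

Model
-----
For tumor ``m`` the count in channel ``j`` is Poisson with intensity

    lambda_j^m = sum_a  x_a^m * mu_aj * omega_j^m,

where ``mu`` (n x 96, rows on the simplex) are the signatures of the n
elementary mutational processes, ``x`` (M x n, non-negative) their
per-tumor activities, and ``omega`` (M x 96) the per-tumor mutational
opportunity. Signatures and activities are estimated by EM:

* E-step — per tumor, maximise the conditional Poisson log-likelihood
  over the activity vector on the non-negative orthant (a convex
  problem), optionally augmented with a pseudocount prior.
* M-step — update the signatures under the row-simplex constraint.

Both steps use minorize-maximise (KL-NMF style) updates, which provably
never decrease the joint likelihood; the E-step is finished by a damped
Newton polish on log-activities for tight KKT residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .channels import N_CHANNELS

__all__ = [
    "FitResult",
    "poisson_loglik",
    "total_loglik",
    "pseudocounts",
    "estep",
    "mstep",
    "fit",
]

_TINY = 1e-300


def _as_2d(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {out.shape}")
    return out


def _check_mu(mu: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    mu = _as_2d(mu, "mu")
    if (mu < 0).any():
        raise ValueError("signature matrix has negative entries")
    sums = mu.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=tol):
        raise ValueError("signature rows must sum to 1")
    return mu


def poisson_loglik(
    X_m: np.ndarray,
    x: np.ndarray,
    omega: np.ndarray,
    mu: np.ndarray,
    *,
    include_constant: bool = True,
) -> float:
    """Log-likelihood of one tumor's channel counts under the model.

    Returns ``sum_j [X_j log lambda_j - lambda_j - log X_j!]`` with
    ``lambda_j = sum_a x_a mu_aj omega_j`` and the convention
    ``0*log 0 = 0``. The ``log X_j!`` constant can be dropped (it does
    not depend on the parameters); inclusion is the default so that the
    value is a true log-probability.
    """
    X_m = np.asarray(X_m, dtype=float)
    x = np.asarray(x, dtype=float)
    omega = np.asarray(omega, dtype=float)
    mu = _check_mu(mu)
    if (x < 0).any():
        raise ValueError("activities must be non-negative")
    if ((omega == 0) & (X_m > 0)).any():
        raise ValueError("channel with zero opportunity has nonzero counts")
    lam = (x @ mu) * omega
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X_m > 0, X_m * np.log(np.maximum(lam, _TINY)), 0.0)
    if (lam[X_m > 0] == 0).any():
        return -np.inf
    out = float(term.sum() - lam.sum())
    if include_constant:
        out -= float(gammaln(X_m + 1).sum())
    return out


def total_loglik(X, x, omega, mu, *, include_constant: bool = True) -> float:
    """Sum of :func:`poisson_loglik` over all tumors (vectorized)."""
    X = _as_2d(X, "X")
    x = _as_2d(x, "x")
    omega = _as_2d(omega, "omega")
    lam = (x @ mu) * omega
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X > 0, X * np.log(np.maximum(lam, _TINY)), 0.0)
    if (lam[X > 0] == 0).any():
        return -np.inf
    out = float(term.sum() - lam.sum())
    if include_constant:
        out -= float(gammaln(X + 1).sum())
    return out


def pseudocounts(
    mu: np.ndarray,
    omega_m: np.ndarray,
    prior_activities: np.ndarray | None = None,
) -> np.ndarray:
    """Pseudocount table regularizing the activity estimate of one tumor.

    ``n`` synthetic counts are spread over the (process, channel) cells
    in proportion to prior weight times spectrum times opportunity:

        Xt_aj = n * w_a * mu_aj * omega_j / sum_b w_b (mu.omega)_b

    With ``prior_activities=None`` all weights are 1 (the uninformed
    prior used for the global fit); passing the globally inferred
    activities gives the informed prior used for per-window inference.
    The table always sums to ``n``, the number of processes.
    """
    mu = _check_mu(mu)
    omega_m = np.asarray(omega_m, dtype=float)
    n = mu.shape[0]
    w = np.ones(n) if prior_activities is None else np.asarray(prior_activities, float)
    if (w < 0).any():
        raise ValueError("prior activities must be non-negative")
    G = mu * omega_m[None, :]
    denom = float((w * G.sum(axis=1)).sum())
    if denom <= 0:
        raise ValueError("prior has zero mass: all w_a * (mu.omega)_a are zero")
    return n * w[:, None] * G / denom


def _estep_objective(x, X_m, G, A, pt_rowsum):
    """Penalized negative log-likelihood (constants dropped)."""
    lam = x @ G
    with np.errstate(divide="ignore"):
        term = np.where(X_m > 0, X_m * np.log(np.maximum(lam, _TINY)), 0.0)
    if (lam[X_m > 0] == 0).any():
        return np.inf
    obj = lam.sum() - term.sum()
    if pt_rowsum is not None:
        pos = pt_rowsum > 0
        if (x[pos] == 0).any():
            return np.inf
        obj -= float((pt_rowsum[pos] * np.log(x[pos])).sum())
    return float(obj)


def estep(
    X_m: np.ndarray,
    omega_m: np.ndarray,
    mu: np.ndarray,
    pseudocounts: np.ndarray | None = None,
    *,
    tol: float = 1e-9,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Maximum (penalized) likelihood activities for one tumor.

    Minimises ``sum_j [lambda_j - X_j log lambda_j] - sum_a Xt_a log x_a``
    over the non-negative orthant, where ``Xt_a`` are the row sums of the
    optional pseudocount table. The objective is convex, so the optimum
    is unique up to flat directions; multiplicative updates are run to a
    small KKT residual and polished by damped Newton steps on
    log-activities.
    """
    X_m = np.asarray(X_m, dtype=float)
    omega_m = np.asarray(omega_m, dtype=float)
    mu = _check_mu(mu)
    if ((omega_m == 0) & (X_m > 0)).any():
        raise ValueError("channel with zero opportunity has nonzero counts")

    n = mu.shape[0]
    G = mu * omega_m[None, :]  # (n, Nc) per-channel emission rates at unit activity
    A = G.sum(axis=1)
    pt = None
    if pseudocounts is not None:
        pt = np.asarray(pseudocounts, dtype=float).sum(axis=1)

    live = A > 0
    if not live.any():
        return np.zeros(n)
    scale = max(A[live].max(), _TINY)
    ktol = tol * scale

    x = np.full(n, (X_m.sum() + (0.0 if pt is None else pt.sum())) / max(n, 1))
    x = np.where(live, x / np.maximum(A, _TINY), 0.0)
    x[live & (x <= 0)] = 1.0

    def grad(xv, lam):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(X_m > 0, X_m / _safe_lam(lam), 0.0)
        g = A - G @ ratio
        if pt is not None:
            g = g - pt / np.maximum(xv, _TINY)
        return g

    def kkt_ok(xv, g):
        act = xv > 1e-10 * max(xv.max(), 1.0)
        if (np.abs(g[act & live]) > ktol).any():
            return False
        return not (g[~act & live] < -ktol).any()

    converged = False
    for sweep in range(max_iter // 500 + 1):
        for _ in range(500):
            lam = x @ G
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(X_m > 0, X_m / _safe_lam(lam), 0.0)
            num = x * (G @ ratio)
            if pt is not None:
                num = num + pt
            x = np.where(live, num / np.maximum(A, _TINY), 0.0)
        g = grad(x, x @ G)
        if not np.isfinite(g).all():
            raise FloatingPointError("non-finite E-step objective gradient")
        if kkt_ok(x, g):
            converged = True
            break
        if sweep >= 1:  # after warm-up, try Newton on the active set
            x = _newton_polish(x, X_m, G, A, pt, live)
            g = grad(x, x @ G)
            if kkt_ok(x, g):
                converged = True
                break
    if not converged:
        warnings.warn("E-step did not reach the KKT tolerance", RuntimeWarning)
    return x


def _newton_polish(x, X_m, G, A, pt, live, iters: int = 30):
    """Damped Newton steps in log-activity space on the active set."""
    x = x.copy()
    f0 = _estep_objective(x, X_m, G, A, pt)
    for _ in range(iters):
        act = np.where(live & (x > 1e-12 * max(x.max(), 1.0)))[0]
        if act.size == 0:
            break
        xa = x[act]
        Ga = G[act]
        lam = x @ G
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(X_m > 0, X_m / _safe_lam(lam), 0.0)
        g = A[act] - Ga @ ratio
        if pt is not None:
            g = g - pt[act] / xa
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(lam > 0, X_m / _safe_lam(lam) ** 2, 0.0)
        H = (Ga * w[None, :]) @ Ga.T
        if pt is not None:
            H = H + np.diag(pt[act] / xa**2)
        # transform to z = log x: Hz = D H D + diag(x*g)
        Hz = (xa[:, None] * H * xa[None, :]) + np.diag(xa * g)
        gz = xa * g
        try:
            step = np.linalg.solve(Hz + 1e-12 * np.trace(Hz) / act.size * np.eye(act.size), gz)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -10, 10)
        improved = False
        t = 1.0
        for _bt in range(25):
            trial = x.copy()
            trial[act] = xa * np.exp(-t * step)
            f1 = _estep_objective(trial, X_m, G, A, pt)
            if f1 <= f0:
                x, f0, improved = trial, f1, True
                break
            t *= 0.5
        if not improved or np.abs(gz).max() < 1e-14 * max(A.max(), 1.0):
            break
    return x


def _safe_lam(lam: np.ndarray) -> np.ndarray:
    """Floor intensities away from zero without denormal underflow.

    The floor is relative to the largest intensity so that ratios
    ``X/lam`` and curvature weights ``X/lam**2`` stay finite even for
    channels whose fitted rate collapsed to (numerical) zero.
    """
    top = float(lam.max()) if lam.size else 0.0
    return np.maximum(lam, 1e-150 * max(top, 1e-150))


def _mu_update(
    c: np.ndarray, d: np.ndarray, kappa0: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise maximiser of sum_j c_j log mu_j - d_j mu_j on the simplex.

    Solved exactly through the Lagrange multiplier: mu_j = c_j/(d_j+k)
    with k the root of f(k) = sum_j c_j/(d_j+k) - 1 = 0, found by
    safeguarded (bracketed) Newton, vectorized over rows; ``kappa0``
    warm-starts the iteration. Rows with all c_j = 0 come back uniform.
    Returns (mu, kappa).
    """
    c = np.atleast_2d(c)
    d = np.atleast_2d(d)
    n, Nc = c.shape
    pos = c > 0
    any_pos = pos.any(axis=1)
    S = c.sum(axis=1)
    d_masked = np.where(pos, d, np.inf)
    dmin = np.where(any_pos, d_masked.min(axis=1), 0.0)
    # f is +inf at the pole k -> -dmin and <= 0 at k = S - dmin
    lo = -dmin
    hi = S - dmin
    span = np.maximum(hi - lo, 1e-300)
    a = lo + 1e-14 * span  # bracket with f(a) > 0 (near the pole)
    b = hi.copy()
    kappa = np.clip(S - (c * np.where(pos, d, 0.0)).sum(axis=1) / np.maximum(S, _TINY),
                    lo + 1e-8 * span, hi)
    if kappa0 is not None:
        ok0 = np.isfinite(kappa0) & (kappa0 > a) & (kappa0 < b)
        kappa = np.where(ok0, kappa0, kappa)

    for _ in range(100):
        denom = d_masked + kappa[:, None]
        terms = np.where(pos, c / np.maximum(denom, _TINY), 0.0)
        f = terms.sum(axis=1) - 1.0
        done = (np.abs(f) < 1e-12) | (b - a < 1e-13 * span) | ~any_pos
        if done.all():
            break
        # keep the bracket: f decreasing in kappa
        shrink = f > 0
        a = np.where(shrink & any_pos, np.maximum(a, kappa), a)
        b = np.where(~shrink & any_pos, np.minimum(b, kappa), b)
        fp = -(np.where(pos, terms / np.maximum(denom, _TINY), 0.0)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            newton = kappa - f / fp
        bad = ~np.isfinite(newton) | (newton <= a) | (newton >= b)
        kappa = np.where(bad, 0.5 * (a + b), newton)
    mu = np.where(pos, c / np.maximum(d_masked + kappa[:, None], _TINY), 0.0)
    mu = np.maximum(mu, 0.0)
    sums = mu.sum(axis=1)
    uniform = ~any_pos | (sums <= 0)
    mu[uniform] = 1.0 / Nc
    sums = mu.sum(axis=1)
    return mu / sums[:, None], kappa


def mstep(
    X: np.ndarray,
    x_hat: np.ndarray,
    omega: np.ndarray,
    *,
    mu_init: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> np.ndarray:
    """Update the signature matrix given fixed activities.

    Maximises ``sum_m log P(X^m | x_hat^m, omega^m, mu)`` over
    row-stochastic ``mu`` by iterated minorize-maximise: allocate
    each channel's counts to processes by responsibility, then solve the
    resulting simplex-constrained weighted problem exactly per row.
    A process with zero total activity carries no information; its row
    is reset to uniform with a warning.
    """
    X = _as_2d(X, "X")
    x_hat = _as_2d(x_hat, "x_hat")
    omega = _as_2d(omega, "omega")
    M, n = x_hat.shape
    mu = (
        np.full((n, X.shape[1]), 1.0 / X.shape[1])
        if mu_init is None
        else _check_mu(mu_init).copy()
    )

    dead = x_hat.sum(axis=0) <= 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} process(es) with zero total activity reset to uniform",
            RuntimeWarning,
        )

    d = x_hat.T @ omega  # (n, Nc)
    prev = -np.inf
    kappa = None
    for _ in range(max_iter):
        lam = (x_hat @ mu) * omega
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(X > 0, X / _safe_lam(lam), 0.0)
        c = mu * (x_hat.T @ (ratio * omega))
        mu, kappa = _mu_update(c, d, kappa)  # all-zero c rows (dead) come back uniform
        obj = total_loglik(X, x_hat, omega, mu, include_constant=False)
        if np.isfinite(prev) and abs(obj - prev) <= tol * (abs(obj) + 1.0):
            break
        prev = obj
    return mu


@dataclass
class FitResult:
    """Outcome of one multi-restart EM fit."""

    mu: np.ndarray  # (n, Nc) signatures, rows on the simplex
    x: np.ndarray  # (M, n) activities
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    restart: int
    seed: int | None
    include_constant: bool = True
    restart_logliks: list[float] = field(default_factory=list)

    @property
    def n_processes(self) -> int:
        return self.mu.shape[0]


def fit(
    X: np.ndarray,
    omega: np.ndarray,
    n: int,
    *,
    restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = 0,
    include_constant: bool = True,
) -> FitResult:
    """Fit ``n`` mutational processes to a count matrix by multi-restart EM.

    Each restart draws initial signature rows from a symmetric
    Dirichlet(1) (seeded per restart), then alternates activity and
    signature minorize-maximise updates until the relative change of the
    total log-likelihood drops below ``tol`` or ``max_iter`` sweeps.
    The restart with the highest final likelihood is returned; process
    labels are arbitrary (no ordering across restarts is attempted).
    """
    X = _as_2d(X, "X")
    omega = _as_2d(omega, "omega")
    if X.shape != omega.shape:
        raise ValueError("count and opportunity matrices must share a shape")
    if ((omega == 0) & (X > 0)).any():
        raise ValueError("channel with zero opportunity has nonzero counts")
    if n < 1 or restarts < 1:
        raise ValueError("need n >= 1 and restarts >= 1")

    M, Nc = X.shape
    const = -float(gammaln(X + 1).sum()) if include_constant else 0.0
    best: FitResult | None = None
    restart_lls: list[float] = []
    for r in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, r]))
        mu = rng.dirichlet(np.ones(Nc), size=n)
        mu = np.maximum(mu, 1e-12)
        mu /= mu.sum(axis=1, keepdims=True)
        A = omega @ mu.T  # (M, n)
        x = (X.sum(axis=1)[:, None] / n) / np.maximum(A, _TINY)

        trace = []
        prev = -np.inf
        converged = False
        it = 0
        kappa = None
        for it in range(1, max_iter + 1):
            lam = (x @ mu) * omega
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(X > 0, X / _safe_lam(lam), 0.0)
            # activity update (per-sample multiplicative step)
            x = x * ((ratio * omega) @ mu.T) / np.maximum(omega @ mu.T, _TINY)
            # signature update (one exact surrogate step)
            lam = (x @ mu) * omega
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(X > 0, X / _safe_lam(lam), 0.0)
            c = mu * (x.T @ (ratio * omega))
            d = x.T @ omega
            mu, kappa = _mu_update(c, d, kappa)
            # convergence is judged on the parameter-dependent part so the
            # trajectory does not depend on whether the constant is reported
            ll_work = total_loglik(X, x, omega, mu, include_constant=False)
            trace.append(ll_work + const)
            if np.isfinite(prev) and abs(ll_work - prev) <= tol * (abs(ll_work) + 1.0):
                converged = True
                break
            prev = ll_work
        ll_final = trace[-1]
        restart_lls.append(ll_final)
        if best is None or ll_final > best.loglik:
            best = FitResult(
                mu=mu.copy(),
                x=x.copy(),
                loglik=ll_final,
                loglik_trace=np.asarray(trace),
                converged=converged,
                n_iter=it,
                restart=r,
                seed=seed,
                include_constant=include_constant,
            )
    assert best is not None
    best.restart_logliks = restart_lls
    if not best.converged:
        warnings.warn("no EM restart converged; returning the best found", RuntimeWarning)
    return best
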