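"""Clustering statistics: dispersion indices, signed window P-value
tracks (kataegis detection) and per-region process enrichment.

The null model throughout is that a process distributes its mutations
over the genome according to a globally uniform activity modulated only
by the local mutational opportunity. Expected per-window counts are
rescaled to the observed total per (sample, process), so the tests are
conditional on that total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

__all__ = [
    "expected_local_counts",
    "dispersion_index",
    "window_pvalues",
    "bonferroni_threshold",
    "region_enrichment",
    "RegionEnrichment",
]

SCORE_CAP = 20.0


def expected_local_counts(
    global_activities: np.ndarray,
    mu_hat: np.ndarray,
    window_omegas: np.ndarray,
) -> np.ndarray:
    """Null expected counts per (window, process).

    Under uniform activity, process a is expected to put
    ``x_a * (mu_a . omega^l)`` mutations into window l (up to the
    overall rescaling applied by the statistics below).
    """
    x = np.asarray(global_activities, dtype=float)
    window_omegas = np.asarray(window_omegas, dtype=float)
    return (window_omegas @ mu_hat.T) * x[None, :]


def dispersion_index(counts: np.ndarray, expected: np.ndarray) -> float:
    """Opportunity-corrected index of dispersion of per-window counts.

    Expected counts are rescaled so their sum matches the observed sum,
    then the variance-to-mean ratio of the standardized counts is
    computed over the windows with positive expectation:

        D = sum_l (c_l - e_l)^2 / e_l  /  (N' - 1).

    Under a homogeneous Poisson null D is ~1; values well above 1
    indicate clustering of mutations beyond the opportunity profile.
    Returns NaN when fewer than two usable windows exist.
    """
    c = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if (e < 0).any():
        raise ValueError("expected counts must be non-negative")
    if e.sum() <= 0:
        return float("nan")
    e = e * (c.sum() / e.sum())
    ok = e > 0
    if ok.sum() < 2:
        return float("nan")
    return float(((c[ok] - e[ok]) ** 2 / e[ok]).sum() / (ok.sum() - 1))


def window_pvalues(
    counts: np.ndarray,
    expected: np.ndarray,
    *,
    cap: float = SCORE_CAP,
    rescale: bool = False,
) -> pd.DataFrame:
    """Signed per-window clustering scores against the opportunity null.

    Per window, the one-sided Poisson tail probability in the direction
    of the deviation is computed: the upper tail P(N >= c) for a
    surplus, the lower tail P(N <= c) for a deficit. The score is the
    signed -log10 P, capped at +-``cap``; positive scores mark a
    surplus of mutations. Windows with zero expectation but observed
    counts get the capped positive score and are flagged.

    With ``rescale=True`` the expectations are first rescaled so their
    sum matches the observed total, making the test conditional on that
    total (the usual mode when the expectations come straight from
    global activity x window opportunity).
    """
    c = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if rescale and e.sum() > 0:
        e = e * (c.sum() / e.sum())
    p = np.ones_like(c)
    score = np.zeros_like(c)
    flag = np.zeros(c.shape, dtype=bool)
    surplus = c >= e
    with np.errstate(divide="ignore"):
        p_up = poisson.sf(c - 1, e)
        p_dn = poisson.cdf(c, e)
        p = np.where(surplus, p_up, p_dn)
        zero_e = (e == 0) & (c > 0)
        p[zero_e] = 0.0
        flag[zero_e] = True
        logp = np.where(p > 0, -np.log10(np.maximum(p, 1e-300)), np.inf)
    score = np.where(surplus, 1.0, -1.0) * np.minimum(logp, cap)
    return pd.DataFrame(
        {
            "observed": c,
            "expected": e,
            "p_value": p,
            "score": score,
            "zero_opportunity": flag,
        }
    )


def bonferroni_threshold(n_windows: int, alpha: float = 0.05) -> float:
    """|score| above which a window is Bonferroni-significant."""
    return -np.log10(alpha / n_windows)


@dataclass
class RegionEnrichment:
    """Observed-vs-expected process activity per annotated region."""

    table: pd.DataFrame  # rows (region, process): observed, expected, ratio, p_value
    region_summary: pd.DataFrame  # per region: opportunity_fraction, mutation_fraction


def region_enrichment(
    observed: np.ndarray,
    region_omegas: np.ndarray,
    global_assigned: np.ndarray,
    mu_hat: np.ndarray,
    *,
    region_labels: list | None = None,
    genome_omega: np.ndarray | None = None,
) -> RegionEnrichment:
    """Compare per-region assigned mutations to the uniform-activity null.

    ``observed[s, a]`` is the number of mutations assigned to process a
    inside region s; ``global_assigned[a]`` the total over the
    territory. The expectation if the process acted uniformly is

        expected_a(s) = global_assigned_a * (mu_a . omega^s) / (mu_a . omega^genome),

    with the genome opportunity defaulting to the sum over regions.
    The ratio observed/expected and a two-sided Poisson P-value are
    reported per cell, plus the opportunity and mutation fractions per
    region. Regions with zero opportunity are excluded with a warning.
    """
    observed = np.asarray(observed, dtype=float)
    region_omegas = np.asarray(region_omegas, dtype=float)
    xg = np.asarray(global_assigned, dtype=float)
    S = region_omegas.shape[0]
    labels = list(region_labels) if region_labels is not None else list(range(S))
    if genome_omega is None:
        genome_omega = region_omegas.sum(axis=0)

    keep = region_omegas.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} region(s) with zero opportunity excluded",
            RuntimeWarning,
        )

    overlap = region_omegas @ mu_hat.T  # (S, n) = (mu_a . omega^s)
    overlap_g = genome_omega @ mu_hat.T  # (n,)
    expected = xg[None, :] * overlap / np.maximum(overlap_g[None, :], 1e-300)

    rows = []
    for s in range(S):
        if not keep[s]:
            continue
        for a in range(xg.size):
            obs, exp = observed[s, a], expected[s, a]
            if exp > 0:
                p = 2.0 * min(poisson.sf(obs - 1, exp), poisson.cdf(obs, exp))
                p = min(p, 1.0)
                ratio = obs / exp
            else:
                p, ratio = np.nan, np.nan
            rows.append((labels[s], a, obs, exp, ratio, p))
    table = pd.DataFrame(
        rows, columns=["region", "process", "observed", "expected", "ratio", "p_value"]
    )

    opp_tot = region_omegas.sum(axis=1)
    mut_tot = observed.sum(axis=1)
    summary = pd.DataFrame(
        {
            "region": labels,
            "opportunity_fraction": opp_tot / max(opp_tot.sum(), 1e-300),
            "mutation_fraction": mut_tot / max(mut_tot.sum(), 1e-300),
        }
    )
    return RegionEnrichment(table, summary)
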