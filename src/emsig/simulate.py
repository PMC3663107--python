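"""Synthetic mutation catalogues with known ground truth.

The generator mirrors the validation design used to benchmark the
inference: tumors belong to one of up to three cancer types, each type
carries five (more generally ``n / n_types``) independently active
processes, signatures are sparse (peaked) Dirichlet draws, and
per-tumor mutation totals follow a log-normal. Windowed genomes with
optional injected mutation clusters provide a testbed for the local
(kataegis) statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import N_CHANNELS, CountMatrix

__all__ = [
    "SimulationTruth",
    "simulate_counts",
    "simulate_windowed_genome",
    "match_and_score",
    "MatchResult",
    "toy_genome_path",
    "toy_opportunity",
]


def toy_genome_path():
    """Path to the packaged synthetic toy genome (48 kb FASTA).

    Three 16 kb contigs drawn from a fixed-seed first-order Markov
    chain with mammal-like composition (41% GC, CpG dinucleotides
    depleted five-fold), so the channel opportunities vary strongly the
    way they do in a real genome.
    """
    from importlib.resources import files

    return files("emsig.data") / "toy_genome.fa"


def toy_opportunity(scale_total: float | None = None) -> np.ndarray:
    """Opportunity vector of the packaged toy genome (copy number 1).

    ``scale_total`` rescales the vector to a given grand total, e.g.
    ``1.8e10`` for a diploid human-genome-sized territory, so that
    simulated activities live on the same scale as in a whole-genome
    analysis.
    """
    from .opportunity import opportunity_from_sequence

    omega = _toy_omega_cache()
    if scale_total is not None:
        omega = omega * (scale_total / omega.sum())
    return omega.copy()


def _toy_omega_cache() -> np.ndarray:
    global _TOY_OMEGA
    if _TOY_OMEGA is None:
        from .opportunity import opportunity_from_sequence

        contigs: dict[str, str] = {}
        name = None
        for line in toy_genome_path().read_text().splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                contigs[name] = []
            elif name is not None:
                contigs[name].append(line.strip())
        ref = {k: "".join(v) for k, v in contigs.items()}
        _TOY_OMEGA = opportunity_from_sequence(ref, default_copy_number=1.0)
    return _TOY_OMEGA


_TOY_OMEGA: np.ndarray | None = None


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated count matrix."""

    mu: np.ndarray  # (n, Nc) signatures, rows on the simplex
    x: np.ndarray  # (M, n) activities
    omega: np.ndarray  # (M, Nc) opportunity used for generation
    seed: int | None
    cancer_type: np.ndarray | None = None  # (M,) type index per tumor
    injections: list = field(default_factory=list)


def _resolve_omega(omega, M: int) -> np.ndarray:
    if omega is None:
        return np.ones((M, N_CHANNELS))
    omega = np.asarray(omega, dtype=float)
    if omega.ndim == 1:
        return np.tile(omega, (M, 1))
    return omega


def simulate_counts(
    n: int,
    M: int,
    *,
    omega: np.ndarray | None = None,
    n_cancer_types: int | None = None,
    signature_concentration: float = 0.1,
    total_median: float = 5000.0,
    total_sigma: float = 0.7,
    signatures: np.ndarray | None = None,
    seed: int | None = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Draw a Poisson count matrix from ``n`` ground-truth processes.

    Signatures are sparse symmetric Dirichlet draws (concentration 0.1
    by default, mimicking strongly peaked real spectra). Tumors are
    spread round-robin over cancer types (one type per five processes
    when ``n`` is a multiple of five, a single type otherwise); only
    the type's block of processes is active in a tumor. Per-tumor
    activity totals are calibrated so that the expected mutation burden
    is log-normal with the given median and log-sd, split across the
    active processes by a uniform Dirichlet.

    ``omega`` may be None (opportunity ignored, all ones), a single
    96-vector shared by all tumors, or a full M x 96 matrix.
    """
    rng = np.random.default_rng(seed)
    omega_mat = _resolve_omega(omega, M)
    if signatures is None:
        mu = rng.dirichlet(np.full(N_CHANNELS, signature_concentration), size=n)
        mu = np.maximum(mu, 1e-12)
        mu /= mu.sum(axis=1, keepdims=True)
    else:
        mu = np.asarray(signatures, dtype=float)

    if n_cancer_types is None:
        n_cancer_types = n // 5 if (n % 5 == 0 and n >= 5) else 1
    if n % n_cancer_types:
        raise ValueError("n must be divisible by the number of cancer types")
    block = n // n_cancer_types
    ctype = np.arange(M) % n_cancer_types

    totals = rng.lognormal(np.log(total_median), total_sigma, size=M)
    x = np.zeros((M, n))
    for m in range(M):
        active = slice(ctype[m] * block, (ctype[m] + 1) * block)
        shares = rng.dirichlet(np.ones(block))
        per_process_overlap = mu[active] @ omega_mat[m]  # (block,)
        x[m, active] = totals[m] * shares / np.maximum(per_process_overlap, 1e-300)

    lam = (x @ mu) * omega_mat
    counts = rng.poisson(lam)
    samples = [f"S{m:03d}" for m in range(M)]
    truth = SimulationTruth(mu=mu, x=x, omega=omega_mat, seed=seed, cancer_type=ctype)
    return CountMatrix(counts, samples), truth


def simulate_windowed_genome(
    window_omegas: np.ndarray,
    signatures: np.ndarray,
    base_activities: np.ndarray,
    *,
    injections: list[tuple[int, int, int]] | None = None,
    seed: int | None = 0,
) -> tuple[np.ndarray, SimulationTruth]:
    """Per-window Poisson counts with optional injected mutation clusters.

    Background counts in window l follow the homogeneous model: Poisson
    with intensity ``sum_a x_a mu_aj omega_j^l`` (uniform activity
    modulated by local opportunity). Each injection ``(window, process,
    count)`` adds that many extra mutations drawn from the process's
    opportunity-weighted channel distribution in that window —
    a synthetic kataegis event.
    """
    rng = np.random.default_rng(seed)
    window_omegas = np.asarray(window_omegas, dtype=float)
    mu = np.asarray(signatures, dtype=float)
    x = np.asarray(base_activities, dtype=float)
    Nb = window_omegas.shape[0]
    lam = (x @ mu)[None, :] * window_omegas  # (Nb, Nc)
    counts = rng.poisson(lam).astype(np.int64)
    injections = injections or []
    for win, proc, extra in injections:
        if not (0 <= win < Nb):
            raise ValueError(f"injection into nonexistent window {win}")
        p = mu[proc] * window_omegas[win]
        if p.sum() <= 0:
            raise ValueError(f"process {proc} has zero opportunity in window {win}")
        counts[win] += rng.multinomial(extra, p / p.sum())
    truth = SimulationTruth(
        mu=mu, x=np.tile(x, (Nb, 1)), omega=window_omegas, seed=seed,
        injections=list(injections),
    )
    return counts, truth


@dataclass
class MatchResult:
    """One-to-one matching between true and inferred signatures."""

    pairs: list[tuple[int, int]]  # (true index, inferred index)
    correlations: np.ndarray  # per matched pair
    unmatched_true: list[int]
    unmatched_inferred: list[int]

    @property
    def median_correlation(self) -> float:
        return float(np.median(self.correlations))


def match_and_score(
    true_mu: np.ndarray,
    inferred_mu: np.ndarray,
    *,
    metric: str = "pearson",
) -> MatchResult:
    """Optimally match inferred to true signatures and score the pairs.

    Solves the assignment problem maximizing the total similarity
    (Pearson correlation by default, cosine optionally) and reports the
    per-pair similarity. With unequal process numbers the surplus side
    is left unmatched and flagged.
    """
    from scipy.optimize import linear_sum_assignment

    T = np.asarray(true_mu, dtype=float)
    I = np.asarray(inferred_mu, dtype=float)
    if metric == "pearson":
        Tc = T - T.mean(axis=1, keepdims=True)
        Ic = I - I.mean(axis=1, keepdims=True)
    elif metric == "cosine":
        Tc, Ic = T, I
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Tn = Tc / np.maximum(np.linalg.norm(Tc, axis=1, keepdims=True), 1e-300)
    In = Ic / np.maximum(np.linalg.norm(Ic, axis=1, keepdims=True), 1e-300)
    sim = Tn @ In.T
    rows, cols = linear_sum_assignment(-sim)
    pairs = list(zip(rows.tolist(), cols.tolist()))
    corr = sim[rows, cols]
    return MatchResult(
        pairs=pairs,
        correlations=corr,
        unmatched_true=[i for i in range(T.shape[0]) if i not in set(rows.tolist())],
        unmatched_inferred=[j for j in range(I.shape[0]) if j not in set(cols.tolist())],
    )
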