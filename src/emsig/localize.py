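"""Assigning mutations to processes, globally and per genomic window.

Once signatures and activities are fitted, each tumor's observed
mutations are apportioned among processes in proportion to activity x
spectrum x opportunity. The same machinery, run window by window with
the globally inferred activities as an informed pseudocount prior,
yields local activity tracks: the input for kataegis detection and
region enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em_core import estep, pseudocounts

__all__ = [
    "assign_global",
    "infer_local",
    "consistency_check",
    "LocalActivityTrack",
]


def assign_global(
    X_m: np.ndarray,
    x_hat_m: np.ndarray,
    mu_hat: np.ndarray,
    omega_m: np.ndarray,
) -> np.ndarray:
    """Estimated mutation counts per (process, channel) for one tumor.

    Returns the n x Nc table

        Xhat_aj = X^m * x_a mu_aj omega_j / sum_b x_b (mu.omega)_b

    whose grand total equals the observed mutation count exactly.
    """
    X_m = np.asarray(X_m, dtype=float)
    x = np.asarray(x_hat_m, dtype=float)
    omega_m = np.asarray(omega_m, dtype=float)
    total = float(X_m.sum())
    G = mu_hat * omega_m[None, :]
    denom = float((x * G.sum(axis=1)).sum())
    if total == 0:
        return np.zeros_like(G)
    if denom <= 0:
        raise ValueError("cannot assign mutations: all activities are zero")
    return total * x[:, None] * G / denom


@dataclass
class LocalActivityTrack:
    """Per-window activities and mutation assignments for one tumor."""

    activities: np.ndarray  # (Nb, n)
    assignments: np.ndarray  # (Nb, n, Nc)
    window_ids: list | None = None

    @property
    def assigned_totals(self) -> np.ndarray:
        """Per-window, per-process assigned mutation counts (Nb, n)."""
        return self.assignments.sum(axis=2)


def infer_local(
    window_counts: np.ndarray,
    window_omegas: np.ndarray,
    global_activities: np.ndarray,
    mu_hat: np.ndarray,
    *,
    window_ids: list | None = None,
) -> LocalActivityTrack:
    """Infer per-window activities with the informed prior.

    For every window the pseudocount table is built from the global
    activities (prior weight of process a proportional to its global
    activity), the penalized activity estimate is computed, and the
    window's mutations are assigned to processes with the local
    activities but the *global* signatures.

    Windows with zero counts are driven by the prior alone; a window
    with zero opportunity in a channel that nevertheless has counts is
    an input error.
    """
    window_counts = np.asarray(window_counts, dtype=float)
    window_omegas = np.asarray(window_omegas, dtype=float)
    Nb = window_counts.shape[0]
    n = mu_hat.shape[0]
    acts = np.zeros((Nb, n))
    assigns = np.zeros((Nb, n, mu_hat.shape[1]))
    for l in range(Nb):
        X_l, om_l = window_counts[l], window_omegas[l]
        if om_l.sum() == 0:
            if X_l.sum() > 0:
                raise ValueError(f"window {l} has mutations but zero opportunity")
            continue
        pt = pseudocounts(mu_hat, om_l, prior_activities=global_activities)
        acts[l] = estep(X_l, om_l, mu_hat, pseudocounts=pt)
        if X_l.sum() > 0:
            assigns[l] = assign_global(X_l, acts[l], mu_hat, om_l)
    return LocalActivityTrack(acts, assigns, window_ids)


def consistency_check(
    local_track: LocalActivityTrack | np.ndarray,
    global_assignment: np.ndarray,
) -> np.ndarray:
    """Relative deviation between summed local and global assignments.

    Returns, per process, ``|sum_l Xhat_a^l - Xhat_a^g| / max(1, Xhat_a^g)``.
    Large values flag a discrepancy between the local decomposition and
    the global generative fit.
    """
    if isinstance(local_track, LocalActivityTrack):
        local_totals = local_track.assigned_totals.sum(axis=0)
    else:
        arr = np.asarray(local_track, dtype=float)
        if arr.ndim == 3:  # (windows, processes, channels)
            local_totals = arr.sum(axis=(0, 2))
        elif arr.ndim == 2:  # (windows, processes)
            local_totals = arr.sum(axis=0)
        else:
            local_totals = arr
    g = np.asarray(global_assignment, dtype=float)
    global_totals = g.sum(axis=-1) if g.ndim > 1 else g
    return np.abs(local_totals - global_totals) / np.maximum(1.0, global_totals)
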