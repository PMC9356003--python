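"""Muscle synergy extraction by non-negative matrix factorization.

Activation envelopes m(t) are modelled as linear combinations of N
time-invariant, non-negative muscle synergy vectors w_i activated by
time-varying non-negative coefficients c_i(t):

    m(t) = sum_i c_i(t) w_i + eps(t)

Synergies are extracted by multiplicative-update NMF minimizing squared
Frobenius error, with random [0, 1] initialization, a stopping rule on the
change of variance accounted for (VAF) over 50 consecutive iterations, and
best-of-restarts selection.  The synergy count is the smallest N whose VAF
exceeds 0.95.  Scale indeterminacy is resolved by unit-norm synergy columns
(scales folded into the coefficients), so scalar-product similarities between
synergies are well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import TrialWindow

_EPS = 1e-12


@dataclass
class SynergyModel:
    """NMF factorization of an activation-envelope matrix.

    W is muscles x N with non-negative unit-norm columns, C is N x samples
    (non-negative); VAF is the uncentered variance accounted for of W @ C.
    """

    W: np.ndarray
    C: np.ndarray
    vaf: float
    n_synergies: int

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.C < 0):
            raise ValueError("W and C must be non-negative")

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.C


@dataclass
class SynergyActivationVector:
    """Unit-norm time-averaged synergy activation for one movement."""

    movement: str
    u: np.ndarray
    degenerate: bool = False


def compute_vaf(M: np.ndarray, W: np.ndarray, C: np.ndarray) -> float:
    """Uncentered VAF = 1 - ||M - W C||_F^2 / ||M||_F^2, clipped to [0, 1]."""
    M = np.asarray(M, float)
    total = float(np.sum(M * M))
    if total <= 0:
        raise ValueError("VAF undefined for an all-zero activation matrix")
    resid = M - W @ C
    return float(np.clip(1.0 - np.sum(resid * resid) / total, 0.0, 1.0))


def per_muscle_vaf(M: np.ndarray, W: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-channel uncentered VAF (exposed as an alternative criterion)."""
    M = np.asarray(M, float)
    resid = M - W @ C
    total = np.sum(M * M, axis=1)
    if np.any(total <= 0):
        raise ValueError("per-muscle VAF undefined for an all-zero channel")
    return np.clip(1.0 - np.sum(resid * resid, axis=1) / total, 0.0, 1.0)


def _mu_nmf(M: np.ndarray, N: int, rng: np.random.Generator,
            tol: float = 1e-5, tol_window: int = 50, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update NMF run from random [0, 1] initialization.

    Stops when the VAF change stays below ``tol`` for ``tol_window``
    consecutive iterations.
    """
    n_ch, n_t = M.shape
    W = rng.uniform(0.0, 1.0, size=(n_ch, N)) + _EPS
    C = rng.uniform(0.0, 1.0, size=(N, n_t)) + _EPS
    vaf_prev = compute_vaf(M, W, C)
    quiet = 0
    for _ in range(max_iter):
        C *= (W.T @ M) / (W.T @ W @ C + _EPS)
        W *= (M @ C.T) / (W @ (C @ C.T) + _EPS)
        vaf = compute_vaf(M, W, C)
        quiet = quiet + 1 if abs(vaf - vaf_prev) < tol else 0
        vaf_prev = vaf
        if quiet >= tol_window:
            break
    return W, C, vaf_prev


def nmf_decompose(M: np.ndarray, N: int, seed: int, *, restarts: int = 30,
                  tol: float = 1e-5, tol_window: int = 50, max_iter: int = 500) -> SynergyModel:
    """Best-of-restarts NMF of an envelope matrix at a fixed synergy count.

    Restart r draws from ``np.random.default_rng([seed, r])``; the solution
    with the highest VAF is kept.  Synergy columns are rescaled to unit norm
    with the scale folded into the coefficients.
    """
    M = np.asarray(M, float)
    if M.ndim != 2:
        raise ValueError("M must be channels x samples")
    if not np.all(np.isfinite(M)) or np.any(M < 0):
        raise ValueError("M must be finite and non-negative")
    if not 1 <= N <= M.shape[0]:
        raise ValueError("N must lie in [1, n_channels]")
    best = None
    for r in range(restarts):
        rng = np.random.default_rng([int(seed), r])
        W, C, vaf = _mu_nmf(M, N, rng, tol=tol, tol_window=tol_window, max_iter=max_iter)
        if best is None or vaf > best[2]:
            best = (W, C, vaf)
    W, C, vaf = best
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return SynergyModel(W=W / norms, C=C * norms[:, None], vaf=vaf, n_synergies=N)


def select_synergy_count(M: np.ndarray, seed: int, *, vaf_threshold: float = 0.95,
                         max_n: int = 4, **nmf_kwargs) -> int:
    """Smallest N whose VAF exceeds the threshold (``max_n`` if none does)."""
    for N in range(1, max_n):
        model = nmf_decompose(M, N, seed, **nmf_kwargs)
        if model.vaf > vaf_threshold:
            return N
    return max_n


def extract_synergies(M: np.ndarray, seed: int, *, vaf_threshold: float = 0.95,
                      max_n: int = 4, **nmf_kwargs) -> SynergyModel:
    """Model-selected NMF: decompose at the smallest adequate synergy count."""
    N = select_synergy_count(M, seed, vaf_threshold=vaf_threshold, max_n=max_n, **nmf_kwargs)
    return nmf_decompose(M, N, seed, **nmf_kwargs)


def synergy_activation_vector(C: np.ndarray, sample_rate: float, window: TrialWindow,
                              movement: str | None = None, dim: int = 3) -> SynergyActivationVector:
    """Unit-norm time-average of synergy coefficients over a task window.

    The per-synergy averages (trapezoidal time integral divided by the task
    duration) are assembled on the synergy axes and normalized; an all-zero
    average is flagged degenerate.
    """
    C = np.asarray(C, float)
    i0 = int(round(window.t_start * sample_rate))
    i1 = int(round(window.t_end * sample_rate))
    if i0 < 0 or i1 > C.shape[1] or i1 - i0 < 2:
        raise ValueError("window outside the coefficient time span")
    seg = C[:, i0:i1]
    means = np.trapezoid(seg, dx=1.0 / sample_rate, axis=1) / ((i1 - i0 - 1) / sample_rate)
    u = pad_to_dim(means[None, :], dim)[0]
    norm = np.linalg.norm(u)
    if norm <= 0:
        return SynergyActivationVector(movement or window.movement, u, degenerate=True)
    return SynergyActivationVector(movement or window.movement, u / norm)


def pad_to_dim(vectors: np.ndarray, d: int = 3) -> np.ndarray:
    """Append zero components so each row vector has dimension ``d``."""
    vectors = np.atleast_2d(np.asarray(vectors, float))
    if vectors.shape[1] > d:
        raise ValueError(f"vectors of dimension {vectors.shape[1]} exceed target {d}")
    if vectors.shape[1] == d:
        return vectors.copy()
    pad = np.zeros((vectors.shape[0], d - vectors.shape[1]))
    return np.hstack([vectors, pad])
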