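"""Motor-intent decoding in synergy space.

Arbitrary activation envelopes are projected onto a fixed synergy basis
(non-negative least squares per sample, the optimum of NMF with the basis
held fixed), yielding synergy activations U_S(t).  Each sample is then decoded
into a two-dimensional motor-intent plane (the α-space) by angular
interpolation between the unit activation vectors of the four principal
movements:

    α_PFDF = [acos(u_PF · Û) - acos(u_DF · Û)] / acos(u_PF · u_DF)
    α_INEV = [acos(u_IN · Û) - acos(u_EV · Û)] / acos(u_IN · u_EV)

with Û = U_S/||U_S||, so pure plantarflexion decodes to α_PFDF = -1 and pure
dorsiflexion to +1 (and analogously inversion/eversion on the α_INEV axis).
The module also computes the synergy-activation margin φ_ij: the angle between
two movements' average activation vectors minus the mean angular deviation of
each movement's samples from its own average (a positive margin means the two
motor commands are robustly distinguishable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import nnls

from .recording import MOVEMENTS

#: Samples with ||U_S|| below this fraction of the trial maximum are treated
#: as rest and excluded from α statistics.
REST_NORM_FRACTION = 1e-3


@dataclass
class DirectionBasis:
    """Unit-norm activation vectors of the four discrete movements."""

    u: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for m in MOVEMENTS:
            if m not in self.u:
                raise ValueError(f"missing direction vector for {m}")
        for a, b in (("PF", "DF"), ("IN", "EV")):
            if self.angle(a, b) <= 0:
                raise ValueError(f"degenerate direction pair {a}-{b}")

    def angle(self, a: str, b: str) -> float:
        return float(np.arccos(np.clip(np.dot(self.u[a], self.u[b]), -1.0, 1.0)))


@dataclass
class AlphaTrace:
    """Decoded motor intent over time."""

    time: np.ndarray
    alpha_inev: np.ndarray
    alpha_pfdf: np.ndarray
    us_norm: np.ndarray
    defined: np.ndarray  # bool mask of decodable samples

    @property
    def alpha(self) -> np.ndarray:
        """Samples x 2 array in (α_INEV, α_PFDF) coordinate order."""
        return np.column_stack([self.alpha_inev, self.alpha_pfdf])


def fixed_basis_decompose(M: np.ndarray, W_fixed: np.ndarray, dim: int = 3) -> np.ndarray:
    """Non-negative coefficients of M on a fixed synergy basis.

    Solved per sample by non-negative least squares; the result is zero-padded
    to ``dim`` synergy axes.
    """
    M = np.asarray(M, float)
    W = np.asarray(W_fixed, float)
    if np.any(W < 0):
        raise ValueError("fixed basis must be non-negative")
    n = W.shape[1]
    C = np.empty((n, M.shape[1]))
    last_col = None
    for t in range(M.shape[1]):
        col = M[:, t]
        if last_col is not None and np.array_equal(col, last_col[0]):
            C[:, t] = last_col[1]
            continue
        C[:, t], _ = nnls(W, col)
        last_col = (col, C[:, t])
    if n < dim:
        C = np.vstack([C, np.zeros((dim - n, M.shape[1]))])
    return C


def alpha_decode(U_S: np.ndarray, basis: DirectionBasis, sample_rate: float = 1.0,
                 rest_fraction: float = REST_NORM_FRACTION) -> AlphaTrace:
    """Decode synergy activations into the α-space motor-intent plane.

    ``U_S`` is synergies x samples.  Samples whose norm falls below
    ``rest_fraction`` of the trace maximum are marked undefined and excluded
    downstream; the decode is invariant to positive scaling of U_S.
    """
    U = np.atleast_2d(np.asarray(U_S, float))
    norms = np.linalg.norm(U, axis=0)
    thresh = rest_fraction * (norms.max() if norms.size else 0.0)
    defined = norms > max(thresh, 0.0)
    Uhat = np.where(defined, U / np.where(norms > 0, norms, 1.0), 0.0)

    def axis(a: str, b: str) -> np.ndarray:
        th_ab = basis.angle(a, b)
        th_a = np.arccos(np.clip(basis.u[a] @ Uhat, -1.0, 1.0))
        th_b = np.arccos(np.clip(basis.u[b] @ Uhat, -1.0, 1.0))
        return np.clip((th_a - th_b) / th_ab, -1.0, 1.0)

    pfdf = np.where(defined, axis("PF", "DF"), np.nan)
    inev = np.where(defined, axis("IN", "EV"), np.nan)
    t = np.arange(U.shape[1]) / sample_rate
    return AlphaTrace(time=t, alpha_inev=inev, alpha_pfdf=pfdf, us_norm=norms, defined=defined)


def _mean_angular_deviation(C: np.ndarray, u: np.ndarray) -> float:
    """Mean |acos(u · ĉ(t))| over non-zero coefficient samples."""
    C = np.atleast_2d(np.asarray(C, float))
    norms = np.linalg.norm(C, axis=0)
    keep = norms > 0
    if not np.any(keep):
        raise ValueError("all coefficient samples are zero")
    chat = C[:, keep] / norms[keep]
    angles = np.abs(np.arccos(np.clip(u @ chat, -1.0, 1.0)))
    return float(np.mean(angles))


def activation_margin(C_i: np.ndarray, C_j: np.ndarray,
                      u_i: np.ndarray, u_j: np.ndarray) -> float:
    """Synergy-activation margin φ_ij between two movements (radians).

    Tolerance term acos(u_i · u_j) minus each movement's mean angular
    deviation of its coefficient samples from its own average vector.
    A margin above 0 flags the pair as robustly decoupled.
    """
    tol = float(np.arccos(np.clip(np.dot(u_i, u_j), -1.0, 1.0)))
    return tol - _mean_angular_deviation(C_i, u_i) - _mean_angular_deviation(C_j, u_j)


@dataclass
class MarginMatrix:
    """Pairwise margins over the 4 movements, symmetric by construction."""

    phi: Mapping[tuple[str, str], float]

    def robust(self, i: str, j: str) -> bool:
        return self.phi[tuple(sorted((i, j)))] > 0.0

    @classmethod
    def from_trials(cls, coeffs: Mapping[str, np.ndarray],
                    u: Mapping[str, np.ndarray]) -> "MarginMatrix":
        phi = {}
        for a_idx, a in enumerate(MOVEMENTS):
            for b in MOVEMENTS[a_idx + 1:]:
                phi[tuple(sorted((a, b)))] = activation_margin(coeffs[a], coeffs[b], u[a], u[b])
        return cls(phi=phi)
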