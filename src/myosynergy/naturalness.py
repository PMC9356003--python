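"""Naturalness of muscle synergies and synergy activations.

Similarity of a limb's synergy structure to the biologically intact (BIO)
reference is quantified by mean scalar products after greedy correspondence
matching: muscle synergy similarity (m.s.s.) on synergy vectors, synergy
activation similarity (s.a.s.) on the per-movement activation vectors.  The
reference basis is the normalized element-wise average of the matched BIO
synergies; BIO limbs themselves are scored by a leave-one-out procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .recording import MOVEMENTS

REFERENCE_DIM = 3


@dataclass
class LimbVectors:
    """Padded, unit-norm synergy vectors and per-movement activation vectors."""

    limb_id: str
    group: str
    W: np.ndarray  # muscles x 3, unit-norm (or zero-padded) columns
    u: Mapping[str, np.ndarray]  # movement -> 3-vector, unit norm


@dataclass
class ReferenceBasis:
    W_rep: np.ndarray
    u_rep: Mapping[str, np.ndarray]


def match_synergies(W_a: np.ndarray, W_b: np.ndarray) -> list[int]:
    """Greedy max-scalar-product correspondence from columns of W_a to W_b.

    Returns a permutation ``perm`` with ``perm[i]`` = column of W_b matched to
    column i of W_a.  Matching proceeds in descending order of the best
    available scalar product; exact ties resolve to the lowest (row, column)
    index pair.
    """
    S = np.asarray(W_a, float).T @ np.asarray(W_b, float)
    if S.shape[0] != S.shape[1]:
        raise ValueError("bases must have the same number of columns")
    n = S.shape[0]
    perm = [-1] * n
    free_a, free_b = set(range(n)), set(range(n))
    for _ in range(n):
        best, best_ij = -np.inf, None
        for i in sorted(free_a):
            for j in sorted(free_b):
                if S[i, j] > best + 1e-15:
                    best, best_ij = S[i, j], (i, j)
        i, j = best_ij
        perm[i] = j
        free_a.remove(i)
        free_b.remove(j)
    return perm


def _apply_perm(vectors: np.ndarray, perm: Sequence[int]) -> np.ndarray:
    """Reorder columns so column ``perm[i]`` moves to position i."""
    out = np.empty_like(vectors)
    for i, j in enumerate(perm):
        out[:, i] = vectors[:, j]
    return out


def _normalize_cols(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    return W / np.where(norms > 0, norms, 1.0)


def build_reference(limbs: Sequence[LimbVectors]) -> ReferenceBasis:
    """Normalized average of the BIO group's matched synergy/activation vectors.

    The first limb anchors the canonical column ordering; every other limb is
    matched to it before element-wise averaging.  The same per-limb synergy
    permutation is applied to the activation-vector axes so coefficient space
    stays consistent.
    """
    if len(limbs) == 0:
        raise ValueError("reference requires at least one limb")
    anchor = limbs[0]
    W_sum = np.zeros((anchor.W.shape[0], REFERENCE_DIM))
    u_sum = {m: np.zeros(REFERENCE_DIM) for m in MOVEMENTS}
    for limb in limbs:
        perm = match_synergies(anchor.W, limb.W)
        W_sum += _apply_perm(limb.W, perm)
        for m in MOVEMENTS:
            u_sum[m] += np.asarray(limb.u[m])[list(perm)]
    W_rep = _normalize_cols(W_sum / len(limbs))
    u_rep = {}
    for m in MOVEMENTS:
        v = u_sum[m] / len(limbs)
        n = np.linalg.norm(v)
        u_rep[m] = v / n if n > 0 else v
    return ReferenceBasis(W_rep=W_rep, u_rep=u_rep)


def pad_columns(W: np.ndarray, d: int = REFERENCE_DIM) -> np.ndarray:
    """Append zero synergy columns so the basis has ``d`` columns."""
    W = np.asarray(W, float)
    if W.shape[1] > d:
        raise ValueError(f"basis has {W.shape[1]} columns, more than {d}")
    if W.shape[1] == d:
        return W.copy()
    return np.hstack([W, np.zeros((W.shape[0], d - W.shape[1]))])


def synergy_similarity(W_subject: np.ndarray, reference: ReferenceBasis) -> float:
    """Mean scalar product of matched synergy pairs (m.s.s.)."""
    W = pad_columns(np.asarray(W_subject, float))
    perm = match_synergies(reference.W_rep, W)
    dots = [float(reference.W_rep[:, i] @ W[:, j]) for i, j in enumerate(perm)]
    return float(np.mean(dots))


def activation_similarity(u_subject: Mapping[str, np.ndarray], reference: ReferenceBasis,
                          W_subject: Optional[np.ndarray] = None) -> float:
    """Mean scalar product of activation vectors across the 4 movements (s.a.s.).

    Activation vectors live on the subject's own synergy axes, whose order is
    arbitrary; when ``W_subject`` is given the axes are first brought into
    the reference ordering via the muscle-synergy correspondence matching.
    """
    if W_subject is not None:
        perm = match_synergies(reference.W_rep, pad_columns(np.asarray(W_subject, float)))
        u_subject = {m: np.asarray(u_subject[m])[list(perm)] for m in MOVEMENTS}
    dots = [float(np.asarray(u_subject[m]) @ reference.u_rep[m]) for m in MOVEMENTS]
    return float(np.mean(dots))


def leave_one_out_similarity(bio_limbs: Sequence[LimbVectors]) -> dict[str, tuple[float, float]]:
    """Score each BIO limb against the reference built from the others.

    Returns ``{limb_id: (mss, sas)}``; requires at least two limbs.
    """
    if len(bio_limbs) < 2:
        raise ValueError("leave-one-out requires at least two BIO limbs")
    out = {}
    for k, limb in enumerate(bio_limbs):
        others = [l for i, l in enumerate(bio_limbs) if i != k]
        ref = build_reference(others)
        out[limb.limb_id] = (synergy_similarity(limb.W, ref),
                             activation_similarity(limb.u, ref, W_subject=limb.W))
    return out
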