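"""Synthetic cohort generator: virtual limbs with known ground truth.

Every downstream stage of the analysis is testable without human recordings
by simulating a cohort of virtual limbs.  A limb owns a non-negative muscle
synergy basis (4 muscles x 3 synergies), per-movement synergy activation
directions, and an agonist-antagonist muscle strain (AMS) degree in [0, 1].
Motor degradation is driven by a configured first-order exponential response
curve r(AMS): the corrupted synergy basis is a convex mixture of the true
columns toward their common centroid, with the mixing weight solved per limb
so that the matched-cosine similarity of corrupted to true synergies equals
r(AMS).  Activation directions are pulled toward coactivation by the same
weight, trajectory shapes blend from diamond (simultaneous 2-DoF) to
axis-aligned (single-DoF) with the fusion level, and perception gain follows
a second response curve.  A noiseless cohort therefore sits exactly on the
configured curves, which is what makes end-to-end recovery of the critical
AMS degree (AMS_c) a meaningful round-trip test.

Geometry of the activation directions: the four movement directions sit on a
30 degree cone around the symmetric axis (1,1,1)/sqrt(3) of synergy space at
azimuths 0 (PF), 90 (EV), 180 (DF) and 270 (IN) degrees, so each direction is
equidistant from the two directions of the orthogonal degree of freedom and
decodes exactly onto its cardinal point of the α-plane.  Each discrete-trial
burst staggers the onsets of the three synergy components, so every synergy
is briefly active alone somewhere in the record; this makes the non-negative
factorization identifiable while leaving the time-averaged activation
direction of each movement untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .decoding import DirectionBasis
from .metrics import TARGETS
from .naturalness import match_synergies
from .recording import MOVEMENTS, MUSCLES, Recording, TrialWindow

LN20 = float(np.log(20.0))

# --- canonical muscle-space synergy basis (TA, TP, GA, PL) -----------------
# w1: plantarflexion synergy dominated by GA with TP, w2: PL, w3: TA.
_W_CANONICAL = np.array([
    [0.00, 0.00, 1.00],
    [0.55, 0.00, 0.00],
    [0.835, 0.00, 0.00],
    [0.00, 1.00, 0.00],
])
_W_CANONICAL /= np.linalg.norm(_W_CANONICAL, axis=0)

# --- symmetric activation-direction geometry in synergy space --------------
_C0 = np.ones(3) / np.sqrt(3.0)
_A_AXIS = np.array([2.0, -1.0, -1.0]) / np.sqrt(6.0)
_B_AXIS = np.array([0.0, 1.0, -1.0]) / np.sqrt(2.0)
_CONE_ANGLE = np.deg2rad(30.0)
_AZIMUTH = {"PF": 0.0, "EV": 0.5 * np.pi, "DF": np.pi, "IN": 1.5 * np.pi}
#: Synergy whose burst starts first in each movement (covers all three axes).
_FIRST_ONSET = {"PF": 0, "EV": 1, "DF": 2, "IN": 0}

_MAX_CONE = np.deg2rad(33.0)  # keeps inverted directions inside the orthant


def _cone_vector(azimuth: float, polar: float = _CONE_ANGLE) -> np.ndarray:
    return (np.cos(polar) * _C0
            + np.sin(polar) * (np.cos(azimuth) * _A_AXIS + np.sin(azimuth) * _B_AXIS))


def canonical_directions() -> dict[str, np.ndarray]:
    return {m: _cone_vector(_AZIMUTH[m]) for m in MOVEMENTS}


def response_curve(ams, ams_c: float) -> np.ndarray:
    """Unit-normalised first-order exponential response, r(1) = 1 exactly."""
    lam = LN20 / ams_c
    a = np.asarray(ams, float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("AMS values must lie in [0, 1]")
    return (1.0 - np.exp(-lam * a)) / (1.0 - np.exp(-lam))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the simulated cohort (defaults mirror the protocol)."""

    n_ami: int = 7
    n_ctl: int = 7
    include_bio: bool = True
    ami_ams: Sequence[float] = (0.19, 0.30, 0.42, 0.55, 0.70, 0.85, 1.00)
    ctl_ams: Sequence[float] = (0.12, 0.16, 0.19, 0.23, 0.28, 0.35, 0.45)
    motor_amsc: float = 0.21
    perception_amsc: float = 0.61
    emg_noise_sd: float = 0.05
    perception_noise_sd: float = 0.05
    w_jitter: float = 0.03
    sample_rate: float = 50.0
    discrete_reps: int = 40
    rep_duration: float = 1.0
    rep_gap: float = 0.25
    circle_cycles: int = 10
    circle_period: float = 4.0
    speed_reps: int = 10
    time_constraints: Sequence[float] = (2.0, 1.5, 1.0, 0.8, 0.5)
    perception_pfdf_trials: int = 40
    perception_inev_trials: int = 30
    pfdf_rom_fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0)
    inev_rom_fractions: Sequence[float] = (0.5, 1.0)
    perception_trial_duration: float = 2.0
    nominal_strain_pfdf: float = 0.15
    nominal_strain_inev: float = 0.10
    ankle_rom_deg: float = 25.0
    subtalar_rom_deg: float = 15.0
    zero_sensation_limbs: Sequence[str] = ()
    burst_duration: float = 0.4
    burst_stagger: float = 0.24
    burst_amplitude: float = 0.7

    def noiseless(self) -> "CohortConfig":
        return replace(self, emg_noise_sd=0.0, perception_noise_sd=0.0, w_jitter=0.0)

    @property
    def nominal_strain(self) -> dict[str, float]:
        return {"PFDF": self.nominal_strain_pfdf, "INEV": self.nominal_strain_inev}

    def __post_init__(self) -> None:
        if self.n_ami + self.n_ctl < 1:
            raise ValueError("cohort must contain at least one limb")
        for a in tuple(self.ami_ams) + tuple(self.ctl_ams):
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"AMS value {a} outside [0, 1]")


@dataclass
class GroundTruthLimb:
    """A virtual limb with its operative (possibly corrupted) synergy model."""

    limb_id: str
    group: str  # AMI | CTL | BIO
    W_true: np.ndarray  # operative muscle synergies, 4 x 3, unit-norm columns
    coeff_templates: Mapping[str, np.ndarray]  # movement -> activation direction
    ams_true: float
    emg_noise_sd: float
    perception_noise_sd: float
    fusion_level: float
    mix_weight: float = 0.0
    perception_gain: float = 1.0
    zero_sensation: bool = False
    n_true: int = 3
    strains: Mapping[str, float] = field(default_factory=dict)
    config: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ams_true <= 1.0:
            raise ValueError("ams_true must lie in [0, 1]")
        if not 0.0 <= self.fusion_level <= 1.0:
            raise ValueError("fusion_level must lie in [0, 1]")
        if self.n_true not in (1, 2, 3):
            raise ValueError("n_true must be 1, 2 or 3")

    @property
    def direction_basis(self) -> DirectionBasis:
        return DirectionBasis(u={m: np.asarray(self.coeff_templates[m]) for m in MOVEMENTS})


# --- basis corruption -------------------------------------------------------

def _normalize_cols(W: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(W, axis=0)
    return W / np.where(n > 0, n, 1.0)


# Pathological coordination basis: altered TP:GA balance and cross-muscle
# bleed (TP+PL, TA+GA couplings).  Its columns lie outside the cone of the
# natural basis and touch the orthant boundary, so corrupted limbs remain
# identifiable by NMF while drifting away from the natural synergies.
_W_PATH = np.array([
    [0.00, 0.00, 0.71],
    [0.99, 0.71, 0.00],
    [0.141, 0.00, 0.71],
    [0.00, 0.71, 0.00],
])
_W_PATH /= np.linalg.norm(_W_PATH, axis=0)


def _corrupt_basis(W: np.ndarray, g: float, g_cen: float = 0.0) -> np.ndarray:
    """Convex corruption of the synergy columns.

    ``g`` mixes each column toward the corresponding pathological
    coordination column; ``g_cen`` additionally pulls all columns toward
    their centroid (the coactivation collapse seen only under near-total
    strain loss).
    """
    Wc = (1.0 - g) * W + g * _W_PATH
    if g_cen > 0:
        Wc = (1.0 - g_cen) * Wc + g_cen * Wc.mean(axis=1, keepdims=True)
    return _normalize_cols(Wc)


def matched_mean_cosine(W_a: np.ndarray, W_b: np.ndarray) -> float:
    perm = match_synergies(W_a, W_b)
    return float(np.mean([W_a[:, i] @ W_b[:, j] for i, j in enumerate(perm)]))


def _solve_mix_weight(W: np.ndarray, target: float, g_cen: float = 0.0) -> float:
    """Mixing weight whose corrupted basis has the target similarity to W.

    The matched similarity is monotone in the weight; targets below the
    reachable floor clamp to the maximal corruption.
    """
    def sim(g: float) -> float:
        return matched_mean_cosine(W, _corrupt_basis(W, g, g_cen))

    if target >= sim(0.0):
        return 0.0
    if target <= sim(1.0):
        return 1.0
    return float(brentq(lambda g: sim(g) - target, 0.0, 1.0, xtol=1e-10))


_OPPOSITE = {"PF": "DF", "DF": "PF", "IN": "EV", "EV": "IN"}

#: Cap on the antagonist-merge weight; keeps the direction pairs separable
#: (and the α-map non-degenerate) even under total fusion.
_MAX_MERGE = 0.45


def _merge_directions(u: np.ndarray, u_opp: np.ndarray, beta: float) -> np.ndarray:
    """Pull a movement's activation direction toward its antagonist's."""
    v = (1.0 - beta) * u + beta * u_opp
    return v / np.linalg.norm(v)


def _corrupted_directions(fusion: float, target: float) -> dict[str, np.ndarray]:
    """Movement directions of a degraded limb.

    Two mechanisms: a fusion-driven antagonist merge (loss of decoupling
    margins) and an azimuthal rotation of the whole direction cone (altered
    coordination mapping) whose angle is solved so that the mean cosine to
    the natural directions equals the configured response-curve ``target``.
    The rotation preserves the mutual geometry of the four directions, so
    the α-space decode stays well conditioned.
    """
    beta = min(fusion, _MAX_MERGE)

    def dirs_at(dphi: float) -> dict[str, np.ndarray]:
        return {m: _merge_directions(_cone_vector(_AZIMUTH[m] + dphi),
                                     _cone_vector(_AZIMUTH[_OPPOSITE[m]] + dphi), beta)
                for m in MOVEMENTS}

    def cos_to_true(dphi: float) -> float:
        d = dirs_at(dphi)
        return float(np.mean([d[m] @ _cone_vector(_AZIMUTH[m]) for m in MOVEMENTS]))

    if target >= cos_to_true(0.0):
        return dirs_at(0.0)
    if target <= cos_to_true(np.pi):
        return dirs_at(np.pi)
    dphi = brentq(lambda x: cos_to_true(x) - target, 0.0, np.pi, xtol=1e-10)
    return dirs_at(float(dphi))


# --- ground-truth cohort ----------------------------------------------------

def _make_limb(limb_id: str, group: str, ams: float, cfg: CohortConfig,
               rng: np.random.Generator) -> GroundTruthLimb:
    W = _W_CANONICAL.copy()
    if cfg.w_jitter > 0:
        W = _normalize_cols(np.clip(W + cfg.w_jitter * rng.uniform(0.0, 1.0, W.shape), 0.0, None))
    r_motor = float(response_curve(ams, cfg.motor_amsc))
    fusion = 1.0 - r_motor
    # the centroid collapse engages only under near-total fusion
    g_cen = 0.9 * max(0.0, fusion - 0.8) / 0.2
    g = _solve_mix_weight(W, r_motor, g_cen)
    W_op = _corrupt_basis(W, g, g_cen)
    dirs = _corrupted_directions(fusion, r_motor)
    gain = float(response_curve(ams, cfg.perception_amsc))
    strains = {dof: ams * nominal for dof, nominal in cfg.nominal_strain.items()}
    return GroundTruthLimb(
        limb_id=limb_id, group=group, W_true=W_op, coeff_templates=dirs,
        ams_true=ams, emg_noise_sd=cfg.emg_noise_sd,
        perception_noise_sd=cfg.perception_noise_sd, fusion_level=fusion,
        mix_weight=g, perception_gain=gain,
        zero_sensation=limb_id in cfg.zero_sensation_limbs,
        strains=strains, config=cfg,
    )


def generate_ground_truth(cohort_config: CohortConfig, seed: int) -> list[GroundTruthLimb]:
    """Deterministically generate the virtual cohort for a seed.

    Each amputated subject contributes a residual limb (AMI or CTL) with its
    configured AMS degree plus a biologically intact (BIO) limb at AMS = 1.
    The fusion level decreases monotonically with AMS along the configured
    motor response curve.
    """
    cfg = cohort_config
    limbs: list[GroundTruthLimb] = []
    idx = 0
    for k in range(cfg.n_ami):
        ams = float(cfg.ami_ams[k % len(cfg.ami_ams)])
        limbs.append(_make_limb(f"AMI-{k + 1}", "AMI", ams, cfg,
                                np.random.default_rng([int(seed), idx])))
        idx += 1
        if cfg.include_bio:
            limbs.append(_make_limb(f"BIO-A{k + 1}", "BIO", 1.0, cfg,
                                    np.random.default_rng([int(seed), idx])))
            idx += 1
    for k in range(cfg.n_ctl):
        ams = float(cfg.ctl_ams[k % len(cfg.ctl_ams)])
        limbs.append(_make_limb(f"CTL-{k + 1}", "CTL", ams, cfg,
                                np.random.default_rng([int(seed), idx])))
        idx += 1
        if cfg.include_bio:
            limbs.append(_make_limb(f"BIO-C{k + 1}", "BIO", 1.0, cfg,
                                    np.random.default_rng([int(seed), idx])))
            idx += 1
    return limbs


# --- α-plane inversion ------------------------------------------------------

def _invert_alpha_targets(targets: np.ndarray, basis: DirectionBasis,
                          stride: int = 1) -> np.ndarray:
    """Unit synergy-space directions whose decoded α equals the targets.

    Solved on the 2-parameter cone (polar, azimuth) around the symmetric axis
    by warm-started least squares at every ``stride``-th sample, with
    normalized linear interpolation in between.
    """
    targets = np.atleast_2d(np.asarray(targets, float))
    n = targets.shape[0]
    knots = list(range(0, n, stride))
    if knots[-1] != n - 1:
        knots.append(n - 1)

    th_pd = basis.angle("PF", "DF")
    th_ie = basis.angle("IN", "EV")
    u_pf, u_df = basis.u["PF"], basis.u["DF"]
    u_in, u_ev = basis.u["IN"], basis.u["EV"]

    def decode_point(v: np.ndarray) -> np.ndarray:
        vn = v / np.linalg.norm(v)
        a_pd = (np.arccos(np.clip(u_pf @ vn, -1, 1)) - np.arccos(np.clip(u_df @ vn, -1, 1))) / th_pd
        a_ie = (np.arccos(np.clip(u_in @ vn, -1, 1)) - np.arccos(np.clip(u_ev @ vn, -1, 1))) / th_ie
        return np.array([a_ie, a_pd])

    def from_params(p: np.ndarray) -> np.ndarray:
        r = np.clip(p[0], 0.0, _MAX_CONE)
        return _cone_vector(p[1], polar=r)

    sol_knots = np.empty((len(knots), 3))
    prev = None
    for ki, i in enumerate(knots):
        x, y = targets[i]
        radius = min(abs(x) + abs(y), 1.0)
        psi = np.arctan2(y, x) if radius > 1e-9 else 0.0

        def resid(p):
            return decode_point(from_params(p)) - targets[i]

        def solve_from(p0):
            return least_squares(resid, p0, method="lm", max_nfev=200)

        sol = solve_from(prev) if prev is not None else None
        if sol is None or np.linalg.norm(sol.fun) > 1e-6:
            # multi-start over azimuths: the basis may be rotated arbitrarily
            r0 = _CONE_ANGLE * max(radius, 0.05)
            for k in range(8):
                cand = solve_from(np.array([r0, psi + 0.5 * np.pi + k * np.pi / 4]))
                if sol is None or np.linalg.norm(cand.fun) < np.linalg.norm(sol.fun):
                    sol = cand
                if np.linalg.norm(sol.fun) <= 1e-9:
                    break
        prev = sol.x
        sol_knots[ki] = from_params(sol.x)

    out = np.empty((n, 3))
    for (ki, i), (kj, j) in zip(enumerate(knots[:-1]), enumerate(knots[1:], start=1)):
        for t in range(i, j + 1):
            w = 0.0 if j == i else (t - i) / (j - i)
            v = (1 - w) * sol_knots[ki] + w * sol_knots[kj]
            out[t] = v / np.linalg.norm(v)
    out[n - 1] = sol_knots[-1]
    return np.clip(out, 0.0, None)


# --- recording assembly helpers --------------------------------------------

def _emit_recording(limb: GroundTruthLimb, C: np.ndarray, windows: list[TrialWindow],
                    rng: np.random.Generator) -> Recording:
    cfg = limb.config
    env = limb.W_true @ C
    if limb.emg_noise_sd > 0:
        # envelope-domain noise is band-limited by the 5 Hz envelope low-pass
        # of the preprocessing chain; rectification keeps envelopes >= 0
        from scipy import signal as sps

        white = rng.normal(0.0, 1.0, env.shape)
        sos = sps.butter(4, 5.0, btype="lowpass", fs=cfg.sample_rate, output="sos")
        coloured = sps.sosfiltfilt(sos, white, axis=-1)
        coloured /= max(float(coloured.std()), 1e-12)
        env = np.clip(env + limb.emg_noise_sd * coloured, 0.0, None)
    return Recording(sample_rate=cfg.sample_rate, signal=env, windows=windows,
                     channel_labels=MUSCLES, domain="envelope")


def _burst(n: int, fs: float, onset: float, duration: float) -> np.ndarray:
    t = np.arange(n) / fs
    phase = (t - onset) / duration
    out = np.sin(np.pi * np.clip(phase, 0.0, 1.0))
    out[(phase < 0) | (phase > 1)] = 0.0
    return out


def generate_discrete_trials(limb: GroundTruthLimb, seed: int) -> Recording:
    """40 repetitions of the fixed PF-IN-DF-EV discrete-movement sequence.

    Within each trial window the three synergy components rise as half-sine
    bursts with staggered onsets (equal burst integrals keep the window-mean
    activation direction exactly on the limb's template).
    """
    cfg = limb.config
    order = ("PF", "IN", "DF", "EV")
    fs = cfg.sample_rate
    win_n = int(round(cfg.rep_duration * fs))
    gap_n = int(round(cfg.rep_gap * fs))
    windows: list[TrialWindow] = []
    cols: list[np.ndarray] = []
    t0 = 0.0
    for _rep in range(cfg.discrete_reps):
        for mov in order:
            p = np.asarray(limb.coeff_templates[mov])
            first = _FIRST_ONSET[mov]
            ranks = sorted(range(3), key=lambda i: (i != first, -p[i]))
            seg = np.zeros((3, win_n))
            for rank, i in enumerate(ranks):
                onset = 0.05 + rank * cfg.burst_stagger
                seg[i] = cfg.burst_amplitude * p[i] * _burst(win_n, fs, onset, cfg.burst_duration)
            cols.append(seg)
            cols.append(np.zeros((3, gap_n)))
            windows.append(TrialWindow(mov, t0, t0 + win_n / fs))
            t0 += (win_n + gap_n) / fs
    C = np.concatenate(cols, axis=1)
    rng = np.random.default_rng([int(seed), 1])
    return _emit_recording(limb, C, windows, rng)


def _diamond_point(phase: np.ndarray, radius: float) -> np.ndarray:
    """Piecewise-linear diamond through PF(0,-r) -> EV(r,0) -> DF(0,r) -> IN(-r,0)."""
    ph = np.mod(phase, 1.0) * 4.0
    seg = np.floor(ph).astype(int)
    f = ph - seg
    corners = np.array([[0.0, -1.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
    return radius * ((1 - f)[:, None] * corners[seg] + f[:, None] * corners[seg + 1])


def _square_point(phase: np.ndarray, radius: float) -> np.ndarray:
    """Axis-aligned square path through the corners (+-r, +-r)."""
    ph = np.mod(phase, 1.0) * 4.0
    seg = np.floor(ph).astype(int)
    f = ph - seg
    corners = np.array([[1.0, -1.0], [1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]])
    return radius * ((1 - f)[:, None] * corners[seg] + f[:, None] * corners[seg + 1])


def generate_circle_task(limb: GroundTruthLimb, seed: int, *,
                         single_dof: Optional[bool] = None) -> Recording:
    """10 cycles of the draw-a-circle task.

    The intended α-plane path is a diamond (simultaneous 2-DoF control)
    blended toward an axis-aligned square with the limb's fusion level; a
    fully fused limb moves one degree of freedom at a time.
    """
    cfg = limb.config
    fs = cfg.sample_rate
    n = int(round(cfg.circle_cycles * cfg.circle_period * fs))
    phase = np.arange(n) / (cfg.circle_period * fs)
    f = 1.0 if single_dof else (0.0 if single_dof is not None else limb.fusion_level)
    alpha = (1 - f) * _diamond_point(phase, 0.8) + f * _square_point(phase, 0.55)
    U = _invert_alpha_targets(alpha, limb.direction_basis, stride=2).T
    C = 0.6 * U
    windows = [TrialWindow("PF", 0.0, n / fs)]
    rng = np.random.default_rng([int(seed), 2])
    return _emit_recording(limb, C, windows, rng)


def generate_speed_accuracy_trials(limb: GroundTruthLimb, seed: int) -> Recording:
    """5 time-constraint blocks x 4 movements x 10 repetitions (200 windows).

    Movement order is randomized within each block.  Tracking follows a
    first-order approach to the target corner whose time constant, and an
    Ornstein-Uhlenbeck intent wander, grow with the fusion level.
    """
    cfg = limb.config
    fs = cfg.sample_rate
    rng = np.random.default_rng([int(seed), 3])
    f = limb.fusion_level
    gap_n = int(round(0.3 * fs))
    windows: list[TrialWindow] = []
    cols: list[np.ndarray] = []
    t0 = 0.0
    basis = limb.direction_basis
    for tc in cfg.time_constraints:
        movs = np.array([m for m in MOVEMENTS for _ in range(cfg.speed_reps)])
        rng.shuffle(movs)
        win_n = int(round(tc * fs))
        tau = tc * (0.06 + 0.5 * f)
        for mov in movs:
            t = np.arange(win_n) / fs
            track = (1.0 - np.exp(-t / tau))[:, None] * TARGETS[mov][None, :]
            wander = np.zeros((win_n, 2))
            if f > 0:
                sd = 0.35 * f
                rho = np.exp(-1.0 / (0.3 * fs))
                eps = rng.normal(0.0, sd * np.sqrt(1 - rho ** 2), size=(win_n, 2))
                for k in range(1, win_n):
                    wander[k] = rho * wander[k - 1] + eps[k]
            alpha = track + wander
            l1 = np.abs(alpha).sum(axis=1)
            over = l1 > 0.98
            alpha[over] *= (0.98 / l1[over])[:, None]
            U = _invert_alpha_targets(alpha, basis, stride=4).T
            cols.append(0.6 * U)
            cols.append(np.zeros((3, gap_n)))
            windows.append(TrialWindow(str(mov), t0, t0 + win_n / fs, time_constraint=float(tc)))
            t0 += (win_n + gap_n) / fs
    C = np.concatenate(cols, axis=1)
    return _emit_recording(limb, C, windows, rng)


def generate_perception_trials(limb: GroundTruthLimb, seed: int) -> tuple[Recording, pd.DataFrame]:
    """Psychometric task: 40 randomized PF/DF and 30 randomized IN/EV trials.

    Commanded positions sit at the configured range-of-motion fractions; the
    mirrored perceived positions follow the limb's perception-gain response
    plus Gaussian noise (a zero-sensation limb reports uncorrelated angles).
    Returns the EMG recording and the goniometry trace (time_s, ankle_deg,
    subtalar_deg).
    """
    cfg = limb.config
    fs = cfg.sample_rate
    rng = np.random.default_rng([int(seed), 4])

    def build(movs: Sequence[str], fractions: Sequence[float], n_trials: int):
        combos = [(m, r) for m in movs for r in fractions]
        reps = -(-n_trials // len(combos))
        trials = (combos * reps)[:n_trials]
        perm = rng.permutation(len(trials))
        return [trials[i] for i in perm]

    trials = (build(("PF", "DF"), cfg.pfdf_rom_fractions, cfg.perception_pfdf_trials)
              + build(("IN", "EV"), cfg.inev_rom_fractions, cfg.perception_inev_trials))

    win_n = int(round(cfg.perception_trial_duration * fs))
    gap_n = int(round(0.3 * fs))
    windows: list[TrialWindow] = []
    cols: list[np.ndarray] = []
    gon_rows = []
    t0 = 0.0
    for mov, rom in trials:
        u = np.asarray(limb.coeff_templates[mov])
        ramp = np.minimum(np.arange(win_n) / (0.15 * fs), 1.0)
        cols.append(rom * u[:, None] * ramp[None, :])
        cols.append(np.zeros((3, gap_n)))
        sign = -1.0 if mov in ("PF", "IN") else 1.0
        commanded = sign * rom
        if limb.zero_sensation:
            perceived = float(rng.uniform(-1.0, 1.0))
        else:
            perceived = limb.perception_gain * commanded
            if limb.perception_noise_sd > 0:
                perceived += float(rng.normal(0.0, limb.perception_noise_sd))
        perceived = float(np.clip(perceived, -1.0, 1.0))
        rom_deg = cfg.ankle_rom_deg if mov in ("PF", "DF") else cfg.subtalar_rom_deg
        gon_rows.append({"t_start": t0, "t_end": t0 + win_n / fs, "movement": mov,
                         "angle_deg": perceived * rom_deg})
        windows.append(TrialWindow(mov, t0, t0 + win_n / fs, rom_fraction=float(rom)))
        t0 += (win_n + gap_n) / fs
    C = np.concatenate(cols, axis=1)
    rec = _emit_recording(limb, C, windows, rng)

    time = rec.time
    ankle = np.zeros_like(time)
    subtalar = np.zeros_like(time)
    for row in gon_rows:
        mask = (time >= row["t_start"]) & (time < row["t_end"])
        if row["movement"] in ("PF", "DF"):
            ankle[mask] = row["angle_deg"]
        else:
            subtalar[mask] = row["angle_deg"]
    gon = pd.DataFrame({"time_s": time, "ankle_deg": ankle, "subtalar_deg": subtalar})
    return rec, gon


def generate_strain_summary(limb: GroundTruthLimb) -> dict[str, float]:
    """Per-DoF maximum fascicle strain implied by the limb's AMS degree."""
    return dict(limb.strains)


def modulate_raw(envelope: Recording, seed: int, carrier_fs: float = 1000.0) -> Recording:
    """Optional raw-domain mode: envelope-modulated broadband interference.

    Used only to exercise the EMG processing chain; the analysis itself
    consumes envelope-domain recordings.
    """
    rng = np.random.default_rng([int(seed), 5])
    n_raw = int(round(envelope.duration * carrier_fs))
    t_raw = np.arange(n_raw) / carrier_fs
    env_up = np.vstack([np.interp(t_raw, envelope.time, ch) for ch in envelope.signal])
    carrier = rng.normal(0.0, 1.0, env_up.shape)
    return Recording(sample_rate=carrier_fs, signal=env_up * carrier,
                     windows=list(envelope.windows), channel_labels=envelope.channel_labels,
                     domain="raw")
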