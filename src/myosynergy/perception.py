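"""Phantom-limb perception capacity from intended vs perceived positions.

Intended positions are decoded from EMG as the trial-averaged signed motor
intent ||U_S||·α per degree of freedom; perceived positions are mirrored
goniometer angles normalized by the intact-limb range of motion to [-1, 1].
A monotone psychometric function (cumulative Gaussian with asymptotes clamped
to the observed perceived extremes) is fitted per degree of freedom, and the
limb perception capacity is the perceived-range width spanned between the 5%
and 95% response levels of the function, normalized by the full +-1 scale and
averaged over the two degrees of freedom.  Uncorrelated (inconsistent or
absent) perception yields a capacity of zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr
from scipy.stats import kendalltau

#: Response-level fractions defining the capacity band.
LEVEL_LO, LEVEL_HI = 0.05, 0.95

#: One-sided rank-correlation significance threshold below which perception
#: is considered consistent with intent.
CONSISTENCY_P = 0.05


@dataclass(frozen=True)
class PerceptionTrial:
    movement: str
    theta_intended: float
    theta_perceived: float
    rom_fraction: Optional[float] = None


@dataclass
class PsychometricFit:
    """Monotone cumulative-Gaussian fit of perceived vs intended position."""

    mu: float
    sigma: float
    lo: float  # lower asymptote (observed perceived minimum)
    hi: float  # upper asymptote (observed perceived maximum)
    r_squared: float
    degenerate: bool
    theta_range: tuple[float, float]

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * ndtr((np.asarray(theta, float) - self.mu) / self.sigma)


def intended_position(us_norm: np.ndarray, alpha_axis: np.ndarray,
                      defined: Optional[np.ndarray] = None) -> float:
    """Trial-averaged signed intent ||U_S||·α for one degree of freedom.

    Undefined (rest) samples contribute zero intent magnitude; a trial with no
    samples at all is rejected.
    """
    us_norm = np.asarray(us_norm, float)
    alpha_axis = np.asarray(alpha_axis, float)
    if us_norm.size == 0:
        raise ValueError("no samples in perception trial window")
    signed = us_norm * np.where(np.isfinite(alpha_axis), alpha_axis, 0.0)
    if defined is not None:
        signed = np.where(defined, signed, 0.0)
    return float(np.mean(signed))


def fit_psychometric(trials: Sequence[PerceptionTrial]) -> PsychometricFit:
    """Least-squares cumulative-Gaussian fit of perceived vs intended position.

    Asymptotes are clamped to the observed perceived extremes; only location
    and scale are fitted.  The fit is flagged degenerate when the perceived
    responses show no one-sided positive rank correlation with intent
    (P >= 0.05), covering both absent and inconsistent perception.
    """
    if len(trials) < 6:
        raise ValueError("psychometric fit requires at least 6 trials")
    theta = np.array([t.theta_intended for t in trials], float)
    perc = np.array([t.theta_perceived for t in trials], float)
    if np.ptp(theta) <= 0:
        raise ValueError("intended positions are constant; fit undefined")
    lo, hi = float(perc.min()), float(perc.max())
    tau, p = kendalltau(theta, perc, alternative="greater")
    degenerate = bool(not np.isfinite(p) or p >= CONSISTENCY_P)

    span = max(hi - lo, 1e-12)
    theta_span = float(np.ptp(theta))

    def resid(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        pred = lo + span * ndtr((theta - mu) / np.exp(log_sigma))
        return pred - perc

    x0 = np.array([float(np.median(theta)), np.log(max(theta_span / 4.0, 1e-3))])
    sol = least_squares(resid, x0, method="lm", max_nfev=2000)
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    ss_res = float(np.sum(sol.fun ** 2))
    ss_tot = float(np.sum((perc - perc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PsychometricFit(mu=mu, sigma=sigma, lo=lo, hi=hi, r_squared=r2,
                           degenerate=degenerate,
                           theta_range=(float(theta.min()), float(theta.max())))


def capacity_from_fit(fit: PsychometricFit) -> float:
    """Perceived-range width between the 5% and 95% response levels, on [0, 1].

    Levels are truncated to the observed perceived extremes when the fitted
    function does not reach them within the observed range.
    """
    if fit.degenerate:
        return 0.0
    level_lo = fit.lo + LEVEL_LO * (fit.hi - fit.lo)
    level_hi = fit.lo + LEVEL_HI * (fit.hi - fit.lo)
    level_lo = min(max(level_lo, fit.lo), fit.hi)
    level_hi = max(min(level_hi, fit.hi), fit.lo)
    return float(np.clip((level_hi - level_lo) / 2.0, 0.0, 1.0))


def limb_perception_capacity(fit_pfdf: Optional[PsychometricFit],
                             fit_inev: Optional[PsychometricFit],
                             zero_sensation: bool = False) -> float:
    """Mean per-DoF capacity; zero for absent or inconsistent sensation."""
    if zero_sensation:
        return 0.0
    caps = []
    for fit in (fit_pfdf, fit_inev):
        caps.append(capacity_from_fit(fit) if fit is not None else 0.0)
    return float(np.mean(caps))
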