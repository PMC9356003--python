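"""Agonist-antagonist muscle strain (AMS) degree and response-curve statistics.

The AMS degree of a residual limb is the mean over the two degrees of freedom
(PF-DF and IN-EV) of the maximum fascicle strain normalized by the nominal
intact-limb strain range, clipped to [0, 1].  Each sensory-motor response
variable y is related to AMS by a first-order exponential response curve

    y = y_inf * (1 - exp(-λ · AMS))            (optional intercept exposed)

whose critical degree AMS_c = ln(20)/λ is the AMS at which the curve reaches
95% of its asymptote.  Association is tested by one-sided Kendall's tau;
AMS_c uncertainty is reported as the jackknife (leave-one-out) mean ± s.d.
Group comparisons use paired/unpaired t-tests, Shapiro-Wilk normality checks,
Cohen's d, and a 2-way interaction ANOVA (group x limb side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

LN20 = float(np.log(20.0))


def compute_ams(strains: Mapping[str, float], nominal_ranges: Mapping[str, float]) -> float:
    """AMS degree: mean over DoFs of strain/nominal, each ratio clipped to [0, 1]."""
    ratios = []
    for dof in ("PFDF", "INEV"):
        if dof not in strains or dof not in nominal_ranges:
            raise ValueError(f"missing strain or nominal range for DoF {dof}")
        nominal = float(nominal_ranges[dof])
        if nominal <= 0:
            raise ValueError("nominal strain ranges must be positive")
        ratios.append(float(np.clip(strains[dof] / nominal, 0.0, 1.0)))
    return float(np.mean(ratios))


def kendall_tau(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Tie-corrected Kendall's tau-b with a one-sided P for positive association."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("kendall_tau needs paired samples, n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("kendall_tau requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined for a constant sample")
    res = stats.kendalltau(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ResponseCurveFit:
    """Exponential AMS->response fit with its critical degree AMS_c."""

    y_inf: float
    lam: float
    intercept: float
    r_squared: float
    saturating: bool
    jackknife_mean: Optional[float] = None
    jackknife_sd: Optional[float] = None
    n: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def ams_c(self) -> float:
        return LN20 / self.lam if (self.saturating and self.lam > 0) else float("nan")

    def predict(self, ams: np.ndarray) -> np.ndarray:
        return self.intercept + self.y_inf * (1.0 - np.exp(-self.lam * np.asarray(ams, float)))


def fit_response_curve(ams, responses, with_intercept: bool = False) -> ResponseCurveFit:
    """Least-squares fit of y = y_inf (1 - exp(-λ AMS)) (+ optional intercept).

    Initialization is deterministic: y_inf from the response maximum, λ from a
    log-linearization of the residual saturation.  A non-positive fitted λ is
    flagged non-saturating (AMS_c undefined).
    """
    a = np.asarray(ams, float)
    y = np.asarray(responses, float)
    if a.size != y.size or a.size < 5:
        raise ValueError("response-curve fit requires paired samples, n >= 5")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(y))):
        raise ValueError("response-curve fit requires finite values")

    y_inf0 = max(float(y.max()), 1e-6)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - y / (y_inf0 * 1.05)
        ok = (frac > 1e-9) & (a > 0)
        lam0 = float(np.median(-np.log(frac[ok]) / a[ok])) if np.any(ok) else 1.0
    lam0 = float(np.clip(lam0, 1e-3, 1e3))

    if with_intercept:
        def resid(p):
            return p[2] + p[0] * (1.0 - np.exp(-p[1] * a)) - y
        x0 = np.array([y_inf0, lam0, 0.0])
    else:
        def resid(p):
            return p[0] * (1.0 - np.exp(-p[1] * a)) - y
        x0 = np.array([y_inf0, lam0])
    sol = least_squares(resid, x0, method="lm", max_nfev=5000)
    y_inf, lam = float(sol.x[0]), float(sol.x[1])
    intercept = float(sol.x[2]) if with_intercept else 0.0
    ss_res = float(np.sum(sol.fun ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # a saturating response needs a positive rate, positive asymptote and a
    # fit that beats the flat mean; otherwise AMS_c is undefined
    saturating = bool(lam > 0 and y_inf > 0 and ss_tot > 0 and r2 > 0)
    return ResponseCurveFit(y_inf=y_inf, lam=lam, intercept=intercept,
                            r_squared=min(r2, 1.0), saturating=saturating, n=int(a.size))


def jackknife_amsc(ams, responses, with_intercept: bool = False,
                   pseudo_values: bool = False) -> tuple[float, float]:
    """Jackknife mean and s.d. of AMS_c from leave-one-out refits.

    By default the plain mean and s.d. of the n leave-one-out estimates are
    reported; ``pseudo_values=True`` switches to the bias-corrected
    pseudo-value formula.  Non-saturating replicates are excluded with a
    warning.
    """
    a = np.asarray(ams, float)
    y = np.asarray(responses, float)
    if a.size < 6:
        raise ValueError("jackknife requires n >= 6")
    estimates = []
    for k in range(a.size):
        keep = np.arange(a.size) != k
        fit = fit_response_curve(a[keep], y[keep], with_intercept=with_intercept)
        if fit.saturating:
            estimates.append(fit.ams_c)
        else:
            warnings.warn(f"leave-one-out replicate {k} non-saturating; excluded",
                          stacklevel=2)
    est = np.asarray(estimates, float)
    if est.size < 2:
        raise ValueError("too few saturating jackknife replicates")
    if pseudo_values:
        full = fit_response_curve(a, y, with_intercept=with_intercept).ams_c
        n = a.size
        pseudo = n * full - (n - 1) * est
        return float(np.mean(pseudo)), float(np.std(pseudo, ddof=1) / np.sqrt(n))
    return float(np.mean(est)), float(np.std(est, ddof=1))


def fit_with_jackknife(ams, responses, with_intercept: bool = False) -> ResponseCurveFit:
    fit = fit_response_curve(ams, responses, with_intercept=with_intercept)
    if fit.saturating:
        try:
            jm, jsd = jackknife_amsc(ams, responses, with_intercept=with_intercept)
            fit.jackknife_mean, fit.jackknife_sd = jm, jsd
        except ValueError as exc:
            fit.warnings.append(str(exc))
    return fit


def cohens_d(x, y) -> float:
    """Cohen's d with the pooled standard deviation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    return float((x.mean() - y.mean()) / pooled)


def _two_way_interaction_anova(values: np.ndarray, group: np.ndarray, side: np.ndarray) -> tuple[float, float]:
    """F and P of the group x side interaction from an OLS two-way ANOVA."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": values, "g": group, "s": side})
    model = ols("y ~ C(g) * C(s)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(g):C(s)"]
    return float(row["F"]), float(row["PR(>F)"])


def group_tests(table: pd.DataFrame, value: str) -> dict[str, float]:
    """The study's group-comparison battery for one response variable.

    ``table`` holds one row per limb with columns ``limb_id``, ``group``
    (AMI/CTL/BIO-A/BIO-C), ``subject`` (pairing key) and the value column.
    Returns paired one-tailed t (AMI vs BIO-A, CTL vs BIO-C; alternative:
    affected < unaffected), unpaired two-tailed t with Cohen's d (AMI vs CTL),
    Shapiro-Wilk P per group, and the 2-way interaction ANOVA.
    """
    def vals(g):
        sub = table[table.group == g].sort_values("subject")
        return sub[value].to_numpy(), sub["subject"].to_numpy()

    ami, ami_subj = vals("AMI")
    ctl, ctl_subj = vals("CTL")
    bio_a, bio_a_subj = vals("BIO-A")
    bio_c, bio_c_subj = vals("BIO-C")
    for g, (v, _) in (("AMI", (ami, 0)), ("CTL", (ctl, 0)), ("BIO-A", (bio_a, 0)), ("BIO-C", (bio_c, 0))):
        if v.size < 2:
            raise ValueError(f"group {g} needs at least 2 limbs")
    if not (np.array_equal(ami_subj, bio_a_subj) and np.array_equal(ctl_subj, bio_c_subj)):
        raise ValueError("paired tests require matching subjects in affected/unaffected groups")

    def paired_t(a, b):
        # t reported as unaffected minus affected, one-tailed for a deficit;
        # identical samples give t = 0 with one-tailed P = 0.5 by convention
        if np.all(a == b):
            return 0.0, 0.5
        t, p = stats.ttest_rel(a, b, alternative="greater")
        return float(t), float(p)

    out: dict[str, float] = {}
    out["t_ami_bioa"], out["p_ami_bioa"] = paired_t(bio_a, ami)
    out["t_ctl_bioc"], out["p_ctl_bioc"] = paired_t(bio_c, ctl)
    t, p = stats.ttest_ind(ami, ctl)
    out["t_ami_ctl"], out["p_ami_ctl"] = float(t), float(p)
    out["cohens_d_ami_ctl"] = cohens_d(ami, ctl)
    for g, v in (("ami", ami), ("ctl", ctl), ("bio", np.concatenate([bio_a, bio_c]))):
        # Shapiro-Wilk needs n >= 3 and a non-degenerate sample
        out[f"shapiro_p_{g}"] = (float(stats.shapiro(v).pvalue)
                                 if v.size >= 3 and np.ptp(v) > 0 else float("nan"))
    values = np.concatenate([ami, ctl, bio_a, bio_c])
    grp = np.array(["AMI"] * ami.size + ["CTL"] * ctl.size + ["AMI"] * bio_a.size + ["CTL"] * bio_c.size)
    side = np.array(["affected"] * (ami.size + ctl.size) + ["unaffected"] * (bio_a.size + bio_c.size))
    out["anova_f_interaction"], out["anova_p_interaction"] = _two_way_interaction_anova(values, grp, side)
    return out
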