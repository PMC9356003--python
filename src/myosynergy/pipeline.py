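"""End-to-end analysis pipeline on a (synthetic) cohort.

Stage order mirrors the experimental protocol: simulate -> extract synergies
from discrete trials -> naturalness against the BIO reference -> decode the
circle and speed-accuracy tasks in α-space -> perception capacity ->
AMS response-curve statistics.  ``run_pipeline`` executes everything in
memory and returns a results bundle (per-limb table, per-variable response
fits, group statistics, rendered report).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import perception as perc
from . import response as resp
from .config import PipelineConfig
from .decoding import AlphaTrace, DirectionBasis, MarginMatrix, alpha_decode, fixed_basis_decompose
from .metrics import economy_of_motion, motor_control_performance, two_dof_controllability
from .naturalness import (LimbVectors, ReferenceBasis, activation_similarity, build_reference,
                          leave_one_out_similarity, pad_columns, synergy_similarity)
from .recording import MOVEMENTS, Recording
from .synergy import SynergyModel, extract_synergies, pad_to_dim
from .synthetic import (GroundTruthLimb, generate_circle_task, generate_discrete_trials,
                        generate_ground_truth, generate_perception_trials,
                        generate_speed_accuracy_trials, generate_strain_summary)

RESPONSE_VARIABLES = ("mss", "sas", "twodof", "lpc")


@dataclass
class LimbResult:
    limb_id: str
    group: str  # AMI | CTL | BIO-A | BIO-C
    subject: str
    ams_degree: float
    model: SynergyModel
    vectors: LimbVectors
    margins: MarginMatrix
    mss: float = np.nan
    sas: float = np.nan
    twodof: float = np.nan
    lpc: float = np.nan
    perf_by_tc: dict[float, float] = field(default_factory=dict)
    econ_by_tc: dict[float, float] = field(default_factory=dict)


@dataclass
class PipelineResults:
    table: pd.DataFrame
    reference: ReferenceBasis
    response_fits: dict[str, resp.ResponseCurveFit]
    taus: dict[str, tuple[float, float]]
    group_stats: dict[str, dict[str, float]]
    limb_results: list[LimbResult]
    config: PipelineConfig


def _subgroup(limb: GroundTruthLimb) -> tuple[str, str]:
    """(reporting group, subject pairing key) for a limb."""
    if limb.group == "BIO":
        tag = limb.limb_id.replace("BIO-", "")  # e.g. A3 / C5
        return f"BIO-{tag[0]}", tag
    side = "A" if limb.group == "AMI" else "C"
    return limb.group, f"{side}{limb.limb_id.split('-')[1]}"


def _movement_coefficients(model: SynergyModel, rec: Recording,
                           decimate: int) -> dict[str, np.ndarray]:
    """Per-movement coefficient samples aligned with the concatenated matrix."""
    coeffs: dict[str, list[np.ndarray]] = {m: [] for m in MOVEMENTS}
    offset = 0
    C = pad_to_dim(model.C.T, 3).T
    for w in rec.windows:
        sl = rec.window_slice(w)
        n = len(range(sl.start, sl.stop, decimate))
        coeffs[w.movement].append(C[:, offset:offset + n])
        offset += n
    return {m: np.concatenate(v, axis=1) for m, v in coeffs.items() if v}


def extract_from_recording(rec: Recording, cfg: PipelineConfig, seed: int,
                           limb_id: str = "", group: str = "") -> tuple[SynergyModel, LimbVectors, MarginMatrix]:
    """Discrete-trial synergy extraction and per-movement activation vectors."""
    M = np.concatenate([rec.window_signal(w)[:, ::cfg.nmf_decimate] for w in rec.windows], axis=1)
    model = extract_synergies(M, seed=seed, vaf_threshold=cfg.vaf_threshold, **cfg.nmf_kwargs)
    coeffs = _movement_coefficients(model, rec, cfg.nmf_decimate)
    u = {}
    for m in MOVEMENTS:
        mean = coeffs[m].mean(axis=1)
        norm = np.linalg.norm(mean)
        u[m] = mean / norm if norm > 0 else mean
    W3 = pad_columns(model.W)
    vectors = LimbVectors(limb_id=limb_id, group=group, W=W3, u=u)
    margins = MarginMatrix.from_trials(coeffs, u)
    return model, vectors, margins


def _task_trace(signal: np.ndarray, W: np.ndarray, basis: DirectionBasis,
                sample_rate: float) -> AlphaTrace:
    U = fixed_basis_decompose(signal, W)
    return alpha_decode(U, basis, sample_rate=sample_rate)


def circle_controllability(rec: Recording, W: np.ndarray, basis: DirectionBasis) -> float:
    """2-DoF controllability of a draw-a-circle recording."""
    trace = _task_trace(rec.signal, W, basis, rec.sample_rate)
    return two_dof_controllability(trace)


def speed_accuracy_metrics(rec: Recording, W: np.ndarray,
                           basis: DirectionBasis) -> tuple[dict[float, float], dict[float, float]]:
    """Per-time-constraint mean motor-control performance and economy of motion."""
    perf: dict[float, list[float]] = {}
    econ: dict[float, list[float]] = {}
    for w in rec.windows:
        trace = _task_trace(rec.window_signal(w), W, basis, rec.sample_rate)
        ok = trace.defined
        if not np.any(ok):
            continue
        alpha = trace.alpha[ok]
        t = trace.time[ok]
        perf.setdefault(w.time_constraint, []).append(
            motor_control_performance(alpha, t, w.movement))
        econ.setdefault(w.time_constraint, []).append(
            economy_of_motion(alpha, w.movement))
    return ({tc: float(np.mean(v)) for tc, v in perf.items()},
            {tc: float(np.mean(v)) for tc, v in econ.items()})


def perception_capacity(rec: Recording, gon: pd.DataFrame, W: np.ndarray,
                        basis: DirectionBasis, ankle_rom_deg: float,
                        subtalar_rom_deg: float) -> float:
    """Limb perception capacity from EMG-decoded intent and mirrored goniometry."""
    trials_pfdf: list[perc.PerceptionTrial] = []
    trials_inev: list[perc.PerceptionTrial] = []
    time = gon["time_s"].to_numpy()
    for w in rec.windows:
        trace = _task_trace(rec.window_signal(w), W, basis, rec.sample_rate)
        is_ankle = w.movement in ("PF", "DF")
        axis = trace.alpha_pfdf if is_ankle else trace.alpha_inev
        theta = perc.intended_position(trace.us_norm, axis, trace.defined)
        mask = (time >= w.t_start) & (time < w.t_end)
        col = "ankle_deg" if is_ankle else "subtalar_deg"
        rom = ankle_rom_deg if is_ankle else subtalar_rom_deg
        perceived = float(gon.loc[mask, col].mean() / rom)
        trial = perc.PerceptionTrial(movement=w.movement, theta_intended=theta,
                                     theta_perceived=perceived, rom_fraction=w.rom_fraction)
        (trials_pfdf if is_ankle else trials_inev).append(trial)
    fit_pfdf = perc.fit_psychometric(trials_pfdf)
    fit_inev = perc.fit_psychometric(trials_inev)
    return perc.limb_perception_capacity(fit_pfdf, fit_inev)


def analyze_limb(limb: GroundTruthLimb, cfg: PipelineConfig, seed: int) -> LimbResult:
    rec = generate_discrete_trials(limb, seed)
    model, vectors, margins = extract_from_recording(rec, cfg, seed,
                                                     limb_id=limb.limb_id, group=limb.group)
    basis = DirectionBasis(u=vectors.u)
    group, subject = _subgroup(limb)
    ams = resp.compute_ams(generate_strain_summary(limb), limb.config.nominal_strain)
    result = LimbResult(limb_id=limb.limb_id, group=group, subject=subject,
                        ams_degree=ams, model=model, vectors=vectors, margins=margins)
    result.twodof = circle_controllability(generate_circle_task(limb, seed), model.W, basis)
    result.perf_by_tc, result.econ_by_tc = speed_accuracy_metrics(
        generate_speed_accuracy_trials(limb, seed), model.W, basis)
    if limb.group != "BIO":
        prec, gon = generate_perception_trials(limb, seed)
        result.lpc = perception_capacity(prec, gon, model.W, basis,
                                         limb.config.ankle_rom_deg,
                                         limb.config.subtalar_rom_deg)
    return result


def run_pipeline(cfg: PipelineConfig, seed: Optional[int] = None,
                 limbs: Optional[list[GroundTruthLimb]] = None) -> PipelineResults:
    """Simulate (or accept) a cohort and run every analysis stage."""
    seed = cfg.seed if seed is None else seed
    if limbs is None:
        limbs = generate_ground_truth(cfg.cohort, seed)
    results = [analyze_limb(limb, cfg, seed + 1000 * i) for i, limb in enumerate(limbs)]

    bio = [r for r in results if r.group.startswith("BIO")]
    if len(bio) < 2:
        raise ValueError("naturalness stage requires at least two BIO limbs")
    reference = build_reference([r.vectors for r in bio])
    loo = leave_one_out_similarity([r.vectors for r in bio])
    for r in results:
        if r.group.startswith("BIO"):
            r.mss, r.sas = loo[r.limb_id]
        else:
            r.mss = synergy_similarity(r.vectors.W, reference)
            r.sas = activation_similarity(r.vectors.u, reference, W_subject=r.vectors.W)

    rows = []
    for r in results:
        row = {"limb_id": r.limb_id, "group": r.group, "subject": r.subject,
               "ams_degree": r.ams_degree, "n_synergies": r.model.n_synergies,
               "vaf": r.model.vaf, "mss": r.mss, "sas": r.sas,
               "twodof": r.twodof, "lpc": r.lpc}
        for tc, v in sorted(r.perf_by_tc.items(), reverse=True):
            row[f"perf_id{tc:g}"] = v
        for tc, v in sorted(r.econ_by_tc.items(), reverse=True):
            row[f"econ_id{tc:g}"] = v
        rows.append(row)
    table = pd.DataFrame(rows)

    residual = table[~table.group.str.startswith("BIO")]
    taus: dict[str, tuple[float, float]] = {}
    fits: dict[str, resp.ResponseCurveFit] = {}
    for var in RESPONSE_VARIABLES:
        y = residual[var].to_numpy(float)
        a = residual["ams_degree"].to_numpy(float)
        if not np.all(np.isfinite(y)) or y.size < 4 or np.ptp(y) == 0:
            continue  # stage not run (or degenerate) for this cohort
        taus[var] = resp.kendall_tau(a, y)
        if y.size >= 5:
            fits[var] = resp.fit_with_jackknife(a, y, with_intercept=cfg.response_intercept)
    for prefix in ("perf", "econ"):
        for col in [c for c in residual.columns if c.startswith(f"{prefix}_id")]:
            y = residual[col].to_numpy(float)
            a = residual["ams_degree"].to_numpy(float)
            if y.size < 4 or np.ptp(y) == 0:
                continue
            taus[col] = resp.kendall_tau(a, y)
            if y.size >= 5:
                fits[col] = resp.fit_with_jackknife(a, y, with_intercept=cfg.response_intercept)

    group_stats: dict[str, dict[str, float]] = {}
    stats_table = table.copy()
    for var in ("mss", "sas", "twodof"):
        group_stats[var] = resp.group_tests(stats_table, var)

    return PipelineResults(table=table, reference=reference, response_fits=fits,
                           taus=taus, group_stats=group_stats, limb_results=results,
                           config=cfg)


_LABELS = {"mss": "muscle synergy similarity", "sas": "synergy activation similarity",
           "twodof": "2-DoF motor controllability", "lpc": "limb perception capacity"}


def results_summary(res: PipelineResults) -> dict:
    """Flat, JSON-ready summary of the statistics a report prints."""
    out: dict[str, object] = {"n_residual_limbs": int((~res.table.group.str.startswith("BIO")).sum())}
    for var, (tau, p) in res.taus.items():
        out[f"tau_{var}"] = tau
        out[f"p_{var}"] = p
    for var, fit in res.response_fits.items():
        out[f"amsc_{var}"] = fit.ams_c if fit.saturating else None
        out[f"amsc_jk_mean_{var}"] = fit.jackknife_mean
        out[f"amsc_jk_sd_{var}"] = fit.jackknife_sd
        out[f"r2_{var}"] = fit.r_squared
    for var, stats in res.group_stats.items():
        for k, v in stats.items():
            out[f"{var}_{k}"] = v
    perf_cols = [v for v in res.response_fits if v.startswith("perf_id")]
    econ_cols = [v for v in res.response_fits if v.startswith("econ_id")]
    for prefix, cols in (("perf", perf_cols), ("econ", econ_cols)):
        if not cols:
            continue
        out[f"tau_{prefix}_mean"] = float(np.mean([res.taus[c][0] for c in cols]))
        jk = [res.response_fits[c].jackknife_mean for c in cols
              if res.response_fits[c].jackknife_mean is not None]
        if jk:
            out[f"amsc_{prefix}_mean"] = float(np.mean(jk))
    return out


def render_report(summary: Mapping[str, object]) -> str:
    """Plain-text report (τ, P, AMS_c ± s.d., R², t, F, d) from a summary dict.

    Accepts the dict produced by :func:`results_summary` (or read back from
    its JSON serialization), so text and JSON reports are numerically
    identical by construction.
    """
    n = summary.get("n_residual_limbs", "?")
    lines = [f"AMS response-curve statistics (residual limbs, n = {n})", ""]
    per_id = sorted({k.removeprefix("tau_") for k in summary
                     if k.startswith(("tau_perf_id", "tau_econ_id"))})
    for var in list(RESPONSE_VARIABLES) + per_id:
        label = _LABELS.get(var, var)
        tau = summary.get(f"tau_{var}")
        if tau is None:
            lines.append(f"{label}: not computed")
            continue
        p = summary.get(f"p_{var}")
        jk_mean = summary.get(f"amsc_jk_mean_{var}")
        jk_sd = summary.get(f"amsc_jk_sd_{var}")
        r2 = summary.get(f"r2_{var}")
        if jk_mean is not None:
            lines.append(f"{label}: tau = {tau:.2f}, P = {p:.3g}; "
                         f"AMS_c = {jk_mean:.2f} +- {jk_sd:.2f} (jackknife), "
                         f"R^2 = {r2:.2f}")
        else:
            lines.append(f"{label}: tau = {tau:.2f}, P = {p:.3g}; AMS_c not determined")
    lines.append("")
    for var in ("mss", "sas", "twodof"):
        if f"{var}_t_ami_bioa" not in summary:
            continue
        label = _LABELS.get(var, var)
        s = {k.removeprefix(f"{var}_"): v for k, v in summary.items()
             if k.startswith(f"{var}_")}
        lines.append(f"{label} group comparisons: "
                     f"t(BIO-A:AMI) = {s['t_ami_bioa']:.2f} (P = {s['p_ami_bioa']:.3g}), "
                     f"t(BIO-C:CTL) = {s['t_ctl_bioc']:.2f} (P = {s['p_ctl_bioc']:.3g}), "
                     f"t(AMI:CTL) = {s['t_ami_ctl']:.2f} (P = {s['p_ami_ctl']:.3g}), "
                     f"d = {s['cohens_d_ami_ctl']:.2f}, "
                     f"F(interaction) = {s['anova_f_interaction']:.2f} "
                     f"(P = {s['anova_p_interaction']:.3g})")
    return "\n".join(lines) + "\n"
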