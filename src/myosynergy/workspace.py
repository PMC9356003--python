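"""File-based pipeline stages over a workspace directory.

Each stage reads the artifacts of the previous one, so the analysis can be
driven entirely from CSV/JSON files (as it would be with recorded data):

    ws/
      config.yaml
      limbs/<limb_id>/   discrete.csv (+_windows), circle.csv, speed.csv
                         (+_windows), perception.csv (+_windows),
                         goniometry.csv, meta.json
      synergy/<limb_id>.json
      naturalness.csv  metrics.csv  perception_capacity.csv
      summary.csv  stats.json  report.txt
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig, save_config
from .decoding import DirectionBasis, fixed_basis_decompose, alpha_decode
from .naturalness import (LimbVectors, activation_similarity, build_reference,
                          leave_one_out_similarity, synergy_similarity)
from .pipeline import (RESPONSE_VARIABLES, circle_controllability, extract_from_recording,
                       perception_capacity, render_report, speed_accuracy_metrics)
from .recording import MOVEMENTS
from .response import compute_ams, fit_with_jackknife, group_tests, kendall_tau
from .synthetic import (generate_circle_task, generate_discrete_trials,
                        generate_ground_truth, generate_perception_trials,
                        generate_speed_accuracy_trials, generate_strain_summary)


def _limb_dirs(ws: Path) -> list[Path]:
    return sorted((ws / "limbs").iterdir())


def stage_simulate(cfg: PipelineConfig, ws: Path, seed: int) -> None:
    ws.mkdir(parents=True, exist_ok=True)
    save_config(cfg, ws / "config.yaml")
    limbs = generate_ground_truth(cfg.cohort, seed)
    for i, limb in enumerate(limbs):
        d = ws / "limbs" / limb.limb_id
        d.mkdir(parents=True, exist_ok=True)
        lseed = seed + 1000 * i
        io.write_recording(generate_discrete_trials(limb, lseed),
                           d / "discrete.csv", d / "discrete_windows.csv")
        io.write_recording(generate_circle_task(limb, lseed), d / "circle.csv")
        io.write_recording(generate_speed_accuracy_trials(limb, lseed),
                           d / "speed.csv", d / "speed_windows.csv")
        if limb.group != "BIO":
            prec, gon = generate_perception_trials(limb, lseed)
            io.write_recording(prec, d / "perception.csv", d / "perception_windows.csv")
            io.write_goniometry(gon, d / "goniometry.csv")
        io.write_json({
            "limb_id": limb.limb_id, "group": limb.group, "seed": lseed,
            "strains": generate_strain_summary(limb),
            "nominal_strain": limb.config.nominal_strain,
            "ankle_rom_deg": limb.config.ankle_rom_deg,
            "subtalar_rom_deg": limb.config.subtalar_rom_deg,
        }, d / "meta.json")


def stage_extract(cfg: PipelineConfig, ws: Path) -> None:
    (ws / "synergy").mkdir(exist_ok=True)
    for d in _limb_dirs(ws):
        meta = io.read_json(d / "meta.json")
        rec = io.read_recording(d / "discrete.csv", d / "discrete_windows.csv")
        model, vectors, margins = extract_from_recording(
            rec, cfg, meta["seed"], limb_id=meta["limb_id"], group=meta["group"])
        io.write_json({
            "limb_id": meta["limb_id"], "group": meta["group"],
            "W": model.W, "n_synergies": model.n_synergies, "vaf": model.vaf,
            "W_padded": vectors.W, "u": {m: vectors.u[m] for m in MOVEMENTS},
            "margins": {"-".join(k): v for k, v in margins.phi.items()},
        }, ws / "synergy" / f"{meta['limb_id']}.json")


def _load_vectors(ws: Path) -> list[tuple[dict, LimbVectors]]:
    out = []
    for p in sorted((ws / "synergy").glob("*.json")):
        data = io.read_json(p)
        vec = LimbVectors(limb_id=data["limb_id"], group=data["group"],
                          W=np.asarray(data["W_padded"]),
                          u={m: np.asarray(v) for m, v in data["u"].items()})
        out.append((data, vec))
    return out


def stage_naturalness(cfg: PipelineConfig, ws: Path) -> None:
    loaded = _load_vectors(ws)
    bio = [v for _, v in loaded if v.group == "BIO"]
    if len(bio) < 2:
        raise ValueError("naturalness stage requires at least two BIO limbs "
                         f"(found {len(bio)})")
    ref = build_reference(bio)
    loo = leave_one_out_similarity(bio)
    rows = []
    for data, vec in loaded:
        if vec.group == "BIO":
            mss, sas = loo[vec.limb_id]
        else:
            mss = synergy_similarity(vec.W, ref)
            sas = activation_similarity(vec.u, ref, W_subject=vec.W)
        rows.append({"limb_id": vec.limb_id, "group": vec.group, "mss": mss, "sas": sas})
    pd.DataFrame(rows).to_csv(ws / "naturalness.csv", index=False)


def _limb_basis(ws: Path, limb_id: str) -> tuple[np.ndarray, DirectionBasis]:
    data = io.read_json(ws / "synergy" / f"{limb_id}.json")
    W = np.asarray(data["W"])
    basis = DirectionBasis(u={m: np.asarray(v) for m, v in data["u"].items()})
    return W, basis


def stage_decode(cfg: PipelineConfig, ws: Path) -> None:
    """Write α-traces of the circle task per limb."""
    (ws / "traces").mkdir(exist_ok=True)
    for d in _limb_dirs(ws):
        limb_id = d.name
        W, basis = _limb_basis(ws, limb_id)
        rec = io.read_recording(d / "circle.csv")
        U = fixed_basis_decompose(rec.signal, W)
        trace = alpha_decode(U, basis, sample_rate=rec.sample_rate)
        pd.DataFrame({
            "time_s": trace.time, "alpha_INEV": trace.alpha_inev,
            "alpha_PFDF": trace.alpha_pfdf, "us_norm": trace.us_norm,
            "defined_flag": trace.defined.astype(int),
        }).to_csv(ws / "traces" / f"{limb_id}_circle.csv", index=False)


def stage_metrics(cfg: PipelineConfig, ws: Path) -> None:
    rows = []
    for d in _limb_dirs(ws):
        limb_id = d.name
        W, basis = _limb_basis(ws, limb_id)
        circle = io.read_recording(d / "circle.csv")
        row = {"limb_id": limb_id,
               "twodof": circle_controllability(circle, W, basis)}
        speed = io.read_recording(d / "speed.csv", d / "speed_windows.csv")
        perf, econ = speed_accuracy_metrics(speed, W, basis)
        for tc, v in sorted(perf.items(), reverse=True):
            row[f"perf_id{tc:g}"] = v
        for tc, v in sorted(econ.items(), reverse=True):
            row[f"econ_id{tc:g}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(ws / "metrics.csv", index=False)


def stage_perception(cfg: PipelineConfig, ws: Path) -> None:
    rows = []
    for d in _limb_dirs(ws):
        if not (d / "perception.csv").exists():
            continue
        meta = io.read_json(d / "meta.json")
        W, basis = _limb_basis(ws, d.name)
        rec = io.read_recording(d / "perception.csv", d / "perception_windows.csv")
        gon = io.read_goniometry(d / "goniometry.csv")
        lpc = perception_capacity(rec, gon, W, basis,
                                  meta["ankle_rom_deg"], meta["subtalar_rom_deg"])
        rows.append({"limb_id": d.name, "lpc": lpc})
    pd.DataFrame(rows).to_csv(ws / "perception_capacity.csv", index=False)


def _reporting_group(limb_id: str, group: str) -> tuple[str, str]:
    if group == "BIO":
        tag = limb_id.replace("BIO-", "")
        return f"BIO-{tag[0]}", tag
    side = "A" if group == "AMI" else "C"
    return group, f"{side}{limb_id.split('-')[1]}"


def stage_respond(cfg: PipelineConfig, ws: Path) -> dict:
    nat = pd.read_csv(ws / "naturalness.csv")
    met = pd.read_csv(ws / "metrics.csv")
    table = nat.merge(met, on="limb_id", how="left")
    pcap = ws / "perception_capacity.csv"
    if pcap.exists():
        cap = pd.read_csv(pcap)
        if len(cap):
            table = table.merge(cap, on="limb_id", how="left")
    if "lpc" not in table.columns:
        table["lpc"] = np.nan
    ams, groups, subjects = [], [], []
    for limb_id, group in zip(table["limb_id"], table["group"]):
        meta = io.read_json(ws / "limbs" / limb_id / "meta.json")
        ams.append(compute_ams(meta["strains"], meta["nominal_strain"]))
        g, s = _reporting_group(limb_id, group)
        groups.append(g)
        subjects.append(s)
    table["ams_degree"] = ams
    table["group"] = groups
    table["subject"] = subjects
    table.to_csv(ws / "summary.csv", index=False)

    residual = table[~table.group.str.startswith("BIO")]
    summary: dict[str, object] = {"n_residual_limbs": int(len(residual))}
    a = residual["ams_degree"].to_numpy(float)
    metric_cols = list(RESPONSE_VARIABLES) + sorted(
        c for c in residual.columns if c.startswith(("perf_id", "econ_id")))
    for var in metric_cols:
        if var not in residual.columns:
            continue
        y = residual[var].to_numpy(float)
        if not np.all(np.isfinite(y)) or y.size < 4 or np.ptp(y) == 0:
            continue
        tau, p = kendall_tau(a, y)
        summary[f"tau_{var}"] = tau
        summary[f"p_{var}"] = p
        if y.size < 5:
            continue
        fit = fit_with_jackknife(a, y, with_intercept=cfg.response_intercept)
        summary[f"amsc_{var}"] = fit.ams_c if fit.saturating else None
        summary[f"amsc_jk_mean_{var}"] = fit.jackknife_mean
        summary[f"amsc_jk_sd_{var}"] = fit.jackknife_sd
        summary[f"r2_{var}"] = fit.r_squared
    for var in ("mss", "sas", "twodof"):
        stats = group_tests(table, var)
        for k, v in stats.items():
            summary[f"{var}_{k}"] = v
    io.write_json(summary, ws / "stats.json")
    (ws / "report.txt").write_text(render_report(summary))
    return summary


def run_all(cfg: PipelineConfig, ws: Path, seed: int) -> dict:
    stage_simulate(cfg, ws, seed)
    stage_extract(cfg, ws)
    stage_naturalness(cfg, ws)
    stage_decode(cfg, ws)
    stage_metrics(cfg, ws)
    stage_perception(cfg, ws)
    return stage_respond(cfg, ws)
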