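"""Config-driven pipeline runs: simulate, analyze, report, sweep.

Each run resolves a :class:`RunConfig` (from YAML or keyword overrides),
writes a frozen copy of the resolved config next to its outputs, and logs
the package version, config hash and per-stage timing, so every artifact
file is reproducible from its config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import DEFAULT_TRIM_FRACTION, FitResult, fit_replicates
from .grid import WHOLE_ROOM, build_grid
from .metrics import (DEFAULT_SMOOTH_WINDOW_H, CalibrationCurve,
                      calibrate_signal, cv_over_time, exposure_summary,
                      normalize_by_mass, smooth_running_average,
                      subtract_background, twa)
from .model import simulate_model1, simulate_model2
from .parameters import EmissionEvent, FlowParameters
from .series import ConcentrationSeries
from .synth import generate_study, scenario

logger = logging.getLogger("sprayroom")

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_report",
           "run_sweep", "preprocess_replicate"]


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    scenario: str = "trigger_50"
    scenario_overrides: dict = field(default_factory=dict)
    input_paths: list[str] = field(default_factory=list)
    outdir: str = "runs/out"
    seed: int = 0
    # preprocessing
    background_window_min: float = 5.0
    smooth_window_h: float = DEFAULT_SMOOTH_WINDOW_H
    reference_mass_g: float = 1.0
    calibration: dict | None = None  # {"slope":..., "intercept":...}
    # fitting
    trim_fraction: float = DEFAULT_TRIM_FRACTION
    fit_initial: float | None = None
    fit_upper_bound: float = 1e3
    # metrics
    durations_h: list[float] = field(default_factory=lambda: [0.1, 0.3])
    cv_ddof: int = 1
    # sweep
    sweep_ratios: list[float] = field(default_factory=lambda: [0.5, 1, 2, 5, 10])
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def resolved_spec(self):
        return scenario(self.scenario, seed=self.seed,
                        **self.scenario_overrides)


def _start_run(config: RunConfig, verb: str) -> Path:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / f"{verb}_config.yaml").write_text(
        yaml.safe_dump({"verb": verb, "version": __version__,
                        "config_hash": config.config_hash(),
                        **config.to_dict()}, sort_keys=False))
    logger.info("sprayroom %s | %s | config %s", __version__, verb,
                config.config_hash())
    return outdir


def preprocess_replicate(series: ConcentrationSeries,
                         config: RunConfig) -> ConcentrationSeries:
    """Run the measurement pipeline on one raw replicate.

    calibrate -> background-subtract -> smooth -> normalize, using the
    replicate's recorded application time, applied mass and (if no explicit
    calibration is configured) instrument gain.
    """
    out = series
    if out.stage == "raw_signal":
        if config.calibration:
            curve = CalibrationCurve(r_squared=1.0, **config.calibration)
        else:
            curve = CalibrationCurve(slope=float(out.meta.get("gain", 1.0)),
                                     intercept=0.0, r_squared=1.0)
        out = calibrate_signal(out, curve)
    t_app = float(out.meta.get("application_time_h", 0.0))
    window = (max(out.times[0], t_app - config.background_window_min / 60.0),
              t_app)
    out = subtract_background(out, window)
    out = smooth_running_average(out, config.smooth_window_h)
    applied = float(out.meta.get("applied_mass_g", config.reference_mass_g))
    return normalize_by_mass(out, applied, config.reference_mass_g)


def _load_or_generate(config: RunConfig) -> list[ConcentrationSeries]:
    if config.input_paths:
        return [ConcentrationSeries.read_csv(p) for p in config.input_paths]
    spec = config.resolved_spec()
    reps, _ = generate_study(spec)
    return reps


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Write noise-free model-1 and model-2 trajectories for the scenario.

    Produces ``model_trajectories.csv`` with a time column plus nine
    trajectory columns (the eight compartments and the well-mixed room).
    """
    outdir = _start_run(config, "simulate")
    t0 = time.perf_counter()
    spec = config.resolved_spec()
    grid = build_grid()
    params = spec.chamber.with_lambda_ex(spec.true_lambda_ex)
    times = spec.time_grid()
    mass = spec.emitted_mass_mg(spec.applied_mass_g)
    m2 = simulate_model2(grid, params,
                         EmissionEvent(source=spec.source, mass=mass), times)
    m1 = simulate_model1(params,
                         EmissionEvent(source=WHOLE_ROOM, mass=mass), times)
    frame = m2.to_frame()
    frame["C_room"] = m1.values[:, 0]
    path = outdir / "model_trajectories.csv"
    frame.to_csv(path, index=False, float_format="%.10g")
    logger.info("simulate done in %.2f s -> %s", time.perf_counter() - t0, path)
    return {"trajectories": path}


def run_sweep(config: RunConfig) -> dict[str, Path]:
    """CV-vs-time curves over a ladder of lambda_ex / lambda ratios."""
    outdir = _start_run(config, "sweep")
    t0 = time.perf_counter()
    spec = config.resolved_spec()
    grid = build_grid()
    dt = spec.sampling_interval_s / 3600.0
    n = int(round(spec.post_application_min / 60.0 / dt))
    times = dt * np.arange(n + 1)  # post-application window only
    mass = spec.emitted_mass_mg(spec.applied_mass_g)
    frame = pd.DataFrame({"time_h": times})
    for ratio in config.sweep_ratios:
        lex = ratio * spec.chamber.air_change_rate
        m2 = simulate_model2(grid, spec.chamber.with_lambda_ex(lex),
                             EmissionEvent(source=spec.source, mass=mass),
                             times)
        frame[f"cv_ratio_{ratio:g}"] = cv_over_time(
            m2, ddof=config.cv_ddof)["cv"].to_numpy()
    path = outdir / "cv_sweep.csv"
    frame.to_csv(path, index=False, float_format="%.8g")
    logger.info("sweep done in %.2f s -> %s", time.perf_counter() - t0, path)
    return {"cv_sweep": path}


def run_analyze(config: RunConfig) -> dict[str, Path]:
    """Preprocess replicates, fit lambda_ex, and write metrics tables.

    Outputs: ``fit_result.json`` (per-replicate estimates plus the trimmed
    mean), ``twa_table.csv`` (replicate x compartment x duration) and
    ``cv_series.csv`` (per replicate and replicate mean).  A non-converged
    fit is logged and flagged in the JSON; the run continues.
    """
    outdir = _start_run(config, "analyze")
    t0 = time.perf_counter()
    grid = build_grid()
    raw = _load_or_generate(config)
    processed = [preprocess_replicate(r, config) for r in raw]

    emissions, params = [], None
    for rep in processed:
        meta = rep.meta
        per_ref = (meta["emitted_mass_mg"] / meta["applied_mass_g"]
                   * config.reference_mass_g)
        emissions.append(EmissionEvent(
            source=meta.get("source", "111"), mass=per_ref,
            start_time=float(meta.get("application_time_h", 0.0))))
        params = FlowParameters(meta.get("volume_m3", 30.0),
                                meta.get("air_change_rate_per_h", 1.0), 0.0)
    fit = fit_replicates(processed, grid, params, emissions,
                         trim_fraction=config.trim_fraction,
                         initial=config.fit_initial)
    if not fit.converged:
        logger.warning("lambda_ex fit did not converge for every replicate")
    fit_path = outdir / "fit_result.json"
    fit.to_json(fit_path)

    twa_rows, cv_frame = [], None
    for k, rep in enumerate(processed):
        t_app = float(rep.meta.get("application_time_h", 0.0))
        summary = exposure_summary(rep, config.durations_h, t_app,
                                   ddof=config.cv_ddof)
        for (comp, dur), val in sorted(summary.twa.items()):
            twa_rows.append({"replicate": k, "compartment": comp,
                             "duration_h": dur, "twa_mg_m3": val})
        col = summary.cv_series["cv"].to_numpy()
        if cv_frame is None:
            cv_frame = pd.DataFrame({"time_h": summary.cv_series["time_h"]})
        cv_frame[f"cv_rep{k}"] = col
    cv_frame["cv_mean"] = cv_frame.filter(like="cv_rep").mean(axis=1)
    twa_path = outdir / "twa_table.csv"
    pd.DataFrame(twa_rows, columns=["replicate", "compartment", "duration_h",
                                    "twa_mg_m3"]).to_csv(
        twa_path, index=False, float_format="%.8g")
    cv_path = outdir / "cv_series.csv"
    cv_frame.to_csv(cv_path, index=False, float_format="%.8g")
    logger.info("analyze done in %.2f s", time.perf_counter() - t0)
    return {"fit": fit_path, "twa": twa_path, "cv": cv_path}


def run_report(config: RunConfig) -> dict[str, Path]:
    """Plots and a summary comparing measured-style vs well-mixed TWA.

    Requires ``run_analyze`` outputs in ``config.outdir``; writes
    ``report_summary.json`` (per-duration TWA ratios C_111 / well-mixed and
    C_222 / well-mixed, per-gram units) plus CV and TWA plots.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = _start_run(config, "report")
    t0 = time.perf_counter()
    twa_path = outdir / "twa_table.csv"
    cv_path = outdir / "cv_series.csv"
    for p in (twa_path, cv_path):
        if not p.exists():
            raise FileNotFoundError(
                f"missing analyze output {p}; run the analyze step first")
    twa_table = pd.read_csv(twa_path, dtype={"compartment": str})
    cv_frame = pd.read_csv(cv_path)

    spec = config.resolved_spec()
    per_gram_mass = spec.mass_fraction * 1000.0 * config.reference_mass_g
    ratios: dict[str, dict[str, float]] = {}
    for dur in config.durations_h:
        horizon = max(dur * 1.5, 0.35)
        m1 = simulate_model1(spec.chamber,
                             EmissionEvent(source=WHOLE_ROOM,
                                           mass=per_gram_mass),
                             np.linspace(0.0, horizon, 400))
        wm = twa(m1, WHOLE_ROOM, dur, 0.0)
        sub = twa_table[np.isclose(twa_table["duration_h"], dur)]
        entry = {"well_mixed_twa_mg_m3": wm}
        for comp in ("111", "222"):
            comp_mean = sub[sub["compartment"] == comp]["twa_mg_m3"].mean()
            entry[f"C_{comp}_twa_mg_m3"] = float(comp_mean)
            entry[f"C_{comp}_over_well_mixed"] = float(comp_mean / wm)
        ratios[f"{dur:g}"] = entry
    summary_path = outdir / "report_summary.json"
    summary_path.write_text(json.dumps(
        {"scenario": spec.name, "twa_ratios_by_duration_h": ratios},
        indent=1))

    fig, ax = plt.subplots(figsize=(6, 4))
    for col in cv_frame.filter(like="cv_rep").columns:
        ax.plot(cv_frame["time_h"], cv_frame[col], alpha=0.5, lw=0.8)
    ax.plot(cv_frame["time_h"], cv_frame["cv_mean"], "k", lw=1.5,
            label="replicate mean")
    ax.set(xlabel="time after application (h)", ylabel="CV across compartments",
           title=f"Spatial uncertainty — {spec.name}")
    ax.legend()
    cv_plot = outdir / "cv_vs_time.png"
    fig.savefig(cv_plot, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    piv = twa_table[twa_table["replicate"] == 0]
    for dur in config.durations_h:
        sub = piv[np.isclose(piv["duration_h"], dur)]
        ax.bar(sub["compartment"], sub["twa_mg_m3"], alpha=0.6,
               label=f"{dur:g} h")
    ax.set(xlabel="compartment", ylabel="TWA (mg m$^{-3}$ g$^{-1}$)",
           title="TWA by compartment (replicate 0)")
    if config.durations_h:
        ax.legend()
    twa_plot = outdir / "twa_by_compartment.png"
    fig.savefig(twa_plot, dpi=120)
    plt.close(fig)
    logger.info("report done in %.2f s", time.perf_counter() - t0)
    return {"summary": summary_path, "cv_plot": cv_plot, "twa_plot": twa_plot}
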