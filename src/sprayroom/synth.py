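"""Synthetic PTR-qMS-like concentration datasets.

Real-time proton-transfer-reaction mass-spectrometry traces of a spray
application are emulated so that fitting and exposure metrics are testable
without chamber measurements.  A replicate is built as:

1. the eight-compartment model solved exactly with the scenario's true
   exchange rate (instantaneous release into the source compartment "111"
   at t = 0, preceded by a pre-application background window);
2. a per-compartment additive background (pre-application levels differ
   slightly between sampling points) plus a slowly varying drift;
3. multiplicative Gaussian noise on the total signal (instrument counting
   noise grows with signal).

Everything stochastic derives from ``(seed, replicate_index)``, so a
replicate is byte-reproducible, and the generating truth (lambda_ex,
backgrounds, applied mass) is recorded in the series metadata for
parameter-recovery tests.

Presets follow the two chamber scenarios: a trigger spray delivering an
ethanol/water mixture at 20, 50 or 80 % (v/v) (three replicates each) and a
single-application n-butane propellant spray.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import expm

from .grid import build_grid
from .model import rate_matrix, solve_matrix_exponential
from .parameters import EmissionEvent, FlowParameters
from .series import ConcentrationSeries

__all__ = ["ScenarioSpec", "PRESETS", "scenario", "generate_replicate",
           "generate_study", "ethanol_mass_fraction"]

_RHO_ETHANOL = 0.789  # g mL^-1 at room temperature
_RHO_WATER = 0.998


def ethanol_mass_fraction(volume_fraction: float) -> float:
    """Mass fraction of ethanol in an ethanol/water mixture of given v/v."""
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume fraction must lie in (0, 1]")
    m_eth = volume_fraction * _RHO_ETHANOL
    return m_eth / (m_eth + (1.0 - volume_fraction) * _RHO_WATER)


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic measurement campaign.

    The chamber defaults (V = 30 m^3, lambda = 1.0 h^-1) and the sampling
    design (>= 5 min of pre-application background, 20 min of
    post-application recording) match the room-chamber protocol the
    generator emulates; ``true_lambda_ex`` defaults to the fitted
    inter-compartment exchange rate of 4.64 h^-1.
    """

    name: str
    chemical: str = "ethanol"
    ethanol_volume_fraction: float | None = 0.5
    chamber: FlowParameters = field(
        default_factory=lambda: FlowParameters(30.0, 1.0, 4.64))
    true_lambda_ex: float = 4.64
    source: str = "111"
    applied_mass_g: float = 2.0
    applied_mass_jitter_sd: float = 0.05  # fractional, replicate to replicate
    chemical_mass_fraction: float | None = None  # derived for ethanol
    sampling_interval_s: float = 1.0  # instrument scan 100 ms is the floor
    pre_application_min: float = 5.0
    post_application_min: float = 20.0
    noise_multiplicative_sd: float = 0.05
    background_mg_m3: float = 5.0
    background_spread: float = 0.2  # fractional spread across compartments
    background_drift_sd: float = 0.1  # mg m^-3, slow additive drift
    background_ceiling_mg_m3: float = 10.0
    replicates: int = 3
    seed: int = 0
    gain: float = 1.0  # instrument signal per (mg m^-3)
    release_mode: str = "instantaneous"  # or "first_order"
    release_rate_per_h: float = 60.0  # for first_order mode

    def __post_init__(self) -> None:
        if self.sampling_interval_s < 0.1:
            raise ValueError("sampling interval below the 100 ms scan speed")
        if self.pre_application_min < 5.0:
            raise ValueError("need at least 5 min of pre-application background")
        if self.background_mg_m3 >= self.background_ceiling_mg_m3:
            raise ValueError("background exceeds the pre-application ceiling")
        if self.release_mode not in ("instantaneous", "first_order"):
            raise ValueError(f"unknown release mode {self.release_mode!r}")

    @property
    def mass_fraction(self) -> float:
        if self.chemical_mass_fraction is not None:
            return self.chemical_mass_fraction
        if self.ethanol_volume_fraction is None:
            raise ValueError("no chemical mass fraction defined")
        return ethanol_mass_fraction(self.ethanol_volume_fraction)

    def emitted_mass_mg(self, applied_mass_g: float) -> float:
        return applied_mass_g * self.mass_fraction * 1000.0

    def time_grid(self) -> np.ndarray:
        dt = self.sampling_interval_s / 3600.0
        t0 = -self.pre_application_min / 60.0
        t1 = self.post_application_min / 60.0
        n = int(round((t1 - t0) / dt))
        return t0 + dt * np.arange(n + 1)


PRESETS: dict[str, ScenarioSpec] = {
    "trigger_20": ScenarioSpec(name="trigger_20", ethanol_volume_fraction=0.2),
    "trigger_50": ScenarioSpec(name="trigger_50", ethanol_volume_fraction=0.5),
    "trigger_80": ScenarioSpec(name="trigger_80", ethanol_volume_fraction=0.8),
    "propellant": ScenarioSpec(
        name="propellant", chemical="n-butane", ethanol_volume_fraction=None,
        chemical_mass_fraction=1.0, applied_mass_g=0.012,
        background_mg_m3=0.3, background_drift_sd=0.01,
        background_ceiling_mg_m3=1.0, replicates=1),
}


def scenario(name: str, **overrides) -> ScenarioSpec:
    """Look up a preset by name, optionally overriding fields."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return replace(spec, **overrides) if overrides else spec


def _first_order_truth(spec: ScenarioSpec, emitted_mass: float,
                       times: np.ndarray) -> np.ndarray:
    """Exact solution with mass released at rate k * (mass remaining).

    The undischarged mass is appended as a ninth linear state feeding the
    source compartment, and the augmented system is propagated with the
    matrix exponential.
    """
    grid = build_grid()
    params = spec.chamber.with_lambda_ex(spec.true_lambda_ex)
    k = spec.release_rate_per_h
    a9 = np.zeros((9, 9))
    a9[:8, :8] = rate_matrix(grid, params)
    a9[grid.index(spec.source), 8] = k / params.compartment_volume
    a9[8, 8] = -k
    state = np.zeros(9)
    state[8] = emitted_mass
    out = np.zeros((times.size, 8))
    prev_t = 0.0
    for i, t in enumerate(times):
        if t < 0:
            continue
        if t > prev_t:
            state = expm(a9 * (t - prev_t)) @ state
            prev_t = t
        out[i] = state[:8]
    return out


def generate_replicate(spec: ScenarioSpec,
                       replicate_index: int = 0) -> ConcentrationSeries:
    """Generate one raw-signal replicate (stage ``raw_signal``).

    Deterministic given ``(spec.seed, replicate_index)``.  Metadata records
    the generating truth: lambda_ex, per-compartment backgrounds, applied and
    emitted mass, and the application time (t = 0).
    """
    rng = np.random.default_rng((spec.seed, replicate_index))
    grid = build_grid()
    params = spec.chamber.with_lambda_ex(spec.true_lambda_ex)
    times = spec.time_grid()

    applied = spec.applied_mass_g * max(
        1.0 + spec.applied_mass_jitter_sd * rng.standard_normal(), 0.1)
    emitted = spec.emitted_mass_mg(applied)

    if spec.release_mode == "first_order":
        truth = _first_order_truth(spec, emitted, times)
    else:
        emission = EmissionEvent(source=spec.source, mass=emitted,
                                 start_time=0.0)
        truth = solve_matrix_exponential(grid, params, emission, times).values

    background = spec.background_mg_m3 * (
        1.0 + spec.background_spread * rng.uniform(-1.0, 1.0, size=8))
    background = np.clip(background, 0.0, spec.background_ceiling_mg_m3 * 0.99)

    drift = np.zeros_like(truth)
    if spec.background_drift_sd > 0:
        # slow drift: random nodes every ~2 min, linearly interpolated
        n_nodes = max(int((times[-1] - times[0]) * 30) + 2, 2)
        node_t = np.linspace(times[0], times[-1], n_nodes)
        for j in range(8):
            nodes = spec.background_drift_sd * rng.standard_normal(n_nodes)
            drift[:, j] = np.interp(times, node_t, nodes)

    clean = truth + background[None, :] + drift
    noise = 1.0 + spec.noise_multiplicative_sd * rng.standard_normal(clean.shape)
    signal = spec.gain * clean * noise

    meta = {
        "scenario": spec.name, "chemical": spec.chemical,
        "replicate": replicate_index, "seed": spec.seed,
        "applied_mass_g": float(applied),
        "emitted_mass_mg": float(emitted),
        "chemical_mass_fraction": float(spec.mass_fraction),
        "true_lambda_ex_per_h": spec.true_lambda_ex,
        "application_time_h": 0.0,
        "background_mg_m3": dict(zip(grid.labels, background.tolist())),
        "gain": spec.gain,
        "volume_m3": spec.chamber.volume,
        "air_change_rate_per_h": spec.chamber.air_change_rate,
        "source": spec.source,
    }
    return ConcentrationSeries(times=times, values=signal,
                               compartments=grid.labels,
                               stage="raw_signal", meta=meta)


def generate_study(spec: ScenarioSpec, outdir: str | Path | None = None,
                   ) -> tuple[list[ConcentrationSeries], dict]:
    """Generate all replicates of a scenario, optionally writing them out.

    Returns the replicate series and a manifest binding scenario, seeds,
    applied masses and the generating truths.  With ``outdir`` set, each
    replicate is written as ``<name>_rep<k>.csv`` (plus metadata sidecar)
    and the manifest as ``<name>_manifest.yaml``; pre-existing files are
    reported as collisions, never overwritten.
    """
    reps = [generate_replicate(spec, k) for k in range(spec.replicates)]
    manifest = {
        "scenario": spec.name, "chemical": spec.chemical,
        "seed": spec.seed, "replicates": spec.replicates,
        "true_lambda_ex_per_h": spec.true_lambda_ex,
        "chamber": {"volume_m3": spec.chamber.volume,
                    "air_change_rate_per_h": spec.chamber.air_change_rate},
        "entries": [
            {"replicate": k, "file": f"{spec.name}_rep{k}.csv",
             "applied_mass_g": rep.meta["applied_mass_g"],
             "emitted_mass_mg": rep.meta["emitted_mass_mg"],
             "seed": [spec.seed, k]}
            for k, rep in enumerate(reps)
        ],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = [outdir / e["file"] for e in manifest["entries"]]
        paths.append(outdir / f"{spec.name}_manifest.yaml")
        clashes = [str(p) for p in paths if p.exists()]
        if clashes:
            raise FileExistsError(f"output path collision: {clashes}")
        for rep, path in zip(reps, paths):
            rep.write_csv(path)
        paths[-1].write_text(yaml.safe_dump(manifest, sort_keys=False))
    return reps, manifest
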