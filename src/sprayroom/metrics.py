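"""Preprocessing of concentration traces and exposure metrics.

The measurement pipeline mirrors how real-time PTR-qMS traces are prepared
before comparison with the models:

1. **calibrate** — convert raw instrument signal to concentration with a
   linear calibration fitted in a small mixing chamber;
2. **background-subtract** — remove each compartment's pre-application
   background (mean over a window of at least 5 min before the release);
3. **smooth** — centred running average (default 2.5 min) against
   instrumental noise;
4. **normalize** — scale by the applied product mass so independent
   applications are comparable per gram.

Each step stamps the series ``stage`` and refuses out-of-order application
(the stage may only move forward through the pipeline).  On the processed
traces two exposure metrics are computed: the time-weighted average (TWA)
concentration over a stated post-application window, and the
cross-compartment coefficient of variation CV(t) — the standard deviation of
the eight compartment concentrations divided by their mean — used as the
spatial-uncertainty indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import ConcentrationSeries, stage_index

__all__ = [
    "CalibrationCurve", "ExposureSummary", "fit_calibration",
    "calibrate_signal", "subtract_background", "smooth_running_average",
    "normalize_by_mass", "cv_over_time", "twa", "exposure_summary",
]

#: Volume of the small calibration (mixing) chamber, m^3.
CALIBRATION_CHAMBER_M3 = 0.29

#: Minimum pre-application background window, hours (5 min).
MIN_BACKGROUND_WINDOW_H = 5.0 / 60.0

#: Default running-average window, hours (2.5 min).
DEFAULT_SMOOTH_WINDOW_H = 2.5 / 60.0

#: Times where the compartment mean falls below this fraction of the series
#: peak mean are masked (NaN) in CV rather than producing exploding ratios.
CV_MASK_FRACTION = 0.01


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear signal-to-concentration calibration.

    ``signal = slope * concentration + intercept`` fitted by ordinary least
    squares against nominal concentrations (injected mass / chamber volume,
    assuming complete evaporation and negligible losses).
    """

    slope: float
    intercept: float
    r_squared: float
    chamber_volume: float = CALIBRATION_CHAMBER_M3

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def to_concentration(self, signal: np.ndarray) -> np.ndarray:
        """Invert the calibration line: (signal - intercept) / slope."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


@dataclass
class ExposureSummary:
    """TWA table and CV series for one processed dataset."""

    twa: dict[tuple[str, float], float]
    cv_series: pd.DataFrame
    durations: tuple[float, ...] = (0.1, 0.3)
    meta: dict = field(default_factory=dict)

    def twa_table(self) -> pd.DataFrame:
        rows = [{"compartment": comp, "duration_h": dur, "twa_mg_m3": val}
                for (comp, dur), val in sorted(self.twa.items())]
        return pd.DataFrame(rows, columns=["compartment", "duration_h",
                                           "twa_mg_m3"])


def _require_stage_before(series: ConcentrationSeries, target: str) -> None:
    if stage_index(series.stage) >= stage_index(target):
        raise ValueError(
            f"out-of-order preprocessing: cannot apply the {target!r} step "
            f"to a series already at stage {series.stage!r}")


def fit_calibration(injected_masses, signals,
                    chamber_volume: float = CALIBRATION_CHAMBER_M3,
                    ) -> CalibrationCurve:
    """Fit the calibration line from chamber injections.

    Parameters
    ----------
    injected_masses : array-like
        Injected chemical masses, mg.  Nominal concentrations are
        ``mass / chamber_volume`` (complete evaporation, negligible losses).
    signals : array-like
        Instrument response at each injection.
    """
    masses = np.asarray(injected_masses, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if masses.size < 3 or sig.size != masses.size:
        raise ValueError("calibration requires at least 3 paired points")
    conc = masses / chamber_volume
    slope, intercept = np.polyfit(conc, sig, 1)
    fitted = slope * conc + intercept
    ss_tot = float(np.sum((sig - sig.mean()) ** 2))
    ss_res = float(np.sum((sig - fitted) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope ({slope:.3g})")
    return CalibrationCurve(slope=float(slope), intercept=float(intercept),
                            r_squared=min(r2, 1.0),
                            chamber_volume=chamber_volume)


def calibrate_signal(series: ConcentrationSeries,
                     curve: CalibrationCurve) -> ConcentrationSeries:
    """Convert a raw-signal series to concentration units (stage ``calibrated``)."""
    _require_stage_before(series, "calibrated")
    return series.with_values(curve.to_concentration(series.values),
                              stage="calibrated",
                              calibration={"slope": curve.slope,
                                           "intercept": curve.intercept,
                                           "r_squared": curve.r_squared})


def subtract_background(series: ConcentrationSeries,
                        background_window: tuple[float, float], *,
                        min_window: float = MIN_BACKGROUND_WINDOW_H,
                        ) -> ConcentrationSeries:
    """Subtract each compartment's mean over the pre-application window.

    The window is half-open, ``[t0, t1)``, so a release at exactly ``t1``
    never contaminates the background estimate.  Negative residual values
    are preserved (never clipped): after removing the background estimate,
    instrument noise legitimately dips below zero.
    """
    _require_stage_before(series, "background_subtracted")
    t0, t1 = background_window
    if t1 - t0 < min_window - 1e-12:
        raise ValueError(
            f"background window must span at least {min_window * 60:.1f} min")
    if t0 < series.times[0] - 1e-12 or t1 > series.times[-1] + 1e-12:
        raise ValueError("background window lies outside the series range")
    mask = (series.times >= t0) & (series.times < t1)
    if not mask.any():
        raise ValueError("background window contains no samples")
    background = series.values[mask].mean(axis=0)
    return series.with_values(series.values - background,
                              stage="background_subtracted",
                              background_mg_m3=dict(zip(series.compartments,
                                                        background.tolist())))


def smooth_running_average(series: ConcentrationSeries,
                           window: float = DEFAULT_SMOOTH_WINDOW_H,
                           ) -> ConcentrationSeries:
    """Centred running average over *window* hours.

    The output grid equals the input grid; near the edges the averaging
    window shrinks symmetrically so no samples are padded or dropped.
    Requires a sampling interval shorter than half the window.
    """
    _require_stage_before(series, "smoothed")
    if window <= 0:
        raise ValueError("smoothing window must be positive")
    dt = float(np.median(np.diff(series.times)))
    if window < 2 * dt:
        raise ValueError("smoothing window shorter than twice the sampling "
                         f"interval ({dt * 3600:.1f} s)")
    half = int(np.floor(window / (2 * dt)))
    n = series.times.size
    out = np.empty_like(series.values)
    csum = np.cumsum(np.vstack([np.zeros((1, series.values.shape[1])),
                                series.values]), axis=0)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return series.with_values(out, stage="smoothed",
                              smooth_window_h=window)


def normalize_by_mass(series: ConcentrationSeries, applied_mass: float,
                      reference_mass: float = 1.0) -> ConcentrationSeries:
    """Scale concentrations by ``reference_mass / applied_mass`` (grams).

    With the default reference of 1 g the output is concentration per gram
    of product applied, making independent applications comparable.
    """
    _require_stage_before(series, "normalized")
    if applied_mass <= 0 or reference_mass <= 0:
        raise ValueError("applied and reference masses must be positive")
    factor = reference_mass / applied_mass
    return series.with_values(series.values * factor, stage="normalized",
                              applied_mass_g=applied_mass,
                              reference_mass_g=reference_mass)


def cv_over_time(series: ConcentrationSeries, *, ddof: int = 1,
                 mask_fraction: float = CV_MASK_FRACTION) -> pd.DataFrame:
    """Cross-compartment coefficient of variation at every time point.

    ``CV(t) = sd(C_1(t) ... C_8(t)) / mean(C_1(t) ... C_8(t))`` with the
    sample (n-1) standard deviation by default (``ddof=0`` gives the
    population variant).  Times where the mean falls below
    ``mask_fraction`` of the peak mean are reported as NaN rather than as
    exploding ratios.

    Returns a DataFrame with columns ``time_h`` and ``cv``.
    """
    if series.n_compartments != 8:
        raise ValueError("CV requires exactly 8 compartments, got "
                         f"{series.n_compartments}")
    mean = series.values.mean(axis=1)
    sd = series.values.std(axis=1, ddof=ddof)
    threshold = mask_fraction * np.nanmax(mean)
    cv = np.where(mean > threshold, sd / np.where(mean > threshold, mean, 1.0),
                  np.nan)
    return pd.DataFrame({"time_h": series.times, "cv": cv})


def twa(series: ConcentrationSeries, compartment: str, duration: float,
        origin: float = 0.0) -> float:
    """Time-weighted average concentration over ``[origin, origin+duration]``.

    Trapezoidal rule on the sampled grid, with the window endpoints
    interpolated linearly; the result is bounded by the trace's min and max
    over the window.
    """
    if duration <= 0:
        raise ValueError("TWA duration must be positive")
    end = origin + duration
    if origin < series.times[0] - 1e-12 or end > series.times[-1] + 1e-12:
        raise ValueError("TWA window extends past the series range")
    trace = series.column(compartment)
    inside = (series.times > origin) & (series.times < end)
    t = np.concatenate(([origin], series.times[inside], [end]))
    c = np.concatenate(([np.interp(origin, series.times, trace)],
                        trace[inside],
                        [np.interp(end, series.times, trace)]))
    return float(np.trapezoid(c, t) / duration)


def exposure_summary(series: ConcentrationSeries,
                     durations=(0.1, 0.3), origin: float = 0.0, *,
                     ddof: int = 1) -> ExposureSummary:
    """TWA per compartment and duration, plus the CV time series."""
    table = {(comp, dur): twa(series, comp, dur, origin)
             for comp in series.compartments for dur in durations}
    cv = (cv_over_time(series, ddof=ddof) if series.n_compartments == 8
          else pd.DataFrame({"time_h": series.times,
                             "cv": np.full(series.times.size, np.nan)}))
    return ExposureSummary(twa=table, cv_series=cv,
                           durations=tuple(durations),
                           meta={"origin_h": origin, "stage": series.stage})
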