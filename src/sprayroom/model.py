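"""Mass-balance models for chemical concentration after a spray application.

Two spatial resolutions are implemented:

* the **well-mixed model** (one zone): ``V dC/dt = -Q C + R_em(t)``, with Q =
  V*lambda the ventilation flow and R_em the emission rate;
* the **eight-compartment model**: the room is split into the 2x2x2 grid of
  :mod:`sprayroom.grid`; each compartment of volume V/8 obeys

  ``(V/8) dC_i/dt = -(Q/4) C_i + Q_ex * sum_j (C_j - C_i)
                    + (Q/4) C_k + R_em,i(t)``

  where j runs over the three face neighbours, k is the upstream compartment
  (outdoor air, at zero concentration, for the y=1 layer), and Q_ex =
  (V/8)*lambda_ex is the symmetric exchange flow between adjacent
  compartments.

Both are linear time-invariant systems; instantaneous releases are applied
as state jumps (C -> C + mass/volume at the release time) with integration
restarted there, never as narrow forcing spikes.  Two solvers are provided:
an adaptive ODE integrator (:func:`simulate_model2`) and an exact
matrix-exponential propagator (:func:`solve_matrix_exponential`) that serves
as its independent oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .grid import WHOLE_ROOM, CompartmentGrid, build_grid
from .parameters import CONSTANT_RATE, INSTANTANEOUS, EmissionEvent, FlowParameters
from .series import ConcentrationSeries

__all__ = [
    "rate_matrix",
    "simulate_model1",
    "simulate_model2",
    "solve_matrix_exponential",
    "mass_balance_residual",
]


def rate_matrix(grid: CompartmentGrid, params: FlowParameters) -> np.ndarray:
    """The 8x8 rate matrix A of the compartment system ``dC/dt = A C + b``.

    Diagonal entries collect the ventilation loss (Q/4 per compartment
    volume V/8, i.e. 2*lambda) and the exchange loss to the three
    neighbours (3*lambda_ex); off-diagonals carry the exchange gain
    (lambda_ex) and, for y=2 rows, the advective gain 2*lambda from the
    upstream compartment.  The matrix is Metzler (non-negative
    off-diagonals), so non-negative states stay non-negative.
    """
    lam, lex = params.air_change_rate, params.lambda_ex
    n = len(grid.labels)
    a = np.zeros((n, n))
    for i, lab in enumerate(grid.labels):
        a[i, i] = -2.0 * lam - 3.0 * lex
        for nb in grid.neighbors[lab]:
            a[i, grid.index(nb)] += lex
        up = grid.upstream[lab]
        if up != "OUTDOOR":
            a[i, grid.index(up)] += 2.0 * lam
    return a


def _emission_events(emission: EmissionEvent, volume_per_comp: float,
                     source_index: int, n: int):
    """Break an emission into state jumps and piecewise-constant forcing.

    Returns ``(jumps, segments)`` where ``jumps`` maps time -> state
    increment vector (mg m^-3) and ``segments`` is a list of
    ``(t_start, t_end, b)`` with ``b`` the concentration source rate vector
    (mg m^-3 h^-1) active on that window.
    """
    jumps: dict[float, np.ndarray] = {}
    segments: list[tuple[float, float, np.ndarray]] = []
    if emission.mass == 0:
        return jumps, segments
    vec = np.zeros(n)
    if emission.mode == INSTANTANEOUS:
        vec[source_index] = emission.mass / volume_per_comp
        jumps[emission.start_time] = vec
    else:
        vec[source_index] = emission.rate / volume_per_comp
        segments.append((emission.start_time, emission.end_time, vec))
    return jumps, segments


def _breakpoints(times: np.ndarray, jumps, segments) -> np.ndarray:
    pts = {times[0], times[-1]}
    for t in jumps:
        if times[0] <= t <= times[-1]:
            pts.add(t)
    for t0, t1, _ in segments:
        for t in (t0, t1):
            if times[0] <= t <= times[-1]:
                pts.add(t)
    return np.array(sorted(pts))


def _forcing_at(segments, t0: float, t1: float, n: int) -> np.ndarray:
    """Constant forcing vector on the open interval (t0, t1)."""
    b = np.zeros(n)
    mid = 0.5 * (t0 + t1)
    for s0, s1, vec in segments:
        if s0 <= mid < s1:
            b = b + vec
    return b


def _check_emission_window(emission: EmissionEvent, times: np.ndarray) -> None:
    if emission.mass > 0 and emission.start_time < times[0]:
        raise ValueError(
            "time grid must start at or before the emission start time")


def _integrate_piecewise(a: np.ndarray, times: np.ndarray, jumps, segments,
                         c0: np.ndarray, exact: bool,
                         rtol: float, atol: float) -> np.ndarray:
    """Propagate the affine system over *times*, restarting at breakpoints.

    At a jump time the reported value is post-jump.  ``exact=True`` uses the
    augmented-matrix exponential ``expm([[A, b], [0, 0]] * dt)``, which
    propagates the affine system without requiring A to be invertible;
    otherwise an adaptive LSODA integration is run per segment.
    """
    n = a.shape[0]
    times = np.asarray(times, dtype=float)
    out = np.empty((times.size, n))
    bps = _breakpoints(times, jumps, segments)
    state = c0.copy()
    for k in range(len(bps) - 1 if len(bps) > 1 else 1):
        t0 = bps[k]
        t1 = bps[k + 1] if len(bps) > 1 else bps[0]
        if t0 in jumps:
            state = state + jumps[t0]
        mask = (times >= t0) & (times <= t1) if t1 > t0 else (times == t0)
        seg_times = times[mask]
        if t1 <= t0:
            out[mask] = state
            continue
        b = _forcing_at(segments, t0, t1, n)
        if exact:
            aug = np.zeros((n + 1, n + 1))
            aug[:n, :n] = a
            aug[:n, n] = b
            prev_t, cur = t0, state
            vals = []
            for t in seg_times:
                if t > prev_t:
                    phi = expm(aug * (t - prev_t))
                    cur = phi[:n, :n] @ cur + phi[:n, n]
                    prev_t = t
                vals.append(cur.copy())
            if seg_times.size:
                out[mask] = np.array(vals)
            if t1 > prev_t:
                phi = expm(aug * (t1 - prev_t))
                cur = phi[:n, :n] @ cur + phi[:n, n]
            state = cur
        else:
            t_eval = seg_times if seg_times.size else None
            sol = solve_ivp(lambda _t, c: a @ c + b, (t0, t1), state,
                            method="LSODA", t_eval=t_eval,
                            rtol=rtol, atol=atol)
            if not sol.success:  # pragma: no cover - LSODA on linear systems
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            if seg_times.size:
                out[mask] = sol.y.T
            # endpoint state for the next segment
            sol_end = solve_ivp(lambda _t, c: a @ c + b, (t0, t1), state,
                                method="LSODA", t_eval=[t1],
                                rtol=rtol, atol=atol) if (t_eval is None or seg_times[-1] != t1) else sol
            state = sol_end.y[:, -1]
    # times before the first breakpoint segment start (grid preceding events)
    return out


def simulate_model1(params: FlowParameters, emission: EmissionEvent,
                    times: np.ndarray, *, rtol: float = 1e-8,
                    atol: float = 1e-12, exact: bool = False,
                    ) -> ConcentrationSeries:
    """Simulate the well-mixed (single-zone) mass balance.

    Solves ``V dC/dt = -Q C + R_em(t)`` from C = 0, applying an
    instantaneous release as the jump ``C -> C + mass/V``.

    Parameters
    ----------
    params : FlowParameters
        Uses ``volume`` and ``air_change_rate`` only.
    emission : EmissionEvent
        Must target :data:`~sprayroom.grid.WHOLE_ROOM`.
    times : array-like
        Strictly increasing output grid, hours, starting at or before the
        emission start.
    exact : bool
        Use the closed-form propagator instead of the adaptive integrator.

    Returns
    -------
    ConcentrationSeries
        Single pseudo-compartment ``WHOLE_ROOM``, stage ``calibrated``.
    """
    if emission.source != WHOLE_ROOM:
        raise ValueError("model 1 emission must target WHOLE_ROOM")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise ValueError("time grid must be 1-D and strictly increasing")
    _check_emission_window(emission, times)
    a = np.array([[-params.air_change_rate]])
    jumps, segments = _emission_events(emission, params.volume, 0, 1)
    values = _integrate_piecewise(a, times, jumps, segments,
                                  np.zeros(1), exact, rtol, atol)
    meta = {"model": "well_mixed", "volume_m3": params.volume,
            "air_change_rate_per_h": params.air_change_rate,
            "emitted_mass_mg": emission.mass}
    return ConcentrationSeries(times=times, values=values,
                               compartments=(WHOLE_ROOM,),
                               stage="calibrated", meta=meta)


def _simulate_compartments(grid: CompartmentGrid, params: FlowParameters,
                           emission: EmissionEvent, times: np.ndarray,
                           exact: bool, rtol: float, atol: float,
                           initial: np.ndarray | None) -> ConcentrationSeries:
    if emission.source not in grid.labels:
        raise ValueError(f"unknown source compartment {emission.source!r}")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise ValueError("time grid must be 1-D and strictly increasing")
    _check_emission_window(emission, times)
    n = len(grid.labels)
    a = rate_matrix(grid, params)
    jumps, segments = _emission_events(emission, params.compartment_volume,
                                       grid.index(emission.source), n)
    c0 = np.zeros(n) if initial is None else np.asarray(initial, dtype=float)
    values = _integrate_piecewise(a, times, jumps, segments, c0,
                                  exact, rtol, atol)
    meta = {"model": "eight_compartment", "volume_m3": params.volume,
            "air_change_rate_per_h": params.air_change_rate,
            "lambda_ex_per_h": params.lambda_ex,
            "emitted_mass_mg": emission.mass, "source": emission.source}
    return ConcentrationSeries(times=times, values=values,
                               compartments=grid.labels,
                               stage="calibrated", meta=meta)


def simulate_model2(grid: CompartmentGrid, params: FlowParameters,
                    emission: EmissionEvent, times: np.ndarray, *,
                    rtol: float = 1e-8, atol: float = 1e-12,
                    initial: np.ndarray | None = None) -> ConcentrationSeries:
    """Integrate the eight-compartment mass balance with LSODA.

    Outdoor (infiltrating) air carries zero concentration; vertical and
    horizontal neighbour exchange are both carried by the Q_ex term, on top
    of the directional Q/4 advection along y.  Instantaneous releases enter
    as a state jump ``C_source -> C_source + mass/(V/8)``.

    ``initial`` optionally sets the concentration vector at ``times[0]``
    (defaults to zero everywhere).
    """
    return _simulate_compartments(grid, params, emission, times,
                                  exact=False, rtol=rtol, atol=atol,
                                  initial=initial)


def solve_matrix_exponential(grid: CompartmentGrid, params: FlowParameters,
                             emission: EmissionEvent, times: np.ndarray, *,
                             initial: np.ndarray | None = None,
                             ) -> ConcentrationSeries:
    """Exact solution of the eight-compartment system via ``expm``.

    Propagates the affine system piecewise with the augmented-matrix
    exponential; exact up to floating point, and the reference oracle for
    :func:`simulate_model2`.
    """
    return _simulate_compartments(grid, params, emission, times,
                                  exact=True, rtol=0.0, atol=0.0,
                                  initial=initial)


def mass_balance_residual(series: ConcentrationSeries,
                          grid: CompartmentGrid,
                          params: FlowParameters,
                          emission: EmissionEvent) -> np.ndarray:
    """Discrete mass-balance residual per time interval, mg h^-1.

    Summing the compartment equations, exchange terms cancel pairwise and

    ``d/dt sum_i (V/8) C_i = sum_i R_em,i - (Q/4) sum_{outlet} C_i``.

    The residual compares the trapezoidal-rule change in airborne mass over
    each interval with the integrated source minus outlet-removal terms;
    jump intervals (containing an instantaneous release) account for the
    released mass.  Should be ~0 for any faithful solver output.
    """
    t = series.times
    v8, q4 = params.compartment_volume, params.q / 4.0
    total = series.values.sum(axis=1) * v8
    outlet_cols = [series.compartments.index(lab) for lab in sorted(grid.outlet)]
    removal = q4 * series.values[:, outlet_cols].sum(axis=1)
    dt = np.diff(t)
    dmass = np.diff(total)
    removed = 0.5 * (removal[1:] + removal[:-1]) * dt
    emitted = np.zeros_like(dt)
    if emission.mass > 0:
        if emission.mode == INSTANTANEOUS:
            # release lands in the interval whose right edge is the first
            # time >= start_time (post-jump convention)
            k = np.searchsorted(t, emission.start_time)
            if 0 < k < t.size:
                emitted[k - 1] = emission.mass
        else:
            lo = np.maximum(t[:-1], emission.start_time)
            hi = np.minimum(t[1:], emission.end_time)
            emitted = emission.rate * np.clip(hi - lo, 0.0, None)
    return dmass - emitted + removed
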