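"""Hodgkin-Huxley single-neuron reference and runtime-scaling benchmarks.

The activation rule of the CA abstracts the firing-rate response (f-I
curve) of a conductance-based neuron.  This module provides the canonical
space-clamped squid-axon Hodgkin-Huxley model (1952 constants, modern sign
convention) to derive that curve, plus wall-clock scaling benchmarks that
contrast the CA's O(N) cost per sweep with the O(N^2) cost of an
all-to-all-coupled HH ODE network.

Currents are membrane current densities in uA/cm^2 (unit membrane area);
voltages in mV, time in ms, rates in Hz.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .activation import ActivationParams
from .lattice import LatticeConfig, build_neighbor_map, initialize_state, step

__all__ = [
    "FICurve",
    "BenchmarkResult",
    "hh_simulate",
    "fi_curve",
    "benchmark_scaling",
]

# 1952 squid-axon constants
C_M = 1.0  # uF/cm^2
G_NA, G_K, G_L = 120.0, 36.0, 0.3  # mS/cm^2
E_NA, E_K, E_L = 50.0, -77.0, -54.4  # mV

V_REST = -65.0
SPIKE_THRESHOLD = 0.0  # mV, upward crossing = spike
REFRACTORY_MS = 2.0


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    out = safe / np.expm1(safe / y)
    return np.where(small, y - x / 2.0, out)


def _alpha_beta(v):
    am = 0.1 * _vtrap(-(v + 40.0), 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _vtrap(-(v + 55.0), 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def _steady_gates(v):
    am, bm, ah, bh, an, bn = _alpha_beta(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def _derivs(v, m, h, n, i_ext):
    am, bm, ah, bh, an, bn = _alpha_beta(v)
    i_ion = (
        G_NA * m**3 * h * (v - E_NA)
        + G_K * n**4 * (v - E_K)
        + G_L * (v - E_L)
    )
    dv = (i_ext - i_ion) / C_M
    return (
        dv,
        am * (1.0 - m) - bm * m,
        ah * (1.0 - h) - bh * h,
        an * (1.0 - n) - bn * n,
    )


def _integrate(i_ext, duration, dt, method="rk4", coupling=None, record_v=False):
    """Fixed-step integration of one or more HH neurons.

    ``i_ext`` is scalar or array (one neuron per entry).  ``coupling``, if
    given, is a dense matrix C adding a current ``C @ v`` per neuron.
    Returns (spike_counts, spike_times or None, v_trace or None); spike
    times are only collected for single-neuron runs.
    """
    i_ext = np.atleast_1d(np.asarray(i_ext, dtype=float))
    n = i_ext.size
    v = np.full(n, V_REST)
    m, h, gate_n = (np.full(n, g) for g in _steady_gates(V_REST))
    n_steps = int(round(duration / dt))
    counts = np.zeros(n, dtype=int)
    last_spike = np.full(n, -np.inf)
    spike_times = [] if n == 1 else None
    trace = np.empty(n_steps + 1) if (record_v and n == 1) else None
    if trace is not None:
        trace[0] = v[0]

    def f(v, m, h, gn):
        drive = i_ext if coupling is None else i_ext + coupling @ v
        return _derivs(v, m, h, gn, drive)

    for k in range(n_steps):
        if method == "euler":
            dv, dm, dh, dn = f(v, m, h, gate_n)
            v_new = v + dt * dv
            m = m + dt * dm
            h = h + dt * dh
            gate_n = gate_n + dt * dn
        else:  # rk4
            k1 = f(v, m, h, gate_n)
            k2 = f(*(s + 0.5 * dt * d for s, d in zip((v, m, h, gate_n), k1)))
            k3 = f(*(s + 0.5 * dt * d for s, d in zip((v, m, h, gate_n), k2)))
            k4 = f(*(s + dt * d for s, d in zip((v, m, h, gate_n), k3)))
            v_new, m, h, gate_n = (
                s + dt / 6.0 * (d1 + 2 * d2 + 2 * d3 + d4)
                for s, d1, d2, d3, d4 in zip((v, m, h, gate_n), k1, k2, k3, k4)
            )
        t_now = (k + 1) * dt
        crossed = (v < SPIKE_THRESHOLD) & (v_new >= SPIKE_THRESHOLD)
        fresh = crossed & (t_now - last_spike >= REFRACTORY_MS)
        counts[fresh] += 1
        last_spike[fresh] = t_now
        if spike_times is not None and fresh[0]:
            spike_times.append(t_now)
        v = v_new
        if trace is not None:
            trace[k + 1] = v[0]
    st = np.array(spike_times) if spike_times is not None else None
    return counts, st, trace


def hh_simulate(
    i_ext: float,
    duration: float = 400.0,
    dt: float = 0.02,
    *,
    method: str = "rk4",
    record_v: bool = False,
):
    """Simulate a single HH neuron at constant drive; returns spike times
    (upward 0-mV crossings separated by >= 2 ms), and optionally the
    voltage trace."""
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    if dt > 0.1:
        warnings.warn(
            f"dt={dt} ms is coarse for HH dynamics; expect integration error",
            RuntimeWarning,
            stacklevel=2,
        )
    _, spikes, trace = _integrate(i_ext, duration, dt, method=method, record_v=record_v)
    return (spikes, trace) if record_v else spikes


@dataclass
class FICurve:
    """Firing rate versus input current, raw plus a normalization recipe.

    ``norm_range`` is the (low, high) current window mapped to [0, 1] on
    the input axis; ``rate_scale`` divides the output axis (defaults to the
    maximum observed rate).
    """

    current: np.ndarray
    rate: np.ndarray
    norm_range: Optional[tuple] = None
    rate_scale: Optional[float] = None
    current_units: str = "uA/cm^2"

    def normalized(self):
        lo, hi = self.norm_range if self.norm_range else (
            float(self.current.min()),
            float(self.current.max()),
        )
        scale = self.rate_scale
        if scale is None:
            scale = float(self.rate.max()) or 1.0
        x = (self.current - lo) / (hi - lo)
        y = self.rate / scale
        return x, y

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.current, self.rate]),
            delimiter=",",
            header="current,rate",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, **kw) -> "FICurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(current=arr[:, 0], rate=arr[:, 1], **kw)


def fi_curve(
    currents: Sequence[float],
    duration: float = 500.0,
    dt: float = 0.02,
    *,
    t_discard: float = 100.0,
    norm_range: Optional[tuple] = None,
    rate_scale: Optional[float] = None,
) -> FICurve:
    """Firing rate for each current on a sorted grid (all neurons are
    integrated simultaneously).  Rates count spikes after ``t_discard`` to
    drop the onset transient."""
    currents = np.asarray(list(currents), dtype=float)
    if np.any(np.diff(currents) < 0):
        raise ValueError("current grid must be sorted ascending")
    if dt > 0.1:
        warnings.warn("dt > 0.1 ms is coarse for HH dynamics", RuntimeWarning)
    # integrate the full grid at once (one neuron per current)
    i_ext = currents
    n = i_ext.size
    v = np.full(n, V_REST)
    m, h, gn = (np.full(n, g) for g in _steady_gates(V_REST))
    n_steps = int(round(duration / dt))
    counts = np.zeros(n, dtype=int)
    last_spike = np.full(n, -np.inf)
    for k in range(n_steps):
        k1 = _derivs(v, m, h, gn, i_ext)
        k2 = _derivs(*(s + 0.5 * dt * d for s, d in zip((v, m, h, gn), k1)), i_ext)
        k3 = _derivs(*(s + 0.5 * dt * d for s, d in zip((v, m, h, gn), k2)), i_ext)
        k4 = _derivs(*(s + dt * d for s, d in zip((v, m, h, gn), k3)), i_ext)
        v_new, m, h, gn = (
            s + dt / 6.0 * (d1 + 2 * d2 + 2 * d3 + d4)
            for s, d1, d2, d3, d4 in zip((v, m, h, gn), k1, k2, k3, k4)
        )
        t_now = (k + 1) * dt
        fresh = (
            (v < SPIKE_THRESHOLD)
            & (v_new >= SPIKE_THRESHOLD)
            & (t_now - last_spike >= REFRACTORY_MS)
        )
        if t_now >= t_discard:
            counts[fresh] += 1
        last_spike[fresh] = t_now
        v = v_new
    rates = counts / ((duration - t_discard) / 1000.0)
    return FICurve(
        current=currents,
        rate=rates,
        norm_range=norm_range,
        rate_scale=rate_scale,
    )


@dataclass
class BenchmarkResult:
    """Measured runtimes over population sizes and the power-law fit
    T = fit_a * (N - fit_b)**fit_c (fit_c estimates the complexity
    exponent)."""

    model: str
    n_values: np.ndarray
    times: np.ndarray
    fit_a: float = np.nan
    fit_b: float = np.nan
    fit_c: float = np.nan
    fit_ok: bool = False
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"N": self.n_values, "time_s": self.times})


def _time_ca(n_cells: int, steps: int) -> float:
    side = max(3, int(round(np.sqrt(n_cells))))
    cfg = LatticeConfig(rows=side, cols=side, timesteps=steps, seed=0)
    nmap = build_neighbor_map(cfg)
    state = initialize_state(cfg)
    p = ActivationParams.linear(0.2, 0.6, 0.8)
    t0 = time.perf_counter()
    for _ in range(steps):
        step(state, nmap, p)
    return time.perf_counter() - t0


def _time_hh_network(n: int, steps: int, dt: float, method: str) -> float:
    rng = np.random.default_rng(0)
    i_ext = rng.uniform(8.0, 12.0, size=n)
    g_c = 0.1
    coupling = g_c * (np.ones((n, n)) - np.eye(n)) / n  # all-to-all, O(N^2)
    t0 = time.perf_counter()
    _integrate(i_ext, steps * dt, dt, method=method, coupling=coupling)
    return time.perf_counter() - t0


def power_law(n, a, b, c):
    return a * np.power(np.maximum(n - b, 1e-9), c)


def benchmark_scaling(
    model: str,
    n_grid: Sequence[int],
    reps: int = 3,
    *,
    steps: int = 100,
    dt: float = 0.025,
) -> BenchmarkResult:
    """Measure wall-clock time versus population size N and fit
    T = a (N - b)^c.  ``model`` is ``"ca"``, ``"hh_euler"`` or ``"hh_rk4"``;
    the number of update sweeps is fixed so only N varies.  ``reps``
    measurement rounds are interleaved across sizes and summarized by the
    median, after subtracting a per-round tiny-population baseline (the
    size-independent dispatch cost, which otherwise masks the scaling at
    small N).  With fewer than 3 sizes the fit is refused and raw times
    are returned."""
    n_values = np.asarray(list(n_grid), dtype=float)
    if np.any(np.diff(n_values) <= 0):
        raise ValueError("N grid must be strictly ascending")
    timer = {
        "ca": lambda n: _time_ca(n, steps),
        "hh_euler": lambda n: _time_hh_network(n, steps, dt, "euler"),
        "hh_rk4": lambda n: _time_hh_network(n, steps, dt, "rk4"),
    }.get(model)
    if timer is None:
        raise ValueError(f"unknown model {model!r}")
    base_n = 16 if model == "ca" else 8
    # single-thread BLAS while timing: the complexity claim concerns the
    # serial operation count, and thread scheduling only adds variance
    try:
        from threadpoolctl import threadpool_limits
        limiter = threadpool_limits(limits=1)
    except ImportError:  # pragma: no cover
        from contextlib import nullcontext
        limiter = nullcontext()
    with limiter:
        timer(int(n_values[0]))  # warmup: first-touch allocation, code paths
        # interleaved rounds (every size measured per round) so slow load
        # drifts hit all sizes alike; a per-round baseline at a tiny
        # population removes the size-independent dispatch cost; the median
        # over rounds resists scheduler spikes
        rounds = np.empty((reps, n_values.size))
        for r in range(reps):
            base = timer(base_n)
            rounds[r] = [timer(int(n)) - base for n in n_values]
    times = np.maximum(np.median(rounds, axis=0), 1e-9)
    result = BenchmarkResult(model=model, n_values=n_values, times=times)
    if n_values.size < 3:
        return result
    try:
        # fit in log space: runtimes span orders of magnitude, so relative
        # residuals keep every size informative; |b| is bounded by the
        # smallest population (a larger shift is no longer a size offset)
        def _log_residual(theta):
            log_a, b, c = theta
            return log_a + c * np.log(np.maximum(n_values - b, 1e-9)) - np.log(times)

        sol = least_squares(
            _log_residual,
            x0=[np.log(times[0] / n_values[0]), 0.0, 1.0],
            bounds=(
                [-np.inf, -n_values[0], 0.1],
                [np.inf, n_values[0] * 0.99, 4.0],
            ),
        )
        if not sol.success:
            raise RuntimeError(sol.message)
        a, b, c = float(np.exp(sol.x[0])), float(sol.x[1]), float(sol.x[2])
        result.fit_a, result.fit_b, result.fit_c = a, b, c
        result.residuals = times - power_law(n_values, a, b, c)
        result.fit_ok = True
    except (RuntimeError, ValueError):
        result.fit_ok = False
    return result
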