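"""Dynamical classification, cobweb traces, bifurcation and phase sweeps.

Lattice-mean dynamics fall into five classes:

* ``0a`` / ``0b`` — quiescent steady state (fast / slow decay to zero);
* ``1a`` / ``1b`` — spiking (nonzero) steady state, with spatially random
  (``1a``) versus spatially coherent, front-dominated (``1b``) transients;
* ``2`` — oscillatory steady state (sustained period-2 alternation of the
  lattice mean), which requires a negatively-sloped rule with ``a1 = 0``
  and ``a0 > 0``.

The classifier works on the mean-activity series plus one transient
snapshot; all thresholds are explicit keyword arguments.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .activation import ActivationParams, evaluate
from .lattice import (
    LatticeConfig,
    NeighborMap,
    RunResult,
    binary_state,
    build_neighbor_map,
    initialize_state,
    run,
)

__all__ = [
    "CLASS_LABELS",
    "REPRESENTATIVE_PARAMS",
    "CobwebTrace",
    "BifurcationResult",
    "classify_run",
    "classify_params",
    "cobweb",
    "bifurcation_scan",
    "phase_sweep",
    "critical_fraction",
    "linear_grid",
    "nonlinear_grid",
    "correlation_length",
    "steady_onset",
]

CLASS_LABELS = ("0a", "0b", "1a", "1b", "2")

#: Representative linear-rule parameter sets, one per dynamical class
#: (chosen from the 0.1-step phase sweep; the oscillatory set is the
#: canonical negatively-sloped rule a0=0.6, a1=0, a2=0.6).
REPRESENTATIVE_PARAMS = {
    "0a": ActivationParams.linear(0.8, 0.9, 0.3),
    "0b": ActivationParams.linear(0.0, 1.0, 0.8),
    "1a": ActivationParams.linear(0.1, 0.4, 0.7),
    "1b": ActivationParams.linear(0.0, 0.6, 0.6),
    "2": ActivationParams.linear(0.6, 0.0, 0.6),
}


class InsufficientDataError(ValueError):
    """Raised when a mean-activity series is too short to classify."""


def correlation_length(field2d: np.ndarray, threshold: float = 1.0 / np.e) -> float:
    """Axis-averaged spatial autocorrelation length of a 2-D field, in cells.

    Computed from the wrapped (FFT) autocorrelation; the length is the first
    lag at which the axial autocorrelation drops below ``threshold``.  A
    near-uniform field has no structure to decorrelate and returns the
    maximum measurable lag.
    """
    x = np.asarray(field2d, dtype=float)
    x = x - x.mean()
    var = np.mean(x * x)
    max_lag = min(x.shape) // 2
    if var < 1e-12:
        return float(max_lag)
    f = np.fft.rfft2(x)
    acf = np.fft.irfft2(f * np.conj(f), s=x.shape).real / (var * x.size)
    lengths = []
    for axial in (acf[1 : max_lag + 1, 0], acf[0, 1 : max_lag + 1]):
        below = np.nonzero(axial < threshold)[0]
        lengths.append(float(below[0] + 1) if below.size else float(max_lag))
    return float(np.mean(lengths))


def classify_run(
    result: RunResult,
    *,
    tol_zero: float = 1e-4,
    t_fast: int = 10,
    osc_amp: float = 1e-3,
    corr_length: float = 5.0,
) -> str:
    """Assign one of the five class labels to a finished run.

    Decision rule: oscillatory (``2``) iff the last-10 mean-activity
    differences strictly alternate in sign with amplitude > ``osc_amp``;
    quiescent (``0``) iff the steady state is below ``tol_zero``, fast
    (``0a``) iff the mean first drops below ``tol_zero`` by ``t_fast``;
    otherwise spiking (``1``), coherent (``1b``) iff the transient snapshot
    at ``t = t_fast`` has autocorrelation length > ``corr_length`` cells.
    """
    series = np.asarray(result.mean_activity, dtype=float)
    if series.size < t_fast + 11:
        raise InsufficientDataError(
            f"need at least {t_fast + 11} timesteps, got {series.size - 1}"
        )
    tail = series[-10:]
    d = np.diff(tail)
    if np.all(np.abs(d) > osc_amp) and np.all(d[:-1] * d[1:] < 0.0):
        return "2"
    if result.steady_state < tol_zero:
        below = np.nonzero(series < tol_zero)[0]
        first = int(below[0]) if below.size else len(series)
        return "0a" if first <= t_fast else "0b"
    snap = result.snapshots.get(min(t_fast, len(series) - 1))
    if snap is None:
        return "1a"
    if correlation_length(snap[0] if snap.ndim == 3 else snap) > corr_length:
        return "1b"
    return "1a"


def _majority(labels: Sequence[str]) -> str:
    """Majority label; ties resolve to the first (lowest-seed) label."""
    counts = Counter(labels)
    top = max(counts.values())
    for lab in labels:
        if counts[lab] == top:
            return lab
    return labels[0]


def classify_params(
    p: ActivationParams,
    cfg: LatticeConfig,
    seeds: Sequence[int] = (0, 1, 2),
    *,
    nmap: Optional[NeighborMap] = None,
    init_states=None,
    **classify_kw,
):
    """Run ``p`` once per seed and return (majority label, mean steady state,
    per-seed labels)."""
    if nmap is None:
        nmap = build_neighbor_map(cfg)
    labels, steadies = [], []
    for k, seed in enumerate(seeds):
        scfg = cfg.with_seed(seed)
        init = init_states[k].copy() if init_states is not None else None
        res = run(scfg, p, init_state=init, nmap=nmap)
        labels.append(classify_run(res, **classify_kw))
        steadies.append(res.steady_state)
    return _majority(labels), float(np.mean(steadies)), labels


# ---------------------------------------------------------------------------
# cobweb analysis of the single-cell map

@dataclass
class CobwebTrace:
    """Graphical iteration of the activation map against the identity line.

    ``points`` alternates vertical and horizontal segments starting from
    ``(a_start, 0)``; ``iterates`` is the plain orbit ``x_{k+1} = f(x_k)``.
    ``terminal`` is ``("zero", ...)``, ``("fixed_point", (x,))``,
    ``("cycle", values)`` or ``("none", ())`` if undecided.
    """

    points: np.ndarray
    iterates: np.ndarray
    start: float
    terminal: tuple


def cobweb(
    p: ActivationParams,
    a_start: float,
    n_iter: int = 100,
    *,
    tol: float = 1e-9,
    max_period: int = 8,
) -> CobwebTrace:
    """Trace the cobweb of the activation map from ``a_start``.

    The geometric trace (vertical to the curve, horizontal to the identity
    line, repeat) is presentation only: the orbit equals plain functional
    iteration of the map.
    """
    if not 0.0 <= a_start <= 1.0:
        raise ValueError("a_start must lie in [0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    xs = np.empty(n_iter + 1)
    xs[0] = a_start
    pts = [(a_start, 0.0)]
    x = a_start
    for k in range(n_iter):
        y = float(evaluate(x, p))
        pts.append((x, y))  # vertical segment to the curve
        pts.append((y, y))  # horizontal segment to the identity line
        x = y
        xs[k + 1] = x
    if abs(xs[-1]) < tol:
        terminal = ("zero", (0.0,))
    elif abs(xs[-1] - xs[-2]) < tol:
        terminal = ("fixed_point", (float(xs[-1]),))
    else:
        terminal = ("none", ())
        for period in range(2, max_period + 1):
            if n_iter >= period and abs(xs[-1] - xs[-1 - period]) < tol:
                terminal = ("cycle", tuple(float(v) for v in xs[-period:]))
                break
    return CobwebTrace(
        points=np.array(pts), iterates=xs, start=float(a_start), terminal=terminal
    )


# ---------------------------------------------------------------------------
# parameter sweeps

@dataclass
class BifurcationResult:
    """Steady-regime values of the lattice mean along an ``a2`` sweep."""

    a0: float
    a1: float
    a2_values: np.ndarray
    steady_values: list  # per a2: the last-10 lattice means, one array per seed

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a2, vals in zip(self.a2_values, self.steady_values):
            for v in np.asarray(vals).ravel():
                rows.append((self.a0, self.a1, float(a2), float(v)))
        return pd.DataFrame(rows, columns=["a0", "a1", "a2", "steady_value"])

    def n_branches(self, a2_index: int, decimals: int = 3) -> int:
        vals = np.asarray(self.steady_values[a2_index]).ravel()
        return int(np.unique(np.round(vals, decimals)).size)


def bifurcation_scan(
    a0: float,
    a1: float,
    a2_grid: Iterable[float],
    cfg: LatticeConfig,
    *,
    order: str = "linear",
    b: float = 1.0,
    seeds: Sequence[int] = (0,),
) -> BifurcationResult:
    """Sweep ``a2`` at fixed ``a0``/``a1``, collecting the last-10 lattice
    means of each run (the points of the bifurcation diagram)."""
    a2_values = np.asarray(list(a2_grid), dtype=float)
    nmap = build_neighbor_map(cfg)
    inits = [initialize_state(cfg.with_seed(s)) for s in seeds]
    steady_values = []
    for a2 in a2_values:
        if order == "linear":
            p = ActivationParams.linear(a0, a1, float(a2))
        else:
            p = ActivationParams.nonlinear(a0, float(a2), b)
        vals = []
        for init in inits:
            res = run(cfg, p, init_state=init.copy(), nmap=nmap)
            vals.append(res.mean_activity[-10:])
        steady_values.append(np.concatenate(vals))
    return BifurcationResult(a0, a1, a2_values, steady_values)


def linear_grid(step: float = 0.1):
    """All (a0, a1, a2) combinations on a regular grid over [0, 1]^3."""
    axis = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return [
        ActivationParams.linear(float(a0), float(a1), float(a2))
        for a0, a1, a2 in itertools.product(axis, axis, axis)
    ]


def nonlinear_grid(a0_values, a2_values, b_values):
    """All (a0, a2, b) combinations of the nonlinear rule."""
    return [
        ActivationParams.nonlinear(float(a0), float(a2), float(b))
        for a0, a2, b in itertools.product(a0_values, a2_values, b_values)
    ]


def phase_sweep(
    params: Iterable[ActivationParams],
    cfg: LatticeConfig,
    *,
    seeds: Sequence[int] = (0, 1, 2),
    **classify_kw,
) -> pd.DataFrame:
    """Classify every parameter set in ``params`` (majority over ``seeds``).

    Returns a table with columns a0, a1, a2, b, order, class,
    steady_state (seed-averaged).  The neighbor map and the per-seed initial
    states are computed once and shared across parameter sets.
    """
    params = list(params)
    nmap = build_neighbor_map(cfg)
    inits = [initialize_state(cfg.with_seed(s)) for s in seeds]
    rows = []
    for p in params:
        label, steady, _ = classify_params(
            p, cfg, seeds, nmap=nmap, init_states=inits, **classify_kw
        )
        rows.append((p.a0, p.a1, p.a2, p.b, p.order, label, steady))
    return pd.DataFrame(
        rows, columns=["a0", "a1", "a2", "b", "order", "class", "steady_state"]
    )


def critical_fraction(
    p: ActivationParams,
    cfg: LatticeConfig,
    f_grid: Iterable[float],
    *,
    seeds: Sequence[int] = (0, 1, 2),
    tol_zero: float = 1e-4,
    nmap: Optional[NeighborMap] = None,
) -> Optional[float]:
    """Smallest initial active fraction sustaining a nonzero steady state.

    Cells start binary: a fraction ``f`` at activity 1, the rest at 0.  For
    each ``f`` (ascending) the steady state is averaged over ``seeds``; the
    first ``f`` whose average exceeds ``tol_zero`` is returned, or ``None``
    if no fraction on the grid sustains activity.
    """
    if nmap is None:
        nmap = build_neighbor_map(cfg)
    for f in sorted(float(f) for f in f_grid):
        steadies = []
        for seed in seeds:
            scfg = cfg.with_seed(seed)
            res = run(scfg, p, init_state=binary_state(scfg, f), nmap=nmap)
            steadies.append(res.steady_state)
        if float(np.mean(steadies)) > tol_zero:
            return f
    return None


def steady_onset(
    series: np.ndarray,
    *,
    period: int = 1,
    tol: float = 1e-3,
    window: int = 10,
) -> Optional[int]:
    """First timestep from which the mean-activity series is steady.

    Steady means ``|s[t + period] - s[t]| < tol`` for ``window`` consecutive
    ``t``; for oscillatory runs use ``period = 2`` (the period-2 envelope).
    Returns ``None`` if the series never settles.
    """
    s = np.asarray(series, dtype=float)
    d = np.abs(s[period:] - s[:-period])
    ok = d < tol
    if ok.size < window:
        return None
    run_len = 0
    for t, flag in enumerate(ok):
        run_len = run_len + 1 if flag else 0
        if run_len >= window:
            return t - window + 1
    return None
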