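"""Lattice geometries, neighbor maps and synchronous CA updates.

Cells live on an ``n_layers x rows x cols`` lattice.  Within a layer the
neighborhood is Moore (the 8 surrounding cells); ``outer_totalistic`` mode
additionally includes the cell itself.  Two boundary conditions are
supported:

* ``toroidal`` — both lattice dimensions wrap;
* ``spherical`` — only columns wrap; the top and bottom rows each form a
  fully-connected pole, with each pole cell also connected to the three
  cells in the adjacent row.

With two layers, each cell gains the co-located cell of the other layer as
one extra neighbor; with three or more layers it gains the co-located cells
of the layers above and below (topmost and bottommost layers adjacent).

A cell's input is the arithmetic mean of its neighborhood's activities; the
update is synchronous.  An optional fraction of cells is clamped to a
constant external activity (``ext_value``, 1 by default), emulating
externally driven neurons; clamped cells participate in their neighbors'
averages and are reset to the clamp value after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .activation import ActivationParams, evaluate

__all__ = [
    "LatticeConfig",
    "NeighborMap",
    "PatchState",
    "RunResult",
    "ConfigError",
    "build_neighbor_map",
    "initialize_state",
    "binary_state",
    "uniform_state",
    "step",
    "run",
]

TOROIDAL = "toroidal"
SPHERICAL = "spherical"
TOTALISTIC = "totalistic"
OUTER_TOTALISTIC = "outer_totalistic"

#: activity level below which an unclamped lattice is treated as extinct
#: (the quiescent state is absorbing, so the remaining steps are all zero)
_DEAD = 1e-15


class ConfigError(ValueError):
    """Raised for invalid lattice configurations."""


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry, clamping and run-length settings for a CA simulation."""

    rows: int = 128
    cols: int = 128
    n_layers: int = 1
    boundary: str = TOROIDAL
    neighborhood: str = TOTALISTIC
    ext_fraction: float = 0.0
    ext_value: float = 1.0
    seed: int = 0
    timesteps: int = 100

    def __post_init__(self) -> None:
        if self.rows < 3 or self.cols < 3:
            raise ConfigError("rows and cols must be >= 3 for a Moore neighborhood")
        if self.n_layers < 1:
            raise ConfigError("n_layers must be >= 1")
        if self.boundary not in (TOROIDAL, SPHERICAL):
            raise ConfigError(f"unknown boundary {self.boundary!r}")
        if self.neighborhood not in (TOTALISTIC, OUTER_TOTALISTIC):
            raise ConfigError(f"unknown neighborhood {self.neighborhood!r}")
        if not 0.0 <= self.ext_fraction <= 1.0:
            raise ConfigError("ext_fraction must lie in [0, 1]")
        if not 0.0 <= self.ext_value <= 1.0:
            raise ConfigError("ext_value must lie in [0, 1]")
        if self.timesteps < 1:
            raise ConfigError("timesteps must be >= 1")

    @property
    def n_cells(self) -> int:
        return self.n_layers * self.rows * self.cols

    @property
    def shape(self) -> tuple:
        return (self.n_layers, self.rows, self.cols)

    def with_seed(self, seed: int) -> "LatticeConfig":
        return replace(self, seed=seed)


@dataclass
class NeighborMap:
    """Per-cell neighbor lists in CSR layout plus the row-averaging matrix.

    ``indptr``/``indices`` give, for flat cell index ``i``, the neighbor
    indices ``indices[indptr[i]:indptr[i+1]]`` (including ``i`` itself in
    outer-totalistic mode).  ``mean_matrix`` is the sparse matrix ``W`` with
    ``W[i, j] = 1/deg(i)`` for each neighbor ``j``, so the vector of
    neighborhood-mean inputs is ``W @ a``.
    """

    shape: tuple
    neighborhood: str
    indptr: np.ndarray
    indices: np.ndarray
    mean_matrix: sp.csr_matrix = field(repr=False)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def counts(self) -> np.ndarray:
        return np.diff(self.indptr)


def _toroidal_pairs(rows: int, cols: int):
    """COO (i, j) pairs of the Moore neighborhood with both dims wrapping."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    i = (r * cols + c).ravel()
    src, dst = [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            j = (((r + dr) % rows) * cols + (c + dc) % cols).ravel()
            src.append(i)
            dst.append(j)
    return np.concatenate(src), np.concatenate(dst)


def _spherical_pairs(rows: int, cols: int):
    """COO pairs for the spherical boundary: columns wrap, rows do not;
    top/bottom rows are fully-connected poles linked to the adjacent row."""
    src, dst = [], []
    # interior rows keep the full Moore stencil (row +/- 1 always in range)
    r, c = np.meshgrid(np.arange(1, rows - 1), np.arange(cols), indexing="ij")
    i = (r * cols + c).ravel()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            j = ((r + dr) * cols + (c + dc) % cols).ravel()
            src.append(i)
            dst.append(j)
    cs = np.arange(cols)
    for row, inner in ((0, 1), (rows - 1, rows - 2)):
        base = row * cols
        # pole: every other cell of the same row
        ii, jj = np.meshgrid(cs, cs, indexing="ij")
        off = ii != jj
        src.append(base + ii[off])
        dst.append(base + jj[off])
        # plus the three cells of the adjacent row (columns c-1, c, c+1)
        for dc in (-1, 0, 1):
            src.append(base + cs)
            dst.append(inner * cols + (cs + dc) % cols)
    return np.concatenate(src), np.concatenate(dst)


def build_neighbor_map(cfg: LatticeConfig) -> NeighborMap:
    """Construct the neighbor map for ``cfg``; deterministic in ``cfg``."""
    rows, cols, layers = cfg.rows, cfg.cols, cfg.n_layers
    rc = rows * cols
    if cfg.boundary == TOROIDAL:
        s0, d0 = _toroidal_pairs(rows, cols)
    else:
        s0, d0 = _spherical_pairs(rows, cols)
    src = [s0 + l * rc for l in range(layers)]
    dst = [d0 + l * rc for l in range(layers)]
    if layers == 2:
        cell = np.arange(rc)
        for l, other in ((0, 1), (1, 0)):
            src.append(cell + l * rc)
            dst.append(cell + other * rc)
    elif layers >= 3:
        cell = np.arange(rc)
        for l in range(layers):
            for other in ((l - 1) % layers, (l + 1) % layers):
                src.append(cell + l * rc)
                dst.append(cell + other * rc)
    if cfg.neighborhood == OUTER_TOTALISTIC:
        all_cells = np.arange(layers * rc)
        src.append(all_cells)
        dst.append(all_cells)
    i = np.concatenate(src)
    j = np.concatenate(dst)
    n = layers * rc
    adj = sp.coo_matrix((np.ones(i.size), (i, j)), shape=(n, n)).tocsr()
    adj.sort_indices()
    counts = np.diff(adj.indptr)
    inv = sp.csr_matrix(
        (np.repeat(1.0 / counts, counts), adj.indices, adj.indptr), shape=(n, n)
    )
    return NeighborMap(
        shape=cfg.shape,
        neighborhood=cfg.neighborhood,
        indptr=adj.indptr.copy(),
        indices=adj.indices.copy(),
        mean_matrix=inv,
    )


@dataclass
class PatchState:
    """Per-cell activities plus the external-input clamp mask."""

    a: np.ndarray  # shape (n_layers, rows, cols), values in [0, 1]
    clamp_mask: np.ndarray  # bool, same shape
    ext_value: float = 1.0

    def copy(self) -> "PatchState":
        return PatchState(self.a.copy(), self.clamp_mask, self.ext_value)

    @property
    def mean_activity(self) -> float:
        return float(self.a.mean())


def _clamp_mask(cfg: LatticeConfig, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(cfg.n_cells, dtype=bool)
    n_ext = int(round(cfg.ext_fraction * cfg.n_cells))
    if n_ext:
        mask[rng.choice(cfg.n_cells, size=n_ext, replace=False)] = True
    return mask.reshape(cfg.shape)


def _rngs(cfg: LatticeConfig):
    """Independent substreams for initial values and clamp placement."""
    ss_vals, ss_clamp = np.random.SeedSequence(cfg.seed).spawn(2)
    return np.random.default_rng(ss_vals), np.random.default_rng(ss_clamp)


def initialize_state(cfg: LatticeConfig) -> PatchState:
    """Uniform-random initial activities with seeded clamp placement."""
    rng_vals, rng_clamp = _rngs(cfg)
    a = rng_vals.uniform(0.0, 1.0, size=cfg.shape)
    mask = _clamp_mask(cfg, rng_clamp)
    a[mask] = cfg.ext_value
    return PatchState(a, mask, cfg.ext_value)


def binary_state(cfg: LatticeConfig, fraction: float) -> PatchState:
    """Initial state with ``round(fraction * N)`` random cells at activity 1
    and the rest at 0 (plus the usual external-input clamps)."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must lie in [0, 1]")
    rng_vals, rng_clamp = _rngs(cfg)
    a = np.zeros(cfg.n_cells)
    n_on = int(round(fraction * cfg.n_cells))
    if n_on:
        a[rng_vals.choice(cfg.n_cells, size=n_on, replace=False)] = 1.0
    a = a.reshape(cfg.shape)
    mask = _clamp_mask(cfg, rng_clamp)
    a[mask] = cfg.ext_value
    return PatchState(a, mask, cfg.ext_value)


def uniform_state(cfg: LatticeConfig, value: float) -> PatchState:
    """Spatially homogeneous initial state (useful for map-level checks)."""
    a = np.full(cfg.shape, float(value))
    _, rng_clamp = _rngs(cfg)
    mask = _clamp_mask(cfg, rng_clamp)
    a[mask] = cfg.ext_value
    return PatchState(a, mask, cfg.ext_value)


def step(state: PatchState, nmap: NeighborMap, p: ActivationParams) -> PatchState:
    """One synchronous update: neighborhood mean -> activation -> re-clamp."""
    a_in = nmap.mean_matrix @ state.a.ravel()
    a_out = evaluate(a_in, p).reshape(state.a.shape)
    if state.clamp_mask.any():
        a_out[state.clamp_mask] = state.ext_value
    state.a = a_out
    return state


@dataclass
class RunResult:
    """Time series and summary of one CA simulation.

    ``mean_activity[t]`` is the lattice mean at timestep ``t`` (``t = 0`` is
    the initial state, so the series has ``timesteps + 1`` entries);
    ``steady_state`` is the mean of the final 10 entries.  ``snapshots``
    maps a timestep to a copy of the full lattice at that time.
    """

    mean_activity: np.ndarray
    snapshots: dict
    steady_state: float
    cfg: LatticeConfig
    params: ActivationParams
    label: Optional[str] = None


def run(
    cfg: LatticeConfig,
    p: ActivationParams,
    *,
    init_state: Optional[PatchState] = None,
    nmap: Optional[NeighborMap] = None,
    snapshot_times=None,
    record_all: bool = False,
) -> RunResult:
    """Simulate ``cfg.timesteps`` synchronous updates.

    ``snapshot_times`` defaults to ``{min(10, timesteps)}`` so the
    classifier's transient snapshot is always available; ``record_all``
    stores every timestep (needed for discrete-state rasters).  Pass
    ``init_state``/``nmap`` to reuse precomputed objects across runs (the
    state is consumed; pass a copy to keep it).
    """
    if nmap is None:
        nmap = build_neighbor_map(cfg)
    state = init_state if init_state is not None else initialize_state(cfg)
    T = cfg.timesteps
    if record_all:
        snap_at = set(range(T + 1))
    elif snapshot_times is None:
        snap_at = {min(10, T)}
    else:
        snap_at = {int(t) for t in snapshot_times}
    means = np.empty(T + 1)
    means[0] = state.mean_activity
    snapshots = {}
    if 0 in snap_at:
        snapshots[0] = state.a.copy()
    clamped = bool(state.clamp_mask.any())
    for t in range(1, T + 1):
        step(state, nmap, p)
        means[t] = state.mean_activity
        if t in snap_at:
            snapshots[t] = state.a.copy()
        if not clamped and means[t] < _DEAD and state.a.max() < _DEAD:
            # quiescence is absorbing for an unclamped lattice
            means[t:] = 0.0
            zero = np.zeros_like(state.a)
            for ts in snap_at:
                if ts > t:
                    snapshots[ts] = zero.copy()
            state.a[:] = 0.0
            break
    tail = means[-10:] if T >= 10 else means
    return RunResult(
        mean_activity=means,
        snapshots=snapshots,
        steady_state=float(tail.mean()),
        cfg=cfg,
        params=p,
    )
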