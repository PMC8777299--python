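"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from neuroca.activation import ActivationParams, evaluate
from neuroca.lattice import LatticeConfig


# ---------------------------------------------------------------------------
# independent brute-force oracle for the lattice update
#
# Adjacency is enumerated cell by cell straight from the geometry rules,
# without the production CSR/matrix machinery, so the two paths share no code.

def brute_force_neighbors(cfg: LatticeConfig):
    """Map flat cell index -> sorted list of neighbor indices."""
    L, R, C = cfg.n_layers, cfg.rows, cfg.cols

    def flat(l, r, c):
        return l * R * C + r * C + c

    out = {}
    for l, r, c in itertools.product(range(L), range(R), range(C)):
        nbrs = set()
        if cfg.boundary == "toroidal":
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    nbrs.add(flat(l, (r + dr) % R, (c + dc) % C))
        else:  # spherical: columns wrap, pole rows fully connected
            if r in (0, R - 1):
                inner = 1 if r == 0 else R - 2
                for c2 in range(C):
                    if c2 != c:
                        nbrs.add(flat(l, r, c2))
                for dc in (-1, 0, 1):
                    nbrs.add(flat(l, inner, (c + dc) % C))
            else:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        nbrs.add(flat(l, r + dr, (c + dc) % C))
        if L == 2:
            nbrs.add(flat(1 - l, r, c))
        elif L >= 3:
            nbrs.add(flat((l - 1) % L, r, c))
            nbrs.add(flat((l + 1) % L, r, c))
        if cfg.neighborhood == "outer_totalistic":
            nbrs.add(flat(l, r, c))
        out[flat(l, r, c)] = sorted(nbrs)
    return out


def brute_force_step(a: np.ndarray, cfg: LatticeConfig, p: ActivationParams):
    """Naive per-cell neighborhood averaging followed by the activation map."""
    flat = a.ravel()
    nbrs = brute_force_neighbors(cfg)
    out = np.empty_like(flat)
    for i in range(flat.size):
        out[i] = evaluate(float(np.mean(flat[nbrs[i]])), p)
    return out.reshape(a.shape)


ALL_GEOMETRIES = [
    pytest.param(b, n, l, id=f"{b}-{n}-{l}layer")
    for b, n, l in itertools.product(
        ("toroidal", "spherical"), ("totalistic", "outer_totalistic"), (1, 2, 4)
    )
]


@pytest.fixture(scope="session")
def linear_phase_table():
    """Classification of the full 0.1-step linear-rule grid at 128x128,
    majority over seeds 0-2 (shared: it is the costly input to several
    dynamical-regime checks)."""
    from neuroca.analysis import linear_grid, phase_sweep

    cfg = LatticeConfig(rows=128, cols=128)
    return phase_sweep(linear_grid(0.1), cfg, seeds=(0, 1, 2))
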