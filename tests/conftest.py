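"""Shared fixtures: small hand-built tissues and session-scoped simulations."""

from __future__ import annotations

import math

import numpy as np
import pytest

from epimech.experiments import reference_sim_config
from epimech.mesh import Cell, Junction, Tissue, Vertex
from epimech.simulator import simulate_dataset


def build_tissue(coords, loops, frame_flags=(), validate=True) -> Tissue:
    """Build a tissue from vertex coordinates and cell loops; junctions are
    derived from consecutive loop pairs."""
    vertices = [Vertex(i, float(x), float(y), i in frame_flags)
                for i, (x, y) in enumerate(coords)]
    seen: dict[frozenset, int] = {}
    junctions = []
    for loop in loops:
        for a, b in zip(loop, loop[1:] + loop[:1]):
            key = frozenset((a, b))
            if key not in seen:
                seen[key] = len(junctions)
                junctions.append(Junction(len(junctions), a, b))
    cells = [Cell(i, list(loop)) for i, loop in enumerate(loops)]
    return Tissue(vertices, junctions, cells, validate=validate)


def unit_square() -> Tissue:
    return build_tissue(
        [(0, 0), (1, 0), (1, 1), (0, 1)],
        [[0, 1, 2, 3]],
    )


def square_grid(nx: int, ny: int, size: float = 1.0) -> Tissue:
    """nx x ny grid of square cells with shared vertices and junctions."""
    coords = [(i * size, j * size) for j in range(ny + 1) for i in range(nx + 1)]
    def vid(i, j):
        return j * (nx + 1) + i
    loops = [
        [vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)]
        for j in range(ny) for i in range(nx)
    ]
    return build_tissue(coords, loops)


def hexagon_lattice(n_rows: int = 4, n_cols: int = 4, radius: float = 1.0) -> Tissue:
    """Perfect regular-hexagon tiling (pointy-top, axial layout)."""
    w = math.sqrt(3.0) * radius
    key2id: dict[tuple[int, int], int] = {}
    coords: list[tuple[float, float]] = []
    loops = []
    for r in range(n_rows):
        for c in range(n_cols):
            cx = c * w + (r % 2) * w / 2
            cy = r * 1.5 * radius
            loop = []
            for k in range(6):
                ang = math.pi / 6 + k * math.pi / 3
                x = cx + radius * math.cos(ang)
                y = cy + radius * math.sin(ang)
                key = (round(x * 1e9), round(y * 1e9))
                if key not in key2id:
                    key2id[key] = len(coords)
                    coords.append((x, y))
                loop.append(key2id[key])
            loops.append(loop)
    return build_tissue(coords, loops)


@pytest.fixture
def unit_square_tissue() -> Tissue:
    return unit_square()


@pytest.fixture(scope="session")
def ref_sim_small():
    """Scaled reference simulation: model A, reference parameters, 10x10
    tile, t = 2000 (a faster stand-in for the 20x20 / t = 5000 protocol)."""
    cfg = reference_sim_config("A", tile=(10, 10), t_end=2000.0, seed=11)
    return simulate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def small_sim_c():
    """Small isotropic-spring (model C) equilibrium used by several tests."""
    cfg = reference_sim_config("C", tile=(6, 6), t_end=1000.0, seed=7)
    return simulate_dataset(cfg), cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
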