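"""Cell-vertex-model simulator producing synthetic equilibrium tissues.

Cells are polygons; vertex positions relax down the gradient of a virtual
work U0 by explicit forward Euler with fixed time step. For the anisotropic
spring family,

    U0 = sum_junctions [ Lam0(theta) l - 1/2 Lam1(theta) l^2 ]
         + sum_cells k/2 (A - A0)^2,

and for the conventional family,

    U0 = sum_junctions Lam0(theta) l + sum_cells 1/2 Gamma L^2
         + sum_cells k/2 (A - A0)^2.

The force on a vertex is the sum of junction tensions T = dU0/dl pulling it
toward the far endpoints plus cell pressures P = -dU0/dA acting through the
shoelace area gradient; derivatives of the orientation-dependent anisotropy
factors are ignored (the anisotropy is frozen at the current junction
angles), which is the standard quasi-static treatment. The area term makes
the simulated pressure law P(A) = -k (A - A0), i.e. linear in A.

Junctions shorter than the T1 threshold may undergo a neighbor-exchange (T1)
transition: the edge is rotated 90 degrees about its midpoint, length
preserved, cell memberships reconnected, and the move is kept only if it
lowers U0.

The initial condition is a bounded Voronoi tessellation of uniformly random
centroids in a rectangle sized so the mean cell area equals the target A0;
the tissue boundary is free (no exterior medium, zero outside pressure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, DomainError, InstabilityError
from .mesh import Cell, Junction, Tissue, Vertex
from .models import ANISO_SPRING, CONVENTIONAL, ModelSpec, ParameterSet, from_polar

__all__ = [
    "SimConfig",
    "SimResult",
    "generate_initial_tile",
    "virtual_work",
    "forces",
    "relax",
    "t1_transition",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Simulation configuration.

    t1_threshold defaults to 0.05 * sqrt(A0) (a length; junctions shorter
    than this may attempt a T1 move). trace_every controls how often U0 is
    appended to the energy trace, in steps.
    """

    spec: ModelSpec = field(default_factory=ModelSpec)
    params: ParameterSet = field(default_factory=ParameterSet)
    tile: tuple[int, int] = (20, 20)
    A0: float = 1.0
    dt: float = 0.1
    t_end: float = 5000.0
    t1_threshold: float | None = None
    seed: int = 0
    trace_every: int = 100
    # final settling phases (dt, duration) run after the main loop: vertices
    # pinned against the |l| kink of a collapse-blocked junction oscillate
    # with amplitude ~ dt * |force|, so a brief decreasing-dt tail shrinks
    # the residual imbalance of their neighbours to the quasi-static level
    # the estimator assumes. Set to () to disable.
    settle_phases: tuple[tuple[float, float], ...] = (
        (0.05, 200.0), (0.01, 50.0), (0.001, 5.0))

    def __post_init__(self):
        if self.dt <= 0 or self.t_end < self.dt:
            raise ConfigurationError("need dt > 0 and t_end >= dt")
        if min(self.tile) < 2:
            raise ConfigurationError("tile counts must be >= 2")
        if self.t1_threshold is None:
            self.t1_threshold = 0.05 * math.sqrt(self.A0)
        if self.t1_threshold < 0:
            raise ConfigurationError("t1_threshold must be >= 0")


@dataclass
class SimResult:
    tissue: Tissue
    truth: ParameterSet
    spec: ModelSpec
    energy_trace: np.ndarray
    t1_count: int
    converged: float  # max |force| at the final step
    config: SimConfig | None = None


# =====================================================================
# internal flat-array state
# =====================================================================

class _State:
    """Flat-array mirror of a Tissue used inside the relaxation loop."""

    def __init__(self, tissue: Tissue):
        self.vertex_ids = sorted(tissue.vertices)
        self.cell_ids = sorted(tissue.cells)
        self.junction_ids = sorted(tissue.junctions)
        vidx = {vid: i for i, vid in enumerate(self.vertex_ids)}
        self.pos = np.array(
            [[tissue.vertices[v].x, tissue.vertices[v].y] for v in self.vertex_ids]
        )
        self.frame_flags = [tissue.vertices[v].frame_boundary for v in self.vertex_ids]
        self.edges = np.array(
            [[vidx[tissue.junctions[j].v1], vidx[tissue.junctions[j].v2]]
             for j in self.junction_ids],
            dtype=np.intp,
        ).reshape(-1, 2)
        self.loops: list[list[int]] = [
            [vidx[v] for v in tissue.cells[c].vertex_loop] for c in self.cell_ids
        ]
        self.provenance = tissue.provenance
        self.pixel_scale = tissue.pixel_scale
        self.rebuild()

    # ------------------------------------------------------------- topology
    def rebuild(self) -> None:
        """Recompute all derived arrays after a topology change."""
        nv = len(self.pos)
        flat, nxt, prv, cof, starts = [], [], [], [], []
        for ci, loop in enumerate(self.loops):
            starts.append(len(flat))
            n = len(loop)
            for i, v in enumerate(loop):
                flat.append(v)
                nxt.append(loop[(i + 1) % n])
                prv.append(loop[(i - 1) % n])
                cof.append(ci)
        self.flat = np.array(flat, dtype=np.intp)
        self.nxt = np.array(nxt, dtype=np.intp)
        self.prv = np.array(prv, dtype=np.intp)
        self.cell_of_flat = np.array(cof, dtype=np.intp)
        self.starts = np.array(starts, dtype=np.intp)

        self.edge_lookup = {
            frozenset((int(a), int(b))): j for j, (a, b) in enumerate(self.edges)
        }
        ec = np.full((len(self.edges), 2), -1, dtype=np.intp)
        for ci, loop in enumerate(self.loops):
            n = len(loop)
            for i in range(n):
                j = self.edge_lookup[frozenset((loop[i], loop[(i + 1) % n]))]
                if ec[j, 0] == -1:
                    ec[j, 0] = ci
                else:
                    ec[j, 1] = ci
        self.edge_cells = ec
        self.interior_edge = ec[:, 1] >= 0

        self.deg = np.bincount(self.edges.ravel(), minlength=nv)
        bv = np.zeros(nv, dtype=bool)
        be = self.edges[~self.interior_edge]
        bv[be.ravel()] = True
        self.boundary_vertex = bv

        vc: list[set[int]] = [set() for _ in range(nv)]
        for ci, loop in enumerate(self.loops):
            for v in loop:
                vc[v].add(ci)
        self.vertex_cells = vc

    # ------------------------------------------------------------- geometry
    def edge_geometry(self):
        """lengths, unit vectors, sin/cos of 2*theta for every junction."""
        p0 = self.pos[self.edges[:, 0]]
        d = self.pos[self.edges[:, 1]] - p0
        l2 = d[:, 0] ** 2 + d[:, 1] ** 2
        l = np.sqrt(l2)
        l2s = np.where(l2 > 0, l2, 1.0)
        inv_l = np.where(l > 0, 1.0 / np.where(l > 0, l, 1.0), 0.0)
        ux = d[:, 0] * inv_l
        uy = d[:, 1] * inv_l
        c2 = (d[:, 0] ** 2 - d[:, 1] ** 2) / l2s
        s2 = 2.0 * d[:, 0] * d[:, 1] / l2s
        return l, ux, uy, s2, c2

    def areas(self) -> np.ndarray:
        x, y = self.pos[self.flat, 0], self.pos[self.flat, 1]
        xn, yn = self.pos[self.nxt, 0], self.pos[self.nxt, 1]
        cross = x * yn - xn * y
        return 0.5 * np.add.reduceat(cross, self.starts)

    def perimeters(self) -> np.ndarray:
        d = self.pos[self.nxt] - self.pos[self.flat]
        seg = np.hypot(d[:, 0], d[:, 1])
        return np.add.reduceat(seg, self.starts)

    # --------------------------------------------------------------- export
    def to_tissue(self) -> Tissue:
        vertices = [
            Vertex(self.vertex_ids[i], float(self.pos[i, 0]), float(self.pos[i, 1]),
                   self.frame_flags[i])
            for i in range(len(self.pos))
        ]
        junctions = [
            Junction(self.junction_ids[j], self.vertex_ids[int(a)], self.vertex_ids[int(b)])
            for j, (a, b) in enumerate(self.edges)
        ]
        cells = [
            Cell(self.cell_ids[ci], [self.vertex_ids[v] for v in loop])
            for ci, loop in enumerate(self.loops)
        ]
        return Tissue(vertices, junctions, cells,
                      pixel_scale=self.pixel_scale, provenance=self.provenance)


def _tension_coeffs(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """Six generic linear tension coefficients for the family's full model."""
    if spec.family == ANISO_SPRING:
        full = ModelSpec(ANISO_SPRING, "A", spec.pressure_form)
        # variants are the full model with the omitted parameters at zero
        return from_polar(full, params).vector()[:-1]
    full = ModelSpec(CONVENTIONAL, "both_aniso", spec.pressure_form)
    return from_polar(full, params).vector()[:-1]


def _junction_tensions(state: _State, spec: ModelSpec, params: ParameterSet,
                       l, s2, c2, coeffs=None) -> np.ndarray:
    c = coeffs if coeffs is not None else _tension_coeffs(spec, params)
    lam0 = c[0] + c[1] * s2 + c[2] * c2
    if spec.family == ANISO_SPRING:
        lam1 = c[3] + c[4] * s2 + c[5] * c2
        return lam0 - lam1 * l
    if params.muG != 0.0:
        raise ConfigurationError(
            "anisotropic cortical elasticity has no cell-level potential; "
            "the simulator supports muG = 0 only"
        )
    L = state.perimeters()
    ec = state.edge_cells
    Lsum = L[ec[:, 0]] + np.where(ec[:, 1] >= 0, L[np.maximum(ec[:, 1], 0)], 0.0)
    gam = c[3] + c[4] * s2 + c[5] * c2
    return lam0 + gam * Lsum


def _state_energy(state: _State, spec: ModelSpec, params: ParameterSet,
                  coeffs=None) -> float:
    l, _, _, s2, c2 = state.edge_geometry()
    A = state.areas()
    area_term = 0.5 * params.k * float(np.sum((A - params.A0) ** 2))
    c = coeffs if coeffs is not None else _tension_coeffs(spec, params)
    lam0 = c[0] + c[1] * s2 + c[2] * c2
    if spec.family == ANISO_SPRING:
        lam1 = c[3] + c[4] * s2 + c[5] * c2
        return float(np.sum(lam0 * l - 0.5 * lam1 * l ** 2)) + area_term
    if params.muG != 0.0:
        raise ConfigurationError("simulator requires muG = 0 (see _junction_tensions)")
    L = state.perimeters()
    return (float(np.sum(lam0 * l)) + 0.5 * params.Gamma0 * float(np.sum(L ** 2))
            + area_term)


def _state_forces(state: _State, spec: ModelSpec, params: ParameterSet,
                  geom=None, coeffs=None) -> np.ndarray:
    """Per-vertex force array, anisotropy frozen at current angles."""
    if geom is None:
        geom = state.edge_geometry()
    l, ux, uy, s2, c2 = geom
    T = _junction_tensions(state, spec, params, l, s2, c2, coeffs)
    nv = len(state.pos)
    e0, e1 = state.edges[:, 0], state.edges[:, 1]
    # tension pulls each endpoint toward the far endpoint
    wx, wy = T * ux, T * uy
    fx = np.bincount(e0, weights=wx, minlength=nv) - np.bincount(e1, weights=wx, minlength=nv)
    fy = np.bincount(e0, weights=wy, minlength=nv) - np.bincount(e1, weights=wy, minlength=nv)
    # pressure P = -k (A - A0) acts through the shoelace area gradient
    A = state.areas()
    P = -params.k * (A - params.A0)
    Pf = P[state.cell_of_flat]
    gx = 0.5 * (state.pos[state.nxt, 1] - state.pos[state.prv, 1])
    gy = 0.5 * (state.pos[state.prv, 0] - state.pos[state.nxt, 0])
    fx += np.bincount(state.flat, weights=Pf * gx, minlength=nv)
    fy += np.bincount(state.flat, weights=Pf * gy, minlength=nv)
    return np.column_stack([fx, fy])


# =====================================================================
# T1 transitions
# =====================================================================

def _local_energy(state: _State, edge_idx: list[int], cell_idx: list[int],
                  spec: ModelSpec, params: ParameterSet, coeffs) -> float:
    """Virtual-work contribution of a subset of edges and cells.

    A T1 flip moves only the two edge endpoints, so the energy change is
    confined to the edges incident to them and the four surrounding cells;
    comparing this local sum before and after is equivalent to comparing
    the global U0 but does not require rebuilding the flat arrays.
    """
    # tiny index sets: plain Python arithmetic beats numpy dispatch here
    pos = state.pos
    edges = state.edges
    c0, c1_, c2_, c3, c4, c5 = (float(v) for v in coeffs)
    aniso = spec.family == ANISO_SPRING
    U = 0.0
    for j in edge_idx:
        va, vb = edges[j, 0], edges[j, 1]
        dx = pos[vb, 0] - pos[va, 0]
        dy = pos[vb, 1] - pos[va, 1]
        l2 = dx * dx + dy * dy
        l = math.sqrt(l2)
        if l2 > 0:
            cc = (dx * dx - dy * dy) / l2
            ss = 2.0 * dx * dy / l2
        else:
            cc = ss = 0.0
        lam0 = c0 + c1_ * ss + c2_ * cc
        if aniso:
            lam1 = c3 + c4 * ss + c5 * cc
            U += lam0 * l - 0.5 * lam1 * l2
        else:
            U += lam0 * l
    k, A0 = params.k, params.A0
    for ci in cell_idx:
        loop = state.loops[ci]
        area = 0.0
        perim = 0.0
        xp, yp = pos[loop[-1], 0], pos[loop[-1], 1]
        for v in loop:
            x, y = pos[v, 0], pos[v, 1]
            area += xp * y - x * yp
            if not aniso:
                perim += math.hypot(x - xp, y - yp)
            xp, yp = x, y
        area *= 0.5
        U += 0.5 * k * (area - A0) ** 2
        if not aniso:
            U += 0.5 * params.Gamma0 * perim * perim
    return U


def _find_directed(loop: list[int], a: int, b: int) -> int:
    """Index i such that loop[i] == a and loop[i+1] == b, or -1."""
    n = len(loop)
    for i in range(n):
        if loop[i] == a and loop[(i + 1) % n] == b:
            return i
    return -1


def _attempt_t1(state: _State, j: int, spec: ModelSpec, params: ParameterSet,
                coeffs=None, rebuild: bool = True,
                open_length: float | None = None) -> bool:
    """Try a T1 flip of junction index j; keep it only if U0 decreases.

    The trial edge is rotated 90 degrees about its midpoint. By default its
    length is preserved; when ``open_length`` is given the trial edge opens
    to at least that length. Opening matters for near-collapsed junctions:
    with the length preserved the energy difference of the flip is O(l) and
    a strongly downhill neighbor exchange is invisible at l ~ 0, leaving
    permanently unbalanced four-fold-like vertex pairs.
    """
    if coeffs is None:
        coeffs = _tension_coeffs(spec, params)
    a, b = int(state.edges[j, 0]), int(state.edges[j, 1])
    if not state.interior_edge[j]:
        return False
    if state.deg[a] != 3 or state.deg[b] != 3:
        return False
    if state.boundary_vertex[a] or state.boundary_vertex[b]:
        return False
    ca_set = state.vertex_cells[a] - set(state.edge_cells[j])
    cb_set = state.vertex_cells[b] - set(state.edge_cells[j])
    if len(ca_set) != 1 or len(cb_set) != 1:
        return False
    ca, cb = ca_set.pop(), cb_set.pop()
    # orient: c1 traverses a->b, c2 traverses b->a
    c1, c2 = int(state.edge_cells[j, 0]), int(state.edge_cells[j, 1])
    if _find_directed(state.loops[c1], a, b) < 0:
        c1, c2 = c2, c1
    if len({c1, c2, ca, cb}) < 4:
        return False
    if len(state.loops[c1]) < 4 or len(state.loops[c2]) < 4:
        return False
    i1 = _find_directed(state.loops[c1], a, b)
    i2 = _find_directed(state.loops[c2], b, a)
    if i1 < 0 or i2 < 0:
        return False
    loop1, loop2 = state.loops[c1], state.loops[c2]
    q1 = loop1[(i1 + 2) % len(loop1)]  # after b in c1
    q2 = loop2[(i2 + 2) % len(loop2)]  # after a in c2
    # junctions to re-anchor: (b, q1) -> (a, q1), (a, q2) -> (b, q2)
    jb = state.edge_lookup.get(frozenset((b, q1)))
    ja = state.edge_lookup.get(frozenset((a, q2)))
    if jb is None or ja is None:
        return False
    p1 = loop1[(i1 - 1) % len(loop1)]  # before a in c1
    p2 = loop2[(i2 - 1) % len(loop2)]  # before b in c2
    j_ap1 = state.edge_lookup.get(frozenset((a, p1)))
    j_bp2 = state.edge_lookup.get(frozenset((b, p2)))
    if j_ap1 is None or j_bp2 is None:
        return False

    # only these edges and cells change geometry or membership
    local_edges = [j, ja, jb, j_ap1, j_bp2]
    local_cells = [c1, c2, ca, cb]
    U_before = _local_energy(state, local_edges, local_cells, spec, params, coeffs)
    saved_pos = state.pos[[a, b]].copy()
    saved = {c: list(state.loops[c]) for c in (c1, c2, ca, cb)}
    saved_edges = state.edges[[ja, jb]].copy()

    # rotate the edge 90 degrees about its midpoint, length preserved;
    # the new a stays on the c1 side (left of the directed edge a->b)
    pa, pb = state.pos[a].copy(), state.pos[b].copy()
    m = 0.5 * (pa + pb)
    half = 0.5 * (pb - pa)
    left = np.array([-half[1], half[0]])
    norm = math.hypot(left[0], left[1])
    if open_length is not None and norm < 0.5 * open_length:
        if norm > 0:
            left *= 0.5 * open_length / norm
        else:
            left = np.array([0.0, 0.5 * open_length])
    state.pos[a] = m + left
    state.pos[b] = m - left

    # combinatorial flip: c1 keeps a, c2 keeps b, ca gains b before a,
    # cb gains a before b
    state.loops[c1] = [v for v in loop1 if v != b]
    state.loops[c2] = [v for v in loop2 if v != a]
    la = state.loops[ca]
    state.loops[ca] = la[: la.index(a)] + [b] + la[la.index(a):]
    lb = state.loops[cb]
    state.loops[cb] = lb[: lb.index(b)] + [a] + lb[lb.index(b):]
    state.edges[jb] = [a, q1]
    state.edges[ja] = [b, q2]

    if _local_energy(state, local_edges, local_cells, spec, params, coeffs) < U_before:
        if rebuild:
            state.rebuild()
        return True
    # revert (derived arrays were never touched, so no rebuild needed)
    state.pos[[a, b]] = saved_pos
    for c, lp in saved.items():
        state.loops[c] = lp
    state.edges[[ja, jb]] = saved_edges
    return False


def _t1_scan(state: _State, threshold: float, spec: ModelSpec,
             params: ParameterSet, lengths: np.ndarray | None = None,
             coeffs=None) -> int:
    """One ascending-length pass over short junctions; returns flips made."""
    l = lengths if lengths is not None else state.edge_geometry()[0]
    mask = (l < threshold) & state.interior_edge
    if not mask.any():
        return 0
    count = 0
    order = np.argsort(l[np.flatnonzero(mask)])
    candidates = np.flatnonzero(mask)[order]
    for j in candidates:
        if _attempt_t1(state, int(j), spec, params, coeffs=coeffs,
                       open_length=threshold):
            count += 1
    return count


# =====================================================================
# public operations
# =====================================================================

def generate_initial_tile(n_rows: int, n_cols: int, A0: float, seed: int) -> Tissue:
    """Bounded Voronoi tessellation of random centroids with mean area A0.

    n_rows x n_cols centroids are placed uniformly in a rectangle of area
    n_rows * n_cols * A0; the tessellation is bounded by mirror-reflecting
    the centroids across the rectangle's sides and corners, which clips
    every original cell exactly to the rectangle, so the mean area is A0 by
    construction.
    """
    if n_rows < 2 or n_cols < 2:
        raise ConfigurationError("tile counts must be >= 2")
    if A0 <= 0:
        raise DomainError("A0 must be positive")
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    s = math.sqrt(A0)
    W, H = n_cols * s, n_rows * s
    for _ in range(5):
        pts = rng.uniform((0.0, 0.0), (W, H), size=(n, 2))
        if n < 2 or pdist(pts).min() > 1e-9 * s:
            break
    else:
        raise DomainError("could not place distinct centroids")

    mirrors = [
        pts * [-1, 1], pts * [1, -1],
        np.column_stack([2 * W - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * H - pts[:, 1]]),
        pts * [-1, -1],
        np.column_stack([2 * W - pts[:, 0], -pts[:, 1]]),
        np.column_stack([-pts[:, 0], 2 * H - pts[:, 1]]),
        np.column_stack([2 * W - pts[:, 0], 2 * H - pts[:, 1]]),
    ]
    vor = Voronoi(np.vstack([pts] + mirrors))

    used: dict[int, int] = {}
    vertices: list[Vertex] = []
    cells: list[Cell] = []
    edge_set: dict[frozenset[int], int] = {}
    junctions: list[Junction] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise DomainError(f"unbounded Voronoi cell for centroid {i}")
        # qhull gives the region vertices of a 2D cell in boundary order but
        # with arbitrary orientation; cells are convex, so sort by angle
        coords = vor.vertices[region]
        cen = coords.mean(axis=0)
        ang = np.arctan2(coords[:, 1] - cen[1], coords[:, 0] - cen[0])
        ordered = [region[t] for t in np.argsort(ang)]
        loop = []
        for vv in ordered:
            if vv not in used:
                used[vv] = len(vertices)
                vertices.append(
                    Vertex(len(vertices), float(vor.vertices[vv, 0]),
                           float(vor.vertices[vv, 1]))
                )
            loop.append(used[vv])
        cells.append(Cell(i, loop))
        for va, vb in zip(loop, loop[1:] + loop[:1]):
            key = frozenset((va, vb))
            if key not in edge_set:
                edge_set[key] = len(junctions)
                junctions.append(Junction(len(junctions), va, vb))
    return Tissue(vertices, junctions, cells, provenance="simulated")


def virtual_work(tissue: Tissue, spec: ModelSpec, params: ParameterSet) -> float:
    """Evaluate the virtual work U0 of a tissue configuration."""
    return _state_energy(_State(tissue), spec, params)


def forces(tissue: Tissue, spec: ModelSpec, params: ParameterSet) -> dict[int, np.ndarray]:
    """Per-vertex net force vectors (frozen-anisotropy gradient of -U0)."""
    state = _State(tissue)
    f = _state_forces(state, spec, params)
    return {vid: f[i] for i, vid in enumerate(state.vertex_ids)}


def t1_transition(tissue: Tissue, junction_id: int, spec: ModelSpec,
                  params: ParameterSet) -> tuple[Tissue, bool]:
    """Attempt a single T1 flip of the named junction.

    Preconditions (interior junction, degree-3 interior endpoints, four
    distinct surrounding cells) are checked; violations skip the move and
    return the tissue unchanged with ``accepted=False``. An attempted move
    is kept only when it lowers the virtual work.
    """
    state = _State(tissue)
    j = state.junction_ids.index(junction_id)
    accepted = _attempt_t1(state, j, spec, params)
    return (state.to_tissue() if accepted else tissue), accepted


def relax(tissue: Tissue, spec: ModelSpec, params: ParameterSet,
          config: SimConfig) -> SimResult:
    """Forward-Euler gradient descent of U0 with per-step T1 scanning."""
    state = _State(tissue)
    trace: list[float] = []
    t1_count = 0
    thr = config.t1_threshold
    coeffs = _tension_coeffs(spec, params)
    step_base = 0

    def _run_phase(dt: float, t_phase: float) -> int:
        nonlocal step_base
        flips_in_phase = 0
        nsteps = int(round(t_phase / dt))
        for step in range(nsteps):
            geom = state.edge_geometry()
            if thr > 0:
                flips = _t1_scan(state, thr, spec, params, lengths=geom[0],
                                 coeffs=coeffs)
                if flips:
                    flips_in_phase += flips
                    geom = state.edge_geometry()
            f = _state_forces(state, spec, params, geom=geom, coeffs=coeffs)
            state.pos += dt * f
            if step % config.trace_every == 0:
                if not np.all(np.isfinite(state.pos)):
                    raise InstabilityError(step_base + step)
                trace.append(_state_energy(state, spec, params, coeffs))
        step_base += nsteps
        return flips_in_phase

    t1_count += _run_phase(config.dt, config.t_end)
    # the settle tail is repeated until one full pass completes without any
    # T1 event, so the run always ends on a quiet, fully relaxed stretch
    # (each accepted flip strictly lowers U0, so this terminates)
    if config.settle_phases:
        for _ in range(10):
            tail_flips = sum(_run_phase(dt, t) for dt, t in config.settle_phases)
            t1_count += tail_flips
            if tail_flips == 0:
                break
    if not np.all(np.isfinite(state.pos)):
        raise InstabilityError(step_base)
    trace.append(_state_energy(state, spec, params, coeffs))
    f = _state_forces(state, spec, params, coeffs=coeffs)
    return SimResult(
        tissue=state.to_tissue(),
        truth=params,
        spec=spec,
        energy_trace=np.array(trace),
        t1_count=t1_count,
        converged=float(np.abs(f).max()),
        config=config,
    )


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate an initial Voronoi tile and relax it to equilibrium."""
    tissue = generate_initial_tile(config.tile[0], config.tile[1], config.A0,
                                   config.seed)
    return relax(tissue, config.spec, config.params, config)
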