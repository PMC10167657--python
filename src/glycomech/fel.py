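"""Free-energy-landscape analysis: minima, minimax paths, barriers, committors.

A reconstructed landscape lives on a rectangular grid.  Minima are found
by persistence (a minimum counts only if it is deeper than a threshold
relative to the lowest saddle connecting it to a deeper basin), barrier
heights come from the minimax path -- the path whose highest point is as
low as possible, found by a widest-path Dijkstra over grid adjacency.
This replaces the hand-drawn reaction coordinate of typical metadynamics
figures with a deterministic, reproducible construction.

Committor probabilities p_B(x) -- the chance that a trajectory started at
x with Maxwell-Boltzmann velocities reaches the product basin before the
reactant basin -- are estimated by short Langevin shots; p_B ~ 0.5 defines
the transition state.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .metad import (HillSchedule, LangevinParams, MetadynamicsError,
                    run_metadynamics, reconstruct_fel)

__all__ = [
    "FELGrid",
    "StationaryPoint",
    "Path",
    "CommittorSpec",
    "CommittorEstimate",
    "BarrierEstimate",
    "find_minima",
    "minimax_path",
    "barrier_height",
    "committor",
    "locate_ts",
    "replicate_barriers",
]


@dataclass
class FELGrid:
    """Rectangular free-energy grid; values in kcal/mol, min normalized to 0."""

    axes: list[np.ndarray]
    values: np.ndarray
    isoline_interval: float = 1.0

    def __post_init__(self):
        self.axes = [np.asarray(a, float) for a in self.axes]
        self.values = np.asarray(self.values, float)
        if self.values.shape != tuple(len(a) for a in self.axes):
            raise ValueError("grid shape does not match axes")
        for a in self.axes:
            if np.any(np.diff(a) <= 0):
                raise ValueError("axes must be strictly increasing")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def normalize(self) -> "FELGrid":
        self.values = self.values - self.values.min()
        return self

    def nearest_index(self, point) -> tuple[int, ...]:
        point = np.atleast_1d(np.asarray(point, float))
        return tuple(int(np.argmin(np.abs(a - p))) for a, p in zip(self.axes, point))

    def coords(self, idx: tuple[int, ...]) -> np.ndarray:
        return np.array([a[i] for a, i in zip(self.axes, idx)])

    def to_frame(self):
        """Long-format DataFrame (one row per grid point) for CSV export."""
        import pandas as pd
        mesh = np.meshgrid(*self.axes, indexing="ij")
        data = {f"cv{i+1}": m.ravel() for i, m in enumerate(mesh)}
        data["free_energy"] = self.values.ravel()
        return pd.DataFrame(data)


@dataclass(frozen=True)
class StationaryPoint:
    position: np.ndarray
    kind: str                 # "minimum" | "saddle"
    value: float
    basin_label: str = ""


@dataclass(frozen=True)
class Path:
    indices: list[tuple[int, ...]]
    points: np.ndarray
    values: np.ndarray
    max_value: float
    arc_length: float


@dataclass(frozen=True)
class CommittorSpec:
    in_reactant: Callable[[np.ndarray], bool]
    in_product: Callable[[np.ndarray], bool]
    n_trials: int
    max_steps: int
    dynamics: LangevinParams
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class CommittorEstimate:
    pB: float
    successes: int
    trials: int               # resolved trials
    unresolved: int
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class BarrierEstimate:
    barriers: tuple[float, ...]
    mean: float
    sd: float
    n: int


# ---------------------------------------------------------------------------
# minima by persistence
# ---------------------------------------------------------------------------

def _neighbors(idx, shape):
    """Full (Moore) neighborhood: 8 neighbors in 2-D, 2 in 1-D."""
    deltas = np.array(np.meshgrid(*[[-1, 0, 1]] * len(shape), indexing="ij"))
    deltas = deltas.reshape(len(shape), -1).T
    for d in deltas:
        if not np.any(d):
            continue
        nb = tuple(int(i + o) for i, o in zip(idx, d))
        if all(0 <= n < s for n, s in zip(nb, shape)):
            yield nb


def find_minima(grid: FELGrid, depth_threshold: float = 0.5) -> list[StationaryPoint]:
    """Local minima deeper than ``depth_threshold`` below their escape saddle.

    Cells are flooded in order of increasing value (a watershed); when a
    growing basin first touches a deeper basin, the contact level is its
    escape saddle and the difference saddle - minimum its persistence.
    Only minima whose persistence exceeds the threshold are reported,
    sorted by value.  The global minimum always persists.
    """
    v = grid.values
    if v.size == 0:
        raise ValueError("empty grid")
    shape = v.shape
    order = np.unravel_index(np.argsort(v, axis=None, kind="stable"), shape)
    order = list(zip(*(o.tolist() for o in order)))

    parent: dict[tuple, tuple] = {}
    basin_min: dict[tuple, float] = {}
    persistence: dict[tuple, float] = {}

    def find(c):
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:
            parent[c], c = root, parent[c]
        return root

    for cell in order:
        lower = [find(nb) for nb in _neighbors(cell, shape) if nb in parent]
        lower = list(dict.fromkeys(lower))
        if not lower:
            parent[cell] = cell
            basin_min[cell] = float(v[cell])
            continue
        # attach to the deepest neighboring basin; merging basins die here
        lower.sort(key=lambda r: basin_min[r])
        survivor = lower[0]
        parent[cell] = survivor
        for r in lower[1:]:
            if r not in persistence:
                persistence[r] = float(v[cell]) - basin_min[r]
            parent[r] = survivor

    minima = []
    vmax = float(v.max())
    for root, vmin in basin_min.items():
        # the unmerged (global) basin persists up to the grid maximum
        pers = persistence.get(root, vmax - vmin)
        if pers > depth_threshold:
            minima.append(StationaryPoint(
                position=grid.coords(root), kind="minimum", value=vmin))
    minima.sort(key=lambda m: m.value)
    return minima


# ---------------------------------------------------------------------------
# minimax (widest) path
# ---------------------------------------------------------------------------

def minimax_path(grid: FELGrid, a, b) -> Path:
    """Path from a to b minimizing the maximum free energy along it.

    Widest-path Dijkstra over the grid's Moore adjacency; deterministic
    (ties broken by cell order).  ``a`` and ``b`` are CV-space points,
    snapped to the nearest grid cell.
    """
    v = grid.values
    start = grid.nearest_index(a)
    goal = grid.nearest_index(b)
    shape = v.shape
    best = {start: float(v[start])}
    prev: dict[tuple, tuple] = {}
    heap = [(float(v[start]), start)]
    visited = set()
    while heap:
        cost, cell = heapq.heappop(heap)
        if cell in visited:
            continue
        visited.add(cell)
        if cell == goal:
            break
        for nb in _neighbors(cell, shape):
            if nb in visited:
                continue
            ncost = max(cost, float(v[nb]))
            if ncost < best.get(nb, math.inf):
                best[nb] = ncost
                prev[nb] = cell
                heapq.heappush(heap, (ncost, nb))
    if goal not in visited:
        raise ValueError("endpoints are not connected on the grid")
    idxs = [goal]
    while idxs[-1] != start:
        idxs.append(prev[idxs[-1]])
    idxs.reverse()
    pts = np.array([grid.coords(i) for i in idxs])
    vals = np.array([v[i] for i in idxs])
    arc = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))) if len(pts) > 1 else 0.0
    return Path(indices=idxs, points=pts, values=vals,
                max_value=float(vals.max()), arc_length=arc)


def _descend(grid: FELGrid, idx: tuple[int, ...]) -> tuple[int, ...]:
    """Steepest-descent walk from a cell to its local grid minimum."""
    v = grid.values
    while True:
        nbs = list(_neighbors(idx, v.shape))
        best = min(nbs, key=lambda n: v[n])
        if v[best] >= v[idx]:
            return idx
        idx = best


def barrier_height(grid: FELGrid, basin_a, basin_b) -> float:
    """Free-energy barrier from basin A to basin B: the minimax-path maximum
    minus the value at the basin-A minimum (the supplied point is first
    relaxed to its local grid minimum).  Invariant to adding a constant."""
    a_min = _descend(grid, grid.nearest_index(basin_a))
    path = minimax_path(grid, grid.coords(a_min), basin_b)
    return float(path.max_value - grid.values[a_min])


# ---------------------------------------------------------------------------
# committor analysis
# ---------------------------------------------------------------------------

def _langevin_shot(surface, x0, dyn: LangevinParams, rng: np.random.Generator,
                   in_reactant, in_product, max_steps: int) -> int:
    """One committor trial; returns +1 (product), -1 (reactant), 0 (unresolved)."""
    x = np.atleast_1d(np.asarray(x0, float)).copy()
    dim = x.shape[0]
    masses = np.broadcast_to(np.asarray(dyn.masses, float), (dim,)).copy()
    v = rng.normal(0.0, np.sqrt(dyn.kT / masses), size=dim)
    dt = dyn.timestep
    c1 = math.exp(-dyn.friction * dt)
    c2 = np.sqrt(dyn.kT * (1.0 - c1 * c1) / masses)
    _, g = surface(x)
    f = -np.asarray(g, float)
    for _ in range(max_steps):
        v += 0.5 * dt * f / masses
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=dim)
        x += 0.5 * dt * v
        _, g = surface(x)
        f = -np.asarray(g, float)
        v += 0.5 * dt * f / masses
        if in_product(x):
            return 1
        if in_reactant(x):
            return -1
    return 0


def _wilson_ci(successes: int, n: int, z: float = 1.959963984540054):
    """Wilson 95% binomial interval (well-behaved at p near 0/1)."""
    if n == 0:
        return 0.0, 1.0
    p = successes / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def committor(surface, point, spec: CommittorSpec) -> CommittorEstimate:
    """Estimate p_B at a configuration by repeated Langevin shots.

    Each trial draws fresh Maxwell-Boltzmann velocities from a sub-seed
    derived from ``spec.seed`` via numpy's seed-sequence spawning.  Trials
    that resolve into neither basin within ``max_steps`` are excluded from
    p_B and reported separately.
    """
    x0 = np.atleast_1d(np.asarray(point, float))
    if spec.in_reactant(x0) or spec.in_product(x0):
        raise ValueError("committor point must lie outside both basins")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_trials)
    succ = fail = unresolved = 0
    for child in children:
        rng = np.random.default_rng(child)
        out = _langevin_shot(surface, x0, spec.dynamics, rng,
                             spec.in_reactant, spec.in_product, spec.max_steps)
        if out == 1:
            succ += 1
        elif out == -1:
            fail += 1
        else:
            unresolved += 1
    resolved = succ + fail
    if resolved == 0:
        raise MetadynamicsError(
            "all committor trials unresolved; increase max_steps")
    pB = succ / resolved
    lo, hi = _wilson_ci(succ, resolved)
    return CommittorEstimate(pB=pB, successes=succ, trials=resolved,
                             unresolved=unresolved, ci_low=lo, ci_high=hi)


def locate_ts(surface, candidates: Sequence, spec: CommittorSpec,
              window: tuple[float, float] = (0.4, 0.6)):
    """Pick the candidate whose committor is nearest 0.5.

    Mirrors the isocommittor refinement protocol: several configurations
    near the putative saddle are shot repeatedly; the transition state is
    the one with p_B closest to 50%, accepted only inside the tolerance
    window (default 0.4-0.6, i.e. at worst 60:40).  Outside the window the
    best candidate is still returned, flagged rejected.
    """
    if not candidates:
        raise ValueError("need at least one TS candidate")
    results = []
    for i, cand in enumerate(candidates):
        sub = CommittorSpec(in_reactant=spec.in_reactant,
                            in_product=spec.in_product,
                            n_trials=spec.n_trials, max_steps=spec.max_steps,
                            dynamics=spec.dynamics,
                            seed=int(np.random.SeedSequence([spec.seed, i])
                                     .generate_state(1)[0] % (2**31)))
        results.append((cand, committor(surface, cand, sub)))
    best, est = min(results, key=lambda r: abs(r[1].pB - 0.5))
    accepted = window[0] <= est.pB <= window[1]
    return np.atleast_1d(np.asarray(best, float)), est, accepted


def replicate_barriers(
    surface,
    cvs,
    schedule: HillSchedule,
    dyn_template: LangevinParams,
    n_steps: int,
    x0,
    basin_a,
    basin_b,
    seeds: Sequence[int],
    grid_axes,
    walls=None,
    time_average_from: float | None = 0.4,
) -> BarrierEstimate:
    """Independent metadynamics replicates -> FEL -> barrier, mean +/- sd.

    Mirrors the replicate-averaging protocol (several runs started from the
    reactant well, barrier averaged).  Any replicate failure aborts with an
    error naming the seed.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two replicate seeds")
    barriers = []
    failed = []
    for seed in seeds:
        dyn = LangevinParams(temperature=dyn_template.temperature,
                             friction=dyn_template.friction,
                             timestep=dyn_template.timestep,
                             masses=dyn_template.masses, seed=int(seed))
        try:
            res = run_metadynamics(surface, cvs, schedule, dyn, n_steps,
                                   x0=x0, walls=walls)
            grid = reconstruct_fel(res.hills, grid_axes,
                                   time_average_from=time_average_from)
            barriers.append(barrier_height(grid, basin_a, basin_b))
        except MetadynamicsError as exc:
            failed.append((seed, str(exc)))
    if failed:
        raise MetadynamicsError(
            f"replicates failed for seeds {[s for s, _ in failed]}: "
            f"{failed[0][1]}; partial barriers: {barriers}")
    arr = np.array(barriers)
    return BarrierEstimate(barriers=tuple(arr.tolist()), mean=float(arr.mean()),
                           sd=float(arr.std(ddof=1)), n=len(arr))
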