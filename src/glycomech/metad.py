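"""A self-contained metadynamics engine on analytic energy surfaces.

Standard (non-well-tempered) metadynamics: repulsive Gaussians of
scheduled height are deposited along collective variables every ``pace``
integration steps while the walker evolves under underdamped Langevin
dynamics (BAOAB splitting).  The negated accumulated bias estimates the
free-energy landscape.  Units are kcal/mol for energies, Angstrom (or the
CV's own dimensionless unit) for coordinates, and a model time unit for
the timestep -- no conversion happens inside the engine.

The deposition schedule mirrors the common practice of starting with
larger hills and ending with smaller ones; both the interpolation law and
the start/end heights are configuration, since protocols differ.
Hills are deposited at the pre-step CV value (the value the walker had
when the deposition step began).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CVFunction",
    "IdentityCV",
    "DistanceDifferenceCV",
    "GaussianHill",
    "HillSchedule",
    "LangevinParams",
    "MetaDynResult",
    "MetadynamicsError",
    "evaluate_bias",
    "height_at",
    "run_metadynamics",
    "reconstruct_fel",
    "hills_to_arrays",
]

# gas constant in kcal / (mol K), CODATA 2018
R_KCAL = 1.98720425864083e-3


class MetadynamicsError(RuntimeError):
    pass


@dataclass(frozen=True)
class CVFunction:
    """A collective variable: scalar function of the configuration + gradient."""

    evaluate: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    kind: str = "custom"


def IdentityCV(index: int, dim: int) -> CVFunction:
    """CV that reads one coordinate of the configuration directly."""
    g = np.zeros(dim)
    g[index] = 1.0

    return CVFunction(
        evaluate=lambda x, i=index: float(x[i]),
        gradient=lambda x, gv=g: gv.copy(),
        kind="identity-axis",
    )


def DistanceDifferenceCV(i: int, j: int, k: int, l: int) -> CVFunction:
    """CV = d(atom_i, atom_j) - d(atom_k, atom_l) on a flat (n*3,) configuration.

    This is the distance-difference form used to follow bond exchange:
    one pair is the bond being formed, the other the bond being broken,
    so the CV is positive before the exchange and negative after.
    Swapping the two pairs negates the value (antisymmetry).
    """

    def _pairs(x: np.ndarray):
        pts = x.reshape(-1, 3)
        return pts, pts[i] - pts[j], pts[k] - pts[l]

    def ev(x: np.ndarray) -> float:
        _, dij, dkl = _pairs(x)
        return float(np.linalg.norm(dij) - np.linalg.norm(dkl))

    def grad(x: np.ndarray) -> np.ndarray:
        pts, dij, dkl = _pairs(x)
        g = np.zeros_like(pts)
        uij = dij / np.linalg.norm(dij)
        ukl = dkl / np.linalg.norm(dkl)
        g[i] += uij
        g[j] -= uij
        g[k] -= ukl
        g[l] += ukl
        return g.reshape(-1)

    return CVFunction(evaluate=ev, gradient=grad, kind="distance-difference")


@dataclass(frozen=True)
class GaussianHill:
    center: np.ndarray    # CV-space vector
    widths: np.ndarray    # per-CV sigma, > 0
    height: float         # kcal/mol, >= 0
    step: int             # MD step index at deposition

    def __post_init__(self):
        object.__setattr__(self, "center", np.atleast_1d(np.asarray(self.center, float)))
        object.__setattr__(self, "widths", np.atleast_1d(np.asarray(self.widths, float)))
        if np.any(self.widths <= 0):
            raise MetadynamicsError("hill widths must be positive")
        if self.height < 0:
            raise MetadynamicsError("hill height must be nonnegative")


@dataclass(frozen=True)
class HillSchedule:
    pace: int                       # MD steps between depositions
    height_start: float             # kcal/mol
    height_end: float
    widths: tuple[float, ...]       # per-CV sigma
    interpolation: str = "linear-in-index"   # or "step-at-fraction"
    step_fraction: float = 0.5      # only for step-at-fraction

    def __post_init__(self):
        if self.pace < 1:
            raise MetadynamicsError("pace must be >= 1")
        if self.height_start < 0 or self.height_end < 0:
            raise MetadynamicsError("hill heights must be nonnegative")
        if self.interpolation not in ("linear-in-index", "step-at-fraction"):
            raise MetadynamicsError(f"unknown interpolation {self.interpolation!r}")


@dataclass(frozen=True)
class LangevinParams:
    temperature: float              # K
    friction: float = 1.0           # 1 / model time
    timestep: float = 0.005         # model time
    masses: float | Sequence[float] = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0 or self.timestep <= 0:
            raise MetadynamicsError("temperature and timestep must be positive")

    @property
    def kT(self) -> float:
        return R_KCAL * self.temperature


@dataclass
class MetaDynResult:
    hills: list[GaussianHill]
    cv_trajectory: np.ndarray       # (n_steps, n_cv)
    positions: np.ndarray           # configuration snapshots at stride
    snapshot_stride: int
    seed: int
    n_steps: int
    metadata: dict = field(default_factory=dict)


def height_at(deposition_index: int, n_depositions: int, schedule: HillSchedule) -> float:
    """Hill height for the given deposition, per the schedule's interpolation.

    linear-in-index interpolates from height_start at the first deposition
    to height_end at the last; step-at-fraction switches abruptly once the
    given fraction of depositions has been laid down.
    """
    if deposition_index < 0:
        raise MetadynamicsError("deposition index must be >= 0")
    if n_depositions <= 1:
        return schedule.height_start
    f = deposition_index / (n_depositions - 1)
    if schedule.interpolation == "linear-in-index":
        return schedule.height_start + f * (schedule.height_end - schedule.height_start)
    return schedule.height_start if f < schedule.step_fraction else schedule.height_end


def hills_to_arrays(hills: Sequence[GaussianHill]):
    """(centers, widths, heights) stacked arrays for vectorized evaluation."""
    centers = np.array([h.center for h in hills])
    widths = np.array([h.widths for h in hills])
    heights = np.array([h.height for h in hills])
    return centers, widths, heights


def evaluate_bias(hills: Sequence[GaussianHill], point) -> tuple[float, np.ndarray]:
    """Accumulated bias V(s) = sum_i h_i exp(-sum_d (s_d - c_id)^2 / 2 sigma_d^2)
    and its analytic gradient with respect to s."""
    point = np.atleast_1d(np.asarray(point, float))
    if not hills:
        return 0.0, np.zeros_like(point)
    centers, widths, heights = hills_to_arrays(hills)
    if centers.shape[1] != point.shape[0]:
        raise MetadynamicsError(
            f"dimension mismatch: hills are {centers.shape[1]}-D, point is "
            f"{point.shape[0]}-D")
    return _bias_from_arrays(centers, widths, heights, point)


def _bias_from_arrays(centers, widths, heights, point):
    diff = point[None, :] - centers
    expo = np.exp(-0.5 * np.sum((diff / widths) ** 2, axis=1))
    v = float(np.dot(heights, expo))
    grad = np.sum((heights * expo)[:, None] * (-diff / widths**2), axis=0)
    return v, grad


def run_metadynamics(
    surface: Callable[[np.ndarray], tuple[float, np.ndarray]],
    cvs: Sequence[CVFunction],
    schedule: HillSchedule,
    dyn: LangevinParams,
    n_steps: int,
    x0: np.ndarray,
    walls: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]] | None = None,
    snapshot_stride: int = 100,
    domain_guard: float = 1e3,
) -> MetaDynResult:
    """Biased Langevin dynamics with scheduled Gaussian deposition.

    ``surface(x) -> (energy, gradient)`` supplies the unbiased potential in
    configuration space.  Hills are deposited every ``schedule.pace`` steps
    at the CV value the walker holds when the deposition step begins.
    ``walls`` may reflect the position/velocity back into a physical domain
    (e.g. the unit disk for normalized puckering CVs).  Identical seeds and
    configurations give bitwise-identical results.
    """
    if n_steps < schedule.pace:
        raise MetadynamicsError("n_steps must be at least one deposition pace")
    x = np.atleast_1d(np.asarray(x0, float)).copy()
    dim = x.shape[0]
    masses = np.broadcast_to(np.asarray(dyn.masses, float), (dim,)).copy()
    rng = np.random.default_rng(dyn.seed)
    v = rng.normal(0.0, np.sqrt(dyn.kT / masses), size=dim)

    dt = dyn.timestep
    c1 = math.exp(-dyn.friction * dt)
    c2 = np.sqrt(dyn.kT * (1.0 - c1 * c1) / masses)

    n_dep = n_steps // schedule.pace
    widths = np.asarray(schedule.widths, float)
    if widths.shape[0] != len(cvs):
        raise MetadynamicsError("one width per CV is required")

    hills: list[GaussianHill] = []
    centers = np.empty((n_dep, len(cvs)))
    warr = np.empty((n_dep, len(cvs)))
    harr = np.empty(n_dep)
    n_hills = 0
    cv_traj = np.empty((n_steps, len(cvs)))
    snaps = []

    def total_force(xv: np.ndarray) -> np.ndarray:
        e, g = surface(xv)
        f = -np.asarray(g, float)
        if n_hills:
            s = np.array([cv.evaluate(xv) for cv in cvs])
            _, gb = _bias_from_arrays(centers[:n_hills], warr[:n_hills],
                                      harr[:n_hills], s)
            for d, cv in enumerate(cvs):
                f -= gb[d] * cv.gradient(xv)
        return f

    f = total_force(x)
    for step in range(n_steps):
        s_pre = np.array([cv.evaluate(x) for cv in cvs])
        cv_traj[step] = s_pre
        if step % schedule.pace == 0:
            h = height_at(n_hills, n_dep, schedule)
            hills.append(GaussianHill(center=s_pre.copy(), widths=widths.copy(),
                                      height=h, step=step))
            centers[n_hills] = s_pre
            warr[n_hills] = widths
            harr[n_hills] = h
            n_hills += 1
            f = total_force(x)   # bias changed under our feet
        # BAOAB
        v += 0.5 * dt * f / masses
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=dim)
        x += 0.5 * dt * v
        if walls is not None:
            x, v = walls(x, v)
        f = total_force(x)
        v += 0.5 * dt * f / masses
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > domain_guard):
            raise MetadynamicsError(f"dynamics diverged at step {step}")
        if step % snapshot_stride == 0:
            snaps.append(x.copy())

    return MetaDynResult(
        hills=hills,
        cv_trajectory=cv_traj,
        positions=np.array(snaps),
        snapshot_stride=snapshot_stride,
        seed=dyn.seed,
        n_steps=n_steps,
        metadata={
            "pace": schedule.pace,
            "height_start": schedule.height_start,
            "height_end": schedule.height_end,
            "widths": tuple(widths.tolist()),
            "temperature": dyn.temperature,
            "friction": dyn.friction,
            "timestep": dyn.timestep,
        },
    )


def reconstruct_fel(hills: Sequence[GaussianHill], axes: Sequence[np.ndarray],
                    time_average_from: float | None = None):
    """Free-energy estimate F(s) = -V_bias(s) on a rectangular grid,
    shifted so the global minimum is zero.

    With ``time_average_from`` (a fraction of the run, e.g. 0.4), the
    estimate is the time average of -V_bias over the last part of the run
    instead of the final bias.  The instantaneous bias of standard
    metadynamics oscillates around -F with an amplitude of a few hill
    heights; its time average converges much more tightly, so barrier
    estimates should use the averaged form.  Because the bias is a sum of
    hills, the average is itself a hill sum with each hill's height scaled
    by the fraction of the averaging window it existed in.

    Returns a :class:`glycomech.fel.FELGrid`.
    """
    from .fel import FELGrid

    if not hills:
        raise MetadynamicsError("cannot reconstruct a FEL from zero hills")
    axes = [np.asarray(a, float) for a in axes]
    centers, widths, heights = hills_to_arrays(hills)
    if centers.shape[1] != len(axes):
        raise MetadynamicsError("grid dimensionality must match hill dimensionality")
    if time_average_from is not None:
        if not 0.0 <= time_average_from < 1.0:
            raise MetadynamicsError("time_average_from must be in [0, 1)")
        steps = np.array([h.step for h in hills], float)
        pace = np.diff(steps).min() if len(steps) > 1 else 1.0
        t_end = steps[-1] + pace
        t0 = time_average_from * t_end
        heights = heights * np.clip((t_end - np.maximum(steps, t0))
                                    / (t_end - t0), 0.0, 1.0)
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)       # (npts, d)
    # vectorized over grid points and hills
    diff = pts[:, None, :] - centers[None, :, :]
    expo = np.exp(-0.5 * np.sum((diff / widths[None, :, :]) ** 2, axis=2))
    bias = expo @ heights
    values = (-bias).reshape([len(a) for a in axes])
    values -= values.min()
    return FELGrid(axes=axes, values=values)


def reflective_disk_walls(radius: float = 1.0, center=(0.0, 0.0)):
    """Reflective wall keeping a 2-D walker inside a disk (the physical
    domain of the normalized puckering coordinates u = qx/Q, v = qy/Q)."""
    c = np.asarray(center, float)

    def walls(x: np.ndarray, v: np.ndarray):
        r = x - c
        d = np.linalg.norm(r)
        if d > radius:
            u = r / d
            x = c + u * (2 * radius - d)      # mirror back inside
            v = v - 2 * np.dot(v, u) * u      # reflect the velocity
        return x, v

    return walls
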