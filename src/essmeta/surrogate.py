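"""Synthetic hinged-domain generator with planted free-energy ground truth.

The surrogate emulates a 171-residue Cα-level domain: a rigid globular core
(residues 1–30 and 63–171) laid out on a Fibonacci sphere spiral, and a
hairpin arm (residues 31–62) that rotates rigidly about a hinge axis
through the south pole of the core.  The hinge angle θ diffuses on a
planted double-well potential, so the free energy along θ — and, by change
of variables, along any monotone descriptor of θ — is known exactly.

Construction guarantees that the three-group hairpin-angle descriptor of a
jitter-free frame equals θ: the hinge-group beads (residues 31–35) lie on
the rotation axis with the 32–35 center of mass exactly at the hinge
point, the remaining arm beads are collinear along the rotated arm
direction, and that direction makes angle θ with the hinge→globular-group
vector by definition.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.optimize import brentq, root

from .constants import KB
from .dynamics import run_langevin
from .io import Structure, Trajectory

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


# ---------------------------------------------------------------------------
# Hinge double-well
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HingePotential:
    """Quartic double well in the hinge angle θ (radians, energies kJ/mol).

    U'(θ) = a (θ−θ_closed)(θ−θ_barrier)(θ−θ_open); the offset is fixed by
    U(θ_closed) = 0, so the barrier top sits at ``depth_closed`` and the
    open minimum at ``depth_closed − depth_open``.
    """

    theta_closed: float
    theta_barrier: float
    theta_open: float
    scale: float

    @staticmethod
    def _antiderivative(theta, c, b, o):
        s1 = c + b + o
        s2 = c * b + c * o + b * o
        s3 = c * b * o
        return (theta ** 4 / 4.0 - s1 * theta ** 3 / 3.0
                + s2 * theta ** 2 / 2.0 - s3 * theta)

    @classmethod
    def fit(cls, theta_closed: float, theta_open: float,
            depth_closed: float, depth_open: float) -> "HingePotential":
        """Plant a quartic with the given minima and well depths.

        Depths are measured from the barrier top; the barrier location is
        solved from the depth ratio (a quartic with stationary points at
        both minima and the barrier has exactly one free barrier position
        for a given ratio).
        """
        if not theta_closed < theta_open:
            raise ValueError("theta_closed must be < theta_open")
        if depth_closed <= 0 or depth_open <= 0:
            raise ValueError("well depths must be positive")

        c, o = theta_closed, theta_open

        def ratio(b):
            pc = cls._antiderivative(c, c, b, o)
            pb = cls._antiderivative(b, c, b, o)
            po = cls._antiderivative(o, c, b, o)
            return (pb - pc) / (pb - po)

        target = depth_closed / depth_open
        eps = 1e-4 * (o - c)  # wide enough to avoid cancellation noise
        b = brentq(lambda x: ratio(x) - target, c + eps, o - eps, xtol=1e-12)
        pc = cls._antiderivative(c, c, b, o)
        pb = cls._antiderivative(b, c, b, o)
        a = depth_closed / (pb - pc)
        return cls(theta_closed=c, theta_barrier=b, theta_open=o, scale=a)

    def energy(self, theta):
        """U(θ) in kJ/mol with U(theta_closed) = 0."""
        theta = np.asarray(theta, dtype=float)
        p = self._antiderivative(theta, self.theta_closed, self.theta_barrier,
                                 self.theta_open)
        p0 = self._antiderivative(self.theta_closed, self.theta_closed,
                                  self.theta_barrier, self.theta_open)
        return self.scale * (p - p0)

    def grad(self, theta):
        """dU/dθ in kJ/mol/rad."""
        c, b, o = self.theta_closed, self.theta_barrier, self.theta_open
        return self.scale * (theta - c) * (theta - b) * (theta - o)

    def grad_scalar(self, theta: float) -> float:
        c, b, o = self.theta_closed, self.theta_barrier, self.theta_open
        return self.scale * (theta - c) * (theta - b) * (theta - o)

    @property
    def barrier(self) -> float:
        return float(self.energy(self.theta_barrier))

    @property
    def depth_closed(self) -> float:
        return float(self.energy(self.theta_barrier) - self.energy(self.theta_closed))

    @property
    def depth_open(self) -> float:
        return float(self.energy(self.theta_barrier) - self.energy(self.theta_open))


# ---------------------------------------------------------------------------
# Surrogate specification and geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateSpec:
    """Full parameterization of the synthetic hinged domain.

    Angles in the spec are user-facing degrees; lengths nm, times ps,
    energies kJ/mol.  ``friction`` is the angular drag coefficient of the
    overdamped hinge dynamics in kJ/mol·ps/rad².
    """

    n_residues: int = 171
    arm_start: int = 31
    arm_end: int = 62
    theta_closed_deg: float = 63.0
    theta_open_deg: float = 100.0
    depth_closed: float = 36.0
    depth_open: float = 4.0
    core_radius: float = 1.35
    arm_length: float = 2.9        # hinge → hairpin-tip cluster center, nm
    arm_spread: float = 0.4        # half-extent of the tip cluster along the arm
    hinge_stalk: float = 0.3       # hinge point offset beyond the core surface
    strut_radius: float = 1.2      # radius of the arm beads packing on the core
    strut_phi_deg: float = -9.0    # their phase offset in the rotation plane
    hinge_spacing: float = 0.12
    core_azimuth: float = 0.0
    jitter_sigma: float = 0.05
    temperature: float = 310.0
    friction: float = 100.0
    dt: float = 0.01
    bead_mass: float = 110.0
    seed: int = 0

    def __post_init__(self):
        if not self.theta_closed_deg < self.theta_open_deg:
            raise ValueError("theta_closed must be < theta_open")
        if self.depth_closed <= 0 or self.depth_open <= 0:
            raise ValueError("well depths must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def theta_closed(self) -> float:
        return math.radians(self.theta_closed_deg)

    @property
    def theta_open(self) -> float:
        return math.radians(self.theta_open_deg)


# Hairpin-group residue numbering shared with the descriptor module.
GLOBULAR_RESIDUES = (111, 112, 113, 122, 123, 124, 125, 162, 163, 164, 165)
HINGE_RESIDUES = (32, 33, 34, 35)
LOOP_RESIDUES = (45, 46, 47, 48, 58, 59, 60, 61)


class HingedDomain:
    """Concrete geometry + potential + dynamics for a :class:`SurrogateSpec`."""

    def __init__(self, spec: SurrogateSpec):
        self.spec = spec
        self.potential = HingePotential.fit(
            spec.theta_closed, spec.theta_open, spec.depth_closed, spec.depth_open)
        self._build_geometry()

    # -- geometry ----------------------------------------------------------

    def _build_geometry(self) -> None:
        spec = self.spec
        n = spec.n_residues
        arm = set(range(spec.arm_start, spec.arm_end + 1))
        core_resids = [r for r in range(1, n + 1) if r not in arm]
        n_core = len(core_resids)
        R = spec.core_radius

        k = np.arange(n_core)
        z = R * (1.0 - 2.0 * (k + 0.5) / n_core)
        rxy = np.sqrt(np.maximum(R * R - z * z, 0.0))
        phi = k * GOLDEN_ANGLE + spec.core_azimuth
        core_xyz = np.column_stack([rxy * np.cos(phi), rxy * np.sin(phi), z])

        self.hinge_point = np.array([0.0, 0.0, -(R + spec.hinge_stalk)])

        # direction from hinge toward the globular-subdomain group COM
        core_map = {r: i for i, r in enumerate(core_resids)}
        g0 = core_xyz[[core_map[r] for r in GLOBULAR_RESIDUES]].mean(axis=0)
        u = g0 - self.hinge_point
        u /= np.linalg.norm(u)
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, u)) > 0.99:
            trial = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, trial)
        axis /= np.linalg.norm(axis)
        self.hinge_axis = axis
        self.u = u
        self.e = np.cross(axis, u)  # unit, completes the rotation plane

        # hinge-group beads on the axis; 32–35 offsets average to zero so the
        # hinge-group COM is exactly the hinge point
        d = spec.hinge_spacing
        hinge_t = {spec.arm_start: -2.5 * d}
        for j, r in enumerate(range(spec.arm_start + 1, spec.arm_start + 5)):
            hinge_t[r] = (j - 1.5) * d

        # remaining arm beads rotate rigidly in the plane spanned by (u, e):
        # bead position = hinge + ρ·(cos(θ+φ)·u + sin(θ+φ)·e).
        # The hairpin out-and-back tip cluster is collinear along the arm
        # direction (φ = 0), so the loop-group COM lies exactly on it; the
        # strut beads just after the hinge carry a phase offset so the
        # closed arm packs against the core surface.
        L, spread = spec.arm_length, spec.arm_spread
        phi_s = math.radians(spec.strut_phi_deg)
        rod: dict[int, tuple[float, float]] = {}  # resid -> (rho, phi)
        strut_resids = range(spec.arm_start + 5, spec.arm_start + 8)
        for j, r in enumerate(strut_resids):
            rod[r] = (spec.strut_radius * (1.0 - 0.12 * j), phi_s)
        out_resids = [r for r in range(spec.arm_start + 8, spec.arm_start + 18)]
        for j, r in enumerate(out_resids):
            rod[r] = (L - spread + 2.0 * spread * j / (len(out_resids) - 1), 0.0)
        back_resids = [r for r in range(spec.arm_start + 18, spec.arm_end + 1)]
        for j, r in enumerate(back_resids):
            rod[r] = (L + spread - 2.0 * spread * (j + 1) / len(back_resids), 0.0)

        self.core_resids = np.array(core_resids)
        self.core_xyz = core_xyz
        self.hinge_resids = np.array(sorted(hinge_t))
        self.hinge_t = np.array([hinge_t[r] for r in sorted(hinge_t)])
        self.rod_resids = np.array(sorted(rod))
        self.rod_rho = np.array([rod[r][0] for r in sorted(rod)])
        self.rod_phi = np.array([rod[r][1] for r in sorted(rod)])

        order = np.argsort(np.concatenate(
            [self.core_resids, self.hinge_resids, self.rod_resids]))
        self._order = order
        self._resids_sorted = np.concatenate(
            [self.core_resids, self.hinge_resids, self.rod_resids])[order]

    @property
    def n_atoms(self) -> int:
        return self.spec.n_residues

    def topology(self) -> Structure:
        """Cα-only topology at the closed-state geometry (no jitter)."""
        return Structure.from_arrays(
            self.frame(self.spec.theta_closed),
            self._resids_sorted,
            "ALA", "CA", self.spec.bead_mass)

    def frames(self, thetas, rng: np.random.Generator | None = None) -> np.ndarray:
        """(n, N, 3) frames for an array of hinge angles (radians).

        With an ``rng``, isotropic Gaussian jitter of scale ``jitter_sigma``
        is added independently to every bead.
        """
        thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
        n = thetas.shape[0]
        coords = np.empty((n, self.n_atoms, 3))
        ang = thetas[:, None] + self.rod_phi[None, :]          # (n, n_rod)
        rod = (self.hinge_point[None, None, :]
               + self.rod_rho[None, :, None]
               * (np.cos(ang)[:, :, None] * self.u[None, None, :]
                  + np.sin(ang)[:, :, None] * self.e[None, None, :]))
        blocks = np.concatenate([
            np.broadcast_to(self.core_xyz, (n,) + self.core_xyz.shape),
            np.broadcast_to(self.hinge_point + self.hinge_t[:, None] * self.hinge_axis,
                            (n, len(self.hinge_t), 3)),
            rod,
        ], axis=1)
        coords[:] = blocks[:, self._order, :]
        if rng is not None and self.spec.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, self.spec.jitter_sigma, coords.shape)
        return coords

    def frame(self, theta: float, rng: np.random.Generator | None = None) -> np.ndarray:
        return self.frames([theta], rng)[0]

    def radius_of_gyration(self, theta: float) -> float:
        """Mass-weighted RG of the jitter-free frame at θ (uniform beads)."""
        xyz = self.frame(theta)
        com = xyz.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((xyz - com) ** 2, axis=1))))

    # -- dynamics ----------------------------------------------------------

    def simulate(self, n_steps: int, stride: int, seed: int,
                 theta0: float | None = None) -> "UnbiasedRun":
        """Unbiased overdamped Langevin run; frames emitted every ``stride``."""
        spec = self.spec
        master = np.random.SeedSequence(seed)
        rng_theta, rng_jitter = [np.random.default_rng(s) for s in master.spawn(2)]
        if theta0 is None:
            theta0 = spec.theta_open
        thetas = run_langevin(
            self.potential.grad_scalar, theta0, n_steps, spec.dt,
            spec.friction, spec.temperature, rng_theta)
        idx = np.arange(stride - 1, n_steps, stride)
        times = (idx + 1) * spec.dt
        frames = self.frames(thetas[idx], rng_jitter)
        traj = Trajectory(self.topology(), frames, times)
        return UnbiasedRun(spec=spec, theta_full=thetas, times=times,
                           thetas=thetas[idx], trajectory=traj)


@dataclass
class UnbiasedRun:
    """Result of an unbiased surrogate simulation."""

    spec: SurrogateSpec
    theta_full: np.ndarray   # θ after every step, radians
    times: np.ndarray        # ps, at the frame stride
    thetas: np.ndarray       # θ at the frame stride, radians
    trajectory: Trajectory


@functools.lru_cache(maxsize=16)
def build_domain(spec: SurrogateSpec) -> HingedDomain:
    """Cached geometry/potential construction for a frozen spec."""
    return HingedDomain(spec)


def frame_from_theta(spec: SurrogateSpec, theta: float,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Single (N, 3) frame at hinge angle θ (radians)."""
    return build_domain(spec).frame(theta, rng)


def simulate_unbiased(spec: SurrogateSpec, n_steps: int, stride: int = 100,
                      seed: int = 0, theta0: float | None = None) -> UnbiasedRun:
    """Unbiased Langevin sampling of the hinge coordinate (see module docs)."""
    return build_domain(spec).simulate(n_steps, stride, seed, theta0)


# ---------------------------------------------------------------------------
# Geometry calibration
# ---------------------------------------------------------------------------

def calibrate_geometry(spec: SurrogateSpec, rg_closed: float,
                       rg_open: float) -> SurrogateSpec:
    """Solve (core_radius, arm_spacing) so the jitter-free closed/open frames
    have the requested radii of gyration (within 1e-3 nm)."""
    if not rg_closed < rg_open:
        raise ValueError("rg_closed must be < rg_open")

    def residual(params):
        r, h = params
        if r <= 0.05 or h <= 0.05:
            return [1e3, 1e3]
        trial = replace(spec, core_radius=float(r), arm_length=float(h))
        dom = HingedDomain(trial)
        return [dom.radius_of_gyration(trial.theta_closed) - rg_closed,
                dom.radius_of_gyration(trial.theta_open) - rg_open]

    sol = root(residual, [spec.core_radius, spec.arm_length], method="hybr",
               options={"xtol": 1e-12})
    # accept on the residual itself; hybr can flag slow progress along the
    # nearly degenerate (radius, length) trade-off direction
    if np.max(np.abs(residual(sol.x))) > 1e-3:
        dom = HingedDomain(spec)
        lo = dom.radius_of_gyration(spec.theta_closed)
        hi = dom.radius_of_gyration(spec.theta_open)
        raise ValueError(
            f"could not calibrate geometry to RG ({rg_closed}, {rg_open}) nm; "
            f"current spec gives ({lo:.3f}, {hi:.3f}) nm — adjust targets or "
            "starting core_radius/arm_length")
    return replace(spec, core_radius=float(sol.x[0]), arm_length=float(sol.x[1]))


def jd_preset(seed: int = 0) -> SurrogateSpec:
    """The study-condition preset: wells at 63°/100° with depths 36/4 kJ/mol,
    geometry calibrated so RG(closed) = 1.55 nm and RG(open) = 1.78 nm,
    T = 310 K."""
    spec = SurrogateSpec(seed=seed)
    return calibrate_geometry(spec, 1.55, 1.78)


# ---------------------------------------------------------------------------
# Analytic benchmark potentials (engine validation oracles)
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkPotential:
    """1D (or separable 2D) analytic potential with exact free energy."""

    dimension: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[float], float]
    #: working interval for sampling / gridding
    support: tuple[float, float]

    def free_energy(self, grid: np.ndarray) -> np.ndarray:
        """Exact FES on a grid (overdamped 1D: F = U), min shifted to 0."""
        f = np.asarray(self.energy(np.asarray(grid, dtype=float)))
        return f - f.min()


def benchmark_double_well(barrier: float, asym: float = 0.0) -> BenchmarkPotential:
    """Quartic with minima exactly at x = ±1, U(−1) = 0, U(+1) = asym,
    U(0) = barrier."""
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    # coefficients [c4, c3, c2, c1, c0] from the five constraints
    A = np.array([
        [-4.0, 3.0, -2.0, 1.0, 0.0],   # U'(-1) = 0
        [4.0, 3.0, 2.0, 1.0, 0.0],     # U'(+1) = 0
        [1.0, -1.0, 1.0, -1.0, 1.0],   # U(-1) = 0
        [1.0, 1.0, 1.0, 1.0, 1.0],     # U(+1) = asym
        [0.0, 0.0, 0.0, 0.0, 1.0],     # U(0) = barrier
    ])
    coeffs = np.linalg.solve(A, np.array([0.0, 0.0, 0.0, asym, barrier]))
    dcoeffs = np.polyder(coeffs)

    def energy(x):
        return np.polyval(coeffs, x)

    def gradient(x):
        return float(np.polyval(dcoeffs, x))

    return BenchmarkPotential(dimension=1, energy=energy, gradient=gradient,
                              support=(-1.8, 1.8))


def boltzmann_density(potential_energy: np.ndarray, temperature: float) -> np.ndarray:
    """Normalized Boltzmann weights exp(−U/kBT) on a grid (oracle helper)."""
    u = np.asarray(potential_energy, dtype=float)
    w = np.exp(-(u - u.min()) / (KB * temperature))
    return w / w.sum()
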