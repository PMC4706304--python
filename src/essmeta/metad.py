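"""Well-tempered metadynamics on a scalar collective variable.

A history-dependent bias V(s) is built from Gaussians deposited along the
trajectory; in the well-tempered scheme each hill's height is damped as
w = w0·exp(−V(s)/kB·ΔT) with ΔT = (γ−1)T, so the converged bias equals
−(1−1/γ)·F(s).  The engine couples the bias force to the surrogate's
overdamped hinge dynamics (or to an analytic benchmark potential) through
the chain rule over the CV gradient.

The bias is represented exactly as the sum of deposited hills; a dense
grid cache holds the exact hill sums at its nodes and serves fast
linearly interpolated lookups to the integrator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import KB
from .dynamics import run_langevin
from .io import Trajectory, write_table, read_table
from .surrogate import (BenchmarkPotential, HingedDomain, SurrogateSpec,
                        build_domain)


@dataclass(frozen=True)
class MetadParams:
    """Deposition settings.  ``sigma`` is in the CV's own units (nm for PCA
    projections); the deposition rate and pace define the initial hill
    height w0 = rate × pace."""

    sigma: float = 0.1
    deposition_rate: float = 0.2   # kJ/mol·ps
    pace: float = 1.0              # ps between hills
    bias_factor: float = 20.0
    temperature: float = 310.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.pace <= 0:
            raise ValueError("pace must be positive")
        if self.deposition_rate < 0:
            raise ValueError("deposition rate must be non-negative")

    @property
    def w0(self) -> float:
        """Initial hill height, kJ/mol."""
        return self.deposition_rate * self.pace

    @property
    def delta_t(self) -> float:
        """Well-tempered ΔT = (γ−1)·T in K."""
        return (self.bias_factor - 1.0) * self.temperature


@dataclass(frozen=True)
class Hill:
    time: float
    center: float
    sigma: float
    height: float

    def __post_init__(self):
        if self.height <= 0 or self.sigma <= 0:
            raise ValueError("hill height and sigma must be positive")


class HillsLog:
    """Record of deposited Gaussians (arrays: time, center, sigma, height)."""

    def __init__(self, times=(), centers=(), sigmas=(), heights=(),
                 bias_factor: float = 20.0):
        self.times = np.asarray(times, dtype=float)
        self.centers = np.asarray(centers, dtype=float)
        self.sigmas = np.asarray(sigmas, dtype=float)
        self.heights = np.asarray(heights, dtype=float)
        self.bias_factor = bias_factor
        n = len(self.times)
        if not (len(self.centers) == len(self.sigmas) == len(self.heights) == n):
            raise ValueError("hill arrays must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        for t, c, s, h in zip(self.times, self.centers, self.sigmas, self.heights):
            yield Hill(t, c, s, h)

    def truncated(self, t_max: float) -> "HillsLog":
        keep = self.times <= t_max
        return HillsLog(self.times[keep], self.centers[keep],
                        self.sigmas[keep], self.heights[keep], self.bias_factor)

    def write(self, path) -> None:
        rows = np.column_stack([self.times, self.centers, self.sigmas,
                                self.heights,
                                np.full(len(self), self.bias_factor)])
        write_table(path, ["time", "center", "sigma", "height", "biasfactor"], rows)

    @classmethod
    def read(cls, path) -> "HillsLog":
        names, rows = read_table(path)
        cols = {n: rows[:, i] for i, n in enumerate(names)}
        bf = float(cols["biasfactor"][0]) if len(rows) else 20.0
        return cls(cols["time"], cols["center"], cols["sigma"], cols["height"], bf)


def hill_height(w0: float, bias_at_center: float, bias_factor: float,
                temperature: float) -> float:
    """Well-tempered damping w = w0·exp(−V(s)/(kB·ΔT)), ΔT = (γ−1)T."""
    if bias_factor <= 1:
        raise ValueError("bias factor must exceed 1")
    return w0 * math.exp(-bias_at_center / (KB * (bias_factor - 1.0) * temperature))


def bias_value_and_gradient(hills: HillsLog, s) -> tuple[np.ndarray, np.ndarray]:
    """Exact hill-sum bias V(s) = Σ h_k exp(−(s−c_k)²/2σ_k²) and dV/ds.

    Accepts scalar or array s; returns matching shapes (kJ/mol and
    kJ/mol per CV unit)."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if len(hills) == 0:
        v = np.zeros_like(s_arr)
        g = np.zeros_like(s_arr)
    else:
        # chunk over evaluation points to bound memory for long hill logs
        v = np.empty_like(s_arr)
        g = np.empty_like(s_arr)
        c, sg, h = hills.centers, hills.sigmas, hills.heights
        for lo in range(0, s_arr.size, 4096):
            blk = s_arr[lo:lo + 4096, None]
            z = (blk - c[None, :]) / sg[None, :]
            e = h[None, :] * np.exp(-0.5 * z * z)
            v[lo:lo + 4096] = e.sum(axis=1)
            g[lo:lo + 4096] = (-(z / sg[None, :]) * e).sum(axis=1)
    if np.isscalar(s) or np.ndim(s) == 0:
        return float(v[0]), float(g[0])
    return v, g


class BiasGrid:
    """Dense cache of the hill-sum bias on an evenly spaced grid.

    Node values are exact running hill sums; lookups between nodes are
    linearly interpolated (error bounded by σ and grid spacing, negligible
    vs kBT at the default resolution).  Lookups outside the grid clamp to
    the edge nodes and are counted for diagnostics.
    """

    def __init__(self, lo: float, hi: float, n: int = 2048,
                 bias_factor: float = 20.0):
        if not hi > lo:
            raise ValueError("grid bounds must satisfy hi > lo")
        self.lo = float(lo)
        self.hi = float(hi)
        self.n = int(n)
        self.nodes = np.linspace(lo, hi, n)
        self.dx = self.nodes[1] - self.nodes[0]
        self.v = np.zeros(n)
        self.dv = np.zeros(n)
        self._times: list[float] = []
        self._centers: list[float] = []
        self._sigmas: list[float] = []
        self._heights: list[float] = []
        self.sigma = 0.1
        self.bias_factor = bias_factor
        self.out_of_range = 0

    def deposit(self, time: float, center: float, height: float,
                sigma: float | None = None) -> None:
        sg = self.sigma if sigma is None else sigma
        z = (self.nodes - center) / sg
        e = height * np.exp(-0.5 * z * z)
        self.v += e
        self.dv += -(z / sg) * e
        self._times.append(time)
        self._centers.append(center)
        self._sigmas.append(sg)
        self._heights.append(height)

    def _locate(self, s: float) -> tuple[int, float]:
        x = (s - self.lo) / self.dx
        if x <= 0.0:
            self.out_of_range += 1
            return 0, 0.0
        if x >= self.n - 1:
            self.out_of_range += 1
            return self.n - 2, 1.0
        i = int(x)
        return i, x - i

    def value(self, s: float) -> float:
        i, f = self._locate(s)
        return self.v[i] * (1.0 - f) + self.v[i + 1] * f

    def grad(self, s: float) -> float:
        i, f = self._locate(s)
        return self.dv[i] * (1.0 - f) + self.dv[i + 1] * f

    def hills(self) -> HillsLog:
        return HillsLog(self._times, self._centers, self._sigmas,
                        self._heights, self.bias_factor)


# ---------------------------------------------------------------------------
# Collective variables on the surrogate's hinge coordinate
# ---------------------------------------------------------------------------

class IdentityCV:
    """CV = the dynamical coordinate itself (benchmark potentials)."""

    kind = "benchmark_coordinate"

    def value(self, q: float) -> float:
        return q

    def grad(self, q: float) -> float:
        return 1.0


class HingeAngleCV:
    """CV = the hinge angle θ itself (radians)."""

    kind = "hinge_angle"

    def value(self, q: float) -> float:
        return q

    def grad(self, q: float) -> float:
        return 1.0


class ModeProjectionCV:
    """Projection of the jitter-free surrogate frame onto a PCA eigenvector.

    For a rigid arm rotation the atomic coordinates are linear in
    (cos θ, sin θ), so the projection reduces to the closed form
    s(θ) = c0 + c1·cos θ + c2·sin θ with an analytic derivative.  Frames
    are projected without re-alignment: the core is rigid, so the optimal
    superposition of a clean frame onto the mean is essentially the
    identity, and any smooth monotone reparameterization is an equally
    valid biasing coordinate.
    """

    kind = "pca_projection"

    def __init__(self, domain: HingedDomain, modes, k: int = 0):
        v = modes.eigenvectors[:, k].reshape(-1, 3)
        idx = modes.atom_indices
        mean = modes.mean
        resids = domain._resids_sorted[idx]

        const = 0.0
        cu = 0.0
        ce = 0.0
        rod_map = {r: (rho, phi) for r, rho, phi in zip(
            domain.rod_resids.tolist(), domain.rod_rho.tolist(),
            domain.rod_phi.tolist())}
        hinge_map = dict(zip(domain.hinge_resids.tolist(), domain.hinge_t.tolist()))
        core_map = {r: i for i, r in enumerate(domain.core_resids.tolist())}
        for row, r in enumerate(resids.tolist()):
            if r in rod_map:
                rho, phi = rod_map[r]
                vu = v[row] @ domain.u
                ve = v[row] @ domain.e
                const += v[row] @ (domain.hinge_point - mean[row])
                # ρ(cos(θ+φ)u + sin(θ+φ)e) expanded in cosθ, sinθ
                cu += rho * (vu * math.cos(phi) + ve * math.sin(phi))
                ce += rho * (ve * math.cos(phi) - vu * math.sin(phi))
            elif r in hinge_map:
                pos = domain.hinge_point + hinge_map[r] * domain.hinge_axis
                const += v[row] @ (pos - mean[row])
            else:
                const += v[row] @ (domain.core_xyz[core_map[r]] - mean[row])
        self.c0 = float(const)
        self.c1 = float(cu)
        self.c2 = float(ce)

    def value(self, theta: float) -> float:
        return self.c0 + self.c1 * math.cos(theta) + self.c2 * math.sin(theta)

    def grad(self, theta: float) -> float:
        return -self.c1 * math.sin(theta) + self.c2 * math.cos(theta)

    def value_array(self, thetas: np.ndarray) -> np.ndarray:
        return self.c0 + self.c1 * np.cos(thetas) + self.c2 * np.sin(thetas)


@dataclass
class MetadRun:
    """Result of a well-tempered metadynamics run."""

    params: MetadParams
    dt: float
    theta_full: np.ndarray        # dynamical coordinate after every step
    cv_full: np.ndarray           # CV value after every step
    times: np.ndarray             # ps, at the frame/CV log stride
    thetas: np.ndarray
    cv: np.ndarray                # CV at the log stride
    hills: HillsLog
    trajectory: Trajectory | None = None

    def write_colvar(self, path) -> None:
        write_table(path, ["time", "cv"], np.column_stack([self.times, self.cv]))


def run_wtmetad(system: SurrogateSpec | BenchmarkPotential,
                cv=None,
                params: MetadParams | None = None,
                n_steps: int = 100_000,
                seed: int = 0,
                stride: int = 50,
                dt: float | None = None,
                friction: float | None = None,
                theta0: float | None = None,
                cv_range: tuple[float, float] | None = None,
                grid_points: int = 2048,
                emit_frames: bool = False,
                modes=None,
                mode_index: int = 0) -> MetadRun:
    """Run well-tempered metadynamics on a surrogate spec or benchmark.

    For a :class:`SurrogateSpec` system, ``cv`` defaults to the projection
    onto PCA mode ``mode_index`` when ``modes`` is given, else to the hinge
    angle itself.  ``cv_range`` bounds the bias grid; by default it spans
    the CV image of a generous hinge-angle interval around the wells (or
    the benchmark support).  Seed-reproducible: one seed stream drives
    noise and jitter.
    """
    params = params or MetadParams()
    master = np.random.SeedSequence(seed)
    rng_theta, rng_jitter = [np.random.default_rng(s) for s in master.spawn(2)]

    if isinstance(system, SurrogateSpec):
        domain = build_domain(system)
        grad_u = domain.potential.grad_scalar
        dt = system.dt if dt is None else dt
        friction = system.friction if friction is None else friction
        temperature = system.temperature
        if theta0 is None:
            theta0 = system.theta_open
        if cv is None:
            if modes is not None:
                cv = ModeProjectionCV(domain, modes, mode_index)
            else:
                cv = HingeAngleCV()
        if cv_range is None:
            margin = 0.45
            grid_th = np.linspace(system.theta_closed - margin,
                                  system.theta_open + margin, 512)
            img = np.array([cv.value(t) for t in grid_th])
            pad = 6.0 * params.sigma
            cv_range = (float(img.min()) - pad, float(img.max()) + pad)
    elif isinstance(system, BenchmarkPotential):
        grad_u = system.gradient
        dt = 0.002 if dt is None else dt
        friction = 10.0 if friction is None else friction
        temperature = params.temperature
        if theta0 is None:
            theta0 = -1.0  # start in the left well
        cv = cv or IdentityCV()
        if cv_range is None:
            pad = 6.0 * params.sigma
            cv_range = (system.support[0] - pad, system.support[1] + pad)
    else:
        raise TypeError("system must be a SurrogateSpec or BenchmarkPotential")

    grid = BiasGrid(cv_range[0], cv_range[1], grid_points,
                    bias_factor=params.bias_factor)
    grid.sigma = params.sigma
    pace_steps = max(1, int(round(params.pace / dt)))

    thetas = run_langevin(
        grad_u, theta0, n_steps, dt, friction, temperature, rng_theta,
        cv_value=cv.value, cv_grad=cv.grad, bias_grid=grid,
        pace_steps=pace_steps if params.w0 > 0 else 0,
        w0=params.w0, bias_factor=params.bias_factor)

    if grid.out_of_range > 0:
        warnings.warn(f"CV left the configured grid {grid.out_of_range} times; "
                      "bias clamped at the edges", RuntimeWarning)

    if hasattr(cv, "value_array"):
        cv_full = cv.value_array(thetas)
    else:
        cv_full = np.array([cv.value(t) for t in thetas])

    idx = np.arange(stride - 1, n_steps, stride)
    times = (idx + 1) * dt
    traj = None
    if emit_frames and isinstance(system, SurrogateSpec):
        frames = domain.frames(thetas[idx], rng_jitter)
        traj = Trajectory(domain.topology(), frames, times)

    return MetadRun(params=params, dt=dt, theta_full=thetas, cv_full=cv_full,
                    times=times, thetas=thetas[idx], cv=cv_full[idx],
                    hills=grid.hills(), trajectory=traj)


def bias_to_fes(hills: HillsLog, bias_factor: float | None = None,
                grid: np.ndarray | None = None):
    """Well-tempered estimator F(s) = −γ/(γ−1)·V(s) + C with min F = 0."""
    from .fes import FESProfile

    if len(hills) == 0:
        raise ValueError("cannot build a FES from an empty hills log")
    gamma = hills.bias_factor if bias_factor is None else bias_factor
    if gamma <= 1:
        raise ValueError("bias factor must exceed 1")
    if grid is None:
        span = hills.centers.max() - hills.centers.min()
        pad = 0.02 * span + 3.0 * hills.sigmas.max()
        grid = np.linspace(hills.centers.min() - pad, hills.centers.max() + pad,
                           512)
    v, _ = bias_value_and_gradient(hills, grid)
    f = -(gamma / (gamma - 1.0)) * v
    f -= f.min()
    return FESProfile(axes=[("cv", np.asarray(grid, float))], values=f,
                      mask=np.ones_like(f, dtype=bool))
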