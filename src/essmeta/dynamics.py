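"""Overdamped Langevin propagation of a single hinge coordinate.

The surrogate domain's only dynamical degree of freedom is the hinge angle
θ; it evolves by the Euler–Maruyama discretisation of overdamped Langevin
dynamics,

    θ_{k+1} = θ_k − (dt/γ) dU/dθ + sqrt(2 kB T dt / γ) ξ_k,   ξ ~ N(0,1),

with γ an angular drag coefficient in kJ/mol·ps/rad².  The same kernel
drives both unbiased sampling and well-tempered metadynamics (the biased
run with deposition rate zero is bit-identical to the unbiased one for the
same seed).
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .constants import KB

#: Single-step displacements beyond this are treated as divergence.
MAX_STEP = math.pi / 4


class DivergentStepError(RuntimeError):
    """Raised when the integrator takes an unphysically large step."""


def run_langevin(
    grad_u: Callable[[float], float],
    theta0: float,
    n_steps: int,
    dt: float,
    friction: float,
    temperature: float,
    rng: np.random.Generator,
    cv_value: Callable[[float], float] | None = None,
    cv_grad: Callable[[float], float] | None = None,
    bias_grid=None,
    pace_steps: int = 0,
    w0: float = 0.0,
    bias_factor: float = 20.0,
) -> np.ndarray:
    """Propagate θ for ``n_steps`` and return the θ value after every step.

    When ``pace_steps > 0`` and ``w0 > 0``, a well-tempered hill of initial
    height ``w0`` is deposited on ``bias_grid`` at the current CV value every
    ``pace_steps`` steps, and the bias force is fed back through the CV
    gradient (chain rule).  Noise consumption is independent of the bias
    settings, so identical seeds give identical unbiased trajectories.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    kT = KB * temperature
    mob = dt / friction
    noise_scale = math.sqrt(2.0 * kT * dt / friction) if temperature > 0 else 0.0
    kT_delta = KB * (bias_factor - 1.0) * temperature if temperature > 0 else math.inf

    depositing = pace_steps > 0 and w0 > 0.0
    if depositing and (bias_grid is None or cv_value is None or cv_grad is None):
        raise ValueError("metadynamics needs a bias grid and a differentiable CV")
    biasing = bias_grid is not None and cv_value is not None

    out = np.empty(n_steps)
    theta = float(theta0)
    block = 8192
    noise = rng.standard_normal(block)
    ni = 0
    for k in range(n_steps):
        force = -grad_u(theta)
        if biasing:
            s = cv_value(theta)
            if depositing and k % pace_steps == 0:
                v_here = bias_grid.value(s)
                h = w0 * math.exp(-v_here / kT_delta) if kT_delta < math.inf else w0
                bias_grid.deposit((k + 1) * dt, s, h)
            force -= bias_grid.grad(s) * cv_grad(theta)
        if ni == block:
            noise = rng.standard_normal(block)
            ni = 0
        step = mob * force + noise_scale * noise[ni]
        ni += 1
        if abs(step) > MAX_STEP:
            raise DivergentStepError(
                f"|Δθ| = {abs(step):.3g} rad at step {k}; reduce dt or "
                "increase friction")
        theta += step
        out[k] = theta
    return out
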