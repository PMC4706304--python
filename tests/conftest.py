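"""Shared fixtures: the calibrated preset, a pre-run ensemble with PCA, and
one well-converged benchmark metadynamics run reused across tests."""

import pytest

from essmeta.io import ResidueSelection
from essmeta.metad import MetadParams, run_wtmetad
from essmeta.pca import essential_modes
from essmeta.pipeline import unbiased_ensemble
from essmeta.surrogate import benchmark_double_well, build_domain, jd_preset


@pytest.fixture(scope="session")
def preset_spec():
    return jd_preset(0)


@pytest.fixture(scope="session")
def domain(preset_spec):
    return build_domain(preset_spec)


@pytest.fixture(scope="session")
def core_selection(preset_spec):
    return ResidueSelection(
        [r for r in range(1, preset_spec.n_residues + 1)
         if r < preset_spec.arm_start or r > preset_spec.arm_end])


@pytest.fixture(scope="session")
def prerun(preset_spec):
    """Six 25 ps unbiased replicas started open (samples both basins)."""
    traj, thetas = unbiased_ensemble(preset_spec, 6, 2500, 5, seed=42)
    return traj, thetas


@pytest.fixture(scope="session")
def prerun_modes(prerun, core_selection):
    traj, _ = prerun
    modes, aligned = essential_modes(traj, fit_selection=core_selection)
    return modes, aligned


@pytest.fixture(scope="session")
def benchmark():
    return benchmark_double_well(15.0, 3.0)


@pytest.fixture(scope="session")
def benchmark_run(benchmark):
    """One 2 ns well-tempered run on the asymmetric benchmark double well."""
    params = MetadParams(sigma=0.1, deposition_rate=0.2, pace=1.0,
                         bias_factor=20.0, temperature=310.0)
    return run_wtmetad(benchmark, params=params, n_steps=1_000_000, seed=11,
                       stride=40, dt=0.002, friction=10.0)
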