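"""One-command orchestration: simulate → PCA → metadynamics → reweighted FES.

The pipeline reproduces the full analysis chain on the synthetic hinged
domain: an unbiased multi-replica pre-run samples the open→closed
transition, PCA on the aligned Cα coordinates extracts the essential
mode, well-tempered metadynamics biases the mode-1 projection, and the
reweighted histograms over radius of gyration and hairpin angle yield the
free-energy profiles whose minima are compared against the planted wells.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import descriptors as desc
from .fes import FESProfile, find_minima, frame_weights, weighted_fes, convergence_series
from .io import ResidueSelection, Trajectory, select_residues, write_pdb_models, write_table
from .metad import MetadParams, ModeProjectionCV, run_wtmetad
from .pca import essential_modes, filter_trajectory
from .surrogate import SurrogateSpec, build_domain, jd_preset, simulate_unbiased

log = logging.getLogger("essmeta")


@dataclass
class RunConfig:
    """Stage toggles and parameters for :func:`run_pipeline`.

    The defaults are the desk-scale study conditions: six unbiased
    replicas of 25 ps started from the open state feed the PCA (long
    enough to dwell in the shallow open well and relax into the closed
    one, so the transition mode is represented); the metadynamics leg
    biases the mode-1 projection for 20 ns with the reference deposition
    settings (σ=0.1, 0.2 kJ/mol·ps, γ=20, 310 K).
    """

    seed: int = 0
    outdir: str | None = None
    spec: SurrogateSpec | None = None      # default: the calibrated preset

    run_unbiased: bool = True
    run_metad: bool = True

    prerun_replicas: int = 6
    prerun_steps: int = 2_500
    prerun_stride: int = 5

    metad_params: MetadParams = field(default_factory=MetadParams)
    metad_steps: int = 2_000_000
    metad_stride: int = 40

    fes_bins: int = 100
    min_depth: float = 2.0
    #: reweighting estimator; the final-bias scheme is robust to the early
    #: exploration transient of runs started in the shallow well, while the
    #: "running" time-dependent-offset variant assumes quasi-equilibrium
    reweight_scheme: str = "final"
    #: minima more than this far above the global minimum are treated as
    #: sampling-edge artifacts
    fes_max_value: float = 50.0
    n_modes: int = 10
    write_trajectories: bool = False


def unbiased_ensemble(spec: SurrogateSpec, n_replicas: int, n_steps: int,
                      stride: int, seed: int) -> tuple[Trajectory, np.ndarray]:
    """Concatenate independent unbiased replicas (all started open) into a
    single ensemble trajectory; returns (trajectory, per-frame θ)."""
    domain = build_domain(spec)
    frames, thetas, times = [], [], []
    offset = 0.0
    ss = np.random.SeedSequence(seed).spawn(n_replicas)
    for r in range(n_replicas):
        run = simulate_unbiased(spec, n_steps, stride,
                                seed=int(ss[r].generate_state(1)[0] % (2 ** 31)))
        frames.append(run.trajectory.frames)
        thetas.append(run.thetas)
        times.append(run.times + offset)
        offset = times[-1][-1] + spec.dt * stride
    traj = Trajectory(domain.topology(), np.concatenate(frames),
                      np.concatenate(times))
    return traj, np.concatenate(thetas)


def surrogate_descriptors(spec: SurrogateSpec, thetas: np.ndarray, seed: int,
                          chunk: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """RG (nm) and hairpin angle (degrees) of jittered frames generated at
    the given hinge angles, computed in chunks to bound memory."""
    domain = build_domain(spec)
    topo = domain.topology()
    rng = np.random.default_rng(seed)
    idx = select_residues(topo, ResidueSelection.from_range(
        1, min(171, spec.n_residues)))
    masses = topo.masses
    rg_out = np.empty(thetas.size)
    ang_out = np.empty(thetas.size)
    for lo in range(0, thetas.size, chunk):
        f = domain.frames(thetas[lo:lo + chunk], rng)
        rg_out[lo:lo + chunk] = desc.rg_series(f, idx, masses[idx])
        ang_out[lo:lo + chunk] = desc.angle_series(f, topo, None, masses)
    return rg_out, ang_out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and optionally writes) a
    machine-readable summary with minima, occupancies, parameters and
    seeds.  Identical config + seed gives an identical summary."""
    t0 = _time.time()
    spec = config.spec if config.spec is not None else jd_preset(config.seed)
    domain = build_domain(spec)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "seed": config.seed,
        "spec": {k: v for k, v in asdict(spec).items()},
        "stages": [],
    }

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    if not config.run_unbiased:
        raise ValueError("the unbiased pre-run is required (it feeds the PCA)")

    # -- stage 1: unbiased ensemble ---------------------------------------
    log.info("stage unbiased: %d replicas x %d steps",
             config.prerun_replicas, config.prerun_steps)
    traj, thetas_unb = unbiased_ensemble(
        spec, config.prerun_replicas, config.prerun_steps,
        config.prerun_stride, seeds[0])
    series = desc.descriptor_series(traj)
    occ = series["state"].value_counts(normalize=True).to_dict()
    summary["stages"].append("unbiased")
    summary["state_occupancy"] = {k: round(float(v), 6)
                                  for k, v in sorted(occ.items())}
    if outdir:
        write_table(outdir / "colvar_unbiased.dat",
                    ["time", "rg", "angle"],
                    series[["time", "rg", "angle"]].to_numpy())
        if config.write_trajectories:
            write_pdb_models(outdir / "unbiased.pdb", traj)

    # -- stage 2: essential dynamics --------------------------------------
    log.info("stage pca: %d frames", traj.n_frames)
    core_sel = ResidueSelection(
        [r for r in range(1, spec.n_residues + 1)
         if r < spec.arm_start or r > spec.arm_end])
    modes, aligned = essential_modes(traj, fit_selection=core_sel,
                                     n_modes=config.n_modes)
    filtered = filter_trajectory(aligned, modes, 0)
    fluct = desc.rmsf(filtered)
    resids = filtered.topology.residue_indices
    arm = (resids >= spec.arm_start) & (resids <= spec.arm_end)
    summary["stages"].append("pca")
    summary["pca"] = {
        "eigenvalues": [round(float(v), 8) for v in modes.eigenvalues[:5]],
        "rmsf_arm_max": round(float(fluct[arm].max()), 6),
        "rmsf_core_max": round(float(fluct[~arm].max()), 6),
    }
    if outdir:
        write_table(outdir / "rmsf_mode1.dat", ["residue", "rmsf"],
                    np.column_stack([resids, fluct]))
        write_table(outdir / "eigenvalues.dat", ["mode", "eigenvalue"],
                    np.column_stack([np.arange(modes.n_modes) + 1,
                                     modes.eigenvalues]))

    if not config.run_metad:
        # unbiased-histogram FES only
        w = np.full(len(series), 1.0 / len(series))
        fes_rg = weighted_fes(series["rg"].to_numpy(), w, spec.temperature,
                              config.fes_bins, ("rg",))
        fes_ang = weighted_fes(series["angle"].to_numpy(), w, spec.temperature,
                               config.fes_bins, ("angle",))
        summary["fes"] = {"source": "unbiased_histogram",
                          "rg_minima": _minima_dict(find_minima(fes_rg, config.min_depth)),
                          "angle_minima": _minima_dict(find_minima(fes_ang, config.min_depth))}
        summary["elapsed_s"] = round(_time.time() - t0, 1)
        _write_summary(summary, outdir)
        return summary

    # -- stage 3: well-tempered metadynamics ------------------------------
    log.info("stage metad: %d steps", config.metad_steps)
    run = run_wtmetad(spec, params=config.metad_params,
                      n_steps=config.metad_steps, seed=seeds[1],
                      stride=config.metad_stride, modes=modes)
    summary["stages"].append("metad")
    summary["metad"] = {
        "n_hills": len(run.hills),
        "first_hill_height": round(float(run.hills.heights[0]), 6),
        "last_hill_height": round(float(run.hills.heights[-1]), 6),
    }
    if outdir:
        run.hills.write(outdir / "hills.dat")
        run.write_colvar(outdir / "colvar_metad.dat")

    # -- stage 4: reweighted FES ------------------------------------------
    log.info("stage fes: %d frames", run.times.size)
    rg, angle = surrogate_descriptors(spec, run.thetas, seeds[2])
    weights = frame_weights(run.cv, run.times, run.hills, spec.temperature,
                            scheme=config.reweight_scheme)
    fes_rg = weighted_fes(rg, weights, spec.temperature, config.fes_bins, ("rg",))
    fes_ang = weighted_fes(angle, weights, spec.temperature, config.fes_bins,
                           ("angle",))
    fes_2d = weighted_fes(np.column_stack([angle, rg]), weights,
                          spec.temperature, config.fes_bins, ("angle", "rg"))
    min_rg = find_minima(fes_rg, config.min_depth, max_value=config.fes_max_value)
    min_ang = find_minima(fes_ang, config.min_depth, max_value=config.fes_max_value)

    cv_c = run_cv_at(spec, modes, spec.theta_closed)
    cv_o = run_cv_at(spec, modes, spec.theta_open)
    half = 0.35 * abs(cv_o - cv_c)
    conv = convergence_series(
        run.hills, config.metad_params.bias_factor,
        tuple(sorted((cv_c - half, cv_c + half))),
        tuple(sorted((cv_o - half, cv_o + half))),
        np.linspace(run.hills.times.max() / 8, run.hills.times.max(), 8))

    summary["stages"].append("fes")
    summary["fes"] = {
        "source": "reweighted_metad",
        "rg_minima": _minima_dict(min_rg),
        "angle_minima": _minima_dict(min_ang),
        "delta_f_converged": bool(conv.attrs["converged"]),
        "delta_f_final": round(float(conv["delta_f"].iloc[-1]), 3),
    }
    if outdir:
        fes_rg.write(outdir / "fes_rg.dat")
        fes_ang.write(outdir / "fes_angle.dat")
        fes_2d.write(outdir / "fes_2d.dat")
        min_rg.to_frame().to_csv(outdir / "minima_rg.csv", index=False)
        min_ang.to_frame().to_csv(outdir / "minima_angle.csv", index=False)
        conv.to_csv(outdir / "convergence.csv", index=False)

    summary["elapsed_s"] = round(_time.time() - t0, 1)
    _write_summary(summary, outdir)
    return summary


def run_cv_at(spec: SurrogateSpec, modes, theta: float) -> float:
    """Mode-1 CV value of the clean frame at hinge angle θ."""
    return ModeProjectionCV(build_domain(spec), modes, 0).value(theta)


def _minima_dict(report) -> list[dict]:
    return [{"location": [round(x, 6) for x in m.location],
             "value": round(m.value, 4), "depth": round(m.depth, 4)}
            for m in report]


def _write_summary(summary: dict, outdir: Path | None) -> None:
    if outdir:
        payload = {k: v for k, v in summary.items() if k != "elapsed_s"}
        (outdir / "summary.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write small deterministic test inputs: a 3-model toy PDB, a 200-frame
    surrogate trajectory, a 50-hill HILLS file and a known-answer FES table."""
    from .metad import BiasGrid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {}

    # 3-model toy PDB (10 atoms, rigid-rotated copies)
    from .io import Structure
    base = rng.normal(0.0, 0.4, (10, 3))
    models = []
    for m in range(3):
        ang = 0.4 * m
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        models.append(Structure.from_arrays(base @ rot.T, range(1, 11),
                                            model_id=m + 1))
    paths["toy_pdb"] = outdir / "toy_ensemble.pdb"
    write_pdb_models(paths["toy_pdb"], models)

    # 200-frame surrogate trajectory
    spec = SurrogateSpec(seed=seed)
    run = simulate_unbiased(spec, 2000, stride=10, seed=seed)
    paths["trajectory"] = outdir / "surrogate_traj.pdb"
    write_pdb_models(paths["trajectory"], run.trajectory)

    # 50-hill HILLS file from a short biased benchmark
    grid = BiasGrid(-2.0, 2.0, 512)
    grid.sigma = 0.1
    v = 0.0
    for k in range(50):
        c = float(rng.uniform(-1.2, 1.2))
        h = 0.2 * np.exp(-grid.value(c) / (0.0083144621 * 19 * 310))
        grid.deposit(float(k + 1), c, h)
    paths["hills"] = outdir / "hills_fixture.dat"
    grid.hills().write(paths["hills"])

    # known-answer FES table: quadratic with min 0 at x=0
    x = np.linspace(-1, 1, 41)
    prof = FESProfile(axes=[("x", x)], values=12.5 * x ** 2,
                      mask=np.ones_like(x, dtype=bool))
    paths["fes"] = outdir / "fes_fixture.dat"
    prof.write(paths["fes"])
    return paths
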