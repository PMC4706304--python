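# essmeta

Essential-coordinate well-tempered metadynamics for mapping a hinged
protein domain's open↔closed free-energy landscape — at desk scale,
against planted ground truth.

## The problem

Domains like the Josephin domain of Ataxin-3 carry a mobile α-helical
hairpin (residues 31–62) that swings between an *open* conformation,
extended into solvent, and a *closed* one packed against the globular
core.  Which state is thermodynamically favored is a free-energy
question, and plain molecular dynamics cannot answer it: once the system
falls into a deep well (tens of kJ/mol), thermal fluctuations never lift
it back out within reachable simulation times.

The standard remedy chains three techniques:

1. **Essential dynamics (PCA)** — diagonalize the covariance of the
   aligned Cα coordinates; the first eigenvector captures the hairpin
   swing and serves as the collective variable (CV) *s*.
2. **Well-tempered metadynamics** — deposit Gaussian bias hills along
   *s* with heights damped as w = w₀·exp(−V(s)/k_BΔT), ΔT = (γ−1)T, so
   the system is pushed over barriers and the converged bias satisfies
   V(s) = −(1−1/γ)·F(s).
3. **Reweighted histograms** — recover the free energy over physically
   meaningful descriptors (radius of gyration R_G over residues 1–171 and
   the three-group hairpin angle) by weighting biased frames with
   w_i ∝ exp(+V(s_i)/k_BT) and taking F = −k_BT ln ρ.

`essmeta` implements this entire chain from scratch, plus a **synthetic
171-bead hinged domain** whose hinge angle diffuses on a planted quartic
double well — wells at 63° and 100°, depths 36 and 4 kJ/mol, geometry
calibrated so R_G(closed) = 1.55 nm and R_G(open) = 1.78 nm at 310 K.
Because the planted free energy is known analytically, every stage of the
pipeline is verifiable end to end.  Multi-model PDB ensembles and
COLVAR/HILLS-style text tables are read and written for interoperability.

Who it is for: anyone building or teaching enhanced-sampling analysis
pipelines who wants a fully testable, dependency-light reference
implementation with exact oracles.

## Worked example

The one-command pipeline — simulate, PCA, metadynamics, reweight, report:

```sh
essmeta run --quick --seed 3 --out demo_run
```

prints the recovered landscape (abridged):

```json
{
  "angle_minima": [
    {"location": [63.636698], "value": 0.0,    "depth": 38.5212},
    {"location": [99.679466], "value": 33.128, "depth": 5.3932}
  ],
  "rg_minima": [
    {"location": [1.551871], "value": 0.0,    "depth": 39.5941},
    {"location": [1.784639], "value": 33.061, "depth": 6.5331}
  ],
  "source": "reweighted_metad"
}
```

Reading this: the reweighted free-energy profile over the hairpin angle
has its global minimum at 63.6° (the closed state; `value` is the free
energy above the global minimum, so 0 here) and a secondary minimum at
99.7° (open) lying 33.1 kJ/mol higher; `depth` is each well's depth below
the lowest separating barrier.  The profile over R_G shows the same two
states at 1.552 and 1.785 nm.  The planted truth is 63°/100°, 1.55/1.78
nm, depths 36/4 kJ/mol — the quick run (6 ns of biasing) recovers
locations to a fraction of a degree / 0.005 nm and depths to a few
kJ/mol; the full-length run (`--seed N` without `--quick`, 20 ns) tightens
the depths further.  `demo_run/` contains the HILLS and COLVAR tables,
eigenvalues, the mode-1-filtered RMSF profile, the 1D and 2D FES grids,
minima tables, the ΔF(t) convergence series and a machine-readable
`summary.json`.

The same stages are available individually (`essmeta simulate`,
`descriptors`, `pca`, `metad`, `fes`, `classify`) and as a Python API:

```python
from essmeta import jd_preset, simulate_unbiased, descriptor_series

spec = jd_preset(seed=0)           # calibrated study conditions
run = simulate_unbiased(spec, n_steps=100_000, stride=100, seed=1)
print(descriptor_series(run.trajectory)[["rg", "angle", "state"]].head())
```

Frames with R_G < 1.6 nm **and** hairpin angle < 80° are classified
closed-like, matching the conventional thresholds for this system.

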