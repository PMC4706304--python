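"""Essential dynamics: PCA on aligned Cα coordinates.

Frames are iteratively superposed to their converged mean, the 3N×3N
coordinate covariance is diagonalized, and the leading eigenvectors define
the essential coordinates.  The projection onto the first eigenvector is
the collective variable used for biased sampling; mode-filtered
trajectories isolate the motion along a single eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .descriptors import kabsch_superpose
from .io import ResidueSelection, Trajectory, select_residues


@dataclass
class EssentialModes:
    """Mean structure and orthonormal covariance eigenbasis.

    mean: (n_sel, 3) nm; eigenvectors: (3n_sel, K) columns, orthonormal;
    eigenvalues: nm², descending."""

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    selection: ResidueSelection
    atom_indices: np.ndarray
    #: positions within ``atom_indices`` used for the superposition fit
    #: (defaults to all; a rigid-core subset avoids hinge-motion leakage
    #: into the fitted rotation)
    fit_positions: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("covariance eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        g = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(g, np.eye(g.shape[0]), atol=1e-8):
            raise ValueError("eigenvector columns must be orthonormal")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


def iterative_align(trajectory: Trajectory,
                    selection: ResidueSelection | None = None,
                    fit_selection: ResidueSelection | None = None,
                    tol: float = 1e-6, max_iter: int = 100
                    ) -> tuple[Trajectory, np.ndarray]:
    """Superpose every frame onto the iteratively converged mean structure.

    The rigid fit is computed over ``fit_selection`` (default: the full
    ``selection``) and applied to all atoms; convergence is declared when
    the mean over the selection shifts by < ``tol`` nm RMS.  Returns the
    aligned trajectory and the converged mean over the selected atoms."""
    if trajectory.n_frames < 2:
        raise ValueError("alignment needs at least 2 frames")
    topo = trajectory.topology
    if selection is None:
        selection = ResidueSelection(np.unique(topo.residue_indices))
    idx = select_residues(topo, selection)
    fit_idx = idx if fit_selection is None else select_residues(topo, fit_selection)

    frames = trajectory.frames.copy()
    fit_mean = frames[0, fit_idx].copy()
    mean = frames[:, idx].mean(axis=0)
    for _ in range(max_iter):
        for f in range(frames.shape[0]):
            frames[f] = kabsch_superpose(frames[f, fit_idx], fit_mean,
                                         apply_to=frames[f])[0]
        fit_mean = frames[:, fit_idx].mean(axis=0)
        new_mean = frames[:, idx].mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            return Trajectory(topo, frames, trajectory.times), mean
    raise RuntimeError(f"alignment did not converge in {max_iter} iterations")


def covariance(aligned: Trajectory, selection: ResidueSelection | None = None
               ) -> np.ndarray:
    """3N×3N coordinate covariance ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩ of an aligned trajectory."""
    if aligned.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    topo = aligned.topology
    if selection is None:
        selection = ResidueSelection(np.unique(topo.residue_indices))
    idx = select_residues(topo, selection)
    x = aligned.frames[:, idx, :].reshape(aligned.n_frames, -1)
    xm = x - x.mean(axis=0)
    return xm.T @ xm / x.shape[0]


def eigendecompose(cov: np.ndarray, mean: np.ndarray,
                   selection: ResidueSelection, atom_indices: np.ndarray,
                   n_modes: int = 10,
                   fit_positions: np.ndarray | None = None) -> EssentialModes:
    """Diagonalize a symmetric covariance into descending essential modes.

    Eigenvector sign convention: the largest-magnitude component of each
    column is positive, so projections are reproducible across runs."""
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance matrix must be symmetric")
    vals, vecs = eigh((cov + cov.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    k = min(n_modes, vals.size)
    vals, vecs = vals[:k].copy(), vecs[:, :k].copy()
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] *= -1.0
    return EssentialModes(mean=np.asarray(mean, float), eigenvectors=vecs,
                          eigenvalues=np.clip(vals, 0.0, None),
                          selection=selection, atom_indices=atom_indices,
                          fit_positions=fit_positions)


def essential_modes(trajectory: Trajectory,
                    selection: ResidueSelection | None = None,
                    fit_selection: ResidueSelection | None = None,
                    n_modes: int = 10) -> tuple[EssentialModes, Trajectory]:
    """Align, build the covariance and diagonalize in one call.

    ``fit_selection`` restricts the superposition fit (e.g. to a rigid
    core) while the covariance still spans the full ``selection``.
    Returns (modes, aligned trajectory)."""
    topo = trajectory.topology
    if selection is None:
        selection = ResidueSelection(np.unique(topo.residue_indices))
    aligned, mean = iterative_align(trajectory, selection, fit_selection)
    cov = covariance(aligned, selection)
    idx = select_residues(topo, selection)
    fit_pos = None
    if fit_selection is not None:
        fit_idx = select_residues(topo, fit_selection)
        fit_pos = np.searchsorted(idx, fit_idx)
        if not np.array_equal(idx[fit_pos], fit_idx):
            raise ValueError("fit_selection must be a subset of selection")
    modes = eigendecompose(cov, mean, selection, idx, n_modes=n_modes,
                           fit_positions=fit_pos)
    return modes, aligned


def _aligned_displacement(frame: np.ndarray, modes: EssentialModes) -> np.ndarray:
    sub = frame[modes.atom_indices]
    if modes.fit_positions is None:
        fitted, _ = kabsch_superpose(sub, modes.mean)
    else:
        pos = modes.fit_positions
        fitted, _ = kabsch_superpose(sub[pos], modes.mean[pos], apply_to=sub)
    return (fitted - modes.mean).ravel()


def project(frame: np.ndarray, modes: EssentialModes, k: int = 0) -> float:
    """Projection s_k = ⟨x_aligned − mean, v_k⟩ of one frame (nm)."""
    if not 0 <= k < modes.n_modes:
        raise IndexError(f"mode index {k} out of range (0..{modes.n_modes - 1})")
    return float(_aligned_displacement(frame, modes) @ modes.eigenvectors[:, k])


def project_series(trajectory: Trajectory, modes: EssentialModes,
                   k: int = 0, align: bool = True) -> np.ndarray:
    """Mode-k projections for every frame of a trajectory."""
    if not 0 <= k < modes.n_modes:
        raise IndexError(f"mode index {k} out of range (0..{modes.n_modes - 1})")
    v = modes.eigenvectors[:, k]
    if align:
        return np.array([_aligned_displacement(f, modes) @ v
                         for f in trajectory.frames])
    x = trajectory.frames[:, modes.atom_indices, :].reshape(trajectory.n_frames, -1)
    return (x - modes.mean.ravel()) @ v


def filter_trajectory(trajectory: Trajectory, modes: EssentialModes,
                      k: int = 0) -> Trajectory:
    """Replace each frame by mean + s_k·v_k (motion along one mode only).

    Expects an already-aligned trajectory (as produced by
    :func:`iterative_align`), so projections are plain inner products and
    filtering is exactly idempotent.  The returned trajectory contains the
    selected atoms only."""
    s = project_series(trajectory, modes, k, align=False)
    v = modes.eigenvectors[:, k]
    flat = modes.mean.ravel()[None, :] + s[:, None] * v[None, :]
    frames = flat.reshape(trajectory.n_frames, -1, 3)
    from .io import Structure

    topo = trajectory.topology
    idx = modes.atom_indices
    sub = Structure.from_arrays(
        modes.mean,
        topo.residue_indices[idx],
        [topo.residue_names[i] for i in idx],
        [topo.atom_names[i] for i in idx],
        topo.masses[idx])
    return Trajectory(sub, frames, trajectory.times)
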