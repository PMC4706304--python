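"""Structural descriptors of the hinge motion.

Radius of gyration over residues 1–171, the three-group hairpin angle
(globular subdomain 111–113/122–125/162–165, hinge 32–35, loop
45–48/58–61), open/closed state classification, Kabsch superposition,
RMSD/RMSF and Cα contact maps.  All operate on nm coordinates; angles are
returned in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io import ResidueSelection, Structure, Trajectory, select_residues


@dataclass(frozen=True)
class HairpinGroups:
    """The three residue groups defining the hairpin angle."""

    globular: ResidueSelection = field(
        default_factory=lambda: ResidueSelection(
            list(range(111, 114)) + list(range(122, 126)) + list(range(162, 166))))
    hinge: ResidueSelection = field(
        default_factory=lambda: ResidueSelection(range(32, 36)))
    loop: ResidueSelection = field(
        default_factory=lambda: ResidueSelection(
            list(range(45, 49)) + list(range(58, 62))))

    def __post_init__(self):
        sets = [set(self.globular), set(self.hinge), set(self.loop)]
        if any(not s for s in sets):
            raise ValueError("all three hairpin groups must be non-empty")
        if (sets[0] & sets[1]) or (sets[0] & sets[2]) or (sets[1] & sets[2]):
            raise ValueError("hairpin groups must be pairwise disjoint")


@dataclass(frozen=True)
class StateThresholds:
    """Classification cutoffs; closed-like means RG < rg_closed_max AND
    angle < angle_closed_max (strict, per the reference convention).

    Secondary boundaries split closed/half-closed (angle) and
    open/half-open (RG)."""

    rg_closed_max: float = 1.6       # nm
    angle_closed_max: float = 80.0   # degrees
    angle_fully_closed: float = 70.0
    rg_fully_open: float = 1.7

    def __post_init__(self):
        if min(self.rg_closed_max, self.angle_closed_max,
               self.angle_fully_closed, self.rg_fully_open) <= 0:
            raise ValueError("thresholds must be positive")


def center_of_mass(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted center Σ mᵢ rᵢ / Σ mᵢ of an (n, 3) coordinate set."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty selection")
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    return masses @ coords / total


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """sqrt(Σ mᵢ|rᵢ − r_com|² / Σ mᵢ) in nm."""
    coords = np.asarray(coords, dtype=float)
    com = center_of_mass(coords, masses)
    d2 = np.sum((coords - com) ** 2, axis=1)
    if masses is None:
        return float(np.sqrt(d2.mean()))
    masses = np.asarray(masses, dtype=float)
    return float(np.sqrt(masses @ d2 / masses.sum()))


def _group_com(frame, structure, selection, masses):
    idx = select_residues(structure, selection, atom_name=None)
    m = None if masses is None else np.asarray(masses)[idx]
    return center_of_mass(np.asarray(frame)[idx], m)


def hairpin_angle(frame: np.ndarray, structure: Structure,
                  groups: HairpinGroups | None = None,
                  masses: np.ndarray | None = None) -> float:
    """Angle (degrees, in [0, 180]) at the hinge-group COM between the
    vectors to the globular-group and loop-group COMs."""
    groups = groups or HairpinGroups()
    if masses is None:
        masses = structure.masses
    g = _group_com(frame, structure, groups.globular, masses)
    h = _group_com(frame, structure, groups.hinge, masses)
    l = _group_com(frame, structure, groups.loop, masses)
    v1, v2 = g - h, l - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("degenerate zero-length vector in hairpin angle")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_state(rg: float, angle: float,
                   thresholds: StateThresholds | None = None) -> str:
    """Label a frame closed / half-closed / half-open / open.

    Closed-like iff rg < rg_closed_max and angle < angle_closed_max, both
    strict; sub-labels from the secondary boundaries."""
    t = thresholds or StateThresholds()
    if rg <= 0 or not 0 <= angle <= 180:
        raise ValueError("rg must be positive and angle within [0, 180]")
    if rg < t.rg_closed_max and angle < t.angle_closed_max:
        return "closed" if angle < t.angle_fully_closed else "half-closed"
    return "open" if rg >= t.rg_fully_open else "half-open"


def is_closed_like(state: str) -> bool:
    return state in ("closed", "half-closed")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None,
                     apply_to: np.ndarray | None = None
                     ) -> tuple[np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns the transformed coordinates (``apply_to`` if given, else the
    mobile set) and the weighted RMSD over the fitted atoms in nm.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    w = np.ones(mobile.shape[0]) if weights is None else np.asarray(weights, float)
    wn = w / w.sum()
    com_m = wn @ mobile
    com_r = wn @ reference
    a = mobile - com_m
    b = reference - com_r
    # collinearity guard: rank of the weighted coordinate cloud
    if np.linalg.matrix_rank(a - wn @ a, tol=1e-10) < 2:
        raise ValueError("selected atoms are collinear; superposition is "
                         "ill-defined")
    rot, _ = Rotation.align_vectors(b, a, weights=w)
    fitted = rot.apply(a) + com_r
    rmsd = float(np.sqrt(wn @ np.sum((fitted - reference) ** 2, axis=1)))
    target = mobile if apply_to is None else np.asarray(apply_to, dtype=float)
    out = rot.apply(target - com_m) + com_r
    return out, rmsd


def rmsf(trajectory: Trajectory, atom_indices: np.ndarray | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position.

    The trajectory is assumed already superposed to a common reference."""
    if trajectory.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    frames = trajectory.frames
    if atom_indices is not None:
        frames = frames[:, atom_indices, :]
    mean = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))


def contact_map(frame: np.ndarray, cutoff: float = 0.8) -> np.ndarray:
    """Symmetric boolean Cα contact matrix (distance < cutoff), false diagonal."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frame = np.asarray(frame, dtype=float)
    d = np.linalg.norm(frame[:, None, :] - frame[None, :, :], axis=2)
    contacts = d < cutoff
    np.fill_diagonal(contacts, False)
    return contacts


def rg_series(frames: np.ndarray, atom_indices: np.ndarray,
              masses: np.ndarray | None = None) -> np.ndarray:
    """Vectorized radius of gyration per frame over a fixed atom subset."""
    sub = frames[:, atom_indices, :]
    if masses is None:
        com = sub.mean(axis=1, keepdims=True)
        return np.sqrt(np.mean(np.sum((sub - com) ** 2, axis=2), axis=1))
    m = np.asarray(masses, dtype=float)
    m = m / m.sum()
    com = np.einsum("i,fij->fj", m, sub)[:, None, :]
    return np.sqrt(np.einsum("i,fi->f", m, np.sum((sub - com) ** 2, axis=2)))


def angle_series(frames: np.ndarray, structure: Structure,
                 groups: HairpinGroups | None = None,
                 masses: np.ndarray | None = None) -> np.ndarray:
    """Vectorized hairpin angle (degrees) per frame."""
    groups = groups or HairpinGroups()
    if masses is None:
        masses = structure.masses
    masses = np.asarray(masses, dtype=float)
    coms = []
    for sel in (groups.globular, groups.hinge, groups.loop):
        idx = select_residues(structure, sel)
        m = masses[idx]
        m = m / m.sum()
        coms.append(np.einsum("i,fij->fj", m, frames[:, idx, :]))
    g, h, l = coms
    v1, v2 = g - h, l - h
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise ValueError("degenerate zero-length vector in hairpin angle")
    cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def descriptor_series(trajectory: Trajectory,
                      rg_selection: ResidueSelection | None = None,
                      groups: HairpinGroups | None = None,
                      thresholds: StateThresholds | None = None,
                      mass_weighted: bool = True) -> pd.DataFrame:
    """Per-frame RG (nm), hairpin angle (degrees) and state label.

    RG defaults to residues 1–171 (the range shared by the reference NMR
    ensembles); set ``mass_weighted=False`` for the geometric variant.
    """
    topo = trajectory.topology
    if rg_selection is None:
        hi = min(171, int(topo.residue_indices.max()))
        rg_selection = ResidueSelection.from_range(1, hi)
    groups = groups or HairpinGroups()
    thresholds = thresholds or StateThresholds()
    masses = topo.masses if mass_weighted else None

    rg_idx = select_residues(topo, rg_selection)
    rg_m = None if masses is None else masses[rg_idx]

    rg = rg_series(trajectory.frames, rg_idx, rg_m)
    ang = angle_series(trajectory.frames, topo, groups, topo.masses)
    states = [classify_state(r, a, thresholds) for r, a in zip(rg, ang)]
    return pd.DataFrame({"time": trajectory.times, "rg": rg,
                         "angle": ang, "state": states})
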