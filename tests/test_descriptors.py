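"""Descriptor oracles: COM/RG/angle against brute-force formulas, Kabsch
against a rotation grid search, the strict state classifier, RMSF closed
forms and contact maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from essmeta import descriptors as desc
from essmeta.io import ResidueSelection, Structure, Trajectory, select_residues


@pytest.fixture
def rng():
    return np.random.default_rng(17)


class TestComRg:
    def test_single_atom_com(self):
        assert np.allclose(desc.center_of_mass(np.array([[1.0, 2.0, 3.0]]),
                                               np.array([12.0])),
                           [1.0, 2.0, 3.0])

    def test_two_equal_masses_midpoint(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert np.allclose(desc.center_of_mass(coords, np.ones(2)), [1, 0, 0])

    def test_com_matches_brute_force(self, rng):
        coords = rng.normal(size=(10, 3))
        masses = rng.uniform(50, 200, 10)
        brute = sum(m * c for m, c in zip(masses, coords)) / masses.sum()
        assert np.abs(desc.center_of_mass(coords, masses) - brute).max() < 1e-12

    def test_rg_coincident_atoms_zero(self):
        assert desc.radius_of_gyration(np.ones((5, 3)), np.ones(5)) == 0.0

    def test_rg_two_masses_half_distance(self):
        coords = np.array([[0.0, 0, 0], [0.8, 0, 0]])
        assert desc.radius_of_gyration(coords, np.ones(2)) \
            == pytest.approx(0.4, abs=1e-14)

    def test_rg_matches_brute_force(self, rng):
        coords = rng.normal(size=(12, 3))
        masses = rng.uniform(50, 200, 12)
        com = sum(m * c for m, c in zip(masses, coords)) / masses.sum()
        brute = np.sqrt(sum(m * ((c - com) ** 2).sum()
                            for m, c in zip(masses, coords)) / masses.sum())
        assert desc.radius_of_gyration(coords, masses) \
            == pytest.approx(brute, abs=1e-12)

    def test_zero_total_mass_rejected(self):
        with pytest.raises(ValueError):
            desc.center_of_mass(np.ones((2, 3)), np.zeros(2))

    def test_preset_closed_frame_rg(self, domain, preset_spec):
        topo = domain.topology()
        idx = select_residues(topo, ResidueSelection.from_range(1, 171))
        frame = domain.frame(preset_spec.theta_closed)
        rg = desc.radius_of_gyration(frame[idx], topo.masses[idx])
        assert rg == pytest.approx(1.55, abs=1e-3)


class TestHairpinAngle:
    def _structure_from_groups(self, g, h, l):
        """One atom per group member; groups get the default residue ids."""
        groups = desc.HairpinGroups()
        coords, resids = [], []
        for sel, point in ((groups.globular, g), (groups.hinge, h),
                           (groups.loop, l)):
            for r in sel:
                coords.append(point)
                resids.append(r)
        order = np.argsort(resids)
        coords = np.asarray(coords, float)[order]
        resids = np.asarray(resids)[order]
        return Structure.from_arrays(coords, resids), coords

    def test_right_angle(self):
        s, coords = self._structure_from_groups([1, 0, 0], [0, 0, 0], [0, 1, 0])
        assert desc.hairpin_angle(coords, s) == pytest.approx(90.0, abs=1e-10)

    def test_collinear_is_180(self):
        s, coords = self._structure_from_groups([-1, 0, 0], [0, 0, 0], [2, 0, 0])
        assert desc.hairpin_angle(coords, s) == pytest.approx(180.0, abs=1e-10)

    def test_matches_arccos_oracle(self, rng):
        g, h, l = rng.normal(size=(3, 3))
        s, coords = self._structure_from_groups(g, h, l)
        v1, v2 = g - h, l - h
        oracle = np.degrees(np.arccos(
            np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert desc.hairpin_angle(coords, s) == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_vertex_rejected(self):
        s, coords = self._structure_from_groups([0, 0, 0], [0, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            desc.hairpin_angle(coords, s)

    def test_surrogate_descriptor_equals_hinge_coordinate(self, domain):
        topo = domain.topology()
        for deg in (63.0, 80.0, 100.0):
            frame = domain.frame(np.radians(deg))
            assert desc.hairpin_angle(frame, topo) == pytest.approx(deg, abs=1e-8)


class TestClassify:
    @pytest.mark.parametrize("rg,angle,closed_like", [
        (1.50, 70.0, True),    # reference closed-like cutoffs
        (1.90, 120.0, False),  # high-RG/high-angle open region
        (1.60, 70.0, False),   # boundary: strict inequality on RG
        (1.50, 80.0, False),   # boundary: strict inequality on angle
    ])
    def test_threshold_rule(self, rg, angle, closed_like):
        assert desc.is_closed_like(desc.classify_state(rg, angle)) == closed_like

    def test_sub_labels(self):
        assert desc.classify_state(1.5, 60.0) == "closed"
        assert desc.classify_state(1.5, 75.0) == "half-closed"
        assert desc.classify_state(1.65, 90.0) == "half-open"
        assert desc.classify_state(1.9, 120.0) == "open"

    @settings(derandomize=True, max_examples=200)
    @given(rg=st.floats(0.5, 2.5), angle=st.floats(0.0, 180.0),
           drg=st.floats(0.0, 0.5), dangle=st.floats(0.0, 50.0))
    def test_monotone_toward_closed(self, rg, angle, drg, dangle):
        """Decreasing RG and angle never flips closed-like to open-like."""
        before = desc.is_closed_like(desc.classify_state(rg, angle))
        smaller = desc.classify_state(max(rg - drg, 1e-3),
                                      max(angle - dangle, 0.0))
        if before:
            assert desc.is_closed_like(smaller)


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(6, 3))
        out, rmsd = desc.kabsch_superpose(x, x)
        assert rmsd < 1e-12
        assert np.abs(out - x).max() < 1e-12

    def test_rigid_transform_recovered(self, rng):
        x = rng.normal(size=(7, 3))
        rot = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90° about z
        moved = x @ rot.T + np.array([1.0, -2.0, 0.5])
        out, rmsd = desc.kabsch_superpose(moved, x)
        assert rmsd < 1e-10
        assert np.abs(out - x).max() < 1e-9

    def test_beats_rotation_grid_search(self, rng):
        """Optimal fit must be at least as good as an exhaustive 2°-step
        search over z-rotations of noisy planar coordinates."""
        ref = rng.normal(size=(5, 3))
        mobile = ref + rng.normal(0.0, 0.1, (5, 3))
        _, rmsd = desc.kabsch_superpose(mobile, ref)
        best = np.inf
        refc = ref - ref.mean(axis=0)
        mobc = mobile - mobile.mean(axis=0)
        for deg in np.arange(0.0, 360.0, 2.0):
            a = np.radians(deg)
            rot = np.array([[np.cos(a), -np.sin(a), 0],
                            [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
            trial = np.sqrt(np.mean(np.sum((mobc @ rot.T - refc) ** 2, axis=1)))
            best = min(best, trial)
        assert rmsd <= best + 1e-4

    def test_superposition_never_increases_rmsd(self, rng):
        ref = rng.normal(size=(9, 3))
        mobile = ref + rng.normal(0.0, 0.3, (9, 3))
        before = np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1)))
        _, after = desc.kabsch_superpose(mobile, ref)
        assert after <= before + 1e-12

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(ValueError):
            desc.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError, match="collinear"):
            desc.kabsch_superpose(line, line)


class TestRmsf:
    def _traj(self, frames):
        s = Structure.from_arrays(frames[0], range(1, frames.shape[1] + 1))
        return Trajectory(s, frames, np.arange(frames.shape[0], dtype=float))

    def test_static_trajectory_zero(self):
        frames = np.tile(np.random.default_rng(0).normal(size=(1, 4, 3)),
                         (5, 1, 1))
        assert np.allclose(desc.rmsf(self._traj(frames)), 0.0)

    def test_square_wave_amplitude(self):
        a = 0.3
        frames = np.zeros((10, 1, 3))
        frames[::2, 0, 0] = a
        frames[1::2, 0, 0] = -a
        assert desc.rmsf(self._traj(frames))[0] == pytest.approx(a, abs=1e-12)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            desc.rmsf(self._traj(np.zeros((1, 2, 3))))

    def test_arm_exceeds_core_on_surrogate(self, prerun, preset_spec):
        traj, _ = prerun
        fluct = desc.rmsf(traj)
        res = traj.topology.residue_indices
        arm = (res >= preset_spec.arm_start) & (res <= preset_spec.arm_end)
        assert fluct[arm].mean() > fluct[~arm].mean()


class TestContacts:
    def test_cutoff_behaviour(self):
        frame = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        assert desc.contact_map(frame, 0.8)[0, 1]
        assert not desc.contact_map(frame, 0.4)[0, 1]

    def test_symmetric_false_diagonal(self):
        frame = np.random.default_rng(2).normal(size=(6, 3))
        cm = desc.contact_map(frame, 1.0)
        assert np.array_equal(cm, cm.T)
        assert not cm.diagonal().any()

    def test_closed_has_more_arm_core_contacts(self, domain, preset_spec):
        topo = domain.topology()
        res = topo.residue_indices
        arm = np.nonzero((res >= 31) & (res <= 62))[0]
        core = np.nonzero((res >= 140) & (res <= 160))[0]
        n_closed = desc.contact_map(domain.frame(preset_spec.theta_closed))[
            np.ix_(arm, core)].sum()
        n_open = desc.contact_map(domain.frame(preset_spec.theta_open))[
            np.ix_(arm, core)].sum()
        assert n_closed > n_open


class TestInvariance:
    def test_rg_and_angle_invariant_under_rigid_motion(self, domain):
        topo = domain.topology()
        frame = domain.frame(1.3, np.random.default_rng(1))
        a = np.radians(35.0)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        moved = frame @ rot.T + np.array([3.0, -1.0, 2.0])
        idx = select_residues(topo, ResidueSelection.from_range(1, 171))
        m = topo.masses
        assert desc.radius_of_gyration(moved[idx], m[idx]) == pytest.approx(
            desc.radius_of_gyration(frame[idx], m[idx]), abs=1e-10)
        assert desc.hairpin_angle(moved, topo) == pytest.approx(
            desc.hairpin_angle(frame, topo), abs=1e-10)
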