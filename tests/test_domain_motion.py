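"""Lid-rotation recovery, classification convention, opening distance."""

import numpy as np
import pytest

import lidmotion as lm
from conftest import interface_pivot, random_rigid_transform, rotation_trajectory
from lidmotion.errors import GeometryError, ResidueLookupError


@pytest.fixture(scope="module")
def ramp_trajectory(scaffold):
    """Noise-free 0→50° counterclockwise ramp, 50 frames."""
    return rotation_trajectory(scaffold, np.linspace(0.0, 50.0, 50))


class TestFitDomainTransform:
    def test_identity_frame(self, scaffold):
        s, topo = scaffold
        ca, _ = s.calpha()
        rids = np.array([a.res_id for a in s.atoms])
        t, pd_rmsd, pdz_rmsd = lm.fit_domain_transform(ca, ca, rids, topo)
        assert pd_rmsd == pytest.approx(0.0, abs=1e-12)
        assert pdz_rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-10)

    @pytest.mark.parametrize("true_angle", [5.0, 40.0, 90.0, 150.0])
    def test_noise_free_angle_recovery_to_microdegrees(self, scaffold, true_angle):
        traj = rotation_trajectory(scaffold, [0.0, true_angle])
        rep = lm.motion_report(traj, scaffold[1])
        assert rep.frames[1].angle_deg == pytest.approx(true_angle, abs=1e-6)
        from conftest import reference_axis
        assert abs(rep.frames[1].axis @ reference_axis(*scaffold)) > 0.999

    def test_rigid_lid_has_zero_internal_rmsd(self, ramp_trajectory, scaffold):
        rep = lm.motion_report(ramp_trajectory, scaffold[1])
        assert max(f.pdz_internal_rmsd for f in rep.frames) < 1e-9

    def test_noisy_recovery_within_three_degrees(self, scaffold):
        traj = rotation_trajectory(scaffold, [0.0, 40.0], noise=0.5, seed=42)
        rep = lm.motion_report(traj, scaffold[1])
        assert rep.frames[1].angle_deg == pytest.approx(40.0, abs=3.0)
        assert rep.frames[1].pdz_internal_rmsd > 0.0   # noise shows up as deformation

    def test_too_few_domain_atoms_raise(self, scaffold):
        s, topo = scaffold
        ca, _ = s.calpha()
        rids = np.array([a.res_id for a in s.atoms])
        import dataclasses
        tiny = dataclasses.replace(topo, pdz_range=(topo.pdz_range[0], topo.pdz_range[0] + 1),
                                   opening_pair=(topo.opening_pair[0], topo.pdz_range[0]))
        with pytest.raises(GeometryError):
            lm.fit_domain_transform(ca, ca, rids, tiny)


class TestClassification:
    def test_counterclockwise_label(self, scaffold):
        traj = rotation_trajectory(scaffold, [0.0, 40.0])
        rep = lm.motion_report(traj, scaffold[1])
        assert rep.final_label == "cc"
        assert rep.final_angle_deg == pytest.approx(40.0, abs=1e-6)

    def test_clockwise_label_mirrors_small_lid_drop(self, scaffold):
        # −10° clockwise ramp: the single-monomer behaviour of the activating
        # hinge-B mutant, smallest labelled rotation
        traj = rotation_trajectory(scaffold, np.linspace(0.0, -10.0, 10))
        rep = lm.motion_report(traj, scaffold[1])
        assert rep.final_label == "c"

    def test_below_threshold_is_irregular(self, scaffold):
        traj = rotation_trajectory(scaffold, [0.0, 3.0])
        rep = lm.motion_report(traj, scaffold[1])
        assert rep.frames[1].label == "i"

    def test_boundary_exactly_at_threshold_classifies_by_sign(self, scaffold):
        s, topo = scaffold
        traj = rotation_trajectory(scaffold, [0.0, -10.0])
        _, rids = s.calpha()
        t, _, _ = lm.fit_domain_transform(traj.frames[1], traj.frames[0],
                                          traj.res_ids, topo)
        label, signed, _ = lm.classify_motion(t, topo, traj.frames[0], traj.res_ids,
                                              threshold_deg=10.0)
        assert signed == pytest.approx(-10.0, abs=1e-6)
        assert label == "c"                      # strict inequality for "i"

    def test_constant_trajectory_all_irregular(self, scaffold):
        traj = rotation_trajectory(scaffold, [0.0] * 5)
        rep = lm.motion_report(traj, scaffold[1])
        assert all(f.label == "i" for f in rep.frames)
        assert rep.max_angle_deg == pytest.approx(0.0, abs=1e-9)


class TestOpeningDistance:
    def test_constructed_distance(self, scaffold):
        s, topo = scaffold
        ca, keys = s.calpha()
        rids = np.array([r for _, r in keys])
        a, b = topo.opening_pair
        coords = ca.copy()
        coords[rids == b] = coords[rids == a] + np.array([23.1, 0.0, 0.0])
        assert lm.opening_distance(coords, rids, topo) == pytest.approx(23.1)

    def test_identical_residue_pair_zero(self, scaffold):
        import dataclasses
        s, topo = scaffold
        ca, keys = s.calpha()
        rids = np.array([r for _, r in keys])
        coords = ca.copy()
        a, b = topo.opening_pair
        coords[rids == b] = coords[rids == a]
        assert lm.opening_distance(coords, rids, topo) == pytest.approx(0.0)

    def test_missing_residue_raises(self, scaffold):
        s, topo = scaffold
        ca, keys = s.calpha()
        rids = np.array([r for _, r in keys])
        keep = rids != topo.opening_pair[1]
        with pytest.raises(ResidueLookupError):
            lm.opening_distance(ca[keep], rids[keep], topo)


class TestMotionReport:
    def test_monotone_ramp_summary(self, ramp_trajectory, scaffold):
        rep = lm.motion_report(ramp_trajectory, scaffold[1])
        assert rep.final_label == "cc"
        assert rep.final_angle_deg == pytest.approx(50.0, abs=1e-6)
        assert rep.max_angle_deg == pytest.approx(50.0, abs=1e-6)
        signed = [f.signed_angle_deg for f in rep.frames]
        assert all(b > a - 1e-9 for a, b in zip(signed, signed[1:]))

    def test_opening_monotone_in_cc_angle(self, scaffold):
        """Δ grows strictly with the imposed rotation when the opening pair
        sits on the moving radius (angles up to 60°): the mobile-side residue
        is the one of largest radius about the axis and its fixed-side
        partner starts angularly behind it, so rotation carries them apart."""
        import dataclasses
        s, topo = scaffold
        pivot = interface_pivot(s, topo)
        ca, keys = s.calpha()
        rids = np.array([r for _, r in keys])
        mobile = np.array([topo.in_pdz(r) for r in rids])
        rel = ca - pivot
        phase = np.arctan2(rel[:, 1], rel[:, 0])
        radial = np.linalg.norm(rel[:, :2], axis=1)
        m_idx = int(np.argmax(np.where(mobile, radial, -1.0)))
        # fixed partner angularly just behind the mobile tip for one of the
        # two rotation senses; orient the reference axis so that sense is cc
        gap_behind = np.mod(phase[m_idx] - phase, 2 * np.pi)
        gap_ahead = np.mod(phase - phase[m_idx], 2 * np.pi)
        for g in (gap_behind, gap_ahead):
            g[mobile] = np.inf
        if gap_behind.min() <= gap_ahead.min():
            f_idx, sense = int(np.argmin(gap_behind)), +1.0
        else:
            f_idx, sense = int(np.argmin(gap_ahead)), -1.0
        ref_vec = ca[rids == 60][0] - ca[rids == 1][0]
        axis_ref = (1, 60) if sense * ref_vec[2] > 0 else (60, 1)
        topo2 = dataclasses.replace(topo, opening_pair=(int(rids[f_idx]), int(rids[m_idx])),
                                    axis_reference=axis_ref)
        rep = lm.motion_report(
            rotation_trajectory(scaffold, sense * np.linspace(0, 60, 13),
                                axis=np.array([0.0, 0.0, 1.0])), topo2)
        deltas = [f.opening_distance for f in rep.frames]
        assert all(b > a for a, b in zip(deltas, deltas[1:]))
        assert rep.opening_monotonic
        assert rep.final_label == "cc"

    def test_global_rigid_motion_equivariance(self, scaffold):
        s, topo = scaffold
        traj = rotation_trajectory(scaffold, np.linspace(0.0, 30.0, 6))
        rep = lm.motion_report(traj, topo)
        rng = np.random.default_rng(5)
        moved_frames = [random_rigid_transform(rng).apply(f) for f in traj.frames]
        moved = lm.Trajectory(topology_ref=traj.topology_ref, frames=moved_frames)
        rep2 = lm.motion_report(moved, topo)
        for f1, f2 in zip(rep.frames, rep2.frames):
            assert f2.signed_angle_deg == pytest.approx(f1.signed_angle_deg, abs=1e-6)
            assert f2.label == f1.label
            assert f2.opening_distance == pytest.approx(f1.opening_distance, abs=1e-6)

    def test_tsv_schema(self, ramp_trajectory, scaffold):
        rep = lm.motion_report(ramp_trajectory, scaffold[1])
        header = rep.to_tsv().splitlines()[0].split("\t")
        assert header == ["frame", "signed_angle_deg", "axis_x", "axis_y",
                          "axis_z", "label", "delta_angstrom"]
        assert len(rep.to_tsv().splitlines()) == 51
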