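import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from salt_twist.frames import (
    RING_ATOMS,
    all_bp_frames,
    bp_frame,
    end_to_end_twist,
    fit_base_frame,
    rebuild_step,
    step_params,
    subhelix_scan,
    template_coords,
    twist_profile,
    _rebuild_batch,
    _steps_batch,
)
from salt_twist.geometry import rotation_about_axis
from salt_twist.model import ReferenceFrame
from salt_twist.synthetic import DuplexSpec, FluctuationSpec, build_duplex, make_trajectory
from conftest import random_rotation


def frame_from(R, o=(0.0, 0.0, 0.0)):
    return ReferenceFrame(np.asarray(o, float), R)


class TestBaseFrameFit:
    def test_identity_pose(self, small_conf):
        """A template placed by a known frame is recovered exactly."""
        f = fit_base_frame(small_conf, "A", 3)
        f.validate()

    def test_known_rotation_translation(self, rng, small_conf):
        """Rotating+translating all atoms moves the fitted frame identically."""
        R0 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t0 = np.array([1.0, 2.0, 3.0])
        moved = small_conf.transformed(R0, t0)
        f0 = fit_base_frame(small_conf, "A", 3)
        f1 = fit_base_frame(moved, "A", 3)
        np.testing.assert_allclose(f1.axes, R0 @ f0.axes, atol=1e-9)
        np.testing.assert_allclose(f1.origin, R0 @ f0.origin + t0, atol=1e-9)

    def test_noisy_fit_matches_svd_oracle(self, rng, small_conf):
        """With coordinate noise the fit matches brute-force SVD superposition."""
        noisy = small_conf.transformed(np.eye(3))
        noisy.coords = noisy.coords + rng.normal(0, 0.05, noisy.coords.shape)
        f = fit_base_frame(noisy, "A", 3)
        base = small_conf.topology.base("A", 3)
        names = RING_ATOMS[base]
        tpl = template_coords(base, names)
        obs = np.array([noisy.atom("A", 3, a) for a in names])
        # independent SVD superposition
        X, Y = tpl - tpl.mean(0), obs - obs.mean(0)
        U, _, Vt = np.linalg.svd(X.T @ Y)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R_ref = Vt.T @ np.diag([1, 1, d]) @ U.T
        ang = Rotation.from_matrix(f.axes.T @ R_ref).magnitude()
        assert ang < 1e-3

    def test_missing_atom_named_in_error(self, small_conf):
        conf = small_conf
        # remove one ring atom by truncating topology lookup
        with pytest.raises(KeyError, match="N3"):
            bad = conf.topology._index.pop(("A", 3, "N3"))
            try:
                fit_base_frame(conf, "A", 3)
            finally:
                conf.topology._index[("A", 3, "N3")] = bad


class TestBpFrame:
    def test_exact_flip_returns_first_frame(self, rng):
        R = random_rotation(rng)
        f1 = frame_from(R, (1.0, 2.0, 3.0))
        f2 = frame_from(R @ np.diag([1.0, -1.0, -1.0]), (3.0, 2.0, 1.0))
        bp = bp_frame(f1, f2)
        np.testing.assert_allclose(bp.axes, R, atol=1e-12)
        np.testing.assert_allclose(bp.origin, (2.0, 2.0, 2.0), atol=1e-12)

    def test_ten_degree_offset_bisected(self):
        flip = np.diag([1.0, -1.0, -1.0])
        R1 = np.eye(3)
        R2_flipped = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        f2 = frame_from(R2_flipped @ flip)
        bp = bp_frame(frame_from(R1), f2)
        ang = Rotation.from_matrix(bp.axes).as_euler("zyx", degrees=True)[0]
        assert ang == pytest.approx(5.0, abs=1e-9)

    def test_matches_chordal_mean_oracle(self, rng):
        """Small perturbations: bp frame equals the brute-force chordal mean."""
        R1 = random_rotation(rng)
        wobble = Rotation.from_rotvec(rng.normal(0, 0.02, 3)).as_matrix()
        R2 = wobble @ R1 @ np.diag([1.0, -1.0, -1.0])
        bp = bp_frame(frame_from(R1), frame_from(R2))
        rots = Rotation.from_matrix(np.stack([R1, R2 @ np.diag([1.0, -1.0, -1.0])]))
        ref = rots.mean().as_matrix()
        assert Rotation.from_matrix(bp.axes.T @ ref).magnitude() < 1e-6

    def test_non_antiparallel_warns(self, rng):
        f1 = frame_from(np.eye(3))
        f2 = frame_from(np.eye(3))  # not flipped: z.z_flipped < 0
        with pytest.warns(UserWarning, match="anti-parallel"):
            bp_frame(f1, f2)


class TestStepParams:
    def test_pure_twist_rise(self):
        f1 = frame_from(np.eye(3))
        R2 = Rotation.from_euler("z", 34, degrees=True).as_matrix()
        f2 = frame_from(R2, (0.0, 0.0, 3.4))
        p = step_params(f1, f2)
        assert p.twist == pytest.approx(34.0, abs=1e-9)
        assert p.helical_twist == pytest.approx(34.0, abs=1e-9)
        assert p.rise == pytest.approx(3.4, abs=1e-9)
        assert p.helical_rise == pytest.approx(3.4, abs=1e-9)
        assert p.roll == pytest.approx(0.0, abs=1e-9)
        assert p.tilt == pytest.approx(0.0, abs=1e-9)

    def test_pure_slide(self):
        f1 = frame_from(np.eye(3))
        f2 = frame_from(np.eye(3), (0.0, 1.0, 0.0))
        p = step_params(f1, f2)
        assert p.twist == pytest.approx(0.0, abs=1e-12)
        assert p.rise == pytest.approx(0.0, abs=1e-12)
        assert p.slide == pytest.approx(1.0, abs=1e-12)

    def test_pure_roll_and_tilt_signs(self):
        f1 = frame_from(np.eye(3))
        p = step_params(f1, frame_from(Rotation.from_euler("y", 8, degrees=True).as_matrix()))
        assert p.roll == pytest.approx(8.0, abs=1e-9)
        assert p.tilt == pytest.approx(0.0, abs=1e-9)
        p = step_params(f1, frame_from(Rotation.from_euler("x", 5, degrees=True).as_matrix()))
        assert p.tilt == pytest.approx(5.0, abs=1e-9)
        assert p.roll == pytest.approx(0.0, abs=1e-9)

    def test_roundtrip_random_frames(self, rng):
        """step_params followed by rebuild_step reproduces frame 2 exactly."""
        for _ in range(20):
            f1 = frame_from(random_rotation(rng), rng.normal(size=3))
            wobble = Rotation.from_rotvec(rng.normal(0, 0.3, 3)).as_matrix()
            f2 = frame_from(wobble @ f1.axes, f1.origin + rng.normal(size=3))
            p = step_params(f1, f2)
            f2_re = rebuild_step(f1, p)
            np.testing.assert_allclose(f2_re.axes, f2.axes, atol=1e-9)
            np.testing.assert_allclose(f2_re.origin, f2.origin, atol=1e-9)

    def test_equivariance_under_rigid_motion(self, rng):
        """Step parameters are invariant when both frames move rigidly."""
        f1 = frame_from(random_rotation(rng), rng.normal(size=3))
        f2 = frame_from(random_rotation(rng) @ f1.axes, f1.origin + rng.normal(size=3))
        Rg, tg = random_rotation(rng), rng.normal(size=3)
        g1 = frame_from(Rg @ f1.axes, Rg @ f1.origin + tg)
        g2 = frame_from(Rg @ f2.axes, Rg @ f2.origin + tg)
        p, q = step_params(f1, f2), step_params(g1, g2)
        for name in ("twist", "roll", "tilt", "shift", "slide", "rise", "helical_twist", "helical_rise"):
            assert getattr(p, name) == pytest.approx(getattr(q, name), abs=1e-9)


class TestEndToEndTwist:
    def test_ideal_helix_identity(self, ideal_conf, ideal_spec):
        series = end_to_end_twist(ideal_conf)
        assert series.twist_deg_bp[0] == pytest.approx(34.286, abs=1e-6)

    def test_constant_z_rotation_invariance(self, small_spec):
        traj = make_trajectory(small_spec, FluctuationSpec(n_frames=20, seed=5))
        Rz = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 123.4)
        s1 = end_to_end_twist(traj)
        s2 = end_to_end_twist(traj.transformed(Rz, (10.0, -3.0, 2.0)))
        np.testing.assert_allclose(s1.twist_deg_bp, s2.twist_deg_bp, atol=1e-9)

    def test_reference_trajectory_sets_baseline(self, small_spec):
        traj = make_trajectory(small_spec, FluctuationSpec(n_frames=10, seed=6))
        series = end_to_end_twist(traj, reference=traj)
        assert np.abs(series.delta.mean()) < 1e-12

    def test_unwrapping_across_full_turns(self):
        """A 33-bp helix accumulates ~3 turns; the branch is the cumulative sum."""
        spec = DuplexSpec()
        conf = build_duplex(spec)
        total = end_to_end_twist(conf).twist_deg_bp[0] * (spec.n_bp - 1)
        assert total == pytest.approx(34.286 * 32, abs=1e-6)  # not mod 360

    def test_terminal_k_on_ideal_helix(self, ideal_conf):
        n = ideal_conf.n_bp
        for k in (1, 2, 3):
            s = end_to_end_twist(ideal_conf, terminal_k=k)
            # averaging k terminal bp frames pulls each end frame inward by
            # (k-1)/2 steps of phase, shortening the span by (k-1) steps;
            # only twist *changes* are compared across conditions, so the
            # constant offset is immaterial
            expected = 34.286 * (n - k) / (n - 1)
            assert s.twist_deg_bp[0] == pytest.approx(expected, abs=1e-6)


class TestTwistProfile:
    def test_three_methods_agree_on_ideal_helix(self, ideal_conf):
        values = [twist_profile(ideal_conf, m).twist_deg_bp[0] for m in ("local_helical", "bp_twist", "end_to_end")]
        np.testing.assert_allclose(values, 34.286, atol=1e-6)

    def test_unknown_method_rejected(self, small_conf):
        with pytest.raises(ValueError, match="unknown twist method"):
            twist_profile(small_conf, "spectral")

    def test_bent_helix_methods_differ_in_absolute_value(self):
        """On a strongly bent helix the three definitions need not agree."""
        spec = DuplexSpec(roll=6.0)
        conf = build_duplex(spec)
        vals = {m: twist_profile(conf, m).twist_deg_bp[0] for m in ("local_helical", "bp_twist", "end_to_end")}
        assert vals["local_helical"] != pytest.approx(vals["bp_twist"], abs=1e-3)

    def test_relative_changes_agree_across_methods(self, small_spec):
        """Mean twist shifts are tracked consistently by all three methods."""
        from salt_twist.synthetic import salt_condition

        base = make_trajectory(small_spec, FluctuationSpec(n_frames=300, seed=7))
        shifted = make_trajectory(salt_condition(small_spec, 1.0), FluctuationSpec(n_frames=300, seed=8))
        deltas = {}
        for m in ("local_helical", "bp_twist", "end_to_end"):
            a = twist_profile(base, m).twist_deg_bp
            b = twist_profile(shifted, m).twist_deg_bp
            se = np.hypot(a.std(ddof=1) / np.sqrt(len(a)), b.std(ddof=1) / np.sqrt(len(b)))
            deltas[m] = (b.mean() - a.mean(), se)
        vals = [v for v, _ in deltas.values()]
        ses = [se for _, se in deltas.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(vals[i] - vals[j]) < 2.0 * np.hypot(ses[i], ses[j])


class TestSubhelixScan:
    def test_ideal_helix_identical_at_every_length(self, ideal_conf):
        df = subhelix_scan(ideal_conf, min_len=2)
        np.testing.assert_allclose(df["twist_deg_bp"], 34.286, atol=1e-6)

    def test_length_two_is_single_step(self, small_conf):
        df = subhelix_scan(small_conf, min_len=2)
        row = df[df["length"] == 2].iloc[0]
        # centered 2-bp window of an ideal helix: one step of 34.286 deg
        assert row["twist_deg_bp"] == pytest.approx(34.286, abs=1e-6)

    def test_min_len_exceeding_helix_rejected(self, small_conf):
        with pytest.raises(ValueError, match="exceeds"):
            subhelix_scan(small_conf, min_len=99)


class TestUnwrapProperty:
    def test_adding_full_turn_changes_total_not_step(self, rng):
        """+360 deg on one step leaves per-step twist in branch, total +360."""
        R1 = np.eye(3)[None]
        o1 = np.zeros((1, 3))
        out_a = _steps_batch(R1, rotation_about_axis(np.array([[0.0, 0.0, 1.0]]), 30.0), o1, o1 + [0, 0, 3.4])
        out_b = _steps_batch(R1, rotation_about_axis(np.array([[0.0, 0.0, 1.0]]), 390.0), o1, o1 + [0, 0, 3.4])
        # the frame at 390 deg IS the frame at 30 deg: per-step twist wraps
        assert out_b["twist"][0] == pytest.approx(30.0, abs=1e-9)
        assert -180.0 < out_b["twist"][0] <= 180.0
        # but rebuilding with twist=390 advances the helix one extra turn of phase
        R2a, _ = _rebuild_batch(R1, o1, 30.0, 0, 0, 0, 0, 3.4)
        R2b, _ = _rebuild_batch(R1, o1, 390.0, 0, 0, 0, 0, 3.4)
        np.testing.assert_allclose(R2a, R2b, atol=1e-9)
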