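import numpy as np
import pytest

from salt_twist.frames import steps_of
from salt_twist.geometry import rotation_about_axis
from salt_twist.helix_params import (
    backbone_epsilon_zeta,
    bi_bii_fraction,
    block_average,
    correlate,
    crookedness,
    helix_profile,
    helix_radius,
    minor_groove_width,
    pucker_phase,
    sugar_pucker,
)
from salt_twist.synthetic import (
    DuplexSpec,
    FluctuationSpec,
    build_duplex,
    make_trajectory,
    pucker_torsions,
    salt_condition,
)


class TestCrookedness:
    def test_straight_ideal_helix_beta_zero(self, ideal_conf):
        df = crookedness(ideal_conf)
        assert df["beta_deg"][0] == pytest.approx(0.0, abs=1e-5)
        assert df["h"][0] == pytest.approx(df["d"][0], abs=1e-6)

    def test_semicircular_arc_chord_over_arc(self):
        """Origins on a semicircle: h/d -> 2/pi, beta -> 50.46 deg."""
        n = 33
        spec = DuplexSpec(twist=0.0, roll=180.0 / (n - 1), rise=3.4)
        conf = build_duplex(spec)
        df = crookedness(conf)
        # discrete chord/arc oracle for an inscribed polygon
        seg = n - 1
        ratio = np.sin(np.pi / 2) / (seg * np.sin(np.pi / (2 * seg)))
        assert df["h"][0] / df["d"][0] == pytest.approx(ratio, abs=1e-6)
        assert df["beta_deg"][0] == pytest.approx(np.degrees(np.arccos(2 / np.pi)), abs=0.5)

    def test_clamp_no_nan(self, small_spec):
        """Shift/slide noise can push h marginally above sum(rise): clamped."""
        traj = make_trajectory(small_spec, FluctuationSpec(n_frames=50, seed=2))
        df = crookedness(traj)
        assert np.all(np.isfinite(df["beta_deg"]))
        assert np.all(df["beta_deg"] >= 0.0)

    def test_h_bounded_by_polyline_length(self, small_spec):
        traj = make_trajectory(small_spec, FluctuationSpec(n_frames=50, seed=3))
        df = crookedness(traj, d_estimator="polyline")
        assert np.all(df["h"] <= df["d"] + 1e-9)

    def test_invariant_under_rigid_motion(self, fluct_traj, rng):
        R = rotation_about_axis(np.array([1.0, 1.0, 1.0]) / np.sqrt(3), 37.0)
        a = crookedness(fluct_traj)
        b = crookedness(fluct_traj.transformed(R, (4.0, 5.0, 6.0)))
        np.testing.assert_allclose(a["beta_deg"], b["beta_deg"], atol=1e-9)


class TestHelixRadius:
    def test_scales_with_radial_P_offset(self, small_conf):
        """Scaling P positions radially from the axis scales the radius."""
        r0 = helix_radius(small_conf)[0]
        out = steps_of(small_conf)
        origins = out["bp_origins"][0]
        axis_dir = (origins[-1] - origins[0]) / np.linalg.norm(origins[-1] - origins[0])
        conf = small_conf.transformed(np.eye(3))
        mask = conf.topology.select("P")
        p = conf.coords[mask]
        # radial expansion about the (straight) axis
        foot = origins[0] + ((p - origins[0]) @ axis_dir)[:, None] * axis_dir
        conf.coords[mask] = foot + 1.1 * (p - foot)
        assert helix_radius(conf)[0] == pytest.approx(1.1 * r0, rel=1e-3)

    def test_matches_brute_force_segment_oracle(self, fluct_traj):
        out = steps_of(fluct_traj)
        fast = helix_radius(fluct_traj)
        f = 7
        origins = out["bp_origins"][f]
        p_atoms = fluct_traj.coords[f][fluct_traj.topology.select("P")]

        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
            return np.linalg.norm(p - (a + t * ab))

        slow = np.mean(
            [min(seg_dist(p, origins[i], origins[i + 1]) for i in range(len(origins) - 1)) for p in p_atoms]
        )
        assert fast[f] == pytest.approx(slow, abs=1e-12)

    def test_requires_phosphates(self, small_conf):
        import copy

        top = small_conf.topology
        mask = ~top.select("P")
        from salt_twist.model import DuplexConformation, DuplexTopology

        stripped = DuplexTopology(
            top.sequence, top.chain_id[mask], top.res_id[mask], top.res_name[mask],
            top.atom_name[mask], top.element[mask],
        )
        conf = DuplexConformation(stripped, small_conf.coords[mask])
        with pytest.raises(ValueError, match="phosphorus"):
            helix_radius(conf)


class TestSugarPucker:
    def test_inverse_identity_examples(self):
        for P0, amp in [(162.0, 38.0), (18.0, 40.0)]:
            nu = pucker_torsions(np.array([P0]), np.array([amp]))
            P, numax = pucker_phase(nu)
            assert P[0] == pytest.approx(P0, abs=1e-9)
            assert numax[0] == pytest.approx(amp, abs=1e-9)

    def test_exhaustive_round_trip_sweep(self):
        P0 = np.arange(0.0, 360.0, 10.0)
        nu = pucker_torsions(P0, np.full_like(P0, 38.0))
        P, numax = pucker_phase(nu)
        assert np.abs(P - P0).max() < 1e-9
        np.testing.assert_allclose(numax, 38.0, atol=1e-9)

    def test_coordinate_level_recovery(self):
        """Pucker measured from built sugar coordinates matches the spec."""
        spec = DuplexSpec(sequence="GATTAC", pucker_P=152.0)
        conf = build_duplex(spec)
        P, numax = sugar_pucker(conf, "A", 3)
        assert P == pytest.approx(152.0, abs=1e-6)
        assert numax == pytest.approx(38.0, abs=1e-6)

    def test_degenerate_flagged(self):
        P, numax = pucker_phase(np.zeros(5))
        assert np.isnan(P) and np.isnan(numax)


class TestMinorGroove:
    def test_uniform_along_ideal_helix(self, ideal_conf):
        df = minor_groove_width(ideal_conf)
        mid = df[(df["position"] > 8) & (df["position"] < 26)]
        assert mid["width_A"].std() < 0.1

    def test_radial_compression_narrows_groove(self, small_conf):
        df0 = minor_groove_width(small_conf)
        conf = small_conf.transformed(np.eye(3))
        out = steps_of(small_conf)
        origins = out["bp_origins"][0]
        axis_dir = (origins[-1] - origins[0]) / np.linalg.norm(origins[-1] - origins[0])
        mask = conf.topology.select("P")
        p = conf.coords[mask]
        foot = origins[0] + ((p - origins[0]) @ axis_dir)[:, None] * axis_dir
        radial = p - foot
        conf.coords[mask] = foot + radial * (1.0 - 1.0 / np.linalg.norm(radial, axis=1))[:, None]
        df1 = minor_groove_width(conf)
        assert df1["width_A"].mean() < df0["width_A"].mean()

    def test_window_search_equals_all_pairs_minimum(self, small_conf):
        """An unbounded window reproduces the brute-force all-pairs minimum."""
        n = small_conf.n_bp
        df = minor_groove_width(small_conf, window=(-(n + 1), n + 1))
        top = small_conf.topology
        pa = {r: small_conf.atom("A", r, "P") for r in range(1, n + 1)}
        pb = {r: small_conf.atom("B", r, "P") for r in range(1, n + 1)}
        for _, row in df.iterrows():
            i = int(row["position"])
            brute = min(np.linalg.norm(pa[i] - q) for q in pb.values())
            assert row["width_A"] == pytest.approx(brute - 5.8, abs=1e-9)

    def test_too_short_rejected(self):
        conf = build_duplex(DuplexSpec(sequence="ACG"))
        with pytest.raises(ValueError, match="too short"):
            minor_groove_width(conf)


class TestBiBii:
    def test_built_duplex_has_uniform_substate(self, small_conf):
        """Fixed idealized backbone internals give one substate everywhere."""
        frac = bi_bii_fraction(small_conf)
        assert frac in (0.0, 1.0)

    def test_counting_mixed_assignment(self, small_conf):
        diff = backbone_epsilon_zeta(small_conf)
        # synthetic assignment: 30% of steps at -90, 70% at +90
        n = diff.shape[-1]
        k = int(round(0.3 * n))
        synthetic = np.where(np.arange(n) < k, -90.0, 90.0)[None, :]
        assert float((synthetic < 0).mean()) == pytest.approx(k / n)


class TestBlockAverage:
    def test_constant_series_zero_se(self):
        t = np.arange(0.0, 1000.0, 0.1)
        ba = block_average(np.full_like(t, 5.0), t, block_ns=200.0, equilibration_ns=200.0)
        assert ba.mean == pytest.approx(5.0)
        assert ba.se == 0.0
        assert ba.n_blocks == 4

    def test_iid_gaussian_matches_clt(self):
        """Block SE approximates sigma/sqrt(N) for iid data (50 seeds)."""
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.arange(20000) * 1.0
            x = rng.normal(0.0, 1.0, t.shape)
            ba = block_average(x, t, block_ns=1000.0, equilibration_ns=0.0)
            ratios.append(ba.se / (1.0 / np.sqrt(len(x))))
        assert 0.7 < np.mean(ratios) < 1.3

    def test_ar1_series_inflates_se(self):
        rng = np.random.default_rng(0)
        n = 20000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = 0.95 * x[i - 1] + rng.normal() * np.sqrt(1 - 0.95**2)
        t = np.arange(n) * 1.0
        ba = block_average(x, t, block_ns=1000.0, equilibration_ns=0.0)
        naive = x.std(ddof=1) / np.sqrt(n)
        assert ba.se > 2.0 * naive

    def test_needs_two_complete_blocks(self):
        t = np.arange(0.0, 300.0, 1.0)
        with pytest.raises(ValueError, match="blocks"):
            block_average(np.ones_like(t), t, block_ns=200.0, equilibration_ns=0.0)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1) == pytest.approx(1.0)
        assert correlate(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=(2, 50))
        r = correlate(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        ref = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        assert r == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(correlate(np.ones(5), np.arange(5.0)))


class TestSaltResponsePattern:
    def test_twist_up_radius_down_beta_down(self, small_spec):
        """The salt-condition ladder reproduces the twist/radius/beta signs."""
        from salt_twist.synthetic import salt_condition_fluct

        base = salt_condition(small_spec, 0.0)
        high = salt_condition(small_spec, 1.8)
        fl = FluctuationSpec(n_frames=150)
        t_lo = make_trajectory(base, salt_condition_fluct(fl, 0.0, seed=21))
        t_hi = make_trajectory(high, salt_condition_fluct(fl, 1.8, seed=22))
        p_lo, p_hi = helix_profile(t_lo, groove=False), helix_profile(t_hi, groove=False)
        assert p_hi["twist_deg_bp"].mean() > p_lo["twist_deg_bp"].mean()
        assert p_hi["radius_A"].mean() < p_lo["radius_A"].mean()
        assert p_hi["beta_deg"].mean() < p_lo["beta_deg"].mean()
        assert p_hi["pucker_deg"].mean() > p_lo["pucker_deg"].mean()


class TestProfileInvariance:
    def test_observables_invariant_under_rigid_motion(self, fluct_traj):
        R = rotation_about_axis(np.array([0.0, 1.0, 0.0]), 61.0)
        a = helix_profile(fluct_traj, groove=True)
        b = helix_profile(fluct_traj.transformed(R, (1.0, -2.0, 3.0)), groove=True)
        for col in ("beta_deg", "radius_A", "pucker_deg", "groove_A", "twist_deg_bp"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-9)
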