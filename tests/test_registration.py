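import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csvmtk import (PhantomSpec, RegParams, RigidTransform2D, block_match,
                    boost_match_weights, cluster_fuzzy_pixels,
                    estimate_rigid_transform, make_brain_phantom,
                    make_motion_series, recursive_similarity,
                    register_time_series, to_polar_output)
from csvmtk.errors import DegenerateFitError
from csvmtk.metrics import probe_grid, target_registration_error
from csvmtk.registration import BlockMatches
from csvmtk.transforms import grid_center
from oracles import rigid_procrustes_closed_form


class TestClustering:
    def test_identical_points_single_cluster_at_the_point(self):
        pts = np.full((6, 2), 3.0)
        cs = cluster_fuzzy_pixels(pts, RegParams(seed=0))
        assert cs.n_clusters == 1
        assert np.allclose(cs.centers[0], (3.0, 3.0))
        assert (cs.memberships == 0).all()

    def test_two_separated_blobs_recovered(self, rng):
        b1 = rng.normal((10, 10), 1.0, (40, 2))
        b2 = rng.normal((40, 40), 1.0, (40, 2))
        cs = cluster_fuzzy_pixels(np.vstack([b1, b2]),
                                  RegParams(m_threshold=5.0, seed=0))
        assert cs.n_clusters == 2
        found = {tuple(np.round(c)) for c in cs.centers}
        for blob in (b1, b2):
            mean = blob.mean(axis=0)
            assert min(np.linalg.norm(c - mean) for c in cs.centers) <= 1.0

    def test_close_blobs_merge_into_one_cluster(self, rng):
        b1 = rng.normal((10, 10), 1.0, (40, 2))
        b2 = rng.normal((13, 10), 1.0, (40, 2))
        cs = cluster_fuzzy_pixels(np.vstack([b1, b2]),
                                  RegParams(m_threshold=5.0, seed=0))
        assert cs.n_clusters == 1

    def test_centers_separated_by_merge_threshold(self, rng):
        pts = rng.uniform(0, 60, (150, 2))
        params = RegParams(m_threshold=8.0, seed=2)
        cs = cluster_fuzzy_pixels(pts, params)
        if cs.n_clusters > 1:
            d = np.linalg.norm(cs.centers[:, None] - cs.centers[None, :],
                               axis=2)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= params.m_threshold
        assert (cs.memberships >= 0).all()

    def test_permutation_of_inputs_leaves_centers_stable(self, rng):
        pts = np.vstack([rng.normal((10, 10), 1.0, (30, 2)),
                         rng.normal((40, 40), 1.0, (30, 2))])
        params = RegParams(seed=4)
        a = cluster_fuzzy_pixels(pts, params)
        b = cluster_fuzzy_pixels(pts[rng.permutation(len(pts))], params)
        assert a.n_clusters == b.n_clusters
        for c in a.centers:
            assert min(np.linalg.norm(c - c2) for c2 in b.centers) < params.tau


class TestRecursion:
    def test_unit_increments_hand_values(self):
        trace = recursive_similarity([1.0, 1.0, 1.0], 0.5)
        assert np.allclose(trace.values, [1.0, 1.5, 1.75])

    def test_vanishing_phi_returns_increments(self):
        inc = [0.3, 0.9, 0.1]
        trace = recursive_similarity(inc, 1e-12)
        assert np.allclose(trace.values, inc)

    def test_constant_increments_converge_to_geometric_limit(self):
        c, phi = 0.8, 0.5
        trace = recursive_similarity([c] * 50, phi)
        assert trace.values[-1] == pytest.approx(c / (1 - phi), rel=0.01)

    @given(st.lists(st.floats(-1.0, 1.0), min_size=1, max_size=30),
           st.floats(0.05, 0.95))
    def test_bounded_increments_give_bounded_accumulation(self, inc, phi):
        bound = max(abs(v) for v in inc)
        trace = recursive_similarity(inc, phi)
        assert np.all(np.abs(trace.values) <= bound / (1 - phi) + 1e-9)


@pytest.fixture(scope="module")
def textured():
    return make_brain_phantom(PhantomSpec(noise_fraction=0.0,
                                          seed=7)).intensity


class TestBlockMatch:

    def test_circular_shift_recovered_by_most_blocks(self, textured):
        moving = np.roll(textured, (2, 0), axis=(0, 1))
        m = block_match(textured, moving, RegParams())
        agree = np.all(np.round(m.displacements) == [2, 0], axis=1)
        assert agree.mean() >= 0.9

    def test_identity_matching_is_exact(self, textured):
        m = block_match(textured, textured, RegParams())
        assert np.allclose(m.displacements, 0.0)
        assert np.allclose(m.ncc, 1.0)

    def test_constant_image_all_blocks_flat(self):
        m = block_match(np.ones((64, 64)), np.ones((64, 64)), RegParams())
        assert len(m) == 0
        assert m.n_flat == 16 * 16

    def test_shape_mismatch_rejected(self, textured):
        with pytest.raises(ValueError):
            block_match(textured, textured[:-2], RegParams())


class TestBoostWeights:
    def synthetic_matches(self, rng, n=60, corrupt=0):
        centers = rng.uniform(10, 80, (n, 2))
        disp = np.tile([1.5, -0.5], (n, 1)) + rng.normal(0, 0.05, (n, 2))
        ncc = np.clip(rng.normal(0.95, 0.02, n), -1, 1)
        bad = np.zeros(n, dtype=bool)
        if corrupt:
            bad[rng.choice(n, corrupt, replace=False)] = True
            disp[bad] += rng.uniform(5, 8, (corrupt, 2)) \
                * rng.choice([-1, 1], (corrupt, 2))
            ncc[bad] -= 0.4
        return BlockMatches(
            centers=centers, displacements=disp, ncc=ncc,
            similarity=ncc.copy(), grad_energy=rng.uniform(0.1, 1.0, n),
            accepted=np.ones(n, dtype=bool)), bad

    def test_pure_translation_field_all_weights_high(self, rng):
        matches, _ = self.synthetic_matches(rng)
        w = boost_match_weights(matches, RegParams(seed=0))
        assert (w >= 0.5).all()

    def test_corrupted_matches_down_weighted(self, rng):
        matches, bad = self.synthetic_matches(rng, corrupt=12)
        w = boost_match_weights(matches, RegParams(seed=0))
        assert w[bad].mean() < w[~bad].mean()

    def test_single_round_reduces_to_one_stump(self, rng):
        from sklearn.tree import DecisionTreeClassifier
        matches, bad = self.synthetic_matches(rng, corrupt=12)
        params = RegParams(n_iters=10, iter_step=10, seed=0)
        w = boost_match_weights(matches, params)
        d = matches.displacements
        med = np.median(d, axis=0)
        desc = np.column_stack([matches.ncc, matches.grad_energy,
                                np.linalg.norm(d - med, axis=1)])
        labels = np.max(np.abs(d - med), axis=1) <= 1.0
        stump = DecisionTreeClassifier(max_depth=1, random_state=0)
        stump.fit(desc, labels)
        assert np.array_equal(w > 0.5, stump.predict(desc))


class TestRigidFit:
    def test_pure_translation_exact(self, rng):
        src = rng.uniform(0, 50, (20, 2))
        t = estimate_rigid_transform(src, src + [-2.0, 3.0],
                                     center=(25.0, 25.0))
        assert t.tx == pytest.approx(3.0, abs=1e-9)
        assert t.ty == pytest.approx(-2.0, abs=1e-9)
        assert t.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_rotation_translation_matches_procrustes_oracle(self, rng):
        center = (20.0, 20.0)
        truth = RigidTransform2D(tx=1.0, ty=1.0, angle_deg=5.0)
        src = rng.uniform(0, 40, (25, 2))
        dst = truth.apply(src, center)
        est = estimate_rigid_transform(src, dst, center=center)
        assert est.tx == pytest.approx(1.0, abs=1e-8)
        assert est.ty == pytest.approx(1.0, abs=1e-8)
        assert est.angle_deg == pytest.approx(5.0, abs=1e-8)
        angle_o, t_o = rigid_procrustes_closed_form(src, dst)
        assert est.angle_deg == pytest.approx(angle_o, abs=1e-8)

    def test_weight_rescaling_leaves_fit_unchanged(self, rng):
        src = rng.uniform(0, 40, (15, 2))
        dst = RigidTransform2D(0.5, -1.0, 2.0).apply(src, (20, 20))
        w = rng.uniform(0.1, 1.0, 15)
        a = estimate_rigid_transform(src, dst, w, center=(20, 20))
        b = estimate_rigid_transform(src, dst, 2.0 * w, center=(20, 20))
        assert a.tx == pytest.approx(b.tx)
        assert a.ty == pytest.approx(b.ty)
        assert a.angle_deg == pytest.approx(b.angle_deg)

    def test_coincident_points_rejected(self):
        pts = np.tile([5.0, 5.0], (4, 1))
        with pytest.raises(DegenerateFitError):
            estimate_rigid_transform(pts, pts + 1.0)


class TestPolarOutput:
    def test_pole_case(self):
        p = to_polar_output((0.0, 0.0, 1.0))
        assert (p.radius, p.gamma_deg, p.phi_deg) == (1.0, 0.0, 0.0)
        assert np.allclose(p.cartesian, (0.0, 0.0, 1.0), atol=1e-12)

    def test_equatorial_diagonal(self):
        p = to_polar_output((1.0, 1.0, 0.0))
        assert p.radius == pytest.approx(np.sqrt(2.0))
        assert p.gamma_deg == pytest.approx(90.0)
        assert p.phi_deg == pytest.approx(45.0)

    def test_round_trip_identity_for_random_vectors(self, rng):
        for _ in range(100):
            v = rng.normal(size=3)
            p = to_polar_output(v)
            assert np.allclose(p.cartesian, v, atol=1e-9)

    def test_zero_vector_convention_and_gate(self):
        p = to_polar_output((0.0, 0.0), gate_value=-0.1)
        assert (p.radius, p.gamma_deg, p.phi_deg) == (0.0, 0.0, 0.0)
        assert p.gate is True
        assert to_polar_output((1.0, 0.0), gate_value=0.5).gate is False


class TestRegisterSeries:
    def test_static_series_recovers_identity(self, motion_base):
        series = make_motion_series(motion_base, 4, max_shift_px=0.0,
                                    max_rot_deg=0.0, seed=1)
        result = register_time_series(series, RegParams(seed=1),
                                      compute_diagnostics=False)
        for t in result.transforms:
            shift, ang = t.magnitude()
            assert shift < 1e-6 and ang < 1e-6

    def test_noiseless_series_tre_below_half_pixel(self, registered_noiseless):
        assert registered_noiseless["result"].diagnostics["mean_tre_px"] <= 0.5

    def test_noisy_series_tre_below_one_pixel(self, registered_noisy):
        assert registered_noisy["result"].diagnostics["mean_tre_px"] <= 1.0

    def test_translation_rotation_recovery_over_seed_family(self, motion_base):
        """Mean per-parameter recovery error over 10 seeded series."""
        t_errs, a_errs = [], []
        for seed in range(10):
            series = make_motion_series(motion_base, 4, max_shift_px=3.0,
                                        max_rot_deg=2.0, seed=200 + seed)
            result = register_time_series(series, RegParams(seed=seed),
                                          compute_diagnostics=False)
            for est, tru in zip(result.transforms[1:],
                                series.truth_transforms[1:]):
                t_errs.extend([abs(est.tx - tru.tx), abs(est.ty - tru.ty)])
                a_errs.append(abs(est.angle_deg - tru.angle_deg))
        assert np.mean(t_errs) <= 0.25
        assert np.mean(a_errs) <= 0.25

    def test_inverse_consistency_between_frame_pairs(self, motion_base):
        series = make_motion_series(motion_base, 2, max_shift_px=2.0,
                                    max_rot_deg=1.0, seed=42)
        forward = register_time_series(series.frames, RegParams(seed=0),
                                       compute_diagnostics=False)
        backward = register_time_series(series.frames[::-1],
                                        RegParams(seed=0),
                                        compute_diagnostics=False)
        comp = forward.transforms[1].then(backward.transforms[1])
        center = grid_center(motion_base.shape)
        probes = probe_grid(motion_base.shape)
        residual = target_registration_error(
            comp, RigidTransform2D(), probes, center)
        assert residual <= 0.5

    def test_diagnostics_report_clusters_and_polar(self, motion_base):
        series = make_motion_series(motion_base, 3, max_shift_px=2.0,
                                    seed=6)
        result = register_time_series(series, RegParams(seed=6))
        frame_info = result.diagnostics["frames"][1]
        assert "cluster_centers" in frame_info
        assert frame_info["polar"]["radius"] >= 0.0
        assert len(result.diagnostics["tre_px"]) == 3
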