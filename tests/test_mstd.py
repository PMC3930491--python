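"""Spiral templates, matching, gain fields, and the competitive dynamics."""

import numpy as np
import pytest

from spiralpath.camera import CameraModel
from spiralpath.mstd import (
    LESION_POOLS,
    MSTdNetwork,
    ModelParams,
    NoEstimateError,
    TemplateBankConfig,
    apply_gain_field,
    build_template_bank,
    lesion,
    make_template,
    match_score,
    match_scores,
    readout_curvature,
    readout_heading,
    run_trial,
    step_dynamics,
    transfer,
)
from spiralpath.mstd import ActivityState
from spiralpath.stimulus import (
    FlowField,
    make_circular_trajectory,
    make_scene,
    make_straight_rotation_trajectory,
    rotational_flow,
)


def flow_from_template(template, n=50, seed=0, spread=1.0, mags=None):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(-spread, spread, size=(n, 2))
    uv = template.field(xy)
    if mags is not None:
        uv = uv * mags[:, None]
    return FlowField(0, xy, uv, np.arange(n))


class TestSpiralTemplate:
    def test_expansion_points_away_from_com(self):
        t = make_template(0.0, (0.2, -0.1))
        pts = np.array([[1.0, 0.0], [0.2, 1.2], [-0.5, -0.8]])
        vecs = t.field(pts)
        rel = pts - np.array(t.com)
        rel /= np.linalg.norm(rel, axis=1, keepdims=True)
        assert np.allclose(vecs, rel, atol=1e-12)

    def test_ccw_center_is_perpendicular_ccw(self):
        t = make_template(np.pi / 2.0, (0.0, 0.0))
        v = t.field(np.array([[1.0, 0.0]]))[0]
        assert np.allclose(v, [0.0, 1.0], atol=1e-12)  # +90 deg from radial

    def test_unit_length_everywhere_except_com(self):
        rng = np.random.default_rng(1)
        t = make_template(1.234, (0.3, 0.4))
        pts = rng.uniform(-2, 2, size=(200, 2))
        norms = np.linalg.norm(t.field(pts), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)
        assert np.allclose(t.field(np.array([t.com])), 0.0)

    def test_radial_and_center_templates_pointwise_orthogonal(self):
        rng = np.random.default_rng(2)
        radial = make_template(0.0, (0.1, -0.2))
        center = make_template(np.pi / 2.0, (0.1, -0.2))
        pts = rng.uniform(-2, 2, size=(100, 2))
        dots = np.einsum("ij,ij->i", radial.field(pts), center.field(pts))
        assert np.allclose(dots, 0.0, atol=1e-12)

    def test_45_degree_spiral_angle(self):
        # derived: at every point the spiral field sits 45 deg from radial
        rng = np.random.default_rng(3)
        spiral = make_template(np.pi / 4.0, (0.0, 0.0))
        radial = make_template(0.0, (0.0, 0.0))
        pts = rng.uniform(-2, 2, size=(100, 2))
        cosang = np.einsum("ij,ij->i", spiral.field(pts), radial.field(pts))
        assert np.allclose(np.degrees(np.arccos(cosang)), 45.0, atol=1e-9)

    def test_spirality_and_orientation_labels(self):
        assert make_template(0.0, (0, 0)).spirality == 0.0
        assert make_template(np.pi / 2, (0, 0)).spirality == pytest.approx(1.0)
        assert make_template(np.pi / 2, (0, 0)).orientation == "ccw"
        assert make_template(3 * np.pi / 2, (0, 0)).orientation == "cw"
        assert make_template(np.pi, (0, 0)).spirality == 0.0
        assert make_template(np.pi, (0, 0)).sense == "contract"
        assert make_template(np.pi / 4, (0, 0)).spirality == pytest.approx(0.5)


class TestTemplateBank:
    def test_default_bank_enumerates_11500_units(self, camera):
        bank = build_template_bank(camera=camera)
        assert bank.n_units == 11500
        assert (bank.n_pattern, bank.n_com) == (23, 500)

    def test_single_unit_bank(self, camera):
        bank = build_template_bank(TemplateBankConfig(1, 1, 1), camera)
        assert bank.n_units == 1

    @pytest.mark.parametrize("shape", [(3, 4, 5), (7, 2, 2), (1, 6, 3)])
    def test_unit_count_is_grid_product(self, camera, shape):
        np_, nx, ny = shape
        bank = build_template_bank(TemplateBankConfig(np_, nx, ny), camera)
        assert bank.n_units == np_ * nx * ny

    def test_com_grid_spans_beyond_fov(self, camera):
        bank = build_template_bank(camera=camera)
        assert bank.coms[:, 0].max() == pytest.approx(1.5 * camera.half_width)
        assert bank.coms[:, 1].max() == pytest.approx(1.5 * camera.half_height)


class TestGainField:
    def test_zero_eye_velocity_is_identity(self, camera):
        flow = flow_from_template(make_template(0.3, (0, 0)), 30, 1)
        assert apply_gain_field(flow, 0.0, 1.0, camera) is flow

    def test_full_gain_cancels_pursuit_rotation(self, camera, ground_scene):
        # flow of straight travel + camera rotation rho, compensated with
        # g=1 and eye velocity rho, equals the rotation-free flow
        rho = 0.08  # rad/s, leftward yaw
        with_rot = make_straight_rotation_trajectory(2.0, -rho)  # yaw rate +rho
        no_rot = make_straight_rotation_trajectory(2.0, 0.0)
        from spiralpath.stimulus import compute_flow

        f_rot = compute_flow(ground_scene, with_rot, camera, 0)
        f_clean = compute_flow(ground_scene, no_rot, camera, 0)
        comp = apply_gain_field(f_rot, rho, 1.0, camera)
        # frame 0: identical poses, identical visible sets
        assert np.array_equal(f_rot.dot_indices, f_clean.dot_indices)
        assert np.max(np.abs(comp.uv - f_clean.uv)) < 1e-6

    def test_partial_gain_reduces_residual_rotation(self, camera, ground_scene):
        rho = 0.1
        traj = make_straight_rotation_trajectory(2.0, -rho)
        from spiralpath.stimulus import compute_flow

        flow = compute_flow(ground_scene, traj, camera, 0)
        clean = compute_flow(
            ground_scene, make_straight_rotation_trajectory(2.0, 0.0), camera, 0
        )
        before = np.linalg.norm(flow.uv - clean.uv)
        after = np.linalg.norm(
            apply_gain_field(flow, rho, 0.7, camera).uv - clean.uv
        )
        assert after < before


class TestMatchScore:
    def test_aligned_flow_is_maximal_over_shared_com(self, camera):
        bank = build_template_bank(TemplateBankConfig(12, 1, 1), camera)
        gen = bank.template(4)
        flow = flow_from_template(gen, 60, 2)
        scores = [match_score(flow, bank.template(u), 20.0, camera)
                  for u in range(bank.n_units)]
        assert int(np.argmax(scores)) == 4
        assert scores[4] > 0

    def test_radial_flow_vs_center_template_is_zero(self, camera):
        radial = make_template(0.0, (0.1, 0.2))
        center = make_template(np.pi / 2.0, (0.1, 0.2))
        flow = flow_from_template(radial, 40, 3)
        assert match_score(flow, center, 20.0, camera) == pytest.approx(0.0, abs=1e-12)

    def test_matches_scalar_loop_oracle(self, camera):
        rng = np.random.default_rng(4)
        xy = rng.uniform(-1, 1, size=(30, 2))
        uv = rng.normal(size=(30, 2))
        uv[5] = 0.0  # zero-length vector contributes nothing
        flow = FlowField(0, xy, uv, np.arange(30))
        template = make_template(2.2, (0.4, -0.3))
        sig = camera.deg_to_image(12.0)
        expected = 0.0
        for i in range(30):
            n = np.hypot(*uv[i])
            if n < 1e-15:
                continue
            d = np.hypot(xy[i, 0] - 0.4, xy[i, 1] + 0.3)
            tvec = template.field(xy[i : i + 1])[0]
            expected += np.exp(-d / sig) * float(uv[i] @ tvec) / n
        expected /= 30
        got = match_score(flow, template, 12.0, camera)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bank_scores_agree_with_single_template_scores(self, camera):
        bank = build_template_bank(TemplateBankConfig(5, 3, 2), camera)
        rng = np.random.default_rng(5)
        flow = FlowField(0, rng.uniform(-1, 1, (25, 2)), rng.normal(size=(25, 2)),
                         np.arange(25))
        S = match_scores(flow, bank, 15.0, camera)
        for u in (0, 7, 13, 29):
            ci, pi = divmod(u, bank.n_pattern)
            assert S[ci, pi] == pytest.approx(
                match_score(flow, bank.template(u), 15.0, camera), abs=1e-12
            )

    def test_score_bounded_by_one(self, camera):
        rng = np.random.default_rng(6)
        bank = build_template_bank(TemplateBankConfig(7, 3, 3), camera)
        for k in range(50):
            n = int(rng.integers(1, 40))
            flow = FlowField(0, rng.uniform(-2, 2, (n, 2)), rng.normal(size=(n, 2)),
                             np.arange(n))
            S = match_scores(flow, bank, float(rng.uniform(2, 30)), camera)
            assert np.all(np.abs(S) <= 1.0 + 1e-12)

    def test_empty_flow_is_undefined(self, camera):
        empty = FlowField(0, np.empty((0, 2)), np.empty((0, 2)), np.empty(0, int))
        with pytest.raises(ValueError):
            match_score(empty, make_template(0.0, (0, 0)), 20.0, camera)


class TestTransfer:
    def test_at_or_below_threshold_is_zero(self):
        assert transfer(0.01) == 0.0
        assert transfer(-5.0) == 0.0
        assert transfer(0.0) == 0.0

    def test_half_saturation_at_gamma_plus_beta(self):
        assert transfer(0.01 + 0.07) == pytest.approx(0.5)

    def test_monotone_and_saturating(self):
        xs = np.linspace(-1, 20, 500)
        ys = transfer(xs)
        assert np.all(np.diff(ys) >= -1e-15)
        assert transfer(1000.0) == pytest.approx(1.0, abs=1e-6)


class TestDynamics:
    def test_zero_input_zero_state_is_fixed_point(self, small_bank, params):
        net = MSTdNetwork(small_bank, params)
        z = net.initial_state()
        S = np.zeros_like(z)
        for _ in range(20):
            z = net.step(z, S, 0.01)
        assert np.allclose(z, 0.0)

    def test_passive_decay_toward_zero(self, small_bank, params):
        net = MSTdNetwork(small_bank, params)
        z = np.full((small_bank.n_com, small_bank.n_pattern), 0.4)
        S = np.zeros_like(z)
        prev = z.copy()
        for _ in range(50):
            z = net.step(z, S, 0.02)
            assert np.all(z <= prev + 1e-12)
            prev = z.copy()
        assert np.all(z < 0.05)

    def test_activities_stay_bounded(self, small_bank, params):
        rng = np.random.default_rng(7)
        net = MSTdNetwork(small_bank, params)
        z = net.initial_state()
        for _ in range(100):
            S = rng.uniform(-1, 1, size=z.shape)
            z = net.step(z, S, 0.01)
            assert np.all((z >= 0.0) & (z <= params.U))

    def test_winner_matches_input_argmax_in_toy_network(self, camera, params):
        # derived oracle: long fine-step explicit Euler integration of a
        # 3-unit network under unequal constant inputs
        bank = build_template_bank(TemplateBankConfig(3, 1, 1), camera)
        net = MSTdNetwork(bank, params)
        S = np.array([[0.15, 0.08, 0.03]])

        def euler(z, dt, steps):
            for _ in range(steps):
                F = transfer(z, params.gamma, params.beta)
                inhib = (F @ net._same.T) + (F @ net._opp.T)
                excit = F + transfer(S, params.gamma, params.beta)
                dz = params.A * (
                    -params.D * z + (params.U - z) * excit - z * inhib
                )
                z = np.clip(z + dt * dz, 0.0, params.U)
            return z

        z_oracle = euler(np.zeros((1, 3)), 1e-3, 40000)
        z_net = net.initial_state()
        for _ in range(4000):
            z_net = net.step(z_net, S, 0.01)
        assert int(np.argmax(z_net)) == int(np.argmax(S)) == int(np.argmax(z_oracle))
        assert np.allclose(z_net, z_oracle, atol=5e-3)
        # the sub-threshold loser is quenched far below the winner; the
        # runner-up is contrast-reduced (soft winner-take-all)
        assert z_net[0, 2] < 0.1 * z_net[0, 0]
        assert z_net[0, 1] < z_net[0, 0]

    def test_soft_wta_ratio_nondecreasing(self, camera, params):
        bank = build_template_bank(TemplateBankConfig(4, 1, 1), camera)
        net = MSTdNetwork(bank, params)
        S = np.array([[0.25, 0.20, 0.12, 0.05]])
        z = net.initial_state()
        ratios = []
        for step in range(2000):  # 20 s = 20 time constants at A = 1
            z = net.step(z, S, 0.01)
            top2 = np.sort(z.ravel())[-2:]
            if top2[0] > 1e-9:
                ratios.append(top2[1] / top2[0])
        tail = ratios[len(ratios) // 4 :]
        assert all(b >= a - 1e-6 for a, b in zip(tail, tail[1:]))

    def test_step_dynamics_wrapper(self, small_bank, params):
        z = np.zeros((small_bank.n_com, small_bank.n_pattern))
        S = np.full_like(z, 0.2)
        out = step_dynamics(z, S, small_bank, params, 0.01)
        assert out.shape == z.shape
        assert np.all(out >= 0)

    def test_nonfinite_state_raises(self, small_bank, params):
        net = MSTdNetwork(small_bank, params)
        z = net.initial_state()
        z[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            net.step(z, np.zeros_like(z), 0.01)


class TestLesion:
    def test_unknown_pool_rejected(self, params):
        with pytest.raises(ValueError):
            lesion(params, "feedback")

    def test_lesion_and_restore_round_trip(self, params):
        lesioned = lesion(params, "spatial")
        assert "spatial" in lesioned.lesions
        from dataclasses import replace

        restored = replace(lesioned, lesions=())
        assert restored == params

    def test_spatial_lesion_zeroes_spatial_term(self, camera, params):
        bank = build_template_bank(TemplateBankConfig(2, 2, 1), camera)
        rng = np.random.default_rng(8)
        z = rng.uniform(0.1, 0.5, size=(2, 2))
        S = np.zeros_like(z)
        full = MSTdNetwork(bank, params).step(z.copy(), S, 0.005)
        cut = MSTdNetwork(bank, lesion(params, "spatial")).step(z.copy(), S, 0.005)
        # removing cross-CoM inhibition can only leave activities higher
        assert np.all(cut >= full - 1e-12)
        assert np.any(cut > full + 1e-9)

    def test_lesioned_trajectory_diverges_from_intact(self, camera, params):
        bank = build_template_bank(TemplateBankConfig(3, 2, 1), camera)
        S = np.array([[0.3, 0.1, 0.05], [0.2, 0.15, 0.02]])
        z_full = np.zeros_like(S)
        z_cut = np.zeros_like(S)
        net_full = MSTdNetwork(bank, params)
        net_cut = MSTdNetwork(bank, lesion(params, "orientation"))
        for _ in range(300):
            z_full = net_full.step(z_full, S, 0.01)
            z_cut = net_cut.step(z_cut, S, 0.01)
        assert not np.allclose(z_full, z_cut, atol=1e-6)


class TestReadouts:
    def _state_with_peak(self, bank, ci, pi):
        z = np.zeros((bank.n_com, bank.n_pattern))
        z[ci, pi] = 0.5
        return ActivityState(bank=bank, history=z[None], argmax_trajectory=np.array([0]))

    def test_hand_built_argmax_readout(self, camera):
        bank = build_template_bank(TemplateBankConfig(8, 5, 4), camera)
        ci, pi = 7, 3
        state = self._state_with_peak(bank, ci, pi)
        s = readout_curvature(state)
        expected = bank.spirality[pi] * bank.orientation_sign[pi]
        assert s == pytest.approx(expected)
        az, el = readout_heading(state, camera)
        cx, cy = bank.coms[ci]
        assert az == pytest.approx(np.degrees(np.arctan2(cx, 1.0)))
        assert el == pytest.approx(np.degrees(np.arctan2(cy, 1.0)))

    def test_radial_peak_reads_zero_curvature(self, camera):
        bank = build_template_bank(TemplateBankConfig(8, 3, 3), camera)
        state = self._state_with_peak(bank, 4, 0)  # pattern 0 is pure expansion
        assert readout_curvature(state) == 0.0

    def test_all_zero_activity_signals_no_estimate(self, small_bank):
        z = np.zeros((small_bank.n_com, small_bank.n_pattern))
        state = ActivityState(small_bank, z[None], np.array([0]))
        with pytest.raises(NoEstimateError):
            readout_curvature(state)

    def test_tie_breaks_toward_lower_spirality(self, camera):
        bank = build_template_bank(TemplateBankConfig(8, 3, 3), camera)
        z = np.zeros((bank.n_com, bank.n_pattern))
        z[0, 3] = 0.4
        z[0, 0] = 0.4  # radial ties with a spiral: radial wins
        state = ActivityState(bank, z[None], np.array([0]))
        assert readout_curvature(state) == 0.0


class TestRunTrial:
    def test_straight_path_peaks_radial_at_foe(self, camera, params):
        bank = build_template_bank(camera=camera)
        scene = make_scene("ground_plane", 150, (1.4, 25.0), 1.6, seed=21,
                           camera=camera)
        traj = make_straight_rotation_trajectory(2.0, 0.0)
        state = run_trial(scene, traj, camera, params, bank, record_history=False)
        assert abs(readout_curvature(state)) <= 0.2
        az, el = readout_heading(state, camera)
        assert abs(az) <= 11.0  # within one CoM grid step of the FoE

    def test_mirrored_trial_flips_orientation_and_heading(self, camera, params):
        bank = build_template_bank(camera=camera)
        scene = make_scene("ground_plane", 150, (1.4, 25.0), 1.6, seed=22,
                           camera=camera)
        mirrored = scene.mirrored_x()
        t_ccw = make_circular_trajectory(30.0, 1, 2.0 / 30.0, "gaze_along_heading")
        t_cw = make_circular_trajectory(30.0, -1, 2.0 / 30.0, "gaze_along_heading")
        s1 = run_trial(scene, t_ccw, camera, params, bank, record_history=False)
        s2 = run_trial(mirrored, t_cw, camera, params, bank, record_history=False)
        assert readout_curvature(s1) == pytest.approx(-readout_curvature(s2), abs=1e-9)
        az1, el1 = readout_heading(s1, camera)
        az2, el2 = readout_heading(s2, camera)
        assert az1 == pytest.approx(-az2, abs=1e-9)
        assert el1 == pytest.approx(el2, abs=1e-9)

    def test_activity_bounded_through_trial(self, camera, params, small_bank):
        scene = make_scene("ground_plane", 60, (1.4, 25.0), 1.6, seed=23,
                           camera=camera)
        traj = make_circular_trajectory(30.0, 1, 2.0 / 30.0, "gaze_along_heading")
        state = run_trial(scene, traj, camera, params, small_bank)
        assert np.all(state.history >= 0.0)
        assert np.all(state.history <= params.U + 1e-6)
        assert state.history.shape[0] == traj.frames
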