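import numpy as np
import pytest

from filmbend.errors import (
    DuplicateSolutionError,
    InvalidParamsError,
    RenderError,
    UnknownSolutionError,
)
from filmbend.synthetic import (
    GeneratorParams,
    SolutionComposition,
    arc_midline,
    emulate_manual_annotation,
    generate_exposure_design,
    render_frame,
    render_frames,
    simulate_session,
    solution_composition,
    standard_solutions,
    true_tip_angle,
)
from filmbend.tracking import TrackerConfig, binarize, row_midpoints
from filmbend.transients import time_to_max_deflection


def empty_flask(sid=1):
    return SolutionComposition(sid, 0.0, 0.0, 0.0, (0.0, 0.0, 0.0))


class TestCompositionTable:
    @pytest.mark.parametrize(
        "sid, volumes, fractions",
        [
            (1, (60, 0, 0), (1.0, 0.0, 0.0)),
            (2, (0, 60, 0), (0.0, 1.0, 0.0)),
            (3, (30, 30, 0), (0.5, 0.5, 0.0)),
            (4, (30, 0, 30), (0.5, 0.0, 0.5)),
            (5, (0, 30, 30), (0.0, 0.5, 0.5)),
            (6, (20, 20, 20), (1 / 3, 1 / 3, 1 / 3)),
        ],
    )
    def test_builtin_solutions(self, sid, volumes, fractions):
        c = solution_composition(sid)
        assert c.volumes_mL == volumes
        np.testing.assert_allclose(
            (c.f_acetone, c.f_ethanol, c.f_water), fractions, atol=1e-12
        )
        assert abs(c.f_acetone + c.f_ethanol + c.f_water - 1.0) < 1e-12

    def test_unknown_id(self):
        with pytest.raises(UnknownSolutionError):
            solution_composition(7)


class TestExposureDesign:
    def test_five_blocks_give_thirty_trials(self, solutions):
        d = generate_exposure_design(5, solutions, seed=1)
        assert d.n_trials == 30
        assert all(t.recovery_s == 60.0 for t in d.trials)
        assert [t.trial_index for t in d.trials] == list(range(1, 31))

    def test_each_block_is_a_permutation(self, solutions):
        d = generate_exposure_design(5, solutions, seed=3)
        ids = [t.solution_id for t in d.trials]
        for b in range(5):
            assert sorted(ids[6 * b: 6 * b + 6]) == [1, 2, 3, 4, 5, 6]

    def test_zero_blocks(self, solutions):
        d = generate_exposure_design(0, solutions, seed=1)
        assert d.n_trials == 0

    def test_deterministic_for_seed(self, solutions):
        a = generate_exposure_design(3, solutions, seed=9)
        b = generate_exposure_design(3, solutions, seed=9)
        assert [t.solution_id for t in a.trials] == [t.solution_id for t in b.trials]

    def test_duplicate_ids_rejected(self, solutions):
        with pytest.raises(DuplicateSolutionError):
            generate_exposure_design(1, [solutions[0], solutions[0]], seed=1)

    def test_block_leaders_uniform_over_seeds(self, solutions):
        """Uniform permutations: each solution leads a block 1/6 of the time."""
        leaders = [
            generate_exposure_design(1, solutions, seed=s).trials[0].solution_id
            for s in range(1000)
        ]
        freq = np.bincount(leaders, minlength=7)[1:] / 1000
        se = np.sqrt((1 / 6) * (5 / 6) / 1000)
        assert np.all(np.abs(freq - 1 / 6) <= 3 * se + 1e-12)


class TestBendingDynamics:
    def test_zero_drive_stays_at_rest(self, quiet_params):
        d = generate_exposure_design(2, [empty_flask()], seed=1, exposure_s=20.0)
        s = simulate_session(d, quiet_params, seed=2)
        np.testing.assert_allclose(s.theta, quiet_params.theta_rest0, atol=1e-9)

    def test_acetone_responds_faster_than_ethanol(self, quiet_params):
        t95 = {}
        for sid in (1, 2):  # pure acetone vs pure ethanol
            d = generate_exposure_design(
                1, [solution_composition(sid)], seed=1, exposure_s=150.0
            )
            s = simulate_session(d, quiet_params, seed=1)
            t95[sid] = time_to_max_deflection(*s.trial_segment(0)).t95_s
        assert t95[1] < t95[2]

    def test_long_exposure_asymptote(self, quiet_params):
        """Single long dry-acetone exposure converges to rest - A_deflect."""
        d = generate_exposure_design(
            1, [solution_composition(1)], seed=1, exposure_s=3000.0
        )
        s = simulate_session(d, quiet_params, seed=1)
        assert abs(s.theta[-1] - (quiet_params.theta_rest0 - quiet_params.A_deflect)) < 0.05

    def test_monotone_without_baseline_drift(self, solutions):
        p = GeneratorParams(frame_rate=5.0, sigma_theta=0.0, gamma_h=0.0)
        d = generate_exposure_design(2, solutions, seed=5, exposure_s=60.0)
        s = simulate_session(d, p, seed=5)
        for i in range(s.n_trials):
            _, th = s.trial_segment(i)
            diffs = np.diff(th)
            assert np.all(diffs <= 1e-9) or np.all(diffs >= -1e-9)

    def test_deflection_amplitude_bound(self, solutions):
        p = GeneratorParams(frame_rate=5.0, sigma_theta=0.0)
        d = generate_exposure_design(3, solutions, seed=6, exposure_s=120.0)
        s = simulate_session(d, p, seed=6)
        bound = p.A_deflect + abs(p.gamma_h) * 1.0 + 1e-9
        assert np.max(np.abs(s.theta - p.theta_rest0)) <= bound

    def test_water_exposure_shifts_pre_trial_angle(self, solutions):
        # full mechanical recovery isolates the water-driven baseline shift
        p = GeneratorParams(frame_rate=5.0, sigma_theta=0.0, k_recover=1.0)
        water_heavy = [solution_composition(4)]  # 50% water
        d = generate_exposure_design(3, water_heavy, seed=2, exposure_s=180.0)
        s = simulate_session(d, p, seed=2)
        later_starts = [s.theta[s.trial_slice(i)][0] for i in range(1, s.n_trials)]
        assert all(abs(a - p.theta_rest0) > 0.5 for a in later_starts)

    def test_history_free_limit(self):
        """With gamma_h=0, tau_h -> inf and full recovery, identical trials
        from the same start produce identical transients."""
        p = GeneratorParams(
            frame_rate=5.0, sigma_theta=0.0, gamma_h=0.0, tau_h=1e12, k_recover=1.0
        )
        d = generate_exposure_design(
            2, [solution_composition(1)], seed=5, exposure_s=60.0
        )
        s = simulate_session(d, p, seed=6)
        _, th1 = s.trial_segment(0)
        _, th2 = s.trial_segment(1)
        np.testing.assert_allclose(th1, th2, atol=1e-10)

    def test_noise_seed_determinism(self, solutions):
        p = GeneratorParams(frame_rate=5.0, sigma_theta=1.0)
        d = generate_exposure_design(1, solutions, seed=1, exposure_s=10.0)
        a = simulate_session(d, p, seed=3)
        b = simulate_session(d, p, seed=3)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidParamsError):
            GeneratorParams(k_acetone=0.01, k_ethanol=0.03).validate()
        with pytest.raises(InvalidParamsError):
            GeneratorParams(mode_weights=(0.5, 0.5, 0.5)).validate()
        with pytest.raises(InvalidParamsError):
            GeneratorParams(tau_h=float("nan")).validate()


class TestRenderer:
    def test_plumb_filament_is_vertical_bar(self, quiet_params):
        fr = render_frame(-90.0, quiet_params)
        ys, xs = np.nonzero(fr.image)
        col_mean_per_row = [xs[ys == y].mean() for y in np.unique(ys)]
        assert np.ptp(col_mean_per_row) < 1e-9

    def test_ground_truth_tip_angle_matches_request(self, quiet_params):
        for th in (-150.0, -90.0, -30.0):
            fr = render_frame(th, quiet_params)
            assert abs(true_tip_angle(fr.midline) - th) < 0.2

    def test_midline_arc_length_equals_filament_length(self, quiet_params):
        mid = arc_midline(-120.0, quiet_params)
        seg = np.diff(mid, axis=0)
        L = np.hypot(seg[:, 0], seg[:, 1]).sum()
        assert abs(L - quiet_params.filament_length_px) < 0.1

    def test_strong_curl_yields_two_cluster_rows(self, quiet_params):
        fr = render_frame(-200.0, quiet_params)  # turn from vertical > 90 deg
        cands, _ = row_midpoints(binarize(fr.image), TrackerConfig())
        assert any(len(xs) == 2 for _, xs in cands)

    def test_geometry_exceeding_canvas_raises(self, quiet_params):
        tiny = quiet_params.replace(image_height_px=100)
        with pytest.raises(RenderError, match="frame 3"):
            render_frame(-90.0, tiny, frame_index=3)

    def test_render_frames_streams_whole_series(self, solutions, quiet_params):
        d = generate_exposure_design(1, solutions[:1], seed=1, exposure_s=2.0)
        s = simulate_session(d, quiet_params, seed=1)
        frames = list(render_frames(s, quiet_params))
        assert len(frames) == len(s.times)
        assert frames[5].time_s == pytest.approx(s.times[5])


class TestManualAnnotation:
    def _midlines(self, params, angles):
        return [(i, arc_midline(a, params)) for i, a in enumerate(angles)]

    def test_noiseless_clicks_lie_on_midline(self, quiet_params):
        mids = self._midlines(quiet_params, [-120.0])
        ann = emulate_manual_annotation(mids, frame_rate=1.0, interval_s=1.0,
                                        click_sd_px=0.0, seed=1)
        mid = mids[0][1]
        for _, row in ann.iterrows():
            d = np.hypot(mid[:, 0] - row.x_px, mid[:, 1] - row.y_px).min()
            assert d < 0.75  # within the midline polyline spacing

    def test_two_points_are_endpoints(self, quiet_params):
        mids = self._midlines(quiet_params, [-90.0])
        ann = emulate_manual_annotation(mids, frame_rate=1.0, interval_s=1.0,
                                        n_points=2, click_sd_px=0.0, seed=1)
        mid = mids[0][1]
        np.testing.assert_allclose(ann.iloc[0][["x_px", "y_px"]], mid[0], atol=0.01)
        np.testing.assert_allclose(ann.iloc[1][["x_px", "y_px"]], mid[-1], atol=0.01)

    def test_click_spacing_roughly_equidistant(self, quiet_params):
        mids = self._midlines(quiet_params, [-140.0])
        ann = emulate_manual_annotation(mids, frame_rate=1.0, interval_s=1.0,
                                        click_sd_px=0.0, seed=1)
        pts = ann[["x_px", "y_px"]].to_numpy()
        gaps = np.hypot(*np.diff(pts, axis=0).T)
        assert np.ptp(gaps) / gaps.mean() < 0.10

    def test_annotation_interval_and_determinism(self, quiet_params):
        angles = np.linspace(-150, -60, 31)
        mids = self._midlines(quiet_params, angles)
        a = emulate_manual_annotation(mids, frame_rate=1.0, interval_s=5.0,
                                      click_sd_px=2.0, seed=4)
        b = emulate_manual_annotation(mids, frame_rate=1.0, interval_s=5.0,
                                      click_sd_px=2.0, seed=4)
        assert sorted(a.frame_index.unique()) == [0, 5, 10, 15, 20, 25, 30]
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
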