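"""Ground-truth generators and their closed loops with the analysis modules."""

import math

import numpy as np
import pytest
from scipy import stats

from clemq import (
    DecayParams,
    LandmarkPair,
    SceneSpec,
    detect_spots,
    eval_decay_model,
    fit_affine,
    generate_clem_scene,
    generate_fraction_data,
    generate_mgb_counts,
)
from clemq.registration import warp_points
from clemq.synthetic_data import generate_observations


class TestGenerateFractionData:
    def test_reproducible_given_seed(self, model2_params):
        obs1, cells1 = generate_fraction_data(model2_params, seed=4)
        obs2, cells2 = generate_fraction_data(model2_params, seed=4)
        assert [(o.t, o.y, o.sem) for o in obs1] == [(o.t, o.y, o.sem) for o in obs2]
        assert cells1.equals(cells2)

    def test_sem_magnitudes_at_replicate_scale(self, model2_params):
        """Replicate SEMs land within 3x of the few-per-mille dispersion
        seen in real triplicate counting experiments."""
        sems = []
        for s in range(5):
            obs, _ = generate_fraction_data(model2_params, seed=s)
            sems.extend(o.sem for o in obs)
        med = float(np.median(sems))
        assert 0.0010 / 3 <= med <= 0.0026 * 3

    def test_plateau_fraction_near_truth(self, model2_params):
        obs, _ = generate_fraction_data(model2_params, seed=8)
        early = [o.y for o in obs if o.t <= 2.0]
        assert np.mean(early) == pytest.approx(0.027, rel=0.15)

    def test_per_cell_table_consistent_with_observations(self, model2_params):
        obs, cells = generate_fraction_data(model2_params, seed=2, n_experiments=3, cells_per_group=10)
        sub = cells[cells.t_days == 5.0]
        per_exp = sub.groupby("experiment").apply(
            lambda d: d.n_labeled.sum() / d.n_granules.sum(), include_groups=False
        )
        o5 = next(o for o in obs if o.t == 5.0)
        assert o5.y == pytest.approx(per_exp.mean())
        assert o5.sem == pytest.approx(per_exp.std(ddof=1) / math.sqrt(3))

    def test_stated_sem_generator_centered_on_model(self, model2_params):
        reps = np.array([
            [o.y for o in generate_observations(model2_params, seed=s)] for s in range(200)
        ])
        truth = eval_decay_model(model2_params, np.array([0.27, 1, 2, 3, 4, 5]))
        np.testing.assert_allclose(reps.mean(axis=0), truth, atol=3 * 0.0026 / math.sqrt(200))


class TestGenerateClemScene:
    def test_ground_truth_consistency_zero_distortion(self):
        spec = SceneSpec(
            seed=10,
            n_granules=25,
            p_505=1.0,
            n_mgbs=0,
            em_noise_sd=0.0,
            flm_noise_sd=0.0,
            affine_matrix=((1.0, 0.0), (0.0, 1.0)),
            affine_translation=(0.0, 0.0),
        )
        scene = generate_clem_scene(spec)
        assert len(scene.granules) == 25
        spots = detect_spots(scene.flm_505, pixel_size_nm=spec.flm_pixel_nm)
        centers = np.array([s.centroid for s in spots])
        # every true labeled granule has a detected spot within half an FLM pixel
        for _, g in scene.granules.iterrows():
            d = np.min(np.linalg.norm(centers - np.array([g.x_nm, g.y_nm]), axis=1))
            assert d < 0.5 * spec.flm_pixel_nm

    def test_known_affine_recovered_from_beads(self):
        spec = SceneSpec(seed=3, n_mgbs=0, em_noise_sd=0.0, flm_noise_sd=0.0)
        scene = generate_clem_scene(spec)
        lms = [
            LandmarkPair((r.x_flm_nm, r.y_flm_nm), (r.x_em_nm, r.y_em_nm))
            for r in scene.beads.itertuples()
        ]
        warp = fit_affine(lms)
        # fitted FLM->EM must invert the applied EM->FLM distortion
        recovered = np.linalg.inv(warp.matrix)
        np.testing.assert_allclose(recovered, np.asarray(spec.affine_matrix), rtol=1e-3)
        back = warp_points(warp, scene.granules[["x_flm_nm", "y_flm_nm"]].to_numpy())
        resid = np.linalg.norm(back - scene.granules[["x_nm", "y_nm"]].to_numpy(), axis=1)
        assert resid.max() < 1e-6

    def test_full_labeling_renders_every_granule(self):
        spec = SceneSpec(seed=6, n_granules=30, p_505=1.0, n_mgbs=0, n_beads=0,
                         em_noise_sd=0.0, flm_noise_sd=0.0)
        scene = generate_clem_scene(spec)
        assert scene.granules.pool_505.all()
        spots = detect_spots(scene.flm_505, pixel_size_nm=spec.flm_pixel_nm)
        assert len(spots) == 30

    def test_em_detection_exact_on_noise_free_scene(self):
        spec = SceneSpec(seed=12, n_mgbs=0, em_noise_sd=0.0, flm_noise_sd=0.0)
        scene = generate_clem_scene(spec)
        inverted = scene.em_image.max() - scene.em_image
        recs = [
            r
            for r in detect_spots(inverted, pixel_size_nm=spec.em_pixel_nm, min_area_px=20)
            if r.diameter >= spec.diameter_min_nm
        ]
        assert len(recs) == len(scene.granules)

    def test_beads_present_in_both_frames_and_mapped(self):
        spec = SceneSpec(seed=2)
        scene = generate_clem_scene(spec)
        assert len(scene.beads) == spec.n_beads
        mapped = spec.distort(scene.beads[["x_em_nm", "y_em_nm"]].to_numpy())
        np.testing.assert_allclose(
            mapped, scene.beads[["x_flm_nm", "y_flm_nm"]].to_numpy(), atol=1e-9
        )

    def test_overcrowded_scene_raises(self):
        spec = SceneSpec(seed=0, em_shape=(64, 64), n_granules=200, n_mgbs=0, placement_retries=50)
        with pytest.raises(RuntimeError, match="place"):
            generate_clem_scene(spec)

    def test_mgb_members_recorded(self):
        spec = SceneSpec(seed=9, n_mgbs=2, mgb_granules_range=(2, 3))
        scene = generate_clem_scene(spec)
        members = scene.granules[scene.granules.mgb_id >= 0]
        assert set(members.mgb_id) == {0, 1}
        assert members.groupby("mgb_id").size().between(2, 3).all()


class TestGenerateMgbCounts:
    @pytest.mark.parametrize("rate, expected", [(0.0, 0), (1.0, 38)])
    def test_degenerate_rates(self, rate, expected):
        counts = generate_mgb_counts(rate, rate, trials=38, seed=1)
        assert counts["young"] == (expected, 38)
        assert counts["old"] == (expected, 38)

    def test_binomial_moments(self):
        succ = np.array([generate_mgb_counts(0.01, 0.05, trials=100, seed=s)["old"][0] for s in range(1000)])
        se = math.sqrt(100 * 0.05 * 0.95) / math.sqrt(1000)
        assert succ.mean() == pytest.approx(5.0, abs=3 * se * math.sqrt(1000) / math.sqrt(1000) * 1)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            generate_mgb_counts(-0.1, 0.5)


class TestClosedLoops:
    def test_scene_to_fraction_recovery(self):
        """Register on beads, warp detected 505 spots into the EM frame,
        count: the recovered labeled fraction must sit inside the exact
        binomial 95% interval of the generator's labeling probability."""
        spec = SceneSpec(seed=21, n_granules=60, p_505=0.15, p_tmr=0.0,
                         n_mgbs=0, em_noise_sd=0.0, flm_noise_sd=0.0)
        scene = generate_clem_scene(spec)
        lms = [
            LandmarkPair((r.x_flm_nm, r.y_flm_nm), (r.x_em_nm, r.y_em_nm))
            for r in scene.beads.itertuples()
        ]
        warp = fit_affine(lms)
        inverted = scene.em_image.max() - scene.em_image
        em_recs = [
            r
            for r in detect_spots(inverted, pixel_size_nm=spec.em_pixel_nm, min_area_px=20)
            if r.diameter >= spec.diameter_min_nm
        ]
        assert len(em_recs) == 60
        spots = detect_spots(scene.flm_505, pixel_size_nm=spec.flm_pixel_nm)
        in_em = warp_points(warp, np.array([s.centroid for s in spots]))
        # count detected spots landing on a true granule (not a bead)
        truth = scene.granules[["x_nm", "y_nm"]].to_numpy()
        n_labeled = sum(
            1 for p in in_em if np.min(np.linalg.norm(truth - p, axis=1)) < 121.5
        )
        assert n_labeled == int(scene.granules.pool_505.sum())
        frac = n_labeled / len(em_recs)
        lo, hi = stats.binom.interval(0.95, 60, spec.p_505)
        assert lo / 60 <= frac <= hi / 60

    def test_kinetics_loop_prefers_true_model(self, model2_params):
        from clemq import compare_models, fit_decay_model

        wins = 0
        n = 15
        for s in range(n):
            obs = generate_observations(model2_params, seed=1000 + s)
            fits = [fit_decay_model(obs, m, seed=s) for m in (1, 2, 3)]
            wins += compare_models(fits, method="laplace_evidence").best_model() == 2
        assert wins > n / 2
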