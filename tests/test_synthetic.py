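"""The synthetic generators: determinism, confinement, generative laws."""
import numpy as np
import pytest

from flysla import (BrainPhantomParams, DotBlotPhantom, RenderParams, WalkerParams,
                    detect_centroid, measure_od, ped_ratio, render_frames,
                    select_dimmed_slices, simulate_walker, synth_brain_stack,
                    synth_dotblot, SpotSpec, ROISpec)


class TestWalker:
    def test_identical_seed_reproduces_identical_output(self):
        p = WalkerParams(duration=50.0, seed=3)
        a, b = simulate_walker(p), simulate_walker(p)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        assert np.array_equal(a.states, b.states)
        c = simulate_walker(WalkerParams(duration=50.0, seed=4))
        assert not np.array_equal(a.x, c.x)

    @pytest.mark.parametrize("seed", range(5))
    def test_confinement_to_arena_disk(self, seed):
        p = WalkerParams(duration=100.0, seed=seed, run_speed_mean=8.0)
        t = simulate_walker(p)
        assert np.max(np.hypot(t.x, t.y)) <= p.arena_radius

    def test_zero_rest_to_run_rate_is_absorbing(self):
        p = WalkerParams(rate_rest_to_run=0.0, duration=60.0, seed=1)
        t = simulate_walker(p)
        assert np.all(t.states == 0)
        # net displacement over any 1-s window stays below the run threshold
        f = int(p.frame_rate)
        dx = t.x[f:] - t.x[:-f]
        dy = t.y[f:] - t.y[:-f]
        assert np.max(np.hypot(dx, dy)) < 1.0

    def test_stationary_run_fraction_matches_markov_chain(self):
        # two-state chain with k1 = k2 = 0.1/s has stationary run prob 0.5
        p = WalkerParams(duration=10_000.0, seed=5)
        t = simulate_walker(p)
        assert t.run_fraction == pytest.approx(0.5, abs=0.02)

    def test_run_fraction_unbiased_over_seeds(self):
        # mean over seeds within 3 SE of k1/(k1+k2)
        fracs = [simulate_walker(WalkerParams(duration=1000.0, seed=s)).run_fraction
                 for s in range(20)]
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.5) < 3 * se

    def test_asymmetric_rates_shift_run_fraction(self):
        p = WalkerParams(rate_rest_to_run=0.3, rate_run_to_rest=0.1,
                         duration=5000.0, seed=2)
        assert simulate_walker(p).run_fraction == pytest.approx(0.75, abs=0.03)

    @pytest.mark.parametrize("bad", [
        dict(rate_rest_to_run=-0.1), dict(run_speed_mean=0.5),
        dict(rest_speed_mean=1.5), dict(wall_bias=1.2),
        dict(arena_radius=0.0), dict(frame_rate=float("nan")),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            WalkerParams(**bad)


class TestRenderer:
    def _point_truth(self, x=0.0, y=0.0):
        from flysla.synthetic import GroundTruth
        p = WalkerParams(duration=0.1, seed=0)
        return GroundTruth(t=np.array([0.0]), x=np.array([x]), y=np.array([y]),
                           states=np.array([0], dtype=np.uint8), params=p)

    def test_fly_at_center_peaks_at_image_center(self):
        rp = RenderParams(image_size=257, background_sd=0.0)
        frame = render_frames(self._point_truth(), rp)[0]
        r, c = np.unravel_index(np.argmax(frame), frame.shape)
        assert (r, c) == (128, 128)

    def test_roundtrip_with_detect_centroid_subpixel(self):
        rp = RenderParams(image_size=64, background_sd=0.0)
        truth = self._point_truth(x=0.337, y=-0.52)
        frame = render_frames(truth, rp)[0]
        cx, cy = detect_centroid(frame, 60)
        px = rp.center_px + truth.x[0] / rp.mm_per_pixel
        py = rp.center_px - truth.y[0] / rp.mm_per_pixel
        assert abs(cx - px) < 0.1 and abs(cy - py) < 0.1

    def test_background_only_frame_has_no_detection(self):
        rp = RenderParams(image_size=64, background_mean=20, background_sd=5.0)
        frame = render_frames(self._point_truth(), rp, seed=9, draw_fly=False)[0]
        assert detect_centroid(frame, 60) is None

    def test_render_params_must_keep_fly_detectable(self):
        with pytest.raises(ValueError):
            RenderParams(fly_peak_intensity=50)
        with pytest.raises(ValueError):
            RenderParams(background_mean=50, background_sd=5)

    def test_position_outside_image_rejected(self):
        rp = RenderParams(image_size=32, mm_per_pixel=0.1)  # 3.2 mm field
        with pytest.raises(ValueError):
            render_frames(self._point_truth(x=9.0), rp)


class TestDotBlot:
    centers = ((30, 30), (30, 90), (90, 30), (90, 90))

    def test_zero_concentration_spot_has_zero_od(self):
        ph = DotBlotPhantom(spot_centers=((40, 40),), concentrations=(0.0,))
        img = synth_dotblot(ph)
        od = measure_od(img, SpotSpec(center=(40, 40), radius=8)).od
        assert od == 0.0

    def test_noiseless_ods_in_exact_concentration_ratio(self):
        ph = DotBlotPhantom(spot_centers=self.centers, concentrations=(1, 2, 4, 8),
                            darkness_per_unit=10.0, background_sd=0.0)
        img = synth_dotblot(ph)
        ods = [measure_od(img, SpotSpec(center=c, radius=8)).od for c in self.centers]
        assert ods == [10.0, 20.0, 40.0, 80.0]

    def test_overlapping_spots_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DotBlotPhantom(spot_centers=((30, 30), (30, 40)), concentrations=(1, 1),
                           spot_radius=8)

    def test_darkness_clipped_at_background(self):
        ph = DotBlotPhantom(spot_centers=((40, 40),), concentrations=(100.0,),
                            darkness_per_unit=10.0, background_mean=200.0)
        img = synth_dotblot(ph)
        assert img[40, 40] == 0  # fully dark, not negative


class TestBrainPhantom:
    def test_uniform_stack_when_contrast_is_one(self):
        bp = BrainPhantomParams(ped_contrast=1.0, noise_sd=0.0)
        stack = synth_brain_stack(bp)
        assert np.all(stack == stack.flat[0])
        spec = ROISpec(top_left=(54, 42), side=12, offset=24)
        assert ped_ratio(stack, spec).R == pytest.approx(1.0)

    def test_dimmed_disk_has_exact_contrast(self):
        bp = BrainPhantomParams(ped_contrast=0.5, noise_sd=0.0)
        stack = synth_brain_stack(bp)
        assert stack[4, 60, 48] == 100 and stack[0, 60, 48] == 200

    def test_selected_slices_are_the_dimmed_ones(self):
        bp = BrainPhantomParams(dimmed_slices=(3, 4, 5), noise_sd=0.0)
        stack = synth_brain_stack(bp)
        spec = ROISpec(top_left=(54, 42), side=12, offset=24)
        assert select_dimmed_slices(stack, spec) == (3, 4, 5)

    def test_determinism_and_noise(self):
        bp = BrainPhantomParams(noise_sd=3.0, seed=7)
        assert np.array_equal(synth_brain_stack(bp), synth_brain_stack(bp))

    def test_ped_disk_must_fit_inside_image(self):
        with pytest.raises(ValueError):
            BrainPhantomParams(ped_center=(5, 48), ped_radius=16)
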