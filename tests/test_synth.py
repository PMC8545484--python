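import numpy as np
import pytest

from mgquant import puncta as pu
from mgquant import synth


class TestDeterminism:
    def test_trace(self):
        a, ta = synth.gen_trace(synth.TraceGenSpec(seed=42))
        b, tb = synth.gen_trace(synth.TraceGenSpec(seed=42))
        assert np.array_equal(a.values, b.values)
        assert ta == tb
        c, _ = synth.gen_trace(synth.TraceGenSpec(seed=43))
        assert not np.array_equal(a.values, c.values)

    def test_puncta_image(self):
        spec = synth.PunctaGenSpec(fov_um=20.0, seed=7)
        a = synth.gen_puncta_image(spec)
        b = synth.gen_puncta_image(spec)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)
        assert np.array_equal(a[2].pre_centroids_um, b[2].pre_centroids_um)

    def test_scene(self):
        spec = synth.SceneGenSpec(n_cells=6, seed=3)
        a, ta = synth.gen_scene(spec)
        b, tb = synth.gen_scene(spec)
        assert np.array_equal(a.masks, b.masks)
        assert np.array_equal(a.bead_xyz_um, b.bead_xyz_um)
        assert ta.internal_counts == tb.internal_counts

    def test_pattern(self):
        spec = synth.PatternGenSpec(seed=9)
        assert np.array_equal(synth.gen_pattern(spec).points,
                              synth.gen_pattern(spec).points)

    def test_current(self):
        spec = synth.EphysGenSpec(duration_s=5.0, seed=11)
        a, ea = synth.gen_current(spec)
        b, eb = synth.gen_current(spec)
        assert np.array_equal(a.samples_pA, b.samples_pA)
        assert np.array_equal(ea.times_s, eb.times_s)


class TestGenTrace:
    def test_zero_rate_zero_noise_flat(self):
        trace, truth = synth.gen_trace(synth.TraceGenSpec(
            transient_rate_per_min=0.0, noise_sd_dff=0.0, drift_amplitude_dff=0.0))
        assert np.allclose(trace.values, 0.0)
        assert truth == []

    def test_poisson_event_count_mean(self):
        # rate 0.13/min over 300 s -> Poisson mean 0.65; check over 1000 seeds
        counts = [
            len(synth.gen_trace(synth.TraceGenSpec(
                transient_rate_per_min=0.13, noise_sd_dff=0.0, seed=s))[1])
            for s in range(1000)
        ]
        mean = np.mean(counts)
        se = np.sqrt(0.65 / 1000)
        assert abs(mean - 0.65) < 3 * se

    def test_kernel_area_matches_trapezoid_oracle(self):
        # analytic area = amplitude*(tau + rise/2); integrate the kernel
        # numerically on a fine grid
        spec = synth.TraceGenSpec(amplitude_dff=0.4, decay_tau_s=8.0, rise_s=1.0)
        t = np.linspace(0, 200, 400001)
        numeric = np.trapezoid(synth.traces.transient_kernel(t, spec), t)
        assert numeric == pytest.approx(0.4 * (8.0 + 0.5), rel=1e-3)
        _, truth = synth.gen_trace(synth.TraceGenSpec(
            transient_rate_per_min=1.0, seed=4))
        for ev in truth:
            assert ev.area_dff_s == pytest.approx(numeric, rel=1e-3)

    def test_drift_is_sinusoidal(self):
        spec = synth.TraceGenSpec(transient_rate_per_min=0.0, noise_sd_dff=0.0,
                                  drift_amplitude_dff=0.05, drift_period_s=300.0)
        trace, _ = synth.gen_trace(spec)
        t = np.arange(300.0)
        assert np.allclose(trace.values, 0.05 * np.sin(2 * np.pi * t / 300.0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            synth.TraceGenSpec(transient_rate_per_min=-1.0)
        with pytest.raises(ValueError):
            synth.TraceGenSpec(noise_sd_dff=-0.1)
        with pytest.raises(ValueError):
            synth.TraceGenSpec(duration_s=0.0)


class TestGenPunctaImage:
    def test_zero_densities_background_only(self):
        spec = synth.PunctaGenSpec(
            fov_um=20.0, density_pre_per_100um2=0.0, density_post_per_100um2=0.0,
            density_coloc_per_100um2=0.0, noise_sd=0.0, seed=0)
        pre, post, truth = synth.gen_puncta_image(spec)
        assert truth.n_pre == truth.n_post == truth.n_coloc == 0
        assert np.all(pre.pixels == spec.background_level)
        assert np.all(post.pixels == spec.background_level)

    def test_all_colocalized_when_densities_equal(self):
        spec = synth.PunctaGenSpec(
            fov_um=30.0, density_pre_per_100um2=10.0, density_post_per_100um2=10.0,
            density_coloc_per_100um2=10.0, seed=1)
        _, _, truth = synth.gen_puncta_image(spec)
        assert truth.n_coloc == truth.n_pre == truth.n_post
        assert len(truth.coloc_pairs) == truth.n_coloc

    def test_coloc_density_exceeding_channel_rejected(self):
        with pytest.raises(ValueError):
            synth.PunctaGenSpec(density_pre_per_100um2=10.0,
                                density_coloc_per_100um2=20.0)

    def test_truth_counts_near_expectation(self):
        # expected = density x (fov^2/100); Poisson SD applies per category
        spec = synth.PunctaGenSpec(seed=5)
        _, _, truth = synth.gen_puncta_image(spec)
        factor = 102.0 ** 2 / 100.0
        for observed, density in ((truth.n_pre, 53.0), (truth.n_post, 42.0),
                                  (truth.n_coloc, 26.0)):
            expected = density * factor
            assert abs(observed - expected) < 4 * np.sqrt(expected)

    def test_eight_bit_clipping_no_wraparound(self):
        spec = synth.PunctaGenSpec(
            fov_um=20.0, density_pre_per_100um2=20.0, density_post_per_100um2=20.0,
            density_coloc_per_100um2=10.0, punctum_intensity=255,
            background_level=250, noise_sd=20.0, seed=2)
        pre, post, _ = synth.gen_puncta_image(spec)
        for img in (pre, post):
            assert img.pixels.dtype == np.uint8
            assert img.pixels.max() == 255  # clipped, not wrapped

    def test_truth_matches_noiseless_render(self):
        # oracle re-measurement: threshold the noiseless render and count
        spec = synth.PunctaGenSpec(fov_um=40.0, noise_sd=0.0,
                                   background_level=0, seed=6)
        pre, post, truth = synth.gen_puncta_image(spec)
        pre_set = pu.find_puncta(
            pu.threshold_channel(pre, pu.BASSOON_THRESHOLD), spec.pixel_size_um)
        post_set = pu.find_puncta(
            pu.threshold_channel(post, pu.HOMER_THRESHOLD), spec.pixel_size_um)
        assert len(pre_set) == truth.n_pre
        assert len(post_set) == truth.n_post
        report = pu.colocalize(pre_set, post_set)
        assert report.n_synapses == truth.n_coloc


class TestGenScene:
    def test_zero_fraction_all_counts_zero(self):
        _, truth = synth.gen_scene(synth.SceneGenSpec(
            n_cells=8, frac_phagocytic=0.0, seed=0))
        assert all(c == 0 for c in truth.internal_counts.values())

    def test_exact_phagocytic_count(self):
        _, truth = synth.gen_scene(synth.SceneGenSpec(
            n_cells=10, frac_phagocytic=0.5, beads_per_phagocytic_cell=1, seed=1))
        assert truth.n_phagocytic == 5

    def test_containment_oracle(self):
        # bead-by-bead point-in-mask lookup at the nearest z-plane
        scene, truth = synth.gen_scene(synth.SceneGenSpec(
            n_cells=6, frac_phagocytic=0.5, beads_per_phagocytic_cell=2,
            n_external_beads=4, seed=2))
        for (x, y, z), expected in zip(scene.bead_xyz_um, truth.bead_cell_labels):
            zi = int(round(z / scene.z_step_um))
            yi = int(round(y / scene.pixel_size_um))
            xi = int(round(x / scene.pixel_size_um))
            assert int(scene.masks[zi, yi, xi]) == expected

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            synth.SceneGenSpec(frac_phagocytic=1.5)


class TestGenPattern:
    def test_poisson_expected_count(self):
        # 100 cells/mm² on a 640-um FOV -> mean n = 40.96
        counts = [
            synth.gen_pattern(synth.PatternGenSpec(seed=s)).n for s in range(500)
        ]
        mean = np.mean(counts)
        se = np.sqrt(40.96 / 500)
        assert abs(mean - 40.96) < 3 * se

    def test_lattice_no_jitter_equal_nnd(self):
        from mgquant.spatial import nearest_neighbor_distances
        pat = synth.gen_pattern(synth.PatternGenSpec(
            mode="jittered_lattice", jitter_sd_um=0.0))
        d = nearest_neighbor_distances(pat)
        assert np.allclose(d, d[0])

    def test_points_inside_fov(self):
        for mode in ("poisson", "jittered_lattice", "clustered"):
            pat = synth.gen_pattern(synth.PatternGenSpec(
                mode=mode, jitter_sd_um=10.0, seed=4))
            assert np.all(pat.points >= 0)
            assert np.all(pat.points <= pat.fov_width_um)

    def test_clustered_is_clumpier_than_poisson(self):
        from mgquant.spatial import nnd_stats
        lam = 5e-4
        poisson_mean = np.mean([
            nnd_stats(synth.gen_pattern(synth.PatternGenSpec(
                intensity_per_um2=lam, seed=s)))[0] for s in range(20)])
        clustered_mean = np.mean([
            nnd_stats(synth.gen_pattern(synth.PatternGenSpec(
                mode="clustered", intensity_per_um2=lam, jitter_sd_um=10.0,
                seed=s)))[0] for s in range(20)])
        assert clustered_mean < poisson_mean

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            synth.PatternGenSpec(mode="hexagonal")


class TestGenCurrent:
    def test_silent_trace_constant(self):
        trace, truth = synth.gen_current(synth.EphysGenSpec(
            duration_s=2.0, event_rate_pre_hz=0.0, event_rate_post_hz=0.0,
            noise_sd_pA=0.0, holding_pA=-80.0))
        assert np.allclose(trace.samples_pA, -80.0)
        assert len(truth) == 0

    def test_rate_switch_counting_oracle(self):
        # pre 2 Hz / post 1 Hz -> pre/post count ratio ~ 2 over many seeds
        pre_n = post_n = 0
        for seed in range(300):
            truth = synth.gen_event_train(synth.EphysGenSpec(
                duration_s=200.0, event_rate_pre_hz=2.0, event_rate_post_hz=1.0,
                ttx_onset_s=100.0, seed=seed))
            pre_n += (truth.times_s < 100.0).sum()
            post_n += (truth.times_s >= 100.0).sum()
        assert pre_n / post_n == pytest.approx(2.0, rel=0.05)

    def test_agonist_step_shifts_mean(self):
        trace, _ = synth.gen_current(synth.EphysGenSpec(
            duration_s=20.0, event_rate_pre_hz=0.0, event_rate_post_hz=0.0,
            noise_sd_pA=0.0, holding_pA=-60.0, agonist_step_pA=-50.0,
            agonist_onset_s=10.0))
        fs = 20000
        assert np.allclose(trace.samples_pA[:10 * fs], -60.0)
        assert np.allclose(trace.samples_pA[10 * fs:], -110.0)

    def test_event_train_matches_rendered_truth(self):
        spec = synth.EphysGenSpec(duration_s=10.0, seed=13)
        _, rendered = synth.gen_current(spec)
        train = synth.gen_event_train(spec)
        assert np.array_equal(rendered.times_s, train.times_s)
        assert np.array_equal(rendered.amplitudes_pA, train.amplitudes_pA)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            synth.EphysGenSpec(event_rate_pre_hz=-1.0)
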