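"""Generator contracts: placement geometry, photometry, stripes, dynamics."""

import numpy as np
import pytest

from mitospim import synthetic as syn
from mitospim.volume import ImageVolume

from conftest import NOISE_FREE, small_scene


class TestPlacement:
    def test_zero_mitotic_fraction_yields_no_mitoses(self):
        truth = syn.place_nuclei(small_scene(seed=1, mitotic_fraction=0.0))
        assert truth.mitotic_ids == []

    def test_separation_and_containment_checked_exhaustively(self):
        spec = syn.SceneSpec(
            spheroid_radius_um=50.0, min_separation_um=9.0, seed=7,
            n_nuclei=150, volume_shape_vox=(128, 192, 192),
        )
        truth = syn.place_nuclei(spec)
        centers = np.array([n.center_um for n in truth.nuclei])
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 9.0
        assert np.all(
            np.linalg.norm(centers - truth.spheroid_center_um, axis=1) <= 50.0
        )

    def test_same_seed_reproduces_identical_scene(self):
        spec = small_scene(seed=42)
        a, b = syn.place_nuclei(spec), syn.place_nuclei(spec)
        assert [n.klass for n in a.nuclei] == [n.klass for n in b.nuclei]
        assert [n.labeled for n in a.nuclei] == [n.labeled for n in b.nuclei]
        np.testing.assert_array_equal(
            np.array([n.center_um for n in a.nuclei]),
            np.array([n.center_um for n in b.nuclei]),
        )

    def test_mitoses_confined_to_rim(self):
        spec = small_scene(seed=5, mitotic_fraction=1.0, labeled_fraction=1.0)
        truth = syn.place_nuclei(spec)
        for nid in truth.mitotic_ids:
            assert truth.depth_of(nid) <= spec.rim_thickness_um + 1e-9

    def test_infeasible_density_raises(self):
        with pytest.raises(RuntimeError, match="reduce density"):
            syn.place_nuclei(small_scene(seed=0, spheroid_radius_um=22.0,
                                         n_nuclei=500))


def _two_nucleus_truth(spec, centers, klasses=("interphase", "interphase")):
    nuclei = [
        syn.Nucleus(i, np.asarray(c, float), k, True)
        for i, (c, k) in enumerate(zip(centers, klasses))
    ]
    return syn.SceneTruth(
        nuclei=nuclei,
        spheroid_center_um=spec.center_um,
        spheroid_radius_um=spec.spheroid_radius_um,
    )


class TestRendering:
    def test_no_attenuation_gives_equal_peaks(self):
        spec = small_scene()
        c = spec.center_um
        truth = _two_nucleus_truth(spec, [c + [0, 0, -12], c + [0, 0, 12]])
        optics = syn.OpticsSpec(
            attenuation_length_um=np.inf, blur_growth_per_um=0.0,
            photon_scale=0.0, read_noise_sd=0.0,
        )
        vol = syn.render_volume(truth, spec, optics).data
        half = vol.shape[2] // 2
        assert np.isclose(vol[:, :, :half].max(), vol[:, :, half:].max(), rtol=1e-3)

    def test_attenuation_follows_closed_form_decay(self):
        spec = small_scene()
        c = spec.center_um
        dx = 24.0
        truth = _two_nucleus_truth(spec, [c + [0, 0, -dx / 2], c + [0, 0, dx / 2]])
        ell = 120.0
        optics = syn.OpticsSpec(
            attenuation_length_um=ell, blur_sigma0_um=0.0,
            blur_growth_per_um=0.0, photon_scale=0.0, read_noise_sd=0.0,
        )
        vol = syn.render_volume(truth, spec, optics).data
        half = vol.shape[2] // 2
        ratio = vol[:, :, half:].max() / vol[:, :, :half].max()
        assert np.isclose(ratio, np.exp(-dx / ell), rtol=0.05)

    def test_mitotic_gain_doubles_peak(self):
        spec = small_scene()
        c = spec.center_um
        truth = _two_nucleus_truth(
            spec, [c + [0, 0, -12], c + [0, 0, 12]], ("interphase", "mitotic")
        )
        truth.nuclei[1].orientation = np.array([0.0, 1.0, 0.0])
        optics = syn.OpticsSpec(
            attenuation_length_um=np.inf, blur_sigma0_um=0.0,
            blur_growth_per_um=0.0, mitotic_gain=2.0,
            photon_scale=0.0, read_noise_sd=0.0,
        )
        vol = syn.render_volume(truth, spec, optics).data
        half = vol.shape[2] // 2
        assert np.isclose(vol[:, :, half:].max() / vol[:, :, :half].max(), 2.0,
                          rtol=0.05)

    def test_unlabeled_nuclei_are_invisible(self):
        spec = small_scene()
        truth = _two_nucleus_truth(spec, [spec.center_um])
        truth.nuclei[0].labeled = False
        vol = syn.render_volume(truth, spec, NOISE_FREE).data
        assert vol.max() == 0.0

    def test_signal_mass_stays_near_spheroid(self, rendered_scene):
        spec, truth, vol = rendered_scene
        optics = syn.OpticsSpec()
        reach = (
            spec.spheroid_radius_um
            + 3 * (optics.blur_sigma0_um + spec.nucleus_radius_um)
        )
        spacing = np.array(spec.spacing_zyx)
        grids = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(vol.shape, spacing)), indexing="ij"
        )
        dist = np.sqrt(sum((g - c) ** 2 for g, c in
                           zip(grids, truth.spheroid_center_um)))
        outside = np.abs(vol.data)[dist > reach]
        # outside the support only read/shot noise remains
        assert np.percentile(outside, 99.9) < 0.05

    def test_attenuation_is_monotone_along_illumination(self):
        spec = small_scene(seed=9, labeled_fraction=1.0)
        truth = syn.place_nuclei(spec)
        vol = syn.render_volume(truth, spec, NOISE_FREE).data
        # mean per-nucleus peak, binned by x position: non-increasing trend
        xs, peaks = [], []
        spacing = np.array(spec.spacing_zyx)
        for n in truth.nuclei:
            idx = np.round(n.center_um / spacing).astype(int)
            lo = np.maximum(idx - 3, 0)
            hi = np.minimum(idx + 4, vol.shape)
            peaks.append(vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].max())
            xs.append(n.center_um[2])
        xs, peaks = np.array(xs), np.array(peaks)
        order = np.argsort(xs)
        first, last = peaks[order[: len(xs) // 3]], peaks[order[-len(xs) // 3:]]
        assert last.mean() <= first.mean()


class TestStripeField:
    def test_zero_density_is_empty(self):
        b, lam = syn.make_stripe_field(
            (2, 32, 32), syn.StripeSpec(noise_density=0.0), seed=1
        )
        assert np.all(b == 0.0) and np.all(lam == 0.0)

    def test_fft_convolution_matches_naive_oracle(self):
        spec = syn.StripeSpec(
            psi_sigma_along_um=3.0, psi_sigma_across_um=0.7, noise_density=1.0
        )
        voxel = (0.645, 0.645, 1.0)
        b, lam = syn.make_stripe_field((1, 16, 16), spec, voxel, seed=2)
        psi = syn.stripe_kernel(3.0, 0.7, voxel)
        ky, kx = psi.shape
        naive = np.zeros((16, 16))
        for iy in range(16):
            for ix in range(16):
                acc = 0.0
                for dy in range(ky):
                    for dx in range(kx):
                        sy = iy - (dy - (ky - 1) // 2)
                        sx = ix - (dx - (kx - 1) // 2)
                        if 0 <= sy < 16 and 0 <= sx < 16:
                            acc += lam[0, sy, sx] * psi[dy, dx]
                naive[iy, ix] = acc
        assert np.max(np.abs(b[0] - naive)) <= 1e-6 * max(np.abs(naive).max(), 1)

    def test_stripes_elongated_along_x(self):
        b, _ = syn.make_stripe_field((1, 256, 256), syn.StripeSpec(), seed=3)
        sl = b[0] - b[0].mean()
        # autocorrelation via FFT
        F = np.fft.rfft2(sl)
        ac = np.fft.irfft2(np.abs(F) ** 2, sl.shape)
        ac /= ac[0, 0]
        lag = 5
        assert ac[0, lag] > ac[lag, 0]


class TestTimelapse:
    def test_single_frame_equals_static_render_plus_stripes(self):
        spec = small_scene(seed=6)
        optics = syn.OpticsSpec()
        stripes = syn.StripeSpec()
        tl = syn.TimelapseSpec(n_frames=1, seed=6)
        vols, truth = syn.render_timelapse(spec, optics, stripes, tl)
        render_seed, stripe_seed = syn.frame_seeds(tl.seed, 0)
        ref_truth = syn.place_nuclei(spec)
        ref = syn.render_volume(ref_truth, spec, optics, seed=render_seed)
        b, _ = syn.make_stripe_field(
            spec.volume_shape_vox, stripes, spec.voxel_size_um, stripe_seed
        )
        np.testing.assert_array_equal(vols[0].data, ref.data + b)

    def test_additive_stripe_composition_is_exact(self):
        spec = small_scene(seed=8)
        tl = syn.TimelapseSpec(n_frames=2, seed=8)
        vols, truth = syn.render_timelapse(spec, syn.OpticsSpec(),
                                           syn.StripeSpec(), tl)
        for v, f in zip(vols, truth.frames):
            np.testing.assert_array_equal(v.data, f.clean + f.stripe)

    def test_drift_shows_up_as_correlation_peak(self):
        spec = small_scene(seed=4)
        tl = syn.TimelapseSpec(
            n_frames=5, drift_per_frame_um=(0.0, 0.0, 1.0), seed=4
        )
        vols, _ = syn.render_timelapse(spec, NOISE_FREE, None, tl)
        a, b = vols[0].data, vols[4].data
        F = np.fft.rfftn(a) * np.conj(np.fft.rfftn(b))
        corr = np.fft.irfftn(F, a.shape, axes=(0, 1, 2))
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        expected_x = 4 * 1.0 / spec.voxel_size_um[0]
        px = peak[2] if peak[2] <= a.shape[2] // 2 else peak[2] - a.shape[2]
        assert abs(-px - expected_x) <= 1.0
        assert peak[0] == 0 and peak[1] == 0

    def test_daughters_appear_at_schedule_end(self):
        spec = small_scene(seed=5, mitotic_fraction=0.0)
        truth0 = syn.place_nuclei(spec)
        rim = [n.id for n in truth0.nuclei
               if n.labeled and truth0.depth_of(n.id) <= spec.rim_thickness_um]
        entry = 1
        tl = syn.TimelapseSpec(
            n_frames=20, division_events=((rim[0], entry),),
            mitosis_duration_min=45.0, seed=5,
        )
        _, truth = syn.render_timelapse(spec, NOISE_FREE, None, tl,
                                        keep_fields=False)
        d1, d2 = truth.daughters[rim[0]]
        first = min(
            f.frame for f in truth.frames if d1 in f.states
        )
        assert first == entry + int(np.ceil(45.0 / 3.0))
        states = [f.states[rim[0]].state for f in truth.frames
                  if rim[0] in f.states]
        assert "metaphase" in states and "anaphase" in states

    def test_paclitaxel_mode_never_reaches_anaphase(self):
        spec = small_scene(seed=5, mitotic_fraction=0.0)
        truth0 = syn.place_nuclei(spec)
        rim = [n.id for n in truth0.nuclei
               if n.labeled and truth0.depth_of(n.id) <= spec.rim_thickness_um]
        tl = syn.TimelapseSpec(
            n_frames=15, division_events=((rim[0], 1),),
            paclitaxel_mode=True, seed=5,
        )
        _, truth = syn.render_timelapse(spec, NOISE_FREE, None, tl,
                                        keep_fields=False)
        states = [f.states[rim[0]].state for f in truth.frames[1:]]
        assert set(states) == {"condensed"}
        assert truth.daughters == {}
        # chromosome centroid jitters frame to frame
        pos = np.array([
            f.states[rim[0]].center_um for f in truth.frames[1:]
        ])
        assert np.linalg.norm(np.diff(pos, axis=0), axis=1).max() > 0.1

    def test_event_on_deep_or_unlabeled_nucleus_is_skipped(self):
        spec = small_scene(seed=5)
        truth0 = syn.place_nuclei(spec)
        deep = min(truth0.nuclei, key=lambda n: -truth0.depth_of(n.id))
        tl = syn.TimelapseSpec(n_frames=3, division_events=((deep.id, 0),),
                               seed=5)
        with pytest.warns(UserWarning, match="skipped"):
            _, truth = syn.render_timelapse(spec, NOISE_FREE, None, tl,
                                            keep_fields=False)
        assert truth.skipped_events and truth.skipped_events[0][0] == deep.id
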