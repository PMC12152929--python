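"""Ground-truth sampling and forward-model rendering of droplet fields."""

import inspect

import numpy as np
import pytest
from scipy import stats as sps

from dropletquant.registration import PlanarTransform
from dropletquant.synthetic import (
    GREEN_ONLY,
    HETEROTYPIC,
    RED_ONLY,
    CompositionModel,
    DropletTruth,
    ImagingConfig,
    PlacementError,
    apply_disassembly,
    make_condition_set,
    render_bead_field,
    render_channels,
    sample_droplet_field,
)
from conftest import NOISELESS

PX_TIRF = 114.17


def _field(composition, n, seed, field_um=60.0, px=PX_TIRF, **kw):
    side = field_um * 1000.0
    return sample_droplet_field(composition, n, (side, side), px, seed=seed, **kw)


class TestSampling:
    def test_identical_seed_identical_truth(self, small_composition):
        a = _field(small_composition, 50, seed=7)
        b = _field(small_composition, 50, seed=7)
        assert a.to_dataframe().equals(b.to_dataframe())
        c = _field(small_composition, 50, seed=8)
        assert not a.to_dataframe().equals(c.to_dataframe())

    def test_pure_heterotypic_population(self):
        cm = CompositionModel(1.0, 0.0, 0.0, 500.0, 0.3)
        truth = _field(cm, 40, seed=1)
        assert all(d.composition == HETEROTYPIC for d in truth.droplets)
        assert all(d.intensity_green > 0 and d.intensity_red > 0 for d in truth.droplets)

    def test_heterotypic_fraction_in_exact_binomial_interval(self):
        # oracle: exact binomial 99% interval around p=0.447 at n=2581
        n, p = 2581, 0.447
        lo, hi = sps.binom.interval(0.99, n, p)
        cm = CompositionModel(p, 0.553 - 0.431, 0.431, 300.0, 0.2)
        truth = _field(cm, n, seed=42, field_um=250.0)
        k = truth.composition_counts()[HETEROTYPIC]
        assert lo <= k <= hi

    def test_composition_frequencies_converge(self, small_composition):
        # pooled over many fields: each class frequency within +/-0.02
        counts = {HETEROTYPIC: 0, GREEN_ONLY: 0, RED_ONLY: 0}
        total = 0
        for seed in range(25):
            truth = _field(small_composition, 400, seed=seed, field_um=120.0)
            for k, v in truth.composition_counts().items():
                counts[k] += v
            total += 400
        assert abs(counts[HETEROTYPIC] / total - 0.447) < 0.02
        assert abs(counts[GREEN_ONLY] / total - 0.122) < 0.02
        assert abs(counts[RED_ONLY] / total - 0.431) < 0.02

    def test_minimum_separation_enforced(self, small_composition):
        truth = _field(small_composition, 80, seed=3, field_um=80.0)
        centers = truth.centers()
        max_r = max(d.radius_nm for d in truth.droplets)
        d2 = np.sum((centers[:, None] - centers[None]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 2.0 * max_r - 1e-6

    def test_placement_failure_names_achieved_count(self, small_composition):
        with pytest.raises(PlacementError, match="achieved"):
            _field(small_composition, 500, seed=1, field_um=8.0)

    def test_exclusive_droplets_have_zero_off_channel_intensity(self):
        with pytest.raises(ValueError):
            DropletTruth(0, (1e3, 1e3), 500.0, GREEN_ONLY, 100.0, 5.0)
        with pytest.raises(ValueError):
            DropletTruth(0, (1e3, 1e3), 500.0, HETEROTYPIC, 100.0, 0.0)


class TestRendering:
    def test_empty_field_mean_is_background(self, small_composition):
        truth = _field(small_composition, 0, seed=1, field_um=30.0)
        cfg = ImagingConfig(background=50.0, read_noise_sd=0.0, shot_noise=True, seed=2)
        green, _ = render_channels(truth, cfg)
        n_pix = green.values.size
        se = np.sqrt(50.0 / n_pix)
        assert abs(green.values.mean() - 50.0) < 3.0 * se

    def test_rendered_centroid_matches_truth(self, small_composition, noiseless_config):
        truth = _field(small_composition, 5, seed=9, field_um=30.0)
        green, _ = render_channels(truth, noiseless_config)
        img = green.values.astype(float)
        px = green.pixel_size_nm
        for d in truth.droplets:
            if d.intensity_green == 0:
                continue
            # brute-force intensity-weighted centroid over a window
            cx, cy = d.center_nm
            half = d.radius_nm + 8 * noiseless_config.psf_sigma_nm
            c0 = max(int((cx - half) / px), 0)
            c1 = min(int(np.ceil((cx + half) / px)), img.shape[1])
            r0 = max(int((cy - half) / px), 0)
            r1 = min(int(np.ceil((cy + half) / px)), img.shape[0])
            win = img[r0:r1, c0:c1]
            rows, cols = np.mgrid[r0:r1, c0:c1]
            tot = win.sum()
            est_x = ((cols + 0.5) * px * win).sum() / tot / px - cx / px
            est_y = ((rows + 0.5) * px * win).sum() / tot / px - cy / px
            assert abs(est_x) < 0.1 and abs(est_y) < 0.1

    def test_total_signal_proportional_to_intensity(self, noiseless_config):
        # same disk radius, intensities 1:3 -> integrated signal 1:3 within 1%
        totals = []
        for amp in (80.0, 240.0):
            truth = sample_droplet_field(
                CompositionModel(0, 1, 0, 500.0, 0.0), 1,
                (20000.0, 20000.0), PX_TIRF, seed=5,
            )
            truth.droplets[0].intensity_green = amp
            green, _ = render_channels(truth, noiseless_config)
            totals.append(green.values.astype(float).sum())
        assert abs(totals[1] / totals[0] - 3.0) < 0.03

    def test_poisson_variance_matches_mean_on_background(self, small_composition):
        truth = _field(small_composition, 0, seed=1, field_um=40.0)
        cfg = ImagingConfig(background=100.0, read_noise_sd=0.0, shot_noise=True, seed=3)
        green, _ = render_channels(truth, cfg)
        vals = green.values.astype(float)
        assert 0.9 < vals.var() / vals.mean() < 1.1

    def test_red_channel_centers_shift_through_transform(self, noiseless_config):
        from dataclasses import replace

        cm = CompositionModel(1.0, 0.0, 0.0, 500.0, 0.0)
        truth = _field(cm, 1, seed=4, field_um=20.0)
        truth.droplets[0].intensity_red = truth.droplets[0].intensity_green
        truth.droplets[0].center_nm = (10000.0, 10000.0)
        shift = PlanarTransform.from_translation(10 * PX_TIRF, 0.0)
        cfg = replace(noiseless_config, channel_transform=shift)
        green, red = render_channels(truth, cfg)
        rolled = np.roll(green.values.astype(int), 10, axis=1)
        # rendered red disk sits 10 px to the right of the green one
        assert np.abs(rolled - red.values.astype(int)).max() <= 1

    def test_clipped_droplet_flagged(self, noiseless_config):
        from dataclasses import replace

        cm = CompositionModel(1.0, 0.0, 0.0, 500.0, 0.0)
        truth = _field(cm, 1, seed=4, field_um=20.0)
        # push the red copy (mostly) out of the field
        shift = PlanarTransform.from_translation(19000.0, 0.0)
        cfg = replace(noiseless_config, channel_transform=shift)
        render_channels(truth, cfg)
        assert truth.clipped_ids == [truth.droplets[0].id]

    def test_speckled_profile_changes_texture_not_footprint(self, small_composition):
        from dataclasses import replace

        truth = _field(small_composition, 3, seed=6, field_um=25.0)
        cfg = ImagingConfig(psf_sigma_nm=150.0, **NOISELESS)
        flat, _ = render_channels(truth, cfg)
        spk, _ = render_channels(truth, replace(cfg, profile="speckled"))
        assert not np.array_equal(flat.values, spk.values)
        assert np.array_equal(flat.values > 0, spk.values > 0) or (
            (flat.values > 0).sum() > 0
        )


class TestBeadField:
    def test_identity_noise_off_byte_identical(self, noiseless_config):
        a, b, _ = render_bead_field(10, PlanarTransform.identity(), noiseless_config, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_minimum_bead_count_enforced(self, noiseless_config):
        with pytest.raises(ValueError):
            render_bead_field(2, PlanarTransform.identity(), noiseless_config, seed=1)

    def test_translation_recovered_by_cross_correlation(self, noiseless_config):
        # oracle: dense upsampled cross-correlation between the two frames
        from skimage.registration import phase_cross_correlation

        tx, ty = 10.5 * PX_TIRF, -3.2 * PX_TIRF
        a, b, _ = render_bead_field(
            15, PlanarTransform.from_translation(tx, ty), noiseless_config, seed=8
        )
        shift, _, _ = phase_cross_correlation(
            a.values.astype(float), b.values.astype(float), upsample_factor=100
        )
        # skimage returns (row, col) displacement of b relative to a
        assert abs(-shift[1] - 10.5) < 0.1
        assert abs(-shift[0] - (-3.2)) < 0.1

    def test_seeded_run_reproducible(self):
        cfg = ImagingConfig(seed=11)
        a1, b1, c1 = render_bead_field(8, PlanarTransform.identity(), cfg, seed=21)
        a2, b2, c2 = render_bead_field(8, PlanarTransform.identity(), cfg, seed=21)
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(b1.values, b2.values)
        assert np.allclose(c1, c2)


class TestConditionSet:
    def test_default_design_thirty_500px_images(self):
        sig = inspect.signature(make_condition_set)
        assert sig.parameters["n_images"].default == 30
        assert sig.parameters["field_size_px"].default == (500, 500)

    def test_reproducible_under_master_seed(self, small_composition):
        kw = dict(
            n_images=3,
            composition=small_composition,
            config=ImagingConfig(pixel_size_nm=325.0, seed=0),
            field_size_px=(96, 96),
            mean_droplets_per_image=5.0,
            seed=99,
        )
        s1 = make_condition_set(**kw)
        s2 = make_condition_set(**kw)
        for ((g1, r1), t1), ((g2, r2), t2) in zip(s1, s2):
            assert np.array_equal(g1.values, g2.values)
            assert np.array_equal(r1.values, r2.values)
            assert t1.to_dataframe().equals(t2.to_dataframe())

    def test_per_image_counts_uncorrelated(self, small_composition):
        # lag-1 correlation of per-image droplet counts over 100 sets
        pairs_x, pairs_y = [], []
        for s in range(100):
            cset = make_condition_set(
                n_images=8,
                composition=small_composition,
                config=ImagingConfig(pixel_size_nm=325.0, seed=0),
                field_size_px=(64, 64),
                mean_droplets_per_image=5.0,
                seed=1000 + s,
            )
            counts = [len(truth.droplets) for _, truth in cset]
            pairs_x.extend(counts[:-1])
            pairs_y.extend(counts[1:])
        r, p = sps.pearsonr(pairs_x, pairs_y)
        assert p > 0.01


class TestDisassembly:
    def test_size_selective_removal_raises_surviving_mean_radius(self, small_composition):
        truth = _field(small_composition, 200, seed=13, field_um=150.0)
        after = apply_disassembly(truth, 0.6, size_selective=True, seed=1)
        r_before = np.mean([d.radius_nm for d in truth.droplets])
        r_after = np.mean([d.radius_nm for d in after.droplets])
        assert len(after.droplets) == 80
        assert r_after > r_before

    def test_zero_removal_is_identity(self, small_composition):
        truth = _field(small_composition, 20, seed=13, field_um=60.0)
        after = apply_disassembly(truth, 0.0, size_selective=True, seed=1)
        assert [d.id for d in after.droplets] == [d.id for d in truth.droplets]
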