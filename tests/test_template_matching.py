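"""Template preparation, micrograph cleanup, matching engine, peak extraction."""

import numpy as np
import pytest
import scipy.fft as sfft

from tomopipe.errors import TomopipeError
from tomopipe.geometry import WedgeSpec, generate_grid, rotate_volume
from tomopipe.template_matching import (MatchResult, erase_gold,
                                        erase_grid_edge, extract_peaks,
                                        lowpass_filter, match_template,
                                        postprocess_cc, prepare_template,
                                        soft_sphere_mask, taper_edges)


@pytest.fixture(scope="module")
def prepared(blob_phantom):
    template, mask = prepare_template(blob_phantom, 1.0, 1.0)
    return template, mask


@pytest.fixture(scope="module")
def tiny_grid():
    return generate_grid(40, 40, 40, 40, "C1")  # identity only


class TestPrepareTemplate:
    def test_equal_voxels_no_lowpass_only_normalizes(self, blob_phantom):
        template, mask = prepare_template(blob_phantom, 1.0, 1.0)
        w = mask / mask.sum()
        assert float((template * w).sum()) == pytest.approx(0.0, abs=1e-9)
        assert float((w * template ** 2).sum()) == pytest.approx(1.0, rel=1e-6)

    def test_resampling_halves_box(self, blob_phantom):
        template, _ = prepare_template(blob_phantom, 2.0, 4.0)
        assert template.shape == (16, 16, 16)

    def test_lowpass_power_confined(self, blob_phantom):
        template, _ = prepare_template(blob_phantom, 1.0, 1.0, lowpass=6.0)
        spec = np.abs(sfft.fftn(template)) ** 2
        freqs = [np.fft.fftfreq(n, d=1.0) for n in template.shape]
        grids = np.meshgrid(*freqs, indexing="ij")
        f = np.sqrt(sum(g * g for g in grids))
        above = spec[f > 1.0 / 6.0 + 0.05].sum()
        assert above < 0.01 * spec.sum()

    def test_beyond_nyquist_lowpass_rejected(self, blob_phantom):
        with pytest.raises(TomopipeError, match="Nyquist"):
            prepare_template(blob_phantom, 1.0, 2.0, lowpass=3.0)


class TestEraseGold:
    def test_beads_suppressed(self):
        rng = np.random.default_rng(0)
        image = rng.normal(0.0, 1.0, (128, 128))
        centers = [(20, 20), (40, 90), (80, 30), (100, 100), (60, 60)]
        yy, xx = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        for cy, cx in centers:
            image[np.hypot(yy - cy, xx - cx) <= 4] += 20.0
        cleaned = erase_gold(image, bead_diameter_px=8, seed=1)
        for cy, cx in centers:
            residual = cleaned[cy - 3:cy + 4, cx - 3:cx + 4]
            assert np.abs(residual).max() < 3.0 * 1.0 + 3.0  # ~3 sigma of bg

    def test_null_image_mostly_untouched(self):
        rng = np.random.default_rng(2)
        image = rng.normal(size=(128, 128))
        cleaned = erase_gold(image, bead_diameter_px=8, seed=3)
        changed = np.abs(cleaned - image) > 1e-12
        # at most one spurious matched-filter detection
        assert changed.sum() <= np.pi * (4 + 2) ** 2 * 1.5

    def test_explicit_empty_positions_is_identity(self):
        image = np.random.default_rng(4).normal(size=(32, 32))
        np.testing.assert_array_equal(
            erase_gold(image, 8, positions=np.zeros((0, 2))), image)

    def test_tiny_bead_rejected(self):
        with pytest.raises(TomopipeError):
            erase_gold(np.zeros((16, 16)), bead_diameter_px=1)


class TestEraseGridEdge:
    def test_dark_border_region_masked(self):
        rng = np.random.default_rng(5)
        image = rng.normal(10.0, 0.5, (96, 96))
        dark = np.zeros((96, 96), dtype=bool)
        dark[:, 64:] = True
        image[dark] = rng.normal(0.5, 0.2, int(dark.sum()))
        cleaned, mask = erase_grid_edge(image, intensity_drop_threshold=0.5)
        assert mask[dark].mean() >= 0.95
        assert mask[~dark].mean() <= 0.02
        assert cleaned[:, 64:].mean() == pytest.approx(10.0, abs=1.0)

    def test_uniform_image_identity(self):
        image = np.full((64, 64), 7.0)
        cleaned, mask = erase_grid_edge(image)
        assert not mask.any()
        np.testing.assert_array_equal(cleaned, image)

    def test_interior_dark_blob_untouched(self):
        rng = np.random.default_rng(6)
        image = rng.normal(10.0, 0.5, (96, 96))
        image[40:56, 40:56] = 0.1
        cleaned, mask = erase_grid_edge(image, intensity_drop_threshold=0.5)
        assert not mask.any()


class TestTaper:
    def test_zero_width_identity(self):
        data = np.random.default_rng(7).normal(size=(32, 32))
        np.testing.assert_array_equal(taper_edges(data, 0), data)

    def test_corner_reaches_mean(self):
        data = np.random.default_rng(8).normal(5.0, 2.0, (64, 64))
        out = taper_edges(data, 8)
        assert out[0, 0] == pytest.approx(data.mean(), abs=0.05 * data.std())

    def test_interior_unchanged(self):
        data = np.random.default_rng(9).normal(size=(64, 64, 32))
        out = taper_edges(data, 6)
        np.testing.assert_array_equal(out[6:-6, 6:-6, 6:-6],
                                      data[6:-6, 6:-6, 6:-6])

    def test_oversized_width_rejected(self):
        with pytest.raises(TomopipeError):
            taper_edges(np.zeros((16, 16)), 8)


class TestMatchTemplate:
    def test_pasted_template_peak(self, prepared, tiny_grid):
        template, mask = prepared
        vol = np.zeros((64, 64, 48), dtype=np.float32)
        b = template.shape[0]
        pos = (30, 25, 20)
        vol[pos[0] - b // 2:pos[0] + b - b // 2,
            pos[1] - b // 2:pos[1] + b - b // 2,
            pos[2] - b // 2:pos[2] + b - b // 2] = template
        res = match_template(vol, template, mask, tiny_grid)
        peak = np.unravel_index(np.argmax(res.cc_map), res.cc_map.shape)
        assert peak == pos
        assert res.cc_map[peak] >= 0.999

    def test_rotated_paste_recovers_orientation_index(self, prepared):
        template, mask = prepared
        grid = generate_grid(30, 120, 30, 120, "C1")
        j = 5
        rotated = rotate_volume(template, grid.matrices[j])
        vol = np.zeros((64, 64, 48), dtype=np.float32)
        b = template.shape[0]
        pos = (30, 25, 20)
        vol[pos[0] - b // 2:pos[0] + b - b // 2,
            pos[1] - b // 2:pos[1] + b - b // 2,
            pos[2] - b // 2:pos[2] + b - b // 2] = rotated
        res = match_template(vol, template, mask, grid)
        peak = np.unravel_index(np.argmax(res.cc_map), res.cc_map.shape)
        assert peak == pos
        assert res.orient_map[peak] == j

    def test_chunked_equals_unchunked(self, prepared):
        template, mask = prepared
        rng = np.random.default_rng(10)
        vol = rng.normal(size=(96, 96, 48)).astype(np.float32)
        b = template.shape[0]
        vol[20:20 + b, 30:30 + b, 10:10 + b] += 2 * template
        grid = generate_grid(45, 90, 45, 90, "C1")
        full = match_template(vol, template, mask, grid)
        chunked = match_template(vol, template, mask, grid, chunk_size=48)
        assert np.abs(full.cc_map - chunked.cc_map).max() < 1e-5
        assert chunked.chunk_layout == (2, 2, 1)

    def test_chunk_smaller_than_template_rejected(self, prepared, tiny_grid):
        template, mask = prepared
        with pytest.raises(TomopipeError, match="chunk"):
            match_template(np.zeros((64, 64, 64), dtype=np.float32),
                           template, mask, tiny_grid, chunk_size=16)

    def test_constant_region_yields_zero_cc(self, prepared, tiny_grid):
        template, mask = prepared
        vol = np.zeros((48, 48, 48), dtype=np.float32)
        vol[:16] = np.random.default_rng(11).normal(size=(16, 48, 48))
        res = match_template(vol, template, mask, tiny_grid)
        assert np.isfinite(res.cc_map).all()
        assert np.abs(res.cc_map[40, 24, 24]) == 0.0

    def test_translation_equivariance_interior(self, prepared, tiny_grid):
        template, mask = prepared
        rng = np.random.default_rng(12)
        vol = rng.normal(size=(64, 64, 48)).astype(np.float32)
        shifted = np.roll(vol, 3, axis=0)
        a = match_template(vol, template, mask, tiny_grid).cc_map
        b = match_template(shifted, template, mask, tiny_grid).cc_map
        # stay clear of the wrapped band (roll is periodic, the matcher is not)
        interior = (slice(20, 48), slice(16, 48), slice(16, 32))
        np.testing.assert_allclose(np.roll(a, 3, axis=0)[interior], b[interior],
                                   atol=1e-5)

    def test_noise_degrades_peak(self, prepared, tiny_grid):
        template, mask = prepared
        vol = np.zeros((64, 64, 48), dtype=np.float32)
        b = template.shape[0]
        vol[20:20 + b, 20:20 + b, 10:10 + b] = template
        clean = match_template(vol, template, mask, tiny_grid).cc_map.max()
        noisy_vol = vol + np.random.default_rng(13).normal(
            0, 0.5, vol.shape).astype(np.float32)
        noisy = match_template(noisy_vol, template, mask, tiny_grid).cc_map.max()
        assert clean >= noisy


class TestPostprocess:
    def test_large_island_removed_peak_kept(self, tiny_grid):
        rng = np.random.default_rng(14)
        cc = rng.normal(0, 0.05, (48, 48, 48)).astype(np.float32)
        cc[10, 10, 10] = 0.9  # point peak
        cc[20:30, 20:30, 20:25] = 0.8  # 500-voxel ridge
        cleaned = postprocess_cc(cc, island_max_size=100)
        assert cleaned[10, 10, 10] == pytest.approx(0.9)
        assert np.abs(cleaned[22:28, 22:28, 21:24]).max() == 0.0

    def test_noise_map_unchanged(self):
        rng = np.random.default_rng(15)
        cc = rng.normal(0, 0.05, (32, 32, 32)).astype(np.float32)
        cleaned = postprocess_cc(cc, island_max_size=100)
        np.testing.assert_array_equal(cleaned, cc)

    def test_infinite_bound_is_identity(self):
        cc = np.random.default_rng(16).normal(size=(16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(postprocess_cc(cc, np.inf), cc)


class TestExtractPeaks:
    @pytest.fixture()
    def spiked_map(self, tiny_grid):
        rng = np.random.default_rng(17)
        cc = rng.normal(0, 1.0, (48, 48, 48)).astype(np.float32)
        cc /= cc.std()
        cc -= cc.mean()
        spikes = [(10, 10, 10), (30, 30, 30), (40, 12, 25), (12, 40, 8),
                  (25, 25, 40)]
        for s in spikes:
            cc[s] = 12.0
        return MatchResult(cc_map=cc,
                           orient_map=np.zeros(cc.shape, dtype=np.int32),
                           grid=tiny_grid), spikes

    def test_sigma_threshold_finds_exactly_the_spikes(self, spiked_map):
        result, spikes = spiked_map
        records = extract_peaks(result, threshold_sigma=7, exclusion_radius=4)
        assert len(records) == len(spikes)
        found = sorted((r.x - 1, r.y - 1, r.z - 1) for r in records)
        assert found == sorted(spikes)
        ccs = [r.cc for r in records]
        assert ccs == sorted(ccs, reverse=True)

    def test_cap_limits_count(self, spiked_map):
        result, _ = spiked_map
        records = extract_peaks(result, threshold_sigma=3, max_particles=3,
                                exclusion_radius=4)
        assert len(records) == 3

    def test_close_spikes_suppressed(self, tiny_grid):
        cc = np.zeros((32, 32, 32), dtype=np.float32)
        cc[10, 10, 10] = 5.0
        cc[10, 10, 12] = 4.0
        result = MatchResult(cc_map=cc,
                             orient_map=np.zeros(cc.shape, dtype=np.int32),
                             grid=tiny_grid)
        records = extract_peaks(result, max_particles=10, exclusion_radius=4)
        near = [r for r in records if abs(r.z - 1 - 10) <= 4 and r.x - 1 == 10]
        assert len(near) == 1

    def test_monotone_in_threshold_and_radius(self, spiked_map):
        result, _ = spiked_map
        n_prev = np.inf
        for sigma in (2, 4, 6, 8):
            n = len(extract_peaks(result, threshold_sigma=sigma,
                                  exclusion_radius=3))
            assert n <= n_prev
            n_prev = n
        n_prev = np.inf
        for radius in (2, 4, 8):
            n = len(extract_peaks(result, threshold_sigma=2,
                                  exclusion_radius=radius))
            assert n <= n_prev
            n_prev = n

    def test_no_criterion_rejected(self, spiked_map):
        result, _ = spiked_map
        with pytest.raises(TomopipeError):
            extract_peaks(result)
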