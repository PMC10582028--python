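"""Extraction, noise traps, constrained alignment, MRA classification,
wedge-compensated averaging, half sets, FSC."""

import numpy as np
import pytest
import scipy.fft as sfft
from scipy.ndimage import shift as nd_shift
from scipy.spatial.transform import Rotation

from tomopipe.errors import TomopipeError, EstimationError
from tomopipe.formats_io import ParticleRecord
from tomopipe.geometry import (Orientation, WedgeSpec, euler_to_matrix,
                               matrix_to_euler, rotation_distance,
                               rotate_volume, wedge_mask, generate_grid)
from tomopipe.reconstruction import Tomogram, wbp_reconstruct
from tomopipe.sta import (ClassModel, ParticleStack, align_particle,
                          average_particles, classify_mra, compute_fsc,
                          extract_particles, make_noise_trap, resolution_at,
                          split_half_sets)
from tomopipe.template_matching import lowpass_filter, soft_sphere_mask


def wedge_filtered(volume, wedge_spec):
    w = wedge_mask(wedge_spec, volume.shape)
    return np.real(sfft.ifftn(sfft.fftn(volume) * w))


@pytest.fixture(scope="module")
def wedge():
    return WedgeSpec.from_range(-45, 45, 3, soft_edge_width=1)


class TestExtract:
    def test_small_shift_not_folded(self):
        table = [ParticleRecord(tag=1, x=30, y=30, z=20, dx=0.4, dy=-0.3)]
        tomo = Tomogram(np.zeros((64, 64, 40), dtype=np.float32), 1.0)
        stack = extract_particles(tomo, table, 16)
        rec = stack.table[0]
        assert (rec.x, rec.y, rec.z) == (30, 30, 20)
        assert rec.dx == pytest.approx(0.4)

    def test_large_shift_folded_with_residual(self):
        table = [ParticleRecord(tag=1, x=30, y=30, z=20, dx=3.7)]
        tomo = Tomogram(np.zeros((64, 64, 40), dtype=np.float32), 1.0)
        stack = extract_particles(tomo, table, 16)
        rec = stack.table[0]
        assert rec.x == 34
        assert rec.dx == pytest.approx(-0.3)

    def test_crop_matches_direct_reconstruction(self, small_tilt_fixture):
        """Crop-from-tomogram vs reconstruct-from-projections equivalence."""
        series = small_tilt_fixture["series"]
        truth = small_tilt_fixture["truth"]
        tomo = wbp_reconstruct(series, 48, "ramp*hamming")
        box = 24
        table = [ParticleRecord(tag=i + 1, x=int(round(p[0])) + 1,
                                y=int(round(p[1])) + 1, z=int(round(p[2])) + 1)
                 for i, p in enumerate(truth.positions)]
        crop_stack = extract_particles(tomo, table, box)
        direct_stack = extract_particles(series, table, box, thickness=48)
        crop_by_tag = {r.tag: b for r, b in zip(crop_stack.table,
                                                crop_stack.boxes)}
        tested = 0
        for rec, sub in zip(direct_stack.table, direct_stack.boxes):
            if rec.tag not in crop_by_tag:
                continue
            cc = np.corrcoef(sub.ravel(), crop_by_tag[rec.tag].ravel())[0, 1]
            assert cc > 0.99
            tested += 1
        assert tested >= 1

    def test_randomize_orientations(self):
        table = [ParticleRecord(tag=i + 1, x=30, y=30, z=20) for i in range(5)]
        tomo = Tomogram(np.zeros((64, 64, 40), dtype=np.float32), 1.0)
        stack = extract_particles(tomo, table, 16, randomize_orientations=True,
                                  seed=3)
        angles = {(r.tdrot, r.tilt, r.narot) for r in stack.table}
        assert len(angles) == 5  # all distinct, none left at identity

    def test_empty_table_rejected(self):
        tomo = Tomogram(np.zeros((32, 32, 32), dtype=np.float32), 1.0)
        with pytest.raises(TomopipeError, match="empty"):
            extract_particles(tomo, [], 16)

    def test_out_of_bounds_skipped(self):
        table = [ParticleRecord(tag=1, x=2, y=2, z=2),
                 ParticleRecord(tag=2, x=30, y=30, z=20)]
        tomo = Tomogram(np.zeros((64, 64, 40), dtype=np.float32), 1.0)
        stack = extract_particles(tomo, table, 16)
        assert [r.tag for r in stack.table] == [2]


class TestNoiseTrap:
    def test_zero_in_mask_mean_and_matched_std(self, blob_phantom):
        mask = soft_sphere_mask(32)
        trap = make_noise_trap(blob_phantom, lowpass=8.0, seed=1, mask=mask)
        w = mask / mask.sum()
        t_std = np.sqrt(float((w * (blob_phantom -
                                    (blob_phantom * w).sum()) ** 2).sum()))
        assert float((trap * w).sum()) == pytest.approx(0.0, abs=1e-6 * t_std)
        trap_std = np.sqrt(float((w * trap ** 2).sum()))
        assert trap_std == pytest.approx(t_std, rel=1e-6)

    def test_band_limited(self, blob_phantom):
        trap = make_noise_trap(blob_phantom, lowpass=8.0, seed=2)
        spec = np.abs(sfft.fftn(trap)) ** 2
        freqs = [np.fft.fftfreq(n) for n in trap.shape]
        grids = np.meshgrid(*freqs, indexing="ij")
        f = np.sqrt(sum(g * g for g in grids))
        assert spec[f > 1 / 8 + 0.04].sum() < 0.01 * spec.sum()

    def test_seeds_give_independent_traps(self, blob_phantom):
        """Different seeds give essentially uncorrelated traps.

        A band-limited 32-box holds only a few hundred effective degrees of
        freedom, so the correlation bound is the ~2-sigma null fluctuation.
        """
        mask = soft_sphere_mask(32)
        sel = mask > 0.5
        ccs = []
        traps = [make_noise_trap(blob_phantom, 4.0, seed=s, mask=mask)
                 for s in range(1, 5)]
        for i in range(len(traps)):
            for j in range(i + 1, len(traps)):
                ccs.append(abs(np.corrcoef(traps[i][sel], traps[j][sel])[0, 1]))
        assert np.mean(ccs) < 0.1
        assert max(ccs) < 0.2


class TestAlign:
    def test_identity(self, blob_phantom):
        mask = soft_sphere_mask(32)
        grid = generate_grid(15, 45, 15, 45)
        ori, shift, cc = align_particle(blob_phantom, blob_phantom, mask, grid)
        assert cc >= 0.999
        assert np.linalg.norm(shift) < 0.1
        assert rotation_distance(euler_to_matrix(ori), np.eye(3)) < 1e-6

    def test_recovers_rotation_and_shift(self, blob_phantom, wedge):
        mask = soft_sphere_mask(32)
        grid = generate_grid(15, 45, 15, 45)
        j = 7
        rot = grid.matrices[j]
        particle = rotate_volume(blob_phantom, rot)
        particle = wedge_filtered(particle, wedge)
        particle = nd_shift(particle, (2.5, 0, 0), order=1)
        ori, shift, cc = align_particle(particle, blob_phantom, mask, grid,
                                        wedge_spec=wedge, shift_limit=4)
        assert rotation_distance(euler_to_matrix(ori), rot) < 1e-6
        assert shift[0] == pytest.approx(2.5, abs=0.25)
        assert abs(shift[1]) < 0.25 and abs(shift[2]) < 0.25

    def test_noise_separable_from_match(self, blob_phantom, wedge):
        mask = soft_sphere_mask(32)
        grid = generate_grid(20, 40, 20, 40)
        matched = wedge_filtered(blob_phantom, wedge)
        _, _, cc_match = align_particle(matched, blob_phantom, mask, grid,
                                        wedge_spec=wedge)
        noise_ccs = []
        for seed in range(5):
            noise = np.random.default_rng(seed).normal(
                size=blob_phantom.shape)
            _, _, cc = align_particle(noise, blob_phantom, mask, grid,
                                      wedge_spec=wedge)
            noise_ccs.append(cc)
        assert cc_match - np.mean(noise_ccs) >= 3 * np.std(noise_ccs)

    def test_empty_mask_rejected(self, blob_phantom):
        grid = generate_grid(20, 40, 20, 40)
        with pytest.raises(EstimationError, match="mask"):
            align_particle(blob_phantom, blob_phantom,
                           np.zeros_like(blob_phantom), grid)


class TestAverage:
    def test_single_identity_particle(self, blob_phantom):
        stack = ParticleStack(boxes=blob_phantom[None].astype(np.float32),
                              table=[ParticleRecord(tag=1)], wedges=[])
        avg = average_particles(stack)
        rms = np.sqrt(((avg - blob_phantom) ** 2).mean())
        assert rms < 1e-5 * blob_phantom.std()

    def test_complementary_wedges_fill_fourier_space(self, blob_phantom, wedge):
        rot = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        ori = matrix_to_euler(rot)
        p1 = wedge_filtered(blob_phantom, wedge)
        p2 = wedge_filtered(rotate_volume(blob_phantom, rot), wedge)
        table = [ParticleRecord(tag=1),
                 ParticleRecord(tag=2, tdrot=ori.tdrot, tilt=ori.tilt,
                                narot=ori.narot)]
        stack = ParticleStack(boxes=np.stack([p1, p2]).astype(np.float32),
                              table=table, wedges=[wedge, wedge])
        avg = average_particles(stack)
        cc = np.corrcoef(avg.ravel(), blob_phantom.ravel())[0, 1]
        assert cc > 0.95
        w = wedge_mask(wedge, blob_phantom.shape)
        coverage = ((sfft.fftshift(w) +
                     rotate_volume(sfft.fftshift(w), rot.T)) > 0.5).mean()
        assert coverage > 0.95

    def test_symmetrization_does_not_hurt(self, wedge):
        from tomopipe.simulator import make_phantom
        phantom = make_phantom("torus", 32, {"ring_radius": 8,
                                             "tube_radius": 3})
        rng = np.random.default_rng(4)
        boxes, table = [], []
        for i in range(6):
            noisy = wedge_filtered(phantom, wedge) + rng.normal(
                0, phantom.std(), phantom.shape)
            boxes.append(noisy)
            table.append(ParticleRecord(tag=i + 1))
        stack = ParticleStack(boxes=np.stack(boxes).astype(np.float32),
                              table=table, wedges=[wedge] * 6)
        plain = average_particles(stack)
        symmetrized = average_particles(stack, symmetry="C4")
        cc_plain = np.corrcoef(plain.ravel(), phantom.ravel())[0, 1]
        cc_sym = np.corrcoef(symmetrized.ravel(), phantom.ravel())[0, 1]
        assert cc_sym >= cc_plain - 1e-6

    def test_half_average_linearity(self, blob_phantom, wedge):
        rng = np.random.default_rng(5)
        boxes = np.stack([
            (wedge_filtered(blob_phantom, wedge) +
             rng.normal(0, 0.5, blob_phantom.shape)).astype(np.float32)
            for _ in range(4)])
        table = [ParticleRecord(tag=i + 1) for i in range(4)]
        stack = ParticleStack(boxes=boxes, table=table, wedges=[wedge] * 4)
        full = average_particles(stack)
        half_a = average_particles(ParticleStack(boxes=boxes[:2],
                                                 table=table[:2],
                                                 wedges=[wedge] * 2))
        half_b = average_particles(ParticleStack(boxes=boxes[2:],
                                                 table=table[2:],
                                                 wedges=[wedge] * 2))
        np.testing.assert_allclose((half_a + half_b) / 2, full,
                                   atol=1e-6 * np.abs(full).max() * 100)

    def test_zero_particles_rejected(self, blob_phantom):
        with pytest.raises(TomopipeError):
            average_particles(ParticleStack(
                boxes=np.zeros((0, 8, 8, 8)), table=[], wedges=[]))


class TestClassify:
    def test_identical_particles_all_in_reference_class(self, blob_phantom):
        stack = ParticleStack(
            boxes=np.stack([blob_phantom] * 4).astype(np.float32),
            table=[ParticleRecord(tag=i + 1) for i in range(4)], wedges=[])
        traps = [make_noise_trap(blob_phantom, 8.0, seed=s) for s in (1, 2)]
        model = ClassModel(references=[blob_phantom] + traps,
                           is_noise_trap=[False, True, True])
        grid = generate_grid(30, 30, 30, 30)
        assignments, table, refs, report = classify_mra(stack, model, 1, grid)
        assert np.all(assignments == 0)

    def test_report_has_one_row_per_iteration(self, blob_phantom):
        stack = ParticleStack(
            boxes=np.stack([blob_phantom] * 3).astype(np.float32),
            table=[ParticleRecord(tag=i + 1) for i in range(3)], wedges=[])
        model = ClassModel(
            references=[blob_phantom,
                        make_noise_trap(blob_phantom, 8.0, seed=1)],
            is_noise_trap=[False, True])
        grid = generate_grid(30, 30, 30, 30)
        _, _, _, report = classify_mra(stack, model, 3, grid)
        assert len(report) == 3
        assert [r["iteration"] for r in report] == [1, 2, 3]


class TestHalfSets:
    def test_benchmark_pick_count_splits_evenly(self):
        """4490 particles split into 2245 + 2245."""
        table = [ParticleRecord(tag=i + 1) for i in range(4490)]
        a, b = split_half_sets(table)
        assert (len(a), len(b)) == (2245, 2245)
        assert {r.half_set for r in a} == {1}
        assert {r.half_set for r in b} == {2}

    def test_odd_count(self):
        table = [ParticleRecord(tag=i + 1) for i in range(5)]
        a, b = split_half_sets(table)
        assert (len(a), len(b)) == (3, 2)
        assert {r.tag for r in a}.isdisjoint({r.tag for r in b})
        assert {r.tag for r in a} | {r.tag for r in b} == set(range(1, 6))

    def test_random_mode_deterministic(self):
        table = [ParticleRecord(tag=i + 1) for i in range(101)]
        a1, b1 = split_half_sets(table, mode="random", seed=9)
        a2, b2 = split_half_sets(table, mode="random", seed=9)
        assert [r.tag for r in a1] == [r.tag for r in a2]
        assert abs(len(a1) - len(b1)) <= 1

    def test_too_few_rejected(self):
        with pytest.raises(TomopipeError):
            split_half_sets([ParticleRecord(tag=1)])


class TestFsc:
    def test_identical_volumes_give_unity(self, blob_phantom):
        curve = compute_fsc(blob_phantom, blob_phantom, voxel_size=2.0)
        assert np.allclose(curve.values, 1.0, atol=1e-9)
        resolution, crossed = resolution_at(curve)
        assert not crossed
        assert resolution == pytest.approx(4.0)  # Nyquist at 2 A/voxel

    def test_resolution_arithmetic(self):
        """A crossing interpolated at shell 16 of a 64-box at 2 A/voxel = 8 A."""
        values = np.ones(33)
        values[17:] = 0.0
        values[16] = 0.143  # exact threshold at shell 16
        from tomopipe.sta import FscCurve
        curve = FscCurve(values=values, box=64, voxel_size=2.0)
        resolution, crossed = resolution_at(curve)
        assert crossed
        assert resolution == pytest.approx(8.0, rel=1e-6)

    def test_independent_noise_within_null_envelope(self):
        rng1 = np.random.default_rng(21)
        rng2 = np.random.default_rng(22)
        n = 48
        a = rng1.normal(size=(n, n, n))
        b = rng2.normal(size=(n, n, n))
        curve = compute_fsc(a, b, voxel_size=1.0)
        freqs = [np.fft.fftfreq(s) * s for s in a.shape]
        grids = np.meshgrid(*freqs, indexing="ij")
        radius = np.sqrt(sum(g * g for g in grids))
        shells = np.minimum(np.round(radius).astype(int), n // 2)
        counts = np.bincount(shells.ravel(), minlength=n // 2 + 1)
        envelope = 3.0 / np.sqrt(np.maximum(counts, 1))
        inside = np.abs(curve.values[1:]) < envelope[1:]
        assert inside.mean() >= 0.95

    def test_box_mismatch_rejected(self):
        with pytest.raises(TomopipeError):
            compute_fsc(np.zeros((8, 8, 8)), np.zeros((16, 16, 16)))
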