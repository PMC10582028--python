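"""MRC/table/STAR round trips and configuration merging."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tomopipe.errors import ConfigError, FormatError
from tomopipe.formats_io import (EffectiveConfig, ParticleRecord, export_star,
                                 load_defaults, merge_config, read_mrc,
                                 read_star, read_table, write_mrc, write_table)


class TestMrc:
    def test_round_trip_identity(self, tmp_path):
        vol = np.zeros((16, 16, 16), dtype=np.float32)
        path = write_mrc(vol, tmp_path / "zeros.mrc", voxel_size=2.0)
        back, header = read_mrc(path)
        np.testing.assert_array_equal(back, vol)
        assert header.voxel_size == pytest.approx(2.0)
        assert header.shape == (16, 16, 16)

    def test_voxel_size_survives_header(self, tmp_path):
        # 1.378 A/voxel: a realistic K3 counting-mode pixel size
        vol = np.random.default_rng(0).normal(size=(8, 8, 8)).astype(np.float32)
        path = write_mrc(vol, tmp_path / "v.mrc", voxel_size=1.378)
        back, header = read_mrc(path)
        assert header.voxel_size == pytest.approx(1.378, abs=1e-5)
        np.testing.assert_array_equal(back, vol)

    def test_truncated_file_is_format_error(self, tmp_path):
        path = write_mrc(np.ones((8, 8, 8), dtype=np.float32), tmp_path / "t.mrc")
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 2])
        with pytest.raises(FormatError, match="truncated"):
            read_mrc(path)

    def test_short_header_is_format_error(self, tmp_path):
        path = tmp_path / "short.mrc"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(FormatError):
            read_mrc(path)

    def test_non_finite_refused(self, tmp_path):
        vol = np.ones((8, 8, 8))
        vol[0, 0, 0] = np.nan
        with pytest.raises(FormatError, match="non-finite"):
            write_mrc(vol, tmp_path / "nan.mrc")

    def test_gemmi_reads_our_mrc(self, tmp_path):
        """Independent reader oracle: gemmi agrees on voxels and cell."""
        gemmi = pytest.importorskip("gemmi")
        vol = np.random.default_rng(1).normal(size=(12, 10, 8)).astype(np.float32)
        path = write_mrc(vol, tmp_path / "g.mrc", voxel_size=2.5)
        mm = gemmi.read_ccp4_map(str(path))
        arr = np.array(mm.grid, copy=False)
        np.testing.assert_allclose(arr, vol, atol=1e-6)
        assert mm.grid.unit_cell.a == pytest.approx(12 * 2.5, rel=1e-5)


finite_float = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False,
                         allow_infinity=False, width=32)


class TestTable:
    def test_round_trip_small(self, tmp_path):
        records = [ParticleRecord(tag=i + 1, cc=0.1 * i, x=10 + i, y=20, z=30,
                                  dx=0.25, tdrot=15.5 * i, class_id=i % 3,
                                  tomogram_id=2)
                   for i in range(10)]
        path = write_table(records, tmp_path / "p.tbl")
        back = read_table(path)
        assert len(back) == 10
        for a, b in zip(records, back):
            for name in ("tag", "x", "y", "z", "class_id", "tomogram_id",
                         "half_set"):
                assert getattr(a, name) == getattr(b, name)
            for name in ("cc", "dx", "dy", "dz", "tdrot", "tilt", "narot"):
                assert getattr(b, name) == pytest.approx(getattr(a, name),
                                                         rel=1e-6, abs=1e-9)

    @given(ccs=st.lists(finite_float, min_size=1, max_size=20),
           angles=st.lists(st.floats(0, 359.99, allow_nan=False),
                           min_size=1, max_size=20))
    def test_round_trip_randomized(self, tmp_path, ccs, angles):
        records = [ParticleRecord(tag=i + 1, cc=float(cc),
                                  tdrot=float(angles[i % len(angles)]))
                   for i, cc in enumerate(ccs)]
        path = write_table(records, tmp_path / "h.tbl")
        back = read_table(path)
        for a, b in zip(records, back):
            assert b.cc == pytest.approx(a.cc, rel=1e-6, abs=1e-9)
            assert b.tdrot == pytest.approx(a.tdrot, rel=1e-6, abs=1e-9)

    def test_cc_values_survive_exactly(self, tmp_path):
        records = [ParticleRecord(tag=1, cc=0.9), ParticleRecord(tag=2, cc=0.5)]
        back = read_table(write_table(records, tmp_path / "cc.tbl"))
        assert [r.cc for r in back] == [0.9, 0.5]

    def test_malformed_row_cites_line(self, tmp_path):
        path = tmp_path / "bad.tbl"
        good = "1 0.5 10 10 10 0 0 0 0 0 0 0 1 0"
        path.write_text(good + "\n1 2 3\n")
        with pytest.raises(FormatError, match=r":2"):
            read_table(path)

    def test_duplicate_tags_rejected(self, tmp_path):
        path = tmp_path / "dup.tbl"
        row = "1 0.5 10 10 10 0 0 0 0 0 0 0 1 0"
        path.write_text(row + "\n" + row + "\n")
        with pytest.raises(FormatError, match="duplicate tag"):
            read_table(path)

    def test_extra_columns_tolerated_with_warning(self, tmp_path):
        path = tmp_path / "extra.tbl"
        path.write_text("1 0.5 10 10 10 0 0 0 0 0 0 0 1 0 99 99\n")
        with pytest.warns(UserWarning, match="extra trailing"):
            back = read_table(path)
        assert back[0].tag == 1


class TestStar:
    def test_particle_and_tomogram_blocks(self, tmp_path):
        records = [ParticleRecord(tag=i + 1, x=10 * i + 1, tomogram_id=1)
                   for i in range(3)]
        dose = [(-45.0 + 3 * i, 3.0 * i) for i in range(31)]
        path = export_star(records, {1: "tomo_a"}, {1: dose}, tmp_path / "p.star")
        blocks = read_star(path)
        assert len(blocks["particles"]) == 3
        assert len(blocks["tomograms"]) == 31

    def test_uneven_dose_preexposure(self, tmp_path):
        """A high-dose zero-tilt image shifts every later pre-exposure value."""
        from tomopipe.simulator import TiltScheme
        scheme = TiltScheme(-45, 45, 3, dose_per_tilt=3.0, zero_tilt_dose=15.0)
        _, pre = scheme.dose_table()
        records = [ParticleRecord(tag=1, tomogram_id=1)]
        dose_rows = list(zip(scheme.angles.tolist(), pre.tolist()))
        path = export_star(records, {1: "t"}, {1: dose_rows}, tmp_path / "d.star")
        rows = read_star(path)["tomograms"]
        pre_vals = [float(r["_preExposure"]) for r in rows]
        # zero-tilt was recorded first at 15 e/A^2: every other image has
        # pre-exposure >= 15, and the zero-tilt image itself has 0
        zero_idx = int(np.argmin(np.abs(scheme.angles)))
        assert pre_vals[zero_idx] == 0.0
        others = [v for i, v in enumerate(pre_vals) if i != zero_idx]
        assert min(others) >= 15.0
        assert len(set(pre_vals)) > 2  # genuinely non-uniform

    def test_identity_orientation_maps_to_zero_angles(self, tmp_path):
        records = [ParticleRecord(tag=1, tomogram_id=1)]
        path = export_star(records, {1: "t"}, {1: []}, tmp_path / "i.star")
        row = read_star(path)["particles"][0]
        for key in ("_angleRot", "_angleTilt", "_anglePsi"):
            assert float(row[key]) == pytest.approx(0.0, abs=1e-6)

    def test_positions_survive_reimport(self, tmp_path):
        records = [ParticleRecord(tag=i + 1, x=5 + i, y=7, z=9, dx=0.25,
                                  tomogram_id=1) for i in range(4)]
        path = export_star(records, {1: "t"}, {1: []}, tmp_path / "r.star")
        rows = read_star(path)["particles"]
        for rec, row in zip(records, rows):
            assert float(row["_coordinateX"]) == pytest.approx(
                rec.x - 1 + rec.dx, abs=1e-6)

    def test_missing_tomogram_description(self, tmp_path):
        records = [ParticleRecord(tag=1, tomogram_id=5)]
        with pytest.raises(FormatError, match="tomogram 5"):
            export_star(records, {1: "t"}, {1: []}, tmp_path / "m.star")


class TestConfig:
    def test_user_value_wins(self):
        eff = merge_config(load_defaults(), {
            "general": {"pixel_size": 2.0},
            "modules": [{"name": "template_match",
                         "params": {"threshold_sigma": 7.0}}]})
        params = dict(eff.modules)["template_match"]
        assert params["threshold_sigma"] == 7.0
        assert eff.provenance["template_match.threshold_sigma"] == "user"

    def test_defaults_used_verbatim_when_omitted(self):
        defaults = load_defaults()
        eff = merge_config(defaults, {"general": {},
                                      "modules": [{"name": "template_match"}]})
        params = dict(eff.modules)["template_match"]
        assert params["threshold_sigma"] == \
            defaults["modules"]["template_match"]["threshold_sigma"]

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="frobnicate"):
            merge_config(load_defaults(), {
                "general": {},
                "modules": [{"name": "template_match",
                             "params": {"frobnicate": 1}}]})

    def test_unknown_module_rejected(self):
        with pytest.raises(ConfigError, match="no_such_module"):
            merge_config(load_defaults(), {"general": {},
                                           "modules": [{"name": "no_such_module"}]})

    def test_missing_general_rejected(self):
        with pytest.raises(ConfigError, match="general"):
            merge_config(load_defaults(), {"modules": []})

    def test_type_mismatch_rejected(self):
        with pytest.raises(ConfigError, match="type mismatch"):
            merge_config(load_defaults(), {
                "general": {},
                "modules": [{"name": "reconstruct",
                             "params": {"filter": 3}}]})

    def test_module_order_preserved(self):
        eff = merge_config(load_defaults(), {
            "general": {},
            "modules": [{"name": "reconstruct"}, {"name": "simulate"},
                        {"name": "template_match"}]})
        assert [m for m, _ in eff.modules] == ["reconstruct", "simulate",
                                               "template_match"]

    def test_merge_idempotent(self):
        defaults = load_defaults()
        eff = merge_config(defaults, {
            "general": {"pixel_size": 2.5},
            "modules": [{"name": "simulate", "params": {"snr": 0.25}}]})
        again = merge_config(defaults, eff.to_user_dict())
        assert again.general == eff.general
        assert again.modules == eff.modules
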