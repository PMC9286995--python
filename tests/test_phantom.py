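"""Phantom generator: exact ground truth, determinism, dataset round-trips."""

import dataclasses

import numpy as np
import pytest

from conftest import make_disc
from lvseg.phantom import (
    PhantomConfig,
    generate_case,
    generate_dataset,
    generate_slice,
    read_contour_txt,
    read_mask_png,
)


def _rng():
    return np.random.default_rng(0)


class TestGenerateSlice:
    def test_noiseless_endo_mask_equals_discrete_disc(self, tiny_phantom_cfg):
        cfg = dataclasses.replace(tiny_phantom_cfg, noise_sd=0.0)
        rec = generate_slice(cfg, (32.0, 32.0), 10.0, 4.0, "ED", _rng())
        oracle = make_disc(cfg.image_size, (32.0, 32.0), 10.0)
        assert np.array_equal(rec.endo_mask, oracle)
        assert rec.endo_mask.sum() == oracle.sum()

    def test_es_radius_is_multiplicative(self, tiny_phantom_cfg):
        cfg = dataclasses.replace(tiny_phantom_cfg, es_scale=0.7)
        rec = generate_slice(cfg, (32.0, 32.0), 10.0, 4.0, "ES", _rng())
        assert rec.endo_radius_px == pytest.approx(7.0)

    def test_endo_strictly_inside_epi(self, tiny_phantom_cfg):
        for seed in range(5):
            rec = generate_slice(tiny_phantom_cfg, (32.0, 31.0), 9.0, 4.0, "ED",
                                 np.random.default_rng(seed))
            assert not np.any(rec.endo_mask & ~rec.epi_mask)
            assert rec.epi_mask.sum() > rec.endo_mask.sum()

    def test_noiseless_pool_intensity_exact(self, tiny_phantom_cfg):
        cfg = dataclasses.replace(tiny_phantom_cfg, noise_sd=0.0)
        rec = generate_slice(cfg, (32.0, 32.0), 10.0, 4.0, "ED", _rng())
        assert rec.image[rec.endo_mask].mean() == cfg.intensity_pool

    def test_out_of_frame_radius_rejected(self, tiny_phantom_cfg):
        with pytest.raises(ValueError, match="frame"):
            generate_slice(tiny_phantom_cfg, (5.0, 32.0), 10.0, 4.0, "ED", _rng())


class TestGenerateCase:
    def test_seeded_determinism_bit_identical(self, tiny_phantom_cfg):
        a = generate_case(tiny_phantom_cfg, 123)
        b = generate_case(tiny_phantom_cfg, 123)
        assert len(a.slices) == len(b.slices)
        for ra, rb in zip(a.slices, b.slices):
            assert np.array_equal(ra.image, rb.image)
            assert np.array_equal(ra.endo_mask, rb.endo_mask)

    def test_slice_count_contract(self, tiny_phantom_cfg):
        cfg = dataclasses.replace(tiny_phantom_cfg, n_slices=8,
                                  endo_radius_px=(8.0, 9.0))
        case = generate_case(cfg, 5)
        assert len(case.phase_slices("ED")) == 8
        assert len(case.phase_slices("ES")) == 8

    def test_apex_taper_cumulative(self, tiny_phantom_cfg):
        cfg = dataclasses.replace(tiny_phantom_cfg, apex_taper=0.9,
                                  endo_radius_px=(10.0, 10.0), n_slices=4,
                                  center_jitter_px=0.0)
        case = generate_case(cfg, 1)
        ed = case.phase_slices("ED")
        assert ed[3].endo_radius_px == pytest.approx(10.0 * 0.9**3)

    def test_radii_non_increasing_base_to_apex(self, tiny_phantom_cfg):
        case = generate_case(tiny_phantom_cfg, 9)
        radii = [s.endo_radius_px for s in case.phase_slices("ED")]
        assert all(a >= b for a, b in zip(radii, radii[1:]))

    def test_taper_below_one_px_truncates_with_warning(self, tiny_phantom_cfg):
        cfg = dataclasses.replace(tiny_phantom_cfg, apex_taper=0.3, n_slices=8,
                                  endo_radius_px=(8.0, 8.0))
        with pytest.warns(UserWarning, match="truncating"):
            case = generate_case(cfg, 2)
        assert 0 < len(case.phase_slices("ED")) < 8


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"es_scale": 0.0},
            {"es_scale": 1.2},
            {"intensity_pool": 100.0, "intensity_myo": 150.0},
            {"endo_radius_px": (30.0, 40.0), "image_size": 64},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomConfig(**kwargs)


class TestGenerateDataset:
    def test_manifest_row_count(self, tiny_phantom_cfg, tmp_path):
        manifest = generate_dataset(tiny_phantom_cfg, 3, 7, tmp_path / "d")
        assert len(manifest) == 3 * 3 * 2  # cases x slices x phases

    def test_mask_roundtrip_lossless(self, tiny_phantom_cfg, tmp_path):
        out = tmp_path / "d"
        manifest = generate_dataset(tiny_phantom_cfg, 1, 7, out)
        case = generate_case(
            tiny_phantom_cfg,
            int(np.random.default_rng(7).integers(0, 2**31 - 1, size=1)[0]),
            case_id="case000",
        )
        row = manifest.iloc[0]
        rec = case.slices[0]
        assert np.array_equal(read_mask_png(out / row["endo_mask"]), rec.endo_mask)
        contour = read_contour_txt(out / row["endo_contour"])
        assert contour.shape[1] == 2 and len(contour) >= 3

    def test_distinct_case_seeds_give_distinct_jitter(self, tiny_phantom_cfg, tmp_path):
        manifest = generate_dataset(tiny_phantom_cfg, 4, 11, tmp_path / "d")
        centers = manifest.groupby("case")[["true_center_row", "true_center_col"]].first()
        assert len(centers.drop_duplicates()) > 1

    def test_refuses_overwrite_without_flag(self, tiny_phantom_cfg, tmp_path):
        generate_dataset(tiny_phantom_cfg, 1, 7, tmp_path / "d")
        with pytest.raises(FileExistsError):
            generate_dataset(tiny_phantom_cfg, 1, 7, tmp_path / "d")
        generate_dataset(tiny_phantom_cfg, 1, 7, tmp_path / "d", overwrite=True)

    def test_fixed_seed_byte_identical_datasets(self, tiny_phantom_cfg, tmp_path):
        generate_dataset(tiny_phantom_cfg, 2, 13, tmp_path / "a")
        generate_dataset(tiny_phantom_cfg, 2, 13, tmp_path / "b")
        files_a = sorted(p.relative_to(tmp_path / "a")
                         for p in (tmp_path / "a").rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(tmp_path / "b")
                         for p in (tmp_path / "b").rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()
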