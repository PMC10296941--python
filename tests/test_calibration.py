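"""Flat-field and transmission-standardization behavior."""

import numpy as np
import pytest

from hsipath.calibration import (
    CalibrationConfig,
    auto_background,
    flat_field,
    transmission_standardize,
)
from hsipath.datacube import DataCube, wavelength_axis
from hsipath.errors import CalibrationError, StageError


def _cube(values, stage="raw"):
    values = np.asarray(values, dtype=float)
    return DataCube(values, wavelength_axis(max(values.shape[0], 2))[: values.shape[0]]
                    if values.shape[0] >= 2 else np.array([410.0]), stage=stage)


def brute_force_column(col: np.ndarray, trim: int) -> np.ndarray:
    """Independent oracle: full sort, slice, mean, divide."""
    ordered = np.sort(col)
    mean = ordered[trim : len(col) - trim].mean()
    return col / mean


class TestFlatField:
    def test_constant_cube_becomes_ones(self):
        out = flat_field(_cube(np.full((3, 20, 5), 7.0)))
        np.testing.assert_allclose(out.values, 1.0)
        assert out.stage == "even"

    def test_single_column_hand_example(self):
        # column [1..5], trim 1 -> divide by mean(2,3,4)=3
        cube = _cube(np.array([1.0, 2, 3, 4, 5]).reshape(1, 5, 1))
        out = flat_field(cube, CalibrationConfig(trim_count=1))
        np.testing.assert_allclose(
            out.values[0, :, 0], [1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3]
        )

    def test_matches_brute_force_oracle_per_band_and_column(self, rng):
        cube = _cube(rng.uniform(0.5, 2.0, size=(4, 50, 6)))
        config = CalibrationConfig(trim_count=150)  # scales down to (50-1)//4 = 12
        out = flat_field(cube, config)
        trim = config.effective_trim(50)
        assert trim == 12
        for b in range(4):
            for c in range(6):
                np.testing.assert_allclose(
                    out.values[b, :, c],
                    brute_force_column(cube.values[b, :, c], trim),
                    rtol=1e-12,
                )

    def test_full_scale_trim_keeps_700_survivors(self, rng):
        col = rng.uniform(0.1, 1.0, size=1000)
        cube = _cube(col.reshape(1, 1000, 1))
        out = flat_field(cube, CalibrationConfig(trim_count=150))
        ordered = np.sort(col)
        kept = ordered[150:850]
        assert kept.size == 700
        np.testing.assert_allclose(out.values[0, :, 0], col / kept.mean(), rtol=1e-12)

    def test_idempotent_on_noiseless_output(self):
        rng = np.random.default_rng(3)
        cube = _cube(rng.uniform(0.5, 1.5, size=(3, 40, 5)))
        once = flat_field(cube)
        twice = flat_field(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-6)

    def test_all_zero_column_raises_naming_column(self):
        values = np.ones((2, 20, 4))
        values[:, :, 2] = 0.0
        with pytest.raises(CalibrationError, match="column 2"):
            flat_field(_cube(values))

    def test_overtrim_rejected_at_full_scale(self):
        # below 601 rows the trim scales down automatically; at full scale
        # an infeasible trim must raise instead of silently shrinking
        with pytest.raises(ValueError):
            flat_field(_cube(np.ones((1, 601, 1))), CalibrationConfig(trim_count=301))


class TestTransmissionStandardize:
    def test_everything_equals_background_gives_ones(self):
        cube = _cube(np.full((3, 4, 4), 0.8), stage="even")
        mask = np.ones((4, 4), dtype=bool)
        out = transmission_standardize(cube, mask)
        np.testing.assert_allclose(out.values, 1.0)
        assert out.stage == "tran"

    def test_two_band_hand_example(self):
        # background SC=[2,4]; tissue pixel [1,1] -> [0.5, 0.25]
        values = np.empty((2, 1, 2))
        values[:, 0, 0] = [2.0, 4.0]  # background pixel
        values[:, 0, 1] = [1.0, 1.0]  # tissue pixel
        mask = np.array([[True, False]])
        out = transmission_standardize(_cube(values, stage="even"), mask)
        np.testing.assert_allclose(out.values[:, 0, 1], [0.5, 0.25])

    def test_background_mean_exactly_one_per_band(self, rng):
        values = rng.uniform(0.5, 2.0, size=(5, 10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:3] = True
        out = transmission_standardize(_cube(values, stage="even"), mask)
        np.testing.assert_allclose(out.values[:, mask].mean(axis=1), 1.0, rtol=1e-14)

    def test_scale_invariance(self, rng):
        values = rng.uniform(0.5, 2.0, size=(4, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[0] = True
        a = transmission_standardize(_cube(values, stage="even"), mask)
        b = transmission_standardize(_cube(values * 3.7, stage="even"), mask)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_empty_mask_and_zero_band_rejected(self):
        cube = _cube(np.ones((2, 4, 4)), stage="even")
        with pytest.raises(ValueError):
            transmission_standardize(cube, np.zeros((4, 4), dtype=bool))
        bad = np.ones((2, 4, 4))
        bad[1] = 0.0
        mask = np.ones((4, 4), dtype=bool)
        with pytest.raises(CalibrationError, match="band 1"):
            transmission_standardize(_cube(bad, stage="even"), mask)


class TestAutoBackground:
    def test_known_background_rectangle_detected(self, rng):
        # flat bright rectangle (rows 0-9) over spectrally structured tissue
        values = np.tile(
            rng.uniform(0.3, 0.8, size=(6, 1, 1)), (1, 40, 40)
        ) * rng.uniform(0.95, 1.05, size=(1, 40, 40))
        values[:, :10, :] = 1.0
        even = _cube(values, stage="even")
        mask = auto_background(even, quantile=0.7)
        background = np.zeros((40, 40), dtype=bool)
        background[:10] = True
        assert mask[background].all()
        assert not mask[~background].any()

    def test_uniform_cube_keeps_bright_flat_pixels(self):
        cube = _cube(np.ones((3, 10, 10)), stage="even")
        mask = auto_background(cube)
        assert mask.all()  # every pixel ties at the quantile and has zero CV

    def test_tissue_only_cube_raises(self, rng):
        # spectrally structured pixels everywhere: CV too high for any pixel
        spectra = rng.uniform(0.2, 1.0, size=(6, 1, 1))
        values = np.tile(spectra, (1, 8, 8))
        with pytest.raises(CalibrationError):
            auto_background(_cube(values, stage="even"), cv_threshold=0.01)

    def test_requires_flat_fielded_stage(self):
        with pytest.raises(StageError):
            auto_background(_cube(np.ones((2, 4, 4)), stage="raw"))


class TestComposedCalibration:
    def test_recovers_clean_spectra_on_noiseless_phantom(self, stripes_slide_noiseless):
        from hsipath.synthetic import POPULATION_IDS

        spec, raw, truth = stripes_slide_noiseless
        even = flat_field(raw)
        tran = transmission_standardize(even, truth.background_mask)
        for name, pid in POPULATION_IDS.items():
            region = truth.population_map == pid
            if not region.any():
                continue
            clean = truth.class_spectra[name]
            recovered = tran.values[:, region]
            rel_err = np.abs(recovered - clean[:, None]) / clean[:, None]
            assert rel_err.max() < 0.01, name
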