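"""Synthetic spectra generator: pH model, mixing, plates, progress series."""

import numpy as np
import pytest

from specunmix import (
    AssayDesign,
    blank_correct,
    make_mixture_spectrum,
    make_progress_series,
    make_reference_spectrum,
    make_validation_plate,
    normalize_to_isosbestic,
    preset_pair,
    unmix,
)
from specunmix.errors import CapacityError, ConstraintError, DesignError
from specunmix.plate_io import read_plate_csv, write_plate_csv
from specunmix.spectra import find_isosbestic_crossings
from specunmix.synthetic import PRESET_PAIRS, GaussianBand


class TestReferenceSpectrumModel:
    def test_low_ph_gives_pure_neutral_species(self, dt_models, grid):
        _, base = dt_models
        spec = make_reference_spectrum(base, 7.0, grid)
        w = 1.0 / (1.0 + 10.0 ** (7.0 - base.pka))
        neutral = sum(b.evaluate(grid) for b in base.bands)
        deprot = sum(b.evaluate(grid) for b in base.deprotonated_bands)
        np.testing.assert_allclose(
            spec.absorbance_au, w * neutral + (1 - w) * deprot, atol=1e-12
        )
        # pKa 9.9 means the neutral species dominates at pH 7 (w > 0.99)
        assert w > 0.99

    def test_ph_equal_pka_is_equal_blend(self, grid):
        _, base = preset_pair("dT-thymine")
        spec = make_reference_spectrum(base, base.pka, grid)
        neutral = sum(b.evaluate(grid) for b in base.bands)
        deprot = sum(b.evaluate(grid) for b in base.deprotonated_bands)
        np.testing.assert_allclose(
            spec.absorbance_au, 0.5 * (neutral + deprot), atol=1e-12
        )

    def test_alkaline_maxima_of_default_pair(self, dt_pure_spectra, grid):
        nuc, base = dt_pure_spectra
        assert abs(grid[np.argmax(nuc.absorbance_au)] - 266.0) <= 1.0
        assert abs(grid[np.argmax(base.absorbance_au)] - 287.0) <= 1.0

    def test_ph_outside_working_range_rejected(self, dt_models, grid):
        with pytest.raises(ValueError, match="range"):
            make_reference_spectrum(dt_models[0], 6.0, grid)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            GaussianBand(200.0, 10.0, 0.5)  # center off the UV/Vis range
        with pytest.raises(ValueError):
            GaussianBand(270.0, -1.0, 0.5)


class TestPresets:
    @pytest.mark.parametrize("name", sorted(PRESET_PAIRS))
    def test_single_crossing_well_separated_maxima(self, name, grid):
        nuc, base = preset_pair(name)
        sn = make_reference_spectrum(nuc, 13.0, grid)
        sb = make_reference_spectrum(base, 13.0, grid)
        crossings = find_isosbestic_crossings(sn, sb, (255.0, 305.0))
        assert len(crossings) == 1
        sep = abs(
            grid[np.argmax(sn.absorbance_au)] - grid[np.argmax(sb.absorbance_au)]
        )
        assert sep >= 15.0

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="available"):
            preset_pair("caffeine-theobromine")


class TestMixtureSpectrum:
    def test_clean_unit_mixture_is_the_pure_spectrum(self, dt_pure_spectra):
        raw, blank = make_mixture_spectrum(
            dt_pure_spectra, [1.0, 0.0], scale=1.0, blank_level=0.0,
            noise_sd=0.0, solvent=None, rng=0,
        )
        np.testing.assert_array_equal(
            raw.absorbance_au, dt_pure_spectra[0].absorbance_au
        )
        np.testing.assert_array_equal(blank.absorbance_au, 0.0)

    def test_same_seed_is_bit_identical(self, dt_pure_spectra):
        a = make_mixture_spectrum(dt_pure_spectra, [0.5, 0.5], rng=42)
        b = make_mixture_spectrum(dt_pure_spectra, [0.5, 0.5], rng=42)
        np.testing.assert_array_equal(a[0].absorbance_au, b[0].absorbance_au)
        np.testing.assert_array_equal(a[1].absorbance_au, b[1].absorbance_au)

    def test_inadmissible_fractions_rejected(self, dt_pure_spectra):
        with pytest.raises(ConstraintError):
            make_mixture_spectrum(dt_pure_spectra, [0.7, 0.7])

    def test_noisy_round_trip_recovers_composition(self, dt_refs, dt_pure_spectra):
        """0.70/0.30 mixtures at assay noise: recovery within 3 pp almost always."""
        hits = 0
        for seed in range(200):
            raw, blank = make_mixture_spectrum(
                dt_pure_spectra, [0.7, 0.3], noise_sd=0.005, rng=seed
            )
            corrected = blank_correct(raw, blank)
            sample = normalize_to_isosbestic(corrected, dt_refs.isosbestic_nm)
            res = unmix(sample, dt_refs)
            if abs(res.fractions[0] - 0.7) <= 0.03:
                hits += 1
        assert hits >= 190


class TestValidationPlate:
    def test_design_geometry_and_determinism(self, dt_models):
        design = AssayDesign()
        pairs = [preset_pair(n) for n in sorted(PRESET_PAIRS)]
        plate = make_validation_plate(design, pairs)
        # 2 blanks + 3 pairs * (2 compounds * 4 reference reps) + 36 samples
        assert len(plate.plate.columns) - 1 == 2 + 24 + 36
        assert len(plate.truth) == 36
        assert plate.layout.blank_wells == ["A1", "A2"]
        again = make_validation_plate(design, pairs)
        np.testing.assert_array_equal(
            plate.plate.to_numpy(), again.plate.to_numpy()
        )

    def test_isosbestic_constants_recorded(self):
        plate = make_validation_plate(AssayDesign(), [preset_pair("dT-thymine")])
        assert plate.isosbestic_nm["dT-thymine"] == 278.0

    def test_zero_replicates_is_a_design_error(self):
        with pytest.raises(DesignError):
            AssayDesign(replicates=0)

    def test_capacity_of_the_plate_enforced(self):
        big = AssayDesign(fractions=tuple(np.linspace(0, 1, 15)), replicates=2)
        with pytest.raises(CapacityError):
            make_validation_plate(big, [preset_pair(n) for n in sorted(PRESET_PAIRS)])

    def test_plate_round_trips_through_csv(self, tmp_path):
        plate = make_validation_plate(AssayDesign(), [preset_pair("dT-thymine")])
        path = tmp_path / "plate.csv"
        write_plate_csv(path, plate.plate, header_comments=["synthetic fixture"])
        spectra = read_plate_csv(path, plate.layout)
        for well in plate.plate.columns[1:]:
            np.testing.assert_array_equal(
                spectra[well].absorbance_au, plate.plate[well].to_numpy()
            )


class TestProgressSeries:
    quiet = dict(
        noise_sd=0.0, blank_level=0.0, solvent=None, dilution_range=(1.0, 1.0)
    )

    def test_conversion_limits(self, dt_models):
        nuc, base = dt_models
        series, conv = make_progress_series(
            nuc, base, x_eq=0.8, k_obs=1e-3,
            times_s=[0.0, 1e7], design=AssayDesign(**self.quiet),
        )
        assert conv[0] == 0.0
        assert conv[1] == pytest.approx(0.8, abs=1e-9)

    def test_noiseless_series_round_trips_through_unmixing(
        self, dt_models, dt_refs
    ):
        nuc, base = dt_models
        times = [0.0, 120.0, 600.0, 1800.0, 7200.0]
        series, conv = make_progress_series(
            nuc, base, x_eq=0.72, k_obs=5e-4, times_s=times,
            design=AssayDesign(**self.quiet),
        )
        for (t, raw, blank), true_conv in zip(series, conv):
            corrected = blank_correct(raw, blank)
            sample = normalize_to_isosbestic(corrected, dt_refs.isosbestic_nm)
            res = unmix(sample, dt_refs)
            assert abs(res.fractions[1] - true_conv) < 1e-6

    def test_invalid_kinetic_parameters(self, dt_models):
        nuc, base = dt_models
        with pytest.raises(DesignError):
            make_progress_series(nuc, base, x_eq=1.2, k_obs=1e-3, times_s=[0])
        with pytest.raises(DesignError):
            make_progress_series(nuc, base, x_eq=0.5, k_obs=-1.0, times_s=[0])


class TestNoiseDegradation:
    @pytest.mark.filterwarnings("ignore:blank-corrected")
    def test_recovery_rmsd_nondecreasing_in_noise(self):
        """More photometric noise never improves composition recovery.

        Pooled over a fixed seed set so well-level cross terms average out.
        """
        pair = [preset_pair("dT-thymine")]
        from specunmix.workflow import validate_plate

        pooled = []
        for sd in (0.0, 0.005, 0.02, 0.05):
            errors = []
            for seed in (1, 2, 3, 4, 5):
                plate = make_validation_plate(
                    AssayDesign(noise_sd=sd, seed=seed), pair
                )
                table = validate_plate(plate)["dT-thymine"]
                actual, predicted = table.pairs("thymine")
                errors.extend((predicted - actual).tolist())
            pooled.append(float(np.sqrt(np.mean(np.square(errors)))))
        assert all(a <= b + 1e-12 for a, b in zip(pooled, pooled[1:]))
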