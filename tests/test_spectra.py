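"""Spectrum model, blank correction, isosbestic detection, normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specunmix import (
    ReferenceSet,
    Spectrum,
    blank_correct,
    find_isosbestic,
    find_isosbestic_crossings,
    linear_combination,
    normalize_to_isosbestic,
    regrid,
)
from specunmix.errors import (
    AmbiguousIsosbesticError,
    ConstraintError,
    GridMismatchError,
    InsufficientSignalError,
    NoIsosbesticError,
)
from specunmix.spectra import average_spectra


class TestSpectrumModel:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            Spectrum([250.0, 251.0, 253.0], [0.1, 0.2, 0.3])

    def test_rejects_decreasing_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum([252.0, 251.0, 250.0], [0.1, 0.2, 0.3])

    def test_rejects_nonfinite_absorbance(self):
        with pytest.raises(ValueError, match="finite"):
            Spectrum([250.0, 251.0, 252.0], [0.1, np.nan, 0.3])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            Spectrum([250.0, 251.0, 252.0], [0.1, 0.2])

    def test_at_returns_grid_value(self, grid):
        spec = Spectrum(grid, np.linspace(0, 1, grid.size))
        assert spec.at(250.0) == 0.0
        assert spec.at(350.0) == 1.0
        with pytest.raises(ValueError, match="not on the spectrum grid"):
            spec.at(275.5)


class TestBlankCorrect:
    def test_measured_signal_minus_blank(self, make_flat):
        # working levels of the assay: ~0.394 AU signal over a 0.032 AU blank
        raw = make_flat(0.394)
        blank = make_flat(0.032)
        corrected = blank_correct(raw, blank)
        assert corrected.at(278.0) == pytest.approx(0.362, abs=1e-12)

    def test_raw_equals_blank_gives_zero(self, make_flat):
        corrected = blank_correct(make_flat(0.2), make_flat(0.2))
        assert np.all(corrected.absorbance_au == 0.0)

    def test_grid_mismatch_is_an_error(self, grid):
        raw = Spectrum(grid, np.ones(grid.size))
        blank = Spectrum(grid[:-1], np.ones(grid.size - 1))
        with pytest.raises(GridMismatchError):
            blank_correct(raw, blank)

    @pytest.mark.filterwarnings("ignore:blank-corrected")
    @given(seed=st.integers(0, 2**32 - 1))
    def test_linearity_in_the_raw_spectrum(self, grid, seed):
        rng = np.random.default_rng(seed)
        a, b, blank = (
            Spectrum(grid, rng.uniform(0, 1, grid.size)) for _ in range(3)
        )
        lhs = blank_correct(
            Spectrum(grid, a.absorbance_au + b.absorbance_au), blank
        )
        rhs = blank_correct(a, blank).absorbance_au + b.absorbance_au
        np.testing.assert_allclose(lhs.absorbance_au, rhs, atol=1e-12)


class TestFindIsosbestic:
    def test_default_pair_crosses_at_278(self, dt_pure_spectra):
        nuc, base = dt_pure_spectra
        assert find_isosbestic(nuc, base) == 278.0

    def test_identical_spectra_are_degenerate(self, dt_pure_spectra):
        nuc, _ = dt_pure_spectra
        with pytest.raises((AmbiguousIsosbesticError, NoIsosbesticError)):
            find_isosbestic(nuc, nuc)

    def test_search_range_excluding_crossing(self, dt_pure_spectra):
        nuc, base = dt_pure_spectra
        with pytest.raises(NoIsosbesticError):
            find_isosbestic(nuc, base, search_range=(320.0, 350.0))

    def test_matches_brute_force_scan_on_random_pairs(self, grid):
        """Detection agrees with an exhaustive sign-change oracle.

        1000 random single-band spectrum pairs; whenever the oracle finds
        a unique crossing, the detector must land within 0.5 nm of the
        nearest grid point to it.
        """

        def oracle_crossings(ya, yb):
            # independent brute force: scan adjacent-point sign changes
            out = []
            d = ya - yb
            for i in range(len(d) - 1):
                if d[i] == 0.0:
                    out.append(grid[i])
                elif d[i] * d[i + 1] < 0:
                    out.append(grid[i] + d[i] / (d[i] - d[i + 1]))
            if d[-1] == 0.0:
                out.append(grid[-1])
            return out

        rng = np.random.default_rng(20190715)
        n_unique = 0
        for _ in range(1000):
            c1, c2 = rng.uniform(255, 300, 2)
            w1, w2 = rng.uniform(8, 25, 2)
            a1, a2 = rng.uniform(0.2, 0.8, 2)
            ya = a1 * np.exp(-0.5 * ((grid - c1) / w1) ** 2)
            yb = a2 * np.exp(-0.5 * ((grid - c2) / w2) ** 2)
            sa, sb = Spectrum(grid, ya), Spectrum(grid, yb)
            expected = oracle_crossings(ya, yb)
            if len(expected) == 1:
                n_unique += 1
                found = find_isosbestic(sa, sb)
                assert abs(found - expected[0]) <= 0.5
            elif len(expected) == 0:
                with pytest.raises(NoIsosbesticError):
                    find_isosbestic(sa, sb)
        assert n_unique > 100  # the comparison actually exercised detection

    def test_all_crossings_reported(self, grid):
        # oscillating difference -> several crossings far apart
        y1 = np.full(grid.size, 0.5)
        y2 = 0.5 + 0.3 * np.sin((grid - 255.0) / 8.0)
        sa, sb = Spectrum(grid, y1), Spectrum(grid, y2)
        crossings = find_isosbestic_crossings(sa, sb)
        assert len(crossings) >= 2
        with pytest.raises(AmbiguousIsosbesticError) as err:
            find_isosbestic(sa, sb)
        assert err.value.candidates == pytest.approx(crossings)


class TestNormalize:
    def test_scales_isosbestic_to_unity(self, grid):
        rng = np.random.default_rng(0)
        spec = Spectrum(grid, rng.uniform(0.1, 0.5, grid.size))
        spec = spec.with_absorbance(
            np.where(grid == 278.0, 0.362, spec.absorbance_au)
        )
        normalized = normalize_to_isosbestic(spec, 278.0)
        assert normalized.at(278.0) == 1.0
        np.testing.assert_allclose(
            normalized.absorbance_au, spec.absorbance_au / 0.362, rtol=1e-12
        )

    def test_idempotent(self, dt_pure_spectra):
        nuc, _ = dt_pure_spectra
        once = normalize_to_isosbestic(nuc, 278.0)
        twice = normalize_to_isosbestic(once, 278.0)
        np.testing.assert_allclose(
            twice.absorbance_au, once.absorbance_au, atol=1e-12
        )

    def test_insufficient_signal_guard(self, make_flat):
        with pytest.raises(InsufficientSignalError):
            normalize_to_isosbestic(make_flat(0.001), 278.0)


class TestLinearCombination:
    def test_unit_vector_returns_endmember(self, dt_refs):
        mixed = linear_combination(dt_refs, [1.0, 0.0])
        np.testing.assert_array_equal(
            mixed.absorbance_au, dt_refs.spectra[0].absorbance_au
        )

    def test_equimolar_mixture_is_pointwise_mean(self, dt_refs):
        mixed = linear_combination(dt_refs, [0.5, 0.5])
        expected = 0.5 * (
            dt_refs.spectra[0].absorbance_au + dt_refs.spectra[1].absorbance_au
        )
        np.testing.assert_allclose(mixed.absorbance_au, expected, atol=1e-15)

    @given(x=st.floats(0.0, 1.0))
    def test_isosbestic_conserved_for_any_composition(self, dt_refs, x):
        mixed = linear_combination(dt_refs, [x, 1.0 - x])
        assert mixed.at(dt_refs.isosbestic_nm) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.7, 0.7], [-0.1, 1.1], [0.2, 0.3]])
    def test_invalid_fraction_vectors_rejected(self, bad, dt_refs):
        with pytest.raises(ConstraintError):
            linear_combination(dt_refs, bad)


class TestReferenceSet:
    def test_requires_unit_absorbance_at_isosbestic(self, dt_pure_spectra):
        nuc, base = dt_pure_spectra
        with pytest.raises(ValueError, match="normalized"):
            ReferenceSet(
                spectra=(nuc, base),
                isosbestic_nm=278.0,
                window=(250.0, 350.0),
                compound_ids=("dT", "thymine"),
            )

    def test_window_must_lie_on_grid(self, dt_refs):
        with pytest.raises(ValueError, match="window"):
            ReferenceSet(
                spectra=dt_refs.spectra,
                isosbestic_nm=278.0,
                window=(200.0, 350.0),
                compound_ids=dt_refs.compound_ids,
            )


class TestUtilities:
    def test_average_spectra_is_pointwise_mean(self, grid):
        rng = np.random.default_rng(1)
        specs = [Spectrum(grid, rng.uniform(0, 1, grid.size)) for _ in range(4)]
        mean = average_spectra(specs)
        np.testing.assert_allclose(
            mean.absorbance_au,
            np.mean([s.absorbance_au for s in specs], axis=0),
            atol=1e-15,
        )

    def test_regrid_is_explicit_and_bounded(self, grid):
        spec = Spectrum(grid, np.linspace(0, 1, grid.size))
        fine = regrid(spec, np.arange(260.0, 301.0, 0.5))
        assert fine.at(260.0) == pytest.approx(spec.at(260.0))
        with pytest.raises(ValueError, match="beyond"):
            regrid(spec, np.arange(200.0, 301.0, 1.0))
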