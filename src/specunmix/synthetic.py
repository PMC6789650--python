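"""Synthetic UV/Vis spectra for assay development and validation.

Real nucleoside/nucleobase spectra are instrument measurements; this
module generates physically plausible stand-ins with the statistical
structure the unmixing assay relies on, so the whole pipeline can be
exercised and validated without a plate reader:

* pure-compound spectra as sums of Gaussian absorption bands, with a
  two-state (neutral/deprotonated) Henderson-Hasselbalch blend giving
  the characteristic alkaline spectral shift of free nucleobases,
* linear mixing of pure spectra on a molar-fraction basis,
* a multiplicative per-well dilution/pathlength factor (the error the
  isosbestic normalization is designed to cancel),
* an additive blank: a flat instrumental offset plus a solvent
  absorbance edge that rises toward the deep UV (alkaline NaOH
  solutions absorb increasingly below ~270 nm) and varies slightly
  from well to well with pipetting, so blank subtraction is imperfect
  at the low-wavelength end,
* Gaussian photometric noise per wavelength, optionally inflated
  toward the deep UV where lamp energy is low and solvent absorbance
  high.

The imperfect blank cancellation and the deep-UV noise are what make
the short-wavelength region information-poor in practice, and hence
what restricting the fitting window to the region above the isosbestic
point protects against.  Default levels emulate the assay's working
regime: ~0.4 AU signals over a ~0.03 AU blank with ~0.005 AU
measurement noise.

All generators are pure functions of their parameters and a seed;
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConstraintError, DesignError
from .plate_io import PlateLayout, WellRecord, well_names
from .spectra import Spectrum, check_fractions, find_isosbestic

__all__ = [
    "GaussianBand",
    "CompoundModel",
    "SolventModel",
    "AssayDesign",
    "SyntheticPlate",
    "default_grid",
    "make_reference_spectrum",
    "make_mixture_spectrum",
    "make_validation_plate",
    "make_progress_series",
    "preset_pair",
    "PRESET_PAIRS",
    "DEFAULT_SEED",
]

#: Default seed for all synthetic randomness, recorded in outputs.
DEFAULT_SEED = 20190715


def default_grid() -> np.ndarray:
    """The instrument grid: 250-350 nm in 1 nm steps."""
    return np.arange(250.0, 351.0, 1.0)


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: center (nm), Gaussian sigma (nm), peak amplitude (AU)."""

    center_nm: float
    width_nm: float
    amplitude_au: float

    def __post_init__(self) -> None:
        if not 240.0 <= self.center_nm <= 360.0:
            raise ValueError(f"band center {self.center_nm} nm outside 240-360 nm")
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude_au < 0:
            raise ValueError("band amplitude must be nonnegative")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        return self.amplitude_au * np.exp(
            -0.5 * ((grid - self.center_nm) / self.width_nm) ** 2
        )


@dataclass(frozen=True)
class CompoundModel:
    """Generative model of one compound's pH-dependent absorption spectrum.

    The spectrum at a given pH is a Henderson-Hasselbalch blend of a
    neutral and a deprotonated species, each a sum of Gaussian bands:
    ``w * neutral + (1 - w) * deprotonated`` with
    ``w = 1 / (1 + 10^(pH - pKa))``.  ``epsilon_scale`` rescales the
    whole spectrum (relative molar absorptivity).
    """

    compound_id: str
    bands: tuple[GaussianBand, ...]
    deprotonated_bands: tuple[GaussianBand, ...]
    pka: float
    epsilon_scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.bands or not self.deprotonated_bands:
            raise ValueError("each species needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(
            self, "deprotonated_bands", tuple(self.deprotonated_bands)
        )
        if self.epsilon_scale <= 0:
            raise ValueError("epsilon_scale must be positive")


def make_reference_spectrum(
    model: CompoundModel, ph: float, grid: Sequence[float] | None = None
) -> Spectrum:
    """Deterministic, noise-free pure-compound spectrum at a given pH.

    ``ph`` must lie in the assay's feasible range 7-13 (bounded below by
    the loss of the alkaline spectral shift and above by compound and
    pentose-1-phosphate stability).
    """
    if not 7.0 <= ph <= 13.0:
        raise ValueError(f"pH {ph} outside the assay's working range 7-13")
    grid_arr = default_grid() if grid is None else np.asarray(grid, dtype=float)
    w = 1.0 / (1.0 + 10.0 ** (ph - model.pka))
    neutral = sum(b.evaluate(grid_arr) for b in model.bands)
    deprot = sum(b.evaluate(grid_arr) for b in model.deprotonated_bands)
    absorbance = model.epsilon_scale * (w * neutral + (1.0 - w) * deprot)
    return Spectrum(
        grid_arr,
        absorbance,
        meta={"compound": model.compound_id, "ph": float(ph), "synthetic": True},
    )


@dataclass(frozen=True)
class SolventModel:
    """Solvent absorbance edge rising toward the deep UV.

    ``amplitude_au * exp(-(lambda - edge_nm) / decay_nm)`` for
    wavelengths above ``edge_nm``; the per-well realization is scaled by
    ``1 + N(0, well_cv)`` to emulate pipetting variation of the alkaline
    diluent, so a measured blank never cancels a sample's solvent
    contribution exactly.
    """

    amplitude_au: float = 0.12
    edge_nm: float = 250.0
    decay_nm: float = 12.0
    well_cv: float = 0.10

    def profile(self, grid: np.ndarray) -> np.ndarray:
        return self.amplitude_au * np.exp(-(grid - self.edge_nm) / self.decay_nm)

    def realize(self, grid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return self.profile(grid) * (1.0 + self.well_cv * rng.standard_normal())


def noise_sigma(
    grid: np.ndarray,
    noise_sd: float,
    uv_factor: float = 0.0,
    uv_decay_nm: float = 10.0,
) -> np.ndarray:
    """Per-wavelength photometric noise s.d. (AU).

    Homoscedastic at ``noise_sd`` when ``uv_factor`` is 0; otherwise the
    s.d. rises toward the deep UV as
    ``noise_sd * (1 + uv_factor * exp(-(lambda - grid[0]) / uv_decay_nm))``,
    emulating the reduced lamp energy and growing solvent absorbance of
    plate readers below ~270 nm.
    """
    return noise_sd * (1.0 + uv_factor * np.exp(-(grid - grid[0]) / uv_decay_nm))


def _blank_absorbance(
    grid: np.ndarray,
    blank_level: float,
    solvent: SolventModel | None,
    sigma: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    base = np.full(grid.shape, blank_level, dtype=float)
    if solvent is not None and blank_level > 0:
        base = base + solvent.realize(grid, rng)
    # noise variates are always drawn so that a zero noise level shares
    # the same solvent/dilution realization as nonzero levels
    return base + sigma * rng.standard_normal(grid.shape)


def make_mixture_spectrum(
    pure_spectra: Sequence[Spectrum],
    x: Sequence[float],
    scale: float = 1.0,
    blank_level: float = 0.028,
    noise_sd: float = 0.005,
    solvent: SolventModel | None = None,
    rng: np.random.Generator | int | None = None,
    noise_uv_factor: float = 0.0,
    noise_uv_decay_nm: float = 10.0,
) -> tuple[Spectrum, Spectrum]:
    """One simulated measurement: (raw mixture spectrum, matched blank).

    ``raw = scale * sum_i x_i * S_i + blank + noise`` where the blank is
    the flat instrumental offset plus (optionally) a per-well solvent
    edge; the returned blank spectrum is an independent realization of
    the same blank model, as measured in its own well.  ``scale`` is the
    multiplicative dilution/pathlength factor.  ``blank_level = 0``
    disables the additive blank entirely.  Noise is homoscedastic at
    ``noise_sd`` unless ``noise_uv_factor > 0`` (see
    :func:`noise_sigma`).
    """
    fractions = check_fractions(x, n=len(pure_spectra))
    if scale <= 0:
        raise ConstraintError("dilution/pathlength scale must be positive")
    first = pure_spectra[0]
    for s in pure_spectra[1:]:
        if not first.same_grid(s):
            raise ConstraintError("pure spectra must share one grid")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(DEFAULT_SEED if rng is None else int(rng))
    grid = first.wavelengths_nm
    sigma = noise_sigma(grid, noise_sd, noise_uv_factor, noise_uv_decay_nm)
    mix = scale * sum(
        f * s.absorbance_au for f, s in zip(fractions, pure_spectra)
    )
    raw_vals = mix + _blank_absorbance(grid, blank_level, solvent, sigma, rng)
    blank_vals = _blank_absorbance(grid, blank_level, solvent, sigma, rng)
    raw = Spectrum(
        grid,
        raw_vals,
        meta={
            "true_fractions": [float(f) for f in fractions],
            "scale": float(scale),
            "synthetic": True,
        },
    )
    blank = Spectrum(grid, blank_vals, meta={"role": "blank", "synthetic": True})
    return raw, blank


@dataclass(frozen=True)
class AssayDesign:
    """Conditions of a validation experiment on one 96-well plate.

    Defaults reproduce the assay's validation design: mixtures from 0
    to 100% base in 20% steps, in duplicate, at ~100 uM total
    UV-active compound, measured at pH 13 with ~0.005 AU photometric
    noise over a blank of ~0.03 AU (0.032 AU at the 278 nm isosbestic
    once the solvent edge is included).  Per-well dilution factors are
    drawn uniformly from ``dilution_range`` — the assay's estimates
    must not depend on them.
    """

    fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    replicates: int = 2
    total_concentration_um: float = 100.0
    ph: float = 13.0
    noise_sd: float = 0.005
    noise_uv_factor: float = 3.0
    noise_uv_decay_nm: float = 12.0
    blank_level: float = 0.020
    solvent: SolventModel | None = field(default_factory=SolventModel)
    dilution_range: tuple[float, float] = (0.9, 1.1)
    n_blanks: int = 2
    reference_replicates: int = 4
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise DesignError("designed fractions must lie in [0, 1]")
        if not self.fractions:
            raise DesignError("design needs at least one fraction")
        if self.replicates < 1:
            raise DesignError("design needs at least one replicate")
        if self.reference_replicates < 1:
            raise DesignError("design needs at least one reference replicate")
        if self.n_blanks < 1:
            raise DesignError("design needs at least one blank well")
        if self.noise_sd < 0:
            raise DesignError("noise_sd must be nonnegative")
        lo, hi = self.dilution_range
        if not 0 < lo <= hi:
            raise DesignError("dilution_range must be positive with lo <= hi")


@dataclass(frozen=True)
class SyntheticPlate:
    """A simulated plate: wide absorbance table, layout, and ground truth."""

    plate: pd.DataFrame            # wavelength_nm + one column per well
    layout: PlateLayout
    truth: pd.DataFrame            # designed base fraction per sample well
    pair_names: tuple[str, ...]
    seed: int
    #: per-pair isosbestic wavelength of the noise-free model spectra,
    #: the synthetic analogue of a characterized compound constant
    isosbestic_nm: dict[str, float] = field(default_factory=dict)


def _pair_name(nucleoside: CompoundModel, base: CompoundModel) -> str:
    return f"{nucleoside.compound_id}-{base.compound_id}"


def make_validation_plate(
    design: AssayDesign,
    pairs: Sequence[tuple[CompoundModel, CompoundModel]],
) -> SyntheticPlate:
    """Simulate a full validation plate for one or more compound pairs.

    Wells are assigned row-major (A1, A2, ...): first the blanks, then
    per pair the pure reference wells (nucleoside, then base, measured
    at nominal concentration without dilution error), then the mixture
    wells for every designed fraction x replicate, each with its own
    random dilution factor.  The ``truth`` table records the designed
    base molar fraction per sample well.
    """
    if not pairs:
        raise DesignError("need at least one compound pair")
    rng = np.random.default_rng(design.seed)
    grid = default_grid()
    conc_scale = design.total_concentration_um / 100.0  # band amplitudes at 100 uM

    wells = iter(well_names())
    columns: dict[str, np.ndarray] = {}
    records: dict[str, WellRecord] = {}
    truth_rows: list[dict[str, object]] = []

    def take_well() -> str:
        try:
            return next(wells)
        except StopIteration:
            raise CapacityError(
                "design exceeds the 96 wells of the plate"
            ) from None

    sigma = noise_sigma(
        grid, design.noise_sd, design.noise_uv_factor, design.noise_uv_decay_nm
    )
    for i in range(design.n_blanks):
        well = take_well()
        columns[well] = _blank_absorbance(
            grid, design.blank_level, design.solvent, sigma, rng
        )
        records[well] = WellRecord(role="blank", sample_id=f"blank_{i + 1}")

    pair_names = []
    isosbestics: dict[str, float] = {}
    for nucleoside, base in pairs:
        pair = _pair_name(nucleoside, base)
        pair_names.append(pair)
        pures = [
            make_reference_spectrum(m, design.ph, grid) for m in (nucleoside, base)
        ]
        isosbestics[pair] = find_isosbestic(pures[0], pures[1])
        for model, pure in zip((nucleoside, base), pures):
            for rep in range(1, design.reference_replicates + 1):
                well = take_well()
                raw, _ = make_mixture_spectrum(
                    [pure, pure],
                    [1.0, 0.0],
                    scale=conc_scale,
                    blank_level=design.blank_level,
                    noise_sd=design.noise_sd,
                    solvent=design.solvent,
                    rng=rng,
                    noise_uv_factor=design.noise_uv_factor,
                    noise_uv_decay_nm=design.noise_uv_decay_nm,
                )
                columns[well] = raw.absorbance_au
                records[well] = WellRecord(
                    role="reference",
                    compound=model.compound_id,
                    pair=pair,
                    replicate=rep,
                )
        for frac in design.fractions:
            for rep in range(1, design.replicates + 1):
                well = take_well()
                scale = conc_scale * rng.uniform(*design.dilution_range)
                raw, _ = make_mixture_spectrum(
                    pures,
                    [1.0 - frac, frac],
                    scale=scale,
                    blank_level=design.blank_level,
                    noise_sd=design.noise_sd,
                    solvent=design.solvent,
                    rng=rng,
                    noise_uv_factor=design.noise_uv_factor,
                    noise_uv_decay_nm=design.noise_uv_decay_nm,
                )
                sample_id = f"{pair}_f{round(frac * 100):03d}"
                columns[well] = raw.absorbance_au
                records[well] = WellRecord(
                    role="sample",
                    sample_id=sample_id,
                    pair=pair,
                    replicate=rep,
                    dilution_factor=float(scale / conc_scale),
                )
                truth_rows.append(
                    {
                        "well": well,
                        "sample_id": sample_id,
                        "pair": pair,
                        "replicate": rep,
                        "nucleoside": nucleoside.compound_id,
                        "base": base.compound_id,
                        "base_fraction": float(frac),
                    }
                )

    plate = pd.DataFrame({"wavelength_nm": grid, **columns})
    return SyntheticPlate(
        plate=plate,
        layout=PlateLayout(records),
        truth=pd.DataFrame(truth_rows),
        pair_names=tuple(pair_names),
        seed=design.seed,
        isosbestic_nm=isosbestics,
    )


def make_progress_series(
    nucleoside: CompoundModel,
    base: CompoundModel,
    x_eq: float,
    k_obs: float,
    times_s: Sequence[float],
    design: AssayDesign | None = None,
) -> tuple[list[tuple[float, Spectrum, Spectrum]], list[float]]:
    """Time course of an enzymatic base-cleavage reaction.

    Conversion follows a single-exponential approach to equilibrium,
    ``x_base(t) = x_eq * (1 - exp(-k_obs * t))``, the progress-curve
    shape of a reversible first-order system far from substrate
    depletion.  Returns ``[(time_s, raw, blank), ...]`` plus the list of
    true conversions.  Noise/blank/dilution conditions come from
    ``design`` (defaults: the standard assay conditions).
    """
    if not 0.0 <= x_eq <= 1.0:
        raise DesignError("equilibrium conversion must lie in [0, 1]")
    if k_obs <= 0:
        raise DesignError("k_obs must be positive")
    times = [float(t) for t in times_s]
    if any(t < 0 for t in times):
        raise DesignError("times must be nonnegative")
    design = design or AssayDesign()
    rng = np.random.default_rng(design.seed)
    grid = default_grid()
    conc_scale = design.total_concentration_um / 100.0
    pures = [make_reference_spectrum(m, design.ph, grid) for m in (nucleoside, base)]
    out = []
    conversions = []
    for t in times:
        conv = x_eq * (1.0 - np.exp(-k_obs * t))
        scale = conc_scale * rng.uniform(*design.dilution_range)
        raw, blank = make_mixture_spectrum(
            pures,
            [1.0 - conv, conv],
            scale=scale,
            blank_level=design.blank_level,
            noise_sd=design.noise_sd,
            solvent=design.solvent,
            rng=rng,
            noise_uv_factor=design.noise_uv_factor,
            noise_uv_decay_nm=design.noise_uv_decay_nm,
        )
        raw = raw.with_meta(time_s=t, true_conversion=float(conv))
        out.append((t, raw, blank))
        conversions.append(float(conv))
    return out, conversions


# --- Compound-pair presets -------------------------------------------------
#
# Band parameters are calibrated only to reproduce the qualitative
# features of alkaline nucleoside/nucleobase pairs: the nucleoside keeps
# its neutral-like band (its ring nitrogen is substituted, pKa above the
# aqueous range) while the free base deprotonates (pKa ~ 9-10) and its
# spectrum broadens and red-shifts, producing a single isosbestic
# crossing.  The thymidine-like preset reproduces the canonical maxima
# (266 nm nucleoside, 287 nm base at pH 13) and an isosbestic point at
# 278 nm; amplitudes give ~0.4 AU at the isosbestic for 100 uM.

def _thymidine_like() -> tuple[CompoundModel, CompoundModel]:
    nucleoside = CompoundModel(
        compound_id="dT",
        bands=(GaussianBand(266.0, 16.0, 0.55),),
        deprotonated_bands=(GaussianBand(266.0, 16.0, 0.42),),
        pka=14.0 - 0.2,  # effectively undissociated below pH 13
    )
    base = CompoundModel(
        compound_id="thymine",
        bands=(GaussianBand(264.5, 15.0, 0.52),),
        deprotonated_bands=(GaussianBand(287.0, 21.0, 0.4404262624744834),),
        pka=9.9,
    )
    return nucleoside, base


def _uridine_like() -> tuple[CompoundModel, CompoundModel]:
    nucleoside = CompoundModel(
        compound_id="dU",
        bands=(GaussianBand(262.0, 15.0, 0.60),),
        deprotonated_bands=(GaussianBand(262.0, 15.0, 0.46),),
        pka=13.8,
    )
    base = CompoundModel(
        compound_id="uracil",
        bands=(GaussianBand(259.5, 14.0, 0.55),),
        deprotonated_bands=(GaussianBand(284.0, 20.0, 0.5164191030451897),),
        pka=9.5,
    )
    return nucleoside, base


def _inosine_like() -> tuple[CompoundModel, CompoundModel]:
    nucleoside = CompoundModel(
        compound_id="dI",
        bands=(GaussianBand(258.0, 14.0, 0.62),),
        deprotonated_bands=(GaussianBand(259.0, 15.0, 0.50),),
        pka=13.5,
    )
    base = CompoundModel(
        compound_id="hypoxanthine",
        bands=(GaussianBand(256.0, 13.0, 0.55),),
        deprotonated_bands=(GaussianBand(277.0, 18.0, 0.5272861195130222),),
        pka=8.9,
    )
    return nucleoside, base


PRESET_PAIRS: dict[str, tuple[CompoundModel, CompoundModel]] = {
    "dT-thymine": _thymidine_like(),
    "dU-uracil": _uridine_like(),
    "dI-hypoxanthine": _inosine_like(),
}


def preset_pair(name: str) -> tuple[CompoundModel, CompoundModel]:
    """Look up a built-in nucleoside/nucleobase compound-pair preset."""
    try:
        return PRESET_PAIRS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESET_PAIRS)}"
        ) from None
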