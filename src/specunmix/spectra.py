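"""Spectrum data model and core spectral algebra.

A UV/Vis absorption spectrum is a vector of absorbance values (AU) on a
strictly increasing, uniformly spaced wavelength grid (nm).  The assay
records spectra on a fixed instrument grid (250-350 nm in 1 nm steps by
default), and every core operation therefore demands *identical* grids:
nothing is ever resampled silently.  An explicit :func:`regrid` utility
exists for the rare case where interpolation is genuinely wanted.

The processing chain for the unmixing assay is

1. blank correction  — subtract the solvent-only (NaOH) spectrum,
2. isosbestic normalization — divide by the absorbance at the
   nucleoside/nucleobase isosbestic point, so that all spectra of
   mixtures at the same total concentration coincide there, and
3. linear combination — a mixture spectrum is the molar-fraction
   weighted sum of the normalized pure-compound spectra.

Normalization removes the dependence on absolute intensity (pathlength,
dilution and pipetting errors), which is what makes the assay robust in
a 96-well plate workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AmbiguousIsosbesticError,
    ConstraintError,
    GridMismatchError,
    InsufficientSignalError,
    NoIsosbesticError,
)

__all__ = [
    "Spectrum",
    "ReferenceSet",
    "blank_correct",
    "find_isosbestic",
    "find_isosbestic_crossings",
    "normalize_to_isosbestic",
    "linear_combination",
    "average_spectra",
    "regrid",
    "DEFAULT_MIN_SIGNAL_AU",
]

#: Minimum blank-corrected absorbance (AU) accepted at the isosbestic
#: point before normalization.  Below this, division amplifies
#: measurement noise unboundedly (typical blanks are ~0.03 AU with
#: ~0.005 AU noise, so 0.01 AU is already deep in the noise floor).
DEFAULT_MIN_SIGNAL_AU = 0.01

_GRID_RTOL = 1e-9


def _as_grid(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("wavelength grid must be 1-D with at least two points")
    steps = np.diff(arr)
    if np.any(steps <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("wavelength grid must be uniformly spaced")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """A single absorption spectrum on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing, uniformly spaced wavelengths in nm.
    absorbance_au
        Absorbance values in AU, one per wavelength; must be finite.
    meta
        Free-form metadata (compound id, well, pH, time point, ...).
        Copied on construction so spectra are effectively immutable.
    """

    wavelengths_nm: np.ndarray
    absorbance_au: np.ndarray
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = _as_grid(self.wavelengths_nm)
        absorb = np.asarray(self.absorbance_au, dtype=float)
        if absorb.shape != grid.shape:
            raise ValueError(
                f"absorbance length {absorb.size} != wavelength count {grid.size}"
            )
        if not np.all(np.isfinite(absorb)):
            raise ValueError("absorbance values must be finite")
        grid.setflags(write=False)
        absorb.setflags(write=False)
        object.__setattr__(self, "wavelengths_nm", grid)
        object.__setattr__(self, "absorbance_au", absorb)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def index_of(self, wavelength_nm: float) -> int:
        """Index of a wavelength that must lie on the grid."""
        idx = int(round((wavelength_nm - self.wavelengths_nm[0]) / self.step_nm))
        if idx < 0 or idx >= len(self) or not np.isclose(
            self.wavelengths_nm[idx], wavelength_nm, rtol=0, atol=1e-6
        ):
            raise ValueError(f"{wavelength_nm} nm is not on the spectrum grid")
        return idx

    def at(self, wavelength_nm: float) -> float:
        """Absorbance at a grid wavelength (no interpolation)."""
        return float(self.absorbance_au[self.index_of(wavelength_nm)])

    def with_absorbance(self, absorbance_au: np.ndarray, **meta_updates: Any) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavelengths_nm, absorbance_au, meta)

    def with_meta(self, **meta_updates: Any) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return replace(self, meta=meta)

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths_nm.shape == other.wavelengths_nm.shape and np.allclose(
            self.wavelengths_nm, other.wavelengths_nm, rtol=_GRID_RTOL, atol=1e-9
        )


def _require_same_grid(a: Spectrum, b: Spectrum, what: str) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"{what}: wavelength grids differ "
            f"({a.wavelengths_nm[0]:g}-{a.wavelengths_nm[-1]:g} nm, n={len(a)} vs "
            f"{b.wavelengths_nm[0]:g}-{b.wavelengths_nm[-1]:g} nm, n={len(b)}); "
            "no silent resampling is performed"
        )


@dataclass(frozen=True)
class ReferenceSet:
    """Normalized pure-compound reference spectra sharing one grid.

    Every member spectrum must have absorbance 1.0 (within 1e-9) at
    ``isosbestic_nm`` — the defining property of isosbestic
    normalization — and the fitting window must lie on the shared grid.
    """

    spectra: tuple[Spectrum, ...]
    isosbestic_nm: float
    window: tuple[float, float]
    compound_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        ids = tuple(str(c) for c in self.compound_ids)
        if len(spectra) < 2:
            raise ValueError("a ReferenceSet needs at least two compounds")
        if len(ids) != len(spectra):
            raise ValueError("compound_ids must match the number of spectra")
        if len(set(ids)) != len(ids):
            raise ValueError("compound_ids must be unique")
        first = spectra[0]
        for spec in spectra[1:]:
            _require_same_grid(first, spec, "reference set")
        lo, hi = (float(self.window[0]), float(self.window[1]))
        if not lo < hi:
            raise ValueError(f"window lo {lo} must be < hi {hi}")
        grid = first.wavelengths_nm
        if lo < grid[0] or hi > grid[-1]:
            raise ValueError(
                f"window {lo}-{hi} nm outside the shared grid "
                f"{grid[0]:g}-{grid[-1]:g} nm"
            )
        iso = float(self.isosbestic_nm)
        first.index_of(iso)  # raises if off-grid
        for cid, spec in zip(ids, spectra):
            a_iso = spec.at(iso)
            if abs(a_iso - 1.0) > 1e-9:
                raise ValueError(
                    f"reference '{cid}' has A({iso:g} nm) = {a_iso:.12f}, "
                    "expected 1.0: references must be isosbestic-normalized"
                )
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "compound_ids", ids)
        object.__setattr__(self, "isosbestic_nm", iso)
        object.__setattr__(self, "window", (lo, hi))

    @property
    def n_compounds(self) -> int:
        return len(self.spectra)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm


def blank_correct(raw: Spectrum, blank: Spectrum) -> Spectrum:
    """Subtract the solvent-only blank from a raw spectrum.

    Both spectra must share an identical grid.  Negative corrected
    absorbances are permitted (noise around zero at low signal) but
    trigger a warning when they are substantial.
    """
    _require_same_grid(raw, blank, "blank correction")
    corrected = raw.absorbance_au - blank.absorbance_au
    if np.any(corrected < -0.05):
        warnings.warn(
            "blank-corrected spectrum has absorbance below -0.05 AU; "
            "check blank assignment",
            stacklevel=2,
        )
    return raw.with_absorbance(corrected, blank_corrected=True)


def find_isosbestic_crossings(
    spec_a: Spectrum,
    spec_b: Spectrum,
    search_range: tuple[float, float] | None = None,
) -> list[float]:
    """All sub-nm crossing wavelengths of two equal-molar pure spectra.

    Crossings are located where the difference ``A_a - A_b`` changes
    sign between adjacent grid points, refined by linear interpolation.
    A grid point where the difference is exactly zero counts as a
    crossing at that wavelength.
    """
    _require_same_grid(spec_a, spec_b, "isosbestic search")
    grid = spec_a.wavelengths_nm
    diff = spec_a.absorbance_au - spec_b.absorbance_au
    if search_range is not None:
        lo, hi = search_range
        mask = (grid >= lo) & (grid <= hi)
        if not mask.any():
            raise NoIsosbesticError(
                f"search range {lo}-{hi} nm does not intersect the grid"
            )
        grid = grid[mask]
        diff = diff[mask]
    crossings: list[float] = []
    for i in range(len(grid) - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0:
            crossings.append(float(grid[i]))
        elif d0 * d1 < 0:
            frac = d0 / (d0 - d1)
            crossings.append(float(grid[i] + frac * (grid[i + 1] - grid[i])))
    if diff[-1] == 0.0:
        crossings.append(float(grid[-1]))
    return crossings


def find_isosbestic(
    spec_a: Spectrum,
    spec_b: Spectrum,
    search_range: tuple[float, float] | None = None,
    cluster_tol_nm: float = 2.0,
) -> float:
    """Locate the isosbestic point of a compound pair.

    The two spectra must be blank-corrected, equal-molar pure-compound
    spectra on one grid.  Returns the grid wavelength nearest the
    (unique) sign change of their difference; the interpolated sub-nm
    crossing is available via :func:`find_isosbestic_crossings`.

    Measurement noise can split one physical crossing into several
    sign changes within a nanometre or two of each other; crossings
    spanning no more than ``cluster_tol_nm`` are therefore treated as a
    single crossing at their mean.

    Raises
    ------
    NoIsosbesticError
        If the difference never changes sign in the searched range.
    AmbiguousIsosbesticError
        If crossings further than ``cluster_tol_nm`` apart are found;
        narrow ``search_range`` or supply the wavelength explicitly
        (instrument-characterized isosbestic points are commonly taken
        from configuration).
    """
    crossings = find_isosbestic_crossings(spec_a, spec_b, search_range)
    if not crossings:
        raise NoIsosbesticError(
            "no isosbestic crossing found"
            + (f" in {search_range[0]}-{search_range[1]} nm" if search_range else "")
        )
    if max(crossings) - min(crossings) > cluster_tol_nm:
        raise AmbiguousIsosbesticError(crossings)
    crossing = float(np.mean(crossings))
    step = spec_a.step_nm
    grid = spec_a.wavelengths_nm
    idx = int(round((crossing - grid[0]) / step))
    idx = min(max(idx, 0), len(grid) - 1)
    return float(grid[idx])


def normalize_to_isosbestic(
    spec: Spectrum,
    isosbestic_nm: float,
    min_signal_au: float = DEFAULT_MIN_SIGNAL_AU,
) -> Spectrum:
    """Scale a blank-corrected spectrum to absorbance 1.0 at the isosbestic point.

    Division by the isosbestic absorbance removes the dependence on
    total concentration and optical pathlength, so spectra of the same
    mixture at different dilutions become identical.  Idempotent: a
    spectrum already at 1.0 is returned unchanged in value.

    Raises
    ------
    InsufficientSignalError
        If the absorbance at ``isosbestic_nm`` is at or below
        ``min_signal_au`` — dividing by a near-zero, noise-dominated
        value would blow up the normalized spectrum.
    """
    a_iso = spec.at(isosbestic_nm)
    if a_iso <= min_signal_au:
        raise InsufficientSignalError(
            f"absorbance {a_iso:.4f} AU at {isosbestic_nm:g} nm is at or below "
            f"the minimum-signal threshold {min_signal_au:g} AU"
        )
    normalized = spec.absorbance_au / a_iso
    return spec.with_absorbance(
        normalized, normalized_at_nm=float(isosbestic_nm), normalization_factor=a_iso
    )


def check_fractions(x: Sequence[float], n: int | None = None, tol: float = 1e-9) -> np.ndarray:
    """Validate a molar-fraction vector: each x_i in [0, 1], sum 1."""
    arr = np.asarray(x, dtype=float)
    if n is not None and arr.size != n:
        raise ConstraintError(f"expected {n} fractions, got {arr.size}")
    if np.any(arr < -tol) or np.any(arr > 1 + tol):
        raise ConstraintError(f"fractions {arr.tolist()} outside [0, 1]")
    total = float(arr.sum())
    if abs(total - 1.0) > max(tol, 1e-9):
        raise ConstraintError(f"fractions sum to {total}, expected 1")
    return np.clip(arr, 0.0, 1.0)


def linear_combination(refs: ReferenceSet, x: Sequence[float]) -> Spectrum:
    """Mixture spectrum as the molar-fraction weighted sum of references.

    Because each reference has absorbance 1.0 at the isosbestic point
    and the weights sum to one, the combination also has absorbance
    exactly 1.0 there, for every admissible ``x``.
    """
    fractions = check_fractions(x, n=refs.n_compounds)
    stack = np.stack([s.absorbance_au for s in refs.spectra])
    mixed = fractions @ stack
    return Spectrum(
        refs.wavelengths_nm,
        mixed,
        meta={
            "fractions": {c: float(f) for c, f in zip(refs.compound_ids, fractions)},
            "normalized_at_nm": refs.isosbestic_nm,
        },
    )


def average_spectra(spectra: Iterable[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra on one shared grid."""
    specs = list(spectra)
    if not specs:
        raise ValueError("cannot average zero spectra")
    first = specs[0]
    for s in specs[1:]:
        _require_same_grid(first, s, "replicate averaging")
    mean = np.mean([s.absorbance_au for s in specs], axis=0)
    return first.with_absorbance(mean, n_averaged=len(specs))


def regrid(spec: Spectrum, new_grid: Sequence[float]) -> Spectrum:
    """Explicitly interpolate a spectrum onto a new uniform grid.

    Linear interpolation; the new grid must lie within the old range.
    This is the only place in the package where resampling happens, and
    it never happens implicitly.
    """
    grid = _as_grid(new_grid)
    if grid[0] < spec.wavelengths_nm[0] or grid[-1] > spec.wavelengths_nm[-1]:
        raise ValueError("new grid extends beyond the measured range")
    interp = np.interp(grid, spec.wavelengths_nm, spec.absorbance_au)
    return Spectrum(grid, interp, meta={**spec.meta, "regridded": True})
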