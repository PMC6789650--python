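"""High-level assay pipeline: plate -> references -> fractions -> statistics.

These functions wire the lower-level modules together in the order a
bench scientist uses them: average and blank-correct the reference
wells, locate (or accept) the isosbestic point, normalize, unmix every
sample well, and score designed vs estimated compositions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import LayoutError
from .metrics import ValidationTable
from .plate_io import PlateLayout
from .spectra import (
    ReferenceSet,
    Spectrum,
    average_spectra,
    blank_correct,
    find_isosbestic,
    normalize_to_isosbestic,
)
from .synthetic import SyntheticPlate
from .unmixing import UnmixResult, unmix

__all__ = ["build_reference_set", "unmix_plate", "validate_plate", "PlateUnmixResult"]


def build_reference_set(
    pure_spectra: dict[str, list[Spectrum]],
    blank: Spectrum,
    isosbestic_nm: float | None = None,
    window: tuple[float, float] | None = None,
    search_range: tuple[float, float] | None = None,
) -> ReferenceSet:
    """Blank-correct, average and normalize pure-compound spectra.

    ``pure_spectra`` maps compound ids to replicate raw spectra (order
    defines the reference order).  When ``isosbestic_nm`` is omitted the
    crossing of the two blank-corrected means is detected automatically
    (two-compound sets only); supplying it explicitly mirrors the usual
    practice of taking characterized constants from configuration.
    """
    corrected = {
        cid: average_spectra([blank_correct(s, blank) for s in reps])
        for cid, reps in pure_spectra.items()
    }
    ids = list(corrected)
    if len(ids) < 2:
        raise ValueError("need at least two pure compounds")
    if isosbestic_nm is None:
        if len(ids) != 2:
            raise ValueError(
                "automatic isosbestic detection needs exactly two compounds; "
                "supply isosbestic_nm explicitly"
            )
        isosbestic_nm = find_isosbestic(
            corrected[ids[0]], corrected[ids[1]], search_range
        )
    normalized = [
        normalize_to_isosbestic(corrected[cid], isosbestic_nm).with_meta(compound=cid)
        for cid in ids
    ]
    grid = normalized[0].wavelengths_nm
    if window is None:
        window = (float(grid[0]), float(grid[-1]))
    return ReferenceSet(
        spectra=tuple(normalized),
        isosbestic_nm=float(isosbestic_nm),
        window=window,
        compound_ids=tuple(ids),
    )


@dataclass(frozen=True)
class PlateUnmixResult:
    """Unmixing results for every sample well of one plate."""

    results: list[tuple[dict, UnmixResult]]
    reference_sets: dict[str, ReferenceSet]


def _group_references(
    spectra: dict[str, Spectrum], layout: PlateLayout
) -> dict[str, dict[str, list[Spectrum]]]:
    """pair -> compound -> replicate raw reference spectra."""
    groups: dict[str, dict[str, list[Spectrum]]] = {}
    for well in layout.wells_with_role("reference"):
        rec = layout.wells[well]
        if rec.compound is None:
            raise LayoutError(f"reference well {well} lacks a compound id")
        pair = rec.pair or "default"
        groups.setdefault(pair, {}).setdefault(rec.compound, []).append(spectra[well])
    return groups


def unmix_plate(
    spectra: dict[str, Spectrum],
    layout: PlateLayout,
    isosbestic_nm: float | dict[str, float] | None = None,
    window: tuple[float, float] | None = None,
    search_range: tuple[float, float] | None = None,
) -> PlateUnmixResult:
    """Full pipeline on one plate's spectra.

    Blanks are averaged into a single blank spectrum; reference wells
    are grouped per compound pair; each sample well is blank-corrected,
    normalized to its pair's isosbestic point, and unmixed over
    ``window`` (default: the full grid).  ``isosbestic_nm`` may be a
    single wavelength, a per-pair mapping, or ``None`` for automatic
    detection.
    """
    layout.require_blank()
    blank = average_spectra([spectra[w] for w in layout.blank_wells])
    ref_groups = _group_references(spectra, layout)
    if not ref_groups:
        raise LayoutError("layout defines no reference wells")
    reference_sets: dict[str, ReferenceSet] = {}
    for pair, compounds in ref_groups.items():
        iso = (
            isosbestic_nm.get(pair)
            if isinstance(isosbestic_nm, dict)
            else isosbestic_nm
        )
        reference_sets[pair] = build_reference_set(
            compounds, blank, iso, window, search_range
        )
    results: list[tuple[dict, UnmixResult]] = []
    for well in sorted(layout.wells_with_role("sample")):
        rec = layout.wells[well]
        pair = rec.pair or next(iter(reference_sets))
        if pair not in reference_sets:
            raise LayoutError(f"sample well {well} references unknown pair {pair!r}")
        refs = reference_sets[pair]
        corrected = blank_correct(spectra[well], blank)
        normalized = normalize_to_isosbestic(corrected, refs.isosbestic_nm)
        res = unmix(normalized, refs, window=refs.window)
        meta = {
            "well": well,
            "sample_id": rec.sample_id,
            "pair": pair,
            "replicate": rec.replicate,
            "time_s": rec.time_s,
        }
        results.append((meta, res))
    return PlateUnmixResult(results=results, reference_sets=reference_sets)


def validate_plate(
    plate: SyntheticPlate,
    window: tuple[float, float] | None = None,
    isosbestic_nm: float | dict[str, float] | None = None,
    search_range: tuple[float, float] = (255.0, 305.0),
) -> dict[str, ValidationTable]:
    """Unmix a simulated validation plate and tabulate actual vs predicted.

    Returns one :class:`ValidationTable` per compound pair, on the
    percent scale, with the designed base fraction as ``actual`` and the
    unmixed estimate as ``predicted``.  Unless overridden, each pair is
    normalized at the isosbestic wavelength the plate carries (derived
    from the noise-free model spectra, playing the role of a
    characterized compound constant).
    """
    if isosbestic_nm is None and plate.isosbestic_nm:
        isosbestic_nm = dict(plate.isosbestic_nm)
    grid = plate.plate["wavelength_nm"].to_numpy(dtype=float)
    spectra = {
        well: Spectrum(grid, plate.plate[well].to_numpy(dtype=float), {"well": well})
        for well in plate.plate.columns[1:]
    }
    out = unmix_plate(
        spectra,
        plate.layout,
        isosbestic_nm=isosbestic_nm,
        window=window,
        search_range=search_range,
    )
    truth = plate.truth.set_index(["sample_id", "replicate"])
    tables: dict[str, ValidationTable] = {}
    for pair in plate.pair_names:
        nuc_id, base_id = out.reference_sets[pair].compound_ids
        rows = []
        for meta, res in out.results:
            if meta["pair"] != pair:
                continue
            designed = float(
                truth.loc[(meta["sample_id"], meta["replicate"]), "base_fraction"]
            )
            rows.append(
                {
                    "sample_id": meta["sample_id"],
                    "replicate": meta["replicate"],
                    f"actual_{base_id}": 100.0 * designed,
                    f"actual_{nuc_id}": 100.0 * (1.0 - designed),
                    f"predicted_{base_id}": 100.0 * res.fraction_of(base_id),
                    f"predicted_{nuc_id}": 100.0 * res.fraction_of(nuc_id),
                }
            )
        tables[pair] = ValidationTable(pd.DataFrame(rows))
    return tables
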