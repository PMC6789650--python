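"""Reading and writing plate data, layouts, configuration and results.

The canonical plate export is a wide CSV: a ``wavelength_nm`` column
followed by one column per well (``A1`` ... ``H12``), one row per
wavelength, optionally preceded by ``#``-prefixed metadata comment
lines.  Layouts and assay configuration are YAML (or JSON, a YAML
subset).  Readers validate and reject malformed input rather than
repairing it; every writer's output is re-readable.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, LayoutError, PlateFormatError
from .spectra import ReferenceSet, Spectrum
from .unmixing import UnmixResult

__all__ = [
    "WellRecord",
    "PlateLayout",
    "AssayConfig",
    "well_names",
    "read_plate_csv",
    "write_plate_csv",
    "write_results",
    "load_config",
    "save_config",
    "read_layout",
    "write_layout",
    "read_reference_bundle",
    "write_reference_bundle",
]

_ROWS = "ABCDEFGH"
_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")
_ROLES = frozenset({"blank", "reference", "sample"})


def well_names() -> list[str]:
    """All 96 well ids in row-major order: A1..A12, B1..B12, ..., H12."""
    return [f"{r}{c}" for r in _ROWS for c in range(1, 13)]


@dataclass(frozen=True)
class WellRecord:
    """Role and sample annotations of one well."""

    role: str
    sample_id: str | None = None
    compound: str | None = None
    pair: str | None = None
    time_s: float | None = None
    dilution_factor: float | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise LayoutError(
                f"unknown well role {self.role!r}; expected one of {sorted(_ROLES)}"
            )


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of well ids to their roles and annotations."""

    wells: Mapping[str, WellRecord]

    def __post_init__(self) -> None:
        wells = dict(self.wells)
        for well in wells:
            if not _WELL_RE.match(well):
                raise LayoutError(f"invalid well id {well!r} for an 8x12 plate")
        object.__setattr__(self, "wells", wells)

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, rec in self.wells.items() if rec.role == role]

    @property
    def blank_wells(self) -> list[str]:
        return self.wells_with_role("blank")

    def require_blank(self) -> None:
        if not self.blank_wells:
            raise LayoutError("layout defines no blank well but blank correction was requested")


def read_plate_csv(path: str | Path, layout: PlateLayout | None = None) -> dict[str, Spectrum]:
    """Read a canonical wide plate CSV into one Spectrum per well.

    The wavelength grid is validated (strictly increasing, uniform
    step).  When a layout is given, its well annotations are joined into
    each spectrum's metadata, and every layout well must be present in
    the file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PlateFormatError(f"{path}: cannot parse plate CSV: {exc}") from exc
    if df.columns[0] != "wavelength_nm":
        raise PlateFormatError(
            f"{path}: first column must be 'wavelength_nm', got {df.columns[0]!r}"
        )
    grid = df["wavelength_nm"].to_numpy(dtype=float)
    if len(np.unique(grid)) != len(grid):
        raise PlateFormatError(f"{path}: duplicated wavelength rows")
    if np.any(np.diff(grid) <= 0):
        raise PlateFormatError(f"{path}: wavelengths must be strictly increasing")
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise PlateFormatError(f"{path}: non-uniform wavelength grid")
    well_cols = [c for c in df.columns[1:]]
    for col in well_cols:
        if not _WELL_RE.match(col):
            raise PlateFormatError(f"{path}: column {col!r} is not a valid well id")
    if layout is not None:
        missing = sorted(set(layout.wells) - set(well_cols))
        if missing:
            raise LayoutError(
                f"layout references wells absent from {path.name}: {missing}"
            )
    spectra: dict[str, Spectrum] = {}
    for col in well_cols:
        vals = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise PlateFormatError(f"{path}: non-finite absorbance in well {col}")
        meta: dict[str, object] = {"well": col, "source": str(path)}
        if layout is not None and col in layout.wells:
            rec = layout.wells[col]
            meta.update({k: v for k, v in asdict(rec).items() if v is not None})
        spectra[col] = Spectrum(grid, vals, meta)
    return spectra


def write_plate_csv(
    path: str | Path,
    plate: pd.DataFrame,
    header_comments: Sequence[str] = (),
) -> None:
    """Write a wide plate table (wavelength_nm + well columns) as canonical CSV."""
    path = Path(path)
    if plate.columns[0] != "wavelength_nm":
        raise PlateFormatError("plate table must start with a 'wavelength_nm' column")
    with path.open("w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        # %.17g round-trips float64 exactly
        plate.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def write_results(
    results: Iterable[tuple[Mapping[str, object], UnmixResult]],
    path: str | Path,
) -> pd.DataFrame:
    """Write unmixing results to CSV, one row per sample.

    ``results`` yields (metadata, UnmixResult) pairs; metadata keys
    ``sample_id``, ``well``, ``time_s`` are emitted when present.
    Fractions are emitted both on the 0-1 scale and in percent, with
    their standard errors, in a deterministic column order.
    """
    rows = []
    for meta, res in results:
        row: dict[str, object] = {
            "sample_id": meta.get("sample_id", ""),
            "well": meta.get("well", ""),
            "time_s": meta.get("time_s", ""),
        }
        for cid, frac, se in zip(res.compound_ids, res.fractions, res.std_errors):
            row[f"fraction_{cid}"] = float(frac)
            row[f"percent_{cid}"] = 100.0 * float(frac)
            row[f"std_error_{cid}"] = float(se)
        row.update(
            residual_ss=res.residual_ss,
            window_lo=res.window[0],
            window_hi=res.window[1],
            n_points=res.n_points,
            converged=res.converged,
            se_reliable=res.se_reliable,
        )
        rows.append(row)
    if not rows:
        raise ValueError("no results to write")
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), index=False, lineterminator="\n")
    return df


@dataclass(frozen=True)
class AssayConfig:
    """Per-compound-pair assay parameters.

    Defaults are the thymidine/thymine constants: isosbestic point at
    278 nm, fitting window 250-310 nm.  Other pairs supply their own
    values (these are instrument/compound characterizations, not
    quantities the software derives).
    """

    isosbestic_nm: float = 278.0
    window: tuple[float, float] = (250.0, 310.0)
    min_signal_au: float = 0.01
    naoh_mm: float = 100.0
    note: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (200.0 <= lo < hi <= 900.0):
            raise ConfigError(f"invalid window {lo}-{hi} nm (need 200 <= lo < hi <= 900)")
        if not 200.0 <= self.isosbestic_nm <= 900.0:
            raise ConfigError(f"isosbestic wavelength {self.isosbestic_nm} nm out of range")
        if self.min_signal_au <= 0:
            raise ConfigError("min_signal_au must be positive")
        object.__setattr__(self, "window", (float(lo), float(hi)))


_CONFIG_KEYS = {"isosbestic_nm", "window", "min_signal_au", "naoh_mm", "note"}


def load_config(path: str | Path) -> AssayConfig:
    """Load assay configuration from YAML/JSON; missing keys take defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        return AssayConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "window" in raw:
        win = raw["window"]
        if not (isinstance(win, (list, tuple)) and len(win) == 2):
            raise ConfigError(f"{path}: window must be a [lo, hi] pair")
        raw["window"] = (float(win[0]), float(win[1]))
    try:
        return AssayConfig(**raw)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: AssayConfig, path: str | Path) -> None:
    data = asdict(config)
    data["window"] = list(data["window"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_layout(path: str | Path) -> PlateLayout:
    """Load a plate layout from YAML: ``wells: {A1: {role: blank}, ...}``."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "wells" not in raw:
        raise LayoutError(f"{path}: layout file must contain a 'wells' mapping")
    wells_raw = raw["wells"]
    if not isinstance(wells_raw, dict):
        raise LayoutError(f"{path}: 'wells' must map well ids to records")
    records: dict[str, WellRecord] = {}
    for well, rec in wells_raw.items():
        if not isinstance(rec, dict) or "role" not in rec:
            raise LayoutError(f"{path}: well {well}: each record needs a 'role'")
        allowed = {"role", "sample_id", "compound", "pair", "time_s",
                   "dilution_factor", "replicate"}
        unknown = set(rec) - allowed
        if unknown:
            raise LayoutError(f"{path}: well {well}: unknown keys {sorted(unknown)}")
        try:
            records[str(well)] = WellRecord(**rec)
        except (TypeError, LayoutError) as exc:
            raise LayoutError(f"{path}: well {well}: {exc}") from exc
    return PlateLayout(records)


def write_reference_bundle(refs: ReferenceSet, path: str | Path) -> None:
    """Write a calibrated reference set as CSV with embedded parameters.

    Columns: ``wavelength_nm`` plus one column per compound (normalized
    absorbance); the isosbestic wavelength and fitting window travel in
    ``#``-prefixed header comments.
    """
    df = pd.DataFrame({"wavelength_nm": refs.wavelengths_nm})
    for cid, spec in zip(refs.compound_ids, refs.spectra):
        df[cid] = spec.absorbance_au
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# isosbestic_nm = {refs.isosbestic_nm:g}\n")
        fh.write(f"# window = {refs.window[0]:g}:{refs.window[1]:g}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def read_reference_bundle(path: str | Path) -> ReferenceSet:
    """Read a reference bundle written by :func:`write_reference_bundle`."""
    path = Path(path)
    params: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                params[key.strip()] = val.strip()
    if "isosbestic_nm" not in params or "window" not in params:
        raise PlateFormatError(
            f"{path}: reference bundle lacks isosbestic_nm/window header comments"
        )
    iso = float(params["isosbestic_nm"])
    lo, _, hi = params["window"].partition(":")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.columns[0] != "wavelength_nm":
        raise PlateFormatError(f"{path}: first column must be 'wavelength_nm'")
    grid = df["wavelength_nm"].to_numpy(dtype=float)
    compound_ids = tuple(df.columns[1:])
    spectra = tuple(
        Spectrum(grid, df[c].to_numpy(dtype=float), {"compound": c})
        for c in compound_ids
    )
    return ReferenceSet(
        spectra=spectra,
        isosbestic_nm=iso,
        window=(float(lo), float(hi)),
        compound_ids=compound_ids,
    )


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    wells = {
        well: {k: v for k, v in asdict(rec).items() if v is not None}
        for well, rec in layout.wells.items()
    }
    Path(path).write_text(yaml.safe_dump({"wells": wells}, sort_keys=True))
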