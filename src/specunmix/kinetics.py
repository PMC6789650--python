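"""Reaction progress curves and initial-rate estimation.

Time-stamped unmixing results become progress curves of conversion
(base molar fraction, 0-1) versus time.  Because the assay quenches an
aliquot of the reaction into alkaline solution before measurement, a
dilution bookkeeping type (:class:`SamplingScheme`) converts between
reaction-stock and in-well concentrations.  The initial rate is the
slope of conversion vs time over the low-conversion region, scaled by
the substrate concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import DesignError, InsufficientDataError
from .unmixing import UnmixResult

__all__ = [
    "SamplingScheme",
    "ProgressCurve",
    "final_concentration",
    "assemble_progress_curve",
    "estimate_initial_rate",
]


@dataclass(frozen=True)
class SamplingScheme:
    """Quench-dilution scheme: an aliquot of reaction pipetted into NaOH.

    Typical schemes: 30 uL of a 2 mM pyrimidine reaction, or 20 uL of a
    purine reaction, into NaOH to a final volume of 500 uL.
    """

    sample_volume_ul: float
    final_volume_ul: float
    stock_concentration_mm: float
    naoh_mm: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.sample_volume_ul <= self.final_volume_ul:
            raise DesignError(
                "need 0 < sample_volume_ul <= final_volume_ul "
                f"(got {self.sample_volume_ul} / {self.final_volume_ul})"
            )
        if self.stock_concentration_mm <= 0:
            raise DesignError("stock concentration must be positive")


def final_concentration(scheme: SamplingScheme) -> float:
    """In-well concentration of UV-active compounds after quenching, in uM."""
    return (
        1000.0
        * scheme.stock_concentration_mm
        * scheme.sample_volume_ul
        / scheme.final_volume_ul
    )


@dataclass(frozen=True)
class ProgressCurve:
    """Conversion (base molar fraction) versus reaction time."""

    times_s: np.ndarray
    conversion: np.ndarray
    std_errors: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        c = np.asarray(self.conversion, dtype=float)
        se = np.asarray(self.std_errors, dtype=float)
        if not (t.shape == c.shape == se.shape):
            raise ValueError("times, conversion and std_errors must align")
        if np.any(np.diff(t) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any((c < -1e-9) | (c > 1 + 1e-9)):
            raise ValueError("conversion must lie in [0, 1]")
        for arr in (t, c, se):
            arr.setflags(write=False)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "conversion", c)
        object.__setattr__(self, "std_errors", se)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def __len__(self) -> int:
        return self.times_s.size


def assemble_progress_curve(
    results: Iterable[tuple[Mapping[str, object], UnmixResult]],
    base_compound: str,
) -> ProgressCurve:
    """Sort time-stamped unmixing results into a progress curve.

    Each result's metadata must carry ``time_s``; conversion is the
    estimated molar fraction of ``base_compound`` and its standard
    error is propagated from the fit.  Input order is irrelevant — the
    curve is sorted by time.
    """
    rows = []
    for meta, res in results:
        if "time_s" not in meta or meta["time_s"] is None:
            raise DesignError(
                f"result {meta.get('sample_id', '?')!r} has no time_s metadata"
            )
        rows.append(
            (
                float(meta["time_s"]),
                res.fraction_of(base_compound),
                res.std_error_of(base_compound),
                str(meta.get("sample_id", "")),
            )
        )
    if not rows:
        raise DesignError("no results to assemble")
    rows.sort(key=lambda r: r[0])
    t, c, se, ids = zip(*rows)
    return ProgressCurve(
        np.array(t), np.array(c), np.array(se), tuple(ids)
    )


def estimate_initial_rate(
    curve: ProgressCurve,
    substrate_concentration_mm: float,
    max_conversion: float = 0.10,
    through_origin: bool = True,
) -> tuple[float, float]:
    """Initial reaction rate in mM/s from the low-conversion region.

    Fits conversion vs time by ordinary least squares over points with
    conversion below ``max_conversion`` and multiplies the slope by the
    substrate concentration.  The regression is forced through the
    origin by default: at t = 0, before enzyme addition, conversion is
    zero by construction of the experiment.

    Returns ``(rate_mm_per_s, standard_error)``.
    """
    mask = curve.conversion < max_conversion
    t = curve.times_s[mask]
    c = curve.conversion[mask]
    if t.size < 2:
        raise InsufficientDataError(
            f"only {t.size} point(s) below conversion {max_conversion}; "
            "need at least 2 for a rate estimate"
        )
    if through_origin:
        denom = float(t @ t)
        if denom == 0.0:
            raise InsufficientDataError("all eligible points are at t = 0")
        slope = float(t @ c) / denom
        resid = c - slope * t
        dof = t.size - 1
        se_slope = float(np.sqrt((resid @ resid) / dof / denom)) if dof > 0 else np.nan
    else:
        design = np.column_stack([t, np.ones_like(t)])
        coef, _, _, _ = np.linalg.lstsq(design, c, rcond=None)
        slope = float(coef[0])
        resid = c - design @ coef
        dof = t.size - 2
        if dof > 0:
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(design.T @ design)
            se_slope = float(np.sqrt(cov[0, 0]))
        else:
            se_slope = np.nan
    rate = slope * substrate_concentration_mm
    return rate, se_slope * substrate_concentration_mm
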