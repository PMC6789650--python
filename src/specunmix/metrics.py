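"""Validation statistics: actual-vs-predicted agreement of molar fractions.

All quantities here live on the percent scale (0-100), the natural unit
for reporting mixture compositions and their errors (in percentage
points, pp).  Molar fractions on the 0-1 scale are converted at this
module's boundary.

Conventions: ``actual`` is the designed (gravimetric/volumetric)
composition of a validation sample; ``predicted`` is the composition
estimated by spectral unmixing.  R-squared uses the standard
definition, ``1 - SS_res / SS_tot`` with ``SS_res = sum((pred -
actual)^2)`` and ``SS_tot = sum((actual - mean(actual))^2)``; the RMSD
is ``sqrt(mean((pred - actual)^2))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError

__all__ = ["ValidationTable", "r_squared", "rmsd", "compare_methods"]

_SUM_TOL_PCT = 1e-6


@dataclass(frozen=True)
class ValidationTable:
    """Paired actual/predicted molar fractions, in percent.

    Wraps a DataFrame with columns ``sample_id``, ``replicate``, and for
    each compound ``actual_<id>`` and ``predicted_<id>``.  Replicates
    are individual rows — each measurement counts as its own data point.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        required = {"sample_id", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"validation table missing columns: {sorted(missing)}")
        compounds = self.__class__._compounds_of(df)
        if not compounds:
            raise ValueError("validation table has no actual_/predicted_ column pairs")
        # designed compositions are physical by construction; estimates from
        # unconstrained comparator methods (e.g. HPLC) may stray a little
        for prefix, slack in (("actual_", _SUM_TOL_PCT), ("predicted_", 5.0)):
            block = df[[prefix + c for c in compounds]].to_numpy(dtype=float)
            if np.any(block < -slack) or np.any(block > 100 + slack):
                raise ValueError(
                    f"{prefix}fractions must lie in [0, 100] percent"
                    + (f" (+/- {slack} pp)" if slack >= 1 else "")
                )
            sums = block.sum(axis=1)
            if np.any(np.abs(sums - 100.0) > max(slack, 1e-3)):
                raise ValueError(
                    f"{prefix}fractions must sum to 100 percent per row "
                    f"(worst row sums to {sums[np.argmax(np.abs(sums - 100))]:.4f})"
                )
        object.__setattr__(self, "data", df)

    @staticmethod
    def _compounds_of(df: pd.DataFrame) -> list[str]:
        actual = {c[len("actual_"):] for c in df.columns if c.startswith("actual_")}
        predicted = {
            c[len("predicted_"):] for c in df.columns if c.startswith("predicted_")
        }
        return sorted(actual & predicted)

    @property
    def compounds(self) -> list[str]:
        return self._compounds_of(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def pairs(self, compound: str) -> tuple[np.ndarray, np.ndarray]:
        """(actual, predicted) percent vectors for one compound."""
        if compound not in self.compounds:
            raise KeyError(f"unknown compound {compound!r}; have {self.compounds}")
        actual = self.data[f"actual_{compound}"].to_numpy(dtype=float)
        predicted = self.data[f"predicted_{compound}"].to_numpy(dtype=float)
        return actual, predicted

    @classmethod
    def from_fractions(
        cls,
        sample_ids,
        replicates,
        actual: dict[str, np.ndarray],
        predicted: dict[str, np.ndarray],
    ) -> "ValidationTable":
        """Build a table from 0-1 molar fractions (converted to percent)."""
        cols: dict[str, object] = {
            "sample_id": list(sample_ids),
            "replicate": list(replicates),
        }
        for cid, vals in actual.items():
            cols[f"actual_{cid}"] = 100.0 * np.asarray(vals, dtype=float)
        for cid, vals in predicted.items():
            cols[f"predicted_{cid}"] = 100.0 * np.asarray(vals, dtype=float)
        return cls(pd.DataFrame(cols))


def r_squared(table: ValidationTable, compound: str) -> float:
    """Coefficient of determination of predicted vs designed fractions.

    ``R^2 = 1 - SS_res / SS_tot`` with residuals taken against the
    designed values and the total sum of squares around the mean of the
    designed values.  Equals 1 for perfect prediction and 0 when the
    predictions do no better than the mean of the design.
    """
    actual, predicted = table.pairs(compound)
    if actual.size < 2:
        raise UndefinedStatisticError("R^2 needs at least two data points")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError(
            "R^2 undefined: designed fractions are all identical"
        )
    ss_res = float(np.sum((predicted - actual) ** 2))
    return 1.0 - ss_res / ss_tot


def rmsd(table: ValidationTable, compound: str) -> float:
    """Root-mean-square deviation of predicted from designed fractions (pp)."""
    actual, predicted = table.pairs(compound)
    if actual.size == 0:
        raise UndefinedStatisticError("RMSD of an empty table")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


def compare_methods(
    table_a: ValidationTable, table_b: ValidationTable, compound: str
) -> pd.DataFrame:
    """Per-sample absolute disagreement between two estimation methods (pp).

    Both tables must contain the same (sample_id, replicate) keys.
    Returns a DataFrame with one row per sample and columns
    ``predicted_a``, ``predicted_b`` and ``abs_difference_pp``; the
    maximum disagreement is stored in ``df.attrs['max_abs_difference_pp']``.
    """
    keys = ["sample_id", "replicate"]
    a = table_a.data[keys + [f"predicted_{compound}"]].rename(
        columns={f"predicted_{compound}": "predicted_a"}
    )
    b = table_b.data[keys + [f"predicted_{compound}"]].rename(
        columns={f"predicted_{compound}": "predicted_b"}
    )
    if sorted(map(tuple, a[keys].to_numpy().tolist())) != sorted(
        map(tuple, b[keys].to_numpy().tolist())
    ):
        raise ValueError("tables do not share the same sample/replicate ids")
    merged = a.merge(b, on=keys, validate="one_to_one")
    merged["abs_difference_pp"] = (merged.predicted_a - merged.predicted_b).abs()
    merged.attrs["max_abs_difference_pp"] = float(merged.abs_difference_pp.max())
    return merged
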