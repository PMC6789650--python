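"""Constrained spectral unmixing: molar fractions from a mixture spectrum.

The estimator solves

    min_x  sum_{lambda in window} ( Y_sample(lambda) - sum_i x_i Y_i(lambda) )^2
    s.t.   0 <= x_i <= 1,  sum_i x_i = 1

where the Y_i are isosbestic-normalized pure-compound spectra and
Y_sample is the blank-corrected, normalized spectrum of the mixture.
The x_i are the molar fractions of the UV-active compounds.

The sum-to-one constraint is enforced by parameterizing the first M-1
fractions and setting x_M = 1 - sum(others).  For the two-component
case that covers this assay (nucleoside + nucleobase) the reduced
problem is a one-dimensional box-constrained convex quadratic, which is
solved exactly in closed form — the global minimizer is the clipped
unconstrained optimum.  For M > 2 components a deterministic SLSQP
minimization from the uniform composition is used.

Standard errors come from the Gauss-Markov covariance of the reduced
linear model, ``sigma^2 (J^T J)^{-1}`` with ``sigma^2`` the residual
variance, propagated through x_M = 1 - sum(others).  When the optimum
sits on a bound (a pure sample) the linearized covariance is not a
valid sampling distribution, and the result is flagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .errors import (
    EmptyWindowError,
    NormalizationError,
    SpecUnmixError,
    UnderdeterminedError,
)
from .spectra import ReferenceSet, Spectrum

__all__ = ["UnmixResult", "unmix", "unmix_grid_oracle", "apply_window"]

#: Acceptable deviation of input spectra from 1.0 at the isosbestic point.
NORMALIZATION_TOL = 1e-6


@dataclass(frozen=True)
class UnmixResult:
    """Estimated molar composition of one mixture spectrum."""

    fractions: np.ndarray
    std_errors: np.ndarray
    residual_ss: float
    window: tuple[float, float]
    n_points: int
    converged: bool
    compound_ids: tuple[str, ...]
    #: False when the optimum lies on a bound (x_i = 0 or 1), where the
    #: linearized standard errors are not trustworthy.
    se_reliable: bool = True

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        se = np.asarray(self.std_errors, dtype=float)
        fr.setflags(write=False)
        se.setflags(write=False)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "std_errors", se)

    def fraction_of(self, compound_id: str) -> float:
        return float(self.fractions[self.compound_ids.index(compound_id)])

    def std_error_of(self, compound_id: str) -> float:
        return float(self.std_errors[self.compound_ids.index(compound_id)])


def apply_window(spec: Spectrum, window: tuple[float, float]) -> Spectrum:
    """Restrict a spectrum to grid points with lo <= lambda <= hi (inclusive)."""
    lo, hi = float(window[0]), float(window[1])
    if lo > hi:
        raise EmptyWindowError(f"window lo {lo} > hi {hi}")
    mask = (spec.wavelengths_nm >= lo - 1e-9) & (spec.wavelengths_nm <= hi + 1e-9)
    if int(mask.sum()) < 2:
        raise EmptyWindowError(
            f"window {lo}-{hi} nm selects fewer than two grid points on "
            f"{spec.wavelengths_nm[0]:g}-{spec.wavelengths_nm[-1]:g} nm"
        )
    return Spectrum(
        spec.wavelengths_nm[mask],
        spec.absorbance_au[mask],
        meta={**spec.meta, "window": (lo, hi)},
    )


def _windowed_design(
    sample: Spectrum,
    refs: ReferenceSet,
    window: tuple[float, float],
    check_normalized: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (A, b, n) restricted to the window: columns of A are references."""
    if not sample.same_grid(refs.spectra[0]):
        raise SpecUnmixError(
            "sample and reference spectra are on different wavelength grids"
        )
    if check_normalized:
        iso = refs.isosbestic_nm
        a_iso = sample.at(iso)
        if abs(a_iso - 1.0) > NORMALIZATION_TOL:
            raise NormalizationError(
                f"sample has A({iso:g} nm) = {a_iso:.6f}; normalize to the "
                "isosbestic point before unmixing"
            )
    sub_sample = apply_window(sample, window)
    sub_refs = [apply_window(s, window) for s in refs.spectra]
    b = sub_sample.absorbance_au
    A = np.column_stack([s.absorbance_au for s in sub_refs])
    n = b.size
    if n < refs.n_compounds:
        raise UnderdeterminedError(
            f"window contains {n} wavelengths for {refs.n_compounds} compounds"
        )
    return A, b, n


def _solve_two_component(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x = [t, 1 - t]; residual = (b - y2) - t (y1 - y2); exact clipped optimum
    d = A[:, 0] - A[:, 1]
    r0 = b - A[:, 1]
    denom = float(d @ d)
    if denom == 0.0:
        raise SpecUnmixError(
            "reference spectra are identical within the window; the "
            "composition is unidentifiable"
        )
    t = float(np.clip((d @ r0) / denom, 0.0, 1.0))
    return np.array([t, 1.0 - t])


def _solve_multi_component(A: np.ndarray, b: np.ndarray, m: int) -> tuple[np.ndarray, bool]:
    def objective(x: np.ndarray) -> float:
        r = b - A @ x
        return float(r @ r)

    def gradient(x: np.ndarray) -> np.ndarray:
        return -2.0 * A.T @ (b - A @ x)

    res = scipy.optimize.minimize(
        objective,
        x0=np.full(m, 1.0 / m),
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0,
                      "jac": lambda x: np.ones_like(x)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    x = np.clip(res.x, 0.0, 1.0)
    x = x / x.sum()
    return x, bool(res.success)


def _standard_errors(
    A: np.ndarray, b: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """Reduced-model covariance: J maps the M-1 free fractions to the residual."""
    n, m = A.shape
    resid = b - A @ x
    ss = float(resid @ resid)
    dof = n - (m - 1)
    se = np.full(m, np.nan)
    if dof > 0:
        s2 = ss / dof
        J = A[:, : m - 1] - A[:, [m - 1]]  # d(model)/d(free fractions)
        jtj = J.T @ J
        try:
            cov = s2 * np.linalg.inv(jtj)
            se_free = np.sqrt(np.diag(cov))
            se_last = float(np.sqrt(np.ones(m - 1) @ cov @ np.ones(m - 1)))
            se = np.concatenate([se_free, [se_last]])
        except np.linalg.LinAlgError:
            pass
    at_bound = bool(np.any(np.isclose(x, 0.0, atol=1e-12)) or
                    np.any(np.isclose(x, 1.0, atol=1e-12)))
    return se, ss, not at_bound


def unmix(
    sample: Spectrum,
    refs: ReferenceSet,
    window: tuple[float, float] | None = None,
    check_normalized: bool = True,
) -> UnmixResult:
    """Estimate molar fractions of a normalized mixture spectrum.

    Parameters
    ----------
    sample
        Blank-corrected spectrum normalized to ``refs.isosbestic_nm``
        (checked unless ``check_normalized=False``).
    refs
        Normalized pure-compound reference spectra.
    window
        Inclusive wavelength range to fit; defaults to ``refs.window``.
        Restricting the window to the information-rich region (typically
        from the isosbestic point upward) can improve accuracy at
        extreme compositions.

    Returns
    -------
    UnmixResult
        Fractions satisfying the box and sum-to-one constraints exactly,
        with one-sigma standard errors and the residual sum of squares
        on the normalized absorbance scale.

    Notes
    -----
    Fully deterministic: identical inputs give identical results.
    Because the fit sees only normalized spectra, the estimate is
    invariant to any overall scaling of the raw sample (dilution,
    pathlength) — only the spectral form matters.
    """
    if window is None:
        window = refs.window
    A, b, n = _windowed_design(sample, refs, window, check_normalized)
    m = refs.n_compounds
    if m == 2:
        x = _solve_two_component(A, b)
        converged = True
    else:
        x, converged = _solve_multi_component(A, b, m)
    se, ss, se_reliable = _standard_errors(A, b, x)
    return UnmixResult(
        fractions=x,
        std_errors=se,
        residual_ss=ss,
        window=(float(window[0]), float(window[1])),
        n_points=n,
        converged=converged,
        compound_ids=refs.compound_ids,
        se_reliable=se_reliable,
    )


def unmix_grid_oracle(
    sample: Spectrum,
    refs: ReferenceSet,
    window: tuple[float, float] | None = None,
    step: float = 1e-4,
    check_normalized: bool = True,
) -> UnmixResult:
    """Exhaustive-search estimator for the two-component problem.

    Evaluates the least-squares objective at every composition
    x_1 in {0, step, 2*step, ..., 1}, x_2 = 1 - x_1, and returns the
    minimizer (ties broken toward smaller x_1).  Brute force by design:
    it shares no code path with :func:`unmix` and serves as an
    independent check of the solver.
    """
    if refs.n_compounds != 2:
        raise SpecUnmixError("the grid oracle supports exactly two compounds")
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-12:
        raise ValueError(f"step {step} does not divide 1 evenly")
    if window is None:
        window = refs.window
    A, b, n = _windowed_design(sample, refs, window, check_normalized)
    t = np.linspace(0.0, 1.0, n_steps + 1)
    # residual matrix: rows = candidate compositions
    resid = (b - A[:, 1])[None, :] - t[:, None] * (A[:, 0] - A[:, 1])[None, :]
    obj = np.einsum("ij,ij->i", resid, resid)
    best = int(np.argmin(obj))  # first minimum = smallest x_1 on ties
    x = np.array([t[best], 1.0 - t[best]])
    se, ss, se_reliable = _standard_errors(A, b, x)
    return UnmixResult(
        fractions=x,
        std_errors=se,
        residual_ss=float(obj[best]),
        window=(float(window[0]), float(window[1])),
        n_points=n,
        converged=True,
        compound_ids=refs.compound_ids,
        se_reliable=se_reliable,
    )
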