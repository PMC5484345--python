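"""Closed-form linear least-squares estimation of CTU parameters.

Integrating the CTU differential system twice over time turns the model
into a relation that is linear in three coefficients:

    C(t) = -alpha * Cbar(t) + beta * cabar(t) + gamma * cabarbar(t)

where an overbar denotes the running time-integral from the first sample
and the double overbar the running double integral of the arterial
curve.  The coefficients map one-to-one onto the kinetic parameters:

    alpha = (Fp+PS)/vp,  beta = Fp,  gamma = Fp*PS/vp
    vp = beta^2/(alpha*beta - gamma),  Fp = beta,
    PS = gamma*beta/(alpha*beta - gamma),  Tp = 1/alpha,
    E = gamma/(alpha*beta)

so a single 3x3 normal-equation solve replaces iterative optimisation.
All integrals use trapezoidal quadrature.  The solution is deliberately
unconstrained: negative vp or an extraction fraction outside [0, 1] are
returned as-is and classified, because those categories carry diagnostic
information (see :mod:`ctufit.qc`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .curve import Curve, check_same_grid
from .model import CTUParams, DerivedParams

__all__ = [
    "LinearCoefficients",
    "LLSResult",
    "running_trapz",
    "build_design_matrix",
    "coeffs_to_params",
    "params_to_coeffs",
    "solve_lls",
]

#: relative determinant threshold below which the normal equations are
#: declared degenerate rather than inverted
DEGENERACY_TOL = 1e-12

_CATEGORIES = ("valid", "E_negative", "E_above_one", "vp_negative", "degenerate")


@dataclass(frozen=True)
class LinearCoefficients:
    """Solution vector (alpha, beta, gamma) of the linearised model.

    alpha : (PS+Fp)/vp, min^-1
    beta  : Fp, min^-1
    gamma : Fp*PS/vp, min^-2
    """

    alpha: float
    beta: float
    gamma: float


@dataclass(frozen=True)
class LLSResult:
    coefficients: LinearCoefficients
    params: CTUParams
    derived: DerivedParams
    category: str
    residual_l2: float
    fitted: Curve | None = None

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def running_trapz(curve: Curve) -> Curve:
    """Cumulative trapezoidal integral of a curve, zero at the first sample."""
    if len(curve) < 2:
        raise ValueError("need at least 2 samples to integrate")
    return curve.with_c(cumulative_trapezoid(curve.c, curve.t, initial=0.0))


def build_design_matrix(C: Curve, ca: Curve) -> np.ndarray:
    """N x 3 design matrix [-Cbar, cabar, cabarbar] on the shared grid.

    The first row is all zeros (every running integral vanishes at the
    first sample) and the third column is by construction the running
    integral of the second.
    """
    check_same_grid(C, ca)
    cbar = running_trapz(C)
    cabar = running_trapz(ca)
    cabarbar = running_trapz(cabar)
    return np.column_stack([-cbar.c, cabar.c, cabarbar.c])


def params_to_coeffs(p: CTUParams) -> LinearCoefficients:
    """Forward map (Fp, vp, PS) -> (alpha, beta, gamma)."""
    if p.vp == 0:
        raise ValueError("vp = 0: coefficients undefined")
    return LinearCoefficients(
        alpha=(p.Fp + p.PS) / p.vp, beta=p.Fp, gamma=p.Fp * p.PS / p.vp
    )


def coeffs_to_params(lc: LinearCoefficients) -> tuple[CTUParams, DerivedParams]:
    """Exact algebraic back-map (alpha, beta, gamma) -> kinetic parameters.

    No clipping or sign correction is applied.  Raises ZeroDivisionError
    when alpha*beta - gamma, alpha or beta vanish (the caller flags such
    solutions as degenerate).
    """
    a, b, g = lc.alpha, lc.beta, lc.gamma
    d = a * b - g
    if d == 0 or a == 0 or b == 0:
        raise ZeroDivisionError("degenerate coefficient vector")
    params = CTUParams(Fp=b, vp=b * b / d, PS=g * b / d)
    derived = DerivedParams(Tp=1.0 / a, E=g / (a * b), Ktrans=g / a)
    return params, derived


def _classify(params: CTUParams, derived: DerivedParams) -> str:
    if params.vp <= 0:
        return "vp_negative"
    if derived.E < 0:
        return "E_negative"
    if derived.E > 1:
        return "E_above_one"
    return "valid"


def _solve_3x3(M: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Analytic (adjugate) inverse of the 3x3 normal matrix; None if singular.

    Degeneracy test: |det| relative to the Hadamard bound prod(diag(M)),
    which is scale-invariant for a Gram matrix.
    """
    (a, b, c), (_, e, f), (_, _, i) = M
    d, g, h = b, c, f  # symmetric
    A = e * i - f * h
    B = -(d * i - f * g)
    Cc = d * h - e * g
    det = a * A + b * B + c * Cc
    hadamard = M[0, 0] * M[1, 1] * M[2, 2]
    if hadamard <= 0 or abs(det) < DEGENERACY_TOL * hadamard:
        return None
    adj = np.array(
        [
            [A, -(b * i - c * h), b * f - c * e],
            [B, a * i - c * g, -(a * f - c * d)],
            [Cc, -(a * h - b * g), a * e - b * d],
        ]
    )
    return adj @ y / det


_NAN_PARAMS = CTUParams(np.nan, np.nan, np.nan)
_NAN_DERIVED = DerivedParams(np.nan, np.nan, np.nan)


def solve_lls(C: Curve, ca: Curve) -> LLSResult:
    """Fit the CTU model by closed-form linear least squares.

    Builds the design matrix A, solves min ||A b - c||_2 through the
    normal equations with analytic 3x3 inversion, maps the coefficient
    vector to kinetic parameters, and classifies the solution.  A
    singular or near-singular system yields ``category='degenerate'``
    with NaN parameters rather than an exception.

    The goodness-of-fit ``residual_l2`` and the ``fitted`` curve refer to
    the linear model reconstruction A b, which is also what the flatness
    QC test inspects for an LLS fit.
    """
    if len(C) < 4:
        raise ValueError("need at least 4 time points to fit 3 coefficients")
    A = build_design_matrix(C, ca)
    y = C.c
    b = _solve_3x3(A.T @ A, A.T @ y)
    if b is None:
        lc = LinearCoefficients(np.nan, np.nan, np.nan)
        return LLSResult(lc, _NAN_PARAMS, _NAN_DERIVED, "degenerate", np.nan)
    lc = LinearCoefficients(*b)
    fitted = A @ b
    residual = float(np.linalg.norm(fitted - y))
    try:
        params, derived = coeffs_to_params(lc)
    except ZeroDivisionError:
        return LLSResult(lc, _NAN_PARAMS, _NAN_DERIVED, "degenerate", residual,
                         C.with_c(fitted))
    return LLSResult(
        lc, params, derived, _classify(params, derived), residual, C.with_c(fitted)
    )
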