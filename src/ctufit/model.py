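"""The compartmental tissue uptake (CTU) forward model.

The CTU model is a three-parameter special case of the two-compartment
exchange model, valid when back-flux of contrast agent from the
extravascular space is negligible (short acquisitions relative to the
extravascular transit time).  Its free parameters are the plasma flow
``Fp`` (min^-1), the fractional plasma volume ``vp`` (dimensionless) and
the permeability-surface-area product ``PS`` (min^-1).  The tissue
concentration is the arterial input convolved with the impulse response

    h(t) = Fp * exp(-t/Tp) + Ktrans * (1 - exp(-t/Tp)),

where Tp = vp/(Fp+PS) is the plasma mean transit time, E = PS/(PS+Fp) the
extraction fraction and Ktrans = E*Fp the volume transfer constant.

Convolution with the exponential kernel is computed exactly under a
piecewise-linear interpolation of the arterial curve between its samples
(a per-interval closed-form recursion), not as a discrete-sum
convolution.  This keeps the forward model accurate on coarsely sampled
grids, which is exactly the regime where fitting is done in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import cumulative_trapezoid

from .curve import Curve

__all__ = [
    "CTUParams",
    "DerivedParams",
    "derived_params",
    "ctu_impulse_response",
    "exp_convolve",
    "ctu_forward",
    "one_compartment_forward",
]


@dataclass(frozen=True)
class CTUParams:
    """Free kinetic parameters of the uptake model.

    Fp : plasma flow per unit tissue volume (min^-1)
    vp : fractional plasma volume (dimensionless)
    PS : permeability-surface-area product per unit tissue volume (min^-1)

    A physically valid set has Fp > 0, vp > 0, PS >= 0.  The linear
    fitter may produce invalid sets (negative vp, E outside [0, 1]); those
    are carried through unclipped and classified downstream.
    """

    Fp: float
    vp: float
    PS: float

    def is_valid(self) -> bool:
        return self.Fp > 0 and self.vp > 0 and self.PS >= 0


@dataclass(frozen=True)
class DerivedParams:
    """Quantities derived from CTUParams.

    Tp : plasma mean transit time, vp/(Fp+PS) (min)
    E : extraction fraction, PS/(PS+Fp) (dimensionless, in [0,1] when valid)
    Ktrans : volume transfer constant, E*Fp (min^-1)
    """

    Tp: float
    E: float
    Ktrans: float


def derived_params(p: CTUParams) -> DerivedParams:
    """Compute (Tp, E, Ktrans) from the free parameters."""
    denom = p.Fp + p.PS
    if denom == 0:
        raise ValueError("Fp + PS = 0: plasma transit time undefined")
    E = p.PS / denom
    return DerivedParams(Tp=p.vp / denom, E=E, Ktrans=E * p.Fp)


def ctu_impulse_response(p: CTUParams, t: np.ndarray | float) -> np.ndarray:
    """Evaluate the CTU impulse response h(t) (min^-1) at times t (min).

    h(0) = Fp and h(t) -> Ktrans as t -> inf; for a valid parameter set
    (E < 1) the response decays monotonically between the two.
    """
    d = derived_params(p)
    t = np.asarray(t, dtype=float)
    decay = np.exp(-t / d.Tp) if d.Tp > 0 else np.where(t > 0, 0.0, 1.0)
    return p.Fp * decay + d.Ktrans * (1.0 - decay)


@njit(cache=False)
def _expconv_kernel(t: np.ndarray, c: np.ndarray, lam: float) -> np.ndarray:
    """g(t_n) = int_0^{t_n} c(s) exp(-lam (t_n - s)) ds, c piecewise linear.

    Per-interval recursion: g_{i+1} = e^{-lam*dt} g_i + closed-form
    contribution of the interval.  All exponents are negative, so the
    recursion is stable for any lam >= 0.
    """
    n = t.size
    out = np.zeros(n)
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        x = lam * dt
        e = math.exp(-x)
        if x > 1e-2:
            # int_0^dt e^{-lam u} du  and  int_0^dt u e^{-lam u} du
            i0 = (1.0 - e) / lam
            i1 = (1.0 - (1.0 + x) * e) / (lam * lam)
        else:
            # series expansions; avoids catastrophic cancellation
            x2 = x * x
            i0 = dt * (1.0 - x / 2.0 + x2 / 6.0 - x2 * x / 24.0 + x2 * x2 / 120.0)
            i1 = dt * dt * (
                0.5 - x / 3.0 + x2 / 8.0 - x2 * x / 30.0 + x2 * x2 / 144.0
            )
        m = (c[i + 1] - c[i]) / dt
        out[i + 1] = e * out[i] + c[i + 1] * i0 - m * i1
    return out


def exp_convolve(ca: Curve, tau: float) -> Curve:
    """Convolve a curve with exp(-t/tau) exactly (piecewise-linear input).

    Parameters
    ----------
    ca : Curve
        Input curve on its own (possibly non-uniform) grid.
    tau : float
        Decay time constant in minutes; must be positive.

    Returns
    -------
    Curve
        ca ⊗ exp(-t/tau) evaluated on ca's grid.  For a unit step input
        the result is tau*(1 - exp(-t/tau)).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return ca.with_c(_expconv_kernel(ca.t, ca.c, 1.0 / tau))


def _running_integral(ca: Curve) -> np.ndarray:
    # trapezoidal running integral; shared convention with the linear fitter
    return cumulative_trapezoid(ca.c, ca.t, initial=0.0)


def ctu_forward(p: CTUParams, ca: Curve) -> Curve:
    """Tissue concentration predicted by the CTU model.

    C(t) = ca ⊗ h with h the CTU impulse response, i.e.

        C = (Fp - Ktrans) * (ca ⊗ e^{-t/Tp}) + Ktrans * ∫ca dt,

    evaluated on ca's grid.  Degenerate parameter regions are handled by
    their limits so the function is safe to call inside a bounded
    optimiser: vp -> 0 collapses the vascular term, Fp+PS -> 0 gives a
    zero curve.
    """
    denom = p.Fp + p.PS
    if denom <= 0:
        return ca.with_c(np.zeros(len(ca)))
    E = p.PS / denom
    ktrans = E * p.Fp
    leak = ktrans * _running_integral(ca)
    if p.vp <= 0:
        # Tp -> 0: the vascular pass is instantaneous and carries no area
        return ca.with_c(leak)
    tp = p.vp / denom
    g = _expconv_kernel(ca.t, ca.c, 1.0 / tp)
    return ca.with_c((p.Fp - ktrans) * g + leak)


def one_compartment_forward(Fp: float, vp: float, ca: Curve) -> Curve:
    """One-compartment model: C(t) = ca ⊗ (Fp * exp(-t*Fp/vp)).

    This is the PS = 0 limit of the CTU model (no extravasation); useful
    as a comparison fit for slowly enhancing curves.
    """
    if Fp <= 0 or vp <= 0:
        raise ValueError("Fp and vp must be positive")
    g = _expconv_kernel(ca.t, ca.c, Fp / vp)
    return ca.with_c(Fp * g)
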