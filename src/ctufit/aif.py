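"""Parker population arterial input function and arterial-curve utilities.

The Parker AIF is a population-averaged model of arterial blood plasma
gadolinium concentration after a standard bolus: two Gaussians describing
the first and second pass plus a sigmoid-modulated exponential washout
tail.  The constants below are the published population values (times and
widths in minutes, amplitudes in mM·min for the Gaussian terms and mM for
the tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curve import Curve

__all__ = ["AIFParams", "PARKER_DEFAULT", "parker_aif", "hematocrit_correct"]


@dataclass(frozen=True)
class AIFParams:
    """Constants of the Parker population AIF functional form.

    ``a1, a2`` are the Gaussian scaling constants (mM·min), ``t1, t2`` the
    Gaussian centres (min), ``sigma1, sigma2`` the Gaussian widths (min);
    ``alpha`` (mM) and ``beta`` (min^-1) set the exponential washout, and
    ``s`` (min^-1), ``tau`` (min) set the sigmoid that switches it on.
    """

    a1: float = 0.809
    a2: float = 0.330
    t1: float = 0.17046
    t2: float = 0.365
    sigma1: float = 0.0563
    sigma2: float = 0.132
    alpha: float = 1.050
    beta: float = 0.1685
    s: float = 38.078
    tau: float = 0.483

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("Gaussian widths must be strictly positive")


#: Published population-average constants.
PARKER_DEFAULT = AIFParams()


def parker_aif(
    t: np.ndarray | float,
    params: AIFParams = PARKER_DEFAULT,
    onset: float = 0.0,
) -> np.ndarray:
    """Evaluate the Parker population AIF.

    Parameters
    ----------
    t : array_like
        Time in minutes.
    params : AIFParams
        Functional-form constants.
    onset : float
        Bolus arrival time in minutes (length of the pre-contrast
        baseline).  The AIF is exactly zero for ``t < onset``.

    Returns
    -------
    ndarray
        Plasma concentration in mM.
    """
    if onset < 0:
        raise ValueError("onset must be non-negative")
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite time values")
    tt = t - onset
    out = np.zeros_like(tt)
    m = tt >= 0
    x = tt[m]
    p = params
    g1 = p.a1 / (p.sigma1 * np.sqrt(2 * np.pi)) * np.exp(
        -((x - p.t1) ** 2) / (2 * p.sigma1**2)
    )
    g2 = p.a2 / (p.sigma2 * np.sqrt(2 * np.pi)) * np.exp(
        -((x - p.t2) ** 2) / (2 * p.sigma2**2)
    )
    tail = p.alpha * np.exp(-p.beta * x) / (1 + np.exp(-p.s * (x - p.tau)))
    out[m] = g1 + g2 + tail
    return out


def hematocrit_correct(ca: Curve, factor: float = 1.18) -> Curve:
    """Scale an arterial curve by a hematocrit correction factor.

    Blood-sampled AIFs measure whole-blood concentration; scaling by a
    factor > 1 (default 1.18, from an assumed large-vessel hematocrit of
    0.38 and small-to-large vessel ratio of 0.7) converts to the plasma
    concentration seen by the tissue.
    """
    if factor <= 0:
        raise ValueError("hematocrit correction factor must be positive")
    return ca.with_c(ca.c * factor)
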