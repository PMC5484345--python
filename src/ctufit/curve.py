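"""Sampled concentration-time curves.

All kinetic code in this package works in minutes (kinetic rate constants
are min^-1) and millimolar concentration. File readers convert seconds to
minutes on ingest; see :mod:`ctufit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Curve:
    """A sampled time series, e.g. tissue C(t) or arterial ca(t).

    Parameters
    ----------
    t : ndarray
        Time stamps in minutes, strictly increasing.
    c : ndarray
        Concentration in mM, same length as ``t``. Values may be negative
        (noisy data) but must be finite.
    """

    t: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if t.ndim != 1 or c.ndim != 1:
            raise ValueError("Curve arrays must be one-dimensional")
        if t.size != c.size:
            raise ValueError(
                f"time and concentration lengths differ: {t.size} vs {c.size}"
            )
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite time stamps")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite concentrations")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "c", c)

    def __len__(self) -> int:
        return self.t.size

    def with_c(self, c: np.ndarray) -> "Curve":
        """Return a new curve on the same grid with replaced concentrations."""
        return Curve(self.t, c)


def check_same_grid(a: Curve, b: Curve, *, rtol: float = 1e-10) -> None:
    """Raise ValueError unless two curves share the same time grid."""
    if len(a) != len(b) or not np.allclose(a.t, b.t, rtol=rtol, atol=0.0):
        raise ValueError("curves are not sampled on the same time grid")
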