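"""Bounded nonlinear least-squares fitting of the analytical CTU model.

This is the conventional route: minimise the L2 distance between the
measured tissue curve and the analytical forward model over (Fp, vp, PS)
with a trust-region-reflective solver and positivity bounds.  It serves
as the reference against which the closed-form linear fit is compared,
and as a refinement stage seeded by the linear estimate on real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curve import Curve, check_same_grid
from .linear import solve_lls
from .model import CTUParams, DerivedParams, ctu_forward, derived_params

__all__ = ["NLLSConfig", "FitResult", "fit_nlls", "default_init", "l2_norm"]

#: fallback initial guess when the linear seed is degenerate: mid-range
#: tumour-like values
_FALLBACK_INIT = CTUParams(Fp=0.3, vp=0.1, PS=0.05)


@dataclass(frozen=True)
class NLLSConfig:
    """Optimiser settings.

    Bounds default to positivity with no upper limit, matching how the
    model is constrained physically; ``init`` is the starting point (use
    :func:`default_init` to seed from the linear fit on real data).
    """

    init: CTUParams = _FALLBACK_INIT
    lower: tuple[float, float, float] = (0.0, 0.0, 0.0)
    upper: tuple[float, float, float] = (np.inf, np.inf, np.inf)
    max_iterations: int = 200
    ftol: float = 1e-8
    xtol: float = 1e-8

    def __post_init__(self) -> None:
        x0 = (self.init.Fp, self.init.vp, self.init.PS)
        for v, lo, hi in zip(x0, self.lower, self.upper):
            if not lo <= v <= hi:
                raise ValueError("initial guess outside bounds")


@dataclass(frozen=True)
class FitResult:
    params: CTUParams
    derived: DerivedParams
    residual_l2: float
    converged: bool
    n_iterations: int


def l2_norm(model: Curve, data: Curve) -> float:
    """Euclidean distance between two curves on the same grid."""
    check_same_grid(model, data)
    return float(np.linalg.norm(model.c - data.c))


def fit_nlls(C: Curve, ca: Curve, cfg: NLLSConfig | None = None) -> FitResult:
    """Fit the CTU model by bounded trust-region nonlinear least squares."""
    check_same_grid(C, ca)
    if cfg is None:
        cfg = NLLSConfig(init=default_init(C, ca))

    def residuals(x: np.ndarray) -> np.ndarray:
        return ctu_forward(CTUParams(*x), ca).c - C.c

    x0 = np.array([cfg.init.Fp, cfg.init.vp, cfg.init.PS])
    res = least_squares(
        residuals,
        x0,
        bounds=(cfg.lower, cfg.upper),
        method="trf",
        ftol=cfg.ftol,
        xtol=cfg.xtol,
        gtol=1e-12,
        max_nfev=cfg.max_iterations * 4,
    )
    params = CTUParams(*res.x)
    try:
        derived = derived_params(params)
    except ValueError:
        derived = DerivedParams(np.nan, np.nan, np.nan)
    return FitResult(
        params=params,
        derived=derived,
        residual_l2=float(np.linalg.norm(res.fun)),
        converged=bool(res.status > 0),
        n_iterations=int(res.nfev),
    )


def default_init(
    C: Curve, ca: Curve, floor: float = 1e-3
) -> CTUParams:
    """Seed the nonlinear fit from the closed-form linear estimate.

    Components of the linear solution that are non-positive or
    non-finite are replaced by a small positive floor so the seed always
    lies inside the positivity bounds; a fixed mid-range default is used
    when the linear system is degenerate.
    """
    lls = solve_lls(C, ca)
    if lls.category == "degenerate":
        return _FALLBACK_INIT

    def proj(v: float) -> float:
        return v if np.isfinite(v) and v > 0 else floor

    return CTUParams(proj(lls.params.Fp), proj(lls.params.vp), proj(lls.params.PS))
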