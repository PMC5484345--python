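"""Voxel-level quality control and classification.

Clinical parameter mapping fits thousands of voxel curves, many of which
are noise-dominated or outside the model's domain of validity.  This
module reproduces a two-stage screen: first generic data quality
(negative distribution volume; a fitted curve indistinguishable from
baseline noise), then model-validity of the unconstrained linear
solution (negative vp, extraction fraction outside [0, 1]).  The
decision ladder is evaluated in that fixed order and each voxel gets
exactly one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid

from .curve import Curve, check_same_grid
from .linear import LLSResult

__all__ = [
    "VoxelQC",
    "distribution_volume",
    "baseline_stats",
    "estimate_cnr",
    "classify_voxel",
]

DECISIONS = (
    "included",
    "excluded_negative_vd",
    "excluded_flat",
    "lls_vp_negative",
    "lls_E_negative",
    "lls_E_above_one",
    "degenerate",
)


@dataclass(frozen=True)
class VoxelQC:
    vd: float
    cnr: float
    baseline_mean: float
    baseline_sd: float
    decision: str

    def __post_init__(self) -> None:
        if self.decision not in DECISIONS:
            raise ValueError(f"unknown decision {self.decision!r}")


def distribution_volume(C: Curve, ca: Curve) -> float:
    """vd = integral of C over the acquisition / integral of ca.

    A physically meaningful voxel has vd > 0; noise-dominated voxels can
    integrate to a negative ratio, which is the first exclusion screen.
    """
    check_same_grid(C, ca)
    denom = float(trapezoid(ca.c, ca.t))
    if denom == 0:
        raise ValueError("arterial curve integrates to zero")
    return float(trapezoid(C.c, C.t)) / denom


def baseline_stats(C: Curve, n_baseline: int) -> tuple[float, float]:
    """Mean and sample SD of the first ``n_baseline`` concentrations."""
    if n_baseline < 2:
        raise ValueError("need at least 2 baseline samples")
    if n_baseline > len(C):
        raise ValueError("n_baseline exceeds curve length")
    base = C.c[:n_baseline]
    return float(np.mean(base)), float(np.std(base, ddof=1))


def estimate_cnr(C: Curve, baseline: tuple[float, float]) -> float:
    """Empirical CNR: (max(C) - baseline mean) / baseline SD.

    Returns +inf when the baseline SD is zero (noise-free data).
    """
    mean, sd = baseline
    if sd == 0:
        return float("inf")
    return (float(np.max(C.c)) - mean) / sd


def classify_voxel(
    C: Curve, ca: Curve, fit: LLSResult, n_baseline: int
) -> VoxelQC:
    """Apply the exclusion ladder to one voxel.

    Order: (1) negative distribution volume; (2) fitted model curve
    completely contained within the 95% confidence band of the baseline
    noise (mean +/- 1.96 sd), i.e. no detectable enhancement; (3) vp <= 0;
    (4) E < 0; (5) E > 1; otherwise included.  A degenerate linear solve
    is labelled as such.
    """
    check_same_grid(C, ca)
    vd = distribution_volume(C, ca)
    mean, sd = baseline_stats(C, n_baseline)
    cnr = estimate_cnr(C, (mean, sd))

    def result(decision: str) -> VoxelQC:
        return VoxelQC(vd=vd, cnr=cnr, baseline_mean=mean, baseline_sd=sd,
                       decision=decision)

    if vd < 0:
        return result("excluded_negative_vd")
    if fit.category == "degenerate":
        return result("degenerate")
    fitted = fit.fitted.c if fit.fitted is not None else None
    if fitted is not None and sd > 0:
        lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
        if np.all((fitted >= lo) & (fitted <= hi)):
            return result("excluded_flat")
    if fit.params.vp <= 0:
        return result("lls_vp_negative")
    if fit.derived.E < 0:
        return result("lls_E_negative")
    if fit.derived.E > 1:
        return result("lls_E_above_one")
    return result("included")
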