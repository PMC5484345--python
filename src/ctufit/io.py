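"""File formats and fitting drivers.

Curve tables are delimited text (CSV) with a header declaring the time
unit: a ``time_s`` or ``time_min`` column, an optional ``ca_mM`` arterial
column, and one or more tissue columns (any other name).  Everything is
converted to minutes on read.  4D voxel data travel as a NIfTI volume
plus a 3D mask, a per-frame time table and an AIF curve table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .curve import Curve
from .linear import solve_lls
from .nonlinear import NLLSConfig, default_init, fit_nlls
from .qc import DECISIONS, classify_voxel
from .simulate import (
    SimConfig,
    TABLE_TISSUES,
    add_noise,
    downsample_jitter,
    generate_noiseless,
    sigma_from_cnr,
)

log = logging.getLogger("ctufit")

__all__ = [
    "read_curves",
    "write_curves",
    "fit_curves",
    "read_volume_bundle",
    "fit_volume",
    "make_fixtures",
    "infer_n_baseline",
]

_TIME_COLS = {"time_s": 1.0 / 60.0, "time_min": 1.0}
_FLOAT_FMT = "%.12g"


def read_curves(
    path: str | Path, unit: str | None = None
) -> tuple[np.ndarray, np.ndarray | None, dict[str, np.ndarray]]:
    """Read a curve table; returns (t_minutes, ca or None, tissue columns).

    The time unit comes from the column name (``time_s``/``time_min``) or,
    for a bare ``time`` column, from the explicit ``unit`` argument.
    Validation errors name the offending column and row.
    """
    df = pd.read_csv(path)
    time_col = next((c for c in df.columns if c in _TIME_COLS), None)
    if time_col is not None:
        scale = _TIME_COLS[time_col]
    elif "time" in df.columns:
        if unit not in ("s", "min"):
            raise ValueError(
                "column 'time' carries no unit; pass unit='s' or unit='min'"
            )
        time_col, scale = "time", (1.0 / 60.0 if unit == "s" else 1.0)
    else:
        raise ValueError(f"{path}: no time_s/time_min/time column found")

    t = df[time_col].to_numpy(dtype=float) * scale
    bad = np.where(~np.isfinite(t))[0]
    if bad.size:
        raise ValueError(f"{path}: non-finite time at row {bad[0]}")
    nonmono = np.where(np.diff(t) <= 0)[0]
    if nonmono.size:
        raise ValueError(
            f"{path}: time not strictly increasing at row {nonmono[0] + 1}"
        )
    ca = None
    tissues: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col == time_col:
            continue
        vals = df[col].to_numpy(dtype=float)
        bad = np.where(~np.isfinite(vals))[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-finite concentration in column {col!r} row {bad[0]}"
            )
        if col == "ca_mM":
            ca = vals
        else:
            tissues[col] = vals
    return t, ca, tissues


def write_curves(
    path: str | Path,
    t_min: np.ndarray,
    ca: np.ndarray | None = None,
    tissues: dict[str, np.ndarray] | None = None,
    unit: str = "s",
) -> None:
    """Write a curve table (time converted to the declared unit)."""
    if unit not in ("s", "min"):
        raise ValueError("unit must be 's' or 'min'")
    cols: dict[str, np.ndarray] = {
        ("time_s" if unit == "s" else "time_min"): np.asarray(t_min)
        * (60.0 if unit == "s" else 1.0)
    }
    if ca is not None:
        cols["ca_mM"] = np.asarray(ca)
    for name, vals in (tissues or {}).items():
        cols[name] = np.asarray(vals)
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def infer_n_baseline(ca: np.ndarray, threshold: float = 0.05) -> int:
    """Number of pre-bolus samples: frames before ca exceeds 5% of its max."""
    ca = np.asarray(ca, dtype=float)
    above = np.where(ca > threshold * np.max(ca))[0]
    n = int(above[0]) if above.size else len(ca)
    return max(n, 2)


_RESULT_COLS = [
    "curve", "method", "Fp", "vp", "PS", "Tp", "E", "Ktrans",
    "residual_l2", "category", "qc_decision",
]


def fit_curves(
    t_min: np.ndarray,
    ca: np.ndarray,
    tissues: dict[str, np.ndarray],
    method: str = "both",
    n_baseline: int | None = None,
) -> pd.DataFrame:
    """Fit every tissue column; one row per (curve, method).

    LLS rows carry the linear-solution validity category and the voxel QC
    decision; degenerate fits are recorded with NaN parameters, never
    dropped.  NLLS is seeded from the linear estimate.
    """
    if method not in ("lls", "nlls", "both"):
        raise ValueError("method must be 'lls', 'nlls' or 'both'")
    if ca is None:
        raise ValueError("fitting requires an arterial column 'ca_mM'")
    ca_curve = Curve(t_min, ca)
    if n_baseline is None:
        n_baseline = infer_n_baseline(ca)
    rows = []
    for name, vals in tissues.items():
        C = Curve(t_min, vals)
        if method in ("lls", "both"):
            res = solve_lls(C, ca_curve)
            qc = classify_voxel(C, ca_curve, res, n_baseline)
            rows.append(
                dict(
                    curve=name, method="lls",
                    Fp=res.params.Fp, vp=res.params.vp, PS=res.params.PS,
                    Tp=res.derived.Tp, E=res.derived.E, Ktrans=res.derived.Ktrans,
                    residual_l2=res.residual_l2, category=res.category,
                    qc_decision=qc.decision,
                )
            )
        if method in ("nlls", "both"):
            cfg = NLLSConfig(init=default_init(C, ca_curve))
            fit = fit_nlls(C, ca_curve, cfg)
            rows.append(
                dict(
                    curve=name, method="nlls",
                    Fp=fit.params.Fp, vp=fit.params.vp, PS=fit.params.PS,
                    Tp=fit.derived.Tp, E=fit.derived.E, Ktrans=fit.derived.Ktrans,
                    residual_l2=fit.residual_l2,
                    category="valid" if fit.converged else "not_converged",
                    qc_decision="",
                )
            )
    return pd.DataFrame(rows, columns=_RESULT_COLS)


def read_volume_bundle(
    volume: str | Path,
    mask: str | Path,
    times: str | Path,
    aif: str | Path,
    unit: str | None = None,
):
    """Load a 4D concentration volume with mask, frame times and AIF."""
    img = nib.load(str(volume))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("volume must be 4D (x, y, z, t)")
    mask_img = nib.load(str(mask))
    mask_arr = np.asarray(mask_img.dataobj) > 0
    if mask_arr.shape != data.shape[:3]:
        raise ValueError("mask shape does not match volume spatial dims")
    t_min, _, _ = read_curves(times, unit=unit)
    if t_min.size != data.shape[3]:
        raise ValueError("frame-time count does not match 4th volume dim")
    ta, ca, _ = read_curves(aif, unit=unit)
    if ta.size != t_min.size or not np.allclose(ta, t_min):
        raise ValueError("AIF time grid does not match frame times")
    if ca is None:
        raise ValueError("AIF table must contain a 'ca_mM' column")
    return data, mask_arr, t_min, ca, img.affine


def fit_volume(
    volume: str | Path,
    mask: str | Path,
    times: str | Path,
    aif: str | Path,
    outdir: str | Path,
    method: str = "lls",
    unit: str | None = None,
    n_baseline: int | None = None,
) -> list[Path]:
    """Fit every masked voxel and write one 3D map per parameter.

    Output: ``<param>_<method>.nii`` for Fp, vp, PS, Tp, E, Ktrans and
    residual, plus an integer QC-decision map (codes index
    :data:`ctufit.qc.DECISIONS`).  Returns the written paths.
    """
    data, mask_arr, t_min, ca, affine = read_volume_bundle(
        volume, mask, times, aif, unit
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    idx = np.argwhere(mask_arr)
    if idx.size == 0:
        log.warning("empty mask: no voxels to fit")
    tissues = {f"{i}_{j}_{k}": data[i, j, k, :] for i, j, k in idx}
    methods = ("lls", "nlls") if method == "both" else (method,)
    written: list[Path] = []
    if tissues:
        table = fit_curves(t_min, ca, tissues, method=method, n_baseline=n_baseline)
    else:
        table = pd.DataFrame(columns=_RESULT_COLS)
    for m in methods:
        sub = table[table.method == m]
        maps = {p: np.full(mask_arr.shape, np.nan) for p in
                ("Fp", "vp", "PS", "Tp", "E", "Ktrans", "residual_l2")}
        qc_map = np.full(mask_arr.shape, -1, dtype=np.int16)
        for _, row in sub.iterrows():
            i, j, k = (int(v) for v in row["curve"].split("_"))
            for p in maps:
                maps[p][i, j, k] = row[p]
            if row["qc_decision"] in DECISIONS:
                qc_map[i, j, k] = DECISIONS.index(row["qc_decision"])
        for p, arr in maps.items():
            path = outdir / f"{p}_{m}.nii"
            nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(path))
            written.append(path)
        if m == "lls":
            path = outdir / f"qc_{m}.nii"
            nib.save(nib.Nifti1Image(qc_map, affine), str(path))
            written.append(path)
    return written


def make_fixtures(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write the standard simulated test fixtures, deterministic per seed.

    For each literature tissue parameter set: a noiseless curve table at
    2-s sampling plus noisy versions at CNR 5, 10 and 20; and one small
    synthetic 4D volume bundle (brain-tumour parameters, CNR 20).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []
    curves: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name, params in TABLE_TISSUES.items():
        cfg = SimConfig(tissue=params)
        ca_m, C_m = generate_noiseless(cfg)
        ca = downsample_jitter(ca_m, cfg.dt_s, t0_s=0.0)
        C = downsample_jitter(C_m, cfg.dt_s, t0_s=0.0)
        path = outdir / f"{name}_noiseless_dt2s.csv"
        write_curves(path, ca.t, ca.c, {"C_mM": C.c})
        written.append(path)
        for cnr in (5, 10, 20):
            sigma = sigma_from_cnr(C_m, cnr)
            Cn = add_noise(C, sigma, rng)
            can = add_noise(ca, sigma, rng)
            path = outdir / f"{name}_cnr{cnr}_dt2s.csv"
            write_curves(path, ca.t, can.c, {"C_mM": Cn.c})
            written.append(path)
            curves[f"{name}_cnr{cnr}"] = (ca.t, can.c, Cn.c)

    # small synthetic volume bundle: 3x3x2 voxels, brain parameters, CNR 20
    cfg = SimConfig(tissue=TABLE_TISSUES["brain"])
    ca_m, C_m = generate_noiseless(cfg)
    ca = downsample_jitter(ca_m, cfg.dt_s, t0_s=0.0)
    C = downsample_jitter(C_m, cfg.dt_s, t0_s=0.0)
    sigma = sigma_from_cnr(C_m, 20.0)
    shape = (3, 3, 2)
    vol = np.empty(shape + (len(C),))
    for i in np.ndindex(shape):
        vol[i] = add_noise(C, sigma, rng).c
    mask = np.ones(shape, dtype=np.int16)
    mask[0, 0, 0] = 0
    affine = np.eye(4)
    vol_path = outdir / "synthetic_volume_4d.nii"
    nib.save(nib.Nifti1Image(vol, affine), str(vol_path))
    mask_path = outdir / "synthetic_volume_mask.nii"
    nib.save(nib.Nifti1Image(mask, affine), str(mask_path))
    times_path = outdir / "synthetic_volume_times.csv"
    write_curves(times_path, C.t)
    aif_path = outdir / "synthetic_volume_aif.csv"
    write_curves(aif_path, ca.t, add_noise(ca, sigma, rng).c)
    written += [vol_path, mask_path, times_path, aif_path]
    return written
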