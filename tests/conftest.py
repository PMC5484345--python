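import numpy as np
import pytest

from ctufit import (
    Curve,
    SimConfig,
    TABLE_TISSUES,
    downsample_jitter,
    generate_noiseless,
)


@pytest.fixture(scope="session")
def master_curves():
    """Cached noiseless (ca, C) master-grid curves per tissue name."""
    cache: dict[str, tuple[Curve, Curve]] = {}

    def get(name: str):
        if name not in cache:
            cache[name] = generate_noiseless(SimConfig(tissue=TABLE_TISSUES[name]))
        return cache[name]

    return get


@pytest.fixture(scope="session")
def brain_coarse(master_curves):
    """Noiseless brain-tumour curves at 2-s sampling, zero jitter."""
    ca, C = master_curves("brain")
    return (
        downsample_jitter(ca, 2.0, t0_s=0.0),
        downsample_jitter(C, 2.0, t0_s=0.0),
    )


def brute_expconv(curve: Curve, tau: float, fine_dt_s: float = 1e-3) -> np.ndarray:
    """Brute-force Riemann-sum oracle for ca (x) exp(-t/tau).

    Midpoint sums on a fine grid (1 ms by default), linearly interpolating
    the input between its samples.  Independent of the closed-form
    recursion under test.
    """
    fdt = fine_dt_s / 60.0
    n_int = np.round((curve.t - curve.t[0]) / fdt).astype(int)
    mids = curve.t[0] + (np.arange(n_int[-1]) + 0.5) * fdt
    cmid = np.interp(mids, curve.t, curve.c)
    out = np.empty(len(curve))
    for i, (tn, k) in enumerate(zip(curve.t, n_int)):
        out[i] = np.sum(cmid[:k] * np.exp(-(tn - mids[:k]) / tau)) * fdt
    return out


def make_voxel_population(ca_master: Curve, n_voxels: int, cnr: float, rng):
    """Simulated voxel population with heterogeneous kinetic parameters.

    Each voxel draws its own (Fp, vp, PS) from the ranges reported for
    valid tumour voxels in clinical cervix data (Fp up to ~2 min^-1, vp
    up to ~0.85, PS up to ~0.2 min^-1), gets its own CTU curve and its
    own noise sized to the target CNR — mimicking the parameter spread
    of a clinical tumour region.
    Returns (t, noisy ca, {name: noisy C}, {name: CTUParams}).
    """
    from ctufit import CTUParams, ctu_forward, sigma_from_cnr

    ca = downsample_jitter(ca_master, 2.0, t0_s=0.0)
    tissues, truths = {}, {}
    sigma_ref = None
    for i in range(n_voxels):
        p = CTUParams(
            Fp=float(rng.uniform(0.1, 2.0)),
            vp=float(rng.uniform(0.05, 0.85)),
            PS=float(rng.uniform(0.005, 0.2)),
        )
        C_m = ctu_forward(p, ca_master)
        sigma = sigma_from_cnr(C_m, cnr)
        if sigma_ref is None:
            sigma_ref = sigma
        C = downsample_jitter(C_m, 2.0, t0_s=0.0)
        name = f"v{i:03d}"
        tissues[name] = C.c + rng.normal(0.0, sigma, len(C))
        truths[name] = p
    ca_noisy = ca.c + rng.normal(0.0, sigma_ref, len(ca))
    return ca.t, ca_noisy, tissues, truths
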