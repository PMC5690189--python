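"""Relative seriality NTCP model (Poisson-statistics dose response).

The single-subvolume response is the Källman double exponential

    P(D) = 2 ** ( -exp( e * gamma * (1 - D / D50) ) )

and the whole-organ complication probability combines the subvolume
responses over the differential DVH as

    P = [ 1 - prod_i (1 - P(D_i)^s) ** dv_i ] ** (1/s)

with D_i the bin midpoint dose and dv_i the bin's fractional volume.
For a uniform dose the organ response reduces to P(D) for every s > 0.
"""

from __future__ import annotations

import numpy as np

from .dvh import DifferentialDVH
from .params import SerialityParams

__all__ = ["subvolume_response", "ntcp", "ntcp_voxelwise", "eqd2_transform"]

_E = float(np.e)
_LN2 = float(np.log(2.0))


def subvolume_response(dose, p: SerialityParams):
    """Complication probability of a subvolume uniformly irradiated to ``dose`` Gy.

    Accepts a scalar or array dose; strictly increasing in dose, 0.5 at d50.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    out = np.exp2(-np.exp(_E * p.gamma * (1.0 - d / p.d50)))
    return float(out) if np.isscalar(dose) else out


def _combine(doses: np.ndarray, dv: np.ndarray, p: SerialityParams) -> float:
    """Seriality combination via a dv-weighted log-sum for numerical safety."""
    prob = subvolume_response(doses, p)
    # log(1 - P^s) computed as log1p(-exp(s*log P)); P > 0 always (double
    # exponential), but P^s can round to 1 at extreme dose -> -inf is the
    # correct limit and yields organ probability 1.
    with np.errstate(divide="ignore"):
        log_surv = np.log1p(-np.exp(p.s * np.log(prob)))
    log_prod = float(np.dot(dv, log_surv))
    if np.isneginf(log_prod):
        return 1.0
    inner = -np.expm1(log_prod)  # 1 - prod(...), accurate near 0
    if inner <= 0.0:
        return 0.0
    return float(np.exp(np.log(inner) / p.s))


def ntcp(d: DifferentialDVH, p: SerialityParams) -> float:
    """Whole-organ complication probability from a differential DVH."""
    return _combine(d.midpoints, d.frac_volume, p)


def ntcp_voxelwise(doses, p: SerialityParams) -> float:
    """Brute-force evaluation on an explicit equal-volume voxel dose list.

    Each voxel carries fractional volume 1/N; no binning is applied.  This
    is the reference route the binned :func:`ntcp` is checked against.
    """
    d = np.asarray(doses, dtype=float)
    if d.size == 0:
        raise ValueError("dose list must be non-empty")
    dv = np.full(d.size, 1.0 / d.size)
    return _combine(d, dv, p)


def eqd2_transform(d: DifferentialDVH, alpha_beta_gy: float, n_fractions: int) -> DifferentialDVH:
    """Optional 2-Gy-equivalent dose transform of a DVH (off by default).

    Each bin dose D delivered in ``n_fractions`` equal fractions maps to
    ``D * (D/n + ab) / (2 + ab)``.  Applied to bin edges; monotone, so bin
    ordering is preserved.
    """
    if alpha_beta_gy <= 0 or n_fractions < 1:
        raise ValueError("alpha_beta_gy must be > 0 and n_fractions >= 1")

    def f(x: np.ndarray) -> np.ndarray:
        return x * (x / n_fractions + alpha_beta_gy) / (2.0 + alpha_beta_gy)

    lo = f(d.lo)
    hi = f(d.hi)
    # degenerate guard: keep strictly positive widths after the transform
    hi = np.maximum(hi, lo + 1e-12)
    return DifferentialDVH(organ=d.organ, lo=lo, hi=hi, frac_volume=d.frac_volume, dose_kind=d.dose_kind)
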