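"""Dose-volume histogram data model, CSV I/O, conversions and scalar metrics.

A *differential* DVH stores, for one organ, the fraction of organ volume
falling in each absorbed-dose bin.  Bins are half-open intervals ``[lo, hi)``
on a contiguous grid starting wherever the export starts; unirradiated
volume is carried explicitly in a zero-dose bin so that the fractional
volumes always sum to one.  A *cumulative* DVH stores the fraction of
volume receiving at least each dose (the form most planning systems
export).

The representative dose of a bin is its midpoint ``(lo + hi) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VOLUME_TOL",
    "DoseBin",
    "DifferentialDVH",
    "CumulativeDVH",
    "DVHFormatError",
    "DVHValidationError",
    "read_dvh_csv",
    "write_dvh_csv",
    "cumulative_to_differential",
    "differential_to_cumulative",
    "rebin",
    "vx",
    "mean_dose",
    "scale_dose",
    "merge_dvhs",
]

#: tolerance on total fractional volume of a differential DVH
VOLUME_TOL = 1e-6

DIFFERENTIAL_COLUMNS = ["patient_id", "modality", "organ", "bin_lo_gy", "bin_hi_gy", "frac_volume"]
CUMULATIVE_COLUMNS = ["patient_id", "modality", "organ", "dose_gy", "frac_volume_ge"]


class DVHFormatError(ValueError):
    """Raised when a DVH file does not conform to the expected CSV dialect."""


class DVHValidationError(ValueError):
    """Raised when DVH contents violate a structural invariant."""


@dataclass(frozen=True)
class DoseBin:
    """One differential-DVH bin: dose interval ``[lo, hi)`` in Gy and the
    fraction of organ volume receiving a dose in that interval."""

    lo: float
    hi: float
    frac_volume: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi):
            raise DVHValidationError(f"bin edges must satisfy 0 <= lo < hi, got [{self.lo}, {self.hi})")
        if not (0.0 <= self.frac_volume <= 1.0):
            raise DVHValidationError(f"frac_volume must be in [0, 1], got {self.frac_volume}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class DifferentialDVH:
    """Binned fractional-volume-versus-dose distribution for one organ.

    Parameters
    ----------
    organ:
        Structure label, e.g. ``"heart"``, ``"lung"``, ``"breast"``.
    lo, hi, frac_volume:
        Equal-length arrays of bin lower/upper edges (Gy) and fractional
        volumes.  Bins must be sorted, contiguous and non-overlapping, and
        the fractional volumes must sum to 1 within :data:`VOLUME_TOL`.
    dose_kind:
        ``"physical_gy"`` or ``"rbe_weighted_gy"`` — bookkeeping only; the
        risk models operate on the numeric dose as given.
    """

    organ: str
    lo: np.ndarray
    hi: np.ndarray
    frac_volume: np.ndarray
    dose_kind: str = "physical_gy"

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        fv = np.asarray(self.frac_volume, dtype=float)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        object.__setattr__(self, "frac_volume", fv)
        if not (lo.shape == hi.shape == fv.shape) or lo.ndim != 1 or lo.size == 0:
            raise DVHValidationError("lo, hi and frac_volume must be equal-length non-empty 1-d arrays")
        if lo[0] < 0:
            raise DVHValidationError(f"first bin edge must be >= 0, got {lo[0]}")
        if np.any(hi <= lo):
            k = int(np.argmax(hi <= lo))
            raise DVHValidationError(f"bin {k} has hi <= lo ([{lo[k]}, {hi[k]}))")
        if lo.size > 1 and not np.allclose(hi[:-1], lo[1:], rtol=0.0, atol=1e-9):
            k = int(np.argmax(~np.isclose(hi[:-1], lo[1:], rtol=0.0, atol=1e-9)))
            raise DVHValidationError(
                f"bins must be contiguous and sorted: bin {k} ends at {hi[k]} but bin {k + 1} starts at {lo[k + 1]}"
            )
        if np.any(fv < -1e-12) or np.any(fv > 1.0 + 1e-12):
            raise DVHValidationError("frac_volume values must lie in [0, 1]")
        total = float(fv.sum())
        if abs(total - 1.0) > VOLUME_TOL:
            raise DVHValidationError(f"frac_volume must sum to 1 within {VOLUME_TOL:g}, got {total!r}")
        if self.dose_kind not in ("physical_gy", "rbe_weighted_gy"):
            raise DVHValidationError(f"unknown dose_kind {self.dose_kind!r}")

    @property
    def n_bins(self) -> int:
        """Number of subvolumes (bins)."""
        return int(self.lo.size)

    @property
    def midpoints(self) -> np.ndarray:
        """Representative dose of each bin (Gy)."""
        return 0.5 * (self.lo + self.hi)

    @property
    def bins(self) -> tuple[DoseBin, ...]:
        return tuple(DoseBin(float(l), float(h), float(f)) for l, h, f in zip(self.lo, self.hi, self.frac_volume))

    @property
    def max_dose(self) -> float:
        """Upper edge of the highest bin holding any volume."""
        nz = np.nonzero(self.frac_volume > 0)[0]
        return float(self.hi[nz[-1]]) if nz.size else float(self.hi[0])

    @classmethod
    def from_bins(cls, organ: str, bins: Sequence[DoseBin], dose_kind: str = "physical_gy") -> "DifferentialDVH":
        b = sorted(bins, key=lambda x: x.lo)
        return cls(
            organ=organ,
            lo=np.array([x.lo for x in b]),
            hi=np.array([x.hi for x in b]),
            frac_volume=np.array([x.frac_volume for x in b]),
            dose_kind=dose_kind,
        )

    @classmethod
    def uniform(cls, organ: str, dose_gy: float, width: float = 0.1, dose_kind: str = "physical_gy") -> "DifferentialDVH":
        """Whole organ in a single bin whose midpoint is exactly ``dose_gy``."""
        lo = max(dose_gy - 0.5 * width, 0.0)
        hi = lo + width
        return cls(organ=organ, lo=np.array([lo]), hi=np.array([hi]), frac_volume=np.array([1.0]), dose_kind=dose_kind)


@dataclass(frozen=True)
class CumulativeDVH:
    """Fraction of organ volume receiving at least each dose.

    ``dose_gy`` must be strictly increasing starting at 0, ``frac_ge``
    non-increasing with ``frac_ge[0] == 1``.
    """

    organ: str
    dose_gy: np.ndarray
    frac_ge: np.ndarray
    dose_kind: str = "physical_gy"

    def __post_init__(self) -> None:
        d = np.asarray(self.dose_gy, dtype=float)
        f = np.asarray(self.frac_ge, dtype=float)
        object.__setattr__(self, "dose_gy", d)
        object.__setattr__(self, "frac_ge", f)
        if d.shape != f.shape or d.ndim != 1 or d.size == 0:
            raise DVHValidationError("dose_gy and frac_ge must be equal-length non-empty 1-d arrays")
        if np.any(np.diff(d) <= 0):
            raise DVHValidationError("doses must be strictly increasing")
        if np.any(np.diff(f) > 1e-12):
            k = int(np.argmax(np.diff(f) > 1e-12))
            raise DVHValidationError(f"fractions must be non-increasing (violated between points {k} and {k + 1})")
        if d[0] != 0.0:
            raise DVHValidationError(f"first dose must be 0, got {d[0]}")
        if abs(f[0] - 1.0) > VOLUME_TOL:
            raise DVHValidationError(f"fraction at dose 0 must be 1, got {f[0]!r}")
        if f[-1] < -1e-12:
            raise DVHValidationError("fractions must be >= 0")


# ---------------------------------------------------------------------------
# CSV I/O


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DVHFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DVHFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_dvh_csv(path: str | Path, form: str = "differential") -> dict[tuple[str, str, str], "DifferentialDVH | CumulativeDVH"]:
    """Read a DVH CSV file; returns ``{(patient_id, modality, organ): dvh}``.

    ``form`` selects the dialect: ``"differential"`` expects columns
    ``patient_id, modality, organ, bin_lo_gy, bin_hi_gy, frac_volume``;
    ``"cumulative"`` expects ``patient_id, modality, organ, dose_gy,
    frac_volume_ge``.
    """
    path = Path(path)
    if form == "differential":
        df = _read_table(path, DIFFERENTIAL_COLUMNS)
        out: dict[tuple[str, str, str], DifferentialDVH | CumulativeDVH] = {}
        for (pid, mod, organ), grp in df.groupby(["patient_id", "modality", "organ"], sort=False):
            grp = grp.sort_values("bin_lo_gy")
            try:
                dvh = DifferentialDVH(
                    organ=str(organ),
                    lo=grp["bin_lo_gy"].to_numpy(),
                    hi=grp["bin_hi_gy"].to_numpy(),
                    frac_volume=grp["frac_volume"].to_numpy(),
                )
            except DVHValidationError as exc:
                raise DVHValidationError(f"{path} ({pid}/{mod}/{organ}): {exc}") from exc
            out[(str(pid), str(mod), str(organ))] = dvh
        return out
    if form == "cumulative":
        df = _read_table(path, CUMULATIVE_COLUMNS)
        out = {}
        for (pid, mod, organ), grp in df.groupby(["patient_id", "modality", "organ"], sort=False):
            grp = grp.sort_values("dose_gy")
            try:
                dvh = CumulativeDVH(
                    organ=str(organ),
                    dose_gy=grp["dose_gy"].to_numpy(),
                    frac_ge=grp["frac_volume_ge"].to_numpy(),
                )
            except DVHValidationError as exc:
                raise DVHValidationError(f"{path} ({pid}/{mod}/{organ}): {exc}") from exc
            out[(str(pid), str(mod), str(organ))] = dvh
        return out
    raise ValueError(f"form must be 'differential' or 'cumulative', got {form!r}")


def write_dvh_csv(
    path: str | Path,
    dvhs: dict[tuple[str, str, str], DifferentialDVH],
) -> None:
    """Write differential DVHs keyed by (patient_id, modality, organ)."""
    frames = []
    for (pid, mod, organ), d in dvhs.items():
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "modality": mod,
                    "organ": organ,
                    "bin_lo_gy": d.lo,
                    "bin_hi_gy": d.hi,
                    "frac_volume": d.frac_volume,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Conversions


def cumulative_to_differential(c: CumulativeDVH) -> DifferentialDVH:
    """First-difference a cumulative DVH into differential bins.

    Bin ``[d_k, d_{k+1})`` receives ``frac_ge[k] - frac_ge[k+1]``; any
    volume still present at the last tabulated dose is assigned to a final
    narrow bin above it.
    """
    if c.dose_gy.size < 2:
        raise DVHValidationError("cumulative DVH needs at least 2 points to convert")
    lo = c.dose_gy[:-1]
    hi = c.dose_gy[1:]
    fv = -np.diff(c.frac_ge)
    fv = np.clip(fv, 0.0, None)
    tail = float(c.frac_ge[-1])
    if tail > 0:
        width = float(hi[-1] - lo[-1])
        lo = np.append(lo, hi[-1])
        hi = np.append(hi, hi[-1] + width)
        fv = np.append(fv, tail)
    return DifferentialDVH(organ=c.organ, lo=lo, hi=hi, frac_volume=fv, dose_kind=c.dose_kind)


def differential_to_cumulative(d: DifferentialDVH) -> CumulativeDVH:
    """Tail-sum a differential DVH: fraction at dose x = volume with lo >= x."""
    tail = np.concatenate([np.cumsum(d.frac_volume[::-1])[::-1], [0.0]])
    doses = np.concatenate([d.lo, [d.hi[-1]]])
    if doses[0] != 0.0:
        doses = np.concatenate([[0.0], doses])
        tail = np.concatenate([[tail[0]], tail])
    # renormalise the tiny float drift so frac(0) is exactly 1
    tail = np.minimum(tail, 1.0)
    tail[0] = 1.0
    return CumulativeDVH(organ=d.organ, dose_gy=doses, frac_ge=tail, dose_kind=d.dose_kind)


def rebin(d: DifferentialDVH, width: float) -> DifferentialDVH:
    """Resample onto a uniform grid of the given bin width.

    Each source bin's volume is apportioned to target bins proportionally
    to dose overlap, so total volume is conserved exactly.
    """
    if width <= 0:
        raise ValueError(f"bin width must be > 0, got {width}")
    top = float(d.hi[-1])
    n = max(int(np.ceil(top / width - 1e-9)), 1)
    edges = np.arange(n + 1) * width
    fv = np.zeros(n)
    for lo, hi, f in zip(d.lo, d.hi, d.frac_volume):
        if f == 0:
            continue
        i0 = min(int(np.floor(lo / width + 1e-12)), n - 1)
        i1 = min(int(np.ceil(hi / width - 1e-12)), n)
        span = hi - lo
        for i in range(i0, i1):
            overlap = min(hi, edges[i + 1]) - max(lo, edges[i])
            if overlap > 0:
                fv[i] += f * overlap / span
    # exact conservation: push float residue into the largest bin
    fv[int(np.argmax(fv))] += float(d.frac_volume.sum()) - float(fv.sum())
    return DifferentialDVH(organ=d.organ, lo=edges[:-1], hi=edges[1:], frac_volume=fv, dose_kind=d.dose_kind)


# ---------------------------------------------------------------------------
# Scalar metrics


def vx(d: DifferentialDVH, threshold: float) -> float:
    """Fraction of organ volume whose bin midpoint dose is >= ``threshold`` Gy."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if threshold == 0:
        return float(d.frac_volume.sum())
    return float(d.frac_volume[d.midpoints >= threshold].sum())


def mean_dose(d: DifferentialDVH) -> float:
    """Volume-weighted mean of bin midpoint doses (Gy)."""
    return float(np.dot(d.midpoints, d.frac_volume))


def scale_dose(d: DifferentialDVH, factor: float, as_rbe: bool = False) -> DifferentialDVH:
    """Multiply all bin edges by ``factor``; volumes are unchanged.

    With ``as_rbe=True`` the result is tagged ``rbe_weighted_gy`` (the
    proton-prescription convention); otherwise ``dose_kind`` is kept.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    kind = "rbe_weighted_gy" if as_rbe else d.dose_kind
    return DifferentialDVH(organ=d.organ, lo=d.lo * factor, hi=d.hi * factor, frac_volume=d.frac_volume, dose_kind=kind)


def merge_dvhs(dvhs: Iterable[DifferentialDVH], weights: Iterable[float], organ: str, width: float = 0.1) -> DifferentialDVH:
    """Volume-weighted combination of per-side DVHs into one paired-organ DVH.

    ``weights`` are relative organ volumes (e.g. left/right lung); they are
    normalised internally.  All inputs are rebinned to a common grid first.
    """
    dvhs = list(dvhs)
    w = np.asarray(list(weights), dtype=float)
    if len(dvhs) != w.size or not len(dvhs):
        raise ValueError("need equally many DVHs and weights (at least one)")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.sum()
    rebinned = [rebin(d, width) for d in dvhs]
    n = max(r.n_bins for r in rebinned)
    fv = np.zeros(n)
    for r, wi in zip(rebinned, w):
        fv[: r.n_bins] += wi * r.frac_volume
    edges = np.arange(n + 1) * width
    fv[int(np.argmax(fv))] += 1.0 - float(fv.sum())
    return DifferentialDVH(organ=organ, lo=edges[:-1], hi=edges[1:], frac_volume=fv, dose_kind=dvhs[0].dose_kind)
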