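"""Cohort-level comparison: per-patient risk tables, modality risk ratios,
paired t-tests, and the dose-uncertainty / neutron-bath sensitivity sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dvh import DifferentialDVH, scale_dose
from .params import ParameterSet, SchneiderParams, SerialityParams
from .schneider import ear
from .seriality import ntcp
from .synth import PatientPlan

__all__ = [
    "RiskResult",
    "CohortRiskTable",
    "RatioSummary",
    "TTestResult",
    "compute_cohort_risks",
    "risk_ratio",
    "paired_t_test",
    "dose_uncertainty_sensitivity",
    "neutron_bath_sensitivity",
]

ENDPOINTS = ("cardiac_mortality", "lung_cancer", "breast_cancer")


@dataclass(frozen=True)
class RiskResult:
    """One (patient, modality, endpoint) risk value.

    ``value`` is a probability for cardiac mortality and cases per 10,000
    person-years for the cancer endpoints; ``horizon_years`` is reporting
    metadata (the models have no time variable).
    """

    patient_id: str
    modality: str
    endpoint: str
    value: float
    horizon_years: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.endpoint == "cardiac_mortality" and not (0.0 <= self.value <= 1.0):
            raise ValueError(f"cardiac risk must be a probability, got {self.value}")
        if self.endpoint != "cardiac_mortality" and self.value < 0:
            raise ValueError(f"EAR must be >= 0, got {self.value}")


class CohortRiskTable:
    """Collection of :class:`RiskResult` rows; at most one per
    (patient, modality, endpoint)."""

    def __init__(self, rows: list[RiskResult]):
        keys = [(r.patient_id, r.modality, r.endpoint) for r in rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (patient, modality, endpoint) rows")
        self.rows = list(rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortRiskTable) and self.rows == other.rows

    def values(self, endpoint: str, modality: str) -> dict[str, float]:
        """``{patient_id: value}`` for one endpoint/modality."""
        return {r.patient_id: r.value for r in self.rows if r.endpoint == endpoint and r.modality == modality}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.rows],
                "modality": [r.modality for r in self.rows],
                "endpoint": [r.endpoint for r in self.rows],
                "value": [r.value for r in self.rows],
                "horizon_years": [r.horizon_years for r in self.rows],
            }
        )


def _required_organs(plan: PatientPlan) -> list[str]:
    organs = ["heart", "lung"]
    if plan.patient.sex == "F":
        organs.append("breast")
    return organs


def compute_cohort_risks(plans: list[PatientPlan], params: ParameterSet) -> CohortRiskTable:
    """Per-patient, per-modality risks for all three endpoints.

    Cardiac mortality from the relative seriality model on the heart DVH;
    lung/breast cancer EAR from the modified linear-quadratic model.
    Male patients produce no breast rows.
    """
    rows = []
    for plan in plans:
        pid = plan.patient.patient_id
        for organ in _required_organs(plan):
            if organ not in plan.dvhs:
                raise ValueError(f"patient {pid!r} ({plan.modality}) is missing a {organ!r} DVH")
        rows.append(
            RiskResult(pid, plan.modality, "cardiac_mortality", ntcp(plan.dvhs["heart"], params.cardiac), params.cardiac.horizon_years)
        )
        rows.append(RiskResult(pid, plan.modality, "lung_cancer", ear(plan.dvhs["lung"], params.lung), params.lung.horizon_years))
        if plan.patient.sex == "F":
            rows.append(
                RiskResult(pid, plan.modality, "breast_cancer", ear(plan.dvhs["breast"], params.breast), params.breast.horizon_years)
            )
    return CohortRiskTable(rows)


@dataclass(frozen=True)
class RatioSummary:
    """Modality-vs-reference risk ratios for one endpoint.

    ``mean_ratio`` is the arithmetic mean of per-patient ratios (patients
    with a zero reference value are excluded and counted); the
    ratio-of-cohort-means is reported alongside for transparency.
    """

    endpoint: str
    modality: str
    reference: str
    per_patient: dict[str, float]
    mean_ratio: float
    ratio_of_means: float
    n_excluded_zero_reference: int


def risk_ratio(table: CohortRiskTable, endpoint: str, modality: str, reference: str) -> RatioSummary:
    a = table.values(endpoint, modality)
    b = table.values(endpoint, reference)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError(f"no overlapping patients for {endpoint}: {modality} vs {reference}")
    per_patient = {}
    excluded = 0
    for pid in shared:
        if b[pid] == 0.0:
            excluded += 1
            continue
        per_patient[pid] = a[pid] / b[pid]
    if not per_patient:
        raise ValueError(f"all reference values are zero for {endpoint}: {modality} vs {reference}")
    mean_a = float(np.mean([a[p] for p in shared]))
    mean_b = float(np.mean([b[p] for p in shared]))
    return RatioSummary(
        endpoint=endpoint,
        modality=modality,
        reference=reference,
        per_patient=per_patient,
        mean_ratio=float(np.mean(list(per_patient.values()))),
        ratio_of_means=mean_a / mean_b if mean_b != 0 else math.nan,
        n_excluded_zero_reference=excluded,
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    degenerate: bool = False  # all differences exactly zero


def paired_t_test(a, b) -> TTestResult:
    """Classical two-sided paired t-test on the differences ``a - b``.

    All-zero differences are reported as the degenerate "no difference"
    case with p = 1 by convention rather than as an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diff = a - b
    if np.all(diff == 0.0):
        return TTestResult(t=0.0, df=n - 1, p_value=1.0, degenerate=True)
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        # constant nonzero difference: infinitely significant
        return TTestResult(t=math.copysign(math.inf, float(diff[0])), df=n - 1, p_value=0.0)
    t = float(np.mean(diff)) / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, df=n - 1, p_value=p)


# ---------------------------------------------------------------------------
# Sensitivity analyses


def _scale_plan(plan: PatientPlan, factor: float) -> PatientPlan:
    return replace(plan, dvhs={o: scale_dose(d, factor) for o, d in plan.dvhs.items()})


def dose_uncertainty_sensitivity(plans: list[PatientPlan], params: ParameterSet, delta: float) -> dict[str, float]:
    """Risk change under a systematic absolute-dose error of +/- ``delta``.

    Recomputes every risk with all doses scaled by (1 - delta) and
    (1 + delta).  Returns the worst case over patients, modalities and the
    two directions: for cardiac mortality the maximum absolute change in
    percentage points, for the cancer endpoints the maximum relative
    change (as a fraction of the unperturbed EAR).
    """
    if not (0.0 <= delta < 1.0):
        raise ValueError(f"delta must be in [0, 1), got {delta}")
    base = compute_cohort_risks(plans, params)
    out = {"cardiac_max_abs_change_pct_points": 0.0, "lung_max_rel_change": 0.0, "breast_max_rel_change": 0.0}
    if delta == 0.0:
        return out
    for factor in (1.0 - delta, 1.0 + delta):
        perturbed = compute_cohort_risks([_scale_plan(p, factor) for p in plans], params)
        for r0, r1 in zip(base.rows, perturbed.rows):
            if r0.endpoint == "cardiac_mortality":
                change = abs(r1.value - r0.value) * 100.0
                out["cardiac_max_abs_change_pct_points"] = max(out["cardiac_max_abs_change_pct_points"], change)
            else:
                key = "lung_max_rel_change" if r0.endpoint == "lung_cancer" else "breast_max_rel_change"
                if r0.value > 0:
                    out[key] = max(out[key], abs(r1.value - r0.value) / r0.value)
    return out


def _add_uniform_dose(d: DifferentialDVH, added_gy: float) -> DifferentialDVH:
    if added_gy == 0.0:
        return d
    return DifferentialDVH(
        organ=d.organ, lo=d.lo + added_gy, hi=d.hi + added_gy, frac_volume=d.frac_volume, dose_kind=d.dose_kind
    )


def neutron_bath_sensitivity(
    plans: list[PatientPlan],
    params: ParameterSet,
    bath_msv_per_gy: float,
    modality: str = "IMPT",
) -> dict[str, float]:
    """Effect of a uniform whole-organ neutron bath on proton-plan risks.

    The bath is ``bath_msv_per_gy`` millisievert of already-RBE-weighted
    equivalent dose per prescribed Gy, added uniformly to every organ DVH
    of the given modality.  Returns the maximum risk increases: absolute
    (probability) for cardiac mortality, absolute EAR for the cancers.
    """
    if bath_msv_per_gy < 0:
        raise ValueError("bath must be >= 0")
    base = compute_cohort_risks(plans, params)
    out = {"cardiac_max_abs_delta": 0.0, "lung_max_ear_delta": 0.0, "breast_max_ear_delta": 0.0}
    if bath_msv_per_gy == 0.0:
        return out
    bathed = []
    for p in plans:
        if p.modality != modality:
            bathed.append(p)
            continue
        added = bath_msv_per_gy * 1e-3 * p.patient.prescription_gy  # Sv -> Gy-equivalent
        bathed.append(replace(p, dvhs={o: _add_uniform_dose(d, added) for o, d in p.dvhs.items()}))
    # shifted DVHs may exceed the nominal planning ceiling by the bath
    rows1 = compute_cohort_risks(bathed, params)
    for r0, r1 in zip(base.rows, rows1.rows):
        delta = r1.value - r0.value
        if r0.endpoint == "cardiac_mortality":
            out["cardiac_max_abs_delta"] = max(out["cardiac_max_abs_delta"], abs(delta))
        elif r0.endpoint == "lung_cancer":
            out["lung_max_ear_delta"] = max(out["lung_max_ear_delta"], abs(delta))
        else:
            out["breast_max_ear_delta"] = max(out["breast_max_ear_delta"], abs(delta))
    return out
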