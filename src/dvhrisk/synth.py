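"""Seeded generator of modality-characteristic synthetic DVH cohorts.

Each organ DVH is a three-component mixture on a 0.1 Gy grid:

* an *in-field* component — truncated normal around the (RBE-weighted)
  prescription dose with a penumbra spread, capped at 108% of the
  prescription (the planning ceiling);
* a *low-dose bath* — truncated exponential;
* the remaining volume at zero dose.

Component weights and shapes come from per-modality profiles; per-patient
variability enters through multiplicative jitter drawn from a stream that
is a pure function of (master seed, patient id, modality, organ), so
adding an organ or patient never perturbs other draws.  The default
prescription table and sex pattern follow a published 20-patient cohort
(9 female / 11 male, prescriptions spanning 20-36 Gy).
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import stats

from .dvh import DifferentialDVH

__all__ = [
    "PatientSpec",
    "OrganProfile",
    "ModalityProfile",
    "PatientPlan",
    "default_profiles",
    "load_profiles",
    "default_dose_table",
    "default_sex_table",
    "generate_organ_dvh",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

MODALITIES = ("3DCRT", "HT", "IMPT")
PLANNING_CEILING = 1.08  # max organ dose as a multiple of prescription
BIN_WIDTH = 0.1

#: the 20 default prescriptions (Gy)
_DOSE_TABLE = (20.0,) + (21.0,) * 9 + (26.5, 30.0, 30.0, 30.0) + (30.6,) * 5 + (36.0,)
#: matching sex pattern (9 F / 11 M)
_SEX_TABLE = ("F", "M", "F", "M", "M", "F", "F", "M", "M", "M", "M", "M", "F", "M", "M", "M", "F", "F", "F", "F")


def default_dose_table(n: int) -> list[float]:
    """First ``n`` default prescriptions, cycling past 20."""
    return [_DOSE_TABLE[i % len(_DOSE_TABLE)] for i in range(n)]


def default_sex_table(n: int) -> list[str]:
    return [_SEX_TABLE[i % len(_SEX_TABLE)] for i in range(n)]


@dataclass(frozen=True)
class PatientSpec:
    """Per-patient metadata driving the generator."""

    patient_id: str
    sex: str
    prescription_gy: float
    organs: tuple[str, ...] = ("heart", "lung")

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.prescription_gy <= 0:
            raise ValueError(f"prescription must be > 0, got {self.prescription_gy}")


@dataclass(frozen=True)
class OrganProfile:
    """Mixture shape for one organ under one modality."""

    in_field_fraction: float
    bath_fraction: float
    bath_scale_gy: float
    penumbra_gy: float
    jitter: float = 0.0

    def __post_init__(self) -> None:
        for name in ("in_field_fraction", "bath_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.in_field_fraction + self.bath_fraction > 1.0 + 1e-12:
            raise ValueError("in_field_fraction + bath_fraction must be <= 1")
        if self.bath_scale_gy <= 0 or self.penumbra_gy <= 0:
            raise ValueError("bath_scale_gy and penumbra_gy must be > 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class ModalityProfile:
    modality: str
    rbe_factor: float
    organs: dict[str, OrganProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rbe_factor <= 0:
            raise ValueError("rbe_factor must be > 0")


@dataclass(frozen=True)
class PatientPlan:
    """One patient's plan under one modality: metadata plus per-organ DVHs."""

    patient: PatientSpec
    modality: str
    dvhs: dict[str, DifferentialDVH]

    def validate_ceiling(self) -> None:
        """Check every organ DVH against the 108%-of-prescription planning
        ceiling (on the RBE-weighted scale for RBE-weighted plans).

        Enforced for generated/read plans; perturbed plans produced by the
        sensitivity analyses may deliberately exceed it.
        """
        ceiling = PLANNING_CEILING * self.patient.prescription_gy
        for organ, d in self.dvhs.items():
            cap = ceiling * (1.1 if d.dose_kind == "rbe_weighted_gy" else 1.0)
            if d.max_dose > cap + 1e-9:
                raise ValueError(
                    f"{self.patient.patient_id}/{self.modality}/{organ}: max dose {d.max_dose:.2f} Gy exceeds planning ceiling {cap:.2f} Gy"
                )


def _parse_profiles(doc: dict) -> dict[str, ModalityProfile]:
    profiles = {}
    for modality, entry in doc.items():
        organs = {
            organ: OrganProfile(
                in_field_fraction=float(v["in_field_fraction"]),
                bath_fraction=float(v["bath_fraction"]),
                bath_scale_gy=float(v["bath_scale_gy"]),
                penumbra_gy=float(v["penumbra_gy"]),
                jitter=float(v.get("jitter", 0.0)),
            )
            for organ, v in entry.items()
            if isinstance(v, dict)
        }
        profiles[modality] = ModalityProfile(modality=modality, rbe_factor=float(entry["rbe_factor"]), organs=organs)
    return profiles


def load_profiles(path: str | Path) -> dict[str, ModalityProfile]:
    with open(path, "rb") as fh:
        return _parse_profiles(tomllib.load(fh))


def default_profiles() -> dict[str, ModalityProfile]:
    data = resources.files("dvhrisk").joinpath("data/default_profiles.toml").read_bytes()
    return _parse_profiles(tomllib.loads(data.decode()))


def _stream(seed: int, *labels: str) -> np.random.Generator:
    """Independent RNG stream keyed by the master seed and string labels."""
    digest = hashlib.sha256(("|".join([str(seed), *labels])).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def generate_organ_dvh(
    spec: PatientSpec,
    profile: ModalityProfile,
    organ: str,
    seed: int,
) -> DifferentialDVH:
    """Generate one organ's differential DVH, deterministic in
    (seed, patient_id, modality, organ)."""
    if organ not in spec.organs:
        raise ValueError(f"organ {organ!r} not in patient {spec.patient_id!r} organs {spec.organs}")
    if organ not in profile.organs:
        raise ValueError(f"profile for {profile.modality!r} has no organ {organ!r}")
    op = profile.organs[organ]
    rng = _stream(seed, spec.patient_id, profile.modality, organ)

    in_field = op.in_field_fraction
    bath = op.bath_fraction
    scale = op.bath_scale_gy
    pen = op.penumbra_gy
    if op.jitter > 0:
        in_field *= float(np.clip(rng.normal(1.0, op.jitter), 0.4, 1.8))
        bath *= float(np.clip(rng.normal(1.0, op.jitter), 0.4, 1.8))
        scale *= float(np.exp(rng.normal(0.0, op.jitter)))
        pen *= float(np.clip(rng.normal(1.0, op.jitter), 0.5, 1.5))
    in_field = min(in_field, 1.0)
    if in_field + bath > 0.98:
        bath = max(0.98 - in_field, 0.0)

    target = profile.rbe_factor * spec.prescription_gy
    ceiling = PLANNING_CEILING * target
    n = int(np.floor(ceiling / BIN_WIDTH + 1e-9))
    edges = np.arange(n + 1) * BIN_WIDTH
    if edges[-1] < ceiling - 1e-9:  # partial top bin, clamped to the ceiling
        edges = np.append(edges, ceiling)
    else:
        edges[-1] = ceiling

    fv = np.zeros(edges.size - 1)
    if in_field > 0:
        cdf = stats.norm.cdf(edges, loc=target, scale=pen)
        mass = np.diff(cdf)
        norm = cdf[-1] - cdf[0]
        fv += in_field * mass / norm
    if bath > 0:
        cdf = stats.expon.cdf(edges, scale=scale)
        mass = np.diff(cdf)
        norm = cdf[-1]
        fv += bath * mass / norm
    fv[0] += 1.0 - in_field - bath
    fv[int(np.argmax(fv))] += 1.0 - float(fv.sum())  # exact volume closure

    kind = "rbe_weighted_gy" if profile.rbe_factor != 1.0 else "physical_gy"
    return DifferentialDVH(organ=organ, lo=edges[:-1], hi=edges[1:], frac_volume=fv, dose_kind=kind)


def generate_cohort(
    n_patients: int,
    seed: int,
    dose_table: list[float] | None = None,
    sex_table: list[str] | None = None,
    profiles: dict[str, ModalityProfile] | None = None,
) -> list[PatientPlan]:
    """Generate ``n_patients`` patients x three modality plans each.

    Female patients get heart, lung and breast DVHs; male patients heart
    and lung only.  Deterministic for fixed arguments.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if dose_table is None:
        dose_table = default_dose_table(n_patients)
    if len(dose_table) != n_patients:
        raise ValueError(f"dose_table has {len(dose_table)} entries for {n_patients} patients")
    if sex_table is None:
        sex_table = default_sex_table(n_patients)
    if len(sex_table) != n_patients:
        raise ValueError(f"sex_table has {len(sex_table)} entries for {n_patients} patients")
    if profiles is None:
        profiles = default_profiles()

    plans = []
    for i, (dose, sex) in enumerate(zip(dose_table, sex_table), start=1):
        organs = ("heart", "lung", "breast") if sex == "F" else ("heart", "lung")
        spec = PatientSpec(patient_id=f"P{i:02d}", sex=sex, prescription_gy=float(dose), organs=organs)
        for modality in MODALITIES:
            prof = profiles[modality]
            dvhs = {organ: generate_organ_dvh(spec, prof, organ, seed) for organ in organs}
            plan = PatientPlan(patient=spec, modality=modality, dvhs=dvhs)
            plan.validate_ceiling()
            plans.append(plan)
    return plans


def write_cohort(plans: list[PatientPlan], out_dir: str | Path) -> None:
    """Write a cohort as ``dvhs.csv`` (differential dialect) plus ``patients.csv``."""
    import pandas as pd

    from .dvh import write_dvh_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dvhs = {(p.patient.patient_id, p.modality, organ): d for p in plans for organ, d in p.dvhs.items()}
    write_dvh_csv(out / "dvhs.csv", dvhs)
    meta = (
        pd.DataFrame(
            {
                "patient_id": [p.patient.patient_id for p in plans],
                "sex": [p.patient.sex for p in plans],
                "prescription_gy": [p.patient.prescription_gy for p in plans],
            }
        )
        .drop_duplicates()
        .reset_index(drop=True)
    )
    meta.to_csv(out / "patients.csv", index=False)


def read_cohort(cohort_dir: str | Path) -> list[PatientPlan]:
    """Read back a cohort written by :func:`write_cohort`."""
    import pandas as pd

    from .dvh import read_dvh_csv

    cohort_dir = Path(cohort_dir)
    meta = pd.read_csv(cohort_dir / "patients.csv", dtype={"patient_id": str})
    dvhs = read_dvh_csv(cohort_dir / "dvhs.csv", form="differential")
    by_plan: dict[tuple[str, str], dict[str, DifferentialDVH]] = {}
    for (pid, mod, organ), d in dvhs.items():
        # the CSV dialect does not carry dose_kind; proton plans are
        # prescribed on the RBE-weighted scale by convention
        if mod == "IMPT":
            d = replace(d, dose_kind="rbe_weighted_gy")
        by_plan.setdefault((pid, mod), {})[organ] = d
    specs = {}
    for _, row in meta.iterrows():
        organs_seen = tuple(
            sorted({organ for (pid, _mod), dd in by_plan.items() if pid == row.patient_id for organ in dd})
        )
        specs[row.patient_id] = PatientSpec(
            patient_id=row.patient_id,
            sex=row.sex,
            prescription_gy=float(row.prescription_gy),
            organs=organs_seen,
        )
    plans = []
    for (pid, mod), organ_dvhs in by_plan.items():
        if pid not in specs:
            raise ValueError(f"DVH file references patient {pid!r} missing from patients.csv")
        plan = PatientPlan(patient=specs[pid], modality=mod, dvhs=organ_dvhs)
        plan.validate_ceiling()
        plans.append(plan)
    return plans
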