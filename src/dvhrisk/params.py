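"""Risk-model parameter sets and config-file loading.

Defaults correspond to published whole-organ parameter sets: cardiac
mortality (relative seriality: D50 = 70.3 Gy, gamma = 0.96, s = 1) and
cancer induction (modified linear-quadratic: breast Rf = 0.62,
alpha = 0.067 /Gy, mu = 4.8; lung Rf = 0.84, alpha = 0.061 /Gy,
mu = 2.7 — mu in cases per 10,000 persons per year per Gy).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "SerialityParams",
    "SchneiderParams",
    "ParameterSet",
    "default_params",
    "load_params",
]


@dataclass(frozen=True)
class SerialityParams:
    """Relative-seriality dose-response parameters.

    d50: uniform whole-organ dose (Gy) giving 50% complication probability.
    gamma: maximum normalized slope of the sigmoid dose-response.
    s: relative seriality (s -> large: serial organ; s -> 0: parallel).
    """

    d50: float = 70.3
    gamma: float = 0.96
    s: float = 1.0
    endpoint: str = "cardiac_mortality"
    horizon_years: int = 15

    def __post_init__(self) -> None:
        if self.d50 <= 0:
            raise ValueError(f"d50 must be > 0, got {self.d50}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0 (the model is undefined at s = 0), got {self.s}")


@dataclass(frozen=True)
class SchneiderParams:
    """Modified linear-quadratic cancer-induction parameters.

    rf: repopulation/repair fraction (0 < rf < 1).
    alpha: repairable-damage coefficient (per Gy).
    mu: linear-no-threshold slope, cases per 10,000 person-years per Gy.
    alpha_prime: effective per-Gy coefficient in the induction formula.
        Defaults to alpha; callers with a beta and dose per fraction can
        build alpha + beta * d_f via :meth:`with_fractionation`.
    """

    rf: float
    alpha: float
    mu: float
    alpha_prime: float | None = None
    endpoint: str = "cancer"
    horizon_years: int = 30

    def __post_init__(self) -> None:
        if not (0.0 < self.rf < 1.0):
            raise ValueError(f"rf must be in (0, 1) — rf = 1 divides by zero — got {self.rf}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.alpha_prime is None:
            object.__setattr__(self, "alpha_prime", self.alpha)
        if self.alpha_prime <= 0:
            raise ValueError(f"alpha_prime must be > 0, got {self.alpha_prime}")

    def with_fractionation(self, beta: float, dose_per_fraction_gy: float) -> "SchneiderParams":
        """Return a copy with ``alpha_prime = alpha + beta * d_f`` (off by default)."""
        if beta < 0 or dose_per_fraction_gy < 0:
            raise ValueError("beta and dose_per_fraction_gy must be >= 0")
        return SchneiderParams(
            rf=self.rf,
            alpha=self.alpha,
            mu=self.mu,
            alpha_prime=self.alpha + beta * dose_per_fraction_gy,
            endpoint=self.endpoint,
            horizon_years=self.horizon_years,
        )


@dataclass(frozen=True)
class ParameterSet:
    """The three default organ/endpoint parameter sets used by the pipeline."""

    cardiac: SerialityParams
    lung: SchneiderParams
    breast: SchneiderParams


def _build(doc: dict) -> ParameterSet:
    c = doc["cardiac_mortality"]
    lg = doc["lung_cancer"]
    br = doc["breast_cancer"]

    def schneider(entry: dict, endpoint: str) -> SchneiderParams:
        p = SchneiderParams(
            rf=float(entry["rf"]),
            alpha=float(entry["alpha"]),
            mu=float(entry["mu"]),
            endpoint=endpoint,
            horizon_years=int(entry.get("horizon_years", 30)),
        )
        if "beta" in entry and "dose_per_fraction_gy" in entry:
            p = p.with_fractionation(float(entry["beta"]), float(entry["dose_per_fraction_gy"]))
        return p

    cardiac = SerialityParams(
        d50=float(c["d50"]),
        gamma=float(c["gamma"]),
        s=float(c["s"]),
        horizon_years=int(c.get("horizon_years", 15)),
    )
    return ParameterSet(
        cardiac=cardiac,
        lung=schneider(lg, "lung_cancer"),
        breast=schneider(br, "breast_cancer"),
    )


def load_params(path: str | Path) -> ParameterSet:
    """Load a parameter set from a TOML file.

    Expected tables: ``[cardiac_mortality]`` with ``d50, gamma, s`` and
    ``[lung_cancer]`` / ``[breast_cancer]`` with ``rf, alpha, mu`` and
    optional ``beta`` + ``dose_per_fraction_gy``.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    try:
        return _build(doc)
    except KeyError as exc:
        raise ValueError(f"parameter file {path} is missing table/key {exc}") from exc


def default_params() -> ParameterSet:
    """The shipped default parameter sets."""
    data = resources.files("dvhrisk").joinpath("data/default_params.toml").read_bytes()
    return _build(tomllib.loads(data.decode()))
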