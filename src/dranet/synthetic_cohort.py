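"""Synthetic per-partner analytic datasets with known true parameters.

Stands in for the upstream cohort-assembly step of a distributed data
network: each data partner ends up with a de-identified patient-level table
(one row per patient, identical schema everywhere) in its own ``dplocal``
folder.  Generating those tables from known coefficients makes every
downstream stage — local statistics, aggregation, Newton–Raphson,
diagnostics — testable against ground truth without any real data.

Generators by family (X holds the covariates, beta the true coefficients
including an intercept where the family has one, s a per-site shift drawn
once per partner from N(0, site_effect_sd^2)):

* linear:   y = X beta + s + N(0, 1)
* logistic: y ~ Bernoulli(expit(X beta + s))
* cox:      T ~ Exponential(rate = exp(x beta + s)) on a unit baseline
            hazard; C ~ Exponential(censoring_rate); time = min(T, C),
            event = 1{T <= C}

A nonzero ``site_effect_sd`` creates real between-site heterogeneity — the
situation that motivates fitting the Cox model stratified by site.
Each partner's rows come from an independent, individually reproducible
random substream spawned from (seed, partner_id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regression_core import DesignSpec, Family

__all__ = [
    "CovariateSpec",
    "CohortSpec",
    "generate_partner_dataset",
    "generate_all_partners",
    "write_dataset",
    "read_dataset",
    "DatasetParseError",
]


class DatasetParseError(ValueError):
    """An analytic dataset file is malformed (missing values, bad schema)."""


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate column: name plus sampling distribution."""

    name: str
    distribution: str = "standard_normal"  # standard_normal | bernoulli | uniform
    q: float = 0.5        # bernoulli success probability
    a: float = 0.0        # uniform lower bound
    b: float = 1.0        # uniform upper bound

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "standard_normal":
            return rng.standard_normal(n)
        if self.distribution == "bernoulli":
            return rng.binomial(1, self.q, size=n).astype(float)
        if self.distribution == "uniform":
            return rng.uniform(self.a, self.b, size=n)
        raise ValueError(f"unknown covariate distribution {self.distribution!r}")


def _default_covariates() -> tuple[CovariateSpec, ...]:
    # one exposure plus two confounder-style covariates: a canonical
    # pharmacoepidemiology-flavored design
    return (
        CovariateSpec("exposure", "bernoulli", q=0.5),
        CovariateSpec("age_std", "standard_normal"),
        CovariateSpec("comorbidity", "bernoulli", q=0.3),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated distributed network."""

    family: Family = Family.LOGISTIC
    n_partners: int = 3
    n_per_partner: tuple[int, ...] = (2000, 2000, 2000)
    covariates: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    true_beta: tuple[float, ...] = (-1.0, 0.5, 0.3, -0.4)
    censoring_rate: float = 0.2
    site_effect_sd: float = 0.0
    seed: int = 20230901

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "n_per_partner", tuple(self.n_per_partner))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "true_beta", tuple(self.true_beta))
        if len(self.n_per_partner) != self.n_partners:
            raise ValueError("n_per_partner length must equal n_partners")
        if any(n <= 0 for n in self.n_per_partner):
            raise ValueError("every partner must have at least one patient")
        expected = len(self.covariates) + (0 if self.family is Family.COX else 1)
        if len(self.true_beta) != expected:
            raise ValueError(
                f"true_beta has length {len(self.true_beta)}, expected {expected} "
                f"for family {self.family.value} with {len(self.covariates)} covariates"
            )
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.site_effect_sd < 0:
            raise ValueError("site_effect_sd must be >= 0")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def design_spec(self) -> DesignSpec:
        if self.family is Family.COX:
            return DesignSpec(
                family=self.family,
                covariate_columns=self.covariate_names,
                time_column="time",
                event_column="event",
            )
        return DesignSpec(
            family=self.family,
            covariate_columns=self.covariate_names,
            outcome_column="y",
        )


def _partner_rng(spec: CohortSpec, partner_id: int) -> np.random.Generator:
    # spawn-key substream: independent across partners, reproducible per partner
    return np.random.default_rng(np.random.SeedSequence([spec.seed, partner_id]))


def generate_partner_dataset(spec: CohortSpec, partner_id: int) -> pd.DataFrame:
    """Generate one partner's patient-level analytic table."""
    if not 1 <= partner_id <= spec.n_partners:
        raise ValueError(f"partner_id {partner_id} outside 1..{spec.n_partners}")
    rng = _partner_rng(spec, partner_id)
    n = spec.n_per_partner[partner_id - 1]
    covs = {c.name: c.sample(rng, n) for c in spec.covariates}
    X = np.column_stack(list(covs.values()))
    site_shift = rng.normal(0.0, spec.site_effect_sd) if spec.site_effect_sd else 0.0
    beta = np.asarray(spec.true_beta, dtype=float)

    df = pd.DataFrame(covs)
    df.insert(0, "patient_id", [f"dp{partner_id}-{i:06d}" for i in range(n)])
    if spec.family is Family.LINEAR:
        eta = beta[0] + X @ beta[1:] + site_shift
        df["y"] = eta + rng.standard_normal(n)
    elif spec.family is Family.LOGISTIC:
        eta = beta[0] + X @ beta[1:] + site_shift
        pi = 0.5 * (1.0 + np.tanh(0.5 * eta))
        df["y"] = rng.binomial(1, pi).astype(int)
    else:
        rate = np.exp(X @ beta + site_shift)
        event_time = rng.exponential(1.0 / rate)
        if spec.censoring_rate > 0:
            censor_time = rng.exponential(1.0 / spec.censoring_rate, size=n)
        else:
            censor_time = np.full(n, np.inf)
        df["time"] = np.minimum(event_time, censor_time)
        df["event"] = (event_time <= censor_time).astype(int)
    return df


def generate_all_partners(spec: CohortSpec) -> list[pd.DataFrame]:
    return [generate_partner_dataset(spec, k) for k in range(1, spec.n_partners + 1)]


def write_dataset(dataset: pd.DataFrame, path: Path) -> None:
    """Write a partner dataset as comma-delimited UTF-8 text with a header row.

    Floats are printed with 17 significant digits so the round trip is
    lossless.
    """
    dataset.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_dataset(path: Path) -> pd.DataFrame:
    """Read an analytic dataset, mapping columns by name; missing values error."""
    try:
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except Exception as exc:
        raise DatasetParseError(f"cannot parse dataset file {path}: {exc}") from exc
    if df.isna().any().any():
        bad = df.isna().any(axis=1)
        first = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
        raise DatasetParseError(
            f"{path}: {int(bad.sum())} row(s) with missing values "
            f"(first at line {first})"
        )
    if "patient_id" in df.columns and df["patient_id"].duplicated().any():
        raise DatasetParseError(f"{path}: duplicate patient_id values")
    return df
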