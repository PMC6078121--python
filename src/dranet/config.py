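"""Run configuration: one flat document holding every tunable default.

All workflow defaults live here so the choices are auditable in one place:
convergence tolerance 1e-6 on the maximum absolute coefficient change,
25 Newton–Raphson iterations at most, fully automated transfers, 0.5 s
poll interval with a 300 s per-iteration timeout, and 20 equal-width
diagnostic bins.  Everything is overridable from a YAML config file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .regression_core import Family
from .synthetic_cohort import CohortSpec, CovariateSpec, _default_covariates
from .transport import AutomationLevel

__all__ = ["RunConfig", "load_config", "save_config"]

_DEFAULT_BETA = {
    Family.LINEAR: (-1.0, 0.5, 0.3, -0.4),
    Family.LOGISTIC: (-1.0, 0.5, 0.3, -0.4),
    Family.COX: (0.5, 0.3, -0.4),  # no intercept in a Cox model
}


@dataclass
class RunConfig:
    family: Family = Family.LOGISTIC
    n_partners: int = 3
    n_per_partner: tuple[int, ...] = ()
    covariates: tuple[CovariateSpec, ...] = ()
    true_beta: tuple[float, ...] = ()
    site_effect_sd: float = 0.0
    censoring_rate: float = 0.2
    seed: int = 20230901
    tolerance: float = 1e-6
    max_iterations: int = 25
    automation: AutomationLevel = AutomationLevel.FULLY_AUTOMATED
    root: Path = Path("dra_run")
    n_bins: int = 20
    poll_interval: float = 0.5
    timeout: float = 300.0

    def __post_init__(self) -> None:
        self.family = Family(self.family)
        self.automation = AutomationLevel(self.automation)
        self.root = Path(self.root)
        if not self.n_per_partner:
            self.n_per_partner = (2000,) * self.n_partners
        self.n_per_partner = tuple(int(n) for n in self.n_per_partner)
        if not self.covariates:
            self.covariates = _default_covariates()
        self.covariates = tuple(
            c if isinstance(c, CovariateSpec) else CovariateSpec(**c)
            for c in self.covariates
        )
        if not self.true_beta:
            self.true_beta = _DEFAULT_BETA[self.family]
        self.true_beta = tuple(float(b) for b in self.true_beta)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_partners < 1:
            raise ValueError("n_partners must be >= 1")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            family=self.family,
            n_partners=self.n_partners,
            n_per_partner=self.n_per_partner,
            covariates=self.covariates,
            true_beta=self.true_beta,
            censoring_rate=self.censoring_rate,
            site_effect_sd=self.site_effect_sd,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family"] = self.family.value
        d["automation"] = self.automation.value
        d["root"] = str(self.root)
        d["n_per_partner"] = list(self.n_per_partner)
        d["true_beta"] = list(self.true_beta)
        d["covariates"] = [asdict(c) for c in self.covariates]
        return d


def load_config(path: Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
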