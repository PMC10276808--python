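"""Configuration objects for the simulated finite population and study runs.

Default parameter values are the data-generating values of the motivating
complex-survey simulation: a target population of 752 census block groups
(BGs) in 8 strata, households (HHs) of two adults, logistic models for a
binary exposure (insomnia) and for binary outcomes (prevalent mild cognitive
impairment at visit 2; hypertension at visits 1 and 2), with HH- and
BG-level normal random effects inducing within-cluster outcome correlation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = ["PopulationConfig", "RunConfig", "DEFAULT_BG_PER_STRATUM"]

#: Fixed uneven split of the 752 BGs across the 8 strata (drawn once from a
#: uniform multinomial at a constant seed and frozen; the split is a design
#: input, not re-randomized per run).
DEFAULT_BG_PER_STRATUM: tuple[int, ...] = (95, 90, 90, 90, 88, 94, 98, 107)


def _log(x: float) -> float:
    return math.log(x)


@dataclass
class PopulationConfig:
    """Data-generating parameters for the finite target population.

    Coefficients are stored on the log-odds scale; the defaults are the
    logs of the reference odds/rate ratios of the motivating study design.  ``confounder_mode`` selects
    which variable fills the confounder slot of the exposure and outcome
    models: ``"age"`` (primary setting) or ``"education"`` (sensitivity
    setting, where education is a noisy copy of age with target correlation
    ``education_rho`` and age remains a sampling-design variable only).
    """

    n_bg: int = 752
    n_strata: int = 8
    bg_per_stratum: tuple[int, ...] = DEFAULT_BG_PER_STRATUM
    hh_per_bg_mean: float = 450.0
    persons_per_hh: int = 2

    # covariate distributions: (mean, sd, lower, upper)
    hh_mean_age_dist: tuple[float, float, float, float] = (40.0, 15.0, 23.0, 69.0)
    age_halfwidth: float = 10.0
    bmi_dist: tuple[float, float, float, float] = (29.0, 9.0, 15.0, 63.0)
    years_dist: tuple[float, float, float, float] = (6.0, 0.5, 3.0, 9.0)

    # cluster random-effect standard deviations
    hh_re_sd: float = 1.0
    bg_re_sd: float = 0.5

    # exposure model: logit Pr(Z=1) = a0 + a1*bmi + a2*confounder
    exposure_coefs: tuple[float, ...] = (_log(0.109), _log(1.025), _log(1.019))
    # prevalent MCI at visit 2: b0 + b1*a + b2*bmi + b3*confounder + h + b
    mci_coefs: tuple[float, ...] = (_log(0.003), _log(1.560), _log(1.018), _log(1.056))
    # hypertension visit 1: g0 + g1*a + g2*bmi + g3*confounder + h + b
    htn1_coefs: tuple[float, ...] = (_log(0.002), _log(1.065), _log(1.088), _log(1.082))
    # hypertension visit 2: f0 + f1*a + f2*bmi + f3*confounder + f4*years + h + b
    htn2_coefs: tuple[float, ...] = (
        _log(0.001), _log(1.247), _log(1.082), _log(1.092), _log(1.098),
    )

    confounder_mode: str = "age"
    education_rho: float | None = None

    seed: int = 0

    def __post_init__(self) -> None:
        self.bg_per_stratum = tuple(int(v) for v in self.bg_per_stratum)
        if self.bg_per_stratum == DEFAULT_BG_PER_STRATUM and (
            self.n_bg != 752 or self.n_strata != 8
        ):
            # smoke-test override: n_bg/n_strata changed without an explicit
            # split -> spread BGs as evenly as possible across strata
            if self.n_bg < self.n_strata:
                raise ValueError("n_bg must be at least n_strata")
            base, rem = divmod(self.n_bg, self.n_strata)
            self.bg_per_stratum = tuple(
                base + (1 if i < rem else 0) for i in range(self.n_strata)
            )
        self.hh_mean_age_dist = tuple(float(v) for v in self.hh_mean_age_dist)
        self.bmi_dist = tuple(float(v) for v in self.bmi_dist)
        self.years_dist = tuple(float(v) for v in self.years_dist)
        self.exposure_coefs = tuple(float(v) for v in self.exposure_coefs)
        self.mci_coefs = tuple(float(v) for v in self.mci_coefs)
        self.htn1_coefs = tuple(float(v) for v in self.htn1_coefs)
        self.htn2_coefs = tuple(float(v) for v in self.htn2_coefs)
        self.validate()

    def validate(self) -> None:
        if self.n_bg <= 0 or self.n_strata <= 0:
            raise ValueError("n_bg and n_strata must be positive")
        if len(self.bg_per_stratum) != self.n_strata:
            raise ValueError(
                f"bg_per_stratum has {len(self.bg_per_stratum)} entries, "
                f"expected n_strata={self.n_strata}"
            )
        if sum(self.bg_per_stratum) != self.n_bg:
            raise ValueError(
                f"bg_per_stratum sums to {sum(self.bg_per_stratum)}, expected {self.n_bg}"
            )
        if min(self.bg_per_stratum) <= 0:
            raise ValueError("every stratum must contain at least one BG")
        if self.hh_per_bg_mean <= 0:
            raise ValueError("hh_per_bg_mean must be positive")
        if self.persons_per_hh != 2:
            raise ValueError("households hold exactly 2 persons in this design")
        for name in ("hh_mean_age_dist", "bmi_dist", "years_dist"):
            mean, sd, lo, hi = getattr(self, name)
            if not all(np.isfinite([mean, sd, lo, hi])):
                raise ValueError(f"{name} has non-finite parameters")
            if not (lo < hi and sd > 0):
                raise ValueError(f"{name} must have lo < hi and sd > 0")
        if self.hh_re_sd < 0 or self.bg_re_sd < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if len(self.exposure_coefs) != 3:
            raise ValueError("exposure_coefs must have 3 entries")
        if len(self.mci_coefs) != 4 or len(self.htn1_coefs) != 4:
            raise ValueError("mci_coefs and htn1_coefs must have 4 entries")
        if len(self.htn2_coefs) != 5:
            raise ValueError("htn2_coefs must have 5 entries")
        if self.confounder_mode not in ("age", "education"):
            raise ValueError("confounder_mode must be 'age' or 'education'")
        if self.confounder_mode == "education":
            if self.education_rho is None or not (0.0 < self.education_rho < 1.0):
                raise ValueError("education mode requires education_rho in (0, 1)")

    @property
    def stratum_of_bg(self) -> np.ndarray:
        """Stratum label (1-based) for each BG id (0..n_bg-1)."""
        return np.repeat(np.arange(1, self.n_strata + 1), self.bg_per_stratum)

    def replace(self, **kwargs) -> "PopulationConfig":
        d = asdict(self)
        d.update(kwargs)
        return PopulationConfig(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PopulationConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    """Top-level configuration for a replicate study run.

    Round-trips losslessly through JSON via :func:`svycausal.io.load_config`.
    """

    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_reps: int = 300
    seed: int = 0
    scenarios: tuple[int, ...] = (1, 2)
    outcomes: tuple[str, ...] = ("mci", "htn")
    specifications: tuple[str, ...] = ("correct", "under")
    out_dir: str = "results"
    float_format: str = "%.3f"

    def __post_init__(self) -> None:
        if isinstance(self.population, dict):
            self.population = PopulationConfig.from_dict(self.population)
        self.scenarios = tuple(int(s) for s in self.scenarios)
        self.outcomes = tuple(self.outcomes)
        self.specifications = tuple(self.specifications)
        if self.n_reps < 2:
            raise ValueError("n_reps must be at least 2")
        if any(s not in (1, 2) for s in self.scenarios):
            raise ValueError("scenarios must be drawn from {1, 2}")
        if any(o not in ("mci", "htn") for o in self.outcomes):
            raise ValueError("outcomes must be drawn from {'mci', 'htn'}")
        if any(s not in ("correct", "under") for s in self.specifications):
            raise ValueError("specifications must be drawn from {'correct', 'under'}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(**d)


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible RNG substream derived from a base seed.

    Each variable family (household counts, ages, BMI, ...) draws from its
    own substream so components are independently reproducible.
    """
    import zlib

    parts = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            parts.append(zlib.crc32(k.encode()))
        else:
            parts.append(int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(parts))
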