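"""Stratified two-stage survey sampling and survey-weight construction.

Stage 1 samples whole block groups (BGs) with stratum-specific inclusion
probabilities (0.25 in strata 1-4, 0.60 in strata 5-8 by default).  Stage 2
samples whole households (HHs) within the retained BGs; in scenario 1 the HH
inclusion probability increases with the oldest member's age,
``expit(-8 + 0.1 * max_HH_age)``, while in scenario 2 a single age-free
constant (the population mean of the scenario-1 probabilities, so expected
sample sizes match) is used.  Both members of a sampled HH enter the sample.

Weights: individual inclusion probability ``p_ijk = p_i * p_ij``, base
weight ``w_ijk = 1 / p_ijk``, and the analysis weight (OSW) is the base
weight normalized by its sample mean, so OSW averages to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .popgen import PopulationFrame
from .config import substream

__all__ = [
    "DesignInfo",
    "SurveySample",
    "hh_inclusion_probability",
    "bg_inclusion_probabilities",
    "draw_survey_sample",
    "EmptySampleError",
]

#: default stage-1 inclusion probability per stratum (1-based labels)
DEFAULT_BG_PROBS = {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25, 5: 0.60, 6: 0.60, 7: 0.60, 8: 0.60}


class EmptySampleError(RuntimeError):
    """Raised when a drawn sample contains no individuals."""


@dataclass
class DesignInfo:
    """Survey-design labels for variance estimation: stratum, PSU, weight."""

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.weights)
        if len(self.strata) != n or len(self.psu) != n:
            raise ValueError("strata, psu, weights must have equal length")
        if np.any(np.asarray(self.weights) < 0):
            raise ValueError("design weights must be nonnegative")

    def subset(self, idx: np.ndarray) -> "DesignInfo":
        return DesignInfo(self.strata[idx], self.psu[idx], self.weights[idx])


def hh_inclusion_probability(max_hh_age) -> np.ndarray | float:
    """Scenario-1 household inclusion probability, expit(-8 + 0.1 * max age)."""
    arr = np.asarray(max_hh_age, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("max_hh_age must be finite")
    out = expit(-8.0 + 0.1 * arr)
    return float(out) if np.isscalar(max_hh_age) else out


def bg_inclusion_probabilities(strata: np.ndarray, bg_probs: dict | None = None) -> np.ndarray:
    probs = DEFAULT_BG_PROBS if bg_probs is None else bg_probs
    return np.array([probs[int(s)] for s in np.asarray(strata)], dtype=float)


@dataclass
class SurveySample:
    """One drawn survey sample with design labels and normalized weights.

    ``frame`` has one row per sampled individual and carries the inclusion
    probabilities ``p_i`` (BG), ``p_ij`` (HH), ``p_ijk`` (individual), the
    base weight ``w_ijk`` and the normalized final weight ``osw``.
    """

    frame: pd.DataFrame
    scenario: int

    @property
    def n(self) -> int:
        return len(self.frame)

    def design(self, weights: np.ndarray | None = None) -> DesignInfo:
        w = self.frame["osw"].to_numpy() if weights is None else np.asarray(weights, float)
        return DesignInfo(
            strata=self.frame["stratum"].to_numpy(),
            psu=self.frame["bg_id"].to_numpy(),
            weights=w,
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def scenario2_hh_probability(population: PopulationFrame) -> float:
    """Age-free stage-2 probability: mean scenario-1 probability over all HHs."""
    return float(hh_inclusion_probability(population.hh_max_age).mean())


def draw_survey_sample(
    population: PopulationFrame,
    scenario: int,
    rng: np.random.Generator,
    bg_probs: dict | None = None,
    hh_probs: np.ndarray | float | None = None,
    columns: list[str] | None = None,
) -> SurveySample:
    """Draw one stratified two-stage sample (Poisson sampling at each stage).

    Each BG is retained independently with its stratum probability, then
    each HH inside a retained BG is retained independently with its stage-2
    probability; all members of retained HHs enter the sample.
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    cfg = population.config
    strata_of_bg = cfg.stratum_of_bg
    p_bg = bg_inclusion_probabilities(strata_of_bg, bg_probs)
    keep_bg = rng.random(cfg.n_bg) < p_bg

    if hh_probs is not None:
        p_hh = np.broadcast_to(np.asarray(hh_probs, dtype=float), (population.n_hh,)).copy()
    elif scenario == 1:
        p_hh = hh_inclusion_probability(population.hh_max_age)
    else:
        p_hh = np.full(population.n_hh, scenario2_hh_probability(population))
    keep_hh = keep_bg[population.hh_bg] & (rng.random(population.n_hh) < p_hh)

    row_mask = keep_hh[population.row_hh]
    idx = np.flatnonzero(row_mask)
    if idx.size == 0:
        raise EmptySampleError("drawn sample is empty")

    row_hh = population.row_hh[idx]
    p_i = p_bg[population.hh_bg[row_hh]]
    p_ij = p_hh[row_hh]
    p_ijk = p_i * p_ij
    w = 1.0 / p_ijk
    osw = w / w.mean()

    base_cols = [
        "bg_id", "stratum", "hh_id", "person_id", "age", "bmi", "years_between",
        "insomnia", "y_mci", "y_htn1", "y_htn2",
    ]
    if population.config.confounder_mode == "education":
        base_cols.insert(7, "education")
    if columns is not None:
        base_cols = columns
    data = {c: population.col(c)[idx] for c in base_cols}
    data.update(p_i=p_i, p_ij=p_ij, p_ijk=p_ijk, w_ijk=w, osw=osw)
    return SurveySample(frame=pd.DataFrame(data), scenario=scenario)


def replicate_rng(seed: int, replicate: int, scenario: int = 1) -> np.random.Generator:
    """Independent RNG substream for one replicate draw (worker-count safe)."""
    return substream(seed, "replicate", scenario, replicate)
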