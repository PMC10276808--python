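"""True causal estimands computed from the doubled potential-outcome frame.

The finite population carries both potential outcomes for every individual,
so the true marginal and conditional effects are obtained by stacking the
population twice — once per exposure level ``a`` — and fitting ordinary
(unweighted) regressions of the potential outcome on ``a``:

* prevalent MCI: logistic regressions; the exponentiated ``a`` coefficient
  is an odds ratio (OR);
* incident hypertension: Poisson log-link regressions of the visit-2
  outcome on ``a`` with offset ``log(years between visits)``, restricted to
  stacked rows free of hypertension at visit 1 under the same ``a``; the
  exponentiated coefficient is an incidence-rate ratio (IRR).

ATE/CATE use the full doubled frame; ATT/CATT restrict to individuals with
observed exposure ``Z = 1``.  Marginal fits adjust for nothing; conditional
fits adjust for BMI and the confounder.  Because the OR is non-collapsible,
the marginal MCI effects are attenuated relative to the generating
conditional OR even though no confounding is present in the doubled frame.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd

from .popgen import PopulationFrame
from .svyglm import GLMSpec, fit_glm

__all__ = ["PotentialFrame", "TrueEffects", "expand_to_potential_frame", "compute_true_effects"]


@dataclass
class PotentialFrame:
    """2N-row stack: one row per (individual, exposure level)."""

    frame: pd.DataFrame
    confounder_col: str

    @property
    def n_rows(self) -> int:
        return len(self.frame)


@dataclass
class TrueEffects:
    """Population causal effects on the ratio scale (OR for MCI, IRR for htn)."""

    mci: dict  # keys: ate, att, cate, catt
    htn: dict

    def get(self, outcome: str, estimand: str) -> float:
        return getattr(self, outcome)[estimand]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TrueEffects":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def expand_to_potential_frame(population: PopulationFrame) -> PotentialFrame:
    """Stack the population once per exposure level ``a`` in {0, 1}.

    The ``a = 0`` rows carry every outcome's Y(0) and the ``a = 1`` rows
    carry Y(1); covariates and the observed exposure ``Z`` are repeated.
    """
    df = population.frame
    required = [f"y_{o}_{a}" for o in ("mci", "htn1", "htn2") for a in (0, 1)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"population lacks potential-outcome columns: {missing}")
    conf = population.confounder_col
    keep = ["bmi", "years_between", "insomnia", conf]
    keep = list(dict.fromkeys(keep))  # dedupe if conf == a kept column
    parts = []
    for a in (0, 1):
        part = df[keep].copy()
        part["a"] = a
        for o in ("mci", "htn1", "htn2"):
            part[f"y_{o}"] = df[f"y_{o}_{a}"].to_numpy()
        parts.append(part)
    stacked = pd.concat(parts, ignore_index=True)
    return PotentialFrame(frame=stacked, confounder_col=conf)


def _effect(frame: pd.DataFrame, family: str, response: str,
            covariates: list[str], offset: str | None) -> float:
    spec = GLMSpec(family=family, response=response,
                   covariates=["a"] + covariates, offset=offset)
    fit = fit_glm(frame, spec)
    return float(np.exp(fit.params[fit.index("a")]))


def compute_true_effects(potential: PotentialFrame) -> TrueEffects:
    """Fit the eight truth regressions and return exponentiated ``a`` effects."""
    df = potential.frame
    conf = potential.confounder_col
    adj = ["bmi", conf]

    exposed = df["insomnia"].to_numpy() == 1
    mci = {
        "ate": _effect(df, "binomial", "y_mci", [], None),
        "cate": _effect(df, "binomial", "y_mci", adj, None),
        "att": _effect(df[exposed], "binomial", "y_mci", [], None),
        "catt": _effect(df[exposed], "binomial", "y_mci", adj, None),
    }

    at_risk = df["y_htn1"].to_numpy() == 0  # per-row: no visit-1 htn under same a
    risk = df[at_risk].copy()
    risk["log_years"] = np.log(risk["years_between"].to_numpy())
    r_exposed = risk["insomnia"].to_numpy() == 1
    htn = {
        "ate": _effect(risk, "poisson", "y_htn2", [], "log_years"),
        "cate": _effect(risk, "poisson", "y_htn2", adj, "log_years"),
        "att": _effect(risk[r_exposed], "poisson", "y_htn2", [], "log_years"),
        "catt": _effect(risk[r_exposed], "poisson", "y_htn2", adj, "log_years"),
    }
    return TrueEffects(mci=mci, htn=htn)
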