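"""Finite-population generator for the survey causal-inference simulation.

The target population is built hierarchically: strata contain census block
groups (BGs), BGs contain two-person households (HHs), and individuals carry
covariates (age, BMI, years between study visits), HH and BG random effects,
a binary exposure (insomnia) drawn from a logistic model, and *both*
potential outcomes for each of three binary endpoints — prevalent mild
cognitive impairment (MCI) at visit 2 and hypertension status at visits 1
and 2 — drawn from logistic models that include the random effects.  The
observed outcome for each endpoint is selected by the realized exposure,
``Y = Z*Y(1) + (1-Z)*Y(0)``.

In the "education" sensitivity mode, a noisy copy of age (``education``)
with a target age correlation replaces age in the exposure and outcome
models; age itself then matters only through the sampling design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri
from scipy.optimize import brentq

from .config import PopulationConfig, substream

__all__ = [
    "PopulationFrame",
    "sample_truncated_normal",
    "generate_population",
    "generate_education",
    "calibrate_intercepts",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Raised when a requested prevalence or correlation is unreachable."""


def sample_truncated_normal(
    mean: float, sd: float, lo: float, hi: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from N(mean, sd^2) conditioned on [lo, hi].

    Uses the inverse-CDF transform on the truncated interval, so the bounds
    are never atoms (no probability mass piles up at lo or hi, unlike
    clipping).  When the interval has vanishing normal mass (sd -> 0 with
    the mean inside the bounds), the degenerate point mass at the clipped
    mean is returned.
    """
    params = np.array([mean, sd, lo, hi], dtype=float)
    if not np.all(np.isfinite(params)):
        raise ValueError("truncated-normal parameters must be finite")
    if not lo < hi:
        raise ValueError("require lo < hi")
    if sd <= 0:
        raise ValueError("require sd > 0")
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    if b - a <= 0:  # numerically degenerate: all mass at one point
        return np.full(n, float(np.clip(mean, lo, hi)))
    u = rng.random(n)
    x = mean + sd * ndtri(a + u * (b - a))
    # inverse-CDF can touch the bounds only through floating rounding
    return np.clip(x, lo, hi)


def generate_education(
    ages: np.ndarray, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Generate an education variable with target correlation ``rho`` to age.

    Each value is drawn Unif(min(age), max(age)) and then replaced by the
    individual's own age with probability ``q``.  ``q`` is solved from the
    mixture moment identities Cov(E, A) = q Var(A) and
    Var(E) = q E[A^2] + (1-q) E[U^2] - (q mu_A + (1-q) mu_U)^2
    so that corr(E, A) = rho.  Returns ``(education, q)``.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be nonempty")
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    mu_a = ages.mean()
    var_a = ages.var()
    if var_a <= 0:
        raise CalibrationError("age variance is zero; correlation target unreachable")
    lo, hi = ages.min(), ages.max()
    mu_u = 0.5 * (lo + hi)
    var_u = (hi - lo) ** 2 / 12.0

    def corr(q: float) -> float:
        var_e = (
            q * (var_a + mu_a**2)
            + (1 - q) * (var_u + mu_u**2)
            - (q * mu_a + (1 - q) * mu_u) ** 2
        )
        return q * var_a / math.sqrt(var_a * var_e)

    try:
        q = brentq(lambda t: corr(t) - rho, 1e-12, 1.0, xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - defensive
        raise CalibrationError(f"correlation {rho} unreachable") from exc
    u = rng.uniform(lo, hi, size=ages.size)
    replace = rng.random(ages.size) < q
    education = np.where(replace, ages, u)
    return education, float(q)


@dataclass
class PopulationFrame:
    """The simulated finite target population.

    ``frame`` holds one row per individual.  The per-household arrays are
    kept alongside so the two-stage sampler can operate on flat numpy
    arrays without re-deriving household structure each replicate.
    """

    frame: pd.DataFrame
    config: PopulationConfig
    hh_bg: np.ndarray        # BG index (0-based) per household
    hh_max_age: np.ndarray   # maximum member age per household
    hh_mean_age: np.ndarray  # drawn household mean age
    row_hh: np.ndarray       # household index per individual row
    _cols: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_hh(self) -> int:
        return len(self.hh_bg)

    def col(self, name: str) -> np.ndarray:
        """Cached numpy view of a frame column (hot-path accessor)."""
        if name not in self._cols:
            self._cols[name] = self.frame[name].to_numpy()
        return self._cols[name]

    @property
    def confounder_col(self) -> str:
        return "education" if self.config.confounder_mode == "education" else "age"

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _linear_predictor(coefs, a, bmi, conf, years=None):
    """Linear predictor of the outcome models (without random effects)."""
    lp = coefs[0] + coefs[1] * a + coefs[2] * bmi + coefs[3] * conf
    if years is not None:
        lp = lp + coefs[4] * years
    return lp


def generate_population(config: PopulationConfig) -> PopulationFrame:
    """Generate the full finite population described by ``config``.

    All stochastic components draw from named substreams of ``config.seed``,
    so regenerating with the same config reproduces the frame exactly.
    """
    cfg = config
    seed = cfg.seed

    # --- household structure -------------------------------------------------
    rng_hh = substream(seed, "hh_counts")
    n_hh_per_bg = np.maximum(
        1, np.rint(rng_hh.exponential(cfg.hh_per_bg_mean, size=cfg.n_bg)).astype(int)
    )
    n_hh = int(n_hh_per_bg.sum())
    hh_bg = np.repeat(np.arange(cfg.n_bg), n_hh_per_bg)

    # --- ages ----------------------------------------------------------------
    mean, sd, lo, hi = cfg.hh_mean_age_dist
    rng_age = substream(seed, "ages")
    hh_mean_age = sample_truncated_normal(mean, sd, lo, hi, n_hh, rng_age)
    lo_age = np.ceil(hh_mean_age - cfg.age_halfwidth).astype(int)
    hi_age = np.maximum(np.floor(hh_mean_age + cfg.age_halfwidth).astype(int), lo_age)
    ages_by_hh = rng_age.integers(lo_age, hi_age + 1, size=(2, n_hh))
    hh_max_age = ages_by_hh.max(axis=0).astype(float)
    # interleave -> rows (hh0 p0, hh0 p1, hh1 p0, ...)
    age = ages_by_hh.T.reshape(-1).astype(float)

    n = 2 * n_hh
    row_hh = np.repeat(np.arange(n_hh), 2)
    bg_id = hh_bg[row_hh]
    stratum = cfg.stratum_of_bg[bg_id]

    # --- other covariates ----------------------------------------------------
    rng_bmi = substream(seed, "bmi")
    bmi = sample_truncated_normal(*cfg.bmi_dist, n, rng_bmi)
    rng_years = substream(seed, "years")
    years = sample_truncated_normal(*cfg.years_dist, n, rng_years)

    # --- random effects -------------------------------------------------------
    rng_re = substream(seed, "random_effects")
    h_hh = rng_re.normal(0.0, cfg.hh_re_sd, size=n_hh) if cfg.hh_re_sd > 0 else np.zeros(n_hh)
    b_bg = rng_re.normal(0.0, cfg.bg_re_sd, size=cfg.n_bg) if cfg.bg_re_sd > 0 else np.zeros(cfg.n_bg)
    h_ij = h_hh[row_hh]
    b_i = b_bg[bg_id]

    # --- confounder slot ------------------------------------------------------
    columns: dict[str, np.ndarray] = {}
    if cfg.confounder_mode == "education":
        rng_edu = substream(seed, "education")
        education, _q = generate_education(age, cfg.education_rho, rng_edu)
        conf = education
        columns["education"] = education
    else:
        conf = age

    # --- exposure -------------------------------------------------------------
    a0, a1, a2 = cfg.exposure_coefs
    p_insomnia = expit(a0 + a1 * bmi + a2 * conf)
    rng_z = substream(seed, "exposure")
    z = (rng_z.random(n) < p_insomnia).astype(np.int8)

    # --- potential outcomes ---------------------------------------------------
    re_sum = h_ij + b_i
    rng_y = substream(seed, "outcomes")
    pot: dict[str, np.ndarray] = {}
    for name, coefs, yrs in (
        ("mci", cfg.mci_coefs, None),
        ("htn1", cfg.htn1_coefs, None),
        ("htn2", cfg.htn2_coefs, years),
    ):
        for a in (0, 1):
            p = expit(_linear_predictor(coefs, a, bmi, conf, yrs) + re_sum)
            pot[f"y_{name}_{a}"] = (rng_y.random(n) < p).astype(np.int8)

    z_bool = z.astype(bool)
    frame = pd.DataFrame(
        {
            "bg_id": bg_id,
            "stratum": stratum,
            "hh_id": row_hh,
            "person_id": np.arange(n),
            "age": age,
            "bmi": bmi,
            "years_between": years,
            **columns,
            "h_ij": h_ij,
            "b_i": b_i,
            "p_insomnia": p_insomnia,
            "insomnia": z,
            **pot,
            "y_mci": np.where(z_bool, pot["y_mci_1"], pot["y_mci_0"]),
            "y_htn1": np.where(z_bool, pot["y_htn1_1"], pot["y_htn1_0"]),
            "y_htn2": np.where(z_bool, pot["y_htn2_1"], pot["y_htn2_0"]),
        }
    )
    return PopulationFrame(
        frame=frame, config=cfg, hh_bg=hh_bg, hh_max_age=hh_max_age,
        hh_mean_age=hh_mean_age, row_hh=row_hh,
    )


def _mean_expit(intercept: float, offset: np.ndarray) -> float:
    return float(expit(intercept + offset).mean())


def _solve_intercept(offset: np.ndarray, target: float) -> float:
    """Monotone bisection for b0 with mean(expit(b0 + offset)) = target."""
    lo, hi = -60.0, 60.0
    if not (_mean_expit(lo, offset) < target < _mean_expit(hi, offset)):
        raise CalibrationError(f"target prevalence {target} unreachable")
    return float(brentq(lambda b: _mean_expit(b, offset) - target, lo, hi, xtol=1e-10))


def calibrate_intercepts(
    config: PopulationConfig,
    targets: dict[str, float],
    rng: np.random.Generator | None = None,
    population: PopulationFrame | None = None,
) -> dict[str, float]:
    """Solve model intercepts so expected prevalences hit ``targets``.

    ``targets`` maps any of ``{"exposure", "mci", "htn1", "htn2"}`` to a
    prevalence in (0, 1).  The expected prevalence is evaluated over the
    realized covariates and random effects of a population drawn from
    ``config`` (or the supplied ``population``), which makes the calibration
    deterministic and exactly monotone in the intercept; outcome targets
    average over the exposure distribution implied by the (possibly
    recalibrated) exposure model.  Raising an intercept strictly raises the
    expected prevalence.
    """
    for key, t in targets.items():
        if key not in ("exposure", "mci", "htn1", "htn2"):
            raise ValueError(f"unknown calibration target {key!r}")
        if not 0.0 < t < 1.0:
            raise CalibrationError(f"target prevalence for {key} must be in (0,1)")
    if population is None:
        population = generate_population(config)
    cfg = population.config
    bmi = population.col("bmi")
    years = population.col("years_between")
    conf = population.col(population.confounder_col)
    re_sum = population.col("h_ij") + population.col("b_i")

    out: dict[str, float] = {}
    a0, a1, a2 = cfg.exposure_coefs
    if "exposure" in targets:
        a0 = _solve_intercept(a1 * bmi + a2 * conf, targets["exposure"])
        out["exposure"] = a0
    pz = expit(a0 + a1 * bmi + a2 * conf)

    model_coefs = {"mci": cfg.mci_coefs, "htn1": cfg.htn1_coefs, "htn2": cfg.htn2_coefs}
    for name in ("mci", "htn1", "htn2"):
        if name not in targets:
            continue
        coefs = model_coefs[name]
        yrs = years if name == "htn2" else None
        off0 = _linear_predictor(coefs, 0, bmi, conf, yrs) + re_sum - coefs[0]
        off1 = off0 + coefs[1]
        target = targets[name]

        def observed_prev(b0: float) -> float:
            return float(np.mean(pz * expit(b0 + off1) + (1 - pz) * expit(b0 + off0)))

        lo, hi = -60.0, 60.0
        if not (observed_prev(lo) < target < observed_prev(hi)):
            raise CalibrationError(f"target prevalence {target} unreachable for {name}")
        out[name] = float(brentq(lambda b: observed_prev(b) - target, lo, hi, xtol=1e-10))
    return out
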