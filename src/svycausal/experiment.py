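"""Monte-Carlo driver: bias and CI coverage of every method configuration.

One finite population is generated per study; its true causal effects are
computed once from the doubled potential-outcome frame.  Replicate survey
samples are then drawn (scenario 1: age-informative design; scenario 2:
age-free design) and every requested method configuration is evaluated on
each replicate.  Performance is summarized per configuration as

* bias  — mean over replicates of (estimate - true effect), on the
  exponentiated (ratio) scale, against the configuration's target estimand
  (ATE/CATE for IPTW, ATT/CATT for matching and odds weighting);
* cover — proportion of replicate 95% Wald CIs containing the true effect,

each with its Monte-Carlo standard error.  Replicate failures (e.g.
propensity separation, empty matched samples) are excluded and counted; a
configuration failing in more than 10% of replicates is flagged invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PopulationConfig, substream
from .popgen import PopulationFrame, generate_population, calibrate_intercepts
from .sampler import draw_survey_sample, EmptySampleError
from .svyglm import GLMConvergenceError
from .truth import TrueEffects, compute_true_effects, expand_to_potential_frame
from .causal import ReplicateEngine, NoOverlapError

logger = logging.getLogger("svycausal")

__all__ = [
    "MethodConfig",
    "run_replicates",
    "classify_robust",
    "run_sensitivity",
    "full_method_grid",
    "robust_method_grid",
    "ROBUST_COVERAGE_BAND",
]

#: closed coverage band defining a "robust" method
ROBUST_COVERAGE_BAND = (0.93, 0.97)

@dataclass(frozen=True)
class MethodConfig:
    """One cell of the method grid.

    ``ps_mode`` is the propensity-score handling of OSW for PSM and the
    weighting families (``osw_weighted`` / ``osw_covariate``) and the
    binning mode for CEM (``coarsened`` / ``coarsened_osw``).
    ``weight_scheme`` must be valid for the family: PSM takes
    ``none|osw|isw``, CEM takes ``cemw|cemw_osw``, weighting takes
    ``psw|psw_osw``.
    """

    family: str
    ps_mode: str
    adjusted: bool
    weight_scheme: str
    specification: str = "correct"
    scenario: int = 1
    outcome: str = "mci"

    def __post_init__(self) -> None:
        valid = {
            "psm": (("osw_weighted", "osw_covariate"), ("none", "osw", "isw")),
            "cem": (("coarsened", "coarsened_osw"), ("cemw", "cemw_osw")),
            "iptw": (("osw_weighted", "osw_covariate"), ("psw", "psw_osw")),
            "odds": (("osw_weighted", "osw_covariate"), ("psw", "psw_osw")),
        }
        if self.family not in valid:
            raise ValueError(f"unknown method family {self.family!r}")
        modes, schemes = valid[self.family]
        if self.ps_mode not in modes:
            raise ValueError(f"ps_mode {self.ps_mode!r} invalid for {self.family}")
        if self.weight_scheme not in schemes:
            raise ValueError(
                f"weight scheme {self.weight_scheme!r} invalid for {self.family}"
            )
        if self.specification not in ("correct", "under"):
            raise ValueError("specification must be 'correct' or 'under'")
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.outcome not in ("mci", "htn"):
            raise ValueError("outcome must be 'mci' or 'htn'")

    @property
    def estimand(self) -> str:
        """Target estimand: ATE for IPTW, ATT otherwise; conditional if adjusted."""
        marginal = "ate" if self.family == "iptw" else "att"
        return ("c" + marginal) if self.adjusted else marginal

    @property
    def key(self) -> tuple:
        return (
            self.outcome, self.scenario, self.specification, self.family,
            self.ps_mode, self.adjusted, self.weight_scheme,
        )

    @property
    def method_id(self) -> tuple:
        """Identity of the method itself, across scenarios/specifications."""
        return (self.family, self.ps_mode, self.adjusted, self.weight_scheme)


def full_method_grid(outcome: str = "mci", scenario: int = 1,
                     specification: str = "correct") -> list[MethodConfig]:
    """All 36 method cells of the comparison (12 PSM + 8 CEM + 16 weighting)."""
    out: list[MethodConfig] = []
    for mode in ("osw_weighted", "osw_covariate"):
        for adjusted in (False, True):
            for scheme in ("none", "osw", "isw"):
                out.append(MethodConfig("psm", mode, adjusted, scheme,
                                        specification, scenario, outcome))
    for mode in ("coarsened", "coarsened_osw"):
        for adjusted in (False, True):
            for scheme in ("cemw", "cemw_osw"):
                out.append(MethodConfig("cem", mode, adjusted, scheme,
                                        specification, scenario, outcome))
    for family in ("iptw", "odds"):
        for mode in ("osw_weighted", "osw_covariate"):
            for adjusted in (False, True):
                for scheme in ("psw", "psw_osw"):
                    out.append(MethodConfig(family, mode, adjusted, scheme,
                                            specification, scenario, outcome))
    return out


def robust_method_grid(outcome: str = "mci", scenario: int = 1,
                       specification: str = "correct") -> list[MethodConfig]:
    """The four matching methods that remain well-calibrated when a design-
    linked confounder is omitted: OSW-as-covariate PSM estimated with OSW,
    and CEM binned on covariates + OSW estimated with CEMW x OSW, each
    unadjusted and adjusted."""
    out = []
    for adjusted in (False, True):
        out.append(MethodConfig("psm", "osw_covariate", adjusted, "osw",
                                specification, scenario, outcome))
        out.append(MethodConfig("cem", "coarsened_osw", adjusted, "cemw_osw",
                                specification, scenario, outcome))
    return out


_FAILURES = (GLMConvergenceError, NoOverlapError, EmptySampleError,
             np.linalg.LinAlgError, ValueError)


def _evaluate_replicate(population, configs, seed, rep):
    """Evaluate every config on freshly drawn replicate samples.

    Returns {config.key: (estimate, ci_lo, ci_hi) or None on failure}.
    """
    conf = population.confounder_col
    results: dict[tuple, tuple | None] = {}
    scenarios = sorted({c.scenario for c in configs})
    for scen in scenarios:
        rng = substream(seed, "replicate", scen, rep)
        try:
            sample = draw_survey_sample(population, scen, rng)
        except EmptySampleError:
            for c in configs:
                if c.scenario == scen:
                    results[c.key] = None
            continue
        scen_cfgs = [c for c in configs if c.scenario == scen]
        engines: dict[tuple, ReplicateEngine] = {}
        for c in scen_cfgs:
            ek = (c.outcome, c.specification)
            if ek not in engines:
                covs = ["bmi"] if c.specification == "under" else ["bmi", conf]
                engines[ek] = ReplicateEngine(sample, c.outcome, covs)
            try:
                est = engines[ek].estimate(c)
                results[c.key] = (est.estimate, est.ci[0], est.ci[1])
            except _FAILURES as exc:
                logger.debug("replicate %d config %s failed: %s", rep, c.key, exc)
                results[c.key] = None
    return results


def _summarize(configs, per_rep, true_effects, n_reps) -> pd.DataFrame:
    rows = []
    for c in configs:
        te = true_effects.get(c.outcome, c.estimand)
        vals = [per_rep[r][c.key] for r in range(n_reps)]
        ok = [v for v in vals if v is not None]
        n_fail = n_reps - len(ok)
        if ok:
            est = np.array([v[0] for v in ok])
            covered = np.array([(v[1] <= te <= v[2]) for v in ok], dtype=float)
            bias = float(est.mean() - te)
            cover = float(covered.mean())
            mc_se_bias = float(est.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else np.nan
            mc_se_cover = float(np.sqrt(cover * (1 - cover) / len(ok)))
        else:
            bias = cover = mc_se_bias = mc_se_cover = np.nan
        rows.append({
            "outcome": c.outcome, "scenario": c.scenario,
            "specification": c.specification, "method": c.family,
            "ps_mode": c.ps_mode, "adjusted": c.adjusted,
            "weights": c.weight_scheme, "estimand": c.estimand,
            "true_effect": te, "bias": bias, "cover": cover,
            "mc_se_bias": mc_se_bias, "mc_se_cover": mc_se_cover,
            "n_reps": len(ok), "n_fail": n_fail,
            "valid": n_fail <= 0.10 * n_reps,
        })
    return pd.DataFrame(rows)


def run_replicates(
    population: PopulationConfig | PopulationFrame,
    method_configs: list[MethodConfig],
    n_reps: int,
    seed: int,
    true_effects: TrueEffects | None = None,
    n_jobs: int = 1,
    progress_every: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo evaluation of ``method_configs`` over replicate samples.

    ``population`` may be a config (one population is generated from it) or
    an already-generated :class:`PopulationFrame`.  The true effects are
    computed once.  Replicates use independent RNG substreams keyed by
    ``(seed, scenario, replicate)``, so results do not depend on worker
    count when ``n_jobs != 1``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if isinstance(population, PopulationConfig):
        population = generate_population(population)
    if true_effects is None:
        true_effects = compute_true_effects(expand_to_potential_frame(population))

    if n_jobs != 1:
        from joblib import Parallel, delayed

        per_rep = Parallel(n_jobs=n_jobs)(
            delayed(_evaluate_replicate)(population, method_configs, seed, r)
            for r in range(n_reps)
        )
    else:
        per_rep = []
        for r in range(n_reps):
            per_rep.append(_evaluate_replicate(population, method_configs, seed, r))
            if progress_every and (r + 1) % progress_every == 0:
                logger.info("replicate %d/%d done", r + 1, n_reps)
    return _summarize(method_configs, per_rep, true_effects, n_reps)


def classify_robust(metrics: pd.DataFrame,
                    band: tuple[float, float] = ROBUST_COVERAGE_BAND) -> pd.DataFrame:
    """Flag methods with coverage inside the closed band in the three
    qualifying cells: scenario 1 & 2 under correct specification, and
    scenario 1 under under-specification."""
    lo, hi = band
    required = [(1, "correct"), (2, "correct"), (1, "under")]
    ids = metrics[["method", "ps_mode", "adjusted", "weights", "outcome"]].drop_duplicates()
    out = []
    for _, row in ids.iterrows():
        sel = metrics[
            (metrics["method"] == row["method"])
            & (metrics["ps_mode"] == row["ps_mode"])
            & (metrics["adjusted"] == row["adjusted"])
            & (metrics["weights"] == row["weights"])
            & (metrics["outcome"] == row["outcome"])
        ]
        flags = []
        for scen, spec in required:
            cell = sel[(sel["scenario"] == scen) & (sel["specification"] == spec)]
            if len(cell) == 0 or not np.isfinite(cell["cover"].iloc[0]):
                flags.append(None)
            else:
                flags.append(bool(lo <= cell["cover"].iloc[0] <= hi))
        robust = None if any(f is None for f in flags) else all(flags)
        rec = dict(row)
        rec["robust"] = robust
        out.append(rec)
    return pd.DataFrame(out)


def run_sensitivity(
    pop_config: PopulationConfig,
    which: str,
    params: dict | None,
    n_reps: int,
    seed: int,
    outcomes: tuple[str, ...] = ("mci", "htn"),
) -> pd.DataFrame:
    """Sensitivity analyses around the main comparison.

    ``which`` selects:

    * ``unmeasured_confounder`` — rerun the full grid with the confounder
      omitted (under-specification), scenarios 1 and 2;
    * ``education_correlation`` — regenerate populations in education mode
      for each rho, robust methods only, correct and under specification,
      scenario 1;
    * ``prevalence_grid`` — recalibrate model intercepts to each
      (exposure, outcome) prevalence pair, robust methods only, scenario 1.
    """
    params = params or {}
    if which == "unmeasured_confounder":
        configs = []
        for outcome in outcomes:
            for scen in (1, 2):
                configs += full_method_grid(outcome, scen, "under")
        return run_replicates(pop_config, configs, n_reps, seed)

    if which == "education_correlation":
        rhos = params.get("rhos", (0.25, 0.5, 0.75))
        frames = []
        for rho in rhos:
            cfg = pop_config.replace(confounder_mode="education", education_rho=rho)
            configs = []
            for outcome in outcomes:
                for spec in ("correct", "under"):
                    configs += robust_method_grid(outcome, 1, spec)
            res = run_replicates(cfg, configs, n_reps, seed)
            res.insert(0, "rho", rho)
            frames.append(res)
        return pd.concat(frames, ignore_index=True)

    if which == "prevalence_grid":
        grid = params.get("prevalences", (0.05, 0.15, 0.25, 0.35))
        frames = []
        base_pop = generate_population(pop_config)
        for p_exp in grid:
            for p_out in grid:
                targets = {"exposure": p_exp, "mci": p_out, "htn1": p_out, "htn2": p_out}
                ints = calibrate_intercepts(pop_config, targets, population=base_pop)
                cfg = pop_config.replace(
                    exposure_coefs=(ints["exposure"],) + pop_config.exposure_coefs[1:],
                    mci_coefs=(ints["mci"],) + pop_config.mci_coefs[1:],
                    htn1_coefs=(ints["htn1"],) + pop_config.htn1_coefs[1:],
                    htn2_coefs=(ints["htn2"],) + pop_config.htn2_coefs[1:],
                )
                configs = []
                for outcome in outcomes:
                    configs += robust_method_grid(outcome, 1, "correct")
                res = run_replicates(cfg, configs, n_reps, seed)
                res.insert(0, "exposure_prevalence", p_exp)
                res.insert(1, "outcome_prevalence", p_out)
                frames.append(res)
        return pd.concat(frames, ignore_index=True)

    raise ValueError(
        "which must be one of 'unmeasured_confounder', "
        "'education_correlation', 'prevalence_grid'"
    )


def plot_prevalence_sensitivity(metrics: pd.DataFrame, out_path, outcome: str = "mci"):
    """Coverage and bias of the robust methods across the prevalence grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = metrics[metrics["outcome"] == outcome]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for (method, mode, adj, wts), grp in sub.groupby(
        ["method", "ps_mode", "adjusted", "weights"]
    ):
        label = f"{method}/{wts}{'/adj' if adj else ''}"
        g = grp.groupby("outcome_prevalence")[["cover", "bias"]].mean()
        axes[0].plot(g.index, g["cover"], marker="o", label=label)
        axes[1].plot(g.index, g["bias"], marker="o", label=label)
    axes[0].axhline(0.95, ls="--", c="gray")
    axes[0].set_ylabel("coverage")
    axes[1].axhline(0.0, ls="--", c="gray")
    axes[1].set_ylabel("bias")
    for ax in axes:
        ax.set_xlabel("outcome prevalence")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
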