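"""Matching- and weighting-based causal estimators for survey samples.

Implements the compared approaches for folding survey weights (OSW) and
design into causal estimation of a binary exposure's effect:

* propensity scores estimated two ways — OSW-weighted logistic regression,
  or unweighted logistic regression with OSW entered as a covariate;
* greedy 1:1 nearest-neighbor propensity matching without replacement
  (PSM), with analysis-weight variants none / OSW / inherited survey
  weights (ISW: a matched unexposed row takes its partner's OSW);
* coarsened exact matching (CEM) on binned covariates, optionally also on
  binned OSW, with CEM weights (CEMW) equalizing bin composition to the
  exposed group, and the CEMW x OSW product variant;
* propensity-score weighting: inverse-probability-of-treatment weights
  (IPTW, targets the ATE) and weighting-by-the-odds (targets the ATT),
  optionally multiplied by OSW;
* weighted absolute standardized mean differences (SMD) for balance
  diagnostics, denominated by the OSW-weighted SD of the full exposed
  group.

Effect estimation fits logistic models (odds ratios, prevalent outcomes)
or Poisson log-link models with a log-time offset (incidence-rate ratios,
incident outcomes); any weighted fit uses the design-based linearized
covariance from :mod:`svycausal.svyglm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import DesignInfo, SurveySample
from .svyglm import GLMFit, GLMSpec, fit_glm, fit_glm_arrays

__all__ = [
    "PropensityFit",
    "MatchedSample",
    "CEMBins",
    "EffectEstimate",
    "estimate_propensity",
    "propensity_weights",
    "psm_greedy_match",
    "assign_isw",
    "coarsen",
    "resolve_coarsen_plan",
    "cem_match",
    "absolute_smd",
    "balance_table",
    "estimate_causal_effect",
    "ReplicateEngine",
    "NoOverlapError",
    "DEFAULT_CEM_PLAN",
    "OSW_CEM_CUTS",
    "PS_CLIP",
]

#: positivity guard: estimated propensities are clipped into this interval
PS_CLIP = 1e-6

#: default coarsening plan: clinical BMI bins; quartiles elsewhere
DEFAULT_CEM_PLAN: dict = {
    "bmi": [18.5, 25.0, 30.0],
    "age": ("quantiles", 4),
    "years_between": ("quantiles", 4),
}
#: OSW gets its own quintile cutpoints when matched on
OSW_CEM_CUTS = ("quantiles", 5)


class NoOverlapError(RuntimeError):
    """All CEM bins pruned, or a matching step found no usable units."""


# --------------------------------------------------------------------------
# propensity scores and propensity weights
# --------------------------------------------------------------------------

@dataclass
class PropensityFit:
    mode: str                 # "osw_weighted" | "osw_covariate"
    e_hat: np.ndarray         # clipped into (PS_CLIP, 1 - PS_CLIP)
    fit: GLMFit
    n_clipped: int = 0


def estimate_propensity(
    sample: pd.DataFrame | SurveySample,
    covariates: list[str],
    mode: str,
    exposure: str = "insomnia",
    osw_col: str = "osw",
) -> PropensityFit:
    """Estimate exposure propensities with one of the two OSW treatments.

    ``osw_weighted`` fits an OSW-weighted logistic regression of exposure
    on the covariates; ``osw_covariate`` fits an unweighted logistic
    regression with OSW appended as an extra covariate.  Either way the
    fitted probabilities (clipped away from 0/1 for positivity) are the
    propensity scores.
    """
    if mode not in ("osw_weighted", "osw_covariate"):
        raise ValueError("mode must be 'osw_weighted' or 'osw_covariate'")
    df = sample.frame if isinstance(sample, SurveySample) else sample
    if mode == "osw_weighted":
        spec = GLMSpec("binomial", exposure, list(covariates), weights=osw_col)
    else:
        extra = [osw_col]
        if float(np.std(df[osw_col].to_numpy(dtype=float))) < 1e-12:
            extra = []  # constant OSW is collinear with the intercept: drop
        spec = GLMSpec("binomial", exposure, list(covariates) + extra)
    fit = fit_glm(df, spec, keep_fitted=True)
    raw = fit.fitted
    e_hat = np.clip(raw, PS_CLIP, 1.0 - PS_CLIP)
    n_clipped = int(np.sum((raw < PS_CLIP) | (raw > 1.0 - PS_CLIP)))
    if n_clipped:
        warnings.warn(f"{n_clipped} propensity scores clipped for positivity",
                      RuntimeWarning, stacklevel=2)
    return PropensityFit(mode=mode, e_hat=e_hat, fit=fit, n_clipped=n_clipped)


def propensity_weights(e_hat: np.ndarray, Z: np.ndarray, kind: str) -> np.ndarray:
    """IPTW (``Z/e + (1-Z)/(1-e)``) or odds weights (``Z + (1-Z) e/(1-e)``)."""
    e = np.asarray(e_hat, dtype=float)
    z = np.asarray(Z, dtype=float)
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    if kind == "iptw":
        return z / e + (1.0 - z) / (1.0 - e)
    if kind == "odds":
        return z + (1.0 - z) * e / (1.0 - e)
    raise ValueError("kind must be 'iptw' or 'odds'")


# --------------------------------------------------------------------------
# propensity-score matching
# --------------------------------------------------------------------------

@dataclass
class MatchedSample:
    """Greedy 1:1 matched pairs (row positions into the analysis frame)."""

    exposed: np.ndarray   # matched exposed row positions
    controls: np.ndarray  # partner unexposed row positions (aligned)

    @property
    def n_pairs(self) -> int:
        return len(self.exposed)

    @property
    def rows(self) -> np.ndarray:
        """All matched row positions, exposed first then partners."""
        return np.concatenate([self.exposed, self.controls])

    def analysis_weights(self, scheme: str, osw: np.ndarray) -> np.ndarray | None:
        """Per-row analysis weights aligned with :attr:`rows`."""
        osw = np.asarray(osw, dtype=float)
        if scheme == "none":
            return None
        if scheme == "osw":
            return osw[self.rows]
        if scheme == "isw":
            return assign_isw(self, osw)
        raise ValueError(f"unknown PSM weight scheme {scheme!r}")


def assign_isw(matched: MatchedSample, osw: np.ndarray) -> np.ndarray:
    """Inherited survey weights: both members of a pair carry the exposed OSW."""
    osw = np.asarray(osw, dtype=float)
    w_exposed = osw[matched.exposed]
    return np.concatenate([w_exposed, w_exposed])


def psm_greedy_match(e_hat: np.ndarray, Z: np.ndarray) -> MatchedSample:
    """Greedy 1:1 nearest-neighbor matching on the propensity score.

    Exposed units are processed in descending order of ``e_hat`` (ties by
    ascending row position); each claims the not-yet-matched unexposed unit
    with the smallest absolute score distance, ties broken by the lowest
    row position.  Matching is without replacement; unmatched unexposed
    units are discarded, so the pair count is ``min(n_exposed, n_unexposed)``.
    """
    e = np.asarray(e_hat, dtype=float)
    z = np.asarray(Z)
    exp_idx = np.flatnonzero(z == 1)
    ctl_idx = np.flatnonzero(z == 0)
    if exp_idx.size == 0 or ctl_idx.size == 0:
        raise NoOverlapError("both exposure groups must be nonempty")

    exposed = exp_idx[np.lexsort((exp_idx, -e[exp_idx]))]
    corder = np.lexsort((ctl_idx, e[ctl_idx]))
    ctl_sorted = ctl_idx[corder]
    ce = e[ctl_sorted]
    m = ctl_sorted.size

    # successor/predecessor pointers over sorted positions 1..m with
    # sentinels 0 (no left neighbor) and m+1 (no right neighbor);
    # removal redirects the pointer past the removed position.
    nr = list(range(m + 2))
    nl = list(range(m + 1))

    def find_right(p: int) -> int:
        path = []
        while p <= m and nr[p] != p:
            path.append(p)
            p = nr[p]
        for q in path:
            nr[q] = p
        return p  # survivor position, or m+1 if none

    def find_left(p: int) -> int:
        path = []
        while p >= 1 and nl[p] != p:
            path.append(p)
            p = nl[p]
        for q in path:
            nl[q] = p
        return p  # survivor position, or 0 if none

    ins = np.searchsorted(ce, e[exposed], side="left")
    pairs_e: list[int] = []
    pairs_c: list[int] = []
    n_matched = 0
    for t in range(exposed.size):
        if n_matched == m:
            break
        s = e[exposed[t]]
        right = find_right(int(ins[t]) + 1)
        left = find_left(int(ins[t]))
        if left >= 1:
            # all controls in left's equal-score run share |D|; the run's
            # first survivor is the lowest-index candidate at that distance
            run_start = int(np.searchsorted(ce, ce[left - 1], side="left")) + 1
            left = find_right(run_start)
        if right > m and left < 1:
            break
        if right > m:
            choice = left
        elif left < 1:
            choice = right
        else:
            dr = abs(ce[right - 1] - s)
            dl = abs(ce[left - 1] - s)
            if dl < dr:
                choice = left
            elif dr < dl:
                choice = right
            else:
                # cross-side |D| tie: lowest row position wins
                choice = left if ctl_sorted[left - 1] < ctl_sorted[right - 1] else right
        pairs_e.append(int(exposed[t]))
        pairs_c.append(int(ctl_sorted[choice - 1]))
        nr[choice] = choice + 1
        nl[choice] = choice - 1
        n_matched += 1
    return MatchedSample(
        exposed=np.asarray(pairs_e, dtype=int), controls=np.asarray(pairs_c, dtype=int)
    )


# --------------------------------------------------------------------------
# coarsened exact matching
# --------------------------------------------------------------------------

def coarsen(values: np.ndarray, cutpoints) -> np.ndarray:
    """Bin values into half-open intervals ``[c_k, c_{k+1})``.

    Values below the first cutpoint fall in bin 0 and values at or above
    the last cutpoint in the final bin; a value exactly at a cutpoint joins
    the right-hand bin.
    """
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.size == 0:
        raise ValueError("cutpoints must be nonempty")
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    return np.searchsorted(cuts, np.asarray(values, dtype=float), side="right")


def resolve_coarsen_plan(df: pd.DataFrame, plan: dict) -> dict[str, np.ndarray]:
    """Turn a plan with explicit cutpoints or ``("quantiles", k)`` entries
    into concrete cutpoint arrays computed from the sample at hand."""
    resolved: dict[str, np.ndarray] = {}
    for var, spec in plan.items():
        if isinstance(spec, tuple) and spec[0] == "quantiles":
            k = int(spec[1])
            qs = np.linspace(0, 1, k + 1)[1:-1]
            cuts = np.unique(np.quantile(df[var].to_numpy(dtype=float), qs))
        else:
            cuts = np.asarray(spec, dtype=float)
        resolved[var] = cuts
    return resolved


@dataclass
class CEMBins:
    """CEM bin assignments, weights and pruning outcome."""

    rows: np.ndarray        # retained row positions
    bin_id: np.ndarray      # bin index per retained row
    cemw: np.ndarray        # CEM weight per retained row
    pruned: np.ndarray      # pruned row positions
    n_bins_retained: int
    n_bins_pruned: int


def cem_match(
    sample: pd.DataFrame | SurveySample,
    coarsen_plan: dict | None = None,
    include_osw: bool = False,
    exposure: str = "insomnia",
    osw_col: str = "osw",
) -> CEMBins:
    """Coarsen, cross-classify, prune, and weight.

    Bins lacking at least one exposed and one unexposed member are pruned.
    Retained exposed rows get weight 1; retained unexposed rows get
    ``(n_unexposed / n_exposed) * (n_b,exposed / n_b,unexposed)`` computed
    over the retained (matched) sample, which equalizes each bin's
    unexposed weight share to the exposed share.
    """
    df = sample.frame if isinstance(sample, SurveySample) else sample
    plan = dict(DEFAULT_CEM_PLAN if coarsen_plan is None else coarsen_plan)
    plan = {k: v for k, v in plan.items() if k in df.columns}
    if include_osw:
        plan[osw_col] = OSW_CEM_CUTS
    if not plan:
        raise ValueError("coarsening plan selects no matching variables")
    resolved = resolve_coarsen_plan(df, plan)

    code = np.zeros(len(df), dtype=np.int64)
    for var, cuts in resolved.items():
        c = coarsen(df[var].to_numpy(), cuts)
        code = code * (cuts.size + 1) + c
    _, bin_inv = np.unique(code, return_inverse=True)

    z = df[exposure].to_numpy().astype(int)
    n_bins = bin_inv.max() + 1
    n_exp_b = np.bincount(bin_inv, weights=z, minlength=n_bins)
    n_ctl_b = np.bincount(bin_inv, weights=1 - z, minlength=n_bins)
    keep_bin = (n_exp_b > 0) & (n_ctl_b > 0)
    if not keep_bin.any():
        raise NoOverlapError("all CEM bins pruned: no exposure overlap")

    row_keep = keep_bin[bin_inv]
    rows = np.flatnonzero(row_keep)
    pruned = np.flatnonzero(~row_keep)
    zb = z[rows]
    bins = bin_inv[rows]
    n_exp = zb.sum()
    n_ctl = len(zb) - n_exp
    ratio = n_ctl / n_exp
    cemw = np.where(zb == 1, 1.0, ratio * n_exp_b[bins] / n_ctl_b[bins])
    # relabel retained bins densely
    _, dense = np.unique(bins, return_inverse=True)
    return CEMBins(
        rows=rows, bin_id=dense, cemw=cemw, pruned=pruned,
        n_bins_retained=int(keep_bin.sum()), n_bins_pruned=int((~keep_bin).sum()),
    )


# --------------------------------------------------------------------------
# balance diagnostics
# --------------------------------------------------------------------------

def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _wsd(x: np.ndarray, w: np.ndarray) -> float:
    m = _wmean(x, w)
    return float(np.sqrt(np.sum(w * (x - m) ** 2) / np.sum(w)))


def absolute_smd(
    sample: pd.DataFrame | SurveySample,
    covariate: str,
    rows: np.ndarray | None = None,
    analysis_weights: np.ndarray | None = None,
    exposure: str = "insomnia",
    osw_col: str = "osw",
) -> float | dict:
    """Weighted absolute standardized mean difference of one covariate.

    Group means use the estimation-stage weights (``analysis_weights``
    aligned with ``rows``; defaults to OSW over the full sample).  The
    denominator is always the OSW-weighted SD of the covariate in the
    *full* exposed group, before any matching or pruning, so before/after
    comparisons share a scale.  Categorical covariates return one SMD per
    level based on level proportions.
    """
    df = sample.frame if isinstance(sample, SurveySample) else sample
    z_full = df[exposure].to_numpy().astype(int)
    osw_full = df[osw_col].to_numpy(dtype=float)
    x_full = df[covariate].to_numpy()

    if rows is None:
        rows = np.arange(len(df))
    if analysis_weights is None:
        analysis_weights = osw_full[rows]
    w = np.asarray(analysis_weights, dtype=float)
    z = z_full[rows]
    x = x_full[rows]

    categorical = not np.issubdtype(np.asarray(x_full).dtype, np.number)
    if categorical:
        out = {}
        for level in pd.unique(pd.Series(x_full)):
            ind_full = (x_full == level).astype(float)
            s_exp = _wsd(ind_full[z_full == 1], osw_full[z_full == 1])
            ind = (x == level).astype(float)
            out[level] = _smd_from(ind, z, w, s_exp)
        return out
    s_exp = _wsd(x_full[z_full == 1], osw_full[z_full == 1])
    return _smd_from(x.astype(float), z, w, s_exp)


def _smd_from(x, z, w, s_exp) -> float:
    if s_exp == 0:
        warnings.warn("zero exposed-group SD: SMD undefined", RuntimeWarning, stacklevel=3)
        return float("nan")
    m1 = _wmean(x[z == 1], w[z == 1])
    m0 = _wmean(x[z == 0], w[z == 0])
    return abs(m1 - m0) / s_exp


def balance_table(
    sample: pd.DataFrame | SurveySample,
    covariates: list[str],
    rows: np.ndarray | None = None,
    analysis_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Before/after SMD table (before = full sample under OSW)."""
    records = []
    for cov in covariates:
        before = absolute_smd(sample, cov)
        after = absolute_smd(sample, cov, rows=rows, analysis_weights=analysis_weights)
        if isinstance(before, dict):
            for level in before:
                records.append(
                    {"covariate": f"{cov}={level}", "smd_before": before[level],
                     "smd_after": after[level]}
                )
        else:
            records.append({"covariate": cov, "smd_before": before, "smd_after": after})
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# effect estimation
# --------------------------------------------------------------------------

@dataclass
class EffectEstimate:
    """One method's exponentiated exposure effect with design-based CI."""

    family: str
    ps_mode: str | None
    adjusted: bool
    weight_scheme: str
    outcome: str
    scale: str            # "OR" | "IRR"
    estimate: float
    se_log: float
    ci: tuple[float, float]
    n_used: int
    estimand: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.estimate <= hi):
            raise ValueError("CI must contain the point estimate")


class ReplicateEngine:
    """Evaluate every method configuration on one analysis sample.

    The engine restricts the sample for incident outcomes (rows with
    observed baseline hypertension are dropped *before* propensity
    estimation and matching), then caches propensity fits, matched samples
    and CEM solutions so weight-scheme and adjustment variants reuse them.
    """

    def __init__(
        self,
        sample: SurveySample | pd.DataFrame,
        outcome: str,
        covariates: list[str],
        cem_plan: dict | None = None,
    ) -> None:
        df = sample.frame if isinstance(sample, SurveySample) else sample
        if outcome not in ("mci", "htn"):
            raise ValueError("outcome must be 'mci' or 'htn'")
        if outcome == "htn":
            df = df[df["y_htn1"].to_numpy() == 0].reset_index(drop=True)
        self.df = df
        self.outcome = outcome
        self.covariates = list(covariates)
        self.cem_plan = cem_plan
        self.z = df["insomnia"].to_numpy().astype(int)
        self.osw = df["osw"].to_numpy(dtype=float)
        self.strata = df["stratum"].to_numpy()
        self.psu = df["bg_id"].to_numpy()
        self._ps: dict[str, PropensityFit] = {}
        self._match: dict[str, MatchedSample] = {}
        self._cem: dict[bool, CEMBins] = {}
        n = len(df)
        self._X_base = [np.ones(n)] + [df[c].to_numpy(dtype=float) for c in self.covariates]
        if outcome == "mci":
            self.y = df["y_mci"].to_numpy(dtype=float)
            self.offset = None
            self.glm_family = "binomial"
            self.scale = "OR"
        else:
            self.y = df["y_htn2"].to_numpy(dtype=float)
            self.offset = np.log(df["years_between"].to_numpy(dtype=float))
            self.glm_family = "poisson"
            self.scale = "IRR"

    def propensity(self, mode: str) -> PropensityFit:
        if mode not in self._ps:
            self._ps[mode] = estimate_propensity(self.df, self.covariates, mode)
        return self._ps[mode]

    def matched(self, mode: str) -> MatchedSample:
        if mode not in self._match:
            self._match[mode] = psm_greedy_match(self.propensity(mode).e_hat, self.z)
        return self._match[mode]

    def cem(self, include_osw: bool) -> CEMBins:
        if include_osw not in self._cem:
            plan = self.cem_plan
            if plan is None:
                plan = {v: DEFAULT_CEM_PLAN.get(v, ("quantiles", 4)) for v in self.covariates}
            self._cem[include_osw] = cem_match(self.df, plan, include_osw=include_osw)
        return self._cem[include_osw]

    # -- fitting ------------------------------------------------------------

    def _fit(self, rows: np.ndarray, weights: np.ndarray | None, adjusted: bool) -> GLMFit:
        cols = [c[rows] for c in self._X_base] if adjusted else [self._X_base[0][rows]]
        X = np.column_stack([cols[0], self.z[rows].astype(float)] + cols[1:])
        names = ["(Intercept)", "insomnia"] + (self.covariates if adjusted else [])
        design = None
        if weights is not None:
            design = DesignInfo(self.strata[rows], self.psu[rows], weights)
        offset = self.offset[rows] if self.offset is not None else None
        return fit_glm_arrays(
            X, self.y[rows], self.glm_family, weights=weights, offset=offset,
            design=design, names=names,
        )

    def estimate(self, cfg) -> EffectEstimate:
        """Run one method configuration (``cfg`` supplies family, ps_mode,
        weight_scheme, adjusted)."""
        family = cfg.family
        scheme = cfg.weight_scheme
        if family == "psm":
            matched = self.matched(cfg.ps_mode)
            rows = matched.rows
            weights = matched.analysis_weights(scheme, self.osw)
        elif family == "cem":
            bins = self.cem(include_osw=(cfg.ps_mode == "coarsened_osw"))
            rows = bins.rows
            if scheme == "cemw":
                weights = bins.cemw
            elif scheme == "cemw_osw":
                weights = bins.cemw * self.osw[rows]
            else:
                raise ValueError(f"invalid CEM weight scheme {scheme!r}")
        elif family in ("iptw", "odds"):
            e_hat = self.propensity(cfg.ps_mode).e_hat
            rows = np.arange(len(self.df))
            psw = propensity_weights(e_hat, self.z, family)
            if scheme == "psw":
                weights = psw
            elif scheme == "psw_osw":
                weights = psw * self.osw
            else:
                raise ValueError(f"invalid weighting scheme {scheme!r}")
        else:
            raise ValueError(f"unknown method family {family!r}")

        fit = self._fit(rows, weights, cfg.adjusted)
        est, lo, hi = fit.exp_effect("insomnia")
        return EffectEstimate(
            family=family,
            ps_mode=getattr(cfg, "ps_mode", None),
            adjusted=cfg.adjusted,
            weight_scheme=scheme,
            outcome=self.outcome,
            scale=self.scale,
            estimate=est,
            se_log=float(fit.se[fit.index("insomnia")]),
            ci=(lo, hi),
            n_used=int(len(rows)),
            estimand=getattr(cfg, "estimand", ""),
        )


def estimate_causal_effect(
    sample: SurveySample | pd.DataFrame,
    outcome: str,
    method_config,
    covariates: list[str] | None = None,
    confounder: str = "age",
    cem_plan: dict | None = None,
) -> EffectEstimate:
    """One-shot estimation of a single method configuration.

    ``covariates`` defaults to ``["bmi", confounder]`` under correct
    specification and ``["bmi"]`` under under-specification (confounder
    omitted from the propensity/coarsening model and the outcome model).
    """
    if covariates is None:
        spec = getattr(method_config, "specification", "correct")
        covariates = ["bmi"] if spec == "under" else ["bmi", confounder]
    engine = ReplicateEngine(sample, outcome, covariates, cem_plan=cem_plan)
    return engine.estimate(method_config)
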