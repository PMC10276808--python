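"""Configuration loading, miniature test fixtures, and the real-data adapter.

All on-disk formats are plain text: JSON for configurations and fitted
summaries, CSV (RFC-4180 via pandas) for populations, samples and metric
tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PopulationConfig, RunConfig
from .popgen import generate_population
from .sampler import draw_survey_sample
from .causal import estimate_propensity, psm_greedy_match, cem_match

__all__ = ["load_config", "make_fixture", "read_analysis_table", "SchemaError"]


class SchemaError(ValueError):
    """A config or data file failed validation; the message names the field."""


def load_config(path) -> RunConfig:
    """Load a JSON run configuration; missing keys fall back to defaults.

    An empty (or whitespace-only) file yields the full default
    configuration.  Unknown keys and out-of-range values raise
    :class:`SchemaError` naming the offending field.
    """
    text = Path(path).read_text().strip()
    if not text:
        data = {}
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"config {path} is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError("config root must be a JSON object")
    try:
        return RunConfig.from_dict(data)
    except (ValueError, TypeError) as exc:
        raise SchemaError(str(exc)) from exc


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)


#: miniature population parameters shared by all fixtures
_FIXTURE_POP = dict(
    n_bg=10,
    n_strata=4,
    bg_per_stratum=(3, 3, 2, 2),
    hh_per_bg_mean=9.0,
    hh_mean_age_dist=(64.0, 6.0, 50.0, 69.0),
)
_FIXTURE_BG_PROBS = {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}


def make_fixture(kind: str, seed: int = 0):
    """Deterministic miniature objects (on the order of 100 rows) for unit
    testing.

    ``kind``: ``population`` | ``sample`` | ``matched`` | ``bins``.
    The fixture population skews old so the age-driven second sampling
    stage keeps enough households for matching to be exercised.
    """
    cfg = PopulationConfig(seed=seed, **_FIXTURE_POP)
    population = generate_population(cfg)
    if kind == "population":
        return population
    rng = np.random.default_rng(seed + 1)
    from .sampler import hh_inclusion_probability

    # keep the age gradient but scale stage-2 retention up so the miniature
    # sample stays large enough for propensity fits and matching
    hh_probs = np.minimum(0.95, 4.0 * hh_inclusion_probability(population.hh_max_age))
    sample = draw_survey_sample(
        population, 1, rng, bg_probs=_FIXTURE_BG_PROBS, hh_probs=hh_probs
    )
    if kind == "sample":
        return sample
    if kind == "matched":
        ps = estimate_propensity(sample, ["bmi", "age"], "osw_covariate")
        return psm_greedy_match(ps.e_hat, sample.frame["insomnia"].to_numpy())
    if kind == "bins":
        plan = {"bmi": [18.5, 25.0, 30.0], "age": ("quantiles", 4)}
        return cem_match(sample, plan, include_osw=False)
    raise ValueError("kind must be population | sample | matched | bins")


_ROLE_TARGETS = {
    "stratum": "stratum",
    "psu": "bg_id",
    "weight": "osw",
    "exposure": "insomnia",
}


def read_analysis_table(
    path,
    column_map: dict,
    exposure_values: dict | None = None,
    dropna: bool = True,
) -> pd.DataFrame:
    """Read a generic flat analysis table into the canonical column layout.

    ``column_map`` binds roles to CSV column names; required roles are
    ``stratum``, ``psu``, ``weight`` and ``exposure``.  Optional roles:
    ``outcome`` (mapped to ``y_mci``), ``baseline_outcome`` (``y_htn1``),
    ``incident_outcome`` (``y_htn2``), ``years`` (``years_between``) and
    ``covariates`` (a list, kept under their own names).  ``exposure_values``
    recodes a non-numeric exposure, e.g. ``{"yes": 1, "no": 0}``.  The
    weight column is validated (positive) and normalized to mean one as the
    OSW; rows with missing values on mapped columns are dropped
    (complete-case) with a count reported via the returned frame's attrs.
    """
    df = pd.read_csv(path)
    for role in ("stratum", "psu", "weight", "exposure"):
        if role not in column_map:
            raise SchemaError(f"column_map is missing required role '{role}'")
    rename: dict[str, str] = {}
    optional = {
        "outcome": "y_mci",
        "baseline_outcome": "y_htn1",
        "incident_outcome": "y_htn2",
        "years": "years_between",
    }
    roles = {**_ROLE_TARGETS, **optional}
    used_cols: list[str] = []
    for role, target in roles.items():
        if role not in column_map:
            continue
        col = column_map[role]
        if col not in df.columns:
            raise SchemaError(f"mapped column '{col}' (role '{role}') not in table")
        rename[col] = target
        used_cols.append(col)
    covariates = list(column_map.get("covariates", []))
    for col in covariates:
        if col not in df.columns:
            raise SchemaError(f"covariate column '{col}' not in table")
        used_cols.append(col)

    out = df[used_cols].rename(columns=rename)
    n_before = len(out)
    if dropna:
        out = out.dropna().reset_index(drop=True)
    n_dropped = n_before - len(out)

    w = out["osw"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(w > 0))
    if bad.size:
        raise SchemaError(f"nonpositive weight at row {int(bad[0])}")
    out["w_ijk"] = w
    out["osw"] = w / w.mean()

    z = out["insomnia"]
    if exposure_values is not None:
        unknown = set(z.unique()) - set(exposure_values)
        if unknown:
            raise SchemaError(f"exposure values {sorted(map(str, unknown))} not in mapping")
        z = z.map(exposure_values)
    z = pd.to_numeric(z, errors="coerce")
    if z.isna().any() or not set(z.unique()) <= {0, 1}:
        raise SchemaError("exposure must be binary 0/1 (or recoded via exposure_values)")
    out["insomnia"] = z.astype(int)
    out.attrs["n_dropped_missing"] = n_dropped
    return out
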