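"""Dyad-level statistical stage: measures table, mixed models, appraisal GLMs.

The dyad-task measures are assembled into a long table (one row per
dyad x conversation task) joined with each partner's trait scores.
Within every dyad the higher scorer on a trait is designated role "A"
and the lower role "B", so a trait enters the models as an ordered pair
of continuous covariates rather than an unordered set.  Conversation
task is categorical with the introduction as the baseline level.

Model fitting itself is delegated: linear mixed models with a dyad
random intercept are estimated by maximum likelihood via statsmodels
``MixedLM``, appraisal items by ordinary least squares.  What this module
owns is the design construction (trait main effects and the two- and
three-way trait x task interactions), the baseline coding, standardized
beta weights (z-scoring the response and continuous predictors and
refitting; task dummies stay binary), the reporting contract (B, beta,
SE, t, df, p, ICC, marginal/conditional R-squared, AIC), and
Benjamini-Hochberg correction across a model family.

Degrees of freedom are residual (n_obs minus fixed-effect parameters),
a deliberate approximation documented in the methods note; Satterthwaite
machinery is outside this package's scope.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .anisotropic import DyadMeasures
from .errors import ConfigurationError, DegenerateDataError, FormatError
from .timeseries import TASKS

MEASURE_COLUMNS = (
    "rr_global", "rr_los", "q_dcrp", "lam_ard", "tt_ard",
    "lam_ver", "lam_hor", "tt_ver", "tt_hor", "speech_time_seconds",
)


@dataclass(frozen=True)
class ModelFit:
    """Coefficient table and fit summaries for one fitted model."""

    response_name: str
    coefficients: pd.DataFrame  # term, B, beta, SE, t, df, p, p_adjusted
    icc: float | None
    marginal_r2: float | None
    conditional_r2: float | None
    aic: float
    n_groups: int | None
    n_obs: int
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Roles, standardization, dyad typing


def assign_roles(score_1: float, score_2: float) -> tuple[str, str]:
    """Designate the higher scorer as "A", the lower as "B" (tie: first is A)."""
    if not (np.isfinite(score_1) and np.isfinite(score_2)):
        raise ConfigurationError("trait scores must be finite")
    return ("A", "B") if score_1 >= score_2 else ("B", "A")


def standardize(values: Iterable[float]) -> np.ndarray:
    """Center to mean 0 and scale to sample standard deviation 1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ConfigurationError("standardize needs at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("cannot standardize a zero-variance vector")
    return (arr - arr.mean()) / sd


def classify_dyad(z_a: float, z_b: float, threshold: float = 0.5) -> str:
    """Descriptive dyad type from two standardized trait scores.

    "++" both >= +threshold SD, "--" both <= -threshold, "+-" one of
    each, "mid" if either member is within the band.  Plotting aid only.
    """

    def level(z: float) -> str:
        if z >= threshold:
            return "high"
        if z <= -threshold:
            return "low"
        return "mid"

    la, lb = level(z_a), level(z_b)
    if "mid" in (la, lb):
        return "mid"
    if la == lb:
        return "++" if la == "high" else "--"
    return "+-"


# ---------------------------------------------------------------------------
# Table assembly


def assemble_measures_table(
    measures: Sequence[DyadMeasures],
    traits: pd.DataFrame,
    trait_names: Sequence[str] = ("extraversion", "agreeableness"),
) -> pd.DataFrame:
    """Long-format dyad-task table with role-ordered trait columns.

    ``traits`` needs one row per participant with ``dyad_id`` plus one
    column per trait; scores are standardized across the whole sample
    before role assignment and dyad typing.  Requires a complete
    dyad x task grid.
    """
    seen = set()
    rows = []
    for m in measures:
        key = (m.dyad_id, m.task)
        if key in seen:
            raise FormatError(f"duplicated (dyad, task) cell: {key}")
        seen.add(key)
        rows.append(
            {
                "dyad_id": m.dyad_id,
                "task": m.task,
                "rr_global": m.rr_global,
                "rr_los": m.rr_los,
                "q_dcrp": m.q_dcrp,
                "lam_ard": m.lam_ard,
                "tt_ard": m.tt_ard,
                "lam_ver": m.line_stats.lam_ver,
                "lam_hor": m.line_stats.lam_hor,
                "tt_ver": m.line_stats.tt_ver,
                "tt_hor": m.line_stats.tt_hor,
                "speech_time_seconds": m.speech_time_seconds,
            }
        )
    table = pd.DataFrame(rows)
    dyad_ids = sorted(table.dyad_id.unique())
    tasks = [t for t in TASKS if t in set(table.task)]
    missing = [
        (d, t) for d in dyad_ids for t in tasks if (d, t) not in seen
    ]
    if missing:
        raise FormatError(f"incomplete dyad x task grid; missing cells: {missing}")
    table["task"] = pd.Categorical(table.task, categories=TASKS, ordered=False)

    traits = traits.copy()
    for trait in trait_names:
        if trait not in traits.columns:
            raise ConfigurationError(f"traits table lacks column {trait!r}")
        z = standardize(traits[trait].to_numpy())
        traits[f"_z_{trait}"] = z
    per_dyad: dict[str, dict[str, float | str]] = {}
    for dyad_id, grp in traits.groupby("dyad_id"):
        if len(grp) != 2:
            raise FormatError(f"dyad {dyad_id} has {len(grp)} participants, expected 2")
        entry: dict[str, float | str] = {}
        for trait in trait_names:
            z1, z2 = grp[f"_z_{trait}"].to_numpy()
            r1, _ = assign_roles(z1, z2)
            hi, lo = (z1, z2) if r1 == "A" else (z2, z1)
            entry[f"{trait}_a"] = hi
            entry[f"{trait}_b"] = lo
            entry[f"dyad_type_{trait}"] = classify_dyad(hi, lo)
        per_dyad[str(dyad_id)] = entry
    for col in per_dyad[next(iter(per_dyad))]:
        table[col] = [per_dyad[d][col] for d in table.dyad_id]
    return table


# ---------------------------------------------------------------------------
# Model fitting


def _term_variables(terms: Sequence[str], table: pd.DataFrame) -> list[str]:
    names: list[str] = []
    for term in terms:
        for tok in re.findall(r"[A-Za-z_][A-Za-z0-9_.]*", term):
            if tok in table.columns and tok not in names:
                names.append(tok)
            elif tok not in table.columns and tok not in ("C", "np"):
                raise ConfigurationError(f"unknown model term variable {tok!r}")
    return names


def _continuous(cols: Sequence[str], table: pd.DataFrame) -> list[str]:
    out = []
    for c in cols:
        if isinstance(table[c].dtype, pd.CategoricalDtype) or table[c].dtype == object:
            continue
        out.append(c)
    return out


def _zscore_frame(table: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    std = table.copy()
    for c in cols:
        std[c] = standardize(std[c].to_numpy())
    return std


def fit_mixed_model(
    table: pd.DataFrame,
    response_name: str,
    fixed_terms: Sequence[str] = ("task",),
    adjust: bool = True,
) -> ModelFit:
    """Two-level linear mixed model: fixed terms + dyad random intercept.

    ML estimation (not REML) so AICs are comparable across fixed-effect
    structures.  ``fixed_terms`` are formula fragments, e.g.
    ``("extraversion_a * extraversion_b * task",)`` for the full trait x
    task interaction design.  BH adjustment (when ``adjust``) spans the
    model's non-intercept terms.
    """
    if response_name not in table.columns:
        raise ConfigurationError(f"response {response_name!r} not in table")
    variables = _term_variables(fixed_terms, table)
    if table["dyad_id"].nunique() < 2:
        raise ConfigurationError("need at least 2 dyads")
    formula = f"{response_name} ~ " + " + ".join(fixed_terms)

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, table, groups=table["dyad_id"])
        res = model.fit(reml=False)
        caught.extend(str(w.message) for w in wlist if issubclass(w.category, (ConvergenceWarning, UserWarning)))

    fe_names = [n for n in res.fe_params.index]
    k = len(fe_names)
    n_obs = int(res.nobs)
    df_resid = max(n_obs - k, 1)

    # Standardized betas: z-score response + continuous predictors, refit.
    cont = _continuous([response_name] + variables, table)
    cont = [c for c in cont if table[c].std(ddof=1) > 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std_tab = _zscore_frame(table, cont)
        res_std = smf.mixedlm(formula, std_tab, groups=std_tab["dyad_id"]).fit(reml=False)

    B = res.fe_params.to_numpy()
    beta = res_std.fe_params.to_numpy()
    se = res.bse_fe.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, B / np.where(se > 0, se, 1.0), np.sign(B) * np.inf)
    tvals = np.where((se == 0) & (B == 0), 0.0, tvals)
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)  # exact fit: |t|=inf -> p=0
    coef = pd.DataFrame(
        {
            "term": fe_names,
            "B": B,
            "beta": beta,
            "SE": se,
            "t": tvals,
            "df": df_resid,
            "p": pvals,
            "p_adjusted": np.nan,
        }
    )
    if adjust:
        mask = coef.term != "Intercept"
        if mask.any():
            coef.loc[mask, "p_adjusted"] = bh_adjust(coef.loc[mask, "p"].to_numpy())

    var_re = float(np.asarray(res.cov_re).ravel()[0])
    var_resid = float(res.scale)
    icc = var_re / (var_re + var_resid) if (var_re + var_resid) > 0 else 0.0
    fixed_fitted = model.exog @ B
    var_f = float(np.var(fixed_fitted))
    total = var_f + var_re + var_resid
    if var_re <= 1e-10:
        caught.append("singular fit: between-dyad variance estimated at ~0")
    return ModelFit(
        response_name=response_name,
        coefficients=coef,
        icc=icc,
        marginal_r2=var_f / total if total > 0 else None,
        conditional_r2=(var_f + var_re) / total if total > 0 else None,
        aic=float(res.aic),
        n_groups=int(table["dyad_id"].nunique()),
        n_obs=n_obs,
        warnings=tuple(dict.fromkeys(caught)),
    )


def fit_appraisal_model(
    table: pd.DataFrame,
    item_name: str,
    predictors: Sequence[str],
    adjust: bool = False,
) -> ModelFit:
    """Ordinary linear model for one 1-5 Likert appraisal item.

    ``predictors`` are formula fragments over trait and coordination
    columns (interactions allowed).  Raw estimates come from the raw fit;
    standardized betas from a z-scored refit.  p-values are returned raw
    by default so BH can be applied across the whole item family with
    :func:`bh_adjust_fits`.
    """
    if item_name not in table.columns:
        raise ConfigurationError(f"item {item_name!r} not in table")
    item = table[item_name].to_numpy(dtype=float)
    if item.min() < 1.0 or item.max() > 5.0:
        raise FormatError(f"item {item_name!r} outside the 1-5 Likert range")
    variables = _term_variables(predictors, table)
    for v in _continuous(variables, table):
        if table[v].std(ddof=1) == 0:
            raise DegenerateDataError(f"predictor {v!r} has zero variance")
    formula = f"{item_name} ~ " + " + ".join(predictors)
    model = smf.ols(formula, table)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        raise ConfigurationError(
            f"rank-deficient design for {item_name!r}: collinear terms among "
            f"{list(model.exog_names)}"
        )
    res = model.fit()
    cont = [c for c in _continuous([item_name] + variables, table)]
    res_std = smf.ols(formula, _zscore_frame(table, cont)).fit()
    coef = pd.DataFrame(
        {
            "term": res.params.index,
            "B": res.params.to_numpy(),
            "beta": res_std.params.to_numpy(),
            "SE": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "df": int(res.df_resid),
            "p": res.pvalues.to_numpy(),
            "p_adjusted": np.nan,
        }
    )
    if adjust:
        mask = coef.term != "Intercept"
        if mask.any():
            coef.loc[mask, "p_adjusted"] = bh_adjust(coef.loc[mask, "p"].to_numpy())
    return ModelFit(
        response_name=item_name,
        coefficients=coef.reset_index(drop=True),
        icc=None,
        marginal_r2=float(res.rsquared),
        conditional_r2=None,
        aic=float(res.aic),
        n_groups=None,
        n_obs=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# Multiple-testing correction


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_adjust_fits(fits: Sequence[ModelFit]) -> list[ModelFit]:
    """Apply BH across the non-intercept terms of a family of fits.

    Returns new ModelFit objects with ``p_adjusted`` filled jointly,
    which is how a set of per-item appraisal models forms one family.
    """
    masks = [f.coefficients.term != "Intercept" for f in fits]
    pooled = np.concatenate(
        [f.coefficients.loc[m, "p"].to_numpy() for f, m in zip(fits, masks)]
    )
    adjusted = bh_adjust(pooled)
    out: list[ModelFit] = []
    pos = 0
    for f, m in zip(fits, masks):
        k = int(m.sum())
        coef = f.coefficients.copy()
        coef.loc[m, "p_adjusted"] = adjusted[pos : pos + k]
        pos += k
        out.append(
            ModelFit(
                response_name=f.response_name,
                coefficients=coef,
                icc=f.icc,
                marginal_r2=f.marginal_r2,
                conditional_r2=f.conditional_r2,
                aic=f.aic,
                n_groups=f.n_groups,
                n_obs=f.n_obs,
                warnings=f.warnings,
            )
        )
    return out
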